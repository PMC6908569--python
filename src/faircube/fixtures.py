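"""Deterministic synthetic exemplar studies.

Generates wide-format matrices with the structure of a targeted
metabolite-profiling supplementary table: by default 61 compounds
measured across rose cultivar x flower-part conditions, with composed
column headers ``<cultivar> <part> — <statistic>``, two statistics per
condition (sample mean and standard error of the mean, n = 3 technical
assays of a single biomaterial per condition), and 8 of the 6 x 3 = 18
theoretical cultivar x part combinations observed (every cultivar at
sepals, plus every part for the reference cultivar 'Old Blush').

Concentrations follow a log-normal value model (metabolite abundances
are positive and right-skewed); SEM columns are generated as a planted
per-cell dispersion divided by sqrt(n), so the mean/SEM relationship is
internally consistent and checkable.

The matched term maps carry **synthetic** chemical identifiers: CHEBI-style
accession numbers and InChI strings minted deterministically from the
compound label.  They are stand-ins for real database records — real
enough in shape for the pipeline, but not real chemistry.  Anatomy and
taxon accessions use well-known terms where one exists.

Everything is seeded: identical parameters and seed give byte-identical
files, and the returned :class:`FixtureTruth` carries the expected cube,
design and maps so every downstream module can be verified without
re-deriving anything from the files.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .annotate import TermMap, normalize_label
from .core import (
    DataCube,
    Factor,
    FactorLevel,
    Measurement,
    MolecularEntity,
    OntologyTerm,
    QuantitationType,
    TreatmentCombination,
)
from .design import DesignModel, infer_design
from .ingest import HeaderSpec

__all__ = [
    "FixtureParams",
    "FixtureTruth",
    "StudyBundle",
    "FixtureError",
    "generate_study",
    "generate_pair",
    "generate_messy_variant",
    "CustomStudy",
    "generate_custom_study",
    "DEFAULT_CULTIVARS",
    "DEFAULT_PARTS",
]

DEFAULT_CULTIVARS = (
    "R. chinensis 'Old Blush'",
    "R. hybrida 'Damask Pearl'",
    "R. hybrida 'Crimson Arrow'",
    "R. hybrida 'Moonlight Veil'",
    "R. hybrida 'Garden Ember'",
    "R. hybrida 'Silver Thorn'",
)
DEFAULT_PARTS = ("sepal", "petal", "stamen")
_PART_PLURAL = {"sepal": "sepals", "petal": "petals", "stamen": "stamens"}

# Rose-scent volatile vocabulary used for entity labels; padded with
# numbered unidentified compounds when more entities are requested.
_COMPOUND_NAMES = [
    "geraniol",
    "beta-citronellol",
    "nerol",
    "citral",
    "eugenol",
    "methyl eugenol",
    "2-phenylethanol",
    "phenylethyl acetate",
    "geranyl acetate",
    "neryl acetate",
    "citronellyl acetate",
    "linalool",
    "alpha-terpineol",
    "beta-ionone",
    "dihydro-beta-ionone",
    "alpha-pinene",
    "beta-pinene",
    "limonene",
    "myrcene",
    "ocimene",
    "farnesol",
    "farnesal",
    "nerolidol",
    "germacrene D",
    "beta-caryophyllene",
    "alpha-humulene",
    "benzaldehyde",
    "benzyl alcohol",
    "benzyl acetate",
    "benzyl benzoate",
    "methyl benzoate",
    "elemicin",
    "3,5-dimethoxytoluene",
    "1,3,5-trimethoxybenzene",
    "orcinol dimethyl ether",
    "theaspirane",
    "rose oxide",
    "geranial",
    "neral",
    "citronellal",
    "hexanal",
    "hexanol",
    "cis-3-hexenol",
    "cis-3-hexenyl acetate",
    "nonanal",
    "decanal",
    "heptanal",
    "2-heptanone",
    "beta-damascenone",
    "beta-damascone",
    "dihydro-beta-damascone",
    "geranylacetone",
    "pentadecane",
    "heptadecane",
    "nonadecane",
    "heneicosane",
    "tricosane",
    "eicosane",
    "methyl geranate",
    "citronellyl formate",
    "geranyl formate",
]


class FixtureError(ValueError):
    """Inconsistent fixture parameters."""


@dataclass(frozen=True)
class FixtureParams:
    """Knobs of the generator; the defaults are the exemplar conditions."""

    n_entities: int = 61
    cultivars: tuple[str, ...] = DEFAULT_CULTIVARS
    parts: tuple[str, ...] = DEFAULT_PARTS
    #: observed layout: every cultivar at parts[0], plus the first
    #: (reference) cultivar at every part.  Override with an explicit
    #: tuple of (cultivar, part) pairs to change the layout.
    observed: tuple[tuple[str, str], ...] | None = None
    sample_size: int = 3
    replicate_semantics: str = "technical"
    unit: str = "ng g-1"
    missing_rate: float = 0.0
    n_unresolved: int = 0
    seed: int = 42
    study_id: str = "rose-exemplar"
    factor_names: tuple[str, str] = ("rose cultivar", "organism part")

    def observed_layout(self) -> tuple[tuple[str, str], ...]:
        if self.observed is not None:
            return self.observed
        ref = self.cultivars[0]
        layout = [(c, self.parts[0]) for c in self.cultivars]
        layout += [(ref, p) for p in self.parts[1:]]
        return tuple(layout)

    def validate(self) -> None:
        if not (0.0 <= self.missing_rate <= 1.0):
            raise FixtureError(f"missing_rate {self.missing_rate} outside [0, 1]")
        if not self.cultivars or not self.parts:
            raise FixtureError("factors need at least one level each")
        if self.n_entities < 1:
            raise FixtureError("need at least one entity")
        if self.n_unresolved > self.n_entities:
            raise FixtureError("cannot withhold more map entries than entities")
        for c, p in self.observed_layout():
            if c not in self.cultivars or p not in self.parts:
                raise FixtureError(f"observed pair ({c!r}, {p!r}) uses unknown levels")


@dataclass
class FixtureTruth:
    """Everything the generator planted, for downstream verification."""

    params: FixtureParams
    cube: DataCube  # annotated, in canonical order — built directly
    design: DesignModel
    maps: dict[str, TermMap]
    header_spec: HeaderSpec
    entity_curies: list[str]
    #: planted per-(entity, treatment) dispersion; SEM = dispersion/sqrt(n)
    dispersions: dict[tuple[str, tuple[str, ...]], float]
    overlap_regions: tuple[int, int, int] | None = None  # (shared, a-only, b-only)


@dataclass
class StudyBundle:
    """Paths of the generated files plus the truth object."""

    matrix_path: Path
    header_spec_path: Path
    term_map_paths: dict[str, Path]
    truth: FixtureTruth


def _entity_labels(n: int, offset: int = 0) -> list[str]:
    labels = []
    i = offset
    while len(labels) < n:
        if i < len(_COMPOUND_NAMES):
            labels.append(_COMPOUND_NAMES[i])
        else:
            labels.append(f"unidentified compound {i + 1:02d}")
        i += 1
    return labels


def _synthetic_curie(label: str) -> str:
    """Deterministic CHEBI-style accession minted from the label (synthetic)."""
    h = int(hashlib.sha1(normalize_label(label).encode()).hexdigest(), 16)
    return f"CHEBI:9{h % 10**5:05d}"


def _synthetic_inchi(label: str) -> str:
    h = hashlib.sha1(normalize_label(label).encode()).hexdigest()[:10].upper()
    return f"InChI=1S/SYN.{h}"


def _obo_iri(curie: str) -> str:
    return "http://purl.obolibrary.org/obo/" + curie.replace(":", "_")


def _chemical_map(labels: list[str], withhold: int) -> TermMap:
    """Chemical term map with synthetic accessions; the last ``withhold``
    labels are deliberately absent (planted unresolved entities)."""
    keep = labels[: len(labels) - withhold]
    entries = {
        lab: {
            "label": lab,
            "curie": _synthetic_curie(lab),
            "iri": _obo_iri(_synthetic_curie(lab)),
            "source": "CHEBI",
            "inchi": _synthetic_inchi(lab),
        }
        for lab in keep
    }
    return TermMap.from_dict(
        {"domain": "chemical", "ontology": "CHEBI", "version": "synthetic", "entries": entries}
    )


def _taxon_map(cultivars: tuple[str, ...]) -> TermMap:
    entries = {}
    for i, c in enumerate(cultivars):
        curie = "NCBITaxon:74649" if i == 0 else f"NCBITaxon:9{i:06d}"
        entries[c] = {
            "label": c,
            "curie": curie,
            "iri": _obo_iri(curie),
            "source": "NCBITaxon",
        }
    return TermMap.from_dict(
        {"domain": "taxon", "ontology": "NCBITaxon", "version": "synthetic", "entries": entries}
    )


_PO = {"sepal": "PO:0009031", "petal": "PO:0009032", "stamen": "PO:0009029"}


def _anatomy_map(parts: tuple[str, ...]) -> TermMap:
    entries = {}
    for i, p in enumerate(parts):
        curie = _PO.get(p, f"PO:8{i:06d}")
        entries[p] = {"label": p, "curie": curie, "iri": _obo_iri(curie), "source": "PO"}
    return TermMap.from_dict(
        {"domain": "anatomy", "ontology": "PO", "version": "synthetic", "entries": entries}
    )


def _statistic_map() -> TermMap:
    return TermMap.from_dict(
        {
            "domain": "statistic",
            "ontology": "STATO",
            "version": "synthetic",
            "entries": {
                "sample mean": {
                    "label": "sample mean",
                    "curie": "STATO:0000401",
                    "iri": _obo_iri("STATO:0000401"),
                    "source": "STATO",
                },
                "standard error of the mean": {
                    "label": "standard error of the mean",
                    "curie": "STATO:0000037",
                    "iri": _obo_iri("STATO:0000037"),
                    "source": "STATO",
                },
            },
            "synonyms": {
                "average": "sample mean",
                "mean": "sample mean",
                "standard error": "standard error of the mean",
                "sem": "standard error of the mean",
            },
        }
    )


def _header_spec(params: FixtureParams) -> HeaderSpec:
    parts_alt = "|".join(_PART_PLURAL.get(p, p + "s") for p in params.parts)
    cname, pname = params.factor_names
    return HeaderSpec.from_dict(
        {
            "rules": [
                {
                    "pattern": rf"^(?P<cultivar>.+?) (?P<part>{parts_alt}) - (?P<stat>.+)$",
                    "factors": {"cultivar": cname, "part": pname},
                    "qtype": "stat",
                }
            ],
            "synonyms": {_PART_PLURAL.get(p, p + "s"): p for p in params.parts},
            "default_qtype": None,
        }
    )


def _fmt(x: float) -> str:
    return repr(float(x))


def generate_study(
    params: FixtureParams, outdir: str | Path
) -> StudyBundle:
    """Write one synthetic study bundle and return it with its truth.

    Files written: ``matrix.csv`` (wide matrix, composed headers),
    ``header_spec.yaml`` and one term map per domain.  Identical
    ``params`` (including seed) give byte-identical files.
    """
    params.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(params.seed)

    labels = _entity_labels(params.n_entities)
    layout = params.observed_layout()
    cname, pname = params.factor_names

    # --- value model: log-normal location per entity + treatment effect ---
    loc = rng.normal(np.log(50.0), 1.0, size=params.n_entities)
    effects = {pair: rng.normal(0.0, 0.5) for pair in layout}
    means: dict[tuple[str, tuple[str, str]], float] = {}
    disps: dict[tuple[str, tuple[str, str]], float] = {}
    for ei, lab in enumerate(labels):
        for pair in layout:
            m = float(np.exp(loc[ei] + effects[pair] + rng.normal(0.0, 0.25)))
            cv = float(rng.uniform(0.05, 0.30))
            means[(lab, pair)] = round(m, 6)
            disps[(lab, pair)] = round(m * cv, 6)

    missing: set[tuple[str, tuple[str, str], str]] = set()
    if params.missing_rate > 0:
        for lab in labels:
            for pair in layout:
                for stat in ("average", "standard error"):
                    if rng.uniform() < params.missing_rate:
                        missing.add((lab, pair, stat))

    # --- wide matrix file -------------------------------------------------
    headers = ["compound"]
    for pair in layout:
        c, p = pair
        composed = f"{c} {_PART_PLURAL.get(p, p + 's')}"
        headers.append(f"{composed} - average")
        headers.append(f"{composed} - standard error")
    lines = [",".join(_csv_quote(h) for h in headers)]
    n = params.sample_size
    for lab in labels:
        row = [_csv_quote(lab)]
        for pair in layout:
            mval = "" if (lab, pair, "average") in missing else _fmt(means[(lab, pair)])
            sval = (
                ""
                if (lab, pair, "standard error") in missing
                else _fmt(float(disps[(lab, pair)]) / float(np.sqrt(n)))
            )
            row.extend([mval, sval])
        lines.append(",".join(row))
    matrix_path = outdir / "matrix.csv"
    matrix_path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="")

    # --- header spec + term maps -----------------------------------------
    spec = _header_spec(params)
    header_spec_path = outdir / "header_spec.yaml"
    header_spec_path.write_text(
        yaml.safe_dump(spec.to_dict(), sort_keys=True, allow_unicode=True),
        encoding="utf-8",
        newline="",
    )
    maps = {
        "chemical": _chemical_map(labels, params.n_unresolved),
        "taxon": _taxon_map(params.cultivars),
        "anatomy": _anatomy_map(params.parts),
        "statistic": _statistic_map(),
    }
    term_map_paths = {}
    for domain, tmap in maps.items():
        p = outdir / f"termmap_{domain}.yaml"
        p.write_text(
            yaml.safe_dump(tmap.to_dict(), sort_keys=True, allow_unicode=True),
            encoding="utf-8",
            newline="",
        )
        term_map_paths[domain] = p

    truth = _build_truth(params, labels, layout, means, disps, missing, maps, spec)
    return StudyBundle(matrix_path, header_spec_path, term_map_paths, truth)


def _csv_quote(s: str) -> str:
    if "," in s or '"' in s:
        return '"' + s.replace('"', '""') + '"'
    return s


def _build_truth(
    params: FixtureParams,
    labels: list[str],
    layout: tuple[tuple[str, str], ...],
    means: dict,
    disps: dict,
    missing: set,
    maps: dict[str, TermMap],
    spec: HeaderSpec,
) -> FixtureTruth:
    """Build the expected annotated cube directly (not via the ingest
    path), in the package's canonical ordering."""
    cname, pname = params.factor_names
    chem, taxon, anatomy, stat = (
        maps["chemical"],
        maps["taxon"],
        maps["anatomy"],
        maps["statistic"],
    )

    def term_of(tmap: TermMap, label: str) -> OntologyTerm | None:
        hits = tmap.entries.get(normalize_label(label))
        return hits[0].term if hits else None

    factors = [
        Factor(
            name=cname,
            levels=[
                FactorLevel(label=c, factor_name=cname, term=term_of(taxon, c))
                for c in sorted(params.cultivars)
            ],
        ),
        Factor(
            name=pname,
            levels=[
                FactorLevel(label=p, factor_name=pname, term=term_of(anatomy, p))
                for p in sorted(params.parts)
            ],
        ),
    ]
    level_lookup = {(f.name, lv.label): lv for f in factors for lv in f.levels}
    treatment_keys = sorted({(c, p) for c, p in layout})
    treatments = {
        key: TreatmentCombination(
            levels=(level_lookup[(cname, key[0])], level_lookup[(pname, key[1])]),
            status="observed",
        )
        for key in treatment_keys
    }
    qmean = QuantitationType(
        input_label="average",
        canonical_name="sample_mean",
        term=term_of(stat, "sample mean"),
    )
    qsem = QuantitationType(
        input_label="standard error",
        canonical_name="standard_error_of_mean",
        term=term_of(stat, "standard error of the mean"),
        requires_sample_size=True,
    )
    entities = []
    for lab in labels:
        hit = chem.entries.get(normalize_label(lab))
        entities.append(
            MolecularEntity(
                input_label=lab,
                normalized_label=normalize_label(lab),
                chebi_term=hit[0].term if hit else None,
                inchi=hit[0].inchi if hit else None,
                resolution="resolved" if hit else "unresolved",
            )
        )
    n = params.sample_size
    measurements = []
    for e in entities:
        for key in treatment_keys:
            pair = (key[0], key[1])
            for q, stat_name in ((qmean, "average"), (qsem, "standard error")):
                if (e.input_label, pair, stat_name) in missing:
                    val = None
                elif q is qmean:
                    val = means[(e.input_label, pair)]
                else:
                    val = float(disps[(e.input_label, pair)]) / float(np.sqrt(n))
                measurements.append(
                    Measurement(
                        entity=e,
                        treatment=treatments[key],
                        qtype=q,
                        value=val,
                        unit=params.unit,
                        sample_size=n,
                        replicate_semantics=params.replicate_semantics,
                    )
                )
    cube = DataCube(
        study_id=params.study_id,
        entities=entities,
        factors=factors,
        observed_treatments=[treatments[k] for k in treatment_keys],
        qtypes=[qmean, qsem],
        measurements=measurements,
        provenance=["synthetic exemplar study"],
    )
    design = infer_design(
        cube, replicate_semantics=params.replicate_semantics, sample_sizes=n
    )
    return FixtureTruth(
        params=params,
        cube=cube,
        design=design,
        maps=maps,
        header_spec=spec,
        entity_curies=[e.chebi_term.curie for e in entities if e.chebi_term],
        dispersions={(lab, key): disps[(lab, key)] for (lab, key) in disps},
    )


def generate_pair(
    params_a: FixtureParams,
    params_b: FixtureParams,
    n_shared: int,
    outdir: str | Path,
) -> tuple[StudyBundle, StudyBundle]:
    """Two studies with exactly ``n_shared`` entities in common.

    Shared entities carry identical labels (hence identical synthetic
    chemical identifiers) in both studies; the remainders are disjoint.
    Each bundle's truth records the planted region counts
    (shared, A-only, B-only).
    """
    if n_shared > min(params_a.n_entities, params_b.n_entities):
        raise FixtureError(
            f"n_shared={n_shared} exceeds a study size "
            f"({params_a.n_entities}, {params_b.n_entities})"
        )
    outdir = Path(outdir)
    labels_a = _entity_labels(params_a.n_entities)
    # B reuses the first n_shared labels of A, then draws fresh labels
    # starting past everything A used.
    extra = _entity_labels(params_b.n_entities - n_shared, offset=params_a.n_entities)
    if params_a.study_id == params_b.study_id:
        params_b = replace(params_b, study_id=params_b.study_id + "-b")
    bundle_a = generate_study(params_a, outdir / "study_a")
    bundle_b = _generate_with_labels(
        params_b, labels_a[:n_shared] + extra, outdir / "study_b"
    )
    regions = (
        n_shared,
        params_a.n_entities - n_shared,
        params_b.n_entities - n_shared,
    )
    bundle_a.truth.overlap_regions = regions
    bundle_b.truth.overlap_regions = regions
    return bundle_a, bundle_b


def _generate_with_labels(
    params: FixtureParams, labels: list[str], outdir: Path
) -> StudyBundle:
    # Same generator, but with an explicit label list: run generate_study
    # then patch labels in by regenerating with a label override.
    bundle = generate_study(replace(params, n_entities=len(labels)), outdir)
    # Rewrite matrix + chemical map + truth with the requested labels.
    old_labels = [e.input_label for e in bundle.truth.cube.entities]
    mapping = dict(zip(old_labels, labels))
    text = bundle.matrix_path.read_text(encoding="utf-8")
    lines = text.split("\n")
    out_lines = [lines[0]]
    for line in lines[1:]:
        if not line:
            out_lines.append(line)
            continue
        cells = _split_csv(line)
        cells[0] = mapping.get(cells[0], cells[0])
        out_lines.append(",".join(_csv_quote(c) for c in cells))
    bundle.matrix_path.write_text("\n".join(out_lines), encoding="utf-8", newline="")
    chem = _chemical_map(labels, params.n_unresolved)
    bundle.truth.maps["chemical"] = chem
    bundle.term_map_paths["chemical"].write_text(
        yaml.safe_dump(chem.to_dict(), sort_keys=True, allow_unicode=True),
        encoding="utf-8",
        newline="",
    )
    for e in bundle.truth.cube.entities:
        new = mapping[e.input_label]
        e.input_label = new
        e.normalized_label = normalize_label(new)
        hit = chem.entries.get(e.normalized_label)
        e.chebi_term = hit[0].term if hit else None
        e.inchi = hit[0].inchi if hit else None
        e.resolution = "resolved" if hit else "unresolved"
    bundle.truth.entity_curies = [
        e.chebi_term.curie for e in bundle.truth.cube.entities if e.chebi_term
    ]
    return bundle


@dataclass
class CustomStudy:
    """A generic k-factor study file for design-recovery testing."""

    matrix_path: Path
    header_spec: HeaderSpec
    factor_levels: dict[str, tuple[str, ...]]
    observed_keys: tuple[tuple[str, ...], ...]
    n_theoretical: int
    classification: str


def generate_custom_study(
    factor_levels: dict[str, tuple[str, ...]],
    outdir: str | Path,
    observed: tuple[tuple[str, ...], ...] | None = None,
    n_observed: int | None = None,
    n_entities: int = 5,
    seed: int = 0,
    study_id: str = "custom",
) -> CustomStudy:
    """Arbitrary crossed-factor study: headers are the level tuple joined
    with " | " plus the statistic as the last segment.

    ``observed`` defaults to the full cartesian product; pass an explicit
    subset, or ``n_observed`` to plant a fractional layout.  A planted
    fraction always covers every level of every factor at least once — a
    level that never appears in any column is unrecoverable from the
    matrix, so an uncovering fraction would not define the design it
    claims to.  Level labels must not contain '|'.
    """
    import itertools

    if not factor_levels or any(not lv for lv in factor_levels.values()):
        raise FixtureError("every factor needs at least one level")
    names = list(factor_levels)
    full = tuple(itertools.product(*factor_levels.values()))
    if observed is None and n_observed is not None:
        max_levels = max(len(v) for v in factor_levels.values())
        if not (max_levels <= n_observed <= len(full)):
            raise FixtureError(
                f"n_observed must lie in [{max_levels}, {len(full)}] to cover "
                "every level"
            )
        # diagonal first (covers all levels), then fill in product order
        diagonal = [
            tuple(v[i % len(v)] for v in factor_levels.values())
            for i in range(max_levels)
        ]
        chosen = list(dict.fromkeys(diagonal))
        for combo in full:
            if len(chosen) >= n_observed:
                break
            if combo not in chosen:
                chosen.append(combo)
        observed = tuple(sorted(chosen))
    observed = observed or full
    full_set = set(full)
    if any(o not in full_set for o in observed):
        raise FixtureError("observed combination outside the cartesian product")
    covered = {
        name: {combo[i] for combo in observed} for i, name in enumerate(names)
    }
    if any(covered[n] != set(factor_levels[n]) for n in names):
        raise FixtureError(
            "observed subset does not cover every factor level; the planted "
            "design would not be recoverable from the matrix"
        )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    labels = _entity_labels(n_entities)
    headers = ["compound"]
    for combo in observed:
        head = " | ".join(combo)
        headers.append(f"{head} | average")
        headers.append(f"{head} | standard error")
    lines = [",".join(_csv_quote(h) for h in headers)]
    for lab in labels:
        row = [_csv_quote(lab)]
        for _combo in observed:
            m = float(np.exp(rng.normal(np.log(10.0), 1.0)))
            row.extend([_fmt(round(m, 6)), _fmt(round(m * 0.1, 6))])
        lines.append(",".join(row))
    matrix_path = outdir / "matrix.csv"
    matrix_path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="")
    groups = " \\| ".join(rf"(?P<g{i}>[^|]+?)" for i in range(len(names)))
    spec = HeaderSpec.from_dict(
        {
            "rules": [
                {
                    "pattern": rf"^{groups} \| (?P<stat>[^|]+)$",
                    "factors": {f"g{i}": n for i, n in enumerate(names)},
                    "qtype": "stat",
                }
            ],
            "synonyms": {},
            "default_qtype": None,
        }
    )
    n_theoretical = len(full)
    if len(names) == 1:
        classification = "single_factor"
    elif len(observed) == n_theoretical:
        classification = "full_factorial"
    else:
        classification = "fractional_factorial"
    return CustomStudy(
        matrix_path=matrix_path,
        header_spec=spec,
        factor_levels={k: tuple(v) for k, v in factor_levels.items()},
        observed_keys=tuple(observed),
        n_theoretical=n_theoretical,
        classification=classification,
    )


PERTURBATIONS = ("header_case", "typographic_quotes", "missing_cells", "ragged_row", "non_numeric")


def generate_messy_variant(
    bundle: StudyBundle, perturbations: dict[str, int | bool], outdir: str | Path
) -> tuple[Path, dict]:
    """Write a perturbed copy of a bundle's matrix plus an expected-failure
    manifest.

    Supported perturbations: ``header_case`` (random-case headers, must
    still ingest cleanly after normalization... case changes are applied
    to the statistic token only, which the synonym table absorbs),
    ``typographic_quotes`` (ASCII quotes/dashes swapped for typographic
    ones), ``missing_cells`` (k cells replaced by the token 'nd'),
    ``non_numeric`` (k cells replaced by a non-numeric token) and
    ``ragged_row`` (one truncated data row).  The manifest states which
    ingest findings a conforming reader must produce.
    """
    unknown = set(perturbations) - set(PERTURBATIONS)
    if unknown:
        raise FixtureError(f"unknown perturbations: {sorted(unknown)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(bundle.truth.params.seed + 1)
    text = bundle.matrix_path.read_text(encoding="utf-8")
    lines = [ln for ln in text.split("\n") if ln != ""]
    manifest: dict[str, object] = {"findings": {}, "structural_error": False}

    if perturbations.get("typographic_quotes"):
        lines[0] = lines[0].replace("'", "’").replace(" - ", " — ")
    if perturbations.get("header_case"):
        lines[0] = lines[0].replace("average", "Average").replace(
            "standard error", "Standard Error"
        )

    data_cells = []  # (line index, cell index >= 1)
    for li in range(1, len(lines)):
        n_cells = lines[li].count(",") + 1
        for ci in range(1, n_cells):
            data_cells.append((li, ci))

    def replace_cells(k: int, token: str) -> int:
        idx = rng.choice(len(data_cells), size=k, replace=False)
        for i in idx:
            li, ci = data_cells[int(i)]
            cells = _split_csv(lines[li])
            cells[ci] = token
            lines[li] = ",".join(_csv_quote(c) for c in cells)
        return k

    k = int(perturbations.get("missing_cells") or 0)
    if k:
        manifest["findings"]["missing_cells"] = replace_cells(k, "nd")
    k = int(perturbations.get("non_numeric") or 0)
    if k:
        manifest["findings"]["BAD_VALUE"] = replace_cells(k, "oops")
    if perturbations.get("ragged_row"):
        li = 1 + int(rng.integers(0, len(lines) - 1))
        cells = _split_csv(lines[li])
        lines[li] = ",".join(_csv_quote(c) for c in cells[:-1])
        manifest["structural_error"] = True
        manifest["ragged_line"] = li + 1

    path = outdir / "matrix_messy.csv"
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="")
    return path, manifest


def _split_csv(line: str) -> list[str]:
    import csv
    import io

    return next(csv.reader(io.StringIO(line)))
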