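"""Domain model for omics results data cubes.

A results matrix (metabolites in rows, composed condition x statistic
headers in columns) is viewed as a three-dimensional data cube:

* molecular entities (the measured compounds),
* statistical treatments (combinations of factor levels, e.g.
  cultivar x organism part),
* quantitation types (the statistic each cell reports, e.g. sample mean
  or standard error of the mean).

Every other module of this package consumes and produces :class:`DataCube`
instances; :func:`check_cube` is the shared structural validator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "OntologyTerm",
    "MolecularEntity",
    "Factor",
    "FactorLevel",
    "TreatmentCombination",
    "QuantitationType",
    "Measurement",
    "DataCube",
    "Violation",
    "check_cube",
    "cube_shape",
    "cube_signature",
    "MISSING",
]

#: Sentinel used for a missing measurement value (kept as a record so the
#: matrix <-> cube mapping stays lossless).
MISSING = None

RESOLUTIONS = ("resolved", "ambiguous", "unresolved")
REPLICATE_SEMANTICS = ("technical", "biological", "unspecified")
CANONICAL_QTYPES = ("sample_mean", "standard_error_of_mean", "other")


@dataclass(frozen=True)
class OntologyTerm:
    """A term from a controlled vocabulary, e.g. CHEBI:17447.

    ``curie`` is a compact identifier ``PREFIX:ACCESSION``; ``iri`` is the
    resolvable form (OBO PURL by convention); ``source`` the ontology short
    name (CHEBI, NCBITaxon, PO, STATO, ...).
    """

    label: str
    curie: str
    iri: str = ""
    source: str = ""

    def curie_valid(self) -> bool:
        parts = self.curie.split(":")
        return len(parts) == 2 and bool(parts[0]) and bool(parts[1])


@dataclass
class MolecularEntity:
    """A measured compound: verbatim source label plus chemical identity."""

    input_label: str
    normalized_label: str
    chebi_term: OntologyTerm | None = None
    inchi: str | None = None
    resolution: str = "unresolved"


@dataclass
class FactorLevel:
    """One discrete value of a factor (e.g. 'sepal' of 'organism part').

    Level objects are shared: the same instance appears in its factor's
    level list and in every treatment tuple using it, so attaching an
    ontology term annotates all views at once.
    """

    label: str
    factor_name: str
    term: OntologyTerm | None = None


@dataclass
class Factor:
    """A categorical independent variable with its ordered level set."""

    name: str
    levels: list[FactorLevel] = field(default_factory=list)
    term: OntologyTerm | None = None
    kind: str = "categorical"

    def level_labels(self) -> list[str]:
        return [lv.label for lv in self.levels]


@dataclass
class TreatmentCombination:
    """One tuple of factor levels — a cell of the experimental design.

    ``levels`` holds exactly one :class:`FactorLevel` per declared factor,
    in factor declaration order.  ``status`` distinguishes combinations
    that are merely possible (theoretical) from those actually reported.
    """

    levels: tuple[FactorLevel, ...]
    status: str = "observed"

    @property
    def key(self) -> tuple[str, ...]:
        """Level labels in factor order — the identity of the treatment."""
        return tuple(lv.label for lv in self.levels)

    def label(self, sep: str = " / ") -> str:
        return sep.join(self.key)


@dataclass
class QuantitationType:
    """The statistic a matrix cell reports.

    ``canonical_name`` is one of ``sample_mean``,
    ``standard_error_of_mean`` or ``other``.  A sample mean must be
    reported with the size of the sample it was computed over, hence
    ``requires_sample_size`` is forced true for it.
    """

    input_label: str
    canonical_name: str = "other"
    term: OntologyTerm | None = None
    requires_sample_size: bool = False

    def __post_init__(self) -> None:
        if self.canonical_name == "sample_mean":
            self.requires_sample_size = True


@dataclass
class Measurement:
    """One cell of the cube: (entity, treatment, qtype) -> value."""

    entity: MolecularEntity
    treatment: TreatmentCombination
    qtype: QuantitationType
    value: float | None
    unit: str = ""
    sample_size: int | None = None
    replicate_semantics: str = "unspecified"

    @property
    def is_missing(self) -> bool:
        return self.value is MISSING or (
            isinstance(self.value, float) and math.isnan(self.value)
        )


@dataclass
class DataCube:
    """Molecular entities x observed treatments x quantitation types."""

    study_id: str
    entities: list[MolecularEntity] = field(default_factory=list)
    factors: list[Factor] = field(default_factory=list)
    observed_treatments: list[TreatmentCombination] = field(default_factory=list)
    qtypes: list[QuantitationType] = field(default_factory=list)
    measurements: list[Measurement] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    def entity_by_label(self, normalized_label: str) -> MolecularEntity | None:
        for e in self.entities:
            if e.normalized_label == normalized_label:
                return e
        return None

    def qtype_by_name(self, canonical_name: str) -> QuantitationType | None:
        for q in self.qtypes:
            if q.canonical_name == canonical_name:
                return q
        return None


@dataclass(frozen=True)
class Violation:
    """One structural problem found by :func:`check_cube`."""

    code: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.code}: {self.message}"


def check_cube(cube: DataCube) -> list[Violation]:
    """Validate every structural invariant of a cube.

    Pure and idempotent: the cube is never mutated and repeated calls
    return identical reports.  Violations are reported, never raised.
    """
    out: list[Violation] = []

    # -- entity invariants -------------------------------------------------
    seen_labels: set[str] = set()
    for e in cube.entities:
        if e.normalized_label in seen_labels:
            out.append(
                Violation(
                    "DUPLICATE_ENTITY",
                    f"normalized label {e.normalized_label!r} occurs more than once",
                )
            )
        seen_labels.add(e.normalized_label)
        if e.resolution not in RESOLUTIONS:
            out.append(
                Violation(
                    "BAD_RESOLUTION",
                    f"entity {e.input_label!r} has resolution {e.resolution!r}",
                )
            )
        if e.resolution == "resolved" and e.chebi_term is None:
            out.append(
                Violation(
                    "RESOLVED_WITHOUT_TERM",
                    f"entity {e.input_label!r} marked resolved but carries no term",
                )
            )
        if e.resolution == "unresolved" and (e.chebi_term or e.inchi):
            out.append(
                Violation(
                    "UNRESOLVED_WITH_IDENTITY",
                    f"entity {e.input_label!r} marked unresolved but carries identifiers",
                )
            )
        if e.chebi_term is not None and not e.chebi_term.curie_valid():
            out.append(
                Violation(
                    "BAD_CURIE",
                    f"entity {e.input_label!r} term curie {e.chebi_term.curie!r} "
                    "is not PREFIX:ACCESSION",
                )
            )

    # -- factor invariants -------------------------------------------------
    factor_names = [f.name for f in cube.factors]
    if len(set(factor_names)) != len(factor_names):
        out.append(Violation("DUPLICATE_FACTOR", "factor names are not unique"))
    for f in cube.factors:
        if not f.levels:
            out.append(Violation("EMPTY_FACTOR", f"factor {f.name!r} has no levels"))
        labels = f.level_labels()
        if len(set(labels)) != len(labels):
            out.append(
                Violation(
                    "DUPLICATE_LEVEL",
                    f"factor {f.name!r} has duplicate level labels",
                )
            )
        for lv in f.levels:
            if lv.factor_name != f.name:
                out.append(
                    Violation(
                        "LEVEL_FACTOR_MISMATCH",
                        f"level {lv.label!r} back-references {lv.factor_name!r}, "
                        f"not {f.name!r}",
                    )
                )

    # -- treatment invariants ----------------------------------------------
    treatment_keys: set[tuple[str, ...]] = set()
    for t in cube.observed_treatments:
        if len(t.levels) != len(cube.factors):
            out.append(
                Violation(
                    "TREATMENT_ARITY",
                    f"treatment {t.key} has {len(t.levels)} levels for "
                    f"{len(cube.factors)} factors",
                )
            )
            continue
        for lv, f in zip(t.levels, cube.factors):
            if lv.factor_name != f.name:
                out.append(
                    Violation(
                        "TREATMENT_FACTOR_ORDER",
                        f"treatment {t.key}: level {lv.label!r} is for "
                        f"{lv.factor_name!r}, expected {f.name!r}",
                    )
                )
            elif lv.label not in f.level_labels():
                out.append(
                    Violation(
                        "UNKNOWN_LEVEL",
                        f"treatment {t.key}: level {lv.label!r} not declared "
                        f"for factor {f.name!r}",
                    )
                )
        if t.key in treatment_keys:
            out.append(
                Violation("DUPLICATE_TREATMENT", f"treatment {t.key} repeated")
            )
        treatment_keys.add(t.key)

    # -- qtype invariants --------------------------------------------------
    for q in cube.qtypes:
        if q.canonical_name not in CANONICAL_QTYPES:
            out.append(
                Violation(
                    "BAD_QTYPE",
                    f"quantitation type {q.input_label!r} has canonical name "
                    f"{q.canonical_name!r}",
                )
            )
        if q.canonical_name == "sample_mean" and not q.requires_sample_size:
            out.append(
                Violation(
                    "MEAN_WITHOUT_N",
                    "sample_mean quantitation type must require a sample size",
                )
            )

    # -- measurement invariants --------------------------------------------
    entity_ids = {id(e) for e in cube.entities}
    qtype_ids = {id(q) for q in cube.qtypes}
    seen_cells: set[tuple[str, tuple[str, ...], str]] = set()
    for m in cube.measurements:
        if id(m.entity) not in entity_ids:
            out.append(
                Violation(
                    "DANGLING_ENTITY",
                    f"measurement references entity {m.entity.input_label!r} "
                    "not contained in the cube",
                )
            )
        if m.treatment.key not in treatment_keys:
            out.append(
                Violation(
                    "DANGLING_TREATMENT",
                    f"measurement references treatment {m.treatment.key} "
                    "not in observed_treatments",
                )
            )
        if id(m.qtype) not in qtype_ids:
            out.append(
                Violation(
                    "DANGLING_QTYPE",
                    f"measurement references quantitation type "
                    f"{m.qtype.input_label!r} not in the cube",
                )
            )
        cell = (m.entity.normalized_label, m.treatment.key, m.qtype.canonical_name)
        if cell in seen_cells:
            out.append(
                Violation("DUPLICATE_MEASUREMENT", f"cell {cell} occurs twice")
            )
        seen_cells.add(cell)
        if m.qtype.requires_sample_size and not m.is_missing and m.sample_size is None:
            out.append(
                Violation(
                    "MISSING_SAMPLE_SIZE",
                    f"cell {cell} reports a {m.qtype.canonical_name} without "
                    "a sample size",
                )
            )
        if m.sample_size is not None and m.sample_size < 1:
            out.append(
                Violation("BAD_SAMPLE_SIZE", f"cell {cell}: sample size must be >= 1")
            )
        if m.replicate_semantics not in REPLICATE_SEMANTICS:
            out.append(
                Violation(
                    "BAD_REPLICATE_SEMANTICS",
                    f"cell {cell}: {m.replicate_semantics!r}",
                )
            )

    # -- cardinality bound -------------------------------------------------
    bound = len(cube.entities) * len(cube.observed_treatments) * len(cube.qtypes)
    if len(cube.measurements) > bound:
        out.append(
            Violation(
                "CARDINALITY_EXCEEDED",
                f"{len(cube.measurements)} measurements exceed the "
                f"entities x treatments x qtypes bound of {bound}",
            )
        )

    return out


def cube_signature(cube: DataCube) -> dict:
    """A plain, fully comparable rendering of a cube in canonical order.

    Two cubes are 'equal up to canonical ordering' iff their signatures
    compare equal; used for serialization round-trip contracts.
    """

    def term_sig(t: OntologyTerm | None):
        return None if t is None else (t.label, t.curie, t.iri, t.source)

    return {
        "study_id": cube.study_id,
        "entities": [
            (e.input_label, e.normalized_label, term_sig(e.chebi_term), e.inchi, e.resolution)
            for e in cube.entities
        ],
        "factors": [
            (
                f.name,
                term_sig(f.term),
                tuple((lv.label, term_sig(lv.term)) for lv in f.levels),
            )
            for f in cube.factors
        ],
        "observed_treatments": sorted(t.key for t in cube.observed_treatments),
        "qtypes": sorted(
            (q.input_label, q.canonical_name, term_sig(q.term), q.requires_sample_size)
            for q in cube.qtypes
        ),
        "measurements": sorted(
            (
                m.entity.normalized_label,
                m.treatment.key,
                m.qtype.canonical_name,
                m.value,
                m.unit,
                m.sample_size,
                m.replicate_semantics,
            )
            for m in cube.measurements
        ),
    }


def cube_shape(cube: DataCube) -> tuple[int, int, int]:
    """Return (n_entities, n_observed_treatments, n_qtypes)."""
    return (
        len(cube.entities),
        len(cube.observed_treatments),
        len(cube.qtypes),
    )
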