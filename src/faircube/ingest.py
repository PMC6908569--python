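"""Reading wide-format matrices and unpacking composed column headers.

Supplementary omics tables compress three dimensions into two by composing
condition and statistic into the column header (e.g.
``R. chinensis 'Old Blush' sepals — average``).  A :class:`HeaderSpec` is a
declarative grammar — an ordered list of regular-expression rules whose
named capture groups are routed either to a factor or to the
quantitation-type slot — that decomposes every header and lets
:func:`unpack_headers` rebuild the full data cube in tidy form.

The grammar is configuration, not code: the same engine serves any matrix
whose headers follow a describable pattern.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .core import (
    MISSING,
    DataCube,
    Factor,
    FactorLevel,
    Measurement,
    MolecularEntity,
    QuantitationType,
    TreatmentCombination,
)

log = logging.getLogger(__name__)

__all__ = [
    "Dialect",
    "RawMatrix",
    "HeaderRule",
    "HeaderSpec",
    "IngestError",
    "StructuralError",
    "UnmatchedHeaderError",
    "AmbiguousHeaderError",
    "ValueParseError",
    "Finding",
    "read_matrix",
    "unpack_headers",
    "unpack_headers_lenient",
    "tidy_table",
    "DEFAULT_MISSING_TOKENS",
]

DEFAULT_MISSING_TOKENS = ("", "nd", "n.d.", "tr")

#: Built-in canonicalization of statistic labels; a HeaderSpec synonym
#: table may rewrite tokens before this lookup, and unknown labels fall
#: through to canonical name "other".
QTYPE_CANON = {
    "average": "sample_mean",
    "mean": "sample_mean",
    "sample mean": "sample_mean",
    "arithmetic mean": "sample_mean",
    "standard error": "standard_error_of_mean",
    "standard error of the mean": "standard_error_of_mean",
    "sem": "standard_error_of_mean",
    "se": "standard_error_of_mean",
}

_TYPOGRAPHIC = str.maketrans(
    {
        "‘": "'",
        "’": "'",
        "“": '"',
        "”": '"',
        "–": "-",
        "—": "-",
        "−": "-",
        " ": " ",
    }
)


def normalize_header(h: str) -> str:
    """Trim, collapse whitespace runs, map typographic quotes/dashes to ASCII."""
    return re.sub(r"\s+", " ", h.translate(_TYPOGRAPHIC)).strip()


class IngestError(Exception):
    """Base class for ingest failures."""


class StructuralError(IngestError):
    pass


class UnmatchedHeaderError(IngestError):
    pass


class AmbiguousHeaderError(IngestError):
    pass


class ValueParseError(IngestError):
    pass


@dataclass(frozen=True)
class Finding:
    """One problem collected in lenient mode."""

    code: str  # UNMATCHED_HEADER | AMBIGUOUS_HEADER | BAD_VALUE
    message: str
    row: str | None = None
    column: str | None = None


@dataclass(frozen=True)
class Dialect:
    """Delimited-text dialect: never guessed, always declared."""

    delimiter: str = ","
    decimal: str = "."
    row_label_col: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "Dialect":
        return cls(
            delimiter=d.get("delimiter", ","),
            decimal=d.get("decimal", "."),
            row_label_col=d.get("row_label_col", 0),
        )


@dataclass
class RawMatrix:
    """A verbatim wide matrix: strings only, no numeric coercion yet."""

    row_labels: list[str]
    column_headers: list[str]
    values: list[list[str]]  # |row_labels| x |column_headers|
    dialect: Dialect = field(default_factory=Dialect)


@dataclass(frozen=True)
class HeaderRule:
    """One grammar rule: a regex with named groups routed to slots.

    ``factors`` maps capture-group name -> factor name; ``qtype_group``
    names the group carrying the statistic label (optional when the spec
    declares a default quantitation type).
    """

    pattern: str
    factors: tuple[tuple[str, str], ...]  # (group, factor name), ordered
    qtype_group: str | None = None

    def compiled(self) -> re.Pattern:
        return re.compile(self.pattern)


@dataclass
class HeaderSpec:
    """Ordered header-grammar rules plus token synonyms.

    Rules are tried in order; exactly one rule must match a given header —
    zero matches is an unmatched-header error, more than one an ambiguity
    error.  ``synonyms`` rewrites captured tokens (e.g. ``sepals`` ->
    ``sepal``) to canonical level / statistic labels before use.
    """

    rules: list[HeaderRule]
    synonyms: dict[str, str] = field(default_factory=dict)
    default_qtype: str | None = None

    def factor_names(self) -> list[str]:
        """Factor declaration order: first appearance across rules."""
        seen: list[str] = []
        for r in self.rules:
            for _, fname in r.factors:
                if fname not in seen:
                    seen.append(fname)
        return seen

    def canonical_token(self, token: str) -> str:
        t = normalize_header(token)
        return self.synonyms.get(t, self.synonyms.get(t.lower(), t))

    @classmethod
    def from_dict(cls, d: dict) -> "HeaderSpec":
        rules = []
        for rd in d.get("rules", []):
            factors = tuple((g, f) for g, f in rd.get("factors", {}).items())
            rules.append(
                HeaderRule(
                    pattern=rd["pattern"],
                    factors=factors,
                    qtype_group=rd.get("qtype"),
                )
            )
        return cls(
            rules=rules,
            synonyms=dict(d.get("synonyms", {})),
            default_qtype=d.get("default_qtype"),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "HeaderSpec":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "rules": [
                {
                    "pattern": r.pattern,
                    "factors": dict(r.factors),
                    **({"qtype": r.qtype_group} if r.qtype_group else {}),
                }
                for r in self.rules
            ],
            "synonyms": dict(self.synonyms),
            "default_qtype": self.default_qtype,
        }


def read_matrix(path: str | Path, dialect: Dialect | None = None) -> RawMatrix:
    """Read a delimited wide matrix verbatim (one header row, one label column).

    Raises :class:`StructuralError` for ragged rows (naming the offending
    line) and :class:`AmbiguousHeaderError` for duplicate headers after
    whitespace normalization.
    """
    dialect = dialect or Dialect()
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=dialect.delimiter)
        rows = list(reader)
    if not rows:
        raise StructuralError(f"{path}: empty file")
    header = rows[0]
    width = len(header)
    lc = dialect.row_label_col
    if lc >= width:
        raise StructuralError(
            f"{path}: row-label column index {lc} out of range for width {width}"
        )
    column_headers = [h for i, h in enumerate(header) if i != lc]
    normed = [normalize_header(h) for h in column_headers]
    dupes = {h for h in normed if normed.count(h) > 1}
    if dupes:
        raise AmbiguousHeaderError(
            f"{path}: duplicate column headers after normalization: {sorted(dupes)}"
        )
    row_labels: list[str] = []
    values: list[list[str]] = []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise StructuralError(
                f"{path}: line {lineno} has {len(row)} fields, expected {width}"
            )
        row_labels.append(row[lc])
        values.append([v for i, v in enumerate(row) if i != lc])
    log.info(
        "read %s: %d rows x %d data columns", path.name, len(row_labels), width - 1
    )
    return RawMatrix(row_labels, column_headers, values, dialect)


def _match_header(header: str, spec: HeaderSpec) -> tuple[HeaderRule, re.Match]:
    h = normalize_header(header)
    hits = [(r, m) for r in spec.rules if (m := r.compiled().fullmatch(h))]
    if not hits:
        tried = [r.pattern for r in spec.rules]
        raise UnmatchedHeaderError(
            f"header {header!r} matched no rule; patterns tried: {tried}"
        )
    if len(hits) > 1:
        raise AmbiguousHeaderError(
            f"header {header!r} matched {len(hits)} rules: "
            f"{[r.pattern for r, _ in hits]}"
        )
    return hits[0]


def _parse_value(
    token: str, decimal: str, missing_tokens: tuple[str, ...]
) -> float | None:
    t = token.strip()
    if t.lower() in {m.lower() for m in missing_tokens}:
        return MISSING
    if decimal != ".":
        t = t.replace(decimal, ".")
    try:
        return float(t)
    except ValueError:
        raise ValueParseError(f"cannot parse {token!r} as a number") from None


def _qtype_sort_key(q: QuantitationType) -> tuple[int, str]:
    order = {"sample_mean": 0, "standard_error_of_mean": 1}
    return (order.get(q.canonical_name, 2), q.input_label)


def _unpack(
    m: RawMatrix,
    spec: HeaderSpec,
    *,
    study_id: str,
    unit: str,
    sample_size: int | None,
    replicate_semantics: str,
    missing_tokens: tuple[str, ...],
    collect: list[Finding] | None,
) -> DataCube:
    factor_order = spec.factor_names()
    if not factor_order:
        raise IngestError("header spec declares no factors")

    # First pass: decompose each column into (level labels per factor, qtype label)
    col_info: list[tuple[int, tuple[str, ...], str] | None] = []
    for ci, header in enumerate(m.column_headers):
        try:
            rule, match = _match_header(header, spec)
        except (UnmatchedHeaderError, AmbiguousHeaderError) as exc:
            if collect is None:
                log.warning("%s", exc)
                raise
            code = (
                "AMBIGUOUS_HEADER"
                if isinstance(exc, AmbiguousHeaderError)
                else "UNMATCHED_HEADER"
            )
            collect.append(Finding(code, str(exc), column=header))
            col_info.append(None)
            continue
        by_factor = {
            fname: spec.canonical_token(match.group(g)) for g, fname in rule.factors
        }
        if rule.qtype_group is not None:
            qlabel = spec.canonical_token(match.group(rule.qtype_group))
        elif spec.default_qtype is not None:
            qlabel = spec.default_qtype
        else:
            raise IngestError(
                f"header {header!r}: rule has no statistic group and the spec "
                "declares no default quantitation type"
            )
        levels = tuple(by_factor.get(f, "") for f in factor_order)
        if "" in levels:
            missing_f = factor_order[levels.index("")]
            raise IngestError(
                f"header {header!r}: matched rule assigns no level for factor "
                f"{missing_f!r}"
            )
        col_info.append((ci, levels, qlabel))

    # Canonical orderings (independent of input column order):
    level_sets: dict[str, set[str]] = {f: set() for f in factor_order}
    qlabels: set[str] = set()
    treatment_keys: set[tuple[str, ...]] = set()
    for info in col_info:
        if info is None:
            continue
        _, levels, qlabel = info
        for f, lv in zip(factor_order, levels):
            level_sets[f].add(lv)
        qlabels.add(qlabel)
        treatment_keys.add(levels)

    factors = [
        Factor(
            name=f,
            levels=[FactorLevel(label=lv, factor_name=f) for lv in sorted(level_sets[f])],
        )
        for f in factor_order
    ]
    level_lookup = {
        (f.name, lv.label): lv for f in factors for lv in f.levels
    }
    treatments = {
        key: TreatmentCombination(
            levels=tuple(level_lookup[(f, lab)] for f, lab in zip(factor_order, key)),
            status="observed",
        )
        for key in sorted(treatment_keys)
    }
    # Package policy: SEM measurements also carry the sample size they
    # derive from, so both summary statistics require one.
    qtypes = {
        q: QuantitationType(
            input_label=q,
            canonical_name=(canon := QTYPE_CANON.get(q.lower(), "other")),
            requires_sample_size=canon
            in ("sample_mean", "standard_error_of_mean"),
        )
        for q in sorted(qlabels)
    }
    qtype_list = sorted(qtypes.values(), key=_qtype_sort_key)

    entities = [
        MolecularEntity(input_label=lab, normalized_label=lab.strip())
        for lab in m.row_labels
    ]

    measurements: list[Measurement] = []
    for ri, entity in enumerate(entities):
        for info in col_info:
            if info is None:
                continue
            ci, levels, qlabel = info
            token = m.values[ri][ci]
            try:
                value = _parse_value(token, m.dialect.decimal, missing_tokens)
            except ValueParseError as exc:
                if collect is None:
                    raise ValueParseError(
                        f"row {entity.input_label!r}, column "
                        f"{m.column_headers[ci]!r}: {exc}"
                    ) from None
                collect.append(
                    Finding(
                        "BAD_VALUE",
                        str(exc),
                        row=entity.input_label,
                        column=m.column_headers[ci],
                    )
                )
                value = MISSING
            qt = qtypes[qlabel]
            measurements.append(
                Measurement(
                    entity=entity,
                    treatment=treatments[levels],
                    qtype=qt,
                    value=value,
                    unit=unit,
                    sample_size=(
                        sample_size
                        if (qt.requires_sample_size or sample_size is not None)
                        else None
                    ),
                    replicate_semantics=replicate_semantics,
                )
            )

    # Deterministic measurement order: entity row order, treatment, qtype.
    tindex = {k: i for i, k in enumerate(sorted(treatment_keys))}
    qindex = {q.input_label: i for i, q in enumerate(qtype_list)}
    eindex = {id(e): i for i, e in enumerate(entities)}
    measurements.sort(
        key=lambda mm: (
            eindex[id(mm.entity)],
            tindex[mm.treatment.key],
            qindex[mm.qtype.input_label],
        )
    )

    return DataCube(
        study_id=study_id,
        entities=entities,
        factors=factors,
        observed_treatments=[treatments[k] for k in sorted(treatment_keys)],
        qtypes=qtype_list,
        measurements=measurements,
        provenance=[f"unpacked {len(m.column_headers)} composed column headers"],
    )


def unpack_headers(
    m: RawMatrix,
    spec: HeaderSpec,
    *,
    study_id: str = "study",
    unit: str = "",
    sample_size: int | None = None,
    replicate_semantics: str = "unspecified",
    missing_tokens: tuple[str, ...] = DEFAULT_MISSING_TOKENS,
) -> DataCube:
    """Decompose composed headers and build the data cube (strict mode).

    Each column yields one factor level per factor named by its matched
    rule plus one quantitation type; row labels become molecular entities;
    the observed treatments are the distinct level tuples seen across
    columns.  Any unmatched/ambiguous header or unparseable non-missing
    cell raises.  Sample size is configuration, not matrix content: it is
    attached to every measurement whose quantitation type requires one.
    """
    return _unpack(
        m,
        spec,
        study_id=study_id,
        unit=unit,
        sample_size=sample_size,
        replicate_semantics=replicate_semantics,
        missing_tokens=missing_tokens,
        collect=None,
    )


def unpack_headers_lenient(
    m: RawMatrix,
    spec: HeaderSpec,
    **kwargs,
) -> tuple[DataCube, list[Finding]]:
    """Like :func:`unpack_headers` but collects failures instead of raising.

    Unmatched/ambiguous columns are dropped from the cube; unparseable
    cells become missing values.  Returns the (possibly partial) cube and
    the full findings report.
    """
    findings: list[Finding] = []
    cube = _unpack(
        m,
        spec,
        study_id=kwargs.pop("study_id", "study"),
        unit=kwargs.pop("unit", ""),
        sample_size=kwargs.pop("sample_size", None),
        replicate_semantics=kwargs.pop("replicate_semantics", "unspecified"),
        missing_tokens=kwargs.pop("missing_tokens", DEFAULT_MISSING_TOKENS),
        collect=findings,
    )
    return cube, findings


def tidy_table(cube: DataCube, identifiers: bool = False) -> pd.DataFrame:
    """Flatten a cube to one record per measurement (long/tidy form).

    Columns: entity label, one column per factor, quantitation type,
    value, unit, sample size — plus CURIE/InChI identifier columns when
    ``identifiers`` is set.  Ordering is deterministic (entity, treatment
    tuple, qtype) and the flattening is lossless.
    """
    factor_names = [f.name for f in cube.factors]
    records = []
    for mm in cube.measurements:
        rec: dict[str, object] = {"entity": mm.entity.input_label}
        if identifiers:
            rec["entity_curie"] = (
                mm.entity.chebi_term.curie if mm.entity.chebi_term else MISSING
            )
            rec["entity_inchi"] = mm.entity.inchi
        for fname, lv in zip(factor_names, mm.treatment.key):
            rec[fname] = lv
        rec["quantitation_type"] = mm.qtype.canonical_name
        rec["value"] = mm.value
        rec["unit"] = mm.unit
        rec["sample_size"] = mm.sample_size
        records.append(rec)
    cols = ["entity"]
    if identifiers:
        cols += ["entity_curie", "entity_inchi"]
    cols += factor_names + ["quantitation_type", "value", "unit", "sample_size"]
    df = pd.DataFrame(records, columns=cols)
    return df
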