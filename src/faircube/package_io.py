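"""Tabular Data Package serialization of an annotated cube.

The package is a directory holding ``datapackage.json`` — a descriptor
with a table schema per resource (field names, value types, per-field
term IRIs, missing-value tokens) — next to the delimited data itself, so
the data can be validated against its own description.  Field naming
follows the Frictionless Table Schema conventions.  Writing is
deterministic: the same cube always produces byte-identical files (fixed
field order, shortest round-trip number formatting, LF line endings).

Also provides a minimal ISA-Tab *investigation* stub that references the
emitted packages, suitable as the starting point of a metabolomics
repository submission.  Study/assay sample-level tables are out of scope.
"""

from __future__ import annotations

import csv
import io
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

from .core import (
    MISSING,
    DataCube,
    Factor,
    FactorLevel,
    Measurement,
    MolecularEntity,
    OntologyTerm,
    QuantitationType,
    TreatmentCombination,
)
__all__ = [
    "PackageError",
    "PackageValidationError",
    "Finding",
    "write_package",
    "read_package",
    "validate_package",
    "write_isatab_stub",
    "DESCRIPTOR_NAME",
]

DESCRIPTOR_NAME = "datapackage.json"
_MISSING_TOKEN = ""  # written for missing cells; declared in the descriptor
_IRI_RE = re.compile(r"^https?://\S+$")


class PackageError(Exception):
    pass


class PackageValidationError(PackageError):
    pass


@dataclass(frozen=True)
class Finding:
    code: str
    message: str
    resource: str | None = None
    row: int | None = None  # 1-based data row
    column: str | None = None


def _fmt(value: float | None) -> str:
    """Shortest round-trip decimal rendering; '.' decimal mark."""
    if value is MISSING:
        return _MISSING_TOKEN
    if isinstance(value, float) and value.is_integer():
        return repr(value)
    return repr(float(value))


def _schema_fields(cube: DataCube) -> list[dict]:
    obo = "http://purl.obolibrary.org/obo/"
    fields: list[dict] = [
        {
            "name": "entity",
            "type": "string",
            "title": "molecular entity label",
            "rdfType": obo + "CHEBI_23367",
        },
        {
            "name": "entity_curie",
            "type": "string",
            "title": "chemical identifier (CURIE)",
        },
        {
            "name": "entity_inchi",
            "type": "string",
            "title": "InChI string",
        },
    ]
    for f in cube.factors:
        fd = {"name": f.name, "type": "string", "title": f"factor: {f.name}"}
        if f.term is not None and f.term.iri:
            fd["rdfType"] = f.term.iri
        fields.append(fd)
    qiris = [q.term.iri for q in cube.qtypes if q.term is not None and q.term.iri]
    qfield = {"name": "quantitation_type", "type": "string"}
    fields.append(qfield)
    fields.append({"name": "value", "type": "number", "rdfType": obo + "PATO_0000033"})
    fields.append({"name": "unit", "type": "string", "rdfType": obo + "UO_0000000"})
    fields.append(
        {"name": "sample_size", "type": "integer", "rdfType": obo + "STATO_0000047"}
    )
    if qiris:
        # column-level semantics: the qtype column draws from these classes
        qfield["constraints"] = {"enum": sorted(q.canonical_name for q in cube.qtypes)}
    return fields


def _cube_metadata(cube: DataCube) -> dict:
    """Side-car metadata needed to reconstruct the cube losslessly."""

    def term_dict(t: OntologyTerm | None) -> dict | None:
        if t is None:
            return None
        return {"label": t.label, "curie": t.curie, "iri": t.iri, "source": t.source}

    return {
        "studyId": cube.study_id,
        "factors": [
            {
                "name": f.name,
                "term": term_dict(f.term),
                "levels": [
                    {"label": lv.label, "term": term_dict(lv.term)} for lv in f.levels
                ],
            }
            for f in cube.factors
        ],
        "quantitationTypes": [
            {
                "inputLabel": q.input_label,
                "canonicalName": q.canonical_name,
                "term": term_dict(q.term),
                "requiresSampleSize": q.requires_sample_size,
            }
            for q in cube.qtypes
        ],
        "entities": [
            {
                "inputLabel": e.input_label,
                "normalizedLabel": e.normalized_label,
                "term": term_dict(e.chebi_term),
                "inchi": e.inchi,
                "resolution": e.resolution,
            }
            for e in cube.entities
        ],
        "replicateSemantics": (
            cube.measurements[0].replicate_semantics if cube.measurements else "unspecified"
        ),
        "provenance": list(cube.provenance),
    }


def write_package(
    cube: DataCube,
    directory: str | Path,
    name: str | None = None,
    title: str | None = None,
) -> dict:
    """Write the cube as a data package; returns the descriptor dict.

    Layout: one denormalized ``measurements`` resource (factor columns
    repeated per row) for maximum portability.  Missing cells are written
    as the declared missing token, so the row count always equals the
    measurement count.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    factor_names = [f.name for f in cube.factors]
    cols = (
        ["entity", "entity_curie", "entity_inchi"]
        + factor_names
        + ["quantitation_type", "value", "unit", "sample_size"]
    )
    data_path = "measurements.csv"
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(cols)
    for m in cube.measurements:
        writer.writerow(
            [
                m.entity.input_label,
                m.entity.chebi_term.curie if m.entity.chebi_term else _MISSING_TOKEN,
                m.entity.inchi or _MISSING_TOKEN,
                *m.treatment.key,
                m.qtype.canonical_name,
                _fmt(m.value),
                m.unit,
                str(m.sample_size) if m.sample_size is not None else _MISSING_TOKEN,
            ]
        )
    (directory / data_path).write_text(buf.getvalue(), encoding="utf-8", newline="")

    descriptor = {
        "name": name or re.sub(r"[^a-z0-9-]+", "-", cube.study_id.lower()).strip("-"),
        "title": title or f"FAIRified results matrix for study {cube.study_id}",
        "profile": "tabular-data-package",
        "licenses": [
            {
                "name": "CC-BY-4.0",
                "path": "https://creativecommons.org/licenses/by/4.0/",
                "title": "Creative Commons Attribution 4.0",
            }
        ],
        "resources": [
            {
                "name": "measurements",
                "path": data_path,
                "profile": "tabular-data-resource",
                "format": "csv",
                "mediatype": "text/csv",
                "dialect": {"delimiter": ",", "lineTerminator": "\n"},
                "schema": {
                    "fields": _schema_fields(cube),
                    "missingValues": [_MISSING_TOKEN],
                },
            }
        ],
        "faircube": _cube_metadata(cube),
    }
    (directory / DESCRIPTOR_NAME).write_text(
        json.dumps(descriptor, indent=2, ensure_ascii=False, sort_keys=False) + "\n",
        encoding="utf-8",
        newline="",
    )
    return descriptor


def _term_from_dict(d: dict | None) -> OntologyTerm | None:
    if d is None:
        return None
    return OntologyTerm(
        label=d.get("label", ""),
        curie=d.get("curie", ""),
        iri=d.get("iri", ""),
        source=d.get("source", ""),
    )


def read_package(directory: str | Path) -> DataCube:
    """Reconstruct a :class:`~faircube.core.DataCube` from a package.

    ``read_package(write_package(c)) == c`` up to canonical ordering.
    Schema/data mismatches raise :class:`PackageValidationError` naming
    the offending cell.
    """
    directory = Path(directory)
    desc_path = directory / DESCRIPTOR_NAME
    if not desc_path.exists():
        raise PackageError(f"no {DESCRIPTOR_NAME} in {directory}")
    descriptor = json.loads(desc_path.read_text(encoding="utf-8"))
    meta = descriptor.get("faircube")
    if meta is None:
        raise PackageError("descriptor lacks the cube metadata block")
    resource = next(
        (r for r in descriptor.get("resources", []) if r.get("name") == "measurements"),
        None,
    )
    if resource is None:
        raise PackageError("descriptor names no 'measurements' resource")
    missing_tokens = set(resource["schema"].get("missingValues", [""]))
    fields = [f["name"] for f in resource["schema"]["fields"]]

    factors: list[Factor] = []
    level_lookup: dict[tuple[str, str], FactorLevel] = {}
    for fd in meta["factors"]:
        levels = [
            FactorLevel(
                label=ld["label"], factor_name=fd["name"], term=_term_from_dict(ld["term"])
            )
            for ld in fd["levels"]
        ]
        f = Factor(name=fd["name"], levels=levels, term=_term_from_dict(fd["term"]))
        factors.append(f)
        for lv in levels:
            level_lookup[(f.name, lv.label)] = lv

    qtypes = [
        QuantitationType(
            input_label=qd["inputLabel"],
            canonical_name=qd["canonicalName"],
            term=_term_from_dict(qd["term"]),
            requires_sample_size=qd["requiresSampleSize"],
        )
        for qd in meta["quantitationTypes"]
    ]
    qtype_by_name = {q.canonical_name: q for q in qtypes}

    entities = [
        MolecularEntity(
            input_label=ed["inputLabel"],
            normalized_label=ed["normalizedLabel"],
            chebi_term=_term_from_dict(ed["term"]),
            inchi=ed["inchi"],
            resolution=ed["resolution"],
        )
        for ed in meta["entities"]
    ]
    entity_by_label = {e.input_label: e for e in entities}

    factor_names = [f.name for f in factors]
    replicate = meta.get("replicateSemantics", "unspecified")

    data_path = directory / resource["path"]
    measurements: list[Measurement] = []
    treatments: dict[tuple[str, ...], TreatmentCombination] = {}
    with open(data_path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header != fields:
            raise PackageValidationError(
                f"data header {header} does not match schema fields {fields}"
            )
        for rownum, row in enumerate(reader, start=1):
            if len(row) != len(fields):
                raise PackageValidationError(
                    f"row {rownum}: {len(row)} cells for {len(fields)} fields"
                )
            rec = dict(zip(fields, row))
            key = tuple(rec[f] for f in factor_names)
            if key not in treatments:
                treatments[key] = TreatmentCombination(
                    levels=tuple(level_lookup[(f, lab)] for f, lab in zip(factor_names, key)),
                    status="observed",
                )
            raw_value = rec["value"]
            if raw_value in missing_tokens:
                value = MISSING
            else:
                try:
                    value = float(raw_value)
                except ValueError:
                    raise PackageValidationError(
                        f"row {rownum}, column 'value': {raw_value!r} is not a number"
                    ) from None
            raw_n = rec.get("sample_size", "")
            if raw_n in missing_tokens:
                n = None
            else:
                try:
                    n = int(raw_n)
                except ValueError:
                    raise PackageValidationError(
                        f"row {rownum}, column 'sample_size': {raw_n!r} is not an integer"
                    ) from None
            measurements.append(
                Measurement(
                    entity=entity_by_label[rec["entity"]],
                    treatment=treatments[key],
                    qtype=qtype_by_name[rec["quantitation_type"]],
                    value=value,
                    unit=rec["unit"],
                    sample_size=n,
                    replicate_semantics=replicate,
                )
            )

    return DataCube(
        study_id=meta["studyId"],
        entities=entities,
        factors=factors,
        observed_treatments=[treatments[k] for k in sorted(treatments)],
        qtypes=qtypes,
        measurements=measurements,
        provenance=list(meta.get("provenance", [])),
    )


def validate_package(directory: str | Path) -> list[Finding]:
    """Report every violation in a package directory; never raises.

    Checks: descriptor presence and JSON well-formedness, resource file
    presence, schema/data arity, declared value types, missing-token
    discipline and term-IRI syntax.
    """
    directory = Path(directory)
    findings: list[Finding] = []
    desc_path = directory / DESCRIPTOR_NAME
    if not desc_path.exists():
        return [Finding("NO_DESCRIPTOR", f"missing {DESCRIPTOR_NAME} in {directory}")]
    try:
        descriptor = json.loads(desc_path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        return [Finding("BAD_JSON", f"descriptor is not valid JSON: {exc}")]
    resources = descriptor.get("resources", [])
    if not resources:
        findings.append(Finding("NO_RESOURCES", "descriptor lists no resources"))
    for r in resources:
        rname = r.get("name", "?")
        schema = r.get("schema", {})
        fields = schema.get("fields", [])
        if not fields:
            findings.append(
                Finding("NO_FIELDS", "resource schema declares no fields", resource=rname)
            )
            continue
        for fd in fields:
            iri = fd.get("rdfType")
            if iri is not None and not _IRI_RE.match(iri):
                findings.append(
                    Finding(
                        "BAD_TERM_IRI",
                        f"field {fd.get('name')!r}: rdfType {iri!r} is not an "
                        "http(s) IRI",
                        resource=rname,
                        column=fd.get("name"),
                    )
                )
        missing_tokens = set(schema.get("missingValues", [""]))
        path = r.get("path")
        if path is None or not (directory / path).exists():
            findings.append(
                Finding("NO_DATA_FILE", f"data file {path!r} missing", resource=rname)
            )
            continue
        names = [fd["name"] for fd in fields]
        types = {fd["name"]: fd.get("type", "string") for fd in fields}
        with open(directory / path, newline="", encoding="utf-8") as fh:
            reader = csv.reader(fh)
            try:
                header = next(reader)
            except StopIteration:
                findings.append(
                    Finding("EMPTY_FILE", "data file has no header row", resource=rname)
                )
                continue
            if header != names:
                findings.append(
                    Finding(
                        "HEADER_MISMATCH",
                        f"data header {header} != schema fields {names}",
                        resource=rname,
                    )
                )
                continue
            for rownum, row in enumerate(reader, start=1):
                if len(row) != len(names):
                    findings.append(
                        Finding(
                            "ARITY",
                            f"{len(row)} cells for {len(names)} fields",
                            resource=rname,
                            row=rownum,
                        )
                    )
                    continue
                for cname, cell in zip(names, row):
                    if cell in missing_tokens:
                        continue
                    t = types[cname]
                    if t == "number":
                        try:
                            float(cell)
                        except ValueError:
                            findings.append(
                                Finding(
                                    "TYPE",
                                    f"{cell!r} is not a number",
                                    resource=rname,
                                    row=rownum,
                                    column=cname,
                                )
                            )
                    elif t == "integer":
                        try:
                            int(cell)
                        except ValueError:
                            findings.append(
                                Finding(
                                    "TYPE",
                                    f"{cell!r} is not an integer",
                                    resource=rname,
                                    row=rownum,
                                    column=cname,
                                )
                            )
    return findings


def write_isatab_stub(
    directory: str | Path,
    study_id: str,
    title: str,
    package_paths: list[str],
    description: str = "",
    ontology_sources: list[tuple[str, str]] | None = None,
) -> Path:
    """Write a minimal ISA-Tab investigation file referencing the packages.

    Sections: ontology sources, investigation, study and study assays;
    each data package appears as one ``Comment[Data Package]`` reference
    column in the assay section.  Deterministic: identical inputs produce
    a byte-identical file.  Raises :class:`PackageError` when mandatory
    metadata (study id or title) is absent.
    """
    missing = [n for n, v in (("study_id", study_id), ("title", title)) if not v]
    if missing:
        raise PackageError(f"missing mandatory metadata: {missing}")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sources = ontology_sources or [
        ("CHEBI", "http://purl.obolibrary.org/obo/chebi.owl"),
        ("NCBITaxon", "http://purl.obolibrary.org/obo/ncbitaxon.owl"),
        ("PO", "http://purl.obolibrary.org/obo/po.owl"),
        ("STATO", "http://purl.obolibrary.org/obo/stato.owl"),
    ]

    def row(label: str, *cells: str) -> str:
        return "\t".join([label, *cells])

    lines = [
        "ONTOLOGY SOURCE REFERENCE",
        row("Term Source Name", *(n for n, _ in sources)),
        row("Term Source File", *(f for _, f in sources)),
        row("Term Source Version", *("" for _ in sources)),
        row("Term Source Description", *(n for n, _ in sources)),
        "INVESTIGATION",
        row("Investigation Identifier", study_id),
        row("Investigation Title", title),
        row("Investigation Description", description),
        "STUDY",
        row("Study Identifier", study_id),
        row("Study Title", title),
        row("Study Description", description),
        "STUDY ASSAYS",
        row("Study Assay Measurement Type", *("metabolite profiling" for _ in package_paths)),
        row("Study Assay Technology Type", *("mass spectrometry" for _ in package_paths)),
        row("Study Assay File Name", *package_paths),
        row("Comment[Data Package]", *package_paths),
    ]
    path = directory / f"i_{study_id}.txt"
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="")
    return path
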