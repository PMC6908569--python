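"""Linked-Data rendering of an annotated cube and its design model.

The triple model (normative for this package):

* one **study** node, linked to one **design** node typed by the design
  classification;
* one node per **independent variable**, carrying its declaration
  position and linked to its **factor level** nodes (each with a level
  position, so the graph preserves ordering exactly);
* one node per **observed treatment**, linked to its member levels;
* one **measurement datum** node per cube measurement, linking exactly
  one entity node, one treatment node and one quantitation-type node,
  plus a numeric value literal, a unit literal and — for quantitation
  types that require it — a sample-size literal;
* entity nodes carry CURIE-derived term IRIs and InChI literals when the
  chemistry is resolved.

All instance IRIs are minted deterministically from the study identifier
plus a stable content hash, so rebuilding the same inputs yields an
IRI-identical statement set (no blank nodes for data).  Which OBO classes
stand behind the model concepts is configuration — a
:class:`VocabularyMap` — never hard-coded logic.

The two canonical data-level queries ("retrieve the study predictor
variables and their levels", "what sample size was the mean computed
over?") are answered over the graph with SPARQL; their answers are
contractually equal to what the in-memory design model reports.
"""

from __future__ import annotations

import hashlib
import logging
import re
from decimal import Decimal
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from rdflib import RDF, RDFS, XSD, Graph, Literal, Namespace, URIRef

from .core import DataCube, OntologyTerm
from .design import DesignModel

log = logging.getLogger(__name__)

__all__ = [
    "VocabularyMap",
    "VocabularyError",
    "DEFAULT_VOCABULARY",
    "build_graph",
    "serialize_graph",
    "query_predictors",
    "query_sample_size",
    "export_plot_table",
    "PREDICTORS_SPARQL",
    "SAMPLE_SIZE_SPARQL",
]

#: Internal predicate namespace — part of this package's triple model.
FC = Namespace("https://w3id.org/faircube/vocab#")

OBO = "http://purl.obolibrary.org/obo/"

#: Default concept->term configuration.  Accessions are illustrative
#: defaults drawn from OBO Foundry ontologies and are expected to be
#: overridden from a vocabulary-map file when exact releases matter.
DEFAULT_VOCABULARY = {
    "study": {"curie": "OBI:0000066", "label": "investigation"},
    "study_design": {"curie": "OBI:0500000", "label": "study design"},
    "single_factor_design": {"curie": "STATO:0000091", "label": "single factor design"},
    "full_factorial_design": {"curie": "STATO:0000270", "label": "full factorial design"},
    "fractional_factorial_design": {
        "curie": "STATO:0000298",
        "label": "fractional factorial design",
    },
    "independent_variable": {"curie": "STATO:0000087", "label": "independent variable"},
    "factor_level": {"curie": "STATO:0000277", "label": "factor level"},
    "treatment": {"curie": "OBI:0000299", "label": "treatment"},
    "measurement_datum": {"curie": "IAO:0000109", "label": "measurement datum"},
    "sample_mean": {"curie": "STATO:0000401", "label": "sample mean"},
    "standard_error_of_mean": {
        "curie": "STATO:0000037",
        "label": "standard error of the mean",
    },
    "other_statistic": {"curie": "STATO:0000039", "label": "statistic"},
    "sample_size": {"curie": "STATO:0000047", "label": "sample size"},
    "molecular_entity": {"curie": "CHEBI:23367", "label": "molecular entity"},
    "organism_part": {"curie": "PO:0025131", "label": "plant anatomical entity"},
    "taxon": {"curie": "NCBITaxon:1", "label": "taxon"},
    "concentration_value": {"curie": "PATO:0000033", "label": "concentration"},
    "unit": {"curie": "UO:0000000", "label": "unit"},
}


class VocabularyError(Exception):
    """A concept needed by the graph builder has no vocabulary entry."""


def _obo_iri(curie: str) -> str:
    return OBO + curie.replace(":", "_")


@dataclass
class VocabularyMap:
    """Concept-name -> ontology-term configuration for the graph builder."""

    concepts: dict[str, OntologyTerm] = field(default_factory=dict)
    base_iri: str = "https://w3id.org/faircube/id/"

    @classmethod
    def default(cls) -> "VocabularyMap":
        return cls.from_dict({"concepts": DEFAULT_VOCABULARY})

    @classmethod
    def from_dict(cls, d: dict) -> "VocabularyMap":
        concepts = {}
        for name, v in (d.get("concepts") or {}).items():
            curie = v["curie"]
            concepts[name] = OntologyTerm(
                label=v.get("label", name),
                curie=curie,
                iri=v.get("iri", _obo_iri(curie)),
                source=curie.split(":", 1)[0],
            )
        return cls(
            concepts=concepts,
            base_iri=d.get("base_iri", "https://w3id.org/faircube/id/"),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "VocabularyMap":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def require(self, concept: str) -> URIRef:
        if concept not in self.concepts:
            raise VocabularyError(
                f"vocabulary map has no entry for concept {concept!r}"
            )
        return URIRef(self.concepts[concept].iri)


def _slug(text: str) -> str:
    return re.sub(r"[^a-z0-9]+", "-", text.lower()).strip("-") or "x"


def _mint(base: str, study_id: str, kind: str, *identity: str) -> URIRef:
    h = hashlib.sha1("".join(identity).encode("utf-8")).hexdigest()[:12]
    head = _slug(identity[0]) if identity else "n"
    return URIRef(f"{base}{_slug(study_id)}/{kind}/{head}-{h}")


def build_graph(
    cube: DataCube, design: DesignModel, vocab: VocabularyMap | None = None
) -> Graph:
    """Emit the RDF graph for an annotated cube and its design model."""
    vocab = vocab or VocabularyMap.default()
    g = Graph()
    g.bind("fc", FC)
    base = vocab.base_iri
    sid = cube.study_id

    study = _mint(base, sid, "study", sid)
    g.add((study, RDF.type, vocab.require("study")))
    g.add((study, RDFS.label, Literal(sid)))

    design_node = _mint(base, sid, "design", sid, design.classification)
    g.add((design_node, RDF.type, vocab.require("study_design")))
    g.add((design_node, RDF.type, vocab.require(f"{design.classification}_design")))
    g.add((design_node, RDFS.label, Literal(f"{sid} {design.classification} design")))
    g.add((study, FC.hasDesign, design_node))
    g.add(
        (design_node, FC.nTheoreticalTreatments, Literal(design.n_theoretical, datatype=XSD.integer))
    )
    g.add(
        (design_node, FC.nObservedTreatments, Literal(design.n_observed, datatype=XSD.integer))
    )

    level_nodes: dict[tuple[str, str], URIRef] = {}
    for fi, f in enumerate(design.factors):
        var = _mint(base, sid, "variable", f.name)
        g.add((var, RDF.type, vocab.require("independent_variable")))
        g.add((var, RDFS.label, Literal(f.name)))
        g.add((var, FC.position, Literal(fi, datatype=XSD.integer)))
        g.add((design_node, FC.hasIndependentVariable, var))
        if f.term is not None and f.term.iri:
            g.add((var, FC.denotes, URIRef(f.term.iri)))
        for li, lv in enumerate(f.levels):
            node = _mint(base, sid, "level", f.name, lv.label)
            level_nodes[(f.name, lv.label)] = node
            g.add((node, RDF.type, vocab.require("factor_level")))
            g.add((node, RDFS.label, Literal(lv.label)))
            g.add((node, FC.position, Literal(li, datatype=XSD.integer)))
            g.add((var, FC.hasLevel, node))
            if lv.term is not None and lv.term.iri:
                g.add((node, FC.denotes, URIRef(lv.term.iri)))

    treatment_nodes: dict[tuple[str, ...], URIRef] = {}
    for t in design.observed_treatments:
        node = _mint(base, sid, "treatment", *t.key)
        treatment_nodes[t.key] = node
        g.add((node, RDF.type, vocab.require("treatment")))
        g.add((node, RDFS.label, Literal(t.label())))
        g.add((study, FC.hasTreatment, node))
        for lv in t.levels:
            g.add((node, FC.hasMemberLevel, level_nodes[(lv.factor_name, lv.label)]))

    entity_nodes: dict[str, URIRef] = {}
    for e in cube.entities:
        node = _mint(base, sid, "entity", e.normalized_label)
        entity_nodes[e.normalized_label] = node
        g.add((node, RDF.type, vocab.require("molecular_entity")))
        g.add((node, RDFS.label, Literal(e.input_label)))
        if e.chebi_term is not None and e.chebi_term.iri:
            g.add((node, FC.denotes, URIRef(e.chebi_term.iri)))
        if e.inchi:
            g.add((node, FC.inchi, Literal(e.inchi)))

    qtype_nodes: dict[str, URIRef] = {}
    for q in cube.qtypes:
        node = _mint(base, sid, "qtype", q.canonical_name)
        qtype_nodes[q.canonical_name] = node
        concept = (
            q.canonical_name
            if q.canonical_name in ("sample_mean", "standard_error_of_mean")
            else "other_statistic"
        )
        g.add((node, RDF.type, vocab.require(concept)))
        g.add((node, RDFS.label, Literal(q.canonical_name)))

    for m in cube.measurements:
        node = _mint(
            base,
            sid,
            "datum",
            m.entity.normalized_label,
            *m.treatment.key,
            m.qtype.canonical_name,
        )
        g.add((node, RDF.type, vocab.require("measurement_datum")))
        g.add((node, FC.isAbout, entity_nodes[m.entity.normalized_label]))
        g.add((node, FC.computedOver, treatment_nodes[m.treatment.key]))
        g.add((node, FC.hasQuantitationType, qtype_nodes[m.qtype.canonical_name]))
        if not m.is_missing:
            # xsd:decimal keeps the full lexical form across turtle
            # round trips (doubles get truncated by the serializer)
            g.add((node, FC.hasValue, Literal(Decimal(repr(float(m.value))))))
        if m.unit:
            g.add((node, FC.hasUnit, Literal(m.unit)))
        if m.sample_size is not None and m.qtype.requires_sample_size:
            g.add(
                (node, FC.hasSampleSize, Literal(m.sample_size, datatype=XSD.integer))
            )
    return g


def serialize_graph(g: Graph, fmt: str, path: str | Path) -> Path:
    """Serialize to Turtle or N-Triples.

    N-Triples output is canonically sorted line-by-line, so two
    serializations of equal graphs are byte-identical.
    """
    path = Path(path)
    if fmt == "turtle":
        path.write_text(g.serialize(format="turtle"), encoding="utf-8", newline="")
    elif fmt == "ntriples":
        lines = sorted(f"{s.n3()} {p.n3()} {o.n3()} ." for s, p, o in g)
        path.write_text(
            "\n".join(lines) + ("\n" if lines else ""), encoding="utf-8", newline=""
        )
    else:
        raise ValueError(f"unknown serialization format {fmt!r}")
    return path


PREDICTORS_SPARQL = """
PREFIX fc: <https://w3id.org/faircube/vocab#>
PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>
SELECT ?varLabel ?varPos ?levelLabel ?levelPos WHERE {
  ?design fc:hasIndependentVariable ?var .
  ?var rdfs:label ?varLabel ; fc:position ?varPos ; fc:hasLevel ?level .
  ?level rdfs:label ?levelLabel ; fc:position ?levelPos .
}
ORDER BY ?varPos ?levelPos
"""

SAMPLE_SIZE_SPARQL = """
PREFIX fc: <https://w3id.org/faircube/vocab#>
PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>
SELECT DISTINCT ?n WHERE {
  ?datum fc:computedOver ?treatment ;
         fc:hasQuantitationType ?qtype ;
         fc:hasSampleSize ?n .
  ?treatment rdfs:label ?tLabel .
  ?qtype rdfs:label ?qLabel .
  FILTER (?tLabel = ?targetT && ?qLabel = ?targetQ)
}
"""


def query_predictors(g: Graph) -> list[tuple[str, list[str]]]:
    """Answer: which independent variables does the study have, with which
    levels?  Returns ``[(variable name, ordered level labels), ...]`` in
    declaration order; empty (with a warning) if the graph has no design.
    """
    rows = list(g.query(PREDICTORS_SPARQL))
    if not rows:
        log.warning("graph contains no design/independent-variable nodes")
        return []
    out: dict[str, list[str]] = {}
    for var_label, _vp, level_label, _lp in rows:
        out.setdefault(str(var_label), []).append(str(level_label))
    return list(out.items())


def query_sample_size(
    g: Graph,
    treatment: str | tuple[str, ...],
    qtype: str = "sample_mean",
) -> int | None:
    """Answer: what sample size was this statistic computed over?

    ``treatment`` is either the treatment label (levels joined with
    " / ") or the level tuple itself; ``qtype`` is the canonical
    quantitation-type name.  Returns the integer or None (with a warning
    when the selector matches nothing).
    """
    t_label = treatment if isinstance(treatment, str) else " / ".join(treatment)
    rows = list(
        g.query(
            SAMPLE_SIZE_SPARQL,
            initBindings={"targetT": Literal(t_label), "targetQ": Literal(qtype)},
        )
    )
    if not rows:
        log.warning(
            "no sample size recorded for treatment %r, qtype %r", t_label, qtype
        )
        return None
    ns = sorted(int(r[0]) for r in rows)
    if len(ns) > 1:
        log.warning("mixed sample sizes %s for %r; returning smallest", ns, t_label)
    return ns[0]


_PLOT_SPARQL = """
PREFIX fc: <https://w3id.org/faircube/vocab#>
PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>
SELECT ?entityLabel ?tLabel ?qLabel ?value WHERE {
  ?datum fc:isAbout ?entity ;
         fc:computedOver ?treatment ;
         fc:hasQuantitationType ?qtype ;
         fc:hasValue ?value .
  ?entity rdfs:label ?entityLabel .
  ?treatment rdfs:label ?tLabel .
  ?qtype rdfs:label ?qLabel .
}
"""


def export_plot_table(
    g: Graph, treatments: list[str] | None = None
) -> pd.DataFrame:
    """Join mean and SEM per (entity, treatment) into a plot-ready table.

    ``treatments`` optionally restricts to the given treatment labels
    (levels joined with " / "); None selects all.  Columns: entity, one
    column per factor (split from the treatment label), mean, sem.  One
    record per (entity, treatment) with a non-missing mean.
    """
    factor_names = [name for name, _levels in query_predictors(g)]
    cells: dict[tuple[str, str], dict[str, float]] = {}
    for entity_label, t_label, q_label, value in g.query(_PLOT_SPARQL):
        t = str(t_label)
        if treatments is not None and t not in treatments:
            continue
        cells.setdefault((str(entity_label), t), {})[str(q_label)] = float(value)
    records = []
    for (entity, t), stats in sorted(cells.items()):
        if "sample_mean" not in stats:
            continue
        rec: dict[str, object] = {"entity": entity}
        parts = t.split(" / ")
        for fname, part in zip(factor_names, parts):
            rec[fname] = part
        rec["mean"] = stats["sample_mean"]
        rec["sem"] = stats.get("standard_error_of_mean")
        records.append(rec)
    cols = ["entity", *factor_names, "mean", "sem"]
    return pd.DataFrame(records, columns=cols)
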