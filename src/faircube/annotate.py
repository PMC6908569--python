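"""Offline ontology annotation of cube labels.

Free-text labels (compound names, cultivar names, anatomy parts,
statistic names) are mapped to ontology terms through local term-map
files — dictionaries keyed by normalized label, one per domain
(chemical / taxon / anatomy / statistic) — so no network access is ever
needed.  Resolution is exact-match only: fuzzy matching silently
reintroduces the imprecision the mapping exists to remove, so near-misses
are at most *reported*, never auto-assigned.

A resolver is anything honouring the :func:`resolve_label` contract;
a live ontology-service client can be plugged in by implementing it.
"""

from __future__ import annotations

import logging
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .core import DataCube, OntologyTerm

log = logging.getLogger(__name__)

__all__ = [
    "DOMAINS",
    "TermEntry",
    "TermMap",
    "TermMapError",
    "AnnotationError",
    "AnnotationReport",
    "normalize_label",
    "resolve_label",
    "annotate_cube",
]

DOMAINS = ("chemical", "taxon", "anatomy", "statistic")

# Greek transliteration used by chemical nomenclature (closed, fixed table).
_GREEK = {
    "α": "alpha",
    "β": "beta",
    "γ": "gamma",
    "δ": "delta",
    "ε": "epsilon",
    "ζ": "zeta",
    "ω": "omega",
}

_ASCII_MAP = str.maketrans(
    {"‘": "'", "’": "'", "“": '"', "”": '"', "–": "-", "—": "-", "−": "-"}
)


def normalize_label(label: str) -> str:
    """Canonicalize a free-text label: case-fold, trim, collapse
    whitespace, map typographic quotes/dashes to ASCII, transliterate
    Greek letters (β -> beta).  Deterministic and idempotent.
    """
    s = unicodedata.normalize("NFC", label).translate(_ASCII_MAP)
    s = "".join(_GREEK.get(ch, ch) for ch in s)
    s = re.sub(r"\s+", " ", s).strip().casefold()
    return s


class TermMapError(Exception):
    """Raised when a term-map file is malformed or internally ambiguous."""


class AnnotationError(Exception):
    """Raised in strict mode when factor->domain routing is incomplete."""


@dataclass(frozen=True)
class TermEntry:
    term: OntologyTerm
    inchi: str | None = None


@dataclass
class TermMap:
    """label -> term dictionary for one domain, with an alias table.

    ``entries`` maps a normalized label to one or more candidate entries
    (more than one = inherently ambiguous label); ``synonyms`` maps an
    alias to a normalized label.  An alias pointing at two different
    labels is an ambiguity reported at load time.
    """

    domain: str
    entries: dict[str, list[TermEntry]] = field(default_factory=dict)
    synonyms: dict[str, str] = field(default_factory=dict)
    ontology: str = ""
    version: str = ""

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise TermMapError(f"unknown domain {self.domain!r}; expected {DOMAINS}")

    @classmethod
    def from_dict(cls, d: dict) -> "TermMap":
        entries: dict[str, list[TermEntry]] = {}
        for label, val in (d.get("entries") or {}).items():
            key = normalize_label(label)
            vals = val if isinstance(val, list) else [val]
            entries[key] = [
                TermEntry(
                    term=OntologyTerm(
                        label=v.get("label", label),
                        curie=v["curie"],
                        iri=v.get("iri", ""),
                        source=v.get("source", d.get("ontology", "")),
                    ),
                    inchi=v.get("inchi"),
                )
                for v in vals
            ]
        synonyms: dict[str, str] = {}
        raw_syn = d.get("synonyms") or {}
        pairs = (
            [(s["alias"], s["target"]) for s in raw_syn]
            if isinstance(raw_syn, list)
            else list(raw_syn.items())
        )
        for alias, target in pairs:
            a, t = normalize_label(alias), normalize_label(target)
            if a in synonyms and synonyms[a] != t:
                raise TermMapError(
                    f"domain {d.get('domain')!r}: alias {alias!r} maps to both "
                    f"{synonyms[a]!r} and {t!r}"
                )
            synonyms[a] = t
        return cls(
            domain=d["domain"],
            entries=entries,
            synonyms=synonyms,
            ontology=d.get("ontology", ""),
            version=d.get("version", ""),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "TermMap":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        def entry_dict(e: TermEntry) -> dict:
            d = {
                "label": e.term.label,
                "curie": e.term.curie,
                "iri": e.term.iri,
                "source": e.term.source,
            }
            if e.inchi:
                d["inchi"] = e.inchi
            return d

        return {
            "domain": self.domain,
            "ontology": self.ontology,
            "version": self.version,
            "entries": {
                k: (entry_dict(v[0]) if len(v) == 1 else [entry_dict(e) for e in v])
                for k, v in self.entries.items()
            },
            "synonyms": dict(self.synonyms),
        }


def _lookup(label: str, tmap: TermMap) -> list[TermEntry]:
    key = normalize_label(label)
    if key in tmap.entries:
        return tmap.entries[key]
    if key in tmap.synonyms:
        return tmap.entries.get(tmap.synonyms[key], [])
    return []


def resolve_label(label: str, tmap: TermMap) -> tuple[OntologyTerm | None, str]:
    """Resolve one label: exact match on the normalized form first, then
    the synonym table.  Returns ``(term, status)`` with status one of
    resolved / ambiguous / unresolved; absence is a status, not an error.
    Pure function of (normalized label, map).
    """
    hits = _lookup(label, tmap)
    if not hits:
        return None, "unresolved"
    if len(hits) > 1:
        return None, "ambiguous"
    return hits[0].term, "resolved"


@dataclass
class AnnotationReport:
    """Three-way partition of the distinct labels submitted per domain."""

    resolved: dict[str, list[str]] = field(default_factory=dict)
    ambiguous: dict[str, list[tuple[str, list[str]]]] = field(default_factory=dict)
    unresolved: dict[str, list[str]] = field(default_factory=dict)

    def counts(self, domain: str) -> tuple[int, int, int]:
        return (
            len(self.resolved.get(domain, [])),
            len(self.ambiguous.get(domain, [])),
            len(self.unresolved.get(domain, [])),
        )

    @property
    def n_unresolved(self) -> int:
        return sum(len(v) for v in self.unresolved.values())

    @property
    def n_ambiguous(self) -> int:
        return sum(len(v) for v in self.ambiguous.values())

    def _record(self, domain: str, label: str, tmap: TermMap) -> None:
        hits = _lookup(label, tmap)
        if not hits:
            self.unresolved.setdefault(domain, []).append(label)
        elif len(hits) > 1:
            self.ambiguous.setdefault(domain, []).append(
                (label, [e.term.curie for e in hits])
            )
        else:
            self.resolved.setdefault(domain, []).append(label)

    def summary(self) -> dict:
        return {
            d: {
                "resolved": len(self.resolved.get(d, [])),
                "ambiguous": len(self.ambiguous.get(d, [])),
                "unresolved": len(self.unresolved.get(d, [])),
            }
            for d in DOMAINS
            if any(
                d in part
                for part in (self.resolved, self.ambiguous, self.unresolved)
            )
        }


def annotate_cube(
    cube: DataCube,
    maps: dict[str, TermMap],
    factor_domains: dict[str, str] | None = None,
    strict: bool = False,
) -> tuple[DataCube, AnnotationReport]:
    """Attach ontology terms across the cube; idempotent.

    ``maps`` is keyed by domain (at most one map each).  The chemical map
    annotates molecular entities (term + InChI), the statistic map
    annotates quantitation types, and taxon/anatomy maps annotate factor
    levels via the explicit ``factor_domains`` routing (factor name ->
    domain) — nothing in a header says which ontology applies, so the
    routing is configuration.  Original labels are always preserved and
    values / shapes / ordering are never touched.
    """
    factor_domains = factor_domains or {}
    report = AnnotationReport()

    chem = maps.get("chemical")
    if chem is not None:
        for e in cube.entities:
            e.normalized_label = normalize_label(e.input_label)
            hits = _lookup(e.input_label, chem)
            report._record("chemical", e.input_label, chem)
            if len(hits) == 1:
                e.chebi_term = hits[0].term
                e.inchi = hits[0].inchi
                e.resolution = "resolved"
            elif len(hits) > 1:
                e.chebi_term, e.inchi, e.resolution = None, None, "ambiguous"
            else:
                e.chebi_term, e.inchi, e.resolution = None, None, "unresolved"

    for f in cube.factors:
        domain = factor_domains.get(f.name)
        if domain is None:
            msg = f"no domain routing configured for factor {f.name!r}"
            if strict and any(m.domain in ("taxon", "anatomy") for m in maps.values()):
                raise AnnotationError(msg)
            log.warning("%s", msg)
            continue
        tmap = maps.get(domain)
        if tmap is None:
            msg = f"factor {f.name!r} routed to domain {domain!r} but no map loaded"
            if strict:
                raise AnnotationError(msg)
            log.warning("%s", msg)
            continue
        for lv in f.levels:
            term, _status = resolve_label(lv.label, tmap)
            report._record(domain, lv.label, tmap)
            lv.term = term

    stat = maps.get("statistic")
    if stat is not None:
        for q in cube.qtypes:
            term, _status = resolve_label(q.input_label, stat)
            report._record("statistic", q.input_label, stat)
            q.term = term

    return cube, report
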