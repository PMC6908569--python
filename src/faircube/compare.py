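"""Cross-study metabolite overlap between two FAIRified cubes.

Entities are joined on the most reliable identifier available per
entity — CURIE first, then InChI, then the normalized label — with the
key type recorded so mixed-confidence joins stay auditable.  The output
is the set algebra needed for Venn / UpSet views: per-study sets, the
intersection, per-study exclusives, a membership matrix and disjoint
region counts (the UpSet convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .core import DataCube

__all__ = ["KEY_POLICY", "entity_keys", "StudyComparison", "compare_studies", "upset_counts"]

#: Default key fallback order (most to least reliable).
KEY_POLICY = ("curie", "inchi", "label")


def entity_keys(
    cube: DataCube, policy: tuple[str, ...] = KEY_POLICY
) -> dict[str, str]:
    """One join key per entity, with the key type used.

    Returns ``{key: key_type}``; key type is the first member of
    ``policy`` available for the entity ('label' keys are the
    low-confidence fallback).
    """
    out: dict[str, str] = {}
    for e in cube.entities:
        for kind in policy:
            if kind == "curie" and e.chebi_term is not None:
                out[e.chebi_term.curie] = "curie"
                break
            if kind == "inchi" and e.inchi:
                out[e.inchi] = "inchi"
                break
            if kind == "label":
                out[e.normalized_label] = "label"
                break
    return out


@dataclass
class StudyComparison:
    """Identifier-keyed membership sets and region counts for two studies."""

    study_a: str
    study_b: str
    keys_a: dict[str, str]
    keys_b: dict[str, str]
    key_policy: tuple[str, ...] = KEY_POLICY

    sets: dict[str, set[str]] = field(init=False)
    intersection: set[str] = field(init=False)
    exclusives: dict[str, set[str]] = field(init=False)
    region_counts: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        a, b = set(self.keys_a), set(self.keys_b)
        self.sets = {self.study_a: a, self.study_b: b}
        self.intersection = a & b
        self.exclusives = {self.study_a: a - b, self.study_b: b - a}
        self.region_counts = {
            f"{self.study_a} only": len(a - b),
            f"{self.study_b} only": len(b - a),
            f"{self.study_a} ∩ {self.study_b}": len(a & b),
        }

    @property
    def union_size(self) -> int:
        return len(self.sets[self.study_a] | self.sets[self.study_b])

    def membership_matrix(self) -> pd.DataFrame:
        """Entity-key x study boolean grid, sorted by key."""
        a, b = self.sets[self.study_a], self.sets[self.study_b]
        keys = sorted(a | b)
        return pd.DataFrame(
            {
                "key": keys,
                "key_type": [
                    self.keys_a.get(k, self.keys_b.get(k)) for k in keys
                ],
                self.study_a: [k in a for k in keys],
                self.study_b: [k in b for k in keys],
            }
        )


def compare_studies(
    a: DataCube, b: DataCube, policy: tuple[str, ...] = KEY_POLICY
) -> StudyComparison:
    """Compare the molecular-entity content of two cubes.

    Symmetric up to a study-label swap; satisfies inclusion–exclusion
    (|A ∪ B| = |A| + |B| − |A ∩ B|) by construction of the key sets.
    """
    name_a = a.study_id if a.study_id != b.study_id else f"{a.study_id}-a"
    name_b = b.study_id if a.study_id != b.study_id else f"{b.study_id}-b"
    return StudyComparison(
        study_a=name_a,
        study_b=name_b,
        keys_a=entity_keys(a, policy),
        keys_b=entity_keys(b, policy),
        key_policy=policy,
    )


def upset_counts(c: StudyComparison) -> pd.DataFrame:
    """Disjoint region counts, plot-ready for an UpSet/Venn rendering.

    Regions are exclusive (UpSet convention, not cumulative), sorted
    descending by count with lexicographic label tie-break.  Counts sum
    to |A ∪ B|.
    """
    rows = sorted(
        c.region_counts.items(), key=lambda kv: (-kv[1], kv[0])
    )
    return pd.DataFrame(rows, columns=["region", "count"])
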