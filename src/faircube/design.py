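"""Experimental-design inference from a data cube.

The theoretical treatment space is the cartesian product of the factor
level sets; the observed treatments are the subset actually reported.
Comparing the two classifies the design:

* ``single_factor`` — exactly one factor;
* ``full_factorial`` — two or more factors, every combination observed;
* ``fractional_factorial`` — two or more factors, a strict non-empty
  subset observed (e.g. 8 of the 6 x 3 = 18 cultivar x organism-part
  combinations).

Only crossed categorical factors are modelled; blocking, nesting and
covariates are out of scope and rejected.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

from .core import DataCube, Factor, TreatmentCombination

__all__ = [
    "DesignError",
    "DesignModel",
    "cartesian_treatments",
    "infer_design",
    "design_report",
    "TECHNICAL_REPLICATE_CAVEAT",
]

TECHNICAL_REPLICATE_CAVEAT = (
    "sample size reflects technical replication: the standard error "
    "estimates measurement variability, not biological variability"
)


class DesignError(Exception):
    """Raised for designs the model cannot represent."""


@dataclass
class DesignModel:
    """Inferred design: factors, treatment spaces, classification, sizes."""

    factors: list[Factor]
    theoretical_treatments: list[TreatmentCombination]
    observed_treatments: list[TreatmentCombination]
    classification: str
    group_sizes: dict[tuple[str, ...], int | None] = field(default_factory=dict)
    replicate_semantics: str = "unspecified"

    @property
    def n_theoretical(self) -> int:
        return len(self.theoretical_treatments)

    @property
    def n_observed(self) -> int:
        return len(self.observed_treatments)


def cartesian_treatments(factors: list[Factor]) -> list[TreatmentCombination]:
    """All level tuples, in lexicographic (factor order, level order) order.

    The count equals the product of the level-set sizes.
    """
    if not factors:
        raise DesignError("no factors: nothing to cross")
    for f in factors:
        if not f.levels:
            raise DesignError(f"factor {f.name!r} has no levels")
    return [
        TreatmentCombination(levels=combo, status="theoretical")
        for combo in itertools.product(*(f.levels for f in factors))
    ]


def _classify(n_factors: int, n_observed: int, n_theoretical: int) -> str:
    if n_factors == 1:
        return "single_factor"
    if n_observed == n_theoretical:
        return "full_factorial"
    return "fractional_factorial"


def infer_design(
    cube: DataCube,
    replicate_semantics: str = "unspecified",
    sample_sizes: int | dict[tuple[str, ...], int] | None = None,
) -> DesignModel:
    """Build the design model for a cube.

    ``sample_sizes`` may be a constant (broadcast over all observed
    treatments) or a per-treatment mapping keyed by the treatment's level
    tuple.  Hand-built cubes whose observed treatments fall outside the
    theoretical space are rejected.
    """
    if not cube.factors:
        raise DesignError("cube declares no factors")
    theoretical = cartesian_treatments(cube.factors)
    theo_keys = {t.key for t in theoretical}
    for t in cube.observed_treatments:
        if t.key not in theo_keys:
            raise DesignError(
                f"observed treatment {t.key} is not in the theoretical "
                "cartesian space — inconsistent cube"
            )
    if sample_sizes is None or isinstance(sample_sizes, int):
        group_sizes = {t.key: sample_sizes for t in cube.observed_treatments}
    else:
        group_sizes = {t.key: sample_sizes.get(t.key) for t in cube.observed_treatments}
    return DesignModel(
        factors=list(cube.factors),
        theoretical_treatments=theoretical,
        observed_treatments=list(cube.observed_treatments),
        classification=_classify(
            len(cube.factors), len(cube.observed_treatments), len(theoretical)
        ),
        group_sizes=group_sizes,
        replicate_semantics=replicate_semantics,
    )


def design_report(d: DesignModel) -> dict:
    """Machine-readable design summary (see :func:`render_design_report`).

    Lists every independent variable with its levels (and ontology terms
    when annotated), the theoretical/observed treatment counts, the
    classification, group sizes and replicate semantics; carries the
    technical-replication caveat when applicable.  Deterministic for a
    fixed model.
    """
    report = {
        "independent_variables": [
            {
                "name": f.name,
                "n_levels": len(f.levels),
                "levels": [
                    {
                        "label": lv.label,
                        **(
                            {"term": {"label": lv.term.label, "curie": lv.term.curie}}
                            if lv.term
                            else {}
                        ),
                    }
                    for lv in f.levels
                ],
                **(
                    {"term": {"label": f.term.label, "curie": f.term.curie}}
                    if f.term
                    else {}
                ),
            }
            for f in d.factors
        ],
        "n_theoretical_treatments": d.n_theoretical,
        "n_observed_treatments": d.n_observed,
        "classification": d.classification,
        "group_sizes": {
            " / ".join(k): v for k, v in sorted(d.group_sizes.items())
        },
        "replicate_semantics": d.replicate_semantics,
    }
    if d.replicate_semantics == "technical":
        report["caveat"] = TECHNICAL_REPLICATE_CAVEAT
    return report


def render_design_report(d: DesignModel) -> str:
    """Plain-text rendering of :func:`design_report` (byte-deterministic)."""
    r = design_report(d)
    lines = [f"Design classification: {r['classification']}"]
    lines.append(
        f"Treatments: {r['n_observed_treatments']} observed of "
        f"{r['n_theoretical_treatments']} theoretical"
    )
    for v in r["independent_variables"]:
        labels = ", ".join(lv["label"] for lv in v["levels"])
        lines.append(f"Variable {v['name']!r} ({v['n_levels']} levels): {labels}")
    lines.append(f"Replicate semantics: {r['replicate_semantics']}")
    sizes = sorted(set(r["group_sizes"].values()))
    if sizes == [None]:
        lines.append("Group sizes: unspecified")
    elif len(sizes) == 1:
        lines.append(f"Group sizes: n={sizes[0]} for every observed treatment")
    else:
        for k, v in r["group_sizes"].items():
            lines.append(f"  {k}: n={v}")
    if "caveat" in r:
        lines.append(f"Caveat: {r['caveat']}")
    return "\n".join(lines) + "\n"


def design_report_json(d: DesignModel) -> str:
    return json.dumps(design_report(d), indent=2, sort_keys=False) + "\n"
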