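"""Shared fixtures: generated exemplar bundles and random-cube builders."""

from __future__ import annotations

import numpy as np
import pytest

from faircube.annotate import annotate_cube
from faircube.core import (
    DataCube,
    Factor,
    FactorLevel,
    Measurement,
    MolecularEntity,
    OntologyTerm,
    QuantitationType,
    TreatmentCombination,
)
from faircube.fixtures import FixtureParams, generate_study
from faircube.ingest import read_matrix, unpack_headers

FACTOR_DOMAINS = {"rose cultivar": "taxon", "organism part": "anatomy"}


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Default exemplar study bundle (61 compounds, 6x3 factors, 8 observed)."""
    return generate_study(FixtureParams(), tmp_path_factory.mktemp("exemplar"))


@pytest.fixture(scope="session")
def exemplar_cube(bundle):
    """The exemplar cube as produced by the real ingest + annotation path."""
    m = read_matrix(bundle.matrix_path)
    cube = unpack_headers(
        m,
        bundle.truth.header_spec,
        study_id=bundle.truth.params.study_id,
        unit=bundle.truth.params.unit,
        sample_size=bundle.truth.params.sample_size,
        replicate_semantics=bundle.truth.params.replicate_semantics,
    )
    cube, _report = annotate_cube(cube, bundle.truth.maps, factor_domains=FACTOR_DOMAINS)
    return cube


def random_cube(rng: np.random.Generator, annotated: bool = True) -> DataCube:
    """A small random but internally consistent cube (for property tests)."""
    n_factors = int(rng.integers(1, 4))
    factors = []
    for fi in range(n_factors):
        n_levels = int(rng.integers(1, 5))
        name = f"factor{fi}"
        factors.append(
            Factor(
                name=name,
                levels=[
                    FactorLevel(label=f"f{fi}l{li}", factor_name=name)
                    for li in range(n_levels)
                ],
            )
        )
    import itertools

    all_combos = list(itertools.product(*(f.levels for f in factors)))
    n_obs = int(rng.integers(1, len(all_combos) + 1))
    chosen = sorted(rng.choice(len(all_combos), size=n_obs, replace=False))
    treatments = [
        TreatmentCombination(levels=tuple(all_combos[i]), status="observed")
        for i in chosen
    ]
    n_entities = int(rng.integers(1, 6))
    entities = []
    for ei in range(n_entities):
        label = f"compound {ei}"
        resolved = annotated and rng.uniform() < 0.7
        entities.append(
            MolecularEntity(
                input_label=label,
                normalized_label=label,
                chebi_term=(
                    OntologyTerm(
                        label=label,
                        curie=f"CHEBI:{10000 + ei}",
                        iri=f"http://purl.obolibrary.org/obo/CHEBI_{10000 + ei}",
                        source="CHEBI",
                    )
                    if resolved
                    else None
                ),
                inchi=f"InChI=1S/SYN.{ei}" if resolved else None,
                resolution="resolved" if resolved else "unresolved",
            )
        )
    qmean = QuantitationType(input_label="average", canonical_name="sample_mean")
    qsem = QuantitationType(
        input_label="standard error",
        canonical_name="standard_error_of_mean",
        requires_sample_size=True,
    )
    measurements = []
    for e in entities:
        for t in treatments:
            for q in (qmean, qsem):
                missing = rng.uniform() < 0.1
                measurements.append(
                    Measurement(
                        entity=e,
                        treatment=t,
                        qtype=q,
                        value=None if missing else round(float(rng.lognormal(3, 1)), 6),
                        unit="ng g-1",
                        sample_size=3,
                        replicate_semantics="technical",
                    )
                )
    return DataCube(
        study_id=f"random-{rng.integers(10**6)}",
        entities=entities,
        factors=factors,
        observed_treatments=treatments,
        qtypes=[qmean, qsem],
        measurements=measurements,
    )
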