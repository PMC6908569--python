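"""The synthetic-study generator: determinism, planted structure, variants."""

import math

import pytest

from faircube.annotate import annotate_cube
from faircube.core import check_cube, cube_shape
from faircube.design import infer_design
from faircube.fixtures import (
    FixtureError,
    FixtureParams,
    generate_custom_study,
    generate_messy_variant,
    generate_pair,
    generate_study,
)
from faircube.ingest import (
    StructuralError,
    read_matrix,
    unpack_headers,
    unpack_headers_lenient,
)

from conftest import FACTOR_DOMAINS


class TestGenerateStudy:
    def test_default_exemplar_structure(self, bundle):
        t = bundle.truth
        assert cube_shape(t.cube) == (61, 8, 2)
        assert t.design.n_theoretical == 18
        assert t.design.n_observed == 8
        assert t.design.classification == "fractional_factorial"
        m = read_matrix(bundle.matrix_path)
        assert (len(m.row_labels), len(m.column_headers)) == (61, 16)

    def test_truth_cube_is_valid(self, bundle):
        assert check_cube(bundle.truth.cube) == []

    def test_two_by_two_full_layout(self, tmp_path):
        params = FixtureParams(
            cultivars=("A", "B"),
            parts=("sepal", "petal"),
            observed=(("A", "sepal"), ("A", "petal"), ("B", "sepal"), ("B", "petal")),
            n_entities=5,
        )
        b = generate_study(params, tmp_path)
        assert b.truth.design.classification == "full_factorial"
        assert b.truth.design.n_observed == b.truth.design.n_theoretical == 4

    def test_same_seed_same_bytes(self, tmp_path):
        p = FixtureParams(seed=99)
        b1 = generate_study(p, tmp_path / "a")
        b2 = generate_study(p, tmp_path / "b")
        assert b1.matrix_path.read_bytes() == b2.matrix_path.read_bytes()
        for domain in b1.term_map_paths:
            assert (
                b1.term_map_paths[domain].read_bytes()
                == b2.term_map_paths[domain].read_bytes()
            )
        assert b1.header_spec_path.read_bytes() == b2.header_spec_path.read_bytes()

    def test_different_seed_different_values(self, tmp_path):
        b1 = generate_study(FixtureParams(seed=1), tmp_path / "a")
        b2 = generate_study(FixtureParams(seed=2), tmp_path / "b")
        assert b1.matrix_path.read_bytes() != b2.matrix_path.read_bytes()

    def test_sem_equals_dispersion_over_sqrt_n(self, bundle):
        """Planted SEM consistency: SEM = dispersion / sqrt(n) to 1e-9,
        and SEM > 0 everywhere."""
        t = bundle.truth
        n = t.params.sample_size
        sems = {
            (m.entity.input_label, m.treatment.key): m.value
            for m in t.cube.measurements
            if m.qtype.canonical_name == "standard_error_of_mean"
        }
        assert len(sems) == 61 * 8
        for (lab, key), sem in sems.items():
            assert sem > 0
            assert math.isclose(sem, t.dispersions[(lab, key)] / math.sqrt(n),
                                abs_tol=1e-9)

    def test_missing_rate_produces_missing_cells(self, tmp_path):
        b = generate_study(FixtureParams(missing_rate=0.1, seed=5), tmp_path)
        n_missing = sum(m.is_missing for m in b.truth.cube.measurements)
        assert 0 < n_missing < 976
        cube = unpack_headers(
            read_matrix(b.matrix_path), b.truth.header_spec, sample_size=3
        )
        assert sum(m.is_missing for m in cube.measurements) == n_missing

    def test_unresolved_knob_plants_map_misses(self, tmp_path):
        b = generate_study(FixtureParams(n_unresolved=5, seed=5), tmp_path)
        cube = unpack_headers(
            read_matrix(b.matrix_path), b.truth.header_spec, sample_size=3
        )
        _, report = annotate_cube(cube, b.truth.maps, factor_domains=FACTOR_DOMAINS)
        assert len(report.unresolved["chemical"]) == 5

    @pytest.mark.parametrize(
        "bad",
        [
            {"missing_rate": 1.5},
            {"n_entities": 0},
            {"cultivars": ()},
            {"observed": (("nope", "sepal"),)},
        ],
    )
    def test_invalid_params_rejected(self, bad, tmp_path):
        with pytest.raises(FixtureError):
            generate_study(FixtureParams(**bad), tmp_path)

    def test_end_to_end_parameter_recovery(self, bundle, exemplar_cube):
        """Ingest + design on the generated files recovers exactly the
        planted factor structure (the central acceptance property)."""
        t = bundle.truth
        d = infer_design(exemplar_cube, replicate_semantics="technical", sample_sizes=3)
        assert [f.name for f in d.factors] == [f.name for f in t.design.factors]
        assert [f.level_labels() for f in d.factors] == [
            f.level_labels() for f in t.design.factors
        ]
        assert {tr.key for tr in d.observed_treatments} == {
            tr.key for tr in t.design.observed_treatments
        }
        assert (d.n_theoretical, d.n_observed, d.classification) == (
            t.design.n_theoretical,
            t.design.n_observed,
            t.design.classification,
        )


class TestGeneratePair:
    def test_planted_regions(self, tmp_path):
        ba, bb = generate_pair(
            FixtureParams(),
            FixtureParams(n_entities=50, seed=43, study_id="rose-b"),
            40,
            tmp_path,
        )
        assert ba.truth.overlap_regions == (40, 21, 10)
        shared = set(ba.truth.entity_curies) & set(bb.truth.entity_curies)
        assert len(shared) == 40

    def test_zero_shared_is_disjoint(self, tmp_path):
        ba, bb = generate_pair(
            FixtureParams(n_entities=6, study_id="a"),
            FixtureParams(n_entities=4, seed=3, study_id="b"),
            0,
            tmp_path,
        )
        assert not set(ba.truth.entity_curies) & set(bb.truth.entity_curies)

    def test_full_share_identical_sets(self, tmp_path):
        ba, bb = generate_pair(
            FixtureParams(n_entities=7, study_id="a"),
            FixtureParams(n_entities=7, seed=3, study_id="b"),
            7,
            tmp_path,
        )
        assert set(ba.truth.entity_curies) == set(bb.truth.entity_curies)

    def test_infeasible_share_rejected(self, tmp_path):
        with pytest.raises(FixtureError):
            generate_pair(
                FixtureParams(n_entities=5),
                FixtureParams(n_entities=4, study_id="b"),
                6,
                tmp_path,
            )


class TestMessyVariant:
    def test_header_noise_ingests_cleanly_after_normalization(self, bundle, tmp_path):
        path, manifest = generate_messy_variant(
            bundle, {"header_case": True, "typographic_quotes": True}, tmp_path
        )
        cube, findings = unpack_headers_lenient(
            read_matrix(path), bundle.truth.header_spec, sample_size=3
        )
        assert findings == []
        assert cube_shape(cube) == (61, 8, 2)

    def test_three_non_numeric_cells_three_findings(self, bundle, tmp_path):
        path, manifest = generate_messy_variant(bundle, {"non_numeric": 3}, tmp_path)
        _, findings = unpack_headers_lenient(
            read_matrix(path), bundle.truth.header_spec, sample_size=3
        )
        assert manifest["findings"]["BAD_VALUE"] == 3
        assert sum(f.code == "BAD_VALUE" for f in findings) == 3

    def test_ragged_row_is_structural_error_in_strict_mode(self, bundle, tmp_path):
        path, manifest = generate_messy_variant(bundle, {"ragged_row": True}, tmp_path)
        assert manifest["structural_error"]
        with pytest.raises(StructuralError):
            read_matrix(path)

    def test_unknown_perturbation_rejected(self, bundle, tmp_path):
        with pytest.raises(FixtureError, match="unknown"):
            generate_messy_variant(bundle, {"frobnicate": 1}, tmp_path)


class TestCustomStudies:
    @pytest.mark.parametrize(
        "level_counts, fraction",
        [
            ((3,), 1.0),
            ((2, 2), 1.0),
            ((2, 3), 0.5),
            ((4, 2, 3), 0.4),
            ((2, 2, 2, 2), 0.6),
            ((6, 3), 8 / 18),
        ],
    )
    def test_design_recovery_sweep(self, level_counts, fraction, tmp_path):
        """Generic k-factor studies: ingest + infer_design recovers the
        planted counts and classification across the sweep."""
        import itertools

        factor_levels = {
            f"var{i}": tuple(f"v{i}.{j}" for j in range(n))
            for i, n in enumerate(level_counts)
        }
        full = list(itertools.product(*factor_levels.values()))
        n_obs = max(max(level_counts), round(len(full) * fraction))
        study = generate_custom_study(
            factor_levels, tmp_path, n_observed=n_obs, seed=3
        )
        cube = unpack_headers(
            read_matrix(study.matrix_path), study.header_spec, sample_size=3
        )
        d = infer_design(cube, sample_sizes=3)
        assert d.n_theoretical == study.n_theoretical
        assert d.n_observed == n_obs
        assert d.classification == study.classification
        assert {f.name for f in d.factors} == set(factor_levels)
        for f in d.factors:
            assert sorted(f.level_labels()) == sorted(
                {key[list(factor_levels).index(f.name)] for key in study.observed_keys}
            )
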