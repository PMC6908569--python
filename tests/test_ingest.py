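"""Matrix reading and composed-header unpacking."""

import numpy as np
import pytest

from faircube.core import cube_shape, cube_signature
from faircube.ingest import (
    AmbiguousHeaderError,
    Dialect,
    HeaderSpec,
    RawMatrix,
    StructuralError,
    UnmatchedHeaderError,
    ValueParseError,
    read_matrix,
    tidy_table,
    unpack_headers,
    unpack_headers_lenient,
)


def write(tmp_path, text, name="m.csv"):
    p = tmp_path / name
    p.write_text(text, encoding="utf-8")
    return p


class TestReadMatrix:
    def test_toy_csv_is_echoed_verbatim(self, tmp_path):
        p = write(tmp_path, "id,a,b\nx,1,2\ny,3,4\nz,5,6\n")
        m = read_matrix(p)
        assert m.row_labels == ["x", "y", "z"]
        assert m.column_headers == ["a", "b"]
        assert m.values == [["1", "2"], ["3", "4"], ["5", "6"]]

    def test_exemplar_dimensions(self, bundle):
        m = read_matrix(bundle.matrix_path)
        assert len(m.row_labels) == 61
        assert len(m.column_headers) == 16  # 8 treatments x 2 statistics

    def test_ragged_row_names_the_line(self, tmp_path):
        p = write(tmp_path, "id,a,b\nx,1,2\ny,3\n")
        with pytest.raises(StructuralError, match="line 3"):
            read_matrix(p)

    def test_duplicate_headers_rejected(self, tmp_path):
        p = write(tmp_path, "id,a, a\nx,1,2\n")
        with pytest.raises(AmbiguousHeaderError):
            read_matrix(p)

    def test_comma_decimal_dialect(self, tmp_path):
        p = write(tmp_path, 'id;a - average\nx;"1,5"\n')
        m = read_matrix(p, Dialect(delimiter=";", decimal=","))
        spec = HeaderSpec.from_dict(
            {
                "rules": [
                    {"pattern": r"^(?P<f>.+) - (?P<stat>.+)$",
                     "factors": {"f": "part"}, "qtype": "stat"}
                ]
            }
        )
        cube = unpack_headers(m, spec, sample_size=3)
        assert cube.measurements[0].value == 1.5


class TestUnpackHeaders:
    def test_composed_rose_header_decomposes(self):
        """'R. chinensis 'Old Blush' sepals — average' splits into the
        cultivar level, the part level (singularized) and the mean qtype."""
        spec = HeaderSpec.from_dict(
            {
                "rules": [
                    {
                        "pattern": r"^(?P<c>.+?) (?P<p>sepals|petals|stamens) - (?P<s>.+)$",
                        "factors": {"c": "rose cultivar", "p": "organism part"},
                        "qtype": "s",
                    }
                ],
                "synonyms": {"sepals": "sepal", "petals": "petal", "stamens": "stamen"},
            }
        )
        m = RawMatrix(
            row_labels=["geraniol"],
            column_headers=["R. chinensis ‘Old Blush’ sepals — average"],
            values=[["12.5"]],
        )
        cube = unpack_headers(m, spec, sample_size=3)
        assert cube.observed_treatments[0].key == ("R. chinensis 'Old Blush'", "sepal")
        assert cube.qtypes[0].canonical_name == "sample_mean"

    def test_single_column_with_default_qtype(self):
        spec = HeaderSpec.from_dict(
            {
                "rules": [{"pattern": r"^(?P<x>.+)$", "factors": {"x": "condition"}}],
                "default_qtype": "average",
            }
        )
        m = RawMatrix(["e1"], ["only"], [["1.0"]])
        cube = unpack_headers(m, spec, sample_size=3)
        assert cube_shape(cube) == (1, 1, 1)
        assert cube.factors[0].level_labels() == ["only"]

    def test_exemplar_recovers_factor_structure(self, exemplar_cube):
        assert [f.name for f in exemplar_cube.factors] == [
            "rose cultivar",
            "organism part",
        ]
        assert [len(f.levels) for f in exemplar_cube.factors] == [6, 3]
        assert len(exemplar_cube.observed_treatments) == 8

    def test_unmatched_header_lists_rules(self, bundle):
        m = read_matrix(bundle.matrix_path)
        m.column_headers[3] = "garbage header"
        with pytest.raises(UnmatchedHeaderError, match="garbage header"):
            unpack_headers(m, bundle.truth.header_spec, sample_size=3)

    def test_ambiguous_header_rejected(self):
        spec = HeaderSpec.from_dict(
            {
                "rules": [
                    {"pattern": r"^(?P<x>.+)$", "factors": {"x": "f"}},
                    {"pattern": r"^(?P<y>\w+)$", "factors": {"y": "f"}},
                ],
                "default_qtype": "average",
            }
        )
        with pytest.raises(AmbiguousHeaderError):
            unpack_headers(RawMatrix(["e"], ["abc"], [["1"]]), spec, sample_size=3)

    def test_non_numeric_cell_raises_with_coordinates(self, bundle):
        m = read_matrix(bundle.matrix_path)
        m.values[2][5] = "oops"
        with pytest.raises(ValueParseError, match="oops"):
            unpack_headers(m, bundle.truth.header_spec, sample_size=3)

    def test_lenient_mode_collects_all_findings(self, bundle):
        m = read_matrix(bundle.matrix_path)
        m.values[2][5] = "oops"
        m.values[7][1] = "worse"
        m.column_headers[0] = "garbage"
        cube, findings = unpack_headers_lenient(
            m, bundle.truth.header_spec, sample_size=3
        )
        codes = sorted(f.code for f in findings)
        assert codes == ["BAD_VALUE", "BAD_VALUE", "UNMATCHED_HEADER"]

    def test_missing_tokens_become_missing_cells(self, bundle):
        m = read_matrix(bundle.matrix_path)
        m.values[0][0] = "n.d."
        cube = unpack_headers(m, bundle.truth.header_spec, sample_size=3)
        missing = [mm for mm in cube.measurements if mm.is_missing]
        assert len(missing) == 1

    def test_column_permutation_yields_identical_cube(self, bundle):
        m = read_matrix(bundle.matrix_path)
        cube_a = unpack_headers(m, bundle.truth.header_spec, sample_size=3)
        rng = np.random.default_rng(5)
        perm = rng.permutation(len(m.column_headers))
        m2 = RawMatrix(
            row_labels=list(m.row_labels),
            column_headers=[m.column_headers[i] for i in perm],
            values=[[row[i] for i in perm] for row in m.values],
            dialect=m.dialect,
        )
        cube_b = unpack_headers(m2, bundle.truth.header_spec, sample_size=3)
        assert cube_signature(cube_a) == cube_signature(cube_b)

    def test_column_conservation(self, bundle, exemplar_cube):
        m = read_matrix(bundle.matrix_path)
        pairs = {
            (mm.treatment.key, mm.qtype.canonical_name)
            for mm in exemplar_cube.measurements
        }
        assert len(pairs) == len(m.column_headers)


class TestTidyTable:
    def test_record_counts(self, exemplar_cube):
        df = tidy_table(exemplar_cube)
        assert len(df) == 976  # 61 x 8 x 2
        assert list(df.columns) == [
            "entity",
            "rose cultivar",
            "organism part",
            "quantitation_type",
            "value",
            "unit",
            "sample_size",
        ]

    def test_empty_cube_gives_empty_table(self):
        from faircube.core import DataCube

        assert len(tidy_table(DataCube(study_id="empty"))) == 0

    def test_round_trip_rewidening_reproduces_grid(self, bundle):
        """Grouping tidy records back by recomposed header equals the
        original matrix cell-for-cell."""
        m = read_matrix(bundle.matrix_path)
        cube = unpack_headers(m, bundle.truth.header_spec, sample_size=3)
        df = tidy_table(cube)
        qlabel = {"sample_mean": "average", "standard_error_of_mean": "standard error"}
        plural = {"sepal": "sepals", "petal": "petals", "stamen": "stamens"}
        wide = {
            (r["entity"], f"{r['rose cultivar']} {plural[r['organism part']]} - "
                          f"{qlabel[r['quantitation_type']]}"): r["value"]
            for _, r in df.iterrows()
        }
        for ri, lab in enumerate(m.row_labels):
            for ci, header in enumerate(m.column_headers):
                assert wide[(lab, header)] == float(m.values[ri][ci])
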