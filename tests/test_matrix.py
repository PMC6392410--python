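"""Record parsing, matrix construction, ordering, and round trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hummnet import (
    BipartiteMatrix,
    InteractionRecord,
    TaxonMaps,
    build_matrix,
    order_matrix,
    read_interaction_records,
    read_tip_order,
)
from hummnet.matrix import MatrixFormatError, UnmappedSpeciesError, write_interaction_records

from .conftest import make_matrix


MAPS = TaxonMaps(
    bird_to_clade={"b1": "Bees", "b2": "Hermits"},
    plant_to_family={"p1": "FamA", "p2": "FamB", "p3": "FamA"},
    family_syndrome={"FamA": "ornithophilous", "FamB": "intermediate"},
)


class TestReadRecords:
    def test_basic_parse(self, tmp_path):
        path = tmp_path / "records.csv"
        path.write_text(
            "bird_species,plant_species,source_id,plant_native\n"
            "b1,p1,src1,true\n"
            "b2,p2,src2,exotic\n"
        )
        records = read_interaction_records(path)
        assert len(records) == 2
        assert records[0].plant_native and not records[1].plant_native

    def test_duplicates_retained_at_read(self, tmp_path):
        path = tmp_path / "records.csv"
        path.write_text(
            "bird_species,plant_species,source_id,plant_native\nb1,p1,s,1\nb1,p1,s,1\n"
        )
        assert len(read_interaction_records(path)) == 2

    def test_empty_species_reports_line(self, tmp_path):
        path = tmp_path / "records.csv"
        path.write_text("bird_species,plant_species,source_id,plant_native\nb1,,s,1\n")
        with pytest.raises(MatrixFormatError, match=":2"):
            read_interaction_records(path)

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "records.csv"
        path.write_text("bird_species,plant_species,source_id\nb1,p1,s\n")
        with pytest.raises(MatrixFormatError, match="plant_native"):
            read_interaction_records(path)

    def test_bad_native_flag_reports_line(self, tmp_path):
        path = tmp_path / "records.csv"
        path.write_text("bird_species,plant_species,source_id,plant_native\nb1,p1,s,maybe\n")
        with pytest.raises(MatrixFormatError, match=":2"):
            read_interaction_records(path)

    def test_write_read_round_trip(self, tmp_path):
        records = [
            InteractionRecord("b1", "p1", "s", True),
            InteractionRecord("b2", "p2", "s", False),
        ]
        path = tmp_path / "records.csv"
        write_interaction_records(records, path)
        assert read_interaction_records(path) == records


class TestBuildMatrix:
    def test_saturated_pairs(self):
        records = [
            InteractionRecord("b1", "p1"),
            InteractionRecord("b1", "p2"),
            InteractionRecord("b2", "p2"),
            InteractionRecord("b2", "p3"),
        ]
        mat = build_matrix(records, MAPS)
        assert mat.shape == (2, 2) and mat.cells.all()

    def test_unmapped_species_listed(self):
        with pytest.raises(UnmappedSpeciesError, match="ghost"):
            build_matrix([InteractionRecord("ghost", "p1")], MAPS)

    def test_native_filter_applies_before_aggregation(self):
        # FamA keeps its native link; FamB only has an exotic member
        records = [
            InteractionRecord("b1", "p1", plant_native=True),
            InteractionRecord("b1", "p2", plant_native=False),
        ]
        full = build_matrix(records, MAPS, native_only=False)
        native = build_matrix(records, MAPS, native_only=True)
        assert set(full.rows) == {"FamA", "FamB"}
        assert set(native.rows) == {"FamA"}
        assert native.n_links <= full.n_links

    def test_empty_after_filter_raises(self):
        records = [InteractionRecord("b1", "p2", plant_native=False)]
        with pytest.raises(ValueError):
            build_matrix(records, MAPS, native_only=True)

    def test_duplication_idempotent(self):
        records = [InteractionRecord("b1", "p1"), InteractionRecord("b2", "p3")]
        once = build_matrix(records, MAPS)
        twice = build_matrix(records * 2, MAPS)
        assert once.rows == twice.rows and once.cols == twice.cols
        assert (once.cells == twice.cells).all()


class TestOrderMatrix:
    def test_degree_sort_descending(self):
        mat = make_matrix([[1, 0, 0], [1, 1, 1], [1, 1, 0]])
        ordered = order_matrix(mat, "degree")
        assert list(ordered.row_degrees()) == [3, 2, 1]
        assert ordered.order_mode == "degree"

    def test_equal_degree_ties_alphabetical(self):
        mat = BipartiteMatrix(["zeta", "alpha"], ["c1", "c2"], np.array([[1, 0], [0, 1]]), "given")
        ordered = order_matrix(mat, "degree")
        assert ordered.rows == ["alpha", "zeta"]

    def test_given_identity_is_noop(self):
        mat = make_matrix([[1, 0], [1, 1]])
        same = order_matrix(mat, "given", row_order=mat.rows, col_order=mat.cols)
        assert (same.cells == mat.cells).all()

    def test_non_permutation_rejected(self):
        mat = make_matrix([[1, 0], [1, 1]])
        with pytest.raises(ValueError, match="missing"):
            order_matrix(mat, "given", row_order=["fam01", "other"], col_order=mat.cols)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_ordering_preserves_degree_multisets(self, seed):
        r = np.random.default_rng(seed)
        cells = (r.random((5, 4)) < 0.5).astype(np.int8)
        cells[cells.sum(axis=1) == 0, 0] = 1
        cells[0, cells.sum(axis=0) == 0] = 1
        mat = make_matrix(cells)
        ordered = order_matrix(mat, "degree")
        assert sorted(ordered.row_degrees()) == sorted(mat.row_degrees())
        assert sorted(ordered.col_degrees()) == sorted(mat.col_degrees())
        assert ordered.n_links == mat.n_links


class TestMatrixCsv:
    def test_round_trip_exact(self, tmp_path):
        mat = make_matrix([[1, 0, 1], [0, 1, 1]])
        path = tmp_path / "matrix.csv"
        mat.write_csv(path)
        back = BipartiteMatrix.read_csv(path)
        assert back.rows == mat.rows and back.cols == mat.cols
        assert (back.cells == mat.cells).all()


class TestTipOrder:
    def test_left_to_right_traversal(self, tmp_path):
        path = tmp_path / "tree.nwk"
        path.write_text("(A,(B,C));\n")
        assert read_tip_order(path) == ["A", "B", "C"]
        path.write_text("((A,B),(C,D));\n")
        assert read_tip_order(path) == ["A", "B", "C", "D"]

    def test_two_trees_rejected(self, tmp_path):
        path = tmp_path / "trees.nwk"
        path.write_text("(A,B);\n(C,D);\n")
        with pytest.raises(MatrixFormatError, match="one tree"):
            read_tip_order(path)

    def test_unbalanced_parentheses_reports_offset(self, tmp_path):
        path = tmp_path / "bad.nwk"
        path.write_text("((A,B);\n")
        with pytest.raises(MatrixFormatError, match="unbalanced"):
            read_tip_order(path)
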