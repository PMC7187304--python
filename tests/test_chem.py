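"""Compound I/O, featurization, Tanimoto similarity and splitting."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from aladdin import (
    Activity,
    CompoundRecord,
    FeatureVector,
    featurize,
    featurize_smiles,
    filter_test_by_train_similarity,
    read_compound_library,
    split_train_test,
    tanimoto,
)
from aladdin.chem import bulk_tanimoto

from conftest import make_raw_compound


# ---------------------------------------------------------------------------
# Library reading
# ---------------------------------------------------------------------------

class TestReadLibrary:
    def test_two_line_table(self, tmp_path):
        p = tmp_path / "lib.smi"
        p.write_text("CCO c1 active\nCCN c2 decoy\n")
        lib = read_compound_library(p, "smiles_table")
        assert len(lib) == 2
        assert sum(c.activity_class is Activity.ACTIVE for c in lib) == 1

    def test_malformed_smiles_skipped(self, tmp_path, caplog):
        rows = ["CCO c1 active", "CCN c2 decoy", "not_a_smiles((( c3 decoy",
                "c1ccccc1 c4 active", "CC(=O)O c5 decoy"]
        p = tmp_path / "lib.smi"
        p.write_text("\n".join(rows) + "\n")
        with caplog.at_level("WARNING"):
            lib = read_compound_library(p, "smiles_table")
        assert len(lib) == 4
        assert any("skipping" in r.message for r in caplog.records)

    def test_duplicate_id_is_hard_error(self, tmp_path):
        p = tmp_path / "lib.smi"
        p.write_text("CCO c1 active\nCCN c1 decoy\n")
        with pytest.raises(ValueError, match="duplicate|conflicting"):
            read_compound_library(p, "smiles_table")

    def test_representations_merged(self, tmp_path):
        p = tmp_path / "lib.smi"
        p.write_text("CCO c1 active taut1\nC(C)O c1 active taut2\nCCN c2 decoy\n")
        lib = {c.compound_id: c for c in read_compound_library(p, "smiles_table")}
        assert len(lib["c1"].representations) == 2
        assert len(lib["c2"].representations) == 1

    def test_csv_roundtrip(self, tmp_path):
        p = tmp_path / "lib.csv"
        p.write_text("compound_id,smiles,activity_class\nc1,CCO,active\nc2,CCN,decoy\n")
        lib = read_compound_library(p, "csv")
        assert {c.compound_id for c in lib} == {"c1", "c2"}


# ---------------------------------------------------------------------------
# Featurization
# ---------------------------------------------------------------------------

class TestFeaturize:
    def test_deterministic_and_canonical(self):
        a = featurize_smiles("c1ccccc1")
        b = featurize_smiles("C1=CC=CC=C1")  # kekulized alias of benzene
        c = featurize_smiles("c1ccccc1")
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(a.values, c.values)
        assert len(a) == 1024 and a.kind == "hashed_circular"

    def test_different_molecules_differ(self):
        ethane = featurize_smiles("CC")
        ethanol = featurize_smiles("CCO")
        assert tanimoto(ethane, ethanol) < 1.0

    @pytest.mark.parametrize("kind,length", [("structural_keys", 167), ("physchem_2d", None)])
    def test_other_descriptor_kinds(self, kind, length):
        fv = featurize_smiles("CCO", kind)
        assert fv.kind == kind
        if length is not None:
            assert len(fv) == length
        else:
            assert len(fv) > 100  # full 2D descriptor set

    def test_raw_kind_returns_stored_vector(self):
        c = make_raw_compound("x", Activity.ACTIVE, [1, 0, 1, 1])
        assert np.array_equal(featurize(c, "raw").values, [1, 0, 1, 1])

    def test_featurize_does_not_mutate(self):
        c = CompoundRecord("x", Activity.ACTIVE, smiles="CCO")
        featurize(c, "hashed_circular")
        assert c.smiles == "CCO"

    def test_missing_smiles_errors(self):
        c = make_raw_compound("x", Activity.ACTIVE, [1, 0])
        with pytest.raises(ValueError, match="no SMILES"):
            featurize(c, "hashed_circular")


# ---------------------------------------------------------------------------
# Tanimoto
# ---------------------------------------------------------------------------

class TestTanimoto:
    def test_hand_computed(self):
        a = np.zeros(8); a[[1, 2, 3]] = 1
        b = np.zeros(8); b[[2, 3, 4]] = 1
        assert tanimoto(a, b) == pytest.approx(2 / 4)

    def test_identity_disjoint_empty(self):
        v = np.array([1, 1, 0, 0])
        assert tanimoto(v, v) == 1.0
        assert tanimoto(v, np.array([0, 0, 1, 1])) == 0.0
        z = np.zeros(4)
        assert tanimoto(z, z) == 1.0  # documented empty-vector convention

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="lengths differ"):
            tanimoto(np.ones(4), np.ones(5))

    @given(st.lists(st.booleans(), min_size=1, max_size=32),
           st.lists(st.booleans(), min_size=1, max_size=32))
    def test_symmetric_bounded_and_one_iff_equal(self, xs, ys):
        n = max(len(xs), len(ys))
        a = np.zeros(n); a[: len(xs)] = xs
        b = np.zeros(n); b[: len(ys)] = ys
        t = tanimoto(a, b)
        assert t == tanimoto(b, a)
        assert 0.0 <= t <= 1.0
        if a.any() or b.any():
            assert (t == 1.0) == bool(np.array_equal(a > 0, b > 0))

    def test_bulk_matches_pairwise(self):
        rng = np.random.default_rng(0)
        A = rng.integers(0, 2, (5, 16))
        B = rng.integers(0, 2, (4, 16))
        M = bulk_tanimoto(A, B)
        for i in range(5):
            for j in range(4):
                assert M[i, j] == pytest.approx(tanimoto(A[i], B[j]))


# ---------------------------------------------------------------------------
# Splitting and similarity filtering
# ---------------------------------------------------------------------------

class TestSplit:
    def test_exact_stratified_fraction(self, raw_library):
        split = split_train_test(raw_library, 0.2, seed=0)
        test_ids = [cid for cid, s in split.items() if s == "test"]
        assert len(test_ids) == 4
        assert sum(cid.startswith("A") for cid in test_ids) == 2

    def test_deterministic(self, raw_library):
        assert split_train_test(raw_library, 0.2, seed=5) == split_train_test(
            raw_library, 0.2, seed=5
        )

    def test_unstratifiable_class_errors(self):
        lib = [make_raw_compound("a", Activity.ACTIVE, [1]),
               make_raw_compound("d1", Activity.DECOY, [1]),
               make_raw_compound("d2", Activity.DECOY, [0])]
        with pytest.raises(ValueError, match="stratify"):
            split_train_test(lib, 0.2, seed=0)


class TestSimilarityFilter:
    def _lib(self):
        # three scaffolds with decreasing relatedness to the train set
        train = [CompoundRecord(f"t{i}", Activity.ACTIVE, smiles=s)
                 for i, s in enumerate(["c1ccccc1CCO", "c1ccccc1CCN"])]
        test = [CompoundRecord("close", Activity.ACTIVE, smiles="c1ccccc1CCO"),
                CompoundRecord("mid", Activity.DECOY, smiles="c1ccccc1CC"),
                CompoundRecord("far", Activity.DECOY, smiles="NCCS")]
        return train, test

    def test_cutoff_one_keeps_everything(self):
        train, test = self._lib()
        assert filter_test_by_train_similarity(test, train, 1.0) == test

    def test_matches_bruteforce_and_nests(self):
        from aladdin.chem import feature_matrix

        train, test = self._lib()
        A = feature_matrix(test) > 0
        B = feature_matrix(train) > 0
        max_tc = bulk_tanimoto(A, B).max(axis=1)
        for cutoff in (0.0, 0.3, 0.5, 0.8):
            got = {c.compound_id for c in filter_test_by_train_similarity(test, train, cutoff)}
            want = {c.compound_id for c, t in zip(test, max_tc) if t <= cutoff}
            assert got == want
        sub_07 = filter_test_by_train_similarity(test, train, 0.7)
        sub_08 = filter_test_by_train_similarity(test, train, 0.8)
        assert set(c.compound_id for c in sub_07) <= set(c.compound_id for c in sub_08)

    def test_empty_result_is_not_an_error(self):
        train, test = self._lib()
        assert filter_test_by_train_similarity(test[:1], train, 0.0) == []

    def test_empty_train_errors(self):
        _, test = self._lib()
        with pytest.raises(ValueError, match="empty train"):
            filter_test_by_train_similarity(test, [], 0.5)
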