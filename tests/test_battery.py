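"""SMOTE, the correctness-classifier battery, model selection and the
similarity selector."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from aladdin import (
    Activity,
    CompoundRecord,
    CorrectnessBattery,
    FeatureVector,
    HyperparameterGrid,
    SimilarityStructureSelector,
    StructureEntry,
    grid_search_cv,
    select_structure_aladdin,
    select_structure_similarity,
    smote_resample,
)
from aladdin.battery import cv_fold_mcc, load_battery, save_battery


def _separable_problem(n=80, n_features=16, seed=0):
    """Labels fully determined by feature 0."""
    rng = np.random.default_rng(seed)
    X = rng.integers(0, 2, (n, n_features)).astype(float)
    y = X[:, 0].astype(int)
    return X, y


class TestSmote:
    def test_balances_to_parity(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(100, 4))
        y = np.array([1] * 90 + [0] * 10)
        Xr, yr = smote_resample(X, y, random_state=0)
        assert (yr == 0).sum() == (yr == 1).sum() == 90
        assert Xr.shape[0] == 180

    def test_synthetic_points_interpolate_minority(self):
        X = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [5.0, 5.0], [6.0, 5.0],
                      [5.0, 6.0], [6.0, 6.0], [5.5, 5.5]])
        y = np.array([0, 0, 0, 1, 1, 1, 1, 1])
        Xr, yr = smote_resample(X, y, k_neighbors=2, random_state=1)
        new = Xr[len(X):]
        # interpolants stay within the minority bounding box
        assert (new >= 0.0 - 1e-9).all() and (new <= 1.0 + 1e-9).all()
        assert (yr[len(X):] == 0).all()

    def test_deterministic_given_seed(self):
        X, y = _separable_problem(60)
        y = np.array([1] * 50 + [0] * 10)
        a = smote_resample(X, y, random_state=7)
        b = smote_resample(X, y, random_state=7)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_balanced_input_unchanged(self):
        X, _ = _separable_problem(20)
        y = np.array([0, 1] * 10)
        Xr, yr = smote_resample(X, y, random_state=0)
        assert np.array_equal(Xr, X) and np.array_equal(yr, y)

    def test_tiny_minority_errors(self):
        X = np.ones((5, 2))
        with pytest.raises(ValueError, match="minority"):
            smote_resample(X, np.array([0, 1, 1, 1, 1]), random_state=0)


class TestCorrectnessBattery:
    def _fit(self, **kw):
        X, y = _separable_problem(100)
        Y = pd.DataFrame({"S2": y, "S1": 1 - y})
        kw.setdefault("n_estimators", 25)
        return CorrectnessBattery(random_state=0, **kw).fit(X, Y), X, Y

    def test_probabilities_in_unit_interval_and_ordered_columns(self):
        battery, X, _ = self._fit()
        proba = battery.predict_proba(X)
        assert battery.structure_ids_ == ["S1", "S2"]
        assert proba.shape == (100, 2)
        assert (proba >= 0).all() and (proba <= 1).all()

    def test_predicts_structure_where_compound_is_correct(self):
        battery, X, Y = self._fit()
        sel = battery.predict(X)
        # feature 0 decides: correct on S2 iff bit set, on S1 iff unset
        expected = np.where(X[:, 0] == 1, "S2", "S1")
        assert (sel == expected).mean() > 0.95

    def test_single_class_structure_dropped_with_warning(self):
        X, y = _separable_problem(50)
        Y = pd.DataFrame({"S1": y, "Sdead": np.ones_like(y)})
        battery = CorrectnessBattery(n_estimators=10, random_state=0).fit(X, Y)
        assert battery.structure_ids_ == ["S1"]
        assert battery.dropped_structures_ == ["Sdead"]

    def test_deterministic_given_seed(self):
        a, X, _ = self._fit()
        b, _, _ = self._fit()
        assert np.array_equal(a.predict_proba(X), b.predict_proba(X))

    def test_identical_score_columns_give_identical_labels(self):
        from aladdin import Activity, ScoreMatrix, assign_correctness_labels, rank_compounds

        scores = {"a1": -9.0, "d1": -8.0, "a2": -5.0, "d2": -4.0}
        classes = {"a1": Activity.ACTIVE, "a2": Activity.ACTIVE,
                   "d1": Activity.DECOY, "d2": Activity.DECOY}
        m = ScoreMatrix(frame=pd.DataFrame({"S1": scores, "S2": scores}))
        l1 = assign_correctness_labels(rank_compounds(m, "S1"), classes, "S1")
        l2 = assign_correctness_labels(rank_compounds(m, "S2"), classes, "S2")
        assert l1.labels == l2.labels

    def test_sklearn_protocol(self):
        est = CorrectnessBattery(n_estimators=12, random_state=3)
        params = est.get_params()
        assert params["n_estimators"] == 12
        cloned = clone(est)
        assert cloned.get_params() == params

    def test_save_load_roundtrip(self, tmp_path):
        battery, X, _ = self._fit()
        save_battery(battery, tmp_path / "bat", fingerprint_config={"kind": "raw"})
        loaded, manifest = load_battery(tmp_path / "bat")
        assert manifest["fingerprint_config"] == {"kind": "raw"}
        assert np.array_equal(loaded.predict_proba(X), battery.predict_proba(X))


class TestGridSearch:
    def test_separable_problem_reaches_high_mcc(self):
        X, y = _separable_problem(120)
        Y = pd.DataFrame({"S1": y})
        grid = HyperparameterGrid(("raw",), (10,), ("sqrt",))
        res = grid_search_cv({"raw": X}, Y, grid, k_folds=5, seed=0)
        assert res.mean_mcc > 0.95

    def test_null_problem_near_zero_mcc(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 2, (200, 16)).astype(float)
        y = rng.integers(0, 2, 200)
        grid = HyperparameterGrid(("raw",), (10,), ("sqrt",))
        res = grid_search_cv({"raw": X}, pd.DataFrame({"S1": y}), grid, k_folds=5, seed=0)
        assert abs(res.mean_mcc) < 0.15

    def test_tie_breaks_toward_smaller_forest_then_sqrt(self):
        # every feature is a copy of the label, so every cell scores MCC 1.0
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 120)
        X = np.tile(y[:, None], (1, 16)).astype(float)
        Y = pd.DataFrame({"S1": y})
        grid = HyperparameterGrid(("raw",), (50, 10), (0.4, "sqrt"))
        res = grid_search_cv({"raw": X}, Y, grid, k_folds=5, seed=0)
        assert res.n_estimators == 10 and res.max_features == "sqrt"
        assert len(res.table) == 4

    def test_too_few_minority_members_error(self):
        X, _ = _separable_problem(30)
        y = np.array([1] * 27 + [0] * 3)
        with pytest.raises(ValueError, match="fold"):
            cv_fold_mcc(X, y, 10, "sqrt", k_folds=5, seed=0)


class TestSelectors:
    def test_aladdin_argmax_and_tiebreak(self):
        assert select_structure_aladdin({"S1": 0.9, "S2": 0.4}) == "S1"
        assert select_structure_aladdin({"S2": 0.5, "S1": 0.5}) == "S1"
        uniform = {f"S{i:02d}": 0.5 for i in range(30)}
        assert select_structure_aladdin(uniform) == "S00"

    def test_similarity_selector_toy_tc(self):
        # query shares 0.2 / 0.7 / 0.5 Tanimoto with the three ligands
        query = np.zeros(20); query[:10] = 1
        lig1 = np.zeros(20); lig1[8:11] = 1          # inter 2, union 11 -> 0.2 (approx)
        lig2 = np.zeros(20); lig2[:7] = 1            # 7/10 = 0.7
        lig3 = np.zeros(20); lig3[:5] = 1            # 5/10 = 0.5
        sel = SimilarityStructureSelector().fit(
            np.vstack([lig1, lig2, lig3]), ["P1", "P2", "P3"]
        )
        assert sel.predict(query[None, :])[0] == "P2"

    def test_similarity_identity_and_degenerate(self):
        compound = CompoundRecord(
            "c", Activity.ACTIVE, features=FeatureVector("raw", np.array([1, 1, 0, 0]))
        )
        same = FeatureVector("raw", np.array([1, 1, 0, 0]))
        other = FeatureVector("raw", np.array([0, 0, 1, 1]))
        ensemble = [
            StructureEntry("SB", cocrystal_ligand_features=other),
            StructureEntry("SA", cocrystal_ligand_features=same),
        ]
        assert select_structure_similarity(compound, ensemble) == "SA"
        tied = [
            StructureEntry("SB", cocrystal_ligand_features=same),
            StructureEntry("SA", cocrystal_ligand_features=same),
        ]
        assert select_structure_similarity(compound, tied) == "SA"

    def test_no_ligand_anywhere_errors(self):
        compound = CompoundRecord(
            "c", Activity.ACTIVE, features=FeatureVector("raw", np.array([1, 0]))
        )
        with pytest.raises(ValueError, match="co-crystal"):
            select_structure_similarity(compound, [StructureEntry("S1")])
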