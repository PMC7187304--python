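"""Per-structure correctness classifiers and structure selection.

The central estimator is :class:`CorrectnessBattery`: one random-forest
classifier per protein structure, each trained to predict whether the
docking protocol will rank a given compound correctly on that structure.
Applied to a query compound, the battery returns one correctness probability
per structure; the compound is then docked only against the argmax
structure.  :class:`SimilarityStructureSelector` provides the ligand-
similarity baseline: pick the structure whose co-crystallized ligand is most
similar (Tanimoto) to the query.

Both follow the scikit-learn estimator protocol (``get_params``/
``set_params``, ``fit``, fitted attributes with trailing underscores) and
compose with sklearn model-selection tooling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import matthews_corrcoef
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_array, check_is_fitted

from .chem import CompoundRecord, FeatureVector, StructureEntry, bulk_tanimoto, featurize
from .sampling import smote_resample

logger = logging.getLogger(__name__)

__all__ = [
    "CorrectnessBattery",
    "SimilarityStructureSelector",
    "HyperparameterGrid",
    "GridSearchResult",
    "cv_fold_mcc",
    "grid_search_cv",
    "select_structure_aladdin",
    "select_structure_similarity",
    "save_battery",
    "load_battery",
]

BATTERY_FORMAT_VERSION = 1

# Desk-scale default forest size; the full exploration grid
# (50/100/500 trees x 6 max_features settings) is in HyperparameterGrid.
DEFAULT_N_ESTIMATORS = 100
DEFAULT_MAX_FEATURES = "sqrt"


def _as_label_frame(Y, structure_ids) -> pd.DataFrame:
    if isinstance(Y, pd.DataFrame):
        return Y.astype(int)
    Y = np.asarray(Y)
    if Y.ndim == 1:
        Y = Y[:, None]
    if structure_ids is None:
        structure_ids = [f"S{i}" for i in range(Y.shape[1])]
    return pd.DataFrame(Y.astype(int), columns=list(structure_ids))


class CorrectnessBattery(BaseEstimator):
    """One correctness classifier per protein structure.

    Parameters
    ----------
    n_estimators, max_features:
        Random-forest hyperparameters (shared across structures; the
        protocol selects one global setup per target).
    use_smote:
        Balance each structure's training labels by synthetic minority
        oversampling before the final fit (k = ``smote_k_neighbors``).
        Cross-validated model selection instead uses ``class_weight=
        'balanced'``; see :func:`grid_search_cv`.
    class_weight:
        Passed to the forests (``None`` when SMOTE already balanced the fit).
    random_state:
        Seeds SMOTE and every forest (per-structure child seeds).

    Attributes
    ----------
    structure_ids_ : list of retained structure ids, lexicographic order.
    estimators_ : dict structure_id -> fitted RandomForestClassifier.
    dropped_structures_ : structures excluded because their labels were
        single-class (degenerate docking columns).
    """

    def __init__(
        self,
        n_estimators: int = DEFAULT_N_ESTIMATORS,
        max_features="sqrt",
        use_smote: bool = True,
        smote_k_neighbors: int = 5,
        class_weight=None,
        random_state: int | None = 0,
    ):
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.use_smote = use_smote
        self.smote_k_neighbors = smote_k_neighbors
        self.class_weight = class_weight
        self.random_state = random_state

    def fit(self, X, Y, structure_ids: Sequence[str] | None = None):
        """Fit one classifier per structure.

        ``Y`` is an (n_compounds, n_structures) binary matrix of correctness
        labels (1 = correctly predicted by docking), as a DataFrame whose
        columns are structure ids or an array plus ``structure_ids``.
        """
        X = check_array(X)
        frame = _as_label_frame(Y, structure_ids)
        if frame.shape[0] != X.shape[0]:
            raise ValueError("X and Y have different numbers of compounds")
        rng = np.random.default_rng(self.random_state)
        self.estimators_ = {}
        self.dropped_structures_ = []
        for sid in sorted(frame.columns.astype(str)):
            y = frame[sid].to_numpy()
            if np.unique(y).size < 2:
                logger.warning("structure %s has single-class labels; dropped from battery", sid)
                self.dropped_structures_.append(sid)
                continue
            seed = int(rng.integers(0, 2**31 - 1))
            X_fit, y_fit = X, y
            if self.use_smote:
                X_fit, y_fit = smote_resample(
                    X, y, k_neighbors=self.smote_k_neighbors, random_state=seed
                )
            clf = RandomForestClassifier(
                n_estimators=self.n_estimators,
                max_features=self.max_features,
                class_weight=self.class_weight,
                random_state=seed,
                n_jobs=1,
            ).fit(X_fit, y_fit)
            self.estimators_[sid] = clf
        if not self.estimators_:
            raise ValueError("no structure retained: all label columns are single-class")
        self.structure_ids_ = sorted(self.estimators_)
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Probability of the "correctly predicted" class, per structure.

        Columns follow ``structure_ids_`` (lexicographic order).
        """
        check_is_fitted(self, "estimators_")
        X = check_array(X)
        cols = []
        for sid in self.structure_ids_:
            clf = self.estimators_[sid]
            idx = int(np.flatnonzero(clf.classes_ == 1)[0])
            cols.append(clf.predict_proba(X)[:, idx])
        return np.column_stack(cols)

    def predict(self, X) -> np.ndarray:
        """Selected structure id per compound: argmax correctness probability,
        exact ties broken toward the lexicographically smallest structure id."""
        proba = self.predict_proba(X)
        idx = proba.argmax(axis=1)  # first max = lexicographically smallest
        return np.asarray(self.structure_ids_, dtype=object)[idx]

    def proba_frame(self, X, index=None) -> pd.DataFrame:
        return pd.DataFrame(self.predict_proba(X), columns=self.structure_ids_, index=index)


class SimilarityStructureSelector(BaseEstimator):
    """Similarity-based structure selection baseline.

    ``fit`` takes the co-crystallized ligand fingerprints of the ensemble
    structures; ``predict`` assigns each query compound the structure whose
    ligand has the highest Tanimoto similarity to it (ties toward the
    lexicographically smallest structure id).
    """

    def __init__(self):
        pass

    def fit(self, ligand_fingerprints, structure_ids: Sequence[str]):
        L = check_array(ligand_fingerprints)
        if L.shape[0] != len(structure_ids):
            raise ValueError("one ligand fingerprint per structure required")
        if L.shape[0] == 0:
            raise ValueError("no structure with a co-crystallized ligand")
        order = np.argsort(np.asarray(structure_ids, dtype=object).astype(str))
        self.structure_ids_ = [str(structure_ids[i]) for i in order]
        self.ligand_fingerprints_ = L[order] > 0
        return self

    def decision_function(self, X) -> np.ndarray:
        """Tanimoto similarity of each query to each structure's ligand."""
        check_is_fitted(self, "ligand_fingerprints_")
        X = check_array(X) > 0
        return bulk_tanimoto(X, self.ligand_fingerprints_)

    def predict(self, X) -> np.ndarray:
        tc = self.decision_function(X)
        idx = tc.argmax(axis=1)
        return np.asarray(self.structure_ids_, dtype=object)[idx]


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------

_MAX_FEATURES_PRIORITY = {"sqrt": 0, 0.2: 1, 0.4: 2, 0.6: 3, 0.8: 4, None: 5}


@dataclass
class HyperparameterGrid:
    """Grid of descriptor sets and random-forest hyperparameters explored
    during cross-validated model selection."""

    descriptor_kinds: tuple[str, ...] = ("hashed_circular", "structural_keys", "physchem_2d")
    n_estimators: tuple[int, ...] = (50, 100, 500)
    max_features: tuple = ("sqrt", 0.2, 0.4, 0.6, 0.8, None)

    def __post_init__(self) -> None:
        if not (self.descriptor_kinds and self.n_estimators and self.max_features):
            raise ValueError("grid axes must be non-empty")

    def cells(self):
        for kind in self.descriptor_kinds:
            for n in self.n_estimators:
                for mf in self.max_features:
                    yield kind, n, mf


@dataclass
class GridSearchResult:
    descriptor_kind: str
    n_estimators: int
    max_features: object
    mean_mcc: float
    std_mcc: float
    table: pd.DataFrame = field(repr=False)


def cv_fold_mcc(
    X: np.ndarray,
    y: np.ndarray,
    n_estimators: int = DEFAULT_N_ESTIMATORS,
    max_features=DEFAULT_MAX_FEATURES,
    k_folds: int = 10,
    seed: int | None = 0,
) -> np.ndarray:
    """Fold-wise MCC of a class-weight-balanced random forest under
    stratified k-fold cross-validation (the model-selection criterion)."""
    X = np.asarray(X)
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if counts.size < 2 or counts.min() < k_folds:
        raise ValueError(
            f"need >= {k_folds} members per label class for {k_folds}-fold stratified CV"
        )
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    out = []
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        clf = RandomForestClassifier(
            n_estimators=n_estimators,
            max_features=max_features,
            class_weight="balanced",
            random_state=None if seed is None else seed + fold,
            n_jobs=1,
        ).fit(X[tr], y[tr])
        out.append(matthews_corrcoef(y[te], clf.predict(X[te])))
    return np.asarray(out)


def grid_search_cv(
    features_by_kind: Mapping[str, np.ndarray],
    label_frame: pd.DataFrame,
    grid: HyperparameterGrid,
    k_folds: int = 10,
    seed: int | None = 0,
) -> GridSearchResult:
    """Select one global modeling setup for a target.

    For every grid cell the fold-averaged MCC is computed per structure
    (class-weighted forests, stratified k-fold CV) and averaged over all
    structures' classifiers; the cell maximizing this structure-averaged MCC
    wins.  Ties break toward fewer trees, then toward 'sqrt' max_features.
    Structures whose labels are single-class are skipped.
    """
    rows = []
    for kind, n_est, mf in grid.cells():
        if kind not in features_by_kind:
            raise KeyError(f"no feature matrix provided for descriptor kind {kind!r}")
        X = features_by_kind[kind]
        fold_values = []
        for sid in label_frame.columns:
            y = label_frame[sid].to_numpy()
            if np.unique(y).size < 2:
                continue
            fold_values.append(cv_fold_mcc(X, y, n_est, mf, k_folds=k_folds, seed=seed))
        if not fold_values:
            raise ValueError("no structure has two label classes; grid search impossible")
        folds = np.concatenate(fold_values)
        rows.append(
            {
                "descriptor_kind": kind,
                "n_estimators": n_est,
                "max_features": mf,
                "mean_mcc": folds.mean(),
                "std_mcc": folds.std(ddof=0),
            }
        )
    table = pd.DataFrame(rows)
    ranked = sorted(
        rows,
        key=lambda r: (
            -r["mean_mcc"],
            r["n_estimators"],
            _MAX_FEATURES_PRIORITY.get(r["max_features"], 99),
        ),
    )
    best = ranked[0]
    return GridSearchResult(
        descriptor_kind=best["descriptor_kind"],
        n_estimators=best["n_estimators"],
        max_features=best["max_features"],
        mean_mcc=float(best["mean_mcc"]),
        std_mcc=float(best["std_mcc"]),
        table=table,
    )


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_battery(
    battery: CorrectnessBattery,
    path,
    *,
    fingerprint_config: dict | None = None,
    cv_table: pd.DataFrame | None = None,
    extra_manifest: dict | None = None,
) -> None:
    """Serialize a fitted battery to a directory: one model blob per
    structure under ``models/`` plus a YAML manifest (format version,
    hyperparameters, fingerprint config, CV MCC table)."""
    import joblib
    import yaml
    from pathlib import Path

    path = Path(path)
    (path / "models").mkdir(parents=True, exist_ok=True)
    check_is_fitted(battery, "estimators_")
    for sid, clf in battery.estimators_.items():
        joblib.dump(clf, path / "models" / f"{sid}.joblib")
    manifest = {
        "format_version": BATTERY_FORMAT_VERSION,
        "params": battery.get_params(),
        "structure_ids": battery.structure_ids_,
        "dropped_structures": battery.dropped_structures_,
        "n_features_in": int(battery.n_features_in_),
        "fingerprint_config": fingerprint_config or {},
    }
    if extra_manifest:
        manifest.update(extra_manifest)
    with open(path / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    if cv_table is not None:
        cv_table.to_csv(path / "cv_mcc.csv", index=False)


def load_battery(path) -> tuple[CorrectnessBattery, dict]:
    """Load a battery saved by :func:`save_battery`; returns (battery, manifest)."""
    import joblib
    import yaml
    from pathlib import Path

    path = Path(path)
    with open(path / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    if manifest.get("format_version") != BATTERY_FORMAT_VERSION:
        raise ValueError(f"unsupported battery format version {manifest.get('format_version')}")
    battery = CorrectnessBattery(**manifest["params"])
    battery.estimators_ = {
        sid: joblib.load(path / "models" / f"{sid}.joblib")
        for sid in manifest["structure_ids"]
    }
    battery.structure_ids_ = list(manifest["structure_ids"])
    battery.dropped_structures_ = list(manifest.get("dropped_structures", []))
    battery.n_features_in_ = int(manifest["n_features_in"])
    return battery, manifest


# ---------------------------------------------------------------------------
# Thin selection wrappers
# ---------------------------------------------------------------------------

def select_structure_aladdin(probabilities: Mapping[str, float]) -> str:
    """Structure with the highest correctness probability (lexicographic
    tiebreak)."""
    if not probabilities:
        raise ValueError("empty probability vector")
    return min(probabilities, key=lambda sid: (-probabilities[sid], sid))


def select_structure_similarity(
    compound: CompoundRecord,
    ensemble: Sequence[StructureEntry],
    *,
    kind: str = "hashed_circular",
    radius: int = 2,
    n_bits: int = 1024,
) -> str:
    """Structure whose co-crystallized ligand is most similar to the compound."""
    fps, sids = [], []
    for s in ensemble:
        if s.cocrystal_ligand_features is not None:
            fps.append(s.cocrystal_ligand_features.values)
            sids.append(s.structure_id)
        elif s.cocrystal_ligand_smiles is not None:
            from .chem import featurize_smiles

            fps.append(featurize_smiles(s.cocrystal_ligand_smiles, kind, radius=radius, n_bits=n_bits).values)
            sids.append(s.structure_id)
    if not fps:
        raise ValueError("no structure in the ensemble has a co-crystallized ligand")
    query = featurize(compound, kind if compound.smiles is not None else "raw", radius=radius, n_bits=n_bits)
    sel = SimilarityStructureSelector().fit(np.asarray(fps), sids)
    return str(sel.predict(query.values[None, :])[0])
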