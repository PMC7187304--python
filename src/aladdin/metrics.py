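"""Virtual-screening and classifier metrics.

ROC/AUC and enrichment factors evaluate ranked hit lists against known
activity classes; MCC and Y-scrambling evaluate the correctness
classifiers; selection diagnostics audit how a structure-selection method
distributes compounds over the ensemble.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import matthews_corrcoef, roc_curve

from .chem import Activity
from .scores import RankedHitList

__all__ = [
    "EvalReport",
    "roc_auc",
    "enrichment_factor",
    "mcc",
    "y_scramble",
    "selection_diagnostics",
    "evaluate_hitlist",
]

EF_FRACTIONS = (0.01, 0.05, 0.10)


@dataclass
class EvalReport:
    """Screening metrics for one method on one compound set."""

    method: str
    auc: float
    roc_points: tuple[np.ndarray, np.ndarray]  # (FPR, TPR)
    ef: dict[float, float]
    n_actives: int
    n_decoys: int
    selection_profile: pd.DataFrame | None = field(default=None, repr=False)

    def to_row(self) -> dict:
        row = {"method": self.method, "auc": self.auc, "n_actives": self.n_actives, "n_decoys": self.n_decoys}
        row.update({f"ef_{int(round(f * 100))}pct": v for f, v in self.ef.items()})
        return row


def _activity_array(hits: RankedHitList, classes: Mapping[str, Activity]) -> np.ndarray:
    return np.array(
        [1 if Activity(classes[cid]) is Activity.ACTIVE else 0 for cid in hits.compound_ids]
    )


def _decision_scores(hits: RankedHitList) -> np.ndarray:
    """Higher-is-better decision values; all missing scores tie at the worst."""
    s = hits.scores.astype(float)
    finite = np.isfinite(s)
    if not finite.any():
        raise ValueError("hit list has no scores at all")
    worst = s[finite].max() + 1.0
    return -np.where(finite, s, worst)


def roc_auc(
    hits: RankedHitList, classes: Mapping[str, Activity]
) -> tuple[float, np.ndarray, np.ndarray]:
    """ROC curve and AUC of a ranked hit list.

    AUC is the trapezoidal area under the ROC curve, which equals the
    Mann-Whitney pairwise concordance (ties between an active and a decoy
    contribute 0.5).  Compounds with missing scores all tie at the worst
    observed score.  Returns (auc, fpr, tpr).
    """
    y = _activity_array(hits, classes)
    if y.min() == y.max():
        raise ValueError("ROC needs both actives and decoys")
    scores = _decision_scores(hits)
    fpr, tpr, _ = roc_curve(y, scores)
    return float(_trapezoid_auc(fpr, tpr)), fpr, tpr


def enrichment_factor(
    hits: RankedHitList, classes: Mapping[str, Activity], fraction: float
) -> float:
    """Enrichment factor at a top fraction of the ranked list.

    EF_f = (active rate among the top ceil(f*N) compounds) / (library-wide
    active rate).  The ceiling keeps the top set non-empty for any f > 0.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    y = _activity_array(hits, classes)
    n = y.size
    n_actives = int(y.sum())
    if n_actives == 0 or n_actives == n:
        raise ValueError("enrichment factor needs both actives and decoys")
    top = math.ceil(fraction * n)
    hit_rate = y[:top].sum() / top
    base_rate = n_actives / n
    return float(hit_rate / base_rate)


def mcc(y_true, y_pred) -> float:
    """Matthews correlation coefficient; 0 when a confusion-matrix margin is
    empty (the standard zero-denominator convention)."""
    return float(matthews_corrcoef(np.asarray(y_true), np.asarray(y_pred)))


def y_scramble(
    X: np.ndarray,
    y: np.ndarray,
    *,
    n_estimators: int | None = None,
    max_features=None,
    k_folds: int = 10,
    n_repeats: int = 10,
    seed: int | None = 0,
) -> tuple[float, float, np.ndarray]:
    """Chance-correlation control: repeat cross-validated training on
    uniformly permuted labels.

    Per repeat the labels are shuffled (seeded), the cross-validated
    fold-averaged MCC is recomputed with the same protocol as model
    selection, and the mean and standard deviation over repeats are returned
    together with the per-repeat values.  A sound setup collapses to an MCC
    of about zero.
    """
    from .battery import DEFAULT_MAX_FEATURES, DEFAULT_N_ESTIMATORS, cv_fold_mcc

    n_estimators = DEFAULT_N_ESTIMATORS if n_estimators is None else n_estimators
    max_features = DEFAULT_MAX_FEATURES if max_features is None else max_features
    rng = np.random.default_rng(seed)
    y = np.asarray(y)
    means = []
    for rep in range(n_repeats):
        y_perm = rng.permutation(y)
        rep_seed = int(rng.integers(0, 2**31 - 1))
        folds = cv_fold_mcc(
            X, y_perm, n_estimators, max_features, k_folds=k_folds, seed=rep_seed
        )
        means.append(folds.mean())
    means = np.asarray(means)
    return float(means.mean()), float(means.std(ddof=0)), means


def selection_diagnostics(
    assignments: Sequence, classes: Mapping[str, Activity]
) -> pd.DataFrame:
    """Per-structure selection profile and active/decoy proportions.

    One row per selected structure: number of compounds routed to it, the
    number of actives among them and the active proportion.  Counts sum to
    the number of assigned compounds.
    """
    rows = []
    for a in assignments:
        if a.structure_id is None:
            raise ValueError("selection diagnostics need a selection-based method")
        rows.append(
            {
                "structure_id": a.structure_id,
                "active": Activity(classes[a.compound_id]) is Activity.ACTIVE,
            }
        )
    df = pd.DataFrame(rows)
    out = (
        df.groupby("structure_id")
        .agg(n_selected=("active", "size"), n_active=("active", "sum"))
        .reset_index()
    )
    out["active_proportion"] = out["n_active"] / out["n_selected"]
    return out.sort_values("structure_id", ignore_index=True)


def evaluate_hitlist(
    method: str,
    hits: RankedHitList,
    classes: Mapping[str, Activity],
    ef_fractions: Sequence[float] = EF_FRACTIONS,
    assignments: Sequence | None = None,
) -> EvalReport:
    """Full screening report (AUC, ROC points, EF at the requested
    fractions, optional selection diagnostics) for one method's hit list."""
    auc_value, fpr, tpr = roc_auc(hits, classes)
    y = _activity_array(hits, classes)
    profile = None
    if assignments is not None and assignments and assignments[0].structure_id is not None:
        profile = selection_diagnostics(assignments, classes)
    return EvalReport(
        method=method,
        auc=auc_value,
        roc_points=(fpr, tpr),
        ef={f: enrichment_factor(hits, classes, f) for f in ef_fractions},
        n_actives=int(y.sum()),
        n_decoys=int(y.size - y.sum()),
        selection_profile=profile,
    )
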