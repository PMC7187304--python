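"""Virtual-screening runs for the four structure-selection protocols.

Methods:

``aladdin``
    Each compound is docked only against the structure whose correctness
    classifier gives the highest probability (one dock call per compound
    under a live backend).
``similarity``
    Each compound is docked against the structure whose co-crystallized
    ligand is most similar to it.
``ensemble``
    All-against-all ensemble docking; per compound the best (lowest) score
    over all structures is kept.
``single:<structure_id>``
    Conventional single-structure docking against one fixed structure.

All methods end in the same place: a rank-ordered hit list of the screened
library by final score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .battery import CorrectnessBattery, SimilarityStructureSelector
from .chem import CompoundRecord, StructureEntry, feature_matrix
from .scores import DockingBackend, RankedHitList, ScoreMatrix, _ranked_from_series

__all__ = ["SelectionAssignment", "ScreenResult", "run_screen"]

METHODS = ("aladdin", "similarity", "ensemble")


@dataclass
class SelectionAssignment:
    """Outcome of structure selection for one compound.

    ``statistic`` is the selection statistic: the max correctness
    probability (aladdin), the max ligand Tanimoto (similarity), or None for
    methods that do not select.  ``structure_id`` is None for ensemble.
    ``score`` is the compound's final screen score (NaN when docking failed).
    """

    compound_id: str
    method: str
    structure_id: str | None
    statistic: float | None
    score: float


@dataclass
class ScreenResult:
    method: str
    assignments: list[SelectionAssignment]
    hits: RankedHitList
    failures: list[str] = field(default_factory=list)

    def assignments_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "compound_id": a.compound_id,
                    "method": a.method,
                    "structure_id": a.structure_id,
                    "statistic": a.statistic,
                    "score": a.score,
                }
                for a in self.assignments
            ]
        )


def _validate(method, compounds, battery, similarity, matrix, backend, structures):
    if not compounds:
        raise ValueError("empty compound set")
    if matrix is None and backend is None:
        raise ValueError("a score matrix or a docking backend is required")
    if backend is not None and structures is None:
        raise ValueError("live-backend mode needs the structure ensemble")
    if method == "aladdin" and battery is None:
        raise ValueError("method 'aladdin' needs a fitted CorrectnessBattery")
    if method == "similarity" and similarity is None:
        raise ValueError("method 'similarity' needs a fitted SimilarityStructureSelector")
    if method.startswith("single:") and not method.split(":", 1)[1]:
        raise ValueError("method 'single:' needs a structure id")
    if not (method in METHODS or method.startswith("single:")):
        raise ValueError(f"unknown screening method {method!r}")


def _score_lookup(compound, sid, matrix, backend, structure_by_id):
    if backend is not None:
        val = backend.dock(compound, structure_by_id[sid])
        return float("nan") if val is None else float(val)
    return matrix.score(compound.compound_id, sid)


def run_screen(
    method: str,
    compounds: Sequence[CompoundRecord],
    *,
    battery: CorrectnessBattery | None = None,
    similarity: SimilarityStructureSelector | None = None,
    matrix: ScoreMatrix | None = None,
    backend: DockingBackend | None = None,
    structures: Sequence[StructureEntry] | None = None,
    structure_ids: Sequence[str] | None = None,
    features: np.ndarray | None = None,
    feature_kind: str = "raw",
) -> ScreenResult:
    """Screen a compound set with one method and rank the outcome.

    Scores come from ``matrix`` (precomputed mode, the default) or from
    ``backend`` (live mode; selection-based methods then issue exactly one
    dock call per compound, ensemble one per compound-structure pair).
    ``structure_ids`` restricts the ensemble (e.g. to the structures the
    battery retained); ``features`` is the precomputed feature matrix
    aligned with ``compounds`` for the aladdin/similarity selectors,
    computed on the fly from ``feature_kind`` when absent.
    """
    compounds = list(compounds)
    _validate(method, compounds, battery, similarity, matrix, backend, structures)

    structure_by_id = {s.structure_id: s for s in structures} if structures else {}
    if structure_ids is None:
        if method == "aladdin":
            structure_ids = list(battery.structure_ids_)
        elif structures is not None:
            structure_ids = [s.structure_id for s in structures]
        elif matrix is not None:
            structure_ids = matrix.structure_ids
    structure_ids = [str(s) for s in structure_ids]

    needs_features = method in ("aladdin", "similarity")
    if needs_features and features is None:
        features = feature_matrix(compounds, feature_kind)

    assignments: list[SelectionAssignment] = []
    if method == "aladdin":
        proba = battery.predict_proba(features)
        keep = [i for i, sid in enumerate(battery.structure_ids_) if sid in set(structure_ids)]
        sids = [battery.structure_ids_[i] for i in keep]
        proba = proba[:, keep]
        sel_idx = proba.argmax(axis=1)
        for i, c in enumerate(compounds):
            sid = sids[int(sel_idx[i])]
            assignments.append(
                SelectionAssignment(
                    c.compound_id, method, sid, float(proba[i].max()),
                    _score_lookup(c, sid, matrix, backend, structure_by_id),
                )
            )
    elif method == "similarity":
        tc = similarity.decision_function(features)
        sel = similarity.predict(features)
        for i, c in enumerate(compounds):
            sid = str(sel[i])
            assignments.append(
                SelectionAssignment(
                    c.compound_id, method, sid, float(tc[i].max()),
                    _score_lookup(c, sid, matrix, backend, structure_by_id),
                )
            )
    elif method == "ensemble":
        for c in compounds:
            col = [
                _score_lookup(c, sid, matrix, backend, structure_by_id) for sid in structure_ids
            ]
            arr = np.asarray(col, dtype=float)
            best = float(np.nanmin(arr)) if np.isfinite(arr).any() else float("nan")
            assignments.append(SelectionAssignment(c.compound_id, method, None, None, best))
    else:  # single:<sid>
        sid = method.split(":", 1)[1]
        if sid not in structure_ids:
            raise ValueError(f"structure {sid!r} not in the ensemble")
        for c in compounds:
            assignments.append(
                SelectionAssignment(
                    c.compound_id, method, sid, None,
                    _score_lookup(c, sid, matrix, backend, structure_by_id),
                )
            )

    series = pd.Series(
        {a.compound_id: a.score for a in assignments}, dtype=float
    )
    hits = _ranked_from_series(series)
    failures = [a.compound_id for a in assignments if not np.isfinite(a.score)]
    return ScreenResult(method=method, assignments=assignments, hits=hits, failures=failures)
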