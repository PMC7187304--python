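"""Docking score matrices, ranking, ensemble aggregation and backend contract.

Scores follow binding-free-energy semantics throughout: lower (more
negative) is more favorable.  Missing scores (failed docking runs) are kept
explicitly as NaN, never coerced to a number, and rank after every scored
compound.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Protocol, Sequence, runtime_checkable

import numpy as np
import pandas as pd

from .chem import CompoundRecord, StructureEntry

logger = logging.getLogger(__name__)

__all__ = [
    "ScoreMatrix",
    "RankedHitList",
    "DockingBackend",
    "CsvScoreBackend",
    "CountingBackend",
    "collapse_representations",
    "rank_compounds",
    "ensemble_best_score",
]


def collapse_representations(raw_scores: Iterable[float | None], favor: str = "best") -> float:
    """Collapse per-representation (tautomer/protomer) scores to one score.

    The default keeps the most favorable (numerically lowest) score obtained
    with any representation of the molecule; ``favor="worst"`` keeps the
    highest.  All-missing input collapses to missing (NaN).
    """
    vals = [s for s in raw_scores if s is not None and np.isfinite(s)]
    if not vals:
        return float("nan")
    return float(min(vals) if favor == "best" else max(vals))


@dataclass
class RankedHitList:
    """A rank-ordered hit list for one screen (best score first).

    Ranks are 1-based; ties are broken by compound_id lexicographically and
    compounds with missing scores are placed after all scored compounds,
    ordered by compound_id.
    """

    compound_ids: list[str]
    scores: np.ndarray  # aligned with compound_ids; NaN = missing

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.compound_ids) != self.scores.size:
            raise ValueError("compound_ids and scores lengths differ")

    @property
    def ranks(self) -> dict[str, int]:
        return {cid: i + 1 for i, cid in enumerate(self.compound_ids)}

    def __len__(self) -> int:
        return len(self.compound_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "compound_id": self.compound_ids,
                "rank": np.arange(1, len(self) + 1),
                "score": self.scores,
            }
        )


def _ranked_from_series(series: pd.Series) -> RankedHitList:
    series = series.copy()
    series.index = series.index.astype(str)
    order = sorted(
        series.index,
        key=lambda cid: (
            (0, float(series[cid])) if np.isfinite(series[cid]) else (1, 0.0),
            cid,
        ),
    )
    return RankedHitList(order, series.loc[order].to_numpy(dtype=float))


@dataclass
class ScoreMatrix:
    """Compound × structure docking score matrix (lower = better; NaN = missing)."""

    frame: pd.DataFrame
    raw: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        vals = self.frame.to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise ValueError("scores must be finite or missing (NaN)")
        if self.frame.index.has_duplicates or self.frame.columns.has_duplicates:
            raise ValueError("duplicate compound or structure ids")
        self.frame = self.frame.rename_axis(index="compound_id", columns="structure_id")

    @property
    def compound_ids(self) -> list[str]:
        return [str(c) for c in self.frame.index]

    @property
    def structure_ids(self) -> list[str]:
        return [str(s) for s in self.frame.columns]

    # -- constructors -------------------------------------------------------
    @classmethod
    def from_long(cls, long: pd.DataFrame, favor: str = "best") -> "ScoreMatrix":
        """Build from long form ``compound_id, structure_id, representation_id, score``.

        Scores of multiple representations of one compound are collapsed to
        the single most favorable score before pivoting.
        """
        required = {"compound_id", "structure_id", "score"}
        if not required <= set(long.columns):
            raise ValueError(f"long score table needs columns {sorted(required)}")
        long = long.copy()
        long["compound_id"] = long["compound_id"].astype(str)
        long["structure_id"] = long["structure_id"].astype(str)
        long["score"] = pd.to_numeric(long["score"], errors="coerce")
        collapsed = (
            long.groupby(["compound_id", "structure_id"])["score"]
            .apply(lambda s: collapse_representations(s.tolist(), favor=favor))
            .reset_index()
        )
        frame = collapsed.pivot(index="compound_id", columns="structure_id", values="score")
        return cls(frame=frame, raw=long)

    @classmethod
    def from_csv(cls, path: str | Path, favor: str = "best") -> "ScoreMatrix":
        long = pd.read_csv(path, dtype={"compound_id": str, "structure_id": str})
        return cls.from_long(long, favor=favor)

    def to_csv(self, path: str | Path) -> None:
        frame = self.frame.rename_axis(index="compound_id", columns=None)
        long = frame.reset_index().melt(
            id_vars="compound_id", var_name="structure_id", value_name="score"
        )
        long["representation_id"] = long["compound_id"] + "/0"
        long[["compound_id", "structure_id", "representation_id", "score"]].to_csv(
            path, index=False
        )

    # -- views --------------------------------------------------------------
    def restrict(self, compound_ids: Sequence[str]) -> "ScoreMatrix":
        missing = set(compound_ids) - set(self.compound_ids)
        if missing:
            raise KeyError(f"unknown compound ids: {sorted(missing)[:5]}")
        return ScoreMatrix(frame=self.frame.loc[list(compound_ids)].copy())

    def column(self, structure_id: str) -> pd.Series:
        if structure_id not in self.frame.columns:
            raise KeyError(f"unknown structure id {structure_id!r}")
        return self.frame[structure_id]

    def score(self, compound_id: str, structure_id: str) -> float:
        return float(self.frame.at[compound_id, structure_id])


def rank_compounds(matrix: ScoreMatrix, structure_id: str) -> RankedHitList:
    """Rank one structure's column, most favorable (lowest) score first."""
    col = matrix.column(structure_id)
    if col.isna().all():
        raise ValueError(f"structure {structure_id!r} has no scores at all")
    return _ranked_from_series(col)


def ensemble_best_score(matrix: ScoreMatrix) -> tuple[pd.Series, list[str]]:
    """Best (lowest) score per compound over all structures.

    This is the conventional all-against-all ensemble reduction.  Compounds
    with no score on any structure are excluded with a warning and returned
    as the second element.
    """
    best = matrix.frame.min(axis=1, skipna=True)
    excluded = [str(c) for c in best.index[best.isna()]]
    if excluded:
        logger.warning("%d compounds have no score on any structure; excluded", len(excluded))
    return best.dropna(), excluded


# ---------------------------------------------------------------------------
# Docking backend contract
# ---------------------------------------------------------------------------

@runtime_checkable
class DockingBackend(Protocol):
    """A docking engine: pure function of (compound, structure, backend config)."""

    def dock(self, compound: CompoundRecord, structure: StructureEntry) -> float | None:
        """Return a finite lower-is-better score, or None on docking failure."""


class CsvScoreBackend:
    """Backend serving precomputed scores from a ScoreMatrix (e.g. a docking
    engine's exported CSV)."""

    def __init__(self, matrix: ScoreMatrix):
        self.matrix = matrix

    def dock(self, compound: CompoundRecord, structure: StructureEntry) -> float | None:
        try:
            val = self.matrix.score(compound.compound_id, structure.structure_id)
        except KeyError:
            return None
        return None if np.isnan(val) else val


class CountingBackend:
    """Wraps a backend and counts dock calls (efficiency audits)."""

    def __init__(self, inner: DockingBackend):
        self.inner = inner
        self.n_calls = 0

    def dock(self, compound: CompoundRecord, structure: StructureEntry) -> float | None:
        self.n_calls += 1
        return self.inner.dock(compound, structure)
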