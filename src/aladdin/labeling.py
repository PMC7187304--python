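"""Rank-based docking-correctness labels.

For one protein structure's rank-ordered hit list, a compound is labeled
"correct" when the docking rank classifies it correctly: actives that reach
a high rank (rank <= n, with n the number of actives in the labeled set) and
decoys that stay at a low rank (rank > n).  Actives at low ranks and decoys
at high ranks are "incorrect".  These binary labels are what the
per-structure correctness classifiers learn.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .chem import Activity
from .scores import RankedHitList

__all__ = ["CorrectnessLabelSet", "assign_correctness_labels"]

CORRECT = "correct"
INCORRECT = "incorrect"


@dataclass
class CorrectnessLabelSet:
    """Binary correctness labels for one structure's hit list.

    ``provenance`` records, per compound, the (rank, activity_class) pair the
    label was derived from.
    """

    structure_id: str
    n_actives: int
    labels: dict[str, str]
    provenance: dict[str, tuple[int, Activity]]

    def label_array(self, compound_ids) -> list[int]:
        """Labels as ints (1 = correct) in the given compound order."""
        return [1 if self.labels[cid] == CORRECT else 0 for cid in compound_ids]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "structure_id": self.structure_id,
                "compound_id": cid,
                "activity_class": self.provenance[cid][1].value,
                "rank": self.provenance[cid][0],
                "label": lab,
            }
            for cid, lab in self.labels.items()
        ]
        return pd.DataFrame(rows).sort_values("rank", ignore_index=True)


def assign_correctness_labels(
    hits: RankedHitList,
    classes: Mapping[str, Activity],
    structure_id: str = "",
) -> CorrectnessLabelSet:
    """Apply the four-way rank/activity labeling rule to one hit list.

    The rank threshold n is the number of actives actually present in the
    ranked list (compounds with missing scores are ranked last and labeled
    like any low-ranked compound).  By construction exactly n compounds hold
    high ranks, hence the number of misranked actives always equals the
    number of misranked decoys; this count invariant is asserted on every
    call.
    """
    ranks = hits.ranks
    missing = [cid for cid in hits.compound_ids if cid not in classes]
    if missing:
        raise KeyError(f"no activity class for compounds: {missing[:5]}")
    n = sum(1 for cid in hits.compound_ids if Activity(classes[cid]) is Activity.ACTIVE)
    if n == 0:
        raise ValueError("labeling needs at least one active (rank threshold undefined)")

    labels: dict[str, str] = {}
    provenance: dict[str, tuple[int, Activity]] = {}
    for cid in hits.compound_ids:
        rank = ranks[cid]
        cls = Activity(classes[cid])
        high = rank <= n
        correct = (cls is Activity.ACTIVE) == high
        labels[cid] = CORRECT if correct else INCORRECT
        provenance[cid] = (rank, cls)

    bad_actives = sum(
        1 for cid, lab in labels.items() if lab == INCORRECT and provenance[cid][1] is Activity.ACTIVE
    )
    bad_decoys = sum(
        1 for cid, lab in labels.items() if lab == INCORRECT and provenance[cid][1] is Activity.DECOY
    )
    assert bad_actives == bad_decoys, "count invariant violated: misranked actives != misranked decoys"
    return CorrectnessLabelSet(
        structure_id=structure_id, n_actives=n, labels=labels, provenance=provenance
    )
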