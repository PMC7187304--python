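"""Synthetic minority oversampling (SMOTE) for the final classifier fits.

Minority-class samples are augmented by interpolation: a synthetic point is
drawn on the segment between a minority sample and one of its k nearest
minority-class neighbours (Euclidean metric, k = 5 by default, matching the
original algorithm), until the classes are balanced.  Fully seeded.
"""

from __future__ import annotations

import numpy as np
from sklearn.neighbors import NearestNeighbors

__all__ = ["smote_resample"]


def smote_resample(
    X: np.ndarray,
    y: np.ndarray,
    k_neighbors: int = 5,
    random_state: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Oversample the minority class of a binary problem to parity.

    Returns (X_resampled, y_resampled) with the original samples first and
    synthetic minority samples appended.  With fewer than 2 minority samples
    interpolation is impossible and a ValueError is raised; ``k_neighbors``
    is clipped to the number of available neighbours.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError(f"smote_resample needs exactly 2 classes, got {classes.size}")
    if counts[0] == counts[1]:
        return X.copy(), y.copy()
    rng = (
        random_state
        if isinstance(random_state, np.random.Generator)
        else np.random.default_rng(random_state)
    )
    minority = classes[np.argmin(counts)]
    n_needed = int(abs(counts[0] - counts[1]))
    X_min = X[y == minority]
    if X_min.shape[0] < 2:
        raise ValueError("minority class too small for SMOTE interpolation")
    k = min(k_neighbors, X_min.shape[0] - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min)
    # first neighbour is the point itself
    neighbour_idx = nn.kneighbors(X_min, return_distance=False)[:, 1:]

    base = rng.integers(0, X_min.shape[0], size=n_needed)
    pick = rng.integers(0, k, size=n_needed)
    gap = rng.random(n_needed)[:, None]
    partners = neighbour_idx[base, pick]
    X_new = X_min[base] + gap * (X_min[partners] - X_min[base])
    return (
        np.vstack([X, X_new]),
        np.concatenate([y, np.full(n_needed, minority, dtype=y.dtype)]),
    )
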