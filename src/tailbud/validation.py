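"""Helpers for scoring recovered objects against ground truth."""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

__all__ = ["match_centroids"]


def match_centroids(
    true_xyz: np.ndarray, found_xyz: np.ndarray, max_dist_um: float
) -> tuple[int, list[tuple[int, int]]]:
    """One-to-one matching of found centroids to true centroids.

    Solves the assignment minimising total distance and keeps pairs
    closer than ``max_dist_um``.  Returns ``(n_matched, pairs)`` where
    each pair is ``(true_index, found_index)``.
    """
    true_xyz = np.atleast_2d(np.asarray(true_xyz, dtype=float))
    found_xyz = np.atleast_2d(np.asarray(found_xyz, dtype=float))
    if true_xyz.size == 0 or found_xyz.size == 0:
        return 0, []
    d = cdist(true_xyz, found_xyz)
    rows, cols = linear_sum_assignment(d)
    pairs = [(int(r), int(c)) for r, c in zip(rows, cols) if d[r, c] <= max_dist_um]
    return len(pairs), pairs
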