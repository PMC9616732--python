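"""Sequence-memory scoring and the sleep retention measure.

Sequence performance for one retrieval block is the correlation between the
order in which the participant placed the n objects and the correct
ascending order 1..n.  Because both vectors are permutations (rank vectors),
Pearson and Spearman correlation coincide.  Scores are Fisher z-transformed;
retention is the post-sleep score as a percentage of the pre-sleep score,
100 * (post / pre).
"""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger(__name__)

#: |r| is clipped to 1 - CLIP before atanh so perfect orders stay finite.
CLIP = 1e-6


def fisher_z(r: float | np.ndarray) -> float | np.ndarray:
    """atanh with |r| clipped to 1 - 1e-6 (keeps r = +-1 finite)."""
    return np.arctanh(np.clip(r, -1 + CLIP, 1 - CLIP))


def sequence_score(selected_order) -> float:
    """Fisher-z correlation of a retrieval order with the correct order.

    ``selected_order[i]`` is the object (1..n) placed at position i+1.
    Raises on inputs that are not a permutation of 1..n (n >= 3).
    """
    order = np.asarray(selected_order)
    n = order.size
    if n < 3 or not np.array_equal(np.sort(order), np.arange(1, n + 1)):
        raise ValueError("input must be a permutation of 1..n with n >= 3")
    r = np.corrcoef(order, np.arange(1, n + 1))[0, 1]
    return float(fisher_z(r))


def retention(pre_z: float, post_z: float) -> float:
    """Retention percentage 100 * (post / pre); NaN when pre <= 0.

    A non-positive pre-sleep score means there is no meaningful baseline to
    retain against; such participants are flagged missing.
    """
    if not pre_z > 0:
        logger.warning("non-positive pre-sleep score %.3f: retention "
                       "undefined", pre_z)
        return float("nan")
    return 100.0 * post_z / pre_z
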