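"""Sliding-window majority-vote smoothing of raw per-base adapter labels.

Each position's final label is the strict-majority vote of the *raw* model
labels in a window of odd width ``W`` centered on it (no iterative
propagation): position ``i`` becomes 1 when the windowed sum of raw labels
exceeds half the window size. Near the read ends the window is truncated to
the valid indices and the threshold is half the truncated window size, so no
phantom labels are invented beyond the read.
"""

from __future__ import annotations

import numpy as np

DEFAULT_WINDOW = 21


def refine(raw_labels, window: int = DEFAULT_WINDOW) -> np.ndarray:
    """Majority-vote smoothing of a 0/1 label track.

    ``window`` must be odd; ``window == 1`` is the identity. The vote is
    strict (sum > size/2), so an exact half -- possible only in truncated
    even-size boundary windows -- votes 0. Output depends only on the raw
    input labels.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError(
            f"window must be an odd positive integer, got {window}; "
            "choose an odd value such as 11, 21 or 31"
        )
    labels = np.asarray(raw_labels)
    if labels.ndim != 1:
        raise ValueError("labels must be one-dimensional")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    n = labels.size
    if n == 0:
        return np.zeros(0, dtype=np.uint8)
    if window == 1:
        return labels.astype(np.uint8).copy()
    k = (window - 1) // 2
    csum = np.concatenate([[0], np.cumsum(labels, dtype=np.int64)])
    idx = np.arange(n)
    lo = np.maximum(idx - k, 0)
    hi = np.minimum(idx + k, n - 1)
    window_sum = csum[hi + 1] - csum[lo]
    window_size = hi - lo + 1
    return (2 * window_sum > window_size).astype(np.uint8)
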