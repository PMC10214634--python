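"""Half-open interval arithmetic.

All intervals are 0-based, half-open ``[start, end)`` pairs of integers, the
BED convention. Interval sets are ``(m, 2)`` integer arrays sorted by start.
"""

from __future__ import annotations

import numpy as np

__all__ = ["as_array", "merge", "total_length", "covered_length", "clip"]


def as_array(intervals) -> np.ndarray:
    """Coerce a list of (start, end) pairs into an (m, 2) int64 array."""
    arr = np.asarray(intervals, dtype=np.int64)
    if arr.size == 0:
        return arr.reshape(0, 2)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("interval set must be an (m, 2) array")
    return arr


def merge(intervals) -> np.ndarray:
    """Sort and union overlapping/adjacent intervals."""
    arr = as_array(intervals)
    if len(arr) == 0:
        return arr
    arr = arr[np.argsort(arr[:, 0], kind="stable")]
    out = [list(arr[0])]
    for s, e in arr[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out, dtype=np.int64)


def total_length(intervals) -> int:
    arr = merge(intervals)
    if len(arr) == 0:
        return 0
    return int((arr[:, 1] - arr[:, 0]).sum())


def clip(intervals, start: int, end: int) -> np.ndarray:
    """Intersect a merged interval set with the window [start, end)."""
    arr = merge(intervals)
    if len(arr) == 0:
        return arr
    s = np.clip(arr[:, 0], start, end)
    e = np.clip(arr[:, 1], start, end)
    keep = e > s
    return np.stack([s[keep], e[keep]], axis=1)


def covered_length(intervals, start: int, end: int) -> int:
    """Length of the union of ``intervals`` that falls inside [start, end)."""
    c = clip(intervals, start, end)
    if len(c) == 0:
        return 0
    return int((c[:, 1] - c[:, 0]).sum())
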