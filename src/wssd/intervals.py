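"""Half-open genomic interval arithmetic on (n, 2) integer arrays.

All coordinates are 0-based, half-open. Functions accept anything
convertible to an (n, 2) int array and return sorted, merged arrays.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "as_intervals",
    "merge",
    "union_length",
    "intersect",
    "subtract",
    "clip",
    "coverage_mask",
]


def as_intervals(iv) -> np.ndarray:
    """Coerce to an (n, 2) int64 array; empty input yields shape (0, 2)."""
    arr = np.asarray(iv, dtype=np.int64)
    if arr.size == 0:
        return arr.reshape(0, 2)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(f"expected (n, 2) intervals, got shape {arr.shape}")
    if np.any(arr[:, 0] > arr[:, 1]):
        raise ValueError("interval start > end")
    return arr


def merge(iv, abut: bool = True) -> np.ndarray:
    """Sort and merge overlapping (and, by default, abutting) intervals."""
    arr = as_intervals(iv)
    arr = arr[arr[:, 0] != arr[:, 1]]  # drop empty
    if len(arr) == 0:
        return arr
    arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
    out = []
    cur_s, cur_e = arr[0]
    for s, e in arr[1:]:
        joined = s <= cur_e if abut else s < cur_e
        if joined:
            cur_e = max(cur_e, e)
        else:
            out.append((cur_s, cur_e))
            cur_s, cur_e = s, e
    out.append((cur_s, cur_e))
    return np.array(out, dtype=np.int64)


def union_length(iv) -> int:
    m = merge(iv)
    if len(m) == 0:
        return 0
    return int((m[:, 1] - m[:, 0]).sum())


def intersect(a, b) -> np.ndarray:
    """Intersection of two interval sets (each merged first)."""
    a = merge(a)
    b = merge(b)
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if s < e:
            out.append((s, e))
        if a[i, 1] < b[j, 1]:
            i += 1
        else:
            j += 1
    return np.array(out, dtype=np.int64).reshape(-1, 2)


def subtract(a, b) -> np.ndarray:
    """Parts of interval set ``a`` not covered by ``b``."""
    a = merge(a)
    b = merge(b)
    if len(a) == 0 or len(b) == 0:
        return a
    out = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j, 1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k, 0] < e:
            if b[k, 0] > cur:
                out.append((cur, b[k, 0]))
            cur = max(cur, b[k, 1])
            k += 1
        if cur < e:
            out.append((cur, e))
    return np.array(out, dtype=np.int64).reshape(-1, 2)


def clip(iv, lo: int, hi: int) -> np.ndarray:
    """Clip intervals to [lo, hi), dropping those that fall outside."""
    arr = as_intervals(iv)
    if len(arr) == 0:
        return arr
    arr = np.clip(arr, lo, hi)
    return arr[arr[:, 0] < arr[:, 1]]


def coverage_mask(iv, length: int) -> np.ndarray:
    """Boolean per-base coverage array of the given length."""
    mask = np.zeros(length, dtype=bool)
    for s, e in clip(iv, 0, length):
        mask[s:e] = True
    return mask
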