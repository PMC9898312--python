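"""Vectorised sampling of many uniform k-subsets without replacement.

The permutation nulls need B independent size-k gene subsets per pathway
size.  For k much smaller than the universe size n, drawing with replacement
and keeping the first k distinct indices in draw order is a uniform k-subset
(the values are exchangeable, so the retained set's law depends only on the
set), and costs O(B * k log k) instead of the O(B * n) of shuffling the whole
universe per replicate.
"""

from __future__ import annotations

import math

import numpy as np


def sample_index_subsets(rng: np.random.Generator, n: int, k: int,
                         b: int) -> np.ndarray:
    """Return a (b, k) integer array; each row a uniform k-subset of range(n).

    Rows are independent.  Column order within a row is arbitrary.
    """
    if not (1 <= k <= n):
        raise ValueError(f"need 1 <= k <= n, got k={k}, n={n}")
    if b < 1:
        raise ValueError("b must be >= 1")
    if k == n:
        return np.tile(np.arange(n), (b, 1))
    if 4 * k > n:
        # dense regime: k smallest of n random keys per row
        keys = rng.random((b, n))
        return np.argpartition(keys, kth=k - 1, axis=1)[:, :k]
    return _sparse_subsets(rng, n, k, b)


def _sparse_subsets(rng, n, k, b):
    # oversample enough that >= k distinct values per row is near-certain
    dup = k * k / n
    m = k + max(8, int(dup + 4 * math.sqrt(dup + 1) + 4))
    out = np.empty((b, k), dtype=np.int64)
    rows = np.arange(b)
    while rows.size:
        idx = rng.integers(0, n, size=(rows.size, m))
        order = np.argsort(idx, axis=1, kind="stable")
        svals = np.take_along_axis(idx, order, axis=1)
        first_sorted = np.ones_like(svals, dtype=bool)
        first_sorted[:, 1:] = svals[:, 1:] != svals[:, :-1]
        # stable sort => the first of each equal run is the earliest draw,
        # so mapping the flags back marks "first occurrence in draw order"
        keep = np.empty_like(first_sorted)
        np.put_along_axis(keep, order, first_sorted, axis=1)
        cnt = np.cumsum(keep, axis=1)
        good = cnt[:, -1] >= k
        if good.any():
            sel = keep[good] & (cnt[good] <= k)
            out[rows[good]] = idx[good][sel].reshape(-1, k)
        rows = rows[~good]
    return out
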