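"""Levenshtein distance engines.

Two flavours are needed by the pipeline:

* global distance between equal-role sequences (barcode set filtering);
* infix (semi-global) distance of a short pattern against a longer text,
  with free leading/trailing text — the primitive behind error-tolerant
  barcode location at read termini.

Both are vectorised row-wise with numpy.  The inner ``D[i][j-1] + 1``
dependency is eliminated with the prefix-minimum identity
``D[i][j] = min_{k<=j} (T[i][k] + j - k)`` where ``T`` holds the two
row-(i-1) branches, which is exact for unit indel costs.
"""

from __future__ import annotations

import numpy as np


def _byte_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _row_update(D: np.ndarray, cost: np.ndarray, first: np.ndarray) -> np.ndarray:
    """One DP row: D is (..., n+1), cost (..., n), first the new D[..., 0]."""
    T = np.minimum(D[..., 1:] + 1, D[..., :-1] + cost)
    T = np.concatenate([first[..., None], T], axis=-1)
    j = np.arange(T.shape[-1])
    return np.minimum.accumulate(T - j, axis=-1) + j


def levenshtein(a: str, b: str) -> int:
    """Global edit distance between two strings."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    av, bv = _byte_array(a), _byte_array(b)
    D = np.arange(len(bv) + 1)
    for i in range(1, len(av) + 1):
        cost = (bv != av[i - 1]).astype(np.int64)
        D = _row_update(D, cost, np.asarray(i))
    return int(D[-1])


def levenshtein_batch(query: str, targets: list[str]) -> np.ndarray:
    """Global edit distance from ``query`` to each equal-length target."""
    if not targets:
        return np.zeros(0, dtype=np.int64)
    n = len(targets[0])
    if any(len(t) != n for t in targets):
        raise ValueError("batch targets must share a common length")
    tv = np.vstack([_byte_array(t) for t in targets])
    qv = _byte_array(query)
    B = tv.shape[0]
    D = np.broadcast_to(np.arange(n + 1), (B, n + 1)).copy()
    for i in range(1, len(qv) + 1):
        cost = (tv != qv[i - 1]).astype(np.int64)
        D = _row_update(D, cost, np.full(B, i))
    return D[:, -1]


def infix_distance_batch(patterns: list[str], text: str) -> np.ndarray:
    """Minimal semi-global distance of each pattern inside ``text``.

    The pattern is consumed entirely; any prefix/suffix of ``text`` is
    free.  All patterns must share one length.  Returns one distance per
    pattern (min over all placements).
    """
    if not patterns:
        return np.zeros(0, dtype=np.int64)
    m = len(patterns[0])
    if any(len(p) != m for p in patterns):
        raise ValueError("batch patterns must share a common length")
    if not text:
        return np.full(len(patterns), m, dtype=np.int64)
    pv = np.vstack([_byte_array(p) for p in patterns])
    tv = _byte_array(text)
    B, n = pv.shape[0], len(tv)
    D = np.zeros((B, n + 1), dtype=np.int64)
    for i in range(1, m + 1):
        cost = (tv[None, :] != pv[:, i - 1, None]).astype(np.int64)
        D = _row_update(D, cost, np.full(B, i))
    return D.min(axis=1)


def _infix_end(pattern: str, text: str) -> tuple[int, int]:
    """(distance, end) of the best placement of pattern inside text."""
    d = _infix_row(pattern, text)
    end = int(np.argmin(d))
    return int(d[end]), end


def _infix_row(pattern: str, text: str) -> np.ndarray:
    pv, tv = _byte_array(pattern), _byte_array(text)
    D = np.zeros(len(tv) + 1, dtype=np.int64)
    for i in range(1, len(pv) + 1):
        cost = (tv != pv[i - 1]).astype(np.int64)
        D = _row_update(D, cost, np.asarray(i))
    return D


def infix_locate(pattern: str, text: str) -> tuple[int, int, int]:
    """Best infix placement of ``pattern`` in ``text``.

    Returns ``(distance, start, end)`` with ``text[start:end]`` the
    matched segment.  Ties break toward the leftmost end position, then
    the longest segment.
    """
    if not pattern:
        return 0, 0, 0
    if not text:
        return len(pattern), 0, 0
    dist, end = _infix_end(pattern, text)
    # locate the start by matching the reversed pattern against the
    # reversed prefix ending at `end`
    _, rev_end = _infix_end(pattern[::-1], text[:end][::-1])
    return dist, end - rev_end, end
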