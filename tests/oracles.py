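"""Independent brute-force oracles used to cross-check the package.

Everything here is written in plain scalar Python, deliberately sharing
no code path with the implementations under test.
"""

from __future__ import annotations

import math

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(s: str) -> str:
    return "".join(COMP[b] for b in reversed(s))


def lev(a: str, b: str) -> int:
    """Classic O(mn) scalar Levenshtein."""
    m, n = len(a), len(b)
    D = list(range(n + 1))
    for i in range(1, m + 1):
        prev = D[0]
        D[0] = i
        for j in range(1, n + 1):
            cur = D[j]
            D[j] = min(D[j] + 1, D[j - 1] + 1, prev + (a[i - 1] != b[j - 1]))
            prev = cur
    return D[n]


def infix_min_distance(pattern: str, text: str) -> int:
    """min over all substrings text[s:e] of lev(pattern, substring).

    One DP per start position; D[m][j] enumerates every end position.
    """
    best = len(pattern)
    for s in range(len(text) + 1):
        t = text[s:]
        D = [0] * (len(t) + 1)
        for i in range(1, len(pattern) + 1):
            prev = D[0]
            D[0] = i
            for j in range(1, len(t) + 1):
                cur = D[j]
                D[j] = min(D[j] + 1, D[j - 1] + 1, prev + (pattern[i - 1] != t[j - 1]))
                prev = cur
        best = min(best, min(D))
    return best


def gotoh_semiglobal_score(read: str, target: str, match=2, mismatch=-3, gap_open=4, gap_extend=2) -> int:
    """Full-matrix affine semi-global score: free leading/trailing target."""
    NEG = -(10**9)
    m, n = len(read), len(target)
    H = [[NEG] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    for j in range(n + 1):
        H[0][j] = 0
    for i in range(1, m + 1):
        for j in range(n + 1):
            if j > 0:
                E[i][j] = max(E[i][j - 1] - gap_extend, H[i][j - 1] - gap_open - gap_extend)
            F[i][j] = max(F[i - 1][j] - gap_extend, H[i - 1][j] - gap_open - gap_extend)
            best = max(E[i][j], F[i][j])
            if j > 0:
                s = match if read[i - 1] == target[j - 1] else mismatch
                best = max(best, H[i - 1][j - 1] + s)
            H[i][j] = best
    return max(H[m])


def structure_score(s: str, min_stem: int = 4, terminal_penalty: float = 3.0) -> float:
    """Enumerate maximal intramolecular self-complementary stems directly.

    A stem (i, j, k) pairs s[i:i+k] with revcomp of s[j:j+k]; run cells
    must satisfy x <= y, i.e. j >= i + k - 1.  Maximality: no outer
    extension (pairing s[i-1] with s[j+k]) and no inner extension
    (pairing s[i+k] with s[j-1] while staying in x <= y).
    """
    L = len(s)
    score = 0.0
    for k in range(min_stem, L + 1):
        for i in range(L - k + 1):
            for j in range(i + k - 1, L - k + 1):
                if s[i : i + k] != revcomp(s[j : j + k]):
                    continue
                if 0 <= i - 1 and j + k < L and COMP[s[i - 1]] == s[j + k]:
                    continue  # outer-extendable
                if i + k < L and j - 1 >= 0 and i + k <= j - 1 and COMP[s[i + k]] == s[j - 1]:
                    continue  # inner-extendable
                score -= 2.0 * k
                if i == 0 or j + k == L:
                    score -= terminal_penalty
    return score


def posterior_by_hand(counts: dict[str, float], e: float, prior: dict[str, float] | None = None) -> dict[str, float]:
    """Term-by-term arithmetic evaluation of the per-strand posterior."""
    symbols = "ACGT-"
    n = sum(counts.get(b, 0) for b in symbols)
    unnorm = {}
    for b in symbols:
        k = counts.get(b, 0)
        like = (1.0 - e) ** k * (e / 4.0) ** (n - k)
        p = prior.get(b, 0.0) if prior else 1.0
        unnorm[b] = p * like
    z = sum(unnorm.values())
    return {b: v / z for b, v in unnorm.items()}


def log_likelihood_by_hand(counts: dict[str, float], e: float, b: str) -> float:
    symbols = "ACGT-"
    n = sum(counts.get(x, 0) for x in symbols)
    k = counts.get(b, 0)
    return k * math.log(1.0 - e) + (n - k) * math.log(e) - (n - k) * math.log(4.0)
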