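"""Independent reference implementations used to cross-check the package.

Everything here is deliberately written a different way from the library
code (plain recursion and per-window loops instead of dynamic programs and
vectorization) and shares only the published energy constants.
"""

from __future__ import annotations

import math
from functools import lru_cache

from seedmir.energy import (
    DUPLEX_INIT,
    MAX_LOOP_SIDE,
    MIN_HAIRPIN,
    hairpin_penalty,
    interior_penalty,
    pair_index,
    stack_energy,
)


# ---------------------------------------------------------------- folding

def reference_mfe(seq: str) -> float:
    """Top-down recursive minimum over single-stem structures (memoized)."""

    @lru_cache(maxsize=None)
    def closed(i: int, j: int) -> float:
        if pair_index(seq[i], seq[j]) < 0 or j - i - 1 < MIN_HAIRPIN:
            return math.inf
        best = hairpin_penalty(j - i - 1)
        for k in range(i + 1, min(i + 1 + MAX_LOOP_SIDE, j) + 1):
            for l in range(max(j - 1 - MAX_LOOP_SIDE, k), j):
                if l - k - 1 < MIN_HAIRPIN:
                    continue
                inner = closed(k, l)
                if inner == math.inf:
                    continue
                a, b = k - i - 1, j - l - 1
                if a == 0 and b == 0:
                    cost = stack_energy(seq[i], seq[j], seq[k], seq[l])
                elif a + b >= 1:
                    cost = interior_penalty(a + b)
                else:
                    continue
                best = min(best, inner + cost)
        return best

    n = len(seq)
    best = 0.0
    for i in range(n):
        for j in range(i + MIN_HAIRPIN + 1, n):
            best = min(best, closed(i, j))
    return best


def enumerate_mfe(seq: str) -> float:
    """Full enumeration of every nested pair chain (tiny sequences only)."""
    n = len(seq)
    pairable = [
        (i, j)
        for i in range(n)
        for j in range(i + MIN_HAIRPIN + 1, n)
        if pair_index(seq[i], seq[j]) >= 0
    ]

    best = [0.0]

    def extend(i: int, j: int, acc: float) -> None:
        # close (i, j) as the hairpin
        total = acc + hairpin_penalty(j - i - 1)
        if total < best[0]:
            best[0] = total
        for k, l in pairable:
            if not (i < k < l < j):
                continue
            a, b = k - i - 1, j - l - 1
            if a > MAX_LOOP_SIDE or b > MAX_LOOP_SIDE:
                continue
            if a == 0 and b == 0:
                cost = stack_energy(seq[i], seq[j], seq[k], seq[l])
            else:
                cost = interior_penalty(a + b)
            extend(k, l, acc + cost)

    for i, j in pairable:
        extend(i, j, 0.0)
    return best[0]


# ---------------------------------------------------------------- targets

_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}
_WOBBLE = {("G", "U"), ("U", "G")}


def naive_site_scan(mirna: str, unigene: str, min_ratio: float = 75.0):
    """Per-window rule evaluation, one position at a time.

    Returns a list of (start0, score, duplex_mfe) for every passing window.
    """
    m = mirna.upper().replace("T", "U")
    s = unigene.upper().replace("T", "U")
    L = len(m)
    perfect = _naive_duplex(m, "".join(_COMP[c] for c in m)[::-1])
    hits = []
    for start in range(len(s) - L + 1):
        w = s[start : start + L]
        states = []
        for p in range(L):  # p: 0-based position from miRNA 5' end
            t = w[L - 1 - p]
            if _COMP[m[p]] == t:
                states.append("M")
            elif (m[p], t) in _WOBBLE:
                states.append("G")
            else:
                states.append("X")
        score = states.count("X") + 0.5 * states.count("G")
        if score > 4:
            continue
        if "XXX" in "".join(states):
            continue
        if any(states[p] == "X" and states[p + 1] == "X" for p in range(1, 11)):
            continue
        if "X" in states[9:11]:
            continue
        if states[:12].count("X") + 0.5 * states[:12].count("G") > 2.5:
            continue
        d = _naive_duplex(m, w)
        if d >= 0 or 100.0 * d / perfect < min_ratio:
            continue
        hits.append((start, score, d))
    return hits


def _naive_duplex(m: str, w: str) -> float:
    """Stack-sum duplex energy recomputed pair by pair."""
    L = len(m)
    paired = []
    for p in range(L):
        t = w[L - 1 - p]
        paired.append(_COMP[m[p]] == t or (m[p], t) in _WOBBLE)
    e = DUPLEX_INIT
    for p in range(L - 1):
        if paired[p] and paired[p + 1]:
            e += stack_energy(m[p], w[L - 1 - p], m[p + 1], w[L - 2 - p])
    return e


# ------------------------------------------------------------- statistics

def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P[X >= k] by direct summation of binomial coefficients."""
    total = 0
    for kk in range(k, min(n, K) + 1):
        total += math.comb(K, kk) * math.comb(N - K, n - kk)
    return total / math.comb(N, n)


def pearson_r(x, y) -> float:
    """Plain covariance-formula Pearson correlation."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / math.sqrt(vx * vy)
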