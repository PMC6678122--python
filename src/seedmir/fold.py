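"""Deterministic minimum-energy folding of single-stem RNA hairpins.

A structure here is a *single stem-loop*: a chain of nested pairs
(i1,j1) > (i2,j2) > ... > (ik,jk) closed by one terminal (hairpin) loop, with
interior/bulge loops between non-stacked consecutive pairs.  Multibranch
structures are outside the model by design, which keeps the energy of every
structure an explicit sum over the shipped constants and makes exhaustive
verification feasible.  The dynamic program minimizes over all single-stem
structures; an external folding engine can be substituted wherever a
``FoldResult`` is consumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .energy import (
    BASE_INDEX,
    MAX_LOOP_SIDE,
    MIN_HAIRPIN,
    PAIR_MATRIX,
    STACK,
    hairpin_penalty,
    interior_penalty,
    normalize_rna,
    stack_energy,
)

_INF = float("inf")


@dataclass(frozen=True)
class FoldResult:
    """Dot-bracket structure and minimum free energy (kcal/mol) of a sequence."""

    structure: str
    mfe: float
    pairs: tuple[tuple[int, int], ...] = field(default=())

    def __post_init__(self):
        if self.structure.count("(") != self.structure.count(")"):
            raise ValueError("unbalanced dot-bracket structure")


def energy_of_structure(seq: str, pairs) -> float:
    """Energy of an explicit single-stem chain of pairs (0-based, outermost first).

    The chain must be strictly nested; consecutive pairs contribute a stack
    term when directly adjacent and an interior/bulge penalty otherwise; the
    innermost pair closes the hairpin loop.
    """
    s = normalize_rna(seq)
    chain = sorted(pairs)
    if not chain:
        return 0.0
    e = 0.0
    for (i, j), (k, l) in zip(chain, chain[1:]):
        if not (i < k < l < j):
            raise ValueError("pairs do not form a nested single-stem chain")
        a, b = k - i - 1, j - l - 1
        if a == 0 and b == 0:
            e += stack_energy(s[i], s[j], s[k], s[l])
        else:
            e += interior_penalty(a + b)
    ii, jj = chain[-1]
    e += hairpin_penalty(jj - ii - 1)
    return e


def fold(seq: str) -> FoldResult:
    """Minimum-energy single-stem structure of ``seq`` under the bundled model.

    Returns the open structure (all dots, MFE 0) when no single-stem structure
    has negative energy.  Deterministic: ties are broken toward the smallest
    outer 5' index, then the shortest span, then stacked continuation.
    """
    s = normalize_rna(seq)
    n = len(s)
    if n == 0:
        raise ValueError("empty sequence")
    enc = np.array([BASE_INDEX[c] for c in s], dtype=np.int8)
    pidx = PAIR_MATRIX[enc[:, None], enc[None, :]]

    # D[span][i] = min energy of a single-stem structure closed by pair (i, i+span)
    D: list[np.ndarray | None] = [None] * n
    for span in range(MIN_HAIRPIN + 1, n):
        m = n - span
        i = np.arange(m)
        j = i + span
        p = pidx[i, j]
        ok = p >= 0
        if not ok.any():
            D[span] = np.full(m, _INF)
            continue
        best = np.where(ok, hairpin_penalty(span - 1), _INF)
        for a in range(MAX_LOOP_SIDE + 1):
            for b in range(MAX_LOOP_SIDE + 1):
                ispan = span - 2 - a - b
                if ispan < MIN_HAIRPIN + 1:
                    continue
                inner = D[ispan][1 + a : 1 + a + m]
                if a == 0 and b == 0:
                    q = pidx[j - 1, i + 1]
                    cost = STACK[np.clip(p, 0, None), np.clip(q, 0, None)]
                else:
                    cost = interior_penalty(a + b)
                best = np.minimum(best, inner + cost)
        D[span] = np.where(ok, best, _INF)

    mfe = 0.0
    loc = None
    for span in range(MIN_HAIRPIN + 1, n):
        col = D[span]
        if col is None:
            continue
        k = int(np.argmin(col))
        e = float(col[k])
        if e < -1e-12:
            idx = int(np.flatnonzero(col <= e + 1e-9)[0])  # leftmost minimum
            key = (round(e, 9), idx, span)
            if loc is None or key < (round(mfe, 9), loc[0], loc[1] - loc[0]):
                mfe, loc = e, (idx, idx + span)

    if loc is None:
        return FoldResult("." * n, 0.0, ())

    pairs = _traceback(s, D, loc)
    struct = dotbracket_from_pairs(n, pairs)
    return FoldResult(struct, mfe, tuple(pairs))


def _traceback(s, D, outer):
    pairs = []
    i, j = outer
    while True:
        pairs.append((i, j))
        span = j - i
        target = D[span][i]
        if abs(hairpin_penalty(span - 1) - target) <= 1e-6:
            return pairs
        found = False
        for a in range(MAX_LOOP_SIDE + 1):
            if found:
                break
            for b in range(MAX_LOOP_SIDE + 1):
                ispan = span - 2 - a - b
                if ispan < MIN_HAIRPIN + 1:
                    continue
                k, l = i + 1 + a, j - 1 - b
                inner = D[ispan][k]
                if inner == _INF:
                    continue
                if a == 0 and b == 0:
                    try:
                        cost = stack_energy(s[i], s[j], s[k], s[l])
                    except ValueError:
                        continue
                else:
                    cost = interior_penalty(a + b)
                if abs(inner + cost - target) <= 1e-6:
                    i, j = k, l
                    found = True
                    break
        if not found:  # numerical dead end; close as hairpin (should not happen)
            return pairs


def pairs_from_dotbracket(structure: str) -> list[tuple[int, int]]:
    stack, pairs = [], []
    for k, c in enumerate(structure):
        if c == "(":
            stack.append(k)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket")
            pairs.append((stack.pop(), k))
    if stack:
        raise ValueError("unbalanced dot-bracket")
    return sorted(pairs)


def dotbracket_from_pairs(n: int, pairs) -> str:
    out = ["."] * n
    for i, j in pairs:
        out[i], out[j] = "(", ")"
    return "".join(out)


def is_single_stem(pairs) -> bool:
    """True iff the pairs form one strictly nested chain (exactly one loop)."""
    chain = sorted(pairs)
    if not chain:
        return False
    for (i, j), (k, l) in zip(chain, chain[1:]):
        if not (i < k < l < j):
            return False
    return True


def terminal_loop(pairs) -> tuple[int, int]:
    """0-based (k, l) of the innermost pair; the loop is positions k+1..l-1."""
    chain = sorted(pairs)
    if not chain or not is_single_stem(chain):
        raise ValueError("not a single-stem structure")
    return chain[-1]


def mature_arm(pairs, start: int, end: int) -> str | None:
    """Arm carrying the interval [start, end) (0-based, half-open), or None.

    The interval must not intrude into the terminal loop and must sit entirely
    on one side of it; assignment follows the midpoint of the terminal loop.
    """
    if not pairs or not is_single_stem(pairs):
        return None
    k, l = terminal_loop(pairs)
    if end - 1 <= k:
        return "5p"
    if start >= l:
        return "3p"
    return None


def paired_in_interval(pairs, start: int, end: int) -> int:
    """Number of paired bases (either partner) within [start, end), 0-based."""
    pos = set()
    for i, j in pairs:
        pos.add(i)
        pos.add(j)
    return sum(1 for p in pos if start <= p < end)
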