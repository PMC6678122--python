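"""Nearest-neighbor free-energy constants and helpers for RNA stems and duplexes.

The engine models only canonical Watson-Crick (AU, UA, CG, GC) and wobble
(GU, UG) pairs.  Stacking free energies are the Turner 2004 values at 37 degC
(kcal/mol) for the 6x6 pair-on-pair table; loop costs are simplified linear
penalties so that every structure energy is an explicit, enumerable sum.
There are no dangling ends, no coaxial stacks and no multibranch loops.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGU"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: canonical + wobble pairs, fixed index order (matches the stack table below)
PAIRS = [("C", "G"), ("G", "C"), ("G", "U"), ("U", "G"), ("A", "U"), ("U", "A")]
PAIR_INDEX = {p: i for i, p in enumerate(PAIRS)}

#: PAIR_MATRIX[x, y] = index of pair (x, y) in PAIRS, or -1 if not pairable
PAIR_MATRIX = np.full((4, 4), -1, dtype=np.int8)
for (x, y), k in PAIR_INDEX.items():
    PAIR_MATRIX[BASE_INDEX[x], BASE_INDEX[y]] = k

# Turner 2004 stack dG at 37 degC, kcal/mol.  STACK[p, q] is the energy of
# outer pair p = (seq[i], seq[j]) closing inner pair (seq[i+1], seq[j-1]),
# with q indexed as the inner pair read from the 3' strand, (seq[j-1], seq[i+1]).
# Row/column order: CG GC GU UG AU UA.
STACK = np.array(
    [
        [-2.40, -3.30, -2.10, -1.40, -2.10, -2.10],
        [-3.30, -3.40, -2.50, -1.50, -2.20, -2.40],
        [-2.10, -2.50, +1.30, -0.50, -1.40, -1.30],
        [-1.40, -1.50, -0.50, +0.30, -0.60, -1.00],
        [-2.10, -2.20, -1.40, -0.60, -1.10, -0.90],
        [-2.10, -2.40, -1.30, -1.00, -0.90, -1.30],
    ]
)

# Linear loop penalties (kcal/mol).  Hairpin loops of s unpaired bases cost
# HAIRPIN_BASE + HAIRPIN_SLOPE*(s - MIN_HAIRPIN); interior/bulge loops with u
# total unpaired bases cost INTERIOR_BASE + INTERIOR_SLOPE*u.
MIN_HAIRPIN = 3
MAX_LOOP_SIDE = 10  # max unpaired bases allowed on each side of an interior loop
HAIRPIN_BASE = 5.0
HAIRPIN_SLOPE = 0.25
INTERIOR_BASE = 2.2
INTERIOR_SLOPE = 0.5

#: duplex initiation penalty for bimolecular miRNA/target hybrids (Turner 2004)
DUPLEX_INIT = 4.09


def normalize_rna(seq: str) -> str:
    """Uppercase, DNA->RNA.  Raises ``ValueError`` on non-ACGU(T) characters."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - set(BASES)
    if bad:
        raise ValueError(f"non-ACGU(T) characters in sequence: {sorted(bad)}")
    return s


def pair_index(x: str, y: str) -> int:
    """Index of pair (x, y) in the stack table, or -1 if x:y cannot pair."""
    return int(PAIR_MATRIX[BASE_INDEX[x], BASE_INDEX[y]])


def stack_energy(a: str, b: str, c: str, d: str) -> float:
    """dG of outer pair a:b stacked on inner pair c:d (5'-a c ... d b-3')."""
    p = pair_index(a, b)
    q = pair_index(d, c)
    if p < 0 or q < 0:
        raise ValueError(f"{a}:{b} on {c}:{d} is not a stack of two pairs")
    return float(STACK[p, q])


def hairpin_penalty(size: int) -> float:
    if size < MIN_HAIRPIN:
        raise ValueError(f"hairpin loop of {size} < {MIN_HAIRPIN} bases")
    return HAIRPIN_BASE + HAIRPIN_SLOPE * (size - MIN_HAIRPIN)


def interior_penalty(unpaired: int) -> float:
    if unpaired < 1:
        raise ValueError("interior loop must have at least one unpaired base")
    return INTERIOR_BASE + INTERIOR_SLOPE * unpaired


def gc_percent(seq: str) -> float:
    s = normalize_rna(seq)
    if not s:
        raise ValueError("empty sequence")
    return 100.0 * (s.count("G") + s.count("C")) / len(s)
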