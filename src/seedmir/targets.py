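"""Rule-based miRNA target prediction on a transcriptome.

Sites are ungapped antiparallel duplexes of miRNA against a same-length mRNA
window, scored per position from the miRNA 5' end: Watson-Crick match 0,
G:U wobble 0.5, mismatch 1.  A site passes when

* total score <= 4;
* no run of 3+ mismatches anywhere;
* no two adjacent mismatches within positions 2-12;
* no mismatch at positions 10-11 (G:U allowed there by default);
* summed penalties over positions 1-12 <= 2.5;
* duplex MFE >= 75% of the MFE against the perfect complement
  (stack-sum nearest-neighbor energies; mismatches break stacking).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .energy import BASE_INDEX, DUPLEX_INIT, PAIR_MATRIX, STACK, normalize_rna

# per-position states
MATCH, WOBBLE, MISMATCH = 0, 1, 2

#: _STATE[miRNA base, target base] (RNA indices A,C,G,U)
_STATE = np.full((4, 4), MISMATCH, dtype=np.int8)
for _m, _t in (("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")):
    _STATE[BASE_INDEX[_m], BASE_INDEX[_t]] = MATCH
for _m, _t in (("G", "U"), ("U", "G")):
    _STATE[BASE_INDEX[_m], BASE_INDEX[_t]] = WOBBLE

_PENALTY = np.array([0.0, 0.5, 1.0])


@dataclass
class TargetRules:
    """Declared complementarity thresholds (defaults as commonly published)."""

    max_score: float = 4.0
    max_adjacent_mismatches: int = 2
    seed_span: tuple[int, int] = (2, 12)  # 1-based inclusive, no adjacent mm
    central_span: tuple[int, int] = (10, 11)  # no mismatches here
    max_seed_penalty: float = 2.5  # positions 1-12, G:U counts 0.5
    min_mfe_ratio: float = 75.0
    allow_gu_central: bool = True  # G:U at 10-11 is not a mismatch


@dataclass
class TargetSite:
    """One miRNA/unigene duplex with positional states and energetics."""

    mirna_id: str
    unigene_id: str
    start: int  # 1-based inclusive on the unigene
    end: int
    states: str  # per position 1..L from miRNA 5' end: M / G / X
    score: float
    duplex_mfe: float
    perfect_mfe: float

    @property
    def mfe_ratio(self) -> float:
        return 100.0 * self.duplex_mfe / self.perfect_mfe


def site_states(mirna: str, window: str) -> np.ndarray:
    """Per-position states (miRNA 5'->3') of the antiparallel ungapped duplex."""
    m = normalize_rna(mirna)
    w = normalize_rna(window)
    if len(m) != len(w):
        raise ValueError("miRNA and target window must have equal length")
    me = np.array([BASE_INDEX[c] for c in m])
    we = np.array([BASE_INDEX[c] for c in w])[::-1]  # antiparallel
    return _STATE[me, we]


def mismatch_score(states: np.ndarray) -> float:
    return float(_PENALTY[states].sum())


def _rules_verdict(states: np.ndarray, rules: TargetRules) -> bool:
    mm = states == MISMATCH
    if not rules.allow_gu_central:
        mm_central = states != MATCH
    else:
        mm_central = mm
    if _PENALTY[states].sum() > rules.max_score:
        return False
    # runs of full mismatches longer than allowed, anywhere
    run = 0
    for x in mm:
        run = run + 1 if x else 0
        if run > rules.max_adjacent_mismatches:
            return False
    lo, hi = rules.seed_span  # no adjacent mismatches inside the span
    for p in range(lo - 1, hi - 1):
        if mm[p] and mm[p + 1]:
            return False
    clo, chi = rules.central_span
    if mm_central[clo - 1 : chi].any():
        return False
    if _PENALTY[states[:12]].sum() > rules.max_seed_penalty:
        return False
    return True


def score_site(
    mirna: str, window: str, rules: TargetRules = TargetRules()
) -> tuple[str, float, bool]:
    """(state string, mismatch score, verdict) for one candidate window.

    The verdict covers the positional rules only; the duplex MFE-ratio filter
    is applied by the scanner (or by comparing :func:`duplex_mfe` against
    :func:`perfect_mfe` directly).
    """
    states = site_states(mirna, window)
    txt = "".join("MGX"[s] for s in states)
    return txt, mismatch_score(states), _rules_verdict(states, rules)


def duplex_mfe(mirna: str, window: str) -> float:
    """Stack-sum duplex energy (kcal/mol): initiation + stacks over paired runs.

    Positions pair when their state is a WC match or a G:U wobble; a stack
    term accrues for each two consecutive paired positions; mismatches break
    stacking and contribute nothing.
    """
    m = normalize_rna(mirna)
    w = normalize_rna(window)[::-1]  # w[p] faces m[p]
    states = site_states(m, window)
    e = DUPLEX_INIT
    for p in range(len(m) - 1):
        if states[p] != MISMATCH and states[p + 1] != MISMATCH:
            pi = PAIR_MATRIX[BASE_INDEX[m[p]], BASE_INDEX[w[p]]]
            qi = PAIR_MATRIX[BASE_INDEX[w[p + 1]], BASE_INDEX[m[p + 1]]]
            e += STACK[pi, qi]
    return float(e)


_RC = str.maketrans("ACGU", "UGCA")


def perfect_complement(mirna: str) -> str:
    """The target window that pairs every miRNA base by Watson-Crick rules."""
    return normalize_rna(mirna).translate(_RC)[::-1]


def perfect_mfe(mirna: str) -> float:
    return duplex_mfe(mirna, perfect_complement(mirna))


def evaluate_site(
    mirna_id: str,
    mirna: str,
    unigene_id: str,
    unigene_seq: str,
    start0: int,
    rules: TargetRules = TargetRules(),
    _perfect: float | None = None,
) -> TargetSite | None:
    """Full evaluation (positional rules + MFE ratio) of one window."""
    L = len(mirna)
    window = unigene_seq[start0 : start0 + L]
    txt, score, ok = score_site(mirna, window, rules)
    if not ok:
        return None
    pmfe = perfect_mfe(mirna) if _perfect is None else _perfect
    dmfe = duplex_mfe(mirna, window)
    site = TargetSite(
        mirna_id, unigene_id, start0 + 1, start0 + L, txt, score, dmfe, pmfe
    )
    if pmfe >= 0 or site.mfe_ratio < rules.min_mfe_ratio:
        return None
    return site


def scan_unigene(
    mirna_id: str,
    mirna: str,
    unigene_id: str,
    unigene_seq: str,
    rules: TargetRules = TargetRules(),
) -> list[TargetSite]:
    """All passing sites of one miRNA on the sense strand of one unigene.

    Positional rules are evaluated for every window with vectorized
    prefilters; the energy filter runs on the survivors.
    """
    m = normalize_rna(mirna)
    s = normalize_rna(unigene_seq)
    L, n = len(m), len(s)
    if n < L:
        return []
    enc = np.array([BASE_INDEX[c] for c in s], dtype=np.int8)
    win = np.lib.stride_tricks.sliding_window_view(enc, L)[:, ::-1]
    me = np.array([BASE_INDEX[c] for c in m], dtype=np.int8)
    states = _STATE[me[None, :], win]  # (n-L+1, L)
    pen = _PENALTY[states]
    mm = states == MISMATCH
    ok = pen.sum(axis=1) <= rules.max_score
    ok &= pen[:, :12].sum(axis=1) <= rules.max_seed_penalty
    if rules.max_adjacent_mismatches == 2 and L >= 3:
        ok &= ~(mm[:, :-2] & mm[:, 1:-1] & mm[:, 2:]).any(axis=1)
    lo, hi = rules.seed_span
    ok &= ~(mm[:, lo - 1 : hi - 1] & mm[:, lo:hi]).any(axis=1)
    clo, chi = rules.central_span
    central = mm if rules.allow_gu_central else (states != MATCH)
    ok &= ~central[:, clo - 1 : chi].any(axis=1)
    pmfe = perfect_mfe(m)
    out = []
    for start0 in np.flatnonzero(ok):
        site = evaluate_site(
            mirna_id, m, unigene_id, s, int(start0), rules, _perfect=pmfe
        )
        if site is not None:
            out.append(site)
    return out


def scan_transcriptome(
    mirnas: dict[str, str],
    transcriptome: dict[str, str],
    rules: TargetRules = TargetRules(),
) -> pd.DataFrame:
    """Evaluate every same-length window of every unigene for every miRNA.

    Returns one row per passing site with pairing string and energetics;
    use :func:`target_gene_counts` for per-miRNA gene counts.
    """
    rows = []
    for mid, mseq in mirnas.items():
        for uid, useq in transcriptome.items():
            for site in scan_unigene(mid, mseq, uid, useq, rules):
                rows.append(
                    {
                        "mirna": site.mirna_id,
                        "unigene": site.unigene_id,
                        "start": site.start,
                        "end": site.end,
                        "score": site.score,
                        "duplex_mfe": round(site.duplex_mfe, 2),
                        "perfect_mfe": round(site.perfect_mfe, 2),
                        "mfe_ratio": round(site.mfe_ratio, 2),
                        "states": site.states,
                    }
                )
    cols = [
        "mirna", "unigene", "start", "end", "score",
        "duplex_mfe", "perfect_mfe", "mfe_ratio", "states",
    ]
    return pd.DataFrame(rows, columns=cols)


def target_gene_counts(sites: pd.DataFrame) -> pd.Series:
    """Targets per miRNA, counting each gene once regardless of site count."""
    if sites.empty:
        return pd.Series(dtype=int, name="n_target_genes")
    return (
        sites.groupby("mirna")["unigene"].nunique().rename("n_target_genes")
    )
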