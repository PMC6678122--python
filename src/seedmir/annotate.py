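"""Classification of clean tags against an rRNA/tRNA/snRNA/snoRNA reference.

A tag is assigned a contaminant class when it matches a reference sequence
full-length, ungapped, with at most one mismatch, on either strand -- a
deterministic, desk-scale stand-in for database screening.  Multi-class hits
resolve by the fixed priority rRNA > tRNA > snRNA > snoRNA.
"""

from __future__ import annotations

from collections import defaultdict

import pandas as pd
from Bio import SeqIO

NCRNA_CLASSES = ("rRNA", "tRNA", "snRNA", "snoRNA")
_PRIORITY = {c: k for k, c in enumerate(NCRNA_CLASSES)}
_RC = str.maketrans("ACGTU", "TGCAA")


def _revcomp_dna(s: str) -> str:
    return s.translate(_RC)[::-1]


def read_contaminants(fasta_path) -> list[tuple[str, str, str]]:
    """Parse contaminant FASTA -> [(record id, class, DNA sequence)].

    Every header must carry a ``class=<rRNA|tRNA|snRNA|snoRNA>`` key; a record
    without one is a hard error.
    """
    out = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        cls = None
        for tok in rec.description.split():
            if tok.startswith("class="):
                cls = tok.split("=", 1)[1]
        if cls is None or cls not in NCRNA_CLASSES:
            raise ValueError(
                f"contaminant record {rec.id!r} lacks a valid class= header key"
            )
        out.append((rec.id, cls, str(rec.seq).upper().replace("U", "T")))
    return out


class ContaminantIndex:
    """Seed-and-verify index for <=1-mismatch full-length tag lookup.

    With at most one mismatch, one of the two halves of the tag must match
    exactly (pigeonhole); reference substrings of every needed half-length are
    indexed once, then each tag needs two dictionary probes plus verification.
    """

    def __init__(self, records, min_len: int = 15, max_len: int = 35):
        self.records = records
        self._seeds: dict[int, dict] = {}
        self._seqs = []
        for rid, cls, seq in records:
            self._seqs.append((cls, seq, False))
            self._seqs.append((cls, _revcomp_dna(seq), True))
        lens = set()
        for L in range(min_len, max_len + 1):
            lens.add(L // 2)
            lens.add(L - L // 2)
        for k in lens:
            idx = defaultdict(list)
            for si, (_cls, seq, _rc) in enumerate(self._seqs):
                for p in range(len(seq) - k + 1):
                    idx[seq[p : p + k]].append((si, p))
            self._seeds[k] = dict(idx)

    def classify(self, tag: str, max_mismatch: int = 1) -> str | None:
        tag = tag.upper().replace("U", "T")
        L = len(tag)
        h = L // 2
        best = None
        candidates = []
        for seed, offset in ((tag[:h], 0), (tag[h:], h)):
            for si, p in self._seeds.get(len(seed), {}).get(seed, ()):  # anchored hits
                candidates.append((si, p - offset))
        for si, start in candidates:
            cls, seq, _rc = self._seqs[si]
            if start < 0 or start + L > len(seq):
                continue
            window = seq[start : start + L]
            mm = sum(1 for a, b in zip(tag, window) if a != b)
            if mm <= max_mismatch:
                if best is None or _PRIORITY[cls] < _PRIORITY[best]:
                    best = cls
        return best


def classify_ncrna(
    tag_counts: pd.DataFrame, contaminant_fasta, max_mismatch: int = 1
) -> tuple[pd.Series, pd.DataFrame]:
    """Assign each tag an ncRNA class or 'unannotated'; report read fractions.

    Returns ``(classes, fractions)``: ``classes`` is a Series indexed like
    ``tag_counts`` with values in {rRNA, tRNA, snRNA, snoRNA, unannotated};
    ``fractions`` gives, per library, the fraction of clean reads in each
    class (columns sum to 1 for non-empty libraries).
    """
    index = ContaminantIndex(read_contaminants(contaminant_fasta))
    classes = pd.Series(
        [index.classify(t, max_mismatch) or "unannotated" for t in tag_counts.index],
        index=tag_counts.index,
        name="class",
    )
    reads_by_class = tag_counts.groupby(classes).sum()
    reads_by_class = reads_by_class.reindex(
        list(NCRNA_CLASSES) + ["unannotated"], fill_value=0
    )
    totals = tag_counts.sum(axis=0)
    fractions = reads_by_class.div(totals.where(totals > 0), axis=1)
    return classes, fractions
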