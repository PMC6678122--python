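"""Raw small-RNA read filtering, adapter trimming and tag collapsing.

Mirrors the standard small-RNA-seq cleanup: drop low-quality reads, reads
carrying 5' adapter sequence, polyA artifacts and reads without a 3' adapter;
trim the 3' adapter; keep inserts of 18-30 nt; collapse identical inserts to
unique tags with read counts.  All rules are explicit and configurable since
vendor pipelines rarely publish theirs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

MIN_LEN = 18
MAX_LEN = 30

#: removal classes, in the order rules are applied
REMOVAL_CLASSES = (
    "low_quality",
    "adapter5",
    "no_adapter3",
    "polyA",
    "too_short",
    "too_long",
)


@dataclass
class LibraryStats:
    """Per-library read accounting (raw/clean/retention/unique tags/lengths)."""

    library_id: str
    n_raw: int = 0
    n_clean: int = 0
    removed: dict = field(default_factory=lambda: {c: 0 for c in REMOVAL_CLASSES})
    length_histogram: dict = field(default_factory=dict)
    n_unique_tags: int = 0

    @property
    def retention(self) -> float:
        return self.n_clean / self.n_raw if self.n_raw else float("nan")

    def to_row(self) -> dict:
        row = {
            "library": self.library_id,
            "raw_reads": self.n_raw,
            "clean_reads": self.n_clean,
            "retention": self.retention,
            "unique_tags": self.n_unique_tags,
        }
        row.update({f"removed_{c}": v for c, v in self.removed.items()})
        return row


def filter_and_trim(
    fastq_path,
    adapter3: str,
    adapter5: str,
    *,
    library_id: str | None = None,
    min_len: int = MIN_LEN,
    max_len: int = MAX_LEN,
    adapter_k: int = 8,
    adapter5_window: int = 10,
    quality_phred: int = 20,
    max_low_quality_frac: float = 0.2,
    polya_frac: float = 0.8,
    polya_tail: int = 10,
    require_adapter3: bool = True,
) -> tuple[dict[str, int], LibraryStats]:
    """Filter one FASTQ library and collapse surviving inserts to tags.

    Rules, applied in order per read:

    1. low quality: more than ``max_low_quality_frac`` of bases below
       ``quality_phred`` (Phred+33);
    2. 5' adapter contamination: the last ``adapter_k`` nt of ``adapter5``
       occur within the first ``adapter5_window`` read positions;
    3. 3' adapter: first occurrence of the first ``adapter_k`` nt of
       ``adapter3`` marks the insert end; absent -> read removed (unless
       ``require_adapter3`` is False, for re-filtering already-trimmed reads);
    4. polyA: insert is >= ``polya_frac`` A, or ends with ``polya_tail`` A;
    5. insert length outside [min_len, max_len] -> too_short / too_long.

    Returns ``(tags, stats)`` where ``tags`` maps insert sequence (DNA, as
    read) to read count.  Malformed FASTQ records raise ``ValueError`` with
    the record index.
    """
    if not adapter3 or (require_adapter3 is True and len(adapter3) < adapter_k):
        raise ValueError(f"adapter3 must be at least {adapter_k} nt")
    if not adapter5:
        raise ValueError("adapter5 must be non-empty")
    lib = library_id or str(fastq_path)
    stats = LibraryStats(lib)
    a3 = adapter3[:adapter_k].upper()
    a5 = adapter5[-adapter_k:].upper()
    qcut = 33 + quality_phred
    tags: Counter[str] = Counter()

    with open(fastq_path) as fh:
        it = FastqGeneralIterator(fh)
        idx = -1
        while True:
            idx += 1
            try:
                rec = next(it, None)
            except ValueError as err:
                raise ValueError(f"malformed FASTQ record #{idx} in {fastq_path}: {err}")
            if rec is None:
                break
            _title, seq, qual = rec
            if len(seq) != len(qual):
                raise ValueError(f"malformed FASTQ record #{idx}: seq/qual length differ")
            stats.n_raw += 1
            seq = seq.upper()

            q = np.frombuffer(qual.encode("ascii"), dtype=np.uint8)
            if q.size and (q < qcut).mean() > max_low_quality_frac:
                stats.removed["low_quality"] += 1
                continue
            if seq.find(a5, 0, adapter5_window + adapter_k - 1) != -1:
                stats.removed["adapter5"] += 1
                continue
            pos = seq.find(a3)
            if pos == -1:
                if require_adapter3:
                    stats.removed["no_adapter3"] += 1
                    continue
                insert = seq
            else:
                insert = seq[:pos]
            if insert and (
                insert.count("A") >= polya_frac * len(insert)
                or insert.endswith("A" * polya_tail)
            ):
                stats.removed["polyA"] += 1
                continue
            if len(insert) < min_len:
                stats.removed["too_short"] += 1
                continue
            if len(insert) > max_len:
                stats.removed["too_long"] += 1
                continue
            stats.n_clean += 1
            tags[insert] += 1

    stats.n_unique_tags = len(tags)
    hist = Counter()
    for t, c in tags.items():
        hist[len(t)] += c
    stats.length_histogram = {ln: hist.get(ln, 0) for ln in range(min_len, max_len + 1)}
    return dict(tags), stats


def collapse(reads: Iterable[str]) -> dict[str, int]:
    """Collapse an iterable of (already filtered) reads to tag -> count."""
    return dict(Counter(reads))


def combine_tag_counts(per_library: dict[str, dict[str, int]]) -> pd.DataFrame:
    """Tags x libraries read-count matrix (int, zeros where absent)."""
    df = pd.DataFrame(per_library).fillna(0).astype(int)
    df.index.name = "tag"
    return df.sort_index()


def length_distribution(
    tag_counts: pd.DataFrame, phases: dict[str, list[str]] | None = None
) -> pd.DataFrame:
    """Read-count histogram over tag length, per library and optionally per phase.

    Returns a DataFrame indexed by length with one column per library (and one
    per phase when ``phases`` maps phase -> library columns).  Empty input
    yields an empty frame.
    """
    if tag_counts.empty:
        return pd.DataFrame()
    lengths = tag_counts.index.str.len()
    hist = tag_counts.groupby(lengths).sum()
    hist.index.name = "length"
    if phases:
        for phase, libs in phases.items():
            hist[phase] = hist[list(libs)].sum(axis=1)
    return hist


def modal_length(hist: pd.Series) -> int:
    """Most abundant read length in one histogram column."""
    return int(hist.idxmax())
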