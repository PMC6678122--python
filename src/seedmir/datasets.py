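"""Published summary tables from the Pongamia developing-seed small RNA study.

These are the printed per-library sequencing statistics and the
differentially expressed miRNAs significant in both phase comparisons, as
reported for nine libraries (three developmental phases x three biological
replicates).  They serve as worked-example inputs for the reporting
arithmetic (totals, retention rates, trend-class counts); the full read data
they summarize is not shipped.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with resources.files("seedmir.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_library_stats() -> pd.DataFrame:
    """Raw/clean/unique-tag counts and miRNA tallies per library."""
    return _load("published_library_stats.tsv")


def load_conserved_reads() -> pd.DataFrame:
    """Reads perfectly matching known plant matures, per library."""
    return _load("published_conserved_reads.tsv")


def load_demir_counts() -> pd.DataFrame:
    """Significantly up-/down-regulated miRNA counts per phase comparison."""
    return _load("published_demir_counts.tsv")


def load_demir_trends() -> pd.DataFrame:
    """miRNAs significant in both comparisons: counts and signed log2 FCs."""
    return _load("published_demir_trends.tsv")
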