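"""Hypergeometric term enrichment with Benjamini-Hochberg FDR control.

For a target gene set of size n drawn from a background of N genes, a term
annotating K background genes and k target genes has upper-tail probability
P = P[X >= k], X ~ Hypergeometric(N, K, n).  BH correction is applied
separately within each annotation family (GO MF / BP / CC, KEGG), mirroring
how such results are conventionally reported.
"""

from __future__ import annotations

import warnings

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

#: annotation table columns
ANNOTATION_COLUMNS = ("gene", "term", "name", "category")


def enrich(
    target_genes,
    annotations: pd.DataFrame,
    background,
    fdr_threshold: float = 0.05,
    min_background_genes: int = 2,
) -> pd.DataFrame:
    """Enrichment table for all terms, sorted by FDR within category.

    ``annotations`` maps genes to terms (columns gene/term/name/category);
    genes annotated with a term several times count once.  Terms with
    K < ``min_background_genes`` are skipped (K = 0 with a warning).
    Requires ``target_genes`` to be a subset of ``background``.
    """
    targets = set(target_genes)
    bg = set(background)
    if not targets <= bg:
        raise ValueError("target genes must be a subset of the background")
    ann = annotations.loc[annotations["gene"].isin(bg)].drop_duplicates(
        subset=["gene", "term"]
    )
    N, n = len(bg), len(targets)
    rows = []
    for (term, name, category), group in ann.groupby(["term", "name", "category"]):
        genes = set(group["gene"])
        K = len(genes)
        k = len(genes & targets)
        if K == 0:
            warnings.warn(f"term {term} has no background genes; skipped")
            continue
        if K < min_background_genes:
            continue
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term": term,
                "name": name,
                "category": category,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "p": p,
            }
        )
    df = pd.DataFrame(
        rows, columns=["term", "name", "category", "k", "n", "K", "N", "p"]
    )
    if df.empty:
        df["fdr"] = []
        df["significant"] = []
        return df
    df["fdr"] = 1.0
    for cat, idx in df.groupby("category").groups.items():
        df.loc[idx, "fdr"] = multipletests(df.loc[idx, "p"], method="fdr_bh")[1]
    df["significant"] = df["fdr"] <= fdr_threshold
    return df.sort_values(["category", "fdr", "p", "term"]).reset_index(drop=True)
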