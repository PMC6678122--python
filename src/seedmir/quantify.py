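"""TPM quantification, differential expression and trend classification.

Expression is reads per million clean reads (TPM) with a 0.01 floor for
zero counts.  A miRNA is differentially expressed between two phases when
|log2 fold change of phase-mean TPM| >= 1 (2-fold) and the Welch t-test on
log2(TPM) across replicates gives P <= 0.05; the two successive comparisons
(II/I, III/II) combine into a trend class (bell, V, monotone, single, ns).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

TPM_FLOOR = 0.01


def tpm(count: float, library_total_clean: float) -> float:
    """Reads per million clean reads; zero counts floor at 0.01."""
    if count < 0:
        raise ValueError("negative read count")
    if library_total_clean <= 0:
        raise ValueError("library total must be positive")
    if count == 0:
        return TPM_FLOOR
    return count / library_total_clean * 1e6


def expression_matrix(
    counts: pd.DataFrame, library_totals: pd.Series | None = None, floor: bool = True
) -> pd.DataFrame:
    """TPM matrix (rows = features, columns = libraries).

    ``library_totals`` defaults to the column sums of ``counts`` (in which
    case each un-floored column sums to exactly 1e6).  The pipeline passes
    total clean reads per library so miRNA TPMs share the library scale.
    """
    if library_totals is None:
        library_totals = counts.sum(axis=0)
    m = counts.div(library_totals, axis=1) * 1e6
    if floor:
        m = m.mask(counts == 0, TPM_FLOOR)
    return m


def log2fc(mean_b: float, mean_a: float) -> float:
    """Signed log2 ratio b/a; antisymmetric under argument swap."""
    if mean_a <= 0 or mean_b <= 0:
        raise ValueError("log2fc requires positive means (apply the TPM floor first)")
    return float(np.log2(mean_b / mean_a))


def de_test(reps_a, reps_b) -> float:
    """Two-sided Welch t-test on log2(TPM) between two replicate groups."""
    a = np.log2(np.asarray(reps_a, dtype=float))
    b = np.log2(np.asarray(reps_b, dtype=float))
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two replicates per phase")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    import warnings

    with warnings.catch_warnings():
        # near-identical groups trigger a scipy precision warning; the limit
        # behavior (p -> 1) is what we want
        warnings.simplefilter("ignore", RuntimeWarning)
        return float(sps.ttest_ind(a, b, equal_var=False).pvalue)


def is_significant(
    lfc: float, p: float, fc_threshold: float = 2.0, p_threshold: float = 0.05
) -> bool:
    """DE call for one comparison: |log2FC| >= log2(fc) and P <= threshold."""
    return bool(abs(lfc) >= np.log2(fc_threshold) and p <= p_threshold)


def classify_trend(sig1: bool, lfc1: float, sig2: bool, lfc2: float) -> str:
    """Trend over phases I->II->III from the two significant signed changes."""
    if sig1 and sig2:
        if lfc1 > 0 and lfc2 < 0:
            return "bell"
        if lfc1 < 0 and lfc2 > 0:
            return "V"
        if lfc1 > 0 and lfc2 > 0:
            return "up-up"
        return "down-down"
    if sig1 or sig2:
        lfc = lfc1 if sig1 else lfc2
        return "single-up" if lfc > 0 else "single-down"
    return "ns"


def differential_expression(
    tpm_df: pd.DataFrame,
    phases: dict[str, list[str]],
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-miRNA phase means, log2 fold changes, P values, flags and trend.

    ``phases`` maps the three phase names (in developmental order) to their
    replicate library columns.  Significance requires both
    |log2FC| >= log2(fc_threshold) and P <= p_threshold.
    """
    names = list(phases)
    if len(names) != 3:
        raise ValueError("expected exactly three phases in developmental order")
    rows = []
    for mid, row in tpm_df.iterrows():
        means = {p: row[list(phases[p])].mean() for p in names}
        out = {"mirna": mid}
        for p in names:
            out[f"mean_tpm_{p}"] = means[p]
        for a, b, tagname in ((names[0], names[1], "II_vs_I"), (names[1], names[2], "III_vs_II")):
            lfc = log2fc(means[b], means[a])
            pval = de_test(row[list(phases[a])], row[list(phases[b])])
            out[f"log2fc_{tagname}"] = lfc
            out[f"p_{tagname}"] = pval
            out[f"sig_{tagname}"] = is_significant(lfc, pval, fc_threshold, p_threshold)
        out["trend"] = classify_trend(
            out["sig_II_vs_I"],
            out["log2fc_II_vs_I"],
            out["sig_III_vs_II"],
            out["log2fc_III_vs_II"],
        )
        rows.append(out)
    return pd.DataFrame(rows).set_index("mirna")


def call_demirs(de: pd.DataFrame) -> dict[str, set]:
    """Significant miRNA sets per comparison and their union (the DEmiR set)."""
    c1 = set(de.index[de["sig_II_vs_I"]])
    c2 = set(de.index[de["sig_III_vs_II"]])
    return {"II_vs_I": c1, "III_vs_II": c2, "union": c1 | c2}


def replicate_qc(tpm_df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation of libraries on log2(TPM) and PCA coordinates.

    Libraries with zero variance get missing correlations.  PCA is the
    eigendecomposition of the library-by-library covariance of the centered
    log2 matrix; signs are fixed so each component's largest loading is
    positive.  Returns (9x9 correlation DataFrame, PC coordinate DataFrame).
    """
    if tpm_df.shape[1] < 2:
        raise ValueError("need at least two libraries")
    x = np.log2(tpm_df.to_numpy(dtype=float))
    libs = tpm_df.columns
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    sd = x.std(axis=0)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    corr_df = pd.DataFrame(corr, index=libs, columns=libs)

    centered = x.T - x.T.mean(axis=0)  # libraries x features, feature-centered
    cov = centered @ centered.T / max(1, centered.shape[1] - 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    coords = vecs[:, :2] * np.sqrt(np.clip(vals[:2], 0, None))
    for k in range(coords.shape[1]):
        if coords[np.argmax(np.abs(coords[:, k])), k] < 0:
            coords[:, k] *= -1
    pca_df = pd.DataFrame(coords, index=libs, columns=["PC1", "PC2"])
    return corr_df, pca_df
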