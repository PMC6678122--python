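"""TPM, fold changes, DE calling, trend classes and replicate QC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from seedmir.quantify import (
    call_demirs,
    classify_trend,
    de_test,
    differential_expression,
    expression_matrix,
    is_significant,
    log2fc,
    replicate_qc,
    tpm,
)


def test_tpm_worked_examples():
    assert tpm(2, 20_000_000) == pytest.approx(0.1)
    assert tpm(0, 123456) == 0.01  # floor for absent miRNAs
    assert tpm(5000, 5000) == pytest.approx(1e6)
    with pytest.raises(ValueError):
        tpm(-1, 100)


def test_prefloor_column_sums_are_one_million():
    rng = np.random.default_rng(0)
    counts = pd.DataFrame(rng.integers(0, 500, (40, 9)))
    m = expression_matrix(counts, floor=False)
    assert np.allclose(m.sum(axis=0), 1e6, rtol=1e-9)
    floored = expression_matrix(counts)
    assert (floored.to_numpy()[counts.to_numpy() == 0] == 0.01).all()


@given(
    a=st.floats(1e-3, 1e6, allow_nan=False),
    b=st.floats(1e-3, 1e6, allow_nan=False),
)
@settings(max_examples=60, derandomize=True)
def test_log2fc_antisymmetry(a, b):
    assert log2fc(a, b) == pytest.approx(-log2fc(b, a), abs=1e-9)


def test_log2fc_examples():
    assert log2fc(4.0, 1.0) == pytest.approx(2.0)
    assert log2fc(3.7, 3.7) == 0.0


def test_floor_symmetry_for_single_phase_expression():
    """Expression only in phase II gives mirrored fold changes (II/I = -III/II)."""
    tpm_i, tpm_ii, tpm_iii = 0.01, tpm(5, 20_000_000), 0.01
    assert log2fc(tpm_ii, tpm_i) == pytest.approx(-log2fc(tpm_iii, tpm_ii))


def test_de_test_behaviour():
    assert de_test([1, 1, 1], [1, 1, 1]) == 1.0
    assert de_test([1, 1, 1], [8, 8.1, 7.9]) < 0.05
    a, b = [1.1, 0.9, 1.0], [3.9, 4.2, 4.1]
    assert de_test(a, b) == pytest.approx(de_test(b, a))
    with pytest.raises(ValueError):
        de_test([1], [2, 3])


def test_significance_thresholds():
    assert is_significant(1.07, 0.01)          # 2.1-fold at P=0.01
    assert not is_significant(0.9, 0.001)      # below 2-fold
    assert not is_significant(3.0, 0.2)        # P too large
    assert is_significant(-1.0, 0.05)          # boundary values count


@pytest.mark.parametrize(
    "lfc1,lfc2,expected",
    [
        (2.01, -2.16, "bell"),
        (1.58, 1.49, "up-up"),
        (-2.50, 1.13, "V"),
        (-1.39, -1.19, "down-down"),
    ],
)
def test_trend_classes_for_double_significant_changes(lfc1, lfc2, expected):
    assert classify_trend(True, lfc1, True, lfc2) == expected


def test_trend_classes_single_and_none():
    assert classify_trend(True, 1.5, False, -0.2) == "single-up"
    assert classify_trend(False, 0.1, True, -1.5) == "single-down"
    assert classify_trend(False, 0.4, False, -0.4) == "ns"


PHASES = {p: [f"MpS{p}-{r}" for r in (1, 2, 3)] for p in ("I", "II", "III")}
LIBS = [l for libs in PHASES.values() for l in libs]


def test_differential_expression_and_demir_partition():
    rows = {
        "up": [10, 11, 9, 41, 39, 40, 160, 170, 150],
        "bell": [10, 10, 11, 80, 85, 78, 11, 9, 10],
        "flat": [50, 52, 48, 51, 49, 50, 50, 51, 49],
    }
    counts = pd.DataFrame(rows, index=LIBS).T
    tpm_df = expression_matrix(counts, pd.Series(1_000_000, index=LIBS))
    de = differential_expression(tpm_df, PHASES)
    assert de.loc["up", "trend"] == "up-up"
    assert de.loc["bell", "trend"] == "bell"
    assert de.loc["flat", "trend"] == "ns"
    sets = call_demirs(de)
    assert sets["union"] == {"up", "bell"}
    both = set(de.index[de["sig_II_vs_I"] & de["sig_III_vs_II"]])
    bothclasses = de.loc[list(both), "trend"].isin(["bell", "V", "up-up", "down-down"])
    assert bothclasses.all()  # double-significant miRNAs get a double-class trend


def test_degenerate_fc_threshold_yields_no_demirs():
    counts = pd.DataFrame(
        {"x": [10, 11, 9, 41, 39, 40, 160, 170, 150]}, index=LIBS
    ).T
    tpm_df = expression_matrix(counts, pd.Series(1_000_000, index=LIBS))
    de = differential_expression(tpm_df, PHASES, fc_threshold=1e6)
    assert call_demirs(de)["union"] == set()


def test_replicate_qc_duplicated_library_and_constant_column():
    rng = np.random.default_rng(1)
    base = rng.lognormal(3, 1, 30)
    df = pd.DataFrame(
        {
            "A1": base,
            "A2": base,  # exact duplicate
            "B1": base * rng.lognormal(0, 0.5, 30),
            "C1": np.ones(30),  # constant -> undefined correlation
        }
    )
    corr, pca = replicate_qc(df)
    assert corr.loc["A1", "A2"] == pytest.approx(1.0)
    assert np.isnan(corr.loc["C1", "A1"])
    assert set(pca.columns) == {"PC1", "PC2"}


def test_replicates_cluster_by_phase(small_pipeline):
    """Within-phase correlations exceed between-phase ones; PC1/2 separate phases."""
    _, out = small_pipeline
    corr = out["qc_correlation"]
    libs = list(corr.columns)
    within, between = [], []
    for i, a in enumerate(libs):
        for b in libs[i + 1:]:
            (within if a.split("-")[0] == b.split("-")[0] else between).append(
                corr.loc[a, b]
            )
    assert np.mean(within) > np.mean(between)
    pca = out["qc_pca"]
    phase_of = {lib: lib.split("-")[0] for lib in libs}
    from sklearn.metrics import silhouette_score

    score = silhouette_score(pca.to_numpy(), [phase_of[l] for l in pca.index])
    assert score > 0


def test_pearson_matches_covariance_formula():
    rng = np.random.default_rng(2)
    x = rng.normal(size=10)
    y = 0.5 * x + rng.normal(size=10)
    df = pd.DataFrame({"a": np.exp(x), "b": np.exp(y)})
    corr, _ = replicate_qc(df)
    assert corr.loc["a", "b"] == pytest.approx(oracles.pearson_r(x, y), abs=1e-9)
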