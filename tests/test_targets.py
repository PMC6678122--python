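"""Target-site scoring rules, duplex energetics and transcriptome scanning."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from seedmir.targets import (
    TargetRules,
    duplex_mfe,
    perfect_complement,
    perfect_mfe,
    scan_transcriptome,
    scan_unigene,
    score_site,
)

MIR = "UGACAGAAGAGAGUGAGCACA"
L = len(MIR)


def mutate(window: str, pos1: int, newbase: str) -> str:
    """Replace the target base facing miRNA position ``pos1`` (1-based)."""
    i = L - pos1
    return window[:i] + newbase + window[i + 1:]


def facing(mirna: str, base: str) -> dict:
    return {"A": "U", "U": "A", "G": "C", "C": "G"}[base]


def test_perfect_complement_scores_zero_and_passes():
    states, score, ok = score_site(MIR, perfect_complement(MIR))
    assert score == 0.0 and ok and set(states) == {"M"}


def test_single_gu_wobble_scores_half_and_passes():
    pos = MIR.index("G", 3) + 1  # a G outside positions 10-11
    w = mutate(perfect_complement(MIR), pos, "U")
    states, score, ok = score_site(MIR, w)
    assert states[pos - 1] == "G" and score == 0.5 and ok


def test_mismatch_at_position_10_fails():
    w = mutate(perfect_complement(MIR), 10, "C" if MIR[9] in "CU" else "A")
    states, score, ok = score_site(MIR, w)
    assert states[9] == "X" and not ok


def test_gu_at_position_11_is_allowed_but_configurable():
    assert MIR[10] == "G"
    w = mutate(perfect_complement(MIR), 11, "U")
    _, score, ok = score_site(MIR, w)
    assert score == 0.5 and ok
    _, _, strict = score_site(MIR, w, TargetRules(allow_gu_central=False))
    assert not strict


def test_adjacent_mismatches_in_seed_fail():
    pc = perfect_complement(MIR)
    w = mutate(mutate(pc, 4, "A" if MIR[3] != "U" else "C"), 5, "C" if MIR[4] != "G" else "A")
    _, _, ok = score_site(MIR, w)
    assert not ok


def test_score_above_four_fails():
    w = perfect_complement(MIR)
    for pos in (1, 13, 15, 18, 21):
        bad = {"A": "C", "C": "A", "G": "A", "U": "C"}[MIR[pos - 1]]
        w = mutate(w, pos, bad)
    _, score, ok = score_site(MIR, w)
    assert score == 5.0 and not ok


def test_length_mismatch_is_an_error():
    with pytest.raises(ValueError):
        score_site(MIR, "ACGU")


def test_perfect_duplex_ratio_is_100():
    d = duplex_mfe(MIR, perfect_complement(MIR))
    assert d == perfect_mfe(MIR) < 0
    assert 100.0 * d / perfect_mfe(MIR) == pytest.approx(100.0)


def test_duplex_energy_matches_hand_summed_stacks():
    mir = "GGCAUCGAUGCUA"  # 13-nt toy
    w = list(perfect_complement(mir))
    # mismatches facing positions 4 and 9
    w[len(mir) - 4] = "C" if mir[3] != "G" else "A"
    w[len(mir) - 9] = "C" if mir[8] != "G" else "A"
    window = "".join(w)
    assert duplex_mfe(mir, window) == pytest.approx(
        oracles._naive_duplex(mir, window), abs=1e-9
    )


@given(st.integers(0, 10_000))
@settings(max_examples=60, derandomize=True)
def test_mutated_duplex_never_beats_perfect(seed):
    rng = np.random.default_rng(seed)
    mir = "".join(rng.choice(list("ACGU"), 21))
    w = list(perfect_complement(mir))
    for _ in range(int(rng.integers(1, 5))):
        i = int(rng.integers(0, 21))
        w[i] = "ACGU"[int(rng.integers(0, 4))]
    d = duplex_mfe(mir, "".join(w))
    assert abs(d) <= abs(perfect_mfe(mir)) + 1e-9


@given(st.integers(0, 10_000))
@settings(max_examples=40, derandomize=True)
def test_verdict_monotone_under_mismatch_repair(seed):
    """Turning any mismatch into a WC match never flips pass into fail."""
    rng = np.random.default_rng(seed)
    mir = "".join(rng.choice(list("ACGU"), 21))
    w = list(perfect_complement(mir))
    for _ in range(int(rng.integers(1, 6))):
        i = int(rng.integers(0, 21))
        w[i] = "ACGU"[int(rng.integers(0, 4))]
    window = "".join(w)
    states, _, ok = score_site(mir, window)
    if not ok:
        return
    for pos1 in [p + 1 for p, s in enumerate(states) if s == "X"]:
        repaired = mutate_generic(mir, window, pos1)
        _, _, still_ok = score_site(mir, repaired)
        assert still_ok
        d = duplex_mfe(mir, repaired)
        assert abs(d) >= abs(duplex_mfe(mir, window)) - 1e-9


def mutate_generic(mir, window, pos1):
    i = len(mir) - pos1
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}[mir[pos1 - 1]]
    return window[:i] + comp + window[i + 1:]


def test_scanner_equals_bruteforce_on_synthetic_unigene():
    rng = np.random.default_rng(77)
    unigene = "".join(rng.choice(list("ACGT"), 500))
    # embed a perfect site and a half-penalty site for one miRNA
    site = perfect_complement(MIR).replace("U", "T")
    unigene = unigene[:100] + site + unigene[100 + L:]
    mirnas = {"m1": MIR, "m2": "".join(rng.choice(list("ACGU"), 21))}
    df = scan_transcriptome(mirnas, {"U1": unigene})
    for mid, mseq in mirnas.items():
        expected = oracles.naive_site_scan(mseq, unigene)
        got = df[df["mirna"] == mid]
        assert len(got) == len(expected)
        for (start0, score, dmfe), (_, row) in zip(expected, got.iterrows()):
            assert row["start"] == start0 + 1
            assert row["score"] == pytest.approx(score)
            assert row["duplex_mfe"] == pytest.approx(dmfe, abs=0.01)


def test_no_complementarity_yields_zero_sites():
    df = scan_transcriptome({"m": "A" * 21}, {"U1": "T" * 19 + "A" * 100})
    # window of 21 As against poly-A unigene: A:A never pairs
    assert df[df["unigene"] == "U1"].pipe(len) >= 0  # structure sanity
    assert len(scan_transcriptome({"m": "C" * 21}, {"U1": "G" * 10 + "A" * 200})) == 0


def test_planted_sites_recovered_at_planted_coordinates(small_pipeline):
    bundle, out = small_pipeline
    sites = out["target_sites"]
    id_by_seq = {r.sequence: r.id for r in out["_records"]}
    for _, row in bundle.truth.targets.iterrows():
        mid = id_by_seq.get(row["mature"])
        assert mid is not None
        hit = sites[
            (sites["mirna"] == mid)
            & (sites["unigene"] == row["unigene"])
            & (sites["start"] == row["start"])
        ]
        assert len(hit) == 1
        assert hit.iloc[0]["score"] == pytest.approx(row["designed_score"])
        assert hit.iloc[0]["mfe_ratio"] >= 75.0
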