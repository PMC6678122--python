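"""Conserved matching, precursor recovery/metrics, novel prediction, Venn."""

import pandas as pd
import pytest

from seedmir.mirna_id import (
    MiRNARecord,
    Precursor,
    TranscriptomeIndex,
    build_tag_map,
    match_conserved,
    parse_reference_name,
    phase_presence,
    precursor_stats,
    recover_precursor,
    revcomp_dna,
)
from seedmir.preprocess import combine_tag_counts

LIBS = [f"MpS{p}-{r}" for p in ("I", "II", "III") for r in (1, 2, 3)]
PHASES = {p: [f"MpS{p}-{r}" for r in (1, 2, 3)] for p in ("I", "II", "III")}

MATURE = "TGACAGAAGAGAGTGAGCACA"
HAIRPIN = MATURE + "GTCTAAATCGGAT" + revcomp_dna(MATURE)[:-2]


def counts_frame(**tags):
    return combine_tag_counts({lib: dict(tags) for lib in LIBS})


def test_exact_match_becomes_conserved_record():
    counts = counts_frame(**{MATURE: 12})
    recs = match_conserved(counts, [("gma-miR156a-5p", MATURE.replace("T", "U"))])
    assert len(recs) == 1
    rec = recs[0]
    assert rec.id == "mpi-miR156a-5p"
    assert rec.family == "MIR156"
    assert rec.arm == "5p"
    assert rec.origin == "conserved"
    assert rec.counts["MpSII-2"] == 12


def test_single_mismatch_is_not_conserved():
    near = "A" + MATURE[1:]
    recs = match_conserved(
        counts_frame(**{near: 50}), [("gma-miR156a-5p", MATURE.replace("T", "U"))]
    )
    assert recs == []


def test_synonyms_resolve_to_first_reference_in_file_order():
    ref = [
        ("gma-miR166a-3p", MATURE.replace("T", "U")),
        ("mtr-miR166b-3p", MATURE.replace("T", "U")),
    ]
    recs = match_conserved(counts_frame(**{MATURE: 1}), ref)
    assert recs[0].id == "mpi-miR166a-3p"
    assert recs[0].synonyms == ("mtr-miR166b-3p",)


def test_unparsable_family_warns_and_is_unknown():
    with pytest.warns(UserWarning):
        local, family, arm = parse_reference_name("xyz-weird-name")
    assert family == "unknown"


def test_precursor_metric_identities():
    p = Precursor(
        unigene_id="U1", start=1, end=149, sequence="G" * 149, structure="." * 149,
        mfe=-55.56, gc=43.78, arm="5p", mature_start=1, mature_end=21,
    )
    assert p.length == 149
    assert p.amfe == pytest.approx(-37.29, abs=0.005)
    assert p.mfei == pytest.approx(-0.852, abs=0.0005)


def test_precursor_stats_means():
    mk = lambda mfe, gc, ln: Precursor(
        "U", 1, ln, "G" * ln, "." * ln, mfe, gc, "5p", 1, 21
    )
    a, b = mk(-50.0, 50.0, 100), mk(-40.0, 50.0, 100)
    stats = precursor_stats([a, b])
    assert stats["mean_mfe"] == pytest.approx(-45.0)
    assert a.amfe == pytest.approx(-50.0) and a.mfei == pytest.approx(-1.0)
    assert stats["mean_mfei"] == pytest.approx((a.mfei + b.mfei) / 2)
    with pytest.raises(ValueError):
        precursor_stats([])


def _record(counts_df):
    return MiRNARecord(
        id="mpi-miR156a-5p", sequence=MATURE.replace("T", "U"), family="MIR156",
        arm="5p", origin="conserved", counts=counts_df.loc[MATURE],
    )


def _study(n_mature_reads):
    left = "CATGGACCTAGACATGAACCGATACGGATTACGGATCCGATTAG"
    right = "CCATGGATCGATTAGCCATGGACCGTTAACGGATCCTTAACCGG"
    unigene = left + HAIRPIN + right
    counts = combine_tag_counts(
        {lib: {MATURE: n_mature_reads} for lib in LIBS}
    )
    index = TranscriptomeIndex({"U1": unigene})
    tag_map = build_tag_map(counts, index)
    return counts, index, tag_map


def test_precursor_recovered_with_anchor_support():
    counts, index, tag_map = _study(50)
    precs = recover_precursor(_record(counts), index, tag_map, counts.sum(axis=1))
    assert len(precs) == 1
    prec = precs[0]
    assert prec.arm == "5p"
    assert prec.anchored_reads_5p == 50 * len(LIBS)
    assert prec.mfe < 0
    assert prec.amfe == pytest.approx(prec.mfe / prec.length * 100)
    assert prec.mfei == pytest.approx(prec.amfe / prec.gc)
    # mature inside the reported window
    assert prec.start <= prec.mature_start <= prec.mature_end <= prec.end


def test_precursor_rejected_at_ten_or_fewer_anchoring_reads():
    counts, index, tag_map = _study(1)  # 9 reads total over 9 libraries
    assert recover_precursor(_record(counts), index, tag_map, counts.sum(axis=1)) == []
    counts, index, tag_map = _study(5)  # 45 reads -> accepted (> 10)
    assert len(recover_precursor(_record(counts), index, tag_map, counts.sum(axis=1))) == 1


def test_mature_absent_from_transcriptome_gives_no_precursor():
    counts = counts_frame(**{MATURE: 100})
    index = TranscriptomeIndex({"U1": "ACGT" * 100})
    tag_map = build_tag_map(counts, index)
    assert recover_precursor(_record(counts), index, tag_map, counts.sum(axis=1)) == []


def venn_record(origin, lib_counts):
    ser = pd.Series(0, index=LIBS)
    for lib, c in lib_counts.items():
        ser[lib] = c
    return MiRNARecord("x", "ACGU" * 5, "F", "5p", origin, ser)


def test_phase_presence_regions():
    recs = [
        venn_record("conserved", {"MpSII-1": 3}),                       # II only
        venn_record("conserved", {lib: 1 for lib in LIBS}),             # all three
        venn_record("novel", {"MpSI-1": 1, "MpSIII-2": 2}),             # I and III
        venn_record("novel", {}),                                       # absent
    ]
    venn = phase_presence(recs, PHASES)
    assert venn.loc["II", "conserved"] == 1
    assert venn.loc["I&II&III", "conserved"] == 1
    assert venn.loc["I&III", "novel"] == 1
    assert venn["total"].sum() == 3  # absent miRNA not counted


def test_planted_recovery_and_exclusions(small_pipeline):
    """On synthetic data: planted conserved all found, no tag is both
    conserved and novel, and phase-exclusive designs land in their region."""
    bundle, out = small_pipeline
    truth = bundle.truth.mirnas
    recs = out["_records"]
    found_cons = {r.sequence for r in recs if r.origin == "conserved"}
    planted_cons = set(truth.loc[truth.origin == "conserved", "sequence"])
    assert found_cons == planted_cons  # full recall, no false conserved
    found_novel = {r.sequence for r in recs if r.origin == "novel"}
    assert not (found_cons & found_novel)
    # AMFE / MFEI identities on every emitted precursor
    precs = out["precursors"]
    for _, p in precs.iterrows():
        assert p["amfe"] == pytest.approx(p["mfe"] / p["length"] * 100, abs=0.01)
        assert p["mfei"] == pytest.approx(p["amfe"] / p["gc"], abs=0.001)
    # venn regions sum to miRNAs present anywhere
    venn = out["venn"]
    assert venn["total"].sum() == len(recs)
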