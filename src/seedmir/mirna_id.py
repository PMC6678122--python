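"""Conserved and novel miRNA identification against a seed transcriptome.

Conserved miRNAs are clean tags identical (0 mismatches) to a mature plant
miRNA reference; their hairpin precursors are recovered from the unigene the
mature maps to, keeping the candidate window that minimizes the minimal
folding free energy index (MFEI = AMFE / GC%, AMFE = MFE/length x 100).
Novel miRNAs are unannotated tags whose genomic neighborhood folds into a
qualifying stem-loop with the mature on one arm.
"""

from __future__ import annotations

import re
import warnings
from collections import defaultdict
from dataclasses import dataclass, field

import pandas as pd

from .energy import gc_percent
from .fold import fold, mature_arm, paired_in_interval, terminal_loop

_RC = str.maketrans("ACGTU", "TGCAA")


def revcomp_dna(s: str) -> str:
    return s.translate(_RC)[::-1]


def as_dna(s: str) -> str:
    return s.upper().replace("U", "T")


def as_rna(s: str) -> str:
    return s.upper().replace("T", "U")


@dataclass
class MiRNARecord:
    """A mature miRNA (conserved or novel) with per-library read counts."""

    id: str
    sequence: str  # RNA alphabet
    family: str
    arm: str | None
    origin: str  # "conserved" | "novel"
    counts: pd.Series
    source_ref: str | None = None
    synonyms: tuple = ()


@dataclass
class Precursor:
    """Candidate hairpin with structure, energetics and arm read support.

    Coordinates are 1-based inclusive on the unigene; AMFE is MFE per 100 nt
    and MFEI is AMFE divided by GC percentage.
    """

    unigene_id: str
    start: int
    end: int
    sequence: str
    structure: str
    mfe: float
    gc: float
    arm: str
    mature_start: int
    mature_end: int
    anchored_reads_5p: int = 0
    anchored_reads_3p: int = 0
    mirna_id: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def amfe(self) -> float:
        return self.mfe / self.length * 100.0

    @property
    def mfei(self) -> float:
        return self.amfe / self.gc


@dataclass
class WindowConfig:
    """Precursor window search: symmetric windows around the mature locus."""

    min_window: int = 60
    max_window: int = 300
    step: int = 20


class TranscriptomeIndex:
    """Exact substring location of tags in unigenes via anchored k-mer seeds."""

    def __init__(self, transcriptome: dict[str, str], k: int = 15):
        self.k = k
        self.seqs = {uid: as_dna(s) for uid, s in transcriptome.items()}
        idx = defaultdict(list)
        for uid, seq in self.seqs.items():
            for p in range(len(seq) - k + 1):
                idx[seq[p : p + k]].append((uid, p))
        self._idx = dict(idx)

    def locate(self, tag: str) -> list[tuple[str, int]]:
        """All (unigene id, 0-based start) exact sense-strand occurrences."""
        t = as_dna(tag)
        if len(t) < self.k:
            return []
        hits = []
        for uid, p in self._idx.get(t[: self.k], ()):  # anchored at tag start
            if self.seqs[uid].startswith(t, p):
                hits.append((uid, p))
        return hits


def build_tag_map(
    tag_counts: pd.DataFrame, index: TranscriptomeIndex
) -> dict[str, list[tuple[int, int, str]]]:
    """unigene -> sorted [(start, end, tag)] (0-based half-open) for all tags."""
    out: dict[str, list] = defaultdict(list)
    for tag in tag_counts.index:
        for uid, p in index.locate(tag):
            out[uid].append((p, p + len(tag), tag))
    return {uid: sorted(v) for uid, v in out.items()}


_NAME_RE = re.compile(r"^([a-z]{3,4})-(.+)$", re.IGNORECASE)
_FAMILY_RE = re.compile(r"miR[a-zA-Z]*?(\d+)", re.IGNORECASE)
_ARM_RE = re.compile(r"-(5p|3p)$")


def parse_reference_name(name: str) -> tuple[str, str, str | None]:
    """miRBase-style name -> (local id with mpi- prefix, family, arm).

    ``gma-miR156a-5p`` -> (``mpi-miR156a-5p``, ``MIR156``, ``5p``).  A name
    whose family cannot be parsed yields family ``unknown`` with a warning.
    """
    m = _NAME_RE.match(name)
    rest = m.group(2) if m else name
    fam = _FAMILY_RE.search(rest)
    if fam:
        family = f"MIR{fam.group(1)}"
    else:
        warnings.warn(f"cannot parse miRNA family from reference name {name!r}")
        family = "unknown"
    arm = _ARM_RE.search(rest)
    return f"mpi-{rest}", family, arm.group(1) if arm else None


def match_conserved(
    tag_counts: pd.DataFrame, mature_reference: list[tuple[str, str]]
) -> list[MiRNARecord]:
    """Tags identical to a reference mature sequence (no mismatches).

    Ties (one sequence under several reference names) resolve to the first
    name in file order; the rest are recorded as synonyms.
    """
    by_seq: dict[str, list[str]] = {}
    for name, seq in mature_reference:
        by_seq.setdefault(as_dna(seq), []).append(name)
    records = []
    for tag in tag_counts.index:
        names = by_seq.get(as_dna(tag))
        if not names:
            continue
        local, family, arm = parse_reference_name(names[0])
        records.append(
            MiRNARecord(
                id=local,
                sequence=as_rna(tag),
                family=family,
                arm=arm,
                origin="conserved",
                counts=tag_counts.loc[tag],
                source_ref=names[0],
                synonyms=tuple(names[1:]),
            )
        )
    return records


def best_hairpin_window(
    unigene_id: str,
    sequence: str,
    mature_start: int,
    mature_end: int,
    cfg: WindowConfig = WindowConfig(),
) -> Precursor | None:
    """MFEI-minimizing single-stem window containing the mature on one arm.

    ``mature_start``/``mature_end`` are 0-based half-open on the unigene.
    Returns None when no window folds with the mature fully inside an arm.
    """
    seq = as_dna(sequence)
    n = len(seq)
    mlen = mature_end - mature_start
    center = (mature_start + mature_end) // 2
    best: Precursor | None = None
    tried: set[tuple[int, int]] = set()
    for w in range(cfg.min_window, cfg.max_window + 1, cfg.step):
        if w < mlen + 10:
            continue
        # the hairpin may extend to either side of the mature (arm position is
        # unknown), so try windows centered on, left-aligned to and
        # right-aligned to the mature locus
        for ws in (center - w // 2, mature_start, mature_end - w):
            ws = max(0, min(ws, mature_start))  # keep the mature inside
            ws = min(ws, max(0, n - w))
            we = min(n, ws + w)
            if we < mature_end:  # clipped off the mature; slide right
                ws = max(0, mature_end - w)
                we = min(n, ws + w)
            if we - ws < mlen + 10 or ws > mature_start or we < mature_end:
                continue
            if (ws, we) in tried:
                continue
            tried.add((ws, we))
            sub = seq[ws:we]
            res = fold(sub)
            if not res.pairs or res.mfe >= 0:
                continue
            arm = mature_arm(res.pairs, mature_start - ws, mature_end - ws)
            if arm is None:
                continue
            cand = Precursor(
                unigene_id=unigene_id,
                start=ws + 1,
                end=we,
                sequence=sub,
                structure=res.structure,
                mfe=res.mfe,
                gc=gc_percent(sub),
                arm=arm,
                mature_start=mature_start + 1,
                mature_end=mature_end,
            )
            if best is None or cand.mfei < best.mfei:
                best = cand
    return best


def arm_intervals(prec: Precursor) -> tuple[tuple[int, int], tuple[int, int]]:
    """0-based half-open (5p arm, 3p arm) intervals on the unigene.

    Arms span from the window edges to the terminal loop (overhanging mature
    ends are part of an arm even when unpaired).
    """
    from .fold import pairs_from_dotbracket

    pairs = pairs_from_dotbracket(prec.structure)
    k, l = terminal_loop(pairs)
    off = prec.start - 1
    return (off, off + k + 1), (off + l, prec.end)


def _anchored_reads(
    prec: Precursor,
    tag_map: dict[str, list[tuple[int, int, str]]],
    totals: pd.Series,
) -> tuple[int, int]:
    arm5, arm3 = arm_intervals(prec)
    r5 = r3 = 0
    for s, e, tag in tag_map.get(prec.unigene_id, ()):  # sorted by start
        if s >= arm3[1]:
            break
        c = int(totals.get(tag, 0))
        if arm5[0] <= s and e <= arm5[1]:
            r5 += c
        elif arm3[0] <= s and e <= arm3[1]:
            r3 += c
    return r5, r3


def recover_precursor(
    mirna: MiRNARecord,
    transcriptome_index: TranscriptomeIndex,
    tag_map: dict[str, list[tuple[int, int, str]]],
    tag_totals: pd.Series,
    min_anchor_reads: int = 10,
    cfg: WindowConfig = WindowConfig(),
) -> list[Precursor]:
    """Putative precursors for a mature miRNA (one per qualifying locus).

    A locus qualifies when its best window folds into a stem-loop with the
    mature on one arm and strictly more than ``min_anchor_reads`` reads anchor
    the 5p and/or the 3p arm.  Empty list when no locus qualifies.
    """
    mature = as_dna(mirna.sequence)
    out = []
    for uid, pos in transcriptome_index.locate(mature):
        prec = best_hairpin_window(
            uid, transcriptome_index.seqs[uid], pos, pos + len(mature), cfg
        )
        if prec is None:
            continue
        r5, r3 = _anchored_reads(prec, tag_map, tag_totals)
        prec.anchored_reads_5p, prec.anchored_reads_3p = r5, r3
        prec.mirna_id = mirna.id
        if max(r5, r3) > min_anchor_reads:
            out.append(prec)
    return out


def precursor_stats(precursors: list[Precursor]) -> dict:
    """Arithmetic means of length, GC%, MFE, AMFE and MFEI over precursors.

    ``mean_mfei`` is the mean of per-precursor MFEIs; ``mfei_from_means``
    (AMFE mean / GC mean) is also reported since summary tables are sometimes
    quoted that way.
    """
    if not precursors:
        raise ValueError("no precursors to summarize")
    n = len(precursors)
    mean = lambda xs: sum(xs) / n
    stats = {
        "n": n,
        "mean_length": mean([p.length for p in precursors]),
        "mean_gc": mean([p.gc for p in precursors]),
        "mean_mfe": mean([p.mfe for p in precursors]),
        "mean_amfe": mean([p.amfe for p in precursors]),
        "mean_mfei": mean([p.mfei for p in precursors]),
    }
    stats["mfei_from_means"] = stats["mean_amfe"] / stats["mean_gc"]
    return stats


@dataclass
class NovelParams:
    """Declared stem-loop criteria for novel miRNA prediction (Mireap-like)."""

    min_len: int = 18
    max_len: int = 26
    min_reads: int = 5  # total reads across libraries for a candidate tag
    max_mfe: float = -18.0
    max_mfei: float = -0.85
    min_paired: int = 16  # mature bases paired within the hairpin, G:U counts
    max_unpaired: int = 4  # unpaired mature bases
    seed_k: int = 12  # reverse-complement seed used to pre-screen loci
    neighborhood: int = 250


def _has_star_seed(seq: str, s: int, e: int, params: NovelParams) -> bool:
    # a genuine hairpin must carry near-reverse-complement sequence nearby;
    # require one exact seed_k-mer of the revcomp within the neighborhood
    rc = revcomp_dna(seq[s:e])
    lo = max(0, s - params.neighborhood)
    hi = min(len(seq), e + params.neighborhood)
    region = seq[lo:hi]
    for off in range(0, len(rc) - params.seed_k + 1, params.seed_k // 2):
        if rc[off : off + params.seed_k] in region:
            return True
    return False


def predict_novel(
    tag_counts: pd.DataFrame,
    transcriptome_index: TranscriptomeIndex,
    tag_map: dict[str, list[tuple[int, int, str]]],
    exclude_tags: set[str] = frozenset(),
    blocked: dict[str, list[tuple[int, int]]] | None = None,
    params: NovelParams = NovelParams(),
    cfg: WindowConfig = WindowConfig(),
) -> tuple[list[MiRNARecord], list[Precursor]]:
    """Predict novel miRNAs among unannotated tags.

    Candidates are visited by decreasing total read count; an accepted
    hairpin claims its arm intervals so that lower-abundance fragments of the
    same precursor do not spawn duplicate predictions.  ``blocked`` intervals
    (e.g. recovered conserved precursors) are never used.  Ids are assigned
    ``mpi-nmiRNNNN-{5p,3p}`` in discovery order; a tag mapping to several
    unigenes yields several precursor records under one id.
    """
    blocked = dict(blocked or {})
    claimed: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for uid, ivs in blocked.items():
        claimed[uid].extend(ivs)
    totals = tag_counts.sum(axis=1)
    cands = [
        t
        for t in tag_counts.index
        if t not in exclude_tags
        and params.min_len <= len(t) <= params.max_len
        and totals[t] >= params.min_reads
    ]
    cands.sort(key=lambda t: (-totals[t], t))
    records, precursors = [], []
    serial = 0
    for tag in cands:
        tag_precs = []
        for uid, pos in transcriptome_index.locate(tag):
            s, e = pos, pos + len(tag)
            if any(s < ce and cs < e for cs, ce in claimed.get(uid, ())):
                continue
            if not _has_star_seed(transcriptome_index.seqs[uid], s, e, params):
                continue
            prec = best_hairpin_window(uid, transcriptome_index.seqs[uid], s, e, cfg)
            if prec is None:
                continue
            from .fold import pairs_from_dotbracket

            pairs = pairs_from_dotbracket(prec.structure)
            off = prec.start - 1
            paired = paired_in_interval(pairs, s - off, e - off)
            if (
                prec.mfe <= params.max_mfe
                and prec.mfei <= params.max_mfei
                and paired >= params.min_paired
                and (len(tag) - paired) <= params.max_unpaired
            ):
                tag_precs.append(prec)
        if not tag_precs:
            continue
        serial += 1
        arm = tag_precs[0].arm
        mid = f"mpi-nmiR{serial:04d}-{arm}"
        rec = MiRNARecord(
            id=mid,
            sequence=as_rna(tag),
            family="novel",
            arm=arm,
            origin="novel",
            counts=tag_counts.loc[tag],
        )
        records.append(rec)
        for prec in tag_precs:
            prec.mirna_id = mid
            r5, r3 = _anchored_reads(prec, tag_map, totals)
            prec.anchored_reads_5p, prec.anchored_reads_3p = r5, r3
            precursors.append(prec)
            for iv in arm_intervals(prec):
                claimed[prec.unigene_id].append(iv)
    return records, precursors


def phase_presence(
    records: list[MiRNARecord], phases: dict[str, list[str]]
) -> pd.DataFrame:
    """Venn partition of miRNAs over phases (present = >=1 read in the phase).

    Returns region counts (rows: 'I', 'II', 'I&II', ..., in subset order)
    with one column per origin plus a total.
    """
    names = list(phases)
    regions = []
    for size in (1, 2, 3):
        if size > len(names):
            break
        from itertools import combinations

        for combo in combinations(names, size):
            regions.append("&".join(combo))
    counts = {r: defaultdict(int) for r in regions}
    for rec in records:
        present = [
            p for p, libs in phases.items() if rec.counts[list(libs)].sum() >= 1
        ]
        if not present:
            continue
        key = "&".join(present)
        counts[key][rec.origin] += 1
    df = pd.DataFrame(
        {
            origin: [counts[r][origin] for r in regions]
            for origin in ("conserved", "novel")
        },
        index=pd.Index(regions, name="region"),
    )
    df["total"] = df.sum(axis=1)
    return df
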