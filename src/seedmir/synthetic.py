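"""Synthetic small-RNA-seq study generator with planted ground truth.

Emulates a three-phase (embryogenesis, seed-filling, desiccation) seed
development small-RNA experiment with three biological replicates per phase:
a unigene transcriptome carrying planted miRNA hairpin precursors, a
miRBase-style mature reference containing the planted conserved matures (plus
decoys, and never the planted novels), a contaminant ncRNA reference, GO/KEGG
annotation tables with one GO term enriched by construction among planted
target genes, and nine FASTQ libraries with adapter/polyA/quality/length
artifacts at configured rates and phase-structured planted expression.

Everything derives from one integer seed; two runs with the same
configuration are byte-identical.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .fold import fold, mature_arm, pairs_from_dotbracket, paired_in_interval
from .energy import gc_percent
from .mirna_id import as_rna, revcomp_dna
from .targets import score_site, duplex_mfe, perfect_mfe

PHASES = ("I", "II", "III")
LIBRARIES = tuple(f"MpS{p}-{r}" for p in PHASES for r in (1, 2, 3))
PHASE_OF = {lib: lib.split("-")[0][3:] for lib in LIBRARIES}

#: expression multipliers per phase for each trend class
PROFILES = {
    "bell": (1.0, 4.0, 1.0),
    "V": (4.0, 1.0, 4.0),
    "up": (1.0, 4.0, 16.0),
    "down": (16.0, 4.0, 1.0),
    "exclusive-I": (1.0, 0.0, 0.0),
    "exclusive-II": (0.0, 1.0, 0.0),
    "exclusive-III": (0.0, 0.0, 1.0),
    "flat": (1.0, 1.0, 1.0),
}

#: trend class the quantifier should assign to each profile at adequate depth
EXPECTED_TREND = {
    "bell": "bell",
    "V": "V",
    "up": "up-up",
    "down": "down-down",
    "exclusive-I": "single-down",
    "exclusive-II": "bell",
    "exclusive-III": "single-up",
    "flat": "ns",
}

_DEFAULT_CYCLE = (
    "bell", "V", "up", "down", "exclusive-I", "exclusive-II", "exclusive-III", "flat",
)

_FAMILY_NUMBERS = (
    156, 159, 160, 164, 166, 167, 168, 171, 172, 319,
    390, 393, 396, 398, 399, 408, 482, 1507, 1510, 2118,
)
_SPECIES = ("gma", "mtr", "ptc")


@dataclass
class ArtifactRates:
    """Fractions of reads per library synthesized as each artifact class."""

    no_adapter3: float = 0.02
    polya: float = 0.02
    low_quality: float = 0.03
    too_short: float = 0.03

    @property
    def total(self) -> float:
        return self.no_adapter3 + self.polya + self.low_quality + self.too_short


@dataclass
class SimulationConfig:
    """Study design knobs; defaults are the conditions the pipeline is tested at."""

    rng_seed: int = 1
    n_unigenes: int = 150
    unigene_length: tuple[int, int] = (400, 800)
    n_conserved_planted: int = 20
    n_novel_planted: int = 10
    n_decoy_reference: int = 30
    n_contaminant_species: int = 3
    phase_depths: tuple = ((100_000,) * 3,) * 3
    adapter3: str = "TGGAATTCTCGGGTGCCAAGG"
    adapter5: str = "GTTCAGAGTTCTACAGTCCGACGATC"
    artifact_rates: ArtifactRates = field(default_factory=ArtifactRates)
    contaminant_fractions: tuple[float, float, float] = (0.083, 0.040, 0.059)
    mirna_fraction: float = 0.06
    replicate_sigma: float = 0.2  # lognormal sd on expected counts
    mature_length: int = 21
    read_length: int = 50
    profile_assignments: dict[int, str] | None = None  # planted index -> class

    def validate(self) -> None:
        ar = self.artifact_rates
        for frac in (
            ar.no_adapter3, ar.polya, ar.low_quality, ar.too_short,
            self.mirna_fraction, *self.contaminant_fractions,
        ):
            if not 0 <= frac <= 1:
                raise ValueError("all fractions must lie in [0, 1]")
        if ar.total >= 1:
            raise ValueError("artifact rates must sum to < 1")
        for phase in self.phase_depths:
            for d in phase:
                if d <= 0:
                    raise ValueError("phase depths must be positive")
        if self.n_conserved_planted < 0 or self.n_novel_planted < 0:
            raise ValueError("planted counts must be >= 0")
        n_planted = self.n_conserved_planted + self.n_novel_planted
        if n_planted > self.n_unigenes:
            raise ValueError("more planted hairpins than unigenes")
        if self.unigene_length[0] < self.mature_length * 2 + 20 + 100:
            raise ValueError(
                "unigenes too short to host hairpin precursors with flanks"
            )

    def profile_of(self, planted_index: int) -> str:
        if self.profile_assignments and planted_index in self.profile_assignments:
            return self.profile_assignments[planted_index]
        return _DEFAULT_CYCLE[planted_index % len(_DEFAULT_CYCLE)]

    def depth(self, library: str) -> int:
        p = PHASES.index(PHASE_OF[library])
        r = int(library.split("-")[1]) - 1
        return int(self.phase_depths[p][r])


@dataclass
class TruthTable:
    """Planted ground truth: miRNAs, their loci and trends, targets, enrichment."""

    mirnas: pd.DataFrame  # index: truth id; columns below
    targets: pd.DataFrame
    enriched_term: str
    counts: pd.DataFrame | None = None  # realized reads per library (filled by simulate)


@dataclass
class ReferenceBundle:
    """All reference inputs the pipeline consumes, with their ground truth."""

    config: SimulationConfig
    unigenes: dict[str, str]
    mature_reference: list[tuple[str, str]]
    contaminants: list[tuple[str, str, str]]  # (id, class, DNA seq)
    go_annotations: pd.DataFrame
    kegg_annotations: pd.DataFrame
    truth: TruthTable

    def write(self, outdir) -> dict[str, str]:
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord
        from Bio import SeqIO

        os.makedirs(outdir, exist_ok=True)
        paths = {}

        def _fasta(name, records):
            path = os.path.join(outdir, name)
            SeqIO.write(records, path, "fasta")
            paths[name] = path

        _fasta(
            "unigenes.fasta",
            [SeqRecord(Seq(s), id=uid, description="") for uid, s in self.unigenes.items()],
        )
        _fasta(
            "mature_reference.fasta",
            [SeqRecord(Seq(s), id=n, description="") for n, s in self.mature_reference],
        )
        _fasta(
            "contaminants.fasta",
            [
                SeqRecord(Seq(s), id=rid, description=f"class={cls}")
                for rid, cls, s in self.contaminants
            ],
        )
        for name, df in (
            ("go_annotations.tsv", self.go_annotations),
            ("kegg_annotations.tsv", self.kegg_annotations),
            ("truth_mirnas.tsv", self.truth.mirnas.reset_index()),
            ("truth_targets.tsv", self.truth.targets),
        ):
            path = os.path.join(outdir, name)
            df.to_csv(path, sep="\t", index=False)
            paths[name] = path
        return paths


def _random_seq(rng, length, alphabet="ACGT") -> str:
    return "".join(np.array(list(alphabet))[rng.integers(0, len(alphabet), length)])


def _build_hairpin(rng, mature: str, arm: str) -> tuple[str, int, int]:
    """Hairpin core around ``mature``: star + randomized loop, 2-nt overhang.

    Returns (core DNA, mature start, mature end) with 0-based half-open
    mature coordinates inside the core.
    """
    loop = _random_seq(rng, int(rng.integers(8, 21)))
    star = revcomp_dna(mature)
    if arm == "5p":
        core = mature + loop + star[:-2]  # leaves the mature 5'-most 2 nt unpaired
        return core, 0, len(mature)
    core = star[2:] + loop + mature
    return core, len(core) - len(mature), len(core)


def _hairpin_ok(core: str, ms: int, me: int) -> bool:
    res = fold(core)
    if not res.pairs or res.mfe > -18.0:
        return False
    if mature_arm(res.pairs, ms, me) is None:
        return False
    amfe = res.mfe / len(core) * 100.0
    if amfe / gc_percent(core) > -0.85:
        return False
    paired = paired_in_interval(res.pairs, ms, me)
    return paired >= 16 and (me - ms) - paired <= 4


def _design_site(rng, mature_dna: str, variant: int) -> tuple[str, float]:
    """A planted target window (DNA, unigene sense strand) for ``mature``.

    variant 0: perfect complement; 1: one G:U wobble; 2: one G:U plus one
    mismatch in the 3' half.  Returns (window, designed mismatch score);
    always compliant with the site rules by construction.
    """
    m = as_rna(mature_dna)
    L = len(m)
    window = list(revcomp_dna(mature_dna))
    score = 0.0
    if variant >= 1:
        for pos in range(12, L):  # 3' half; G:U legal anywhere
            if m[pos] == "G":
                window[L - 1 - pos] = "T"  # G:U wobble
                score += 0.5
                break
            if m[pos] == "U":
                window[L - 1 - pos] = "G"
                score += 0.5
                break
    if variant >= 2:
        for pos in range(L - 1, 13, -1):
            i = L - 1 - pos
            cur = window[i]
            if score_site(m, as_rna("".join(window)))[0][pos] != "M":
                continue
            bad = {"A": "C", "C": "A", "G": "A", "U": "C"}[m[pos]]
            window[i] = bad
            cand = "".join(window)
            st, sc, ok = score_site(m, as_rna(cand))
            d = duplex_mfe(m, as_rna(cand))
            if ok and 100.0 * d / perfect_mfe(m) >= 75.0:
                score += 1.0
                break
            window[i] = cur
    return "".join(window), score


def make_references(config: SimulationConfig) -> ReferenceBundle:
    """Generate transcriptome, references, annotations and truth table.

    Every planted precursor is refolded with the bundled engine and must meet
    the stem-loop criteria (single stem, MFE <= -18, MFEI <= -0.85, mature on
    one arm); construction retries with fresh random parts and fails loudly
    if a compliant hairpin cannot be embedded at the configured lengths.
    """
    config.validate()
    rng = np.random.default_rng(int(config.rng_seed) % 2**31)
    n_planted = config.n_conserved_planted + config.n_novel_planted

    planted = []  # dicts describing planted miRNAs
    seen_matures: set[str] = set()
    for i in range(n_planted):
        origin = "conserved" if i < config.n_conserved_planted else "novel"
        for _attempt in range(40):
            mature = _random_seq(rng, config.mature_length)
            arm = ("5p", "3p")[int(rng.integers(0, 2))]
            core, ms, me = _build_hairpin(rng, mature, arm)
            if mature not in seen_matures and _hairpin_ok(core, ms, me):
                break
        else:
            raise ValueError(
                "could not construct a compliant hairpin at the requested lengths"
            )
        seen_matures.add(mature)
        if origin == "conserved":
            fam_no = _FAMILY_NUMBERS[i % len(_FAMILY_NUMBERS)]
            letter = chr(ord("a") + i // len(_FAMILY_NUMBERS))
            species = _SPECIES[i % len(_SPECIES)]
            ref_name = f"{species}-miR{fam_no}{letter}-{arm}"
            truth_id = f"mpi-miR{fam_no}{letter}-{arm}"
            family = f"MIR{fam_no}"
        else:
            ref_name = None
            truth_id = f"planted-novel-{i - config.n_conserved_planted + 1:03d}"
            family = "novel"
        planted.append(
            dict(
                truth_id=truth_id,
                origin=origin,
                sequence=as_rna(mature),
                mature_dna=mature,
                family=family,
                arm=arm,
                ref_name=ref_name,
                core=core,
                core_ms=ms,
                core_me=me,
                trend=config.profile_of(i),
            )
        )

    # unigenes: the first n_planted host hairpins, the rest are plain
    unigenes: dict[str, str] = {}
    lo, hi = config.unigene_length
    for u in range(config.n_unigenes):
        uid = f"Unigene{u + 1}"
        total = int(rng.integers(lo, hi + 1))
        if u < n_planted:
            core = planted[u]["core"]
            flank = total - len(core)
            left = int(rng.integers(50, max(51, flank - 50)))
            seq = _random_seq(rng, left) + core + _random_seq(rng, flank - left)
            planted[u]["unigene"] = uid
            planted[u]["prec_start"] = left + 1
            planted[u]["prec_end"] = left + len(core)
            planted[u]["mat_start"] = left + planted[u]["core_ms"] + 1
            planted[u]["mat_end"] = left + planted[u]["core_me"]
            unigenes[uid] = seq
        else:
            unigenes[uid] = _random_seq(rng, total)

    # planted target sites in non-hairpin unigenes
    plain = [f"Unigene{u + 1}" for u in range(n_planted, config.n_unigenes)]
    target_rows = []
    if plain:
        for i, p in enumerate(planted):
            uid = plain[i % len(plain)]
            window, designed = _design_site(rng, p["mature_dna"], i % 3)
            seq = unigenes[uid]
            pos = int(rng.integers(20, len(seq) - len(window) - 20))
            unigenes[uid] = seq[:pos] + window + seq[pos + len(window):]
            target_rows.append(
                dict(
                    truth_id=p["truth_id"],
                    mature=p["sequence"],
                    unigene=uid,
                    start=pos + 1,
                    end=pos + len(window),
                    designed_score=designed,
                )
            )
    targets_df = pd.DataFrame(
        target_rows,
        columns=["truth_id", "mature", "unigene", "start", "end", "designed_score"],
    )

    # mature reference: planted conserved (verbatim) + decoys, never the novels
    mature_reference = [
        (p["ref_name"], p["sequence"]) for p in planted if p["origin"] == "conserved"
    ]
    decoy_fams = tuple(range(2000, 2000 + config.n_decoy_reference))
    for d in range(config.n_decoy_reference):
        while True:
            seq = as_rna(_random_seq(rng, config.mature_length))
            if seq not in {s for _n, s in mature_reference}:
                break
        name = f"{_SPECIES[d % 3]}-miR{decoy_fams[d]}-5p"
        mature_reference.append((name, seq))

    # contaminant reference
    lengths = {"rRNA": (800, 1500), "tRNA": (70, 90), "snRNA": (100, 200), "snoRNA": (80, 150)}
    contaminants = []
    for cls, (clo, chi) in lengths.items():
        for k in range(config.n_contaminant_species):
            contaminants.append(
                (f"{cls}_sp{k + 1}", cls, _random_seq(rng, int(rng.integers(clo, chi))))
            )

    # annotations: one GO BP term enriched among planted target genes
    enriched_term = "GO:1000001"
    target_genes = sorted(set(targets_df["unigene"]))
    all_genes = sorted(unigenes, key=lambda u: int(u.replace("Unigene", "")))
    go_rows = [
        dict(gene=g, term=enriched_term, name="planted seed process", category="BP")
        for g in target_genes
    ]
    extra = [g for g in all_genes if g not in set(target_genes)]
    for g in extra[:2]:  # slight background presence keeps K > k possible
        go_rows.append(
            dict(gene=g, term=enriched_term, name="planted seed process", category="BP")
        )
    for t in range(10):
        term = f"GO:200000{t}" if t < 10 else f"GO:20000{t}"
        cat = ("MF", "BP", "CC")[t % 3]
        members = rng.choice(all_genes, size=max(2, int(0.2 * len(all_genes))), replace=False)
        for g in sorted(members):
            go_rows.append(dict(gene=g, term=term, name=f"random term {t}", category=cat))
    go_df = pd.DataFrame(go_rows, columns=["gene", "term", "name", "category"])
    kegg_rows = []
    for t in range(5):
        members = rng.choice(all_genes, size=max(2, int(0.15 * len(all_genes))), replace=False)
        for g in sorted(members):
            kegg_rows.append(
                dict(gene=g, term=f"ko0000{t + 1}", name=f"pathway {t + 1}", category="KEGG")
            )
    kegg_df = pd.DataFrame(kegg_rows, columns=["gene", "term", "name", "category"])

    mirnas_df = pd.DataFrame(
        [
            {
                k: p[k]
                for k in (
                    "truth_id", "origin", "sequence", "family", "arm", "ref_name",
                    "unigene", "prec_start", "prec_end", "mat_start", "mat_end", "trend",
                )
            }
            for p in planted
        ],
    )
    if not mirnas_df.empty:
        mirnas_df = mirnas_df.set_index("truth_id")
    else:
        mirnas_df = pd.DataFrame(
            columns=[
                "origin", "sequence", "family", "arm", "ref_name", "unigene",
                "prec_start", "prec_end", "mat_start", "mat_end", "trend",
            ],
            index=pd.Index([], name="truth_id"),
        )

    # per-miRNA relative abundance, fixed across libraries
    mirnas_df["base_weight"] = (
        rng.lognormal(0.0, 0.5, len(mirnas_df)) if len(mirnas_df) else []
    )

    truth = TruthTable(mirnas=mirnas_df, targets=targets_df, enriched_term=enriched_term)
    return ReferenceBundle(
        config=config,
        unigenes=unigenes,
        mature_reference=mature_reference,
        contaminants=contaminants,
        go_annotations=go_df,
        kegg_annotations=kegg_df,
        truth=truth,
    )


def _background_length_probs(phase: str) -> tuple[np.ndarray, np.ndarray]:
    lengths = np.arange(18, 31)
    secondary = 21 if phase == "I" else 22
    probs = np.full(len(lengths), (1.0 - 0.30 - 0.18) / 11)
    probs[lengths == 24] = 0.30
    probs[lengths == secondary] = 0.18
    return lengths, probs / probs.sum()


def simulate_libraries(
    bundle: ReferenceBundle, outdir
) -> tuple[dict[str, str], pd.DataFrame, pd.DataFrame]:
    """Write nine FASTQ libraries; return (paths, truth counts, components).

    Planted read counts follow the assigned trend profile with multiplicative
    lognormal replicate noise and Poisson sampling; contaminant fragments,
    degradation-like background (random unigene substrings) and the four
    artifact classes fill the remaining depth.  Also records realized
    per-library planted counts in ``bundle.truth.counts``.
    """
    config = bundle.config
    os.makedirs(outdir, exist_ok=True)
    mir = bundle.truth.mirnas
    n_m = len(mir)
    weights = mir["base_weight"].to_numpy() if n_m else np.array([])
    share = weights / weights.sum() if n_m else weights
    mults = np.array([PROFILES[t] for t in mir["trend"]]) if n_m else np.zeros((0, 3))
    mean_mult = mults.mean(axis=1) if n_m else np.array([])

    a3 = config.adapter3.upper()
    paths: dict[str, str] = {}
    truth_counts = pd.DataFrame(0, index=mir.index, columns=list(LIBRARIES))
    comp_rows = []
    unigene_ids = list(bundle.unigenes)
    unigene_seqs = [bundle.unigenes[u] for u in unigene_ids]

    for li, lib in enumerate(LIBRARIES):
        rng = np.random.default_rng([int(config.rng_seed) % 2**31, 7919 + li])
        phase = PHASE_OF[lib]
        pi = PHASES.index(phase)
        depth = config.depth(lib)
        lengths, lprobs = _background_length_probs(phase)

        # fractions are of non-artifact ("clean-equivalent") reads so that the
        # recovered clean-read fractions match the configured ones
        clean_depth = depth * (1.0 - config.artifact_rates.total)

        # planted counts
        if n_m:
            expected = (
                clean_depth * config.mirna_fraction * share * mults[:, pi]
                / np.where(mean_mult > 0, mean_mult, 1.0)
            )
            noise = rng.lognormal(0.0, config.replicate_sigma, n_m)
            counts = rng.poisson(expected * noise)
        else:
            counts = np.array([], dtype=int)
        truth_counts[lib] = counts

        ar = config.artifact_rates
        n_cont = round(clean_depth * config.contaminant_fractions[pi])
        n_art = {
            "no_adapter3": round(depth * ar.no_adapter3),
            "polyA": round(depth * ar.polya),
            "low_quality": round(depth * ar.low_quality),
            "too_short": round(depth * ar.too_short),
        }
        n_planted = int(counts.sum())
        bg_frac = max(
            0.0, 1.0 - ar.total - config.contaminant_fractions[pi] - config.mirna_fraction
        )
        n_bg = round(depth * bg_frac)

        reads: list[tuple[str, str]] = []  # (sequence, quality)

        def normal_read(insert: str) -> tuple[str, str]:
            seq = (insert + a3)[: config.read_length]
            return seq, "G" * len(seq)

        for seq_rna, c in zip(mir["sequence"], counts):
            insert = seq_rna.replace("U", "T")
            reads.extend([normal_read(insert)] * int(c))

        for _ in range(n_cont):
            rec = bundle.contaminants[int(rng.integers(0, len(bundle.contaminants)))]
            L = int(rng.choice(lengths, p=lprobs))
            L = min(L, len(rec[2]))
            p0 = int(rng.integers(0, len(rec[2]) - L + 1))
            reads.append(normal_read(rec[2][p0 : p0 + L]))

        for _ in range(n_bg):
            ui = int(rng.integers(0, len(unigene_seqs)))
            s = unigene_seqs[ui]
            L = int(rng.choice(lengths, p=lprobs))
            L = min(L, len(s))
            p0 = int(rng.integers(0, len(s) - L + 1))
            reads.append(normal_read(s[p0 : p0 + L]))

        a3_seed = a3[:8]
        for _ in range(n_art["no_adapter3"]):
            while True:
                seq = _random_seq(rng, config.read_length)
                if a3_seed not in seq:
                    break
            reads.append((seq, "G" * len(seq)))
        for _ in range(n_art["polyA"]):
            reads.append(normal_read("A" * int(rng.integers(20, 27))))
        for _ in range(n_art["low_quality"]):
            L = int(rng.choice(lengths, p=lprobs))
            ui = int(rng.integers(0, len(unigene_seqs)))
            s = unigene_seqs[ui]
            L = min(L, len(s))
            p0 = int(rng.integers(0, len(s) - L + 1))
            seq, _q = normal_read(s[p0 : p0 + L])
            qual = np.full(len(seq), ord("G"), dtype=np.uint8)
            n_low = int(np.ceil(0.6 * len(seq)))
            low_pos = rng.choice(len(seq), size=n_low, replace=False)
            qual[low_pos] = ord("+")  # Phred 10
            reads.append((seq, qual.tobytes().decode("ascii")))
        for _ in range(n_art["too_short"]):
            reads.append(normal_read(_random_seq(rng, int(rng.integers(10, 18)), "CGT")))

        order = rng.permutation(len(reads))
        path = os.path.join(outdir, f"{lib}.fastq")
        with open(path, "w") as fh:
            for serial, ri in enumerate(order):
                seq, qual = reads[ri]
                fh.write(f"@{lib}_{serial + 1}\n{seq}\n+\n{qual}\n")
        paths[lib] = path
        comp_rows.append(
            dict(
                library=lib,
                total=len(reads),
                planted=n_planted,
                contaminant=n_cont,
                background=n_bg,
                **{f"artifact_{k}": v for k, v in n_art.items()},
            )
        )

    components = pd.DataFrame(comp_rows).set_index("library")
    bundle.truth.counts = truth_counts
    truth_counts.rename_axis("truth_id").to_csv(
        os.path.join(outdir, "truth_counts.tsv"), sep="\t"
    )
    components.to_csv(os.path.join(outdir, "component_counts.tsv"), sep="\t")
    return paths, truth_counts, components


def simulate_dataset(config: SimulationConfig, outdir) -> tuple[ReferenceBundle, dict[str, str]]:
    """Generate references and libraries under ``outdir`` in one call."""
    bundle = make_references(config)
    bundle.write(outdir)
    paths, _, _ = simulate_libraries(bundle, outdir)
    return bundle, paths
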