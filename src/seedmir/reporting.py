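"""Pipeline orchestration, summary tables and qRT-PCR comparison utilities.

``run_pipeline`` chains preprocessing -> ncRNA screening -> miRNA
identification -> quantification -> target prediction -> enrichment on a
nine-library experiment and writes every stage's result as TSV.  The module
also provides the 2^-ddCt relative-expression computation and the
sequencing-vs-qPCR profile correlation used for validation summaries.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from Bio import SeqIO

from . import annotate, mirna_id, preprocess, quantify, targets as targets_mod
from .enrichment import enrich
from .synthetic import LIBRARIES, PHASES, PHASE_OF

logger = logging.getLogger("seedmir")


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full pipeline run (defaults as published)."""

    fastq: dict[str, str]  # library id -> FASTQ path
    transcriptome_fasta: str
    mature_reference_fasta: str
    contaminant_fasta: str
    go_annotations: str
    kegg_annotations: str
    outdir: str
    adapter3: str = "TGGAATTCTCGGGTGCCAAGG"
    adapter5: str = "GTTCAGAGTTCTACAGTCCGACGATC"
    min_len: int = 18
    max_len: int = 30
    min_anchor_reads: int = 10  # precursor accepted only above this
    fc_threshold: float = 2.0
    p_threshold: float = 0.05
    fdr_threshold: float = 0.05
    novel_params: mirna_id.NovelParams = field(default_factory=mirna_id.NovelParams)
    target_rules: targets_mod.TargetRules = field(default_factory=targets_mod.TargetRules)

    def phases(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {p: [] for p in PHASES}
        for lib in self.fastq:
            out[PHASE_OF.get(lib, lib.rstrip("-123").lstrip("MpS"))].append(lib)
        return {p: libs for p, libs in out.items() if libs}

    def validate(self) -> None:
        for name in ("fc_threshold", "p_threshold", "fdr_threshold", "min_anchor_reads"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for path in (
            self.transcriptome_fasta, self.mature_reference_fasta,
            self.contaminant_fasta, self.go_annotations, self.kegg_annotations,
            *self.fastq.values(),
        ):
            if not os.path.exists(path):
                raise FileNotFoundError(path)


def _read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns a dict of DataFrames and writes TSVs + run log.

    Stage order: preprocess -> annotate -> identify -> quantify -> targets ->
    enrichment.  Any stage failure aborts with the stage name in the raised
    exception.  Deterministic for fixed inputs.
    """
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    handler = logging.FileHandler(os.path.join(config.outdir, "run.log"), mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    out: dict = {}
    stage = "setup"
    try:
        stage = "preprocess"
        logger.info("preprocess: adapters %s / %s, insert %d-%d nt",
                    config.adapter3, config.adapter5, config.min_len, config.max_len)
        per_lib, stats_rows = {}, []
        for lib, path in config.fastq.items():
            tags, stats = preprocess.filter_and_trim(
                path, config.adapter3, config.adapter5, library_id=lib,
                min_len=config.min_len, max_len=config.max_len,
            )
            per_lib[lib] = tags
            stats_rows.append(stats.to_row())
        tag_counts = preprocess.combine_tag_counts(per_lib)
        library_stats = pd.DataFrame(stats_rows).set_index("library")
        phases = config.phases()
        out["library_stats"] = library_stats
        out["length_distribution"] = preprocess.length_distribution(tag_counts, phases)
        clean_totals = library_stats["clean_reads"].astype(float)

        stage = "annotate"
        classes, fractions = annotate.classify_ncrna(tag_counts, config.contaminant_fasta)
        out["ncrna_fractions"] = fractions
        keep = classes == "unannotated"
        mirna_tags = tag_counts.loc[keep]
        logger.info("annotate: %d/%d tags unannotated", int(keep.sum()), len(classes))

        stage = "identify"
        transcriptome = _read_fasta(config.transcriptome_fasta)
        mature_ref = [
            (rec.id, str(rec.seq)) for rec in SeqIO.parse(config.mature_reference_fasta, "fasta")
        ]
        conserved = mirna_id.match_conserved(mirna_tags, mature_ref)
        index = mirna_id.TranscriptomeIndex(transcriptome)
        tag_map = mirna_id.build_tag_map(mirna_tags, index)
        tag_totals = mirna_tags.sum(axis=1)
        conserved_precursors: list[mirna_id.Precursor] = []
        blocked: dict[str, list[tuple[int, int]]] = {}
        for rec in conserved:
            precs = mirna_id.recover_precursor(
                rec, index, tag_map, tag_totals, config.min_anchor_reads
            )
            conserved_precursors.extend(precs)
            for prec in precs:
                blocked.setdefault(prec.unigene_id, []).append(
                    (prec.start - 1, prec.end)
                )
        conserved_tags = {mirna_id.as_dna(r.sequence) for r in conserved}
        # also block every conserved mature locus (precursor recovered or not)
        for rec in conserved:
            for uid, pos in index.locate(mirna_id.as_dna(rec.sequence)):
                blocked.setdefault(uid, []).append((pos, pos + len(rec.sequence)))
        novel, novel_precursors = mirna_id.predict_novel(
            mirna_tags, index, tag_map,
            exclude_tags=conserved_tags, blocked=blocked, params=config.novel_params,
        )
        records = conserved + novel
        logger.info(
            "identify: %d conserved (%d precursors), %d novel (%d precursors)",
            len(conserved), len(conserved_precursors), len(novel), len(novel_precursors),
        )
        out["mirnas"] = pd.DataFrame(
            [
                dict(
                    mirna=r.id, sequence=r.sequence, family=r.family, arm=r.arm,
                    origin=r.origin, source_ref=r.source_ref,
                    **{lib: int(r.counts[lib]) for lib in tag_counts.columns},
                )
                for r in records
            ]
        ).set_index("mirna") if records else pd.DataFrame()
        out["precursors"] = pd.DataFrame(
            [
                dict(
                    mirna=p.mirna_id, unigene=p.unigene_id, start=p.start, end=p.end,
                    length=p.length, gc=round(p.gc, 2), mfe=round(p.mfe, 2),
                    amfe=round(p.amfe, 2), mfei=round(p.mfei, 4),
                    anchored_5p=p.anchored_reads_5p, anchored_3p=p.anchored_reads_3p,
                    arm=p.arm, structure=p.structure,
                )
                for p in conserved_precursors + novel_precursors
            ]
        )
        out["venn"] = mirna_id.phase_presence(records, phases)
        out["_records"] = records
        out["_conserved_precursors"] = conserved_precursors
        out["_novel_precursors"] = novel_precursors

        stage = "quantify"
        counts = out["mirnas"][list(tag_counts.columns)] if records else pd.DataFrame()
        if records:
            tpm = quantify.expression_matrix(counts, clean_totals)
            de = quantify.differential_expression(
                tpm, phases, config.fc_threshold, config.p_threshold
            )
            corr, pca = quantify.replicate_qc(tpm)
        else:
            tpm = de = corr = pca = pd.DataFrame()
        out["tpm"] = tpm
        out["de"] = de
        out["qc_correlation"] = corr
        out["qc_pca"] = pca

        stage = "targets"
        mirna_seqs = {r.id: r.sequence for r in records}
        sites = targets_mod.scan_transcriptome(
            mirna_seqs, transcriptome, config.target_rules
        )
        out["target_sites"] = sites
        out["target_gene_counts"] = targets_mod.target_gene_counts(sites)

        stage = "enrichment"
        demirs = quantify.call_demirs(de)["union"] if len(de) else set()
        demir_targets = (
            set(sites.loc[sites["mirna"].isin(demirs), "unigene"]) if len(sites) else set()
        )
        go = pd.read_csv(config.go_annotations, sep="\t")
        kegg = pd.read_csv(config.kegg_annotations, sep="\t")
        background = set(transcriptome)
        out["enrichment"] = (
            pd.concat(
                [
                    enrich(demir_targets, go, background, config.fdr_threshold),
                    enrich(demir_targets, kegg, background, config.fdr_threshold),
                ],
                ignore_index=True,
            )
            if demir_targets
            else enrich(set(), go, background, config.fdr_threshold)
        )
        out["demirs"] = sorted(demirs)

        stage = "write"
        for name in (
            "library_stats", "length_distribution", "ncrna_fractions", "mirnas",
            "precursors", "venn", "tpm", "de", "qc_correlation", "qc_pca",
            "target_sites", "enrichment",
        ):
            df = out[name]
            df.to_csv(os.path.join(config.outdir, f"{name}.tsv"), sep="\t")
        logger.info("pipeline complete: %d miRNAs, %d DEmiRs, %d target sites",
                    len(records), len(demirs), len(sites))
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out


def ddct(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> float:
    """Relative expression by the 2^-ddCt method."""
    for v in (ct_target_sample, ct_ref_sample, ct_target_calibrator, ct_ref_calibrator):
        if not np.isfinite(v):
            raise ValueError("Ct values must be finite")
    dd = (ct_target_sample - ct_ref_sample) - (ct_target_calibrator - ct_ref_calibrator)
    return float(2.0 ** (-dd))


def profile_correlation(seq_log2fc, qpcr_log2fc) -> dict:
    """Pearson r and least-squares fit between sequencing and qPCR profiles.

    Returns NaNs when either vector has zero variance (correlation undefined).
    """
    x = np.asarray(seq_log2fc, dtype=float)
    y = np.asarray(qpcr_log2fc, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need paired vectors of length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        return {"r": float("nan"), "slope": float("nan"),
                "intercept": float("nan"), "p": float("nan")}
    fit = sps.linregress(x, y)
    return {"r": float(fit.rvalue), "slope": float(fit.slope),
            "intercept": float(fit.intercept), "p": float(fit.pvalue)}


def trend_counts(de: pd.DataFrame) -> pd.Series:
    """Number of miRNAs per trend class among those significant anywhere."""
    demirs = de.loc[de["sig_II_vs_I"] | de["sig_III_vs_II"]]
    return demirs["trend"].value_counts()


def demir_union_size(n_comp1: int, n_comp2: int, n_both: int) -> int:
    """Total DEmiRs over two comparisons by inclusion-exclusion."""
    if min(n_comp1, n_comp2) < n_both:
        raise ValueError("overlap exceeds a comparison's DEmiR count")
    return n_comp1 + n_comp2 - n_both
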