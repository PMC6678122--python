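"""Shared fixtures: seeded synthetic studies and pipeline runs."""

from __future__ import annotations

import pytest

from seedmir.reporting import PipelineConfig, run_pipeline
from seedmir.synthetic import SimulationConfig, simulate_dataset


def pipeline_config_for(directory, paths, outdir) -> PipelineConfig:
    d = str(directory)
    return PipelineConfig(
        fastq=paths,
        transcriptome_fasta=f"{d}/unigenes.fasta",
        mature_reference_fasta=f"{d}/mature_reference.fasta",
        contaminant_fasta=f"{d}/contaminants.fasta",
        go_annotations=f"{d}/go_annotations.tsv",
        kegg_annotations=f"{d}/kegg_annotations.tsv",
        outdir=str(outdir),
    )


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        rng_seed=11,
        phase_depths=((20_000,) * 3,) * 3,
        n_conserved_planted=10,
        n_novel_planted=5,
        n_unigenes=80,
    )


@pytest.fixture(scope="session")
def small_study(small_config, tmp_path_factory):
    """(bundle, fastq paths, directory) for a modest nine-library study."""
    d = tmp_path_factory.mktemp("study_small")
    bundle, paths = simulate_dataset(small_config, d)
    return bundle, paths, d


@pytest.fixture(scope="session")
def small_pipeline(small_study, tmp_path_factory):
    bundle, paths, d = small_study
    out = run_pipeline(pipeline_config_for(d, paths, tmp_path_factory.mktemp("out_small")))
    return bundle, out


@pytest.fixture(scope="session")
def full_pipeline(tmp_path_factory):
    """Default study conditions (1e5 reads/library, 20+10 planted miRNAs)."""
    d = tmp_path_factory.mktemp("study_full")
    bundle, paths = simulate_dataset(SimulationConfig(rng_seed=20260927 % 2**31), d)
    out = run_pipeline(pipeline_config_for(d, paths, tmp_path_factory.mktemp("out_full")))
    return bundle, out
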