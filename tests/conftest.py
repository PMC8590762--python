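"""Shared fixtures.

The expensive session fixtures run the scaled simulation benchmark (5-Mb
diploid genome, 50x reads, three seeds per read class, plus one haploid
replicate) and a correction round on a 2-Mb replicate. They are computed
once per session and only when a test requests them.
"""
from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import numpy as np
import pytest

from asmeval.alignment import align_reads
from asmeval.assembly_stats import Contig, read_fasta, write_fasta
from asmeval.correction import correct_assembly
from asmeval.evaluate import evaluate_assembly
from asmeval.simulate import (SimulationConfig, run_replicate,
                              simulate_diploid, simulate_reads, spike_errors)

SEEDS = (1, 2, 3)


def small_sim_config(**overrides) -> SimulationConfig:
    """A fast sub-megabase configuration for unit-level pipeline tests."""
    base = dict(genome_length=400_000, n_snp=128, n_sv=16, n_expansion=2,
                n_collapse=2, n_switch=1, n_inversion=0, n_small_errors=76,
                rng_seed=11)
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def scaled_runs():
    """Scaled benchmark: {(ploidy, datatype, seed): ReplicateOutcome}."""
    runs = {}
    for seed in SEEDS:
        for dt in ("hifi", "clr"):
            runs[("diploid", dt, seed)] = run_replicate(seed=seed, datatype=dt)
    runs[("haploid", "hifi", SEEDS[0])] = run_replicate(
        seed=SEEDS[0], datatype="hifi", diploid=False)
    return runs


@pytest.fixture(scope="session")
def correction_round(tmp_path_factory):
    """One correction pass on a 2-Mb HiFi replicate: evaluation results
    before and after correction."""
    wd = tmp_path_factory.mktemp("correction")
    cfg = SimulationConfig(genome_length=2_000_000, n_snp=640, n_sv=80,
                           n_expansion=4, n_collapse=4, n_switch=1,
                           n_inversion=0, n_small_errors=380, rng_seed=5)
    rng = np.random.default_rng(cfg.rng_seed)
    _, hap1, hap2, variants = simulate_diploid(cfg, rng)
    sim = spike_errors(hap1, variants, cfg, rng)
    asm = wd / "assembly.fa"
    reads = wd / "reads.fa"
    write_fasta([Contig(n, s) for n, s in sim.contigs], asm)
    simulate_reads([hap1, hap2], cfg, reads, rng)
    bam = align_reads(reads, asm, "hifi", wd / "aln.bam")
    before = evaluate_assembly(asm, alignments=bam, datatype="hifi")
    contigs = read_fasta(asm)
    corrected, patches, failed = correct_assembly(
        contigs, before.structural, before.small, bam)
    corr_fa = wd / "corrected.fa"
    write_fasta(corrected, corr_fa)
    after = evaluate_assembly(corr_fa, reads=reads, datatype="hifi")
    return {"before": before, "after": after, "patches": patches,
            "failed": failed, "truth": sim.truth}


@pytest.fixture(scope="session")
def tiny_alignment(tmp_path_factory):
    """A small aligned replicate (400-kb genome) reused by parsing and
    determinism tests: paths to assembly, reads, sorted BAM, and truth."""
    wd = tmp_path_factory.mktemp("tiny")
    cfg = small_sim_config()
    rng = np.random.default_rng(cfg.rng_seed)
    _, hap1, hap2, variants = simulate_diploid(cfg, rng)
    sim = spike_errors(hap1, variants, cfg, rng)
    asm = wd / "assembly.fa"
    reads = wd / "reads.fa"
    write_fasta([Contig(n, s) for n, s in sim.contigs], asm)
    simulate_reads([hap1, hap2], cfg, reads, rng)
    bam = align_reads(reads, asm, "hifi", wd / "aln.bam")
    return {"dir": wd, "assembly": asm, "reads": reads, "bam": bam,
            "truth": sim.truth, "config": cfg}
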