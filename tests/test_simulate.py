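import gzip
import math

import numpy as np
import pytest

from asmeval import _seq
from asmeval.simulate import (SimulationConfig, TruthRecord, score_calls,
                              score_structural, simulate_diploid,
                              simulate_reads, spike_errors, split_at_n)
from asmeval.smallscale import BASE_SUBSTITUTION, SmallScaleError
from asmeval.structural import (COLLAPSE, EXPANSION, HAPLOTYPE_SWITCH,
                                StructuralError)

from conftest import small_sim_config


def cfg_small(**kw) -> SimulationConfig:
    base = dict(genome_length=200_000, n_snp=100, n_sv=10, n_expansion=2,
                n_collapse=2, n_switch=0, n_inversion=0, n_small_errors=20,
                rng_seed=1)
    base.update(kw)
    return SimulationConfig(**base)


class TestSimulateDiploid:
    def test_het_hom_counts(self):
        cfg = cfg_small(n_snp=100, n_sv=0)
        _, _, _, variants = simulate_diploid(cfg)
        het = sum(1 for v in variants if v.is_het)
        assert het == 67
        assert len(variants) - het == 33

    def test_no_variants_identity(self):
        cfg = cfg_small(n_snp=0, n_sv=0)
        genome, hap1, hap2, variants = simulate_diploid(cfg)
        assert hap1 == genome and hap2 == genome and variants == []

    def test_same_seed_identical(self):
        a = simulate_diploid(cfg_small())
        b = simulate_diploid(cfg_small())
        assert a[0] == b[0] and a[1] == b[1] and a[2] == b[2]

    def test_het_variants_on_one_haplotype(self):
        cfg = cfg_small(n_snp=60, n_sv=0)
        genome, hap1, hap2, variants = simulate_diploid(cfg)
        for v in variants:
            in1 = hap1[v.hap1_pos] == v.alt
            if v.genotype == "hom":
                assert in1
            elif v.genotype == "het2":
                assert hap1[v.hap1_pos] == genome[v.pos]

    def test_sv_sizes_at_least_floor(self):
        _, _, _, variants = simulate_diploid(cfg_small(n_sv=15, n_snp=0))
        assert all(v.size >= 50 for v in variants)


class TestSpikeErrors:
    def test_truth_counts_match_composition(self):
        cfg = small_sim_config(n_expansion=9, n_collapse=9, n_switch=2,
                               n_inversion=0, n_small_errors=100)
        rng = np.random.default_rng(cfg.rng_seed)
        _, hap1, _, variants = simulate_diploid(cfg, rng)
        sim = spike_errors(hap1, variants, cfg, rng)
        struct = [t for t in sim.truth if t.cls == "structural"]
        small = [t for t in sim.truth if t.cls == "small"]
        assert len(struct) == 20 and len(small) == 100
        kinds = {k: sum(1 for t in struct if t.kind == k)
                 for k in (EXPANSION, COLLAPSE, HAPLOTYPE_SWITCH)}
        assert kinds == {EXPANSION: 9, COLLAPSE: 9, HAPLOTYPE_SWITCH: 2}

    def test_zero_composition_identity(self):
        cfg = cfg_small(n_expansion=0, n_collapse=0, n_switch=0,
                        n_inversion=0, n_small_errors=0)
        rng = np.random.default_rng(1)
        _, hap1, _, variants = simulate_diploid(cfg, rng)
        sim = spike_errors(hap1, variants, cfg, rng)
        assert "".join(s for _, s in sim.contigs) == hap1

    def test_collapse_shortens_assembly(self):
        cfg = cfg_small(n_expansion=0, n_collapse=1, n_switch=0,
                        n_small_errors=0)
        rng = np.random.default_rng(2)
        _, hap1, _, variants = simulate_diploid(cfg, rng)
        sim = spike_errors(hap1, variants, cfg, rng)
        (t,) = sim.truth
        assert t.kind == COLLAPSE
        assert len(sim.contigs[0][1]) == len(hap1) - t.size

    def test_truth_coordinates_on_assembly(self):
        cfg = cfg_small(n_expansion=2, n_collapse=0, n_switch=0,
                        n_small_errors=10)
        rng = np.random.default_rng(3)
        _, hap1, _, variants = simulate_diploid(cfg, rng)
        sim = spike_errors(hap1, variants, cfg, rng)
        L = len(sim.contigs[0][1])
        for t in sim.truth:
            assert 0 <= t.pos < L

    def test_substitutions_place_non_haplotype_bases(self):
        cfg = cfg_small(n_expansion=0, n_collapse=0, n_small_errors=40,
                        small_mix=(1.0, 0.0, 0.0))
        rng = np.random.default_rng(4)
        genome, hap1, _, variants = simulate_diploid(cfg, rng)
        sim = spike_errors(hap1, variants, cfg, rng)
        asm = sim.contigs[0][1]
        subs = [t for t in sim.truth if t.kind == BASE_SUBSTITUTION]
        assert len(subs) == 40
        assert len(asm) == len(hap1)
        diffs = sum(1 for a, b in zip(asm, hap1) if a != b)
        assert diffs == len(subs)
        for t in subs:
            assert asm[t.pos] != hap1[t.pos]


class TestSplitAtN:
    def test_split_and_filter(self):
        seq = "A" * 12_000 + "N" * 5 + "C" * 3000 + "N" + "G" * 15_000
        contigs = split_at_n(seq, min_len=10_000)
        assert [len(s) for _, s in contigs] == [12_000, 15_000]


class TestSimulateReads:
    def test_depth_accounting(self, tmp_path):
        cfg = cfg_small(read_depth=20.0)
        rng = np.random.default_rng(5)
        hap = _seq.random_sequence(150_000, rng)
        out = tmp_path / "r.fa"
        simulate_reads([hap], cfg, out, rng)
        total = sum(len(l.strip()) for l in open(out) if not l.startswith(">"))
        assert abs(total - 20.0 * 150_000) / (20.0 * 150_000) < 0.02

    def test_perfect_accuracy_reads_are_substrings(self, tmp_path, monkeypatch):
        import asmeval.simulate as sim_mod
        monkeypatch.setitem(sim_mod.ACCURACY, "hifi", 1.0)
        rng = np.random.default_rng(6)
        hap = _seq.random_sequence(60_000, rng)
        out = tmp_path / "r.fa"
        simulate_reads([hap], cfg_small(read_depth=3.0), out, rng)
        both = hap + "|" + _seq.revcomp(hap)
        n = 0
        for line in open(out):
            if line.startswith(">"):
                continue
            assert line.strip() in both
            n += 1
        assert n > 0

    def test_seeded_runs_identical(self, tmp_path):
        cfg = cfg_small(read_depth=5.0)
        hap = _seq.random_sequence(50_000, np.random.default_rng(7))
        a, b = tmp_path / "a.fq.gz", tmp_path / "b.fq.gz"
        simulate_reads([hap], cfg, a, np.random.default_rng(42))
        simulate_reads([hap], cfg, b, np.random.default_rng(42))
        assert gzip.open(a).read() == gzip.open(b).read()


class TestScoring:
    def t(self, kind, pos, size=100):
        return TruthRecord("structural", kind, "c", pos, size)

    def c(self, kind, pos, size=100, n=10):
        return StructuralError(kind, "c", pos, pos + size, size, n, 50.0,
                               0.9, 60.0)

    def test_f1_formula_example(self):
        truth = [self.t(EXPANSION, p) for p in (1000, 10_000, 20_000, 30_000)]
        calls = [self.c(EXPANSION, p) for p in (1000, 10_000, 20_000, 30_000,
                                                90_000)]
        r = score_structural(calls, truth)
        assert r.recall == pytest.approx(1.0)
        assert r.precision == pytest.approx(0.8)
        assert r.f1 == pytest.approx(2 * 1.0 * 0.8 / 1.8)

    def test_identity_perfect_score(self):
        truth = [self.t(COLLAPSE, 5000)]
        r = score_structural([self.c(COLLAPSE, 5000)], truth)
        assert (r.recall, r.precision, r.f1) == (1.0, 1.0, 1.0)

    def test_match_within_window_and_size_tolerance(self):
        truth = [self.t(EXPANSION, 1000, size=100)]
        r = score_structural([self.c(EXPANSION, 1020, size=90)], truth)
        assert r.tp == 1

    def test_size_tolerance_rejects_half(self):
        truth = [self.t(EXPANSION, 1000, size=100)]
        r = score_structural([self.c(EXPANSION, 1000, size=40)], truth)
        assert r.tp == 0

    def test_switch_matches_expansion_call(self):
        truth = [TruthRecord("structural", HAPLOTYPE_SWITCH, "c", 1000, 80,
                             80, 70)]
        r = score_structural([self.c(EXPANSION, 1010, size=80)], truth)
        assert r.tp == 1

    def test_empty_calls_nan_precision(self):
        r = score_structural([], [self.t(EXPANSION, 1000)])
        assert math.isnan(r.precision) and r.f1 == 0.0

    def test_one_to_one_matching(self):
        truth = [self.t(EXPANSION, 1000)]
        calls = [self.c(EXPANSION, 1000), self.c(EXPANSION, 1010)]
        r = score_structural(calls, truth)
        assert r.tp == 1 and r.fp == 1

    def test_small_kind_must_match(self):
        truth = [TruthRecord("small", BASE_SUBSTITUTION, "c", 100, 1)]
        calls = [SmallScaleError("SmallCollapse", "c", 100, 1, "", "G", 50,
                                 48, 1e-9)]
        _, r = score_calls([], calls, truth)
        assert r.tp == 0
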