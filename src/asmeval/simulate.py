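"""Simulation benchmark: synthetic diploid genomes, assemblies with spiked
errors, long-read simulation, and truth-based scoring.

The generator emulates the benchmark design used to validate the detector:
a random genome acquires SNPs and indel SVs (67% heterozygous, 33%
homozygous; SV sizes follow a geometric-like spectrum with a 50 bp floor);
haplotype 1 becomes the "assembly" after spiking structural errors
(expansions, collapses, haplotype switches at heterozygous insertion loci,
inversions) and small-scale errors (50% base substitutions, 25% 1-bp
expansions, 25% 1-bp collapses); reads are sampled from both haplotypes
with CLR-like (85% accuracy, indel-rich) or HiFi-like (98% accuracy,
substitution-leaning) i.i.d. error profiles and a normal length
distribution (mean 15,000, sd 3,000). Scoring matches calls to spiked
truth with a positional window and reciprocal size tolerance.
"""
from __future__ import annotations

import gzip
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from . import _seq
from .smallscale import (BASE_SUBSTITUTION, SMALL_COLLAPSE, SMALL_EXPANSION,
                         SmallScaleError)
from .structural import (COLLAPSE, EXPANSION, HAPLOTYPE_SWITCH, INVERSION,
                         StructuralError)

ACCURACY = {"hifi": 0.98, "clr": 0.85, "nano": 0.85}
# fraction of errors that are substitutions / insertions / deletions
ERROR_MIX = {"hifi": (0.6, 0.2, 0.2), "clr": (0.1, 0.6, 0.3),
             "nano": (0.1, 0.6, 0.3)}


@dataclass
class SimulationConfig:
    genome_length: int = 5_000_000
    n_snp: int = 1600
    n_sv: int = 200
    het_fraction: float = 0.67
    sv_min_size: int = 50
    sv_size_mean: float = 300.0
    sv_max_size: int = 5000
    n_expansion: int = 9
    n_collapse: int = 9
    n_switch: int = 2
    n_inversion: int = 0
    inversion_size_range: tuple[int, int] = (2000, 6000)
    n_small_errors: int = 950
    small_mix: tuple[float, float, float] = (0.5, 0.25, 0.25)
    structural_spacing: int = 2000
    read_depth: float = 50.0
    read_length_mean: float = 15000.0
    read_length_sd: float = 3000.0
    read_min_length: int = 1000
    datatype: str = "hifi"
    min_contig: int = 10_000
    rng_seed: int = 0

    @property
    def read_accuracy(self) -> float:
        return ACCURACY[self.datatype]


@dataclass
class Variant:
    kind: str              # snp | ins | del
    pos: int               # base-genome coordinate
    size: int
    alt: str               # inserted sequence / substituted base
    genotype: str          # hom | het1 | het2 (haplotype carrying the allele)
    hap1_pos: int = -1     # locus position on haplotype 1

    @property
    def is_het(self) -> bool:
        return self.genotype != "hom"


@dataclass
class TruthRecord:
    cls: str               # structural | small
    kind: str
    contig_id: str
    pos: int               # assembly coordinate
    size: int
    expansion_size: int | None = None
    collapse_size: int | None = None


@dataclass
class BenchmarkResult:
    tp: int
    fp: int
    fn: int
    recall: float
    precision: float
    f1: float
    match_window: int = 500
    size_tolerance: float = 0.5


@dataclass
class SimulatedAssembly:
    contigs: list[tuple[str, str]]      # (name, sequence)
    truth: list[TruthRecord]
    # step map from haplotype-1 coordinates to assembly coordinates:
    # sorted edit positions and the cumulative offset that applies at or
    # after each position
    edit_pos: "np.ndarray | None" = None
    edit_off: "np.ndarray | None" = None

    def hap1_to_assembly(self, pos: int) -> int:
        if self.edit_pos is None or len(self.edit_pos) == 0:
            return pos
        i = int(np.searchsorted(self.edit_pos, pos, side="right")) - 1
        return pos + (int(self.edit_off[i]) if i >= 0 else 0)


def _apply_edits(genome: str, edits: list[tuple]) -> tuple[str, list[int]]:
    """Apply non-overlapping edits (pos, del_len, ins_seq) left-to-right.

    Returns the edited sequence and the output coordinate of each edit.
    """
    parts = []
    out_pos = []
    cur = 0
    off = 0
    for pos, del_len, ins in sorted(edits, key=lambda e: e[0]):
        if pos < cur:
            raise ValueError("overlapping edits")
        parts.append(genome[cur:pos])
        out_pos.append(pos + off)
        parts.append(ins)
        cur = pos + del_len
        off += len(ins) - del_len
    parts.append(genome[cur:])
    return "".join(parts), out_pos


def _sample_positions(
    rng: np.random.Generator, n: int, lo: int, hi: int, spacing: int,
    forbidden: Sequence[tuple[int, int]] = (),
    pad: int = 0,
) -> list[int]:
    """Uniform positions in [lo, hi), at least ``spacing`` apart and more
    than ``pad`` away from every forbidden interval."""
    import bisect

    fb = sorted(forbidden)
    fb_starts = [s for s, _ in fb]
    max_fb_len = max(((t - s) for s, t in fb), default=0)
    out: list[int] = []
    for _ in range(200):
        if len(out) >= n:
            break
        for p in rng.integers(lo, hi, size=4 * (n - len(out)) + 16):
            p = int(p)
            i = bisect.bisect_left(out, p)
            if i < len(out) and out[i] - p < spacing:
                continue
            if i > 0 and p - out[i - 1] < spacing:
                continue
            j = bisect.bisect_right(fb_starts, p + pad)
            clash = False
            for k in range(j - 1, -1, -1):
                s, t = fb[k]
                if s < p - pad - max_fb_len:
                    break
                if t > p - pad:
                    clash = True
                    break
            if clash:
                continue
            bisect.insort(out, p)
            if len(out) == n:
                break
    if len(out) < n:
        raise ValueError(
            f"could not place {n} loci with spacing {spacing} in [{lo},{hi})"
        )
    return out


def _sv_size(rng: np.random.Generator, cfg: SimulationConfig) -> int:
    excess = rng.geometric(1.0 / max(cfg.sv_size_mean - cfg.sv_min_size, 1.0))
    return int(min(cfg.sv_min_size + excess - 1, cfg.sv_max_size))


def simulate_diploid(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[str, str, str, list[Variant]]:
    """Simulate a base genome and two haplotypes carrying SNPs and SVs.

    Exactly round(het_fraction * n) variants are heterozygous (assigned by
    seeded shuffle, alternating the carrier haplotype); the rest are applied
    to both haplotypes. Returns (genome, hap1, hap2, variants).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    L = cfg.genome_length
    if L < (cfg.n_sv + 2) * (cfg.structural_spacing + cfg.sv_max_size):
        if cfg.n_sv * (2 * cfg.sv_max_size) > L:
            raise ValueError("genome too small for requested variant counts")
    genome = _seq.random_sequence(L, rng)

    sv_pos = _sample_positions(rng, cfg.n_sv, 1000, L - cfg.sv_max_size - 1000,
                               2 * cfg.sv_max_size)
    variants: list[Variant] = []
    for p in sv_pos:
        size = _sv_size(rng, cfg)
        if rng.random() < 0.5:
            variants.append(Variant("ins", p, size,
                                    _seq.random_sequence(size, rng), ""))
        else:
            variants.append(Variant("del", p, size, "", ""))
    sv_spans = [(v.pos, v.pos + (v.size if v.kind == "del" else 0))
                for v in variants]
    snp_pos = _sample_positions(rng, cfg.n_snp, 100, L - 100, 2,
                                forbidden=sv_spans, pad=2)
    for p in snp_pos:
        ref = genome[p]
        alt = rng.permutation([b for b in "ACGT" if b != ref])[0]
        variants.append(Variant("snp", p, 1, str(alt), ""))

    n = len(variants)
    n_het = round(cfg.het_fraction * n)
    order = rng.permutation(n)
    for rank, idx in enumerate(order):
        if rank < n_het:
            variants[idx].genotype = "het1" if rng.random() < 0.5 else "het2"
        else:
            variants[idx].genotype = "hom"

    def build_hap(which: str) -> tuple[str, dict[int, int]]:
        edits = []
        carried = []
        for i, v in enumerate(variants):
            applies = v.genotype == "hom" or v.genotype == which
            if not applies:
                edits.append((v.pos, 0, ""))   # marker edit to map coordinate
                carried.append((i, False))
                continue
            carried.append((i, True))
            if v.kind == "snp":
                edits.append((v.pos, 1, v.alt))
            elif v.kind == "ins":
                edits.append((v.pos, 0, v.alt))
            else:
                edits.append((v.pos, v.size, ""))
        hap, out_pos = _apply_edits(genome, edits)
        order_idx = sorted(range(len(edits)), key=lambda k: edits[k][0])
        pos_map = {}
        for rank, k in enumerate(order_idx):
            pos_map[carried[k][0]] = out_pos[rank]
        return hap, pos_map

    hap1, map1 = build_hap("het1")
    hap2, _ = build_hap("het2")
    for i, v in enumerate(variants):
        v.hap1_pos = map1[i]
    return genome, hap1, hap2, variants


def split_at_n(seq: str, min_len: int = 10_000, name_prefix: str = "ctg") -> list[tuple[str, str]]:
    """Split a simulated genome into contigs at N runs; drop short fragments."""
    contigs = []
    for i, frag in enumerate(f for f in seq.split("N") if f):
        if len(frag) >= min_len:
            contigs.append((f"{name_prefix}{len(contigs)}", frag))
    return contigs


def spike_errors(
    hap1: str,
    variants: Sequence[Variant],
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> SimulatedAssembly:
    """Spike structural and small-scale errors into haplotype 1.

    Haplotype switches are placed at heterozygous insertion loci carried by
    haplotype 1: the assembly keeps only half of the inserted allele, so it
    matches neither haplotype (reads from haplotype 2 indicate an expansion
    of the kept half, reads from haplotype 1 a collapse of the missing
    half). Structural errors keep >=``structural_spacing`` bp apart and away
    from variant loci; small-scale errors avoid both.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed + 1)
    L = len(hap1)
    var_spans = []
    for v in variants:
        pad = v.size if v.kind != "snp" else 1
        var_spans.append((v.hap1_pos - 1, v.hap1_pos + pad + 1))

    # haplotype switches: heterozygous hap1 insertions large enough that
    # both the kept and the removed half clear the structural size floor
    switch_cands = [
        v for v in variants
        if v.kind == "ins" and v.genotype == "het1" and v.size >= 120
    ]
    if len(switch_cands) < cfg.n_switch:
        raise ValueError("not enough large heterozygous insertions for "
                         "haplotype-switch spiking")
    picks = rng.permutation(len(switch_cands))[: cfg.n_switch]
    switches = [switch_cands[i] for i in sorted(picks)]
    switch_spans = [(v.hap1_pos, v.hap1_pos + v.size) for v in switches]

    n_struct = cfg.n_expansion + cfg.n_collapse + cfg.n_inversion
    struct_pos = _sample_positions(
        rng, n_struct, 12_000, L - 12_000,
        cfg.structural_spacing + cfg.sv_max_size,
        forbidden=var_spans, pad=500,
    )
    struct_pos = [int(p) for p in rng.permutation(struct_pos)]
    edits: list[tuple] = []       # (pos, del_len, ins_seq)
    meta: list[tuple] = []        # parallel to edits: (cls, kind, size, ...)

    i = 0
    for _ in range(cfg.n_expansion):
        s = _sv_size(rng, cfg)
        edits.append((struct_pos[i], 0, _seq.random_sequence(s, rng)))
        meta.append(("structural", EXPANSION, s, None, None))
        i += 1
    for _ in range(cfg.n_collapse):
        s = _sv_size(rng, cfg)
        edits.append((struct_pos[i], s, ""))
        meta.append(("structural", COLLAPSE, s, None, None))
        i += 1
    for _ in range(cfg.n_inversion):
        lo, hi = cfg.inversion_size_range
        s = int(rng.integers(lo, hi))
        p = struct_pos[i]
        edits.append((p, s, _seq.revcomp(hap1[p : p + s])))
        meta.append(("structural", INVERSION, s, None, None))
        i += 1
    for v in switches:
        keep = v.size // 2
        p = v.hap1_pos
        edits.append((p + keep, v.size - keep, ""))
        meta.append(("structural", HAPLOTYPE_SWITCH, max(keep, v.size - keep),
                     keep, v.size - keep))

    struct_forbidden = (
        var_spans
        + [(p, p + cfg.sv_max_size) for p in struct_pos]
        + switch_spans
    )
    small_pos = _sample_positions(rng, cfg.n_small_errors, 1000, L - 1000, 50,
                                  forbidden=struct_forbidden, pad=50)
    small_pos = [int(p) for p in rng.permutation(small_pos)]
    p_sub, p_exp, _ = cfg.small_mix
    for j, p in enumerate(small_pos):
        u = rng.random()
        if u < p_sub:
            ref = hap1[p]
            alt = str(rng.permutation([b for b in "ACGT" if b != ref])[0])
            edits.append((p, 1, alt))
            meta.append(("small", BASE_SUBSTITUTION, 1, None, None))
        elif u < p_sub + p_exp:
            # 1-bp expansion: assembly gains one base
            edits.append((p, 0, _seq.random_sequence(1, rng)))
            meta.append(("small", SMALL_EXPANSION, 1, None, None))
        else:
            # 1-bp collapse: assembly loses one base
            edits.append((p, 1, ""))
            meta.append(("small", SMALL_COLLAPSE, 1, None, None))

    order = sorted(range(len(edits)), key=lambda k: edits[k][0])
    assembly, out_pos = _apply_edits(hap1, [edits[k] for k in order])
    epos, eoff = [], []
    running = 0
    for k in order:
        pos, del_len, ins = edits[k]
        running += len(ins) - del_len
        epos.append(pos + del_len)
        eoff.append(running)
    contigs = split_at_n(assembly, cfg.min_contig)
    # all coordinates are on the unsplit assembly; with no N runs there is a
    # single contig and coordinates carry over unchanged
    name = contigs[0][0] if contigs else "ctg0"
    truth = []
    for rank, k in enumerate(order):
        cls, kind, size, exp_s, col_s = meta[k]
        pos = out_pos[rank]
        if kind == HAPLOTYPE_SWITCH:
            # anchor the record at the locus start (the edit sits at the
            # kept-half/removed-half boundary)
            pos -= exp_s
        truth.append(TruthRecord(cls, kind, name, pos, size, exp_s, col_s))
    truth.sort(key=lambda t: t.pos)
    return SimulatedAssembly(contigs, truth, np.array(epos), np.array(eoff))


def _mutate_read(codes: np.ndarray, rate: float, mix: tuple[float, float, float],
                 rng: np.random.Generator) -> np.ndarray:
    """Apply i.i.d. substitution/insertion/deletion errors to a read."""
    if rate <= 0:
        return codes
    n = codes.size
    u = rng.random(n)
    err = u < rate
    if not err.any():
        return codes
    kind = rng.random(n)  # only consulted at error positions
    p_sub, p_ins, _ = mix
    sub = err & (kind < p_sub)
    ins = err & (kind >= p_sub) & (kind < p_sub + p_ins)
    dele = err & (kind >= p_sub + p_ins)
    out = codes.copy()
    if sub.any():
        out[sub] = (out[sub] + rng.integers(1, 4, size=int(sub.sum()),
                                            dtype=np.uint8)) % 4
    counts = np.ones(n, dtype=np.int64)
    counts[dele] = 0
    counts[ins] = 2
    res = np.repeat(out, counts)
    if ins.any():
        idx = np.repeat(np.arange(n), counts)
        dup = np.empty(idx.size, dtype=bool)
        dup[0] = False
        np.not_equal(idx[1:], idx[:-1], out=dup[1:])
        dup = ~dup
        dup[0] = False
        res[dup] = rng.integers(0, 4, size=int(dup.sum()), dtype=np.uint8)
    return res


def simulate_reads(
    haplotypes: Sequence[str],
    cfg: SimulationConfig,
    out_path: str | Path,
    rng: np.random.Generator | None = None,
) -> int:
    """Sample reads at the configured depth, split evenly across haplotypes,
    and write FASTA/FASTQ (gzip by extension). Returns the read count."""
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed + 2)
    out_path = Path(out_path)
    fastq = ".fq" in out_path.name or ".fastq" in out_path.name
    opener = gzip.open if out_path.name.endswith(".gz") else open
    mix = ERROR_MIX[cfg.datatype]
    rate = 1.0 - cfg.read_accuracy
    n_reads = 0
    with opener(out_path, "wt") as fh:
        for h, hap in enumerate(haplotypes):
            codes_full = _seq.encode(hap)
            target = cfg.read_depth * len(hap) / len(haplotypes)
            made = 0
            while made < target:
                ln = int(rng.normal(cfg.read_length_mean, cfg.read_length_sd))
                ln = max(cfg.read_min_length, min(ln, len(hap)))
                start = int(rng.integers(0, len(hap) - ln + 1))
                frag = _mutate_read(codes_full[start : start + ln], rate, mix, rng)
                seq = _seq.decode(frag)
                if rng.random() < 0.5:
                    seq = _seq.revcomp(seq)
                name = f"h{h}_{n_reads}"
                if fastq:
                    fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
                else:
                    fh.write(f">{name}\n{seq}\n")
                made += ln
                n_reads += 1
    return n_reads


def _kind_compatible(a: str, b: str) -> bool:
    if a == b:
        return True
    switchable = {EXPANSION, COLLAPSE, HAPLOTYPE_SWITCH}
    return (a == HAPLOTYPE_SWITCH and b in switchable) or (
        b == HAPLOTYPE_SWITCH and a in switchable)


def score_structural(
    calls: Sequence[StructuralError],
    truth: Sequence[TruthRecord],
    match_window: int = 500,
    size_tolerance: float = 0.5,
) -> BenchmarkResult:
    """Greedy one-to-one matching of structural calls to spiked truth.

    A pair matches when kinds are compatible (haplotype switches match
    expansions, collapses, and switches at their locus), breakpoints are
    within ``match_window``, and sizes agree within the reciprocal
    ``size_tolerance`` (waived for switch pairs, whose two sides make a
    single size ambiguous).
    """
    pairs = []
    for ci, c in enumerate(calls):
        for ti, t in enumerate(truth):
            if c.contig_id != t.contig_id or not _kind_compatible(c.kind, t.kind):
                continue
            d = min(abs(c.start - t.pos), abs(c.end - (t.pos + t.size)))
            if d > match_window:
                continue
            if HAPLOTYPE_SWITCH not in (c.kind, t.kind):
                lo, hi = sorted((c.size, t.size))
                if hi > 0 and lo / hi < size_tolerance:
                    continue
            pairs.append((d, ci, ti))
    pairs.sort()
    used_c: set[int] = set()
    used_t: set[int] = set()
    for _, ci, ti in pairs:
        if ci in used_c or ti in used_t:
            continue
        used_c.add(ci)
        used_t.add(ti)
    return _result(len(used_t), len(calls), len(truth), match_window,
                   size_tolerance)


def score_small(
    calls: Sequence[SmallScaleError],
    truth: Sequence[TruthRecord],
    match_window: int = 5,
) -> BenchmarkResult:
    """One-to-one matching of small-scale calls to truth by kind and
    position (within a few bp to absorb aligner indel left-shifting)."""
    pairs = []
    for ci, c in enumerate(calls):
        for ti, t in enumerate(truth):
            if c.contig_id != t.contig_id or c.kind != t.kind:
                continue
            d = abs(c.pos - t.pos)
            if d <= match_window:
                pairs.append((d, ci, ti))
    pairs.sort()
    used_c: set[int] = set()
    used_t: set[int] = set()
    for _, ci, ti in pairs:
        if ci in used_c or ti in used_t:
            continue
        used_c.add(ci)
        used_t.add(ti)
    return _result(len(used_t), len(calls), len(truth), match_window, 0.0)


def _result(tp: int, n_calls: int, n_truth: int, window: int,
            tol: float) -> BenchmarkResult:
    fp = n_calls - tp
    fn = n_truth - tp
    recall = tp / n_truth if n_truth else 0.0
    precision = tp / n_calls if n_calls else float("nan")
    if n_calls and (recall + precision) > 0:
        f1 = 2 * recall * precision / (recall + precision)
    else:
        f1 = 0.0
    return BenchmarkResult(tp, fp, fn, recall, precision, f1, window, tol)


def score_calls(
    structural_calls: Sequence[StructuralError],
    small_calls: Sequence[SmallScaleError],
    truth: Sequence[TruthRecord],
    match_window: int = 500,
    size_tolerance: float = 0.5,
    small_window: int = 5,
) -> tuple[BenchmarkResult, BenchmarkResult]:
    t_struct = [t for t in truth if t.cls == "structural"]
    t_small = [t for t in truth if t.cls == "small"]
    return (
        score_structural(structural_calls, t_struct, match_window, size_tolerance),
        score_small(small_calls, t_small, small_window),
    )


@dataclass
class ReplicateOutcome:
    structural: BenchmarkResult
    small: BenchmarkResult
    evaluation: "object"            # EvaluationResult (import kept lazy)
    truth: list[TruthRecord]
    n_het_snp: int = 0
    n_het_sv: int = 0
    n_het_snp_called: int = 0       # het SNP sites reported as small errors


def run_replicate(
    seed: int,
    datatype: str = "hifi",
    diploid: bool = True,
    workdir: str | Path | None = None,
    config: SimulationConfig | None = None,
    keep_files: bool = False,
) -> ReplicateOutcome:
    """Simulate one benchmark replicate end to end and score the calls.

    Builds the diploid (or haploid: single haplotype, homozygous-only
    variants) genome, spikes errors into haplotype 1, simulates reads,
    runs the full evaluation via the external aligner, and scores against
    the spiked truth.
    """
    import shutil
    import tempfile

    from .assembly_stats import Contig, write_fasta
    from .evaluate import EvalParams, evaluate_assembly

    cfg = config if config is not None else SimulationConfig()
    cfg = replace(cfg, rng_seed=seed, datatype=datatype)
    if not diploid:
        cfg = replace(cfg, het_fraction=0.0, n_switch=0)
    rng = np.random.default_rng(cfg.rng_seed)
    _, hap1, hap2, variants = simulate_diploid(cfg, rng)
    sim = spike_errors(hap1, variants, cfg, rng)

    tmp = Path(workdir) if workdir else Path(tempfile.mkdtemp(prefix="asmeval_sim_"))
    tmp.mkdir(parents=True, exist_ok=True)
    try:
        asm_fa = tmp / "assembly.fa"
        write_fasta([Contig(n, s) for n, s in sim.contigs], asm_fa)
        reads_fa = tmp / "reads.fa"
        haps = [hap1, hap2] if diploid else [hap1]
        simulate_reads(haps, cfg, reads_fa, rng)
        result = evaluate_assembly(
            asm_fa, reads=reads_fa, datatype=datatype,
            params=EvalParams(datatype=datatype),
        )
        s_bench, m_bench = score_calls(result.structural, result.small, sim.truth)
        n_het_snp = sum(1 for v in variants if v.kind == "snp" and v.is_het)
        n_het_sv = sum(1 for v in variants if v.kind != "snp" and v.is_het)
        het_snp_asm = {sim.hap1_to_assembly(v.hap1_pos)
                       for v in variants if v.kind == "snp" and v.is_het}
        called = {p for e in result.small for p in (e.pos - 1, e.pos, e.pos + 1)}
        n_het_snp_called = sum(1 for p in het_snp_asm if p in called)
        return ReplicateOutcome(s_bench, m_bench, result, sim.truth,
                                n_het_snp, n_het_sv, n_het_snp_called)
    finally:
        if workdir is None and not keep_files:
            shutil.rmtree(tmp, ignore_errors=True)


def write_truth_beds(truth: Sequence[TruthRecord], out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    with open(out_dir / "truth_structural.bed", "w") as fs, \
         open(out_dir / "truth_small.bed", "w") as fm:
        for t in truth:
            end = t.pos + max(t.size, 1)
            line = f"{t.contig_id}\t{t.pos}\t{end}\t{t.kind}\t{t.size}\t.\n"
            (fs if t.cls == "structural" else fm).write(line)


def read_truth_bed(path: str | Path, cls: str) -> list[TruthRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            out.append(TruthRecord(cls, f[3], f[0], int(f[1]), int(f[4])))
    return out


def write_truth_vcf(variants: Sequence[Variant], genome_name: str,
                    path: str | Path) -> None:
    """Minimal VCF of the simulated variants (base-genome coordinates)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=asmeval-simulate\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSIM\n")
        for v in sorted(variants, key=lambda v: v.pos):
            if v.kind == "snp":
                ref, alt = "N", v.alt
            elif v.kind == "ins":
                ref, alt = "N", "<INS>"
            else:
                ref, alt = "<DEL>", "N"
            gt = "1/1" if v.genotype == "hom" else ("1|0" if v.genotype == "het1" else "0|1")
            fh.write(
                f"{genome_name}\t{v.pos + 1}\t.\t{ref}\t{alt}\t.\tPASS\t"
                f"KIND={v.kind};SVLEN={v.size}\tGT\t{gt}\n"
            )
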