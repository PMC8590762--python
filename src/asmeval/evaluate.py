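"""End-to-end reference-free assembly evaluation.

Streams read-to-contig alignments (from an external aligner pipe or a
SAM/BAM file) once, accumulating pileup counts, coverage and structural
signals per contig through the compiled kernels, then calls structural and
small-scale errors and computes the QV report.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam

from . import _kernels, _seq
from .alignment import AlignmentSegment, ReadAlignStats, stream_minimap2
from .assembly_stats import AssemblyStats, Contig, contig_stats, read_fasta
from .report import QVReport, compute_qv, write_report
from .smallscale import SmallScaleError, call_from_pileup_arrays
from .structural import (RawSignal, StructuralError, StructuralParams,
                         detect_structural_errors, split_read_signals)

_EVT_KIND = {_kernels.EVT_EXPANSION: "expansion", _kernels.EVT_COLLAPSE: "collapse"}


@dataclass
class EvalParams:
    datatype: str = "hifi"
    min_contig: int = 0
    structural: StructuralParams = field(default_factory=StructuralParams)
    small_min_fraction: float = 0.2
    small_min_depth: int = 5


@dataclass
class EvaluationResult:
    stats: AssemblyStats
    align_stats: ReadAlignStats
    structural: list[StructuralError]
    small: list[SmallScaleError]
    qv: QVReport
    depth_by_contig: dict[str, np.ndarray]
    params: EvalParams


class _ContigAcc:
    """Pileup accumulators and pending segment batch for one contig."""

    __slots__ = ("codes", "sub_counts", "ins_count", "ins_base_counts",
                 "ins_len_sum", "del_count", "cov_diff", "batch", "batch_ops",
                 "batch_bases")

    def __init__(self, sequence: str):
        L = len(sequence)
        self.codes = _seq.encode(sequence)
        self.sub_counts = np.zeros((4, L), dtype=np.uint16)
        self.ins_count = np.zeros(L, dtype=np.uint16)
        self.ins_base_counts = np.zeros((4, L), dtype=np.uint16)
        self.ins_len_sum = np.zeros(L, dtype=np.uint32)
        self.del_count = np.zeros(L, dtype=np.uint16)
        self.cov_diff = np.zeros(L + 1, dtype=np.int32)
        self.batch: list[tuple] = []  # (ops, lens, ref_start, codes, read_id, mapq)
        self.batch_ops = 0
        self.batch_bases = 0


def _flush(acc: _ContigAcc, contig_id: str, signals: list[RawSignal],
           small_limit: int, struct_limit: int) -> None:
    if not acc.batch:
        return
    nseg = len(acc.batch)
    ops = np.concatenate([b[0] for b in acc.batch])
    lens = np.concatenate([b[1] for b in acc.batch])
    n_ops = np.array([b[0].size for b in acc.batch], dtype=np.int32)
    seg_op_start = np.zeros(nseg, dtype=np.int32)
    np.cumsum(n_ops[:-1], out=seg_op_start[1:])
    seg_ref_start = np.array([b[2] for b in acc.batch], dtype=np.int32)
    code_lens = np.array([b[3].size for b in acc.batch], dtype=np.int64)
    seg_read_off = np.zeros(nseg, dtype=np.int64)
    np.cumsum(code_lens[:-1], out=seg_read_off[1:])
    read_codes = np.concatenate([b[3] for b in acc.batch])
    big = int(((lens >= struct_limit) & ((ops == 1) | (ops == 2) | (ops == 3))).sum())
    cap = big + 1
    evt_kind = np.zeros(cap, dtype=np.int8)
    evt_pos = np.zeros(cap, dtype=np.int32)
    evt_size = np.zeros(cap, dtype=np.int32)
    evt_seg = np.zeros(cap, dtype=np.int32)
    n_evt = _kernels.accumulate_batch(
        ops, lens, seg_op_start, n_ops, seg_ref_start, seg_read_off,
        read_codes, acc.codes, acc.sub_counts, acc.ins_count,
        acc.ins_base_counts, acc.ins_len_sum, acc.del_count, acc.cov_diff,
        small_limit, struct_limit, evt_kind, evt_pos, evt_size, evt_seg,
    )
    for i in range(n_evt):
        b = acc.batch[evt_seg[i]]
        signals.append(
            RawSignal(_EVT_KIND[int(evt_kind[i])], contig_id, int(evt_pos[i]),
                      int(evt_size[i]), b[4], b[5])
        )
    acc.batch = []
    acc.batch_ops = 0
    acc.batch_bases = 0


def evaluate_alignment_stream(
    af: pysam.AlignmentFile,
    contigs: Sequence[Contig],
    params: EvalParams,
    n_reads: int | None = None,
) -> EvaluationResult:
    """Single-pass evaluation over a SAM/BAM record stream."""
    by_name = {c.name: c for c in contigs}
    accs: dict[str, _ContigAcc] = {}
    signals: list[RawSignal] = []
    seg_meta: dict[str, list[tuple]] = {}
    n_total = 0
    aligned_bases = 0
    small_limit = params.structural.min_size
    struct_limit = params.structural.min_size

    for rec in af:
        if rec.is_secondary:
            continue
        if rec.is_unmapped:
            n_total += 1
            continue
        if not rec.is_supplementary:
            n_total += 1
        cid = rec.reference_name
        contig = by_name.get(cid)
        if contig is None:
            raise ValueError(f"alignment references unknown contig {cid!r}")
        if contig.length < params.min_contig:
            continue
        acc = accs.get(cid)
        if acc is None:
            acc = accs[cid] = _ContigAcc(contig.sequence)
        ct = rec.cigartuples
        if not ct:
            continue
        arr = np.array(ct, dtype=np.int32)
        ops = arr[:, 0].astype(np.int8)
        lens = arr[:, 1]
        seq = rec.query_sequence
        if seq:
            codes = _seq.encode(seq)
        else:
            consumed = int(lens[(ops == 0) | (ops == 1) | (ops == 4)
                                | (ops == 7) | (ops == 8)].sum())
            codes = np.full(consumed, 4, dtype=np.uint8)
        acc.batch.append((ops, lens, rec.reference_start, codes,
                          rec.query_name, rec.mapping_quality))
        acc.batch_ops += ops.size
        acc.batch_bases += codes.size
        aligned_bases += rec.reference_end - rec.reference_start

        read_len = int(lens[(ops == 0) | (ops == 1) | (ops == 4) | (ops == 5)
                            | (ops == 7) | (ops == 8)].sum())
        lead = tail = 0
        i = 0
        while i < ops.size and ops[i] in (4, 5):
            lead += int(lens[i])
            i += 1
        j = ops.size - 1
        while j > i and ops[j] in (4, 5):
            tail += int(lens[j])
            j -= 1
        if rec.is_reverse:
            rstart, rend, strand = tail, read_len - lead, "-"
        else:
            rstart, rend, strand = lead, read_len - tail, "+"
        seg_meta.setdefault(rec.query_name, []).append(
            (cid, rec.reference_start, rec.reference_end, rstart, rend,
             strand, rec.mapping_quality)
        )
        if acc.batch_ops > 3_000_000 or acc.batch_bases > 64_000_000:
            _flush(acc, cid, signals, small_limit, struct_limit)

    for cid, acc in accs.items():
        _flush(acc, cid, signals, small_limit, struct_limit)

    depth_by_contig = {
        cid: np.cumsum(acc.cov_diff[:-1]).astype(np.int32)
        for cid, acc in accs.items()
    }
    stats = contig_stats(contigs, params.min_contig)
    mean_depth = aligned_bases / stats.total_bases if stats.total_bases else 0.0

    for read_id, metas in seg_meta.items():
        if len(metas) < 2:
            continue
        segs = [
            AlignmentSegment(read_id, m[0], m[1], m[2], m[3], m[4], m[5],
                             m[6], True, False)
            for m in metas
        ]
        signals.extend(split_read_signals(segs, params.structural.min_size))

    structural = detect_structural_errors(
        signals, depth_by_contig, mean_depth, params.structural
    )

    small: list[SmallScaleError] = []
    for cid in sorted(accs):
        acc = accs[cid]
        small.extend(
            call_from_pileup_arrays(
                cid, acc.codes, depth_by_contig[cid], acc.sub_counts,
                acc.ins_count, acc.ins_base_counts, acc.ins_len_sum,
                acc.del_count, params.datatype, params.small_min_fraction,
                params.small_min_depth,
            )
        )
    small.sort(key=lambda e: (e.contig_id, e.pos))

    # exclude small calls inside structural error spans (they are the same
    # underlying event seen at base resolution)
    if structural:
        spans: dict[str, list[tuple[int, int]]] = {}
        for e in structural:
            spans.setdefault(e.contig_id, []).append((e.start - 10, e.end + 10))
        small = [
            e for e in small
            if not any(s <= e.pos < t for s, t in spans.get(e.contig_id, ()))
        ]

    n_mapped = len(seg_meta)
    n_split = sum(1 for v in seg_meta.values() if len(v) > 1)
    if n_reads is None:
        n_reads = n_total
    align_stats = ReadAlignStats(
        mapping_rate=n_mapped / n_reads if n_reads else 0.0,
        splitting_rate=n_split / n_mapped if n_mapped else 0.0,
        mean_depth=mean_depth,
        n_reads=n_reads,
        n_mapped=n_mapped,
        n_split=n_split,
    )
    qv = compute_qv(structural, small, stats.total_bases)
    return EvaluationResult(stats, align_stats, structural, small, qv,
                            depth_by_contig, params)


def evaluate_assembly(
    contig_fasta: str | Path,
    reads: str | Path | None = None,
    datatype: str = "hifi",
    alignments: str | Path | None = None,
    out_dir: str | Path | None = None,
    params: EvalParams | None = None,
    threads: int = 1,
    n_reads: int | None = None,
) -> EvaluationResult:
    """Evaluate an assembly from reads (aligned on the fly with minimap2)
    or from precomputed SAM/BAM alignments.

    When ``out_dir`` is given, the text/JSON summary and the structural and
    small-scale BED files are written there.
    """
    if params is None:
        params = EvalParams(datatype=datatype)
    else:
        params.datatype = datatype
    contigs = read_fasta(contig_fasta)
    if alignments is not None:
        with pysam.AlignmentFile(str(alignments), check_sq=False) as af:
            result = evaluate_alignment_stream(af, contigs, params, n_reads)
    elif reads is not None:
        with stream_minimap2(reads, contig_fasta, datatype, threads) as af:
            result = evaluate_alignment_stream(af, contigs, params, n_reads)
    else:
        raise ValueError("provide either reads or precomputed alignments")
    if out_dir is not None:
        write_report(result.stats, result.align_stats, result.structural,
                     result.small, result.qv, out_dir)
    return result
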