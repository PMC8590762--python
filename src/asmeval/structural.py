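"""Structural assembly error (>=50 bp) detection from read alignments.

Raw signals come from two alignment features: large CIGAR indels within a
segment (a deletion in the read alignment means the contig carries extra
sequence — an expansion; an insertion means the contig is missing sequence
— a collapse), and split alignments of one read (coordinate gaps between
same-strand segments yield expansion/collapse signals, strand flips yield
inversion signals). Signals are clustered per type with a window that
widens with the cluster's size estimate, so repeat-induced breakpoint
shifts still cluster while clean regions keep a tight window. Expansion
clusters overlapping collapse clusters are merged into haplotype-switch
candidates (reads from one haplotype report an expansion, the other a
collapse). Candidates are finally filtered on supporting-read count, on the
ratio of error-supporting reads to local coverage (~100% expected for real
errors vs ~50% for heterozygous variants), on local coverage, and on mean
mapping quality.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Sequence

import numpy as np

from .alignment import AlignmentSegment

EXPANSION = "Expansion"
COLLAPSE = "Collapse"
HAPLOTYPE_SWITCH = "HaplotypeSwitch"
INVERSION = "Inversion"

_SIGNAL_TO_KIND = {
    "expansion": EXPANSION,
    "collapse": COLLAPSE,
    "inversion": INVERSION,
}


@dataclass
class StructuralParams:
    min_size: int = 50
    min_support: int = 3
    ratio_cutoff: float = 0.75
    depth_cap: float = 3.0          # x assembly mean depth
    mq_cutoff: float = 20.0
    base_window: int = 500
    repeat_tolerance_factor: float = 2.0
    depth_pad: int = 50


@dataclass
class RawSignal:
    kind: str                       # expansion | collapse | inversion
    contig_id: str
    pos: int                        # left breakpoint, 0-based
    size: int                       # inversions: inverted span
    read_id: str
    mapq: int

    @property
    def end(self) -> int:
        # collapses are point events on the contig
        return self.pos + (self.size if self.kind != "collapse" else 1)


@dataclass
class SignalCluster:
    kind: str
    contig_id: str
    start: int
    end: int
    size_estimate: int
    supporting_reads: set[str] = field(default_factory=set)
    members: list[RawSignal] = field(default_factory=list)
    # populated for haplotype-switch candidates
    expansion_size: int | None = None
    collapse_size: int | None = None

    @property
    def n_support(self) -> int:
        return len(self.supporting_reads)

    def mean_mapq(self) -> float:
        return float(np.mean([m.mapq for m in self.members])) if self.members else 0.0


@dataclass
class StructuralError:
    kind: str
    contig_id: str
    start: int
    end: int
    size: int
    n_support: int
    local_depth: float
    support_ratio: float
    mean_mapq: float
    expansion_size: int | None = None
    collapse_size: int | None = None


def _forward_sorted(segments: Sequence[AlignmentSegment]) -> list[AlignmentSegment]:
    return sorted(segments, key=lambda s: s.read_start)


def split_read_signals(
    segments: Sequence[AlignmentSegment], min_size: int = 50
) -> list[RawSignal]:
    """Signals from the split alignments of a single read on one contig."""
    out: list[RawSignal] = []
    by_contig: dict[str, list[AlignmentSegment]] = {}
    for s in segments:
        by_contig.setdefault(s.contig_id, []).append(s)
    for contig_id, segs in by_contig.items():
        if len(segs) < 2:
            continue
        segs = _forward_sorted(segs)
        span_by_strand = {"+": 0, "-": 0}
        for s in segs:
            span_by_strand[s.strand] += s.contig_span()
        dominant = "+" if span_by_strand["+"] >= span_by_strand["-"] else "-"
        mapq = int(np.mean([s.mapq for s in segs]))
        read_id = segs[0].read_id
        # strand-flipped blocks: inversion signals
        i = 0
        while i < len(segs):
            if segs[i].strand != dominant:
                j = i
                while j + 1 < len(segs) and segs[j + 1].strand != dominant:
                    j += 1
                start = min(s.contig_start for s in segs[i : j + 1])
                end = max(s.contig_end for s in segs[i : j + 1])
                if end - start >= min_size:
                    out.append(
                        RawSignal("inversion", contig_id, start, end - start,
                                  read_id, mapq)
                    )
                i = j + 1
            else:
                i += 1
        # coordinate gaps between consecutive same-strand segments
        for a, b in zip(segs, segs[1:]):
            if a.strand != b.strand:
                continue
            rgap = b.read_start - a.read_end
            if a.strand == "+":
                cgap = b.contig_start - a.contig_end
                bp = a.contig_end
            else:
                cgap = a.contig_start - b.contig_end
                bp = b.contig_end
            delta = cgap - rgap
            if delta >= min_size:
                out.append(RawSignal("expansion", contig_id, bp, delta, read_id, mapq))
            elif -delta >= min_size and cgap > -min_size:
                out.append(RawSignal("collapse", contig_id, max(bp, 0), -delta,
                                     read_id, mapq))
    return out


def extract_signals(
    segments: Sequence[AlignmentSegment], min_size: int = 50
) -> list[RawSignal]:
    """All raw structural signals from the segments of one read.

    Large CIGAR deletions/insertions give expansion/collapse signals at
    their contig coordinates; split alignments add gap and inversion
    signals.
    """
    out: list[RawSignal] = []
    for seg in segments:
        if not (seg.is_primary or seg.is_supplementary):
            continue
        cpos = seg.contig_start
        for op, ln in seg.cigar:
            if op in (0, 7, 8):
                cpos += ln
            elif op == 1:
                if ln >= min_size:
                    out.append(RawSignal("collapse", seg.contig_id, cpos, ln,
                                         seg.read_id, seg.mapq))
            elif op in (2, 3):
                if ln >= min_size:
                    out.append(RawSignal("expansion", seg.contig_id, cpos, ln,
                                         seg.read_id, seg.mapq))
                cpos += ln
    out.extend(split_read_signals([s for s in segments
                                   if s.is_primary or s.is_supplementary],
                                  min_size))
    return out


def cluster_signals(
    signals: Sequence[RawSignal],
    base_window: int = 500,
    repeat_tolerance_factor: float = 2.0,
) -> list[SignalCluster]:
    """Greedy left-to-right clustering of same-kind, same-contig signals.

    A signal joins the open cluster when its position is within
    max(base_window, repeat_tolerance_factor * cluster median size) of the
    cluster's rightmost member; each read contributes once to the
    supporting-read set.
    """
    clusters: list[SignalCluster] = []
    for sig in sorted(signals, key=lambda s: s.pos):
        cur = clusters[-1] if clusters else None
        if cur is not None:
            window = max(base_window,
                         repeat_tolerance_factor * cur.size_estimate)
            joins = sig.pos - cur.members[-1].pos <= window
        else:
            joins = False
        if joins:
            cur.members.append(sig)
            cur.supporting_reads.add(sig.read_id)
            cur.start = min(cur.start, sig.pos)
            cur.end = max(cur.end, sig.end)
            cur.size_estimate = int(median(m.size for m in cur.members))
        else:
            clusters.append(
                SignalCluster(sig.kind, sig.contig_id, sig.pos, sig.end,
                              sig.size, {sig.read_id}, [sig])
            )
    return clusters


def merge_haplotype_switches(
    expansions: Sequence[SignalCluster],
    collapses: Sequence[SignalCluster],
    base_window: int = 500,
) -> tuple[list[SignalCluster], list[SignalCluster], list[SignalCluster]]:
    """Merge overlapping expansion/collapse clusters into switch candidates.

    Expansion clusters are scanned by position; each may consume the
    nearest-by-midpoint unconsumed collapse cluster whose window-padded
    interval intersects its own. Returns (switches, remaining_expansions,
    remaining_collapses).
    """
    switches: list[SignalCluster] = []
    remaining_exp: list[SignalCluster] = []
    used = [False] * len(collapses)
    cols = sorted(range(len(collapses)), key=lambda i: collapses[i].start)
    for exp in sorted(expansions, key=lambda c: c.start):
        lo, hi = exp.start - base_window, exp.end + base_window
        mid = (exp.start + exp.end) / 2
        best = None
        for i in cols:
            if used[i]:
                continue
            col = collapses[i]
            if col.start - base_window > hi:
                break
            if col.end + base_window < lo:
                continue
            d = abs((col.start + col.end) / 2 - mid)
            if best is None or d < best[0]:
                best = (d, i)
        if best is None:
            remaining_exp.append(exp)
            continue
        used[best[1]] = True
        col = collapses[best[1]]
        sw = SignalCluster(
            HAPLOTYPE_SWITCH, exp.contig_id,
            min(exp.start, col.start), max(exp.end, col.end),
            max(exp.size_estimate, col.size_estimate),
            exp.supporting_reads | col.supporting_reads,
            exp.members + col.members,
            expansion_size=exp.size_estimate,
            collapse_size=col.size_estimate,
        )
        switches.append(sw)
    remaining_col = [c for i, c in enumerate(collapses) if not used[i]]
    return switches, remaining_exp, remaining_col


def filter_structural(
    clusters: Iterable[SignalCluster],
    depth_by_contig: dict[str, np.ndarray],
    assembly_mean_depth: float,
    params: StructuralParams = StructuralParams(),
) -> list[StructuralError]:
    """Apply the support / ratio / coverage / mapping-quality filters."""
    out: list[StructuralError] = []
    for cl in clusters:
        if cl.n_support < params.min_support:
            continue
        if cl.kind == HAPLOTYPE_SWITCH:
            if min(cl.expansion_size or 0, cl.collapse_size or 0) < params.min_size:
                continue
        elif cl.size_estimate < params.min_size:
            continue
        depth = depth_by_contig.get(cl.contig_id)
        if depth is None or depth.size == 0:
            continue
        lo = max(cl.start - params.depth_pad, 0)
        hi = min(cl.end + params.depth_pad, depth.size)
        local = float(depth[lo:hi].mean()) if hi > lo else 0.0
        if local <= 0:
            continue
        ratio = cl.n_support / local
        if ratio < params.ratio_cutoff:
            continue
        if assembly_mean_depth > 0 and local > params.depth_cap * assembly_mean_depth:
            continue
        mq = cl.mean_mapq()
        if mq < params.mq_cutoff:
            continue
        kind = cl.kind if cl.kind == HAPLOTYPE_SWITCH else _SIGNAL_TO_KIND[cl.members[0].kind]
        out.append(
            StructuralError(kind, cl.contig_id, cl.start, cl.end,
                            cl.size_estimate, cl.n_support, local, ratio, mq,
                            cl.expansion_size, cl.collapse_size)
        )
    out.sort(key=lambda e: (e.contig_id, e.start))
    return out


def detect_structural_errors(
    signals: Sequence[RawSignal],
    depth_by_contig: dict[str, np.ndarray],
    assembly_mean_depth: float,
    params: StructuralParams = StructuralParams(),
) -> list[StructuralError]:
    """Cluster raw signals per contig and type, merge switches, filter."""
    groups: dict[tuple[str, str], list[RawSignal]] = {}
    for s in signals:
        if s.size >= params.min_size:
            groups.setdefault((s.contig_id, s.kind), []).append(s)
    all_clusters: list[SignalCluster] = []
    contigs = {cid for cid, _ in groups}
    for cid in sorted(contigs):
        exp = cluster_signals(groups.get((cid, "expansion"), []),
                              params.base_window, params.repeat_tolerance_factor)
        col = cluster_signals(groups.get((cid, "collapse"), []),
                              params.base_window, params.repeat_tolerance_factor)
        inv = cluster_signals(groups.get((cid, "inversion"), []),
                              params.base_window, params.repeat_tolerance_factor)
        switches, exp, col = merge_haplotype_switches(exp, col, params.base_window)
        all_clusters.extend(switches + exp + col + inv)
    return filter_structural(all_clusters, depth_by_contig,
                             assembly_mean_depth, params)
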