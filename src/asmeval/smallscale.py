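"""Small-scale (<50 bp) consensus error calling from pileup.

At every covered contig position, spanning reads are treated as independent
trials: a read either agrees with the contig or supports an alternative
event (different base, insertion, or deletion). True consensus errors are
supported by reads from both haplotypes (~100% of reads), heterozygous
variants by one haplotype (~50%). A one-tailed binomial test on the
error-supporting read count separates the two: the null probability of
support is p = 0.5 for high-accuracy (HiFi) data and p = 0.4 for noisy
(CLR/Nanopore) data, and candidates are reported when the upper-tail
p-value falls below 0.01 (HiFi) or 0.05 (CLR/Nanopore). Positions where
fewer than 20% of reads support the alternative are excluded up front as
sequencing noise.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy.stats import binom

from . import _seq
from .alignment import AlignmentSegment

# (null support probability, significance threshold) per datatype
DATATYPE_PARAMS = {
    "hifi": (0.5, 0.01),
    "clr": (0.4, 0.05),
    "nano": (0.4, 0.05),
}

SMALL_LIMIT = 50  # indels at or above this size are structural, not small

BASE_SUBSTITUTION = "BaseSubstitution"
SMALL_EXPANSION = "SmallExpansion"   # contig has extra bases; reads delete
SMALL_COLLAPSE = "SmallCollapse"     # contig misses bases; reads insert


@dataclass
class PileupColumn:
    contig_id: str
    pos: int
    depth: int                      # spanning reads (includes deleting reads)
    ref_base: str
    base_counts: dict[str, int] = field(default_factory=dict)
    ins_counts: dict[str, int] = field(default_factory=dict)
    del_counts: dict[int, int] = field(default_factory=dict)
    n_deleting: int = 0             # reads whose alignment deletes this column


@dataclass
class SmallCandidate:
    contig_id: str
    pos: int
    kind: str
    contig_allele: str
    read_allele: str
    n_reads: int
    n_supp: int


@dataclass
class SmallScaleError:
    kind: str
    contig_id: str
    pos: int
    size: int
    contig_allele: str
    read_allele: str
    n_reads: int
    n_supp: int
    p_value: float

    @property
    def support_fraction(self) -> float:
        return self.n_supp / self.n_reads if self.n_reads else 0.0

    @property
    def affected_bases(self) -> int:
        return 1 if self.kind == BASE_SUBSTITUTION else self.size


def pileup(
    segments: Sequence[AlignmentSegment], contig_id: str, contig_seq: str
) -> Iterator[PileupColumn]:
    """Build pileup columns from alignment segments (reference Python path).

    Segments must carry ``read_sequence`` (aligned orientation). Insertions
    are anchored at the position preceding them; deletions are counted at
    every deleted column and as a length event at the anchor. This
    straightforward implementation serves the column-level API and small
    inputs; the evaluation pipeline uses a compiled equivalent.
    """
    L = len(contig_seq)
    depth = np.zeros(L + 1, dtype=np.int64)
    cols: dict[int, PileupColumn] = {}

    def col(pos: int) -> PileupColumn:
        c = cols.get(pos)
        if c is None:
            c = cols[pos] = PileupColumn(contig_id, pos, 0, contig_seq[pos])
        return c

    for seg in segments:
        if seg.contig_id != contig_id or not (seg.is_primary or seg.is_supplementary):
            continue
        depth[seg.contig_start] += 1
        depth[seg.contig_end] -= 1
        seq = seg.read_sequence or ""
        cpos, rpos = seg.contig_start, 0
        for op, ln in seg.cigar:
            if op in (0, 7, 8):  # M/=/X
                for j in range(ln):
                    rb = seq[rpos + j] if rpos + j < len(seq) else "N"
                    if rb != contig_seq[cpos + j]:
                        c = col(cpos + j)
                        c.base_counts[rb] = c.base_counts.get(rb, 0) + 1
                cpos += ln
                rpos += ln
            elif op == 1:  # I
                if ln < SMALL_LIMIT:
                    a = max(cpos - 1, 0)
                    ins = seq[rpos : rpos + ln] or "N" * ln
                    c = col(a)
                    c.ins_counts[ins] = c.ins_counts.get(ins, 0) + 1
                rpos += ln
            elif op in (2, 3):  # D/N
                if ln < SMALL_LIMIT:
                    anchor = col(cpos)
                    anchor.del_counts[ln] = anchor.del_counts.get(ln, 0) + 1
                    for j in range(ln):
                        col(cpos + j).n_deleting += 1
                cpos += ln
            elif op == 4:  # S
                rpos += ln
    cov = np.cumsum(depth[:-1])
    for pos in sorted(cols):
        c = cols[pos]
        c.depth = int(cov[pos])
        yield c


def binomial_pvalue(n_supp: int, n_reads: int, p: float) -> float:
    """Exact upper-tail binomial probability P(X >= n_supp | n_reads, p)."""
    if not (0 <= n_supp <= n_reads):
        raise ValueError("require 0 <= n_supp <= n_reads")
    if not (0.0 < p < 1.0):
        raise ValueError("require 0 < p < 1")
    if n_supp == 0:
        return 1.0
    return float(binom.sf(n_supp - 1, n_reads, p))


def candidate_small_errors(
    columns: Iterable[PileupColumn],
    min_fraction: float = 0.2,
    min_depth: int = 5,
) -> list[SmallCandidate]:
    """Pick the single most-supported alternative event per column.

    A candidate is kept when its support reaches ``min_fraction`` of the
    spanning reads (boundary inclusive); columns below ``min_depth`` are
    uncallable and skipped.
    """
    out = []
    for c in columns:
        if c.depth < min_depth:
            continue
        best = None  # (count, priority, kind, contig_allele, read_allele)
        for base, n in c.base_counts.items():
            if base != c.ref_base and (best is None or n > best[0]):
                best = (n, 2, BASE_SUBSTITUTION, c.ref_base, base)
        n_ins = sum(c.ins_counts.values())
        if n_ins and (best is None or n_ins > best[0]):
            allele = max(c.ins_counts, key=c.ins_counts.get)
            best = (n_ins, 1, SMALL_COLLAPSE, "", allele)
        if c.n_deleting and (best is None or c.n_deleting > best[0]):
            best = (c.n_deleting, 0, SMALL_EXPANSION, c.ref_base, "")
        if best is None:
            continue
        n_supp = best[0]
        if n_supp / c.depth >= min_fraction:
            out.append(
                SmallCandidate(c.contig_id, c.pos, best[2], best[3], best[4],
                               c.depth, n_supp)
            )
    return out


def call_small_errors(
    candidates: Sequence[SmallCandidate], datatype: str
) -> list[SmallScaleError]:
    """Binomial-test candidates at the datatype's null p and threshold."""
    if datatype not in DATATYPE_PARAMS:
        raise ValueError(f"datatype must be one of {sorted(DATATYPE_PARAMS)}")
    p0, alpha = DATATYPE_PARAMS[datatype]
    out = []
    for c in candidates:
        pv = binomial_pvalue(c.n_supp, c.n_reads, p0)
        if pv < alpha:
            size = max(len(c.read_allele), len(c.contig_allele), 1)
            out.append(
                SmallScaleError(c.kind, c.contig_id, c.pos, size,
                                c.contig_allele, c.read_allele,
                                c.n_reads, c.n_supp, pv)
            )
    return out


def call_from_pileup_arrays(
    contig_id: str,
    contig_codes: np.ndarray,
    depth: np.ndarray,
    sub_counts: np.ndarray,
    ins_count: np.ndarray,
    ins_base_counts: np.ndarray,
    ins_len_sum: np.ndarray,
    del_count: np.ndarray,
    datatype: str,
    min_fraction: float = 0.2,
    min_depth: int = 5,
) -> list[SmallScaleError]:
    """Vectorised candidate selection + binomial test over whole-contig
    pileup accumulators (the compiled pipeline path).

    Adjacent deletion-supported columns are merged into a single expansion
    record spanning the run, so a k-bp expansion is one error of size k.
    """
    p0, alpha = DATATYPE_PARAMS[datatype]
    d = depth.astype(np.int64)
    alt_sub = sub_counts.max(axis=0).astype(np.int64)
    # insertion support follows the most common inserted allele (grouped by
    # first base), matching the per-sequence insertion counts of the column
    # API; ins_count retains the total for mean-length estimation
    ins = ins_base_counts.max(axis=0).astype(np.int64)
    dele = del_count.astype(np.int64)
    top = np.maximum(np.maximum(alt_sub, ins), dele)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(d > 0, top / np.maximum(d, 1), 0.0)
    cand = np.flatnonzero((d >= min_depth) & (top > 0) & (frac >= min_fraction))
    if cand.size == 0:
        return []
    # event choice per candidate column: ties favour substitution, then
    # insertion, then deletion
    k_sub = alt_sub[cand] == top[cand]
    k_ins = (~k_sub) & (ins[cand] == top[cand])
    n_supp = top[cand]
    n_reads = d[cand]
    pv = binom.sf(n_supp - 1, n_reads, p0)
    sig = pv < alpha
    sub_arg = sub_counts[:, cand].argmax(axis=0)
    ins_arg = ins_base_counts[:, cand].argmax(axis=0)

    errors: list[SmallScaleError] = []
    open_run: list[int] | None = None  # indices into cand for a deletion run

    def flush_run():
        nonlocal open_run
        if not open_run:
            return
        idxs = open_run
        open_run = None
        positions = [int(cand[i]) for i in idxs]
        start, end = positions[0], positions[-1] + 1
        best = max(idxs, key=lambda i: n_supp[i])
        errors.append(
            SmallScaleError(
                SMALL_EXPANSION, contig_id, start, end - start,
                _seq.decode(contig_codes[start:end]), "",
                int(n_reads[best]), int(n_supp[best]),
                float(min(pv[i] for i in idxs)),
            )
        )

    for i in range(cand.size):
        if not sig[i]:
            continue
        pos = int(cand[i])
        if k_sub[i]:
            flush_run()
            ref = _seq.decode(contig_codes[pos : pos + 1])
            alt = "ACGT"[int(sub_arg[i])]
            errors.append(
                SmallScaleError(BASE_SUBSTITUTION, contig_id, pos, 1, ref, alt,
                                int(n_reads[i]), int(n_supp[i]), float(pv[i]))
            )
        elif k_ins[i]:
            flush_run()
            mean_len = max(1, round(float(ins_len_sum[pos]) / max(1, ins[pos])))
            allele = "ACGT"[int(ins_arg[i])] * mean_len
            errors.append(
                SmallScaleError(SMALL_COLLAPSE, contig_id, pos, mean_len, "",
                                allele, int(n_reads[i]), int(n_supp[i]),
                                float(pv[i]))
            )
        else:
            if open_run and cand[open_run[-1]] == pos - 1:
                open_run.append(i)
            else:
                flush_run()
                open_run = [i]
    flush_run()
    errors.sort(key=lambda e: e.pos)
    return errors
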