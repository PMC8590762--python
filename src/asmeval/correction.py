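"""Targeted assembly error correction.

Small-scale errors are corrected in place with the allele supported by the
majority of reads. Structural errors are corrected by local reassembly:
the error-supporting reads around the locus (one haplotype's reads for a
haplotype switch) are collapsed into a consensus which replaces the
flanked region of the original contig. The built-in consensus engine is a
greedy star alignment: every read is aligned to a backbone read (edlib)
and a column-majority vote produces the consensus; an external assembler
can be plugged in instead. Errors whose local reassembly fails to anchor
on both flanks are retained and reported, never silently dropped.
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import edlib
import pysam

from .assembly_stats import Contig
from .smallscale import (BASE_SUBSTITUTION, SMALL_COLLAPSE, SMALL_EXPANSION,
                         SmallScaleError)
from .structural import HAPLOTYPE_SWITCH, StructuralError

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 5000
ANCHOR_LEN = 500


@dataclass
class Patch:
    contig_id: str
    replace_start: int
    replace_end: int
    replacement: str
    source: str              # substitution | local_assembly
    provenance: str
    support: int = 0


def small_error_patches(small_errors: Sequence[SmallScaleError]) -> list[Patch]:
    """Turn small-scale calls into 0/1-bp patches on original coordinates.

    Overlapping calls are resolved in favour of the lower p-value.
    """
    by_pos: dict[tuple[str, int], SmallScaleError] = {}
    for e in small_errors:
        key = (e.contig_id, e.pos)
        old = by_pos.get(key)
        if old is None or e.p_value < old.p_value:
            if old is not None:
                logger.info("dropping overlapping small-scale call at %s:%d",
                            e.contig_id, e.pos)
            by_pos[key] = e
    patches = []
    for e in by_pos.values():
        prov = f"small:{e.kind}:{e.pos}"
        if e.kind == BASE_SUBSTITUTION:
            patches.append(Patch(e.contig_id, e.pos, e.pos + 1, e.read_allele,
                                 "substitution", prov, e.n_supp))
        elif e.kind == SMALL_EXPANSION:
            # contig has extra bases: remove them
            patches.append(Patch(e.contig_id, e.pos, e.pos + e.size, "",
                                 "substitution", prov, e.n_supp))
        elif e.kind == SMALL_COLLAPSE:
            # contig misses bases: insert after the anchor column
            patches.append(Patch(e.contig_id, e.pos + 1, e.pos + 1,
                                 e.read_allele, "substitution", prov, e.n_supp))
    return patches


def correct_small(
    contigs: Sequence[Contig], small_errors: Sequence[SmallScaleError]
) -> list[Contig]:
    """Apply majority-allele substitutions for all small-scale errors."""
    corrected, _ = apply_patches(contigs, small_error_patches(small_errors))
    return corrected


def _query_window(rec: pysam.AlignedSegment, lo: int, hi: int) -> str | None:
    """Read subsequence whose alignment covers contig window [lo, hi),
    clamped to the aligned part of the read."""
    seq = rec.query_sequence
    if not seq:
        return None
    q_lo, q_hi = None, None
    qpos, rpos = 0, rec.reference_start
    for op, ln in rec.cigartuples:
        if op in (0, 7, 8):
            if q_lo is None and rpos + ln > lo:
                q_lo = qpos + max(0, lo - rpos)
            if rpos + ln >= hi:
                q_hi = qpos + min(ln, hi - rpos)
                break
            qpos += ln
            rpos += ln
        elif op == 1:
            qpos += ln
        elif op in (2, 3):
            if q_lo is None and rpos + ln > lo:
                q_lo = qpos
            if rpos + ln >= hi:
                q_hi = qpos
                break
            rpos += ln
        elif op == 4:
            qpos += ln
    if q_lo is None:
        q_lo = 0
    if q_hi is None:
        q_hi = len(seq)
    return seq[q_lo:q_hi] if q_hi > q_lo else None


def collect_error_reads(
    error: StructuralError,
    bam_path: str | Path,
    flank: int = DEFAULT_FLANK,
    min_support: int = 3,
    max_reads: int = 60,
) -> list[str]:
    """Reads overlapping the error locus +/- flank, clipped to the window.

    For a haplotype switch only reads carrying the majority side's signal
    are collected (expansion side on ties), so the consensus reconstructs
    one haplotype. For other errors, reads must reach both flanks (anchored
    in the current repeat unit) to be used.
    """
    lo = max(0, error.start - flank)
    hi = error.end + flank
    picked: list[tuple[str, str]] = []  # (side, seq)
    with pysam.AlignmentFile(str(bam_path)) as af:
        for rec in af.fetch(error.contig_id, lo, min(hi, af.get_reference_length(error.contig_id))):
            if rec.is_secondary or rec.is_supplementary or rec.is_unmapped:
                continue
            if rec.reference_start > error.start - 200 or rec.reference_end < error.end + 200:
                # not anchored across the locus
                continue
            side = _read_side(rec, error)
            if error.kind == HAPLOTYPE_SWITCH and side is None:
                continue
            seq = _query_window(rec, lo, hi)
            if seq:
                picked.append((side or "", seq))
    if error.kind == HAPLOTYPE_SWITCH:
        counts = Counter(side for side, _ in picked)
        exp_n, col_n = counts.get("expansion", 0), counts.get("collapse", 0)
        chosen = "expansion" if exp_n >= col_n else "collapse"
        reads = [s for side, s in picked if side == chosen]
    else:
        reads = [s for _, s in picked]
    if len(reads) < min_support:
        raise UncorrectableError(
            f"{error.kind} at {error.contig_id}:{error.start}: only "
            f"{len(reads)} usable reads"
        )
    return reads[:max_reads]


def _read_side(rec: pysam.AlignedSegment, error: StructuralError) -> str | None:
    """Classify a read as expansion- or collapse-signalling at the locus."""
    rpos = rec.reference_start
    window_lo, window_hi = error.start - 500, error.end + 500
    for op, ln in rec.cigartuples:
        if op in (0, 7, 8):
            rpos += ln
        elif op == 1:
            if ln >= 40 and window_lo <= rpos <= window_hi:
                return "collapse"
        elif op in (2, 3):
            if ln >= 40 and window_lo <= rpos <= window_hi:
                return "expansion"
            rpos += ln
    return None


class UncorrectableError(RuntimeError):
    pass


def star_consensus(reads: Sequence[str], min_reads: int = 3) -> str:
    """Greedy star-alignment consensus of a read set.

    The longest read is the backbone; every other read is infix-aligned to
    it with edlib and votes per backbone column (base, deletion) and per
    junction (insertion). Majority vote yields the consensus.
    """
    if len(reads) < min_reads:
        raise UncorrectableError(f"consensus needs >= {min_reads} reads")
    backbone = max(reads, key=len)
    L = len(backbone)
    base_votes = [Counter() for _ in range(L)]
    ins_votes = [Counter() for _ in range(L + 1)]
    cov = [0] * L
    for read in reads:
        if read is backbone:
            tpos = 0
            for ch in backbone:
                base_votes[tpos][ch] += 1
                cov[tpos] += 1
                tpos += 1
            continue
        res = edlib.align(read, backbone, task="path", mode="HW")
        locs = res.get("locations") or []
        if not locs or res["cigar"] is None:
            continue
        tpos = locs[0][0]
        qpos = 0
        num = ""
        for ch in res["cigar"]:
            if ch.isdigit():
                num += ch
                continue
            ln = int(num)
            num = ""
            if ch == "=" or ch == "X" or ch == "M":
                for j in range(ln):
                    base_votes[tpos + j][read[qpos + j]] += 1
                    cov[tpos + j] += 1
                tpos += ln
                qpos += ln
            elif ch == "I":  # in read, absent from backbone
                ins_votes[tpos][read[qpos : qpos + ln]] += 1
                qpos += ln
            elif ch == "D":  # backbone base absent from read
                for j in range(ln):
                    base_votes[tpos + j]["-"] += 1
                    cov[tpos + j] += 1
                tpos += ln
    out: list[str] = []
    for i in range(L):
        if cov[i] == 0:
            out.append(backbone[i])
            continue
        ins = ins_votes[i]
        if ins:
            seq, n = ins.most_common(1)[0]
            if n * 2 > cov[i]:
                out.append(seq)
        base, _ = base_votes[i].most_common(1)[0]
        if base != "-":
            out.append(base)
    return "".join(out)


def local_reassemble(
    reads: Sequence[str],
    engine: Callable[[Sequence[str]], str] | None = None,
    min_reads: int = 3,
) -> str:
    """Produce a consensus for the locus from its read subset.

    ``engine`` may be any callable mapping reads to a single consensus
    sequence (e.g. an external assembler adapter); the default is the
    built-in star-alignment consensus.
    """
    if engine is None:
        return star_consensus(reads, min_reads)
    if len(reads) < min_reads:
        raise UncorrectableError(f"local assembly needs >= {min_reads} reads")
    return engine(reads)


def structural_patch(
    contig: Contig,
    error: StructuralError,
    consensus: str,
    flank: int = DEFAULT_FLANK,
    anchor_len: int = ANCHOR_LEN,
    max_anchor_divergence: float = 0.25,
) -> Patch:
    """Anchor the local consensus on both flanks of the error and cut the
    replacement sequence between the anchors."""
    lo = max(0, error.start - flank)
    hi = min(len(contig.sequence), error.end + flank)
    left = contig.sequence[lo : lo + anchor_len]
    right = contig.sequence[hi - anchor_len : hi]
    la = edlib.align(left, consensus, task="locations", mode="HW")
    ra = edlib.align(right, consensus, task="locations", mode="HW")
    limit = max_anchor_divergence * anchor_len
    if (not la["locations"] or not ra["locations"]
            or la["editDistance"] > limit or ra["editDistance"] > limit):
        raise UncorrectableError(
            f"{error.kind} at {error.contig_id}:{error.start}: consensus "
            "does not anchor on both flanks"
        )
    l_end = la["locations"][0][1] + 1      # exclusive end of left anchor
    r_start = ra["locations"][-1][0]
    if r_start < l_end:
        raise UncorrectableError(
            f"{error.kind} at {error.contig_id}:{error.start}: anchors "
            "cross in consensus"
        )
    return Patch(
        error.contig_id, lo + anchor_len, hi - anchor_len,
        consensus[l_end:r_start], "local_assembly",
        f"structural:{error.kind}:{error.start}", error.n_support,
    )


def apply_patches(
    contigs: Sequence[Contig], patches: Sequence[Patch]
) -> tuple[list[Contig], list[Patch]]:
    """Apply patches in descending coordinate order per contig.

    Overlapping patches keep the higher-support one; the losers are
    returned as conflicts. Output contigs keep their names.
    """
    by_contig: dict[str, list[Patch]] = {}
    for p in patches:
        if p.replace_end < p.replace_start:
            raise ValueError("patch with negative span")
        by_contig.setdefault(p.contig_id, []).append(p)
    conflicts: list[Patch] = []
    out: list[Contig] = []
    for c in contigs:
        plist = sorted(by_contig.get(c.name, []),
                       key=lambda p: (p.replace_start, -p.support))
        kept: list[Patch] = []
        for p in plist:
            if kept and p.replace_start < kept[-1].replace_end:
                if p.support > kept[-1].support:
                    conflicts.append(kept.pop())
                    kept.append(p)
                else:
                    conflicts.append(p)
                logger.info("overlapping patches at %s:%d", c.name,
                            p.replace_start)
            else:
                kept.append(p)
        seq = c.sequence
        for p in reversed(kept):
            seq = seq[: p.replace_start] + p.replacement + seq[p.replace_end :]
        out.append(Contig(c.name, seq))
    return out, conflicts


def correct_assembly(
    contigs: Sequence[Contig],
    structural: Sequence[StructuralError],
    small: Sequence[SmallScaleError],
    bam_path: str | Path | None,
    flank: int = DEFAULT_FLANK,
    engine: Callable[[Sequence[str]], str] | None = None,
) -> tuple[list[Contig], list[Patch], list[StructuralError]]:
    """One full correction round.

    Returns (corrected contigs, applied patches, uncorrected structural
    errors). Structural correction needs a sorted, indexed BAM; when
    ``bam_path`` is None only small-scale errors are corrected.
    """
    by_name = {c.name: c for c in contigs}
    patches: list[Patch] = []
    uncorrected: list[StructuralError] = []
    if bam_path is not None:
        for err in structural:
            try:
                reads = collect_error_reads(err, bam_path, flank)
                consensus = local_reassemble(reads, engine)
                patches.append(structural_patch(by_name[err.contig_id], err,
                                                consensus, flank))
            except UncorrectableError as exc:
                logger.warning("uncorrectable: %s", exc)
                uncorrected.append(err)
    else:
        uncorrected = list(structural)
    struct_spans = {
        (p.contig_id, p.replace_start, p.replace_end) for p in patches
    }
    small_patches = [
        p for p in small_error_patches(small)
        if not any(cid == p.contig_id and s <= p.replace_start < t
                   for cid, s, t in struct_spans)
    ]
    corrected, conflicts = apply_patches(contigs, patches + small_patches)
    applied = [p for p in patches + small_patches if p not in conflicts]
    return corrected, applied, uncorrected


def write_patch_log(patches: Sequence[Patch], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tstart\tend\tnew_len\tsource\tprovenance\tsupport\n")
        for p in sorted(patches, key=lambda p: (p.contig_id, p.replace_start)):
            fh.write(
                f"{p.contig_id}\t{p.replace_start}\t{p.replace_end}\t"
                f"{len(p.replacement)}\t{p.source}\t{p.provenance}\t{p.support}\n"
            )
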