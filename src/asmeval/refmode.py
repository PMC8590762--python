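"""Reference-based synteny statistics and error-coordinate projection.

When a reference genome is available, contigs are aligned to it (minimap2
asm5 preset) and the aligned blocks yield NA50 (N50 over aligned block
lengths, with the half-total taken from the full assembly length), contig
mapping rate, and reference genome coverage. Error coordinates on contigs
can be projected onto the reference through the matched bases of the
blocks; errors in unaligned regions are flagged unprojectable. Note that
contig-to-reference differences include genetic variants of the sequenced
individual; this module projects coordinates, it does not call errors.
"""
from __future__ import annotations

import bisect
import subprocess
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .alignment import _OP_CODE, require_aligner
from .assembly_stats import Contig, _nx_from_lengths


@dataclass
class AlignedBlock:
    contig_id: str
    contig_start: int
    contig_end: int
    ref_id: str
    ref_start: int
    ref_end: int
    strand: str
    cigar: list[tuple[int, int]]
    is_primary: bool = True

    def contig_span(self) -> int:
        return self.contig_end - self.contig_start


@dataclass
class RefAlignStats:
    na50: int
    contig_mapping_rate: float
    genome_coverage: float
    n_blocks: int


@dataclass
class ProjectedError:
    error: object
    ref_id: str | None
    ref_pos: int | None
    projectable: bool
    approximate: bool = False


def _parse_cigar(cg: str) -> list[tuple[int, int]]:
    out = []
    n = ""
    for ch in cg:
        if ch.isdigit():
            n += ch
        else:
            out.append((_OP_CODE[ch], int(n)))
            n = ""
    return out


def parse_paf_blocks(path: str | Path) -> list[AlignedBlock]:
    blocks = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            tags = dict((t[:4], t[5:]) for t in f[12:] if len(t) > 5)
            cg = tags.get("cg:Z")
            if cg is None:
                raise ValueError(
                    "PAF lacks cg CIGAR tags; run minimap2 with -c"
                )
            if tags.get("tp:A") == "S":
                continue
            blocks.append(
                AlignedBlock(f[0], int(f[2]), int(f[3]), f[5], int(f[7]),
                             int(f[8]), f[4], _parse_cigar(cg))
            )
    return blocks


def map_contigs(
    contigs_fasta: str | Path,
    reference_fasta: str | Path,
    paf_out: str | Path,
    threads: int = 1,
    minimap2: str = "minimap2",
) -> list[AlignedBlock]:
    """Align contigs to the reference (asm5 preset) and parse the blocks."""
    exe = require_aligner(minimap2)
    cmd = [exe, "-cx", "asm5", "--secondary=no", "-t", str(threads),
           str(reference_fasta), str(contigs_fasta)]
    with open(paf_out, "w") as out:
        proc = subprocess.run(cmd, stdout=out, stderr=subprocess.PIPE)
    if proc.returncode != 0:
        raise RuntimeError(
            f"minimap2 exited with {proc.returncode}:\n{proc.stderr.decode()}"
        )
    return parse_paf_blocks(paf_out)


def _union_length(intervals: list[tuple[int, int]]) -> int:
    total = 0
    last = None
    for s, t in sorted(intervals):
        if last is None or s > last:
            total += t - s
            last = t
        elif t > last:
            total += t - last
            last = t
    return total


def ref_stats(
    blocks: Sequence[AlignedBlock],
    contigs: Sequence[Contig],
    ref_lengths: dict[str, int],
) -> RefAlignStats:
    """NA50, contig mapping rate and reference genome coverage."""
    assembly_total = sum(c.length for c in contigs)
    block_lengths = [b.contig_span() for b in blocks]
    na50 = _nx_from_lengths(block_lengths, assembly_total)
    per_contig: dict[str, list[tuple[int, int]]] = {}
    per_ref: dict[str, list[tuple[int, int]]] = {}
    for b in blocks:
        per_contig.setdefault(b.contig_id, []).append(
            (b.contig_start, b.contig_end))
        per_ref.setdefault(b.ref_id, []).append((b.ref_start, b.ref_end))
    mapped = sum(_union_length(iv) for iv in per_contig.values())
    covered = sum(_union_length(iv) for iv in per_ref.values())
    ref_total = sum(ref_lengths.values())
    return RefAlignStats(
        na50=na50,
        contig_mapping_rate=mapped / assembly_total if assembly_total else 0.0,
        genome_coverage=covered / ref_total if ref_total else 0.0,
        n_blocks=len(blocks),
    )


class _BlockIndex:
    """Per-base contig->reference mapping from the match ops of one block.

    Match segments store (contig_lo, contig_hi, ref_at_lo, direction); on
    '-' strand blocks the CIGAR walks the reverse-complemented contig
    against the forward reference, so contig coordinates descend from
    contig_end while reference coordinates ascend.
    """

    def __init__(self, block: AlignedBlock):
        self.block = block
        segs: list[tuple[int, int, int, int]] = []
        rpos = block.ref_start
        if block.strand == "+":
            cpos = block.contig_start
            for op, ln in block.cigar:
                if op in (0, 7, 8):
                    segs.append((cpos, cpos + ln, rpos, 1))
                    cpos += ln
                    rpos += ln
                elif op == 1:
                    cpos += ln
                elif op in (2, 3):
                    rpos += ln
        else:
            cpos = block.contig_end
            for op, ln in block.cigar:
                if op in (0, 7, 8):
                    # contig interval [cpos-ln, cpos) maps reversed
                    segs.append((cpos - ln, cpos, rpos, -1))
                    cpos -= ln
                    rpos += ln
                elif op == 1:
                    cpos -= ln
                elif op in (2, 3):
                    rpos += ln
        self.segs = sorted(segs)
        self.starts = [s[0] for s in self.segs]

    def project(self, pos: int) -> tuple[int, bool] | None:
        """Reference coordinate of a contig position inside this block.

        Positions that fall in unmatched (indel) columns inherit the
        nearest match to the left and are flagged approximate.
        """
        if not (self.block.contig_start <= pos < self.block.contig_end):
            return None
        i = bisect.bisect_right(self.starts, pos) - 1
        if i < 0:
            i = 0
        lo, hi, r0, d = self.segs[i]
        if lo <= pos < hi:
            if d == 1:
                return r0 + (pos - lo), False
            return r0 + (hi - 1 - pos), False
        # in an indel gap: use the nearest matched column to the left
        anchor = hi - 1 if pos >= hi else lo
        if d == 1:
            return r0 + (anchor - lo), True
        return r0 + (hi - 1 - anchor), True


def project_to_reference(errors: Sequence, blocks: Sequence[AlignedBlock]) -> list[ProjectedError]:
    """Project contig-coordinate errors (anything with .contig_id and
    .start or .pos) onto the reference through aligned blocks."""
    indexes: dict[str, list[_BlockIndex]] = {}
    for b in blocks:
        indexes.setdefault(b.contig_id, []).append(_BlockIndex(b))
    out = []
    for e in errors:
        pos = getattr(e, "start", None)
        if pos is None:
            pos = e.pos
        hit = None
        for idx in indexes.get(e.contig_id, ()):
            res = idx.project(pos)
            if res is not None:
                hit = (idx.block.ref_id, res[0], res[1])
                if not res[1]:
                    break
        if hit is None:
            out.append(ProjectedError(e, None, None, False))
        else:
            out.append(ProjectedError(e, hit[0], hit[1], True, hit[2]))
    return out


def dotplot_data(blocks: Sequence[AlignedBlock]) -> pd.DataFrame:
    """Plot-ready table of aligned segment pairs sorted by reference."""
    rows = [
        {
            "ref_id": b.ref_id,
            "ref_start": b.ref_start,
            "ref_end": b.ref_end,
            "contig_id": b.contig_id,
            "contig_start": b.contig_start,
            "contig_end": b.contig_end,
            "strand": b.strand,
        }
        for b in blocks
    ]
    df = pd.DataFrame(
        rows, columns=["ref_id", "ref_start", "ref_end", "contig_id",
                       "contig_start", "contig_end", "strand"]
    )
    if len(df):
        df = df.sort_values(["ref_id", "ref_start"]).reset_index(drop=True)
    return df
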