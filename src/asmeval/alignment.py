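"""Read-to-contig alignment: minimap2 invocation, parsing, and statistics.

Alignments are produced by an external minimap2 (long-read presets selected
by datatype) or supplied precomputed as SAM/BAM or PAF-with-CIGAR. All
coordinates are 0-based half-open; read coordinates are always on the
forward-oriented read.
"""
from __future__ import annotations

import shutil
import subprocess
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pysam

CIGAR_OPS = "MIDNSHP=X"
_OP_CODE = {c: i for i, c in enumerate(CIGAR_OPS)}
# which ops consume reference / read
_REF_OPS = {0, 2, 3, 7, 8}
_READ_OPS = {0, 1, 4, 7, 8}

PRESETS = {"clr": "map-pb", "hifi": "map-hifi", "nano": "map-ont"}


class AlignerNotFoundError(RuntimeError):
    pass


class AlignerFailedError(RuntimeError):
    pass


@dataclass
class AlignmentSegment:
    """One aligned block of a read on a contig.

    ``cigar`` is a list of (op_code, length) pairs with SAM numeric op codes
    (see :data:`CIGAR_OPS`). ``read_start``/``read_end`` are on the forward
    orientation of the read regardless of strand.
    """

    read_id: str
    contig_id: str
    contig_start: int
    contig_end: int
    read_start: int
    read_end: int
    strand: str
    mapq: int
    is_primary: bool
    is_supplementary: bool
    cigar: list[tuple[int, int]] = field(default_factory=list)
    read_length: int = 0
    read_sequence: str | None = None  # aligned orientation, as stored in SAM

    @property
    def cigar_string(self) -> str:
        return "".join(f"{ln}{CIGAR_OPS[op]}" for op, ln in self.cigar)

    def contig_span(self) -> int:
        return self.contig_end - self.contig_start


@dataclass
class ReadAlignStats:
    mapping_rate: float
    splitting_rate: float
    mean_depth: float
    n_reads: int
    n_mapped: int
    n_split: int


def require_aligner(minimap2: str = "minimap2") -> str:
    exe = shutil.which(minimap2)
    if exe is None:
        raise AlignerNotFoundError(
            f"{minimap2!r} not found on PATH; install minimap2 "
            "(e.g. 'conda install -c bioconda minimap2') or supply "
            "precomputed alignments"
        )
    return exe


def minimap2_command(
    reads: str | Path,
    contigs: str | Path,
    datatype: str,
    threads: int = 1,
    minimap2: str = "minimap2",
) -> list[str]:
    if datatype not in PRESETS:
        raise ValueError(f"datatype must be one of {sorted(PRESETS)}")
    exe = require_aligner(minimap2)
    return [
        exe,
        "-a",
        "-x",
        PRESETS[datatype],
        "--secondary=no",
        "-t",
        str(threads),
        str(contigs),
        str(reads),
    ]


def align_reads(
    reads: str | Path,
    contigs: str | Path,
    datatype: str,
    out_bam: str | Path,
    threads: int = 1,
    minimap2: str = "minimap2",
) -> Path:
    """Align reads to contigs and write a coordinate-sorted BAM with CIGARs."""
    cmd = minimap2_command(reads, contigs, datatype, threads, minimap2)
    out_bam = Path(out_bam)
    mm = subprocess.Popen(cmd, stdout=subprocess.PIPE, stderr=subprocess.PIPE)
    sort = subprocess.Popen(
        ["samtools", "sort", "-@", str(threads), "-o", str(out_bam), "-"],
        stdin=mm.stdout,
        stderr=subprocess.PIPE,
    )
    mm.stdout.close()
    _, sort_err = sort.communicate()
    _, mm_err = mm.communicate()
    if mm.returncode != 0:
        raise AlignerFailedError(
            f"minimap2 exited with {mm.returncode}:\n{mm_err.decode()}"
        )
    if sort.returncode != 0:
        raise AlignerFailedError(
            f"samtools sort exited with {sort.returncode}:\n{sort_err.decode()}"
        )
    subprocess.run(["samtools", "index", str(out_bam)], check=False)
    return out_bam


@contextmanager
def stream_minimap2(
    reads: str | Path,
    contigs: str | Path,
    datatype: str,
    threads: int = 1,
    minimap2: str = "minimap2",
):
    """Yield a pysam.AlignmentFile reading SAM straight from minimap2 stdout."""
    cmd = minimap2_command(reads, contigs, datatype, threads, minimap2)
    proc = subprocess.Popen(cmd, stdout=subprocess.PIPE, stderr=subprocess.PIPE)
    try:
        with pysam.AlignmentFile(proc.stdout, "r") as af:
            yield af
    finally:
        proc.stdout.close()
        err = proc.stderr.read()
        proc.stderr.close()
        proc.wait()
        if proc.returncode not in (0, None):
            raise AlignerFailedError(
                f"minimap2 exited with {proc.returncode}:\n{err.decode()}"
            )


def _clip_lengths(cigar: list[tuple[int, int]]) -> tuple[int, int]:
    lead = 0
    for op, ln in cigar:
        if op in (4, 5):
            lead += ln
        else:
            break
    tail = 0
    for op, ln in reversed(cigar):
        if op in (4, 5):
            tail += ln
        else:
            break
    return lead, tail


def segment_from_pysam(rec: pysam.AlignedSegment) -> AlignmentSegment:
    cigar = list(rec.cigartuples or [])
    read_len = sum(ln for op, ln in cigar if op in _READ_OPS or op == 5)
    lead, tail = _clip_lengths(cigar)
    if rec.is_reverse:
        read_start, read_end = tail, read_len - lead
        strand = "-"
    else:
        read_start, read_end = lead, read_len - tail
        strand = "+"
    return AlignmentSegment(
        read_id=rec.query_name,
        contig_id=rec.reference_name,
        contig_start=rec.reference_start,
        contig_end=rec.reference_end,
        read_start=read_start,
        read_end=read_end,
        strand=strand,
        mapq=rec.mapping_quality,
        is_primary=not (rec.is_secondary or rec.is_supplementary),
        is_supplementary=rec.is_supplementary,
        cigar=cigar,
        read_length=read_len,
        read_sequence=rec.query_sequence,
    )


def _parse_paf_line(line: str) -> AlignmentSegment:
    f = line.rstrip("\n").split("\t")
    tags = dict((t[:4], t[5:]) for t in f[12:] if len(t) > 5)
    cg = tags.get("cg:Z")
    if cg is None:
        raise ValueError(
            "PAF record lacks a cg CIGAR tag; rerun minimap2 with -c to "
            "emit base-level alignments"
        )
    cigar = []
    n = ""
    for ch in cg:
        if ch.isdigit():
            n += ch
        else:
            cigar.append((_OP_CODE[ch], int(n)))
            n = ""
    tp = tags.get("tp:A", "P")
    return AlignmentSegment(
        read_id=f[0],
        contig_id=f[5],
        contig_start=int(f[7]),
        contig_end=int(f[8]),
        read_start=int(f[2]),
        read_end=int(f[3]),
        strand=f[4],
        mapq=int(f[11]),
        is_primary=tp != "S",
        is_supplementary=False,
        cigar=cigar,
        read_length=int(f[1]),
    )


def parse_alignments(
    path: str | Path, include_secondary: bool = False
) -> Iterator[AlignmentSegment]:
    """Stream alignment segments from SAM/BAM or PAF (cg tag required).

    Unmapped records are skipped; secondary alignments are excluded unless
    ``include_secondary`` (they never enter error calling either way).
    """
    path = Path(path)
    if path.suffix.lower() == ".paf":
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                seg = _parse_paf_line(line)
                if seg.is_primary or include_secondary:
                    yield seg
        return
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for rec in af:
            if rec.is_unmapped:
                continue
            if rec.is_secondary and not include_secondary:
                continue
            yield segment_from_pysam(rec)


def alignment_stats(
    segments: Iterable[AlignmentSegment],
    n_reads: int,
    total_contig_bases: int,
) -> ReadAlignStats:
    """Read mapping rate, splitting rate and mean alignment depth.

    ``n_reads`` is the total read count (mapped or not). Depth is aligned
    contig span divided by assembly size; a read is split if it has more
    than one (primary+supplementary) segment, counted once.
    """
    import warnings

    seg_count: dict[str, int] = {}
    aligned_bases = 0
    for seg in segments:
        if not (seg.is_primary or seg.is_supplementary):
            continue
        seg_count[seg.read_id] = seg_count.get(seg.read_id, 0) + 1
        aligned_bases += seg.contig_span()
    n_mapped = len(seg_count)
    n_split = sum(1 for v in seg_count.values() if v > 1)
    if n_reads == 0:
        warnings.warn("no input reads; rates reported as 0")
        return ReadAlignStats(0.0, 0.0, 0.0, 0, 0, 0)
    return ReadAlignStats(
        mapping_rate=n_mapped / n_reads,
        splitting_rate=(n_split / n_mapped) if n_mapped else 0.0,
        mean_depth=aligned_bases / total_contig_bases if total_contig_bases else 0.0,
        n_reads=n_reads,
        n_mapped=n_mapped,
        n_split=n_split,
    )


def depth_profile(segments: Iterable[AlignmentSegment], contig_length: int) -> np.ndarray:
    """Per-position coverage (contig span) from primary+supplementary segments."""
    diff = np.zeros(contig_length + 1, dtype=np.int32)
    for seg in segments:
        if not (seg.is_primary or seg.is_supplementary):
            continue
        diff[seg.contig_start] += 1
        diff[seg.contig_end] -= 1
    return np.cumsum(diff[:-1]).astype(np.int32)
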