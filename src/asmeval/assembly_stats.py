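"""Contig loading and continuity metrics.

Continuity is summarised by the number of contigs, total bases, the two
longest contig lengths and N50 (the length of the shortest contig at which
the descending cumulative length reaches half of the assembly total; the
half-total boundary is inclusive).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pysam


@dataclass
class Contig:
    """A single assembled sequence; the sequence is stored uppercase."""

    name: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class AssemblyStats:
    n_contigs: int
    total_bases: int
    longest: int
    second_longest: int
    n50: int
    min_contig_filter: int = 0


class DuplicateContigError(ValueError):
    pass


def read_fasta(path: str | Path) -> list[Contig]:
    """Read a (possibly gzipped) FASTA file into a list of contigs.

    Record order is preserved, lowercase bases are uppercased and duplicate
    record names raise :class:`DuplicateContigError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    contigs: list[Contig] = []
    seen: set[str] = set()
    with pysam.FastxFile(str(path)) as fx:
        for rec in fx:
            if rec.name in seen:
                raise DuplicateContigError(
                    f"duplicate sequence name {rec.name!r} in {path}"
                )
            seen.add(rec.name)
            contigs.append(Contig(rec.name, (rec.sequence or "").upper()))
    return contigs


def write_fasta(contigs: Iterable[Contig], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            fh.write(f">{c.name}\n")
            for i in range(0, len(c.sequence), width):
                fh.write(c.sequence[i : i + width] + "\n")


def n50_from_lengths(lengths: Sequence[int]) -> int:
    """N50 of a set of lengths with an inclusive half-total boundary."""
    return _nx_from_lengths(lengths, sum(lengths))


def _nx_from_lengths(lengths: Sequence[int], total: int, frac: float = 0.5) -> int:
    if not lengths or total <= 0:
        return 0
    half = frac * total
    acc = 0
    for ln in sorted(lengths, reverse=True):
        acc += ln
        if acc >= half:
            return ln
    return 0


def contig_stats(contigs: Sequence[Contig], min_len: int = 0) -> AssemblyStats:
    """Continuity statistics over contigs of length >= ``min_len``."""
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    lengths = sorted((c.length for c in contigs if c.length >= min_len), reverse=True)
    if not lengths:
        if contigs:
            warnings.warn("all contigs removed by the length filter")
        return AssemblyStats(0, 0, 0, 0, 0, min_len)
    return AssemblyStats(
        n_contigs=len(lengths),
        total_bases=sum(lengths),
        longest=lengths[0],
        second_longest=lengths[1] if len(lengths) > 1 else 0,
        n50=n50_from_lengths(lengths),
        min_contig_filter=min_len,
    )
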