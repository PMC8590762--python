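"""Assembly quality (QV) estimation and evaluation report output.

The total erroneous bases N_Err = N_Exp + N_Col + N_Her + N_Small + n_Inv,
where the first four terms are bases affected by expansions, collapses,
haplotype switches and small-scale errors, and each inversion contributes
a count of one. The per-base error rate is E = N_Err / N_asm and the
Phred-scaled quality is QV = -10 log10 E. An error-free assembly is
reported as a lower bound using a pseudo-count of 0.5 errors.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

from .alignment import ReadAlignStats
from .assembly_stats import AssemblyStats
from .smallscale import (BASE_SUBSTITUTION, SMALL_COLLAPSE, SMALL_EXPANSION,
                         SmallScaleError)
from .structural import (COLLAPSE, EXPANSION, HAPLOTYPE_SWITCH, INVERSION,
                         StructuralError)

REPORT_VERSION = "asmeval-report-1"


@dataclass
class QVReport:
    n_exp: int          # bases in expansions
    n_col: int          # bases in collapses
    n_her: int          # bases in haplotype switches (larger affected side)
    n_small: int        # bases in small-scale errors
    n_inv: int          # inversion count (each contributes 1 to N_Err)
    n_err: int
    n_asm: int
    error_rate: float
    qv: float
    qv_is_lower_bound: bool = False

    def qv_string(self) -> str:
        return f"{'>=' if self.qv_is_lower_bound else ''}{self.qv:.2f}"


def compute_qv(
    structural: Sequence[StructuralError],
    small: Sequence[SmallScaleError],
    n_asm: int,
) -> QVReport:
    if n_asm <= 0:
        raise ValueError("N_asm must be positive")
    n_exp = sum(e.size for e in structural if e.kind == EXPANSION)
    n_col = sum(e.size for e in structural if e.kind == COLLAPSE)
    n_her = sum(
        max(e.expansion_size or 0, e.collapse_size or 0, e.size)
        for e in structural
        if e.kind == HAPLOTYPE_SWITCH
    )
    n_inv = sum(1 for e in structural if e.kind == INVERSION)
    n_small = sum(e.affected_bases for e in small)
    n_err = n_exp + n_col + n_her + n_small + n_inv
    lower_bound = n_err == 0
    eff_err = n_err if n_err else 0.5
    e_rate = eff_err / n_asm
    qv = -10.0 * math.log10(e_rate)
    return QVReport(n_exp, n_col, n_her, n_small, n_inv, n_err, n_asm,
                    n_err / n_asm, qv, lower_bound)


def write_structural_bed(errors: Sequence[StructuralError], path: str | Path) -> None:
    """BED6+ : contig, start, end, kind, n_support, strand(.), ratio, size, mapq."""
    with open(path, "w") as fh:
        for e in errors:
            fh.write(
                f"{e.contig_id}\t{e.start}\t{e.end}\t{e.kind}\t{e.n_support}\t."
                f"\t{e.support_ratio:.3f}\t{e.size}\t{e.mean_mapq:.1f}\n"
            )


def read_structural_bed(path: str | Path) -> list[StructuralError]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            out.append(
                StructuralError(f[3], f[0], int(f[1]), int(f[2]), int(f[7]),
                                int(f[4]), 0.0, float(f[6]), float(f[8]))
            )
    return out


def write_small_bed(errors: Sequence[SmallScaleError], path: str | Path) -> None:
    """BED6+ : contig, start, end, kind, n_supp/n_reads, strand(.), p, alleles."""
    with open(path, "w") as fh:
        for e in errors:
            end = e.pos + (e.size if e.kind == SMALL_EXPANSION else 1)
            fh.write(
                f"{e.contig_id}\t{e.pos}\t{end}\t{e.kind}\t{e.n_supp}/{e.n_reads}"
                f"\t.\t{e.p_value:.3e}\t{e.contig_allele}>{e.read_allele}\n"
            )


def read_small_bed(path: str | Path) -> list[SmallScaleError]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            n_supp, n_reads = (int(x) for x in f[4].split("/"))
            contig_allele, _, read_allele = f[7].partition(">")
            kind = f[3]
            size = int(f[2]) - int(f[1]) if kind == SMALL_EXPANSION else max(
                len(read_allele), 1)
            out.append(
                SmallScaleError(kind, f[0], int(f[1]), size, contig_allele,
                                read_allele, n_reads, n_supp, float(f[6]))
            )
    return out


def summary_lines(
    stats: AssemblyStats,
    align_stats: ReadAlignStats | None,
    structural: Sequence[StructuralError],
    small: Sequence[SmallScaleError],
    qv: QVReport,
) -> list[str]:
    per_mbp = (
        len(small) / (stats.total_bases / 1e6) if stats.total_bases else 0.0
    )
    by_kind = {k: 0 for k in (EXPANSION, COLLAPSE, HAPLOTYPE_SWITCH, INVERSION)}
    for e in structural:
        by_kind[e.kind] = by_kind.get(e.kind, 0) + 1
    small_by_kind = {k: 0 for k in (BASE_SUBSTITUTION, SMALL_COLLAPSE, SMALL_EXPANSION)}
    for e in small:
        small_by_kind[e.kind] = small_by_kind.get(e.kind, 0) + 1
    lines = [
        f"report_version: {REPORT_VERSION}",
        f"n_contigs: {stats.n_contigs}",
        f"total_bases: {stats.total_bases}",
        f"longest_contig: {stats.longest}",
        f"second_longest_contig: {stats.second_longest}",
        f"n50: {stats.n50}",
    ]
    if align_stats is not None:
        lines += [
            f"mapping_rate: {align_stats.mapping_rate:.4f}",
            f"splitting_rate: {align_stats.splitting_rate:.4f}",
            f"mean_depth: {align_stats.mean_depth:.2f}",
        ]
    lines += [
        f"structural_errors: {len(structural)}",
        f"structural_expansion: {by_kind[EXPANSION]}",
        f"structural_collapse: {by_kind[COLLAPSE]}",
        f"structural_haplotype_switch: {by_kind[HAPLOTYPE_SWITCH]}",
        f"structural_inversion: {by_kind[INVERSION]}",
        f"small_scale_errors: {len(small)}",
        f"small_base_substitution: {small_by_kind[BASE_SUBSTITUTION]}",
        f"small_collapse: {small_by_kind[SMALL_COLLAPSE]}",
        f"small_expansion: {small_by_kind[SMALL_EXPANSION]}",
        f"small_scale_per_mbp: {per_mbp:.2f}",
        f"n_err_bases: {qv.n_err}",
        f"error_rate: {qv.error_rate:.3e}",
        f"qv: {qv.qv_string()}",
    ]
    return lines


def write_report(
    stats: AssemblyStats,
    align_stats: ReadAlignStats | None,
    structural: Sequence[StructuralError],
    small: Sequence[SmallScaleError],
    qv: QVReport,
    out_dir: str | Path,
) -> Path:
    """Write summary.txt, summary.json and the two BED files; returns out_dir."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lines = summary_lines(stats, align_stats, structural, small, qv)
    (out_dir / "summary.txt").write_text("\n".join(lines) + "\n")
    payload = {
        "assembly": asdict(stats),
        "alignment": asdict(align_stats) if align_stats else None,
        "qv": asdict(qv),
        "n_structural": len(structural),
        "n_small": len(small),
    }
    (out_dir / "summary.json").write_text(json.dumps(payload, indent=2) + "\n")
    write_structural_bed(structural, out_dir / "structural_errors.bed")
    write_small_bed(small, out_dir / "small_scale_errors.bed")
    return out_dir
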