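"""Structural-variant screen: control subtraction and gene overlap.

Case SV calls are screened by removing any call matched in a control (same
type, reciprocal overlap above a threshold; breakend records by breakpoint
proximity), then intersecting survivors with gene intervals and the
candidate laterality-gene list.  Intervals are 0-based half-open (BED
convention) and converted at no point — the variant table's 1-based world
never mixes with this module's coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

SV_TYPES = ("DEL", "DUP", "INV", "BND")
DEFAULT_RECIPROCAL_OVERLAP = 0.5
BND_PROXIMITY_BP = 500


@dataclass(frozen=True)
class SVCall:
    subject_id: str
    chrom: str
    start: int  # 0-based
    end: int    # half-open
    sv_type: str
    quality_pass: bool = True

    def __post_init__(self):
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown sv_type {self.sv_type!r}")
        if self.sv_type != "BND" and not self.start < self.end:
            raise ValueError(f"degenerate interval in {self}")


@dataclass(frozen=True)
class GeneInterval:
    gene: str
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"degenerate gene interval {self}")


def read_sv_calls(path: str | Path) -> list[SVCall]:
    """Read SV calls from a BED-like TSV.

    Columns: subject_id, chrom, start, end, sv_type, quality_pass.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "subject_id": str})
    return [
        SVCall(r.subject_id, r.chrom, int(r.start), int(r.end), r.sv_type,
               bool(r.quality_pass))
        for r in df.itertuples()
    ]


def read_gene_bed(path: str | Path) -> list[GeneInterval]:
    """Read gene intervals from BED (chrom, start, end, gene)."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "gene"], dtype={"chrom": str})
    return [GeneInterval(r.gene, r.chrom, int(r.start), int(r.end)) for r in df.itertuples()]


def reciprocal_overlap(a_start, a_end, b_start, b_end) -> float:
    """min(overlap/len_a, overlap/len_b); 0 when disjoint."""
    ov = min(a_end, b_end) - max(a_start, b_start)
    if ov <= 0:
        return 0.0
    return min(ov / (a_end - a_start), ov / (b_end - b_start))


def quality_filter_svs(svs: list[SVCall]) -> list[SVCall]:
    """Keep only calls passing the upstream genotyper's quality filter."""
    return [sv for sv in svs if sv.quality_pass]


def subtract_control_svs(
    case_svs: list[SVCall],
    control_svs: list[SVCall],
    min_reciprocal_overlap: float = DEFAULT_RECIPROCAL_OVERLAP,
    bnd_proximity: int = BND_PROXIMITY_BP,
) -> list[SVCall]:
    """Remove case SVs that are present in any control.

    Presence means a control call of the same type on the same chromosome
    with reciprocal overlap >= the threshold; BND records match by
    breakpoint within ``bnd_proximity`` bp instead.  Pure subset operation.
    """
    by_type: dict[tuple[str, str], list[SVCall]] = {}
    for sv in control_svs:
        by_type.setdefault((sv.chrom, sv.sv_type), []).append(sv)

    kept = []
    for sv in case_svs:
        ctrls = by_type.get((sv.chrom, sv.sv_type), [])
        if sv.sv_type == "BND":
            present = any(abs(sv.start - c.start) <= bnd_proximity for c in ctrls)
        else:
            present = any(
                reciprocal_overlap(sv.start, sv.end, c.start, c.end)
                >= min_reciprocal_overlap
                for c in ctrls
            )
        if not present:
            kept.append(sv)
    return kept


def sv_gene_hits(
    svs: list[SVCall],
    gene_intervals: list[GeneInterval],
    candidate_genes=(),
) -> pd.DataFrame:
    """Genes overlapped (>=1 bp) by each subject's retained SVs.

    BND records are excluded from gene overlap.  Returns one row per
    (subject, gene) with a flag for candidate-list membership.
    """
    trees: dict[str, IntervalTree] = {}
    for gi in gene_intervals:
        trees.setdefault(gi.chrom, IntervalTree()).addi(gi.start, gi.end, gi.gene)
    wanted = set(candidate_genes)

    hits: dict[str, set[str]] = {}
    for sv in svs:
        if sv.sv_type == "BND":
            continue
        tree = trees.get(sv.chrom)
        if tree is None:
            continue
        for iv in tree.overlap(sv.start, sv.end):
            hits.setdefault(sv.subject_id, set()).add(iv.data)

    rows = [
        {"subject_id": sid, "gene": g, "in_candidate_list": g in wanted}
        for sid in sorted(hits)
        for g in sorted(hits[sid])
    ]
    return pd.DataFrame(rows, columns=["subject_id", "gene", "in_candidate_list"])


def mean_genes_per_subject(hit_table: pd.DataFrame, subject_ids) -> float:
    """Average number of SV-affected genes per subject (zeros included)."""
    subject_ids = list(subject_ids)
    if not subject_ids:
        return 0.0
    counts = hit_table.groupby("subject_id")["gene"].nunique() if len(hit_table) else pd.Series(dtype=int)
    return float(sum(counts.get(s, 0) for s in subject_ids) / len(subject_ids))
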