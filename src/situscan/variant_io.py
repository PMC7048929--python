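"""Reading multi-sample variant data and site-level quality control.

Variants are held in a pandas DataFrame with one row per (site, alt allele):
multi-allelic sites are decomposed before anything downstream sees them.
Core columns are ``chrom, pos, ref, alt, vqsr_label, quality_depth,
call_rate`` followed by one genotype column per subject (named by subject
id) holding integer codes from :data:`GT_HOM_REF` etc.  Coordinates are
1-based VCF convention throughout.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

# genotype codes
GT_HOM_REF = 0
GT_HET = 1
GT_HOM_ALT = 2
GT_MISSING = -1

CORE_COLUMNS = ["chrom", "pos", "ref", "alt", "vqsr_label", "quality_depth", "call_rate"]

SUBJECT_GROUPS = ("si_pcd", "si_nonpcd", "control")

#: matches GATK tranche labels such as VQSRTrancheSNP99.90to100.00
_TRANCHE_RE = re.compile(r"(\d+(?:\.\d+)?)to(\d+(?:\.\d+)?)")


def variant_key(chrom, pos, ref, alt) -> str:
    return f"{chrom}:{pos}:{ref}:{alt}"


def add_key(variants: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with a ``key`` column (chrom:pos:ref:alt)."""
    out = variants.copy()
    out["key"] = [
        variant_key(c, p, r, a)
        for c, p, r, a in zip(out["chrom"], out["pos"], out["ref"], out["alt"])
    ]
    return out


def genotype_columns(variants: pd.DataFrame) -> list[str]:
    """Subject genotype columns, in subject order."""
    skip = set(CORE_COLUMNS) | {"key"}
    return [c for c in variants.columns if c not in skip]


def read_subject_meta(meta_path: str | Path) -> pd.DataFrame:
    """Read the subject metadata TSV.

    Expected columns: subject_id, group, sex, ehi, forced_switch,
    daily_wet_cough, chd.
    """
    meta = pd.read_csv(meta_path, sep="\t", dtype={"subject_id": str})
    required = {"subject_id", "group", "sex", "ehi", "forced_switch", "daily_wet_cough", "chd"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata file {meta_path} lacks columns: {sorted(missing)}")
    if meta["subject_id"].duplicated().any():
        dupes = meta.loc[meta["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject ids in metadata: {dupes}")
    bad_group = set(meta["group"]) - set(SUBJECT_GROUPS)
    if bad_group:
        raise ValueError(f"unknown subject groups: {sorted(bad_group)}")
    meta["forced_switch"] = meta["forced_switch"].astype(bool)
    meta["chd"] = meta["chd"].astype(bool)
    return meta


def _decompose_genotype(gt_alleles: tuple[int, int] | None, focal_index: int) -> int:
    """Map a diploid allele-index pair onto the focal alt of a decomposed site.

    Alleles equal to the focal alt count as alt; any other allele (reference
    or a different alt) counts as reference for this record.
    """
    if gt_alleles is None:
        return GT_MISSING
    a, b = gt_alleles
    if a < 0 or b < 0:
        return GT_MISSING
    n_alt = int(a == focal_index) + int(b == focal_index)
    return (GT_HOM_REF, GT_HET, GT_HOM_ALT)[n_alt]


def read_cohort(vcf_path: str | Path, meta_path: str | Path):
    """Read a multi-sample VCF plus subject metadata.

    Returns ``(variants, subjects)``: the decomposed variant table and the
    metadata table, with genotype columns aligned to subject-table order.
    Every VCF sample must be present in the metadata.
    """
    from cyvcf2 import VCF

    subjects = read_subject_meta(meta_path)
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    known = set(subjects["subject_id"])
    for s in samples:
        if s not in known:
            raise ValueError(f"sample {s!r} in VCF is absent from metadata")

    rows = []
    gt_rows = []
    for rec in vcf:
        qd = rec.INFO.get("QD")
        filt = rec.FILTER if rec.FILTER is not None else "PASS"
        pairs = [tuple(g[:2]) if len(g) >= 2 else None for g in rec.genotypes]
        for ai, alt in enumerate(rec.ALT, start=1):
            gts = np.array([_decompose_genotype(p, ai) for p in pairs], dtype=np.int8)
            call_rate = float((gts != GT_MISSING).sum()) / len(gts) if len(gts) else 0.0
            rows.append(
                {
                    "chrom": rec.CHROM,
                    "pos": rec.POS,
                    "ref": rec.REF,
                    "alt": alt,
                    "vqsr_label": filt,
                    "quality_depth": float(qd) if qd is not None else np.nan,
                    "call_rate": call_rate,
                }
            )
            gt_rows.append(gts)

    variants = pd.DataFrame(rows, columns=CORE_COLUMNS)
    gt = pd.DataFrame(
        np.vstack(gt_rows) if gt_rows else np.empty((0, len(samples)), dtype=np.int8),
        columns=samples,
    )
    # align genotype columns to subject-table order (samples may be a subset order)
    ordered = [s for s in subjects["subject_id"] if s in samples]
    variants = pd.concat([variants, gt[ordered]], axis=1)
    return variants, subjects


def compute_call_rate(variants: pd.DataFrame) -> pd.Series:
    """Recompute per-record call rate from the genotype columns."""
    cols = genotype_columns(variants)
    gt = variants[cols].to_numpy()
    return pd.Series((gt != GT_MISSING).sum(axis=1) / max(len(cols), 1), index=variants.index)


def tranche_lower_bound(vqsr_label: str) -> float | None:
    """Lower bound of a VQSR tranche label, or None for PASS/'.'/unparseable.

    GATK writes labels like ``VQSRTrancheSNP99.90to100.00``; any FILTER value
    other than PASS/'.' is treated as a tranche label.
    """
    if vqsr_label in ("PASS", ".", "", None):
        return None
    m = _TRANCHE_RE.search(vqsr_label)
    if m is None:
        return None
    return float(m.group(1))


def site_quality_filter(
    variants: pd.DataFrame,
    tranche_cut: float = 99.9,
    qd_min: float = 9.0,
    call_rate_min: float = 0.8,
) -> pd.DataFrame:
    """Site-level QC: drop low-confidence tranches and low-quality records.

    Removes records whose VQSR tranche lower bound is >= ``tranche_cut``
    (PASS always retained), whose quality depth is <= ``qd_min``, or whose
    call rate is <= ``call_rate_min``; boundaries are closed on the removed
    side, as in GATK-style tranche filtering.  Records missing a quality
    depth are kept with a warning.  Order is preserved.
    """
    keep = np.ones(len(variants), dtype=bool)
    for i, label in enumerate(variants["vqsr_label"]):
        lb = tranche_lower_bound(label)
        if lb is not None and lb >= tranche_cut:
            keep[i] = False

    qd = variants["quality_depth"].to_numpy(dtype=float)
    missing_qd = np.isnan(qd)
    if missing_qd.any():
        log.warning("%d records lack a quality_depth value; kept", int(missing_qd.sum()))
    keep &= missing_qd | (qd > qd_min)

    cr = variants["call_rate"].to_numpy(dtype=float)
    missing_cr = np.isnan(cr)
    if missing_cr.any():
        log.warning("%d records lack a call_rate value; kept", int(missing_cr.sum()))
    keep &= missing_cr | (cr > call_rate_min)

    return variants.loc[keep]


def normalize_variant(
    pos: int,
    ref: str,
    alt: str,
    reference_context: tuple[int, str] | None = None,
):
    """Normalize one allele pair to its minimal, left-most representation.

    Shared trailing then leading bases are trimmed, keeping one anchor base
    for indels; given ``reference_context`` as ``(window_start_pos,
    sequence)`` (1-based start), indels are additionally left-aligned to the
    smallest position admitting the same allele change.  Idempotent.

    Returns ``(pos, ref, alt)``.
    """
    if ref == alt:
        raise ValueError(f"ref == alt at pos {pos}: {ref!r}")
    if not ref or not alt:
        raise ValueError(f"empty allele at pos {pos}")

    if reference_context is not None:
        win_start, seq = reference_context
        offset = pos - win_start
        if offset < 0 or offset + len(ref) > len(seq):
            raise ValueError(f"record at pos {pos} outside reference context window")
        if seq[offset : offset + len(ref)] != ref:
            raise ValueError(
                f"ref allele {ref!r} at pos {pos} inconsistent with reference context"
            )

    # trim shared trailing bases (keep at least one base each)
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # left-align indels within the reference context before trimming prefixes
    if reference_context is not None and len(ref) != len(alt):
        win_start, seq = reference_context
        while (
            ref[-1] == alt[-1]
            and pos - win_start - 1 >= 0
        ):
            prev = seq[pos - win_start - 1]
            ref, alt = prev + ref[:-1], prev + alt[:-1]
            pos -= 1
            # re-trim any trailing match created by the shift
            while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
                ref, alt = ref[:-1], alt[:-1]
    # trim shared leading bases, keeping one anchor base for indels
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def normalize_table(variants: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`normalize_variant` (no reference context) to every row."""
    out = variants.copy()
    norm = [normalize_variant(p, r, a) for p, r, a in zip(out["pos"], out["ref"], out["alt"])]
    out["pos"] = [n[0] for n in norm]
    out["ref"] = [n[1] for n in norm]
    out["alt"] = [n[2] for n in norm]
    return out


def write_variant_table(variants: pd.DataFrame, path: str | Path) -> None:
    """Serialize the internal table to TSV for audit."""
    variants.to_csv(path, sep="\t", index=False)


def read_variant_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return df
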