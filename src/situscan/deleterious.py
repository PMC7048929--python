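"""Annotation-level deleteriousness selection.

Three successive pure-subset filters, applied after site QC:

1. impact selection — keep coding MEDIUM/HIGH and non-coding HIGH records;
2. the PolyPhen–SIFT cross-rules with synonymous removal;
3. model-specific population allele-frequency thresholds (recessive 0.005,
   dominant 5e-5).

Annotations travel as extra columns on the variant table: ``gene,
consequence, impact, coding, polyphen, sift, af_<db>..., clinvar, aac``.
The consequence→impact mapping follows the Gemini/VEP severity convention
and ships as ``data/impact_map.tsv`` so it can be audited or overridden.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

AF_DATABASES = ("gnomad", "esp", "kg1000", "exac")
AF_COLUMNS = tuple(f"af_{db}" for db in AF_DATABASES)

IMPACTS = ("HIGH", "MEDIUM", "LOW", "MODIFIER")

RECESSIVE_MAX_AF = 0.005
DOMINANT_MAX_AF = 5e-5

ANNOTATION_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene", "consequence", "impact", "coding",
    "polyphen", "sift", *AF_COLUMNS, "clinvar", "aac",
]


@dataclass(frozen=True)
class FilterModelConfig:
    """Frequency-filter settings for one inheritance model."""

    model: str  # "recessive" or "dominant"
    max_af: float = field(default=None)  # type: ignore[assignment]
    af_databases: tuple[str, ...] = AF_DATABASES

    def __post_init__(self):
        if self.model not in ("recessive", "dominant"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.max_af is None:
            object.__setattr__(
                self, "max_af",
                RECESSIVE_MAX_AF if self.model == "recessive" else DOMINANT_MAX_AF,
            )
        if not (0 < self.max_af < 1):
            raise ValueError(f"max_af must be in (0,1), got {self.max_af}")


def load_impact_map(path: str | Path | None = None) -> pd.DataFrame:
    """Load the consequence→(impact, coding) mapping table."""
    if path is None:
        with resources.files("situscan").joinpath("data/impact_map.tsv").open() as fh:
            table = pd.read_csv(fh, sep="\t")
    else:
        table = pd.read_csv(path, sep="\t")
    table["coding"] = table["coding"].astype(bool)
    return table.set_index("consequence")


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read an annotation sidecar TSV keyed by (chrom, pos, ref, alt)."""
    ann = pd.read_csv(path, sep="\t", dtype={"chrom": str, "clinvar": str, "aac": str})
    ann["clinvar"] = ann["clinvar"].fillna("")
    return ann


def attach_annotations(
    variants: pd.DataFrame,
    annotations: pd.DataFrame,
    impact_map: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Merge annotations onto the variant table by (chrom, pos, ref, alt).

    Where the sidecar supplies no explicit impact/coding flag, they are
    filled from the consequence mapping.  Unknown consequence terms without
    an explicit impact are logged and left with missing impact (they fall
    out at impact selection).
    """
    if impact_map is None:
        impact_map = load_impact_map()
    merged = variants.merge(annotations, on=["chrom", "pos", "ref", "alt"], how="left")
    cons = merged["consequence"]
    if "impact" not in merged.columns:
        merged["impact"] = pd.NA
    if "coding" not in merged.columns:
        merged["coding"] = pd.NA
    mapped = cons.map(impact_map["impact"])
    merged["impact"] = merged["impact"].fillna(mapped)
    coding_fill = cons.map(impact_map["coding"])
    merged["coding"] = np.where(merged["coding"].notna(), merged["coding"], coding_fill)
    unknown = cons.notna() & merged["impact"].isna()
    if unknown.any():
        log.warning(
            "%d records have consequence terms outside the impact map and no "
            "explicit impact; they will not pass impact selection",
            int(unknown.sum()),
        )
    return merged


def impact_select(annotated: pd.DataFrame) -> pd.DataFrame:
    """Keep coding MEDIUM/HIGH records and non-coding HIGH records.

    In practice the retained non-coding class is splice donor/acceptor
    variants.  Records with missing impact are dropped (and were already
    logged at annotation time).
    """
    impact = annotated["impact"]
    coding = annotated["coding"].map(lambda v: bool(v) if pd.notna(v) else False)
    keep = (impact == "HIGH") | (coding & (impact == "MEDIUM"))
    return annotated.loc[keep.fillna(False)]


def prediction_filter(annotated: pd.DataFrame) -> pd.DataFrame:
    """Synonymous removal plus the PolyPhen–SIFT cross-rules.

    Removes synonymous records; removes MEDIUM records called benign by
    PolyPhen unless SIFT calls them deleterious; removes MEDIUM records
    called tolerated by SIFT unless PolyPhen calls them probably damaging.
    HIGH records pass unconditionally.  ``possibly_damaging`` counts as
    non-benign but does not rescue a tolerated SIFT call; unknown
    predictions neither remove nor rescue.
    """
    cons = annotated["consequence"].fillna("")
    if "polyphen" in annotated.columns:
        polyphen = annotated["polyphen"].fillna("unknown")
    else:
        polyphen = pd.Series("unknown", index=annotated.index)
    if "sift" in annotated.columns:
        sift = annotated["sift"].fillna("unknown")
    else:
        sift = pd.Series("unknown", index=annotated.index)
    medium = annotated["impact"] == "MEDIUM"

    drop = cons == "synonymous_variant"
    drop |= medium & (polyphen == "benign") & (sift != "deleterious")
    drop |= medium & (sift == "tolerated") & (polyphen != "probably_damaging")
    return annotated.loc[~drop]


def max_known_af(annotated: pd.DataFrame, databases=AF_DATABASES) -> pd.Series:
    """Row-wise maximum allele frequency over the consulted databases.

    NaN where no database reports a frequency.
    """
    cols = [f"af_{db}" for db in databases if f"af_{db}" in annotated.columns]
    if not cols:
        return pd.Series(np.nan, index=annotated.index)
    return annotated[cols].max(axis=1, skipna=True)


def frequency_filter(annotated: pd.DataFrame, config: FilterModelConfig) -> pd.DataFrame:
    """Population-frequency exclusion for one inheritance model.

    Recessive: remove records whose maximum known frequency is >= 0.005.
    Dominant: remove records whose maximum known frequency exceeds 5e-5
    (threshold inclusive, so af == 5e-5 is kept).  Records unknown to every
    database are retained under both models.
    """
    mx = max_known_af(annotated, config.af_databases)
    if config.model == "recessive":
        drop = mx >= config.max_af
    else:
        drop = mx > config.max_af
    return annotated.loc[~drop.fillna(False)]


def deleteriousness_pipeline(
    annotated: pd.DataFrame, config: FilterModelConfig
) -> pd.DataFrame:
    """impact selection → prediction cross-rules → frequency threshold."""
    out = impact_select(annotated)
    out = prediction_filter(out)
    out = frequency_filter(out, config)
    return out
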