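"""ClinVar-term matching, candidate-gene screening and case classification.

Assigned genes are matched against phenotype keyword groups searched in the
ClinVar annotation strings (situs inversus, heterotaxy/situs ambiguus,
PCD/Kartagener, left-right, asymmetry/laterality), and each case is
classified as solved via a PCD gene, solved via a non-PCD laterality gene,
or unsolved.  Natural handedness applies the forced-switch override to the
Edinburgh Handedness Inventory score.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .inheritance import GeneAssignment

log = logging.getLogger(__name__)

EHI_AMBIDEXTERITY_BOUND = 0.5


@dataclass(frozen=True)
class TermQueryGroup:
    """One phenotype query: substring patterns plus whole-token abbreviations.

    Patterns are case-insensitive substrings; abbreviations match only as a
    whole '|'-separated token of the annotation string, because a bare
    substring like "SI" would over-match.
    """

    group_id: str
    patterns: tuple[str, ...]
    abbreviations: tuple[str, ...] = ()

    def matches(self, term: str) -> bool:
        low = term.lower()
        if any(p.lower() in low for p in self.patterns):
            return True
        tokens = {t.strip().lower() for t in term.split("|")}
        return any(a.lower() in tokens for a in self.abbreviations)


#: the study's ClinVar phenotype queries, with Table-1-style abbreviations
DEFAULT_QUERY_GROUPS = (
    TermQueryGroup("si", ("situs inversus",), ("SI",)),
    TermQueryGroup("htx", ("heterotaxy", "heterotaxia", "situs ambiguus"), ("HTX", "SA")),
    TermQueryGroup("pcd", ("ciliary dyskinesia", "kartagener"), ("PCD",)),
    TermQueryGroup("left_right", ("left-right",)),
    TermQueryGroup("asymmetry", ("asymmetry", "laterality")),
)


def load_query_groups(path: str | Path) -> tuple[TermQueryGroup, ...]:
    """Load query groups from YAML: {group_id: {patterns: [...], abbreviations: [...]}}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return tuple(
        TermQueryGroup(gid, tuple(spec.get("patterns", ())), tuple(spec.get("abbreviations", ())))
        for gid, spec in raw.items()
    )


def match_terms(
    assignments: list[GeneAssignment],
    query_groups=DEFAULT_QUERY_GROUPS,
) -> list[tuple[GeneAssignment, frozenset]]:
    """Attach to each assignment the set of query group_ids its ClinVar terms match."""
    out = []
    for a in assignments:
        matched = frozenset(
            g.group_id for g in query_groups
            if any(g.matches(t) for t in a.clinvar_terms)
        )
        out.append((a, matched))
    return out


@dataclass(frozen=True)
class SubjectClassification:
    subject_id: str
    group: str
    status: str  # solved_pcd_gene | solved_laterality_gene | unsolved
    causal_assignment: GeneAssignment | None = None
    all_matching: tuple[GeneAssignment, ...] = ()
    ambiguous: bool = False
    natural_handedness: str | None = None


def classify_subject(
    subject: pd.Series,
    matched_assignments: list[tuple[GeneAssignment, frozenset]],
) -> SubjectClassification:
    """Classify one case from its matched (post-exclusion) assignments.

    PCD-gene matches take priority over situs-inversus/heterotaxy matches,
    mirroring the interpretation that PCD genes are the likely cause even
    in cases without a PCD diagnosis.  Deterministic: ties are ordered by
    gene symbol and flagged ambiguous.
    """
    sid = subject["subject_id"]
    mine = [(a, m) for a, m in matched_assignments if a.subject_id == sid]
    pcd_hits = sorted((a for a, m in mine if "pcd" in m), key=lambda a: a.gene)
    lat_hits = sorted((a for a, m in mine if m & {"si", "htx"}), key=lambda a: a.gene)
    nh = natural_handedness(subject)
    if pcd_hits:
        return SubjectClassification(
            sid, subject["group"], "solved_pcd_gene", pcd_hits[0], tuple(pcd_hits),
            ambiguous=len({a.gene for a in pcd_hits}) > 1, natural_handedness=nh,
        )
    if lat_hits:
        return SubjectClassification(
            sid, subject["group"], "solved_laterality_gene", lat_hits[0], tuple(lat_hits),
            ambiguous=len({a.gene for a in lat_hits}) > 1, natural_handedness=nh,
        )
    return SubjectClassification(sid, subject["group"], "unsolved", natural_handedness=nh)


def classify_cohort(
    subjects: pd.DataFrame,
    matched_assignments: list[tuple[GeneAssignment, frozenset]],
    case_groups=("si_pcd", "si_nonpcd"),
) -> list[SubjectClassification]:
    return [
        classify_subject(row, matched_assignments)
        for _, row in subjects.iterrows()
        if row["group"] in case_groups
    ]


def read_candidate_list(path: str | Path) -> list[str]:
    """Read a candidate gene list: one symbol per line, '#' comments."""
    genes: list[str] = []
    seen = set()
    for line in Path(path).read_text().splitlines():
        sym = line.split("#", 1)[0].strip()
        if not sym:
            continue
        if sym in seen:
            log.warning("duplicate candidate gene %s deduplicated", sym)
            continue
        seen.add(sym)
        genes.append(sym)
    return genes


def default_candidate_list() -> list[str]:
    """The packaged candidate laterality/ciliopathy gene list."""
    from importlib import resources

    with resources.as_file(
        resources.files("situscan").joinpath("data/candidate_genes.txt")
    ) as p:
        return read_candidate_list(p)


def candidate_list_match(
    assignments: list[GeneAssignment], candidate_genes: list[str]
) -> list[GeneAssignment]:
    """Assignments whose gene appears in the candidate list.

    Used as the secondary screen of cases left unsolved by ClinVar matching.
    """
    wanted = set(candidate_genes)
    return [a for a in assignments if a.gene in wanted]


def natural_handedness(subject: pd.Series) -> str | None:
    """Natural handedness with the childhood forced-switch override.

    Left when EHI < 0 or the subject reports having been forced to switch
    from left to right; right otherwise.  Subjects with |EHI| below the
    ambidexterity bound of 0.5 return None (excluded from handedness
    counts, with a warning); scores of exactly 0.5 still count, matching
    the handedness records of the studied cohort.
    """
    ehi = float(subject["ehi"])
    if abs(ehi) < EHI_AMBIDEXTERITY_BOUND:
        warnings.warn(
            f"subject {subject['subject_id']} has |EHI| < 0.5 (ambidextrous); "
            "excluded from handedness counts",
            stacklevel=2,
        )
        return None
    if ehi < 0 or bool(subject["forced_switch"]):
        return "left"
    return "right"


def classification_frame(classifications: list[SubjectClassification]) -> pd.DataFrame:
    """Per-subject report table (one row per case)."""
    rows = []
    for c in classifications:
        rows.append(
            {
                "subject_id": c.subject_id,
                "group": c.group,
                "status": c.status,
                "mechanism": c.causal_assignment.mechanism if c.causal_assignment else "",
                "gene": c.causal_assignment.gene if c.causal_assignment else "",
                "clinvar": " | ".join(c.causal_assignment.clinvar_terms)
                if c.causal_assignment else "",
                "natural_handedness": c.natural_handedness or "ambidextrous",
                "ambiguous": c.ambiguous,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id", "group", "status", "mechanism", "gene", "clinvar",
            "natural_handedness", "ambiguous",
        ],
    )
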