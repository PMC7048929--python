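"""Gene-level inheritance-model assignment.

Turns per-subject filtered mutations into gene assignments:

* recessive — a gene is recessively mutated in a subject when it carries a
  homozygous mutation or at least two distinct heterozygous mutations
  (possible compound heterozygote); on chromosome X females need two
  mutations while males need one (hemizygous);
* dominant — any single qualifying rare variant assigns the gene;
* phase exclusion — compound-het candidates whose variant pairs are
  read-backed as definitely cis are discarded;
* control exclusion — genes assigned in any unaffected control are removed
  from case lists, and mirrored back the other way.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import pandas as pd

from .variant_io import GT_HET, GT_HOM_ALT, variant_key

log = logging.getLogger(__name__)

X_CHROMS = {"X", "chrX"}

MECHANISMS = ("hom", "chet", "hemizygous_x", "dominant_het")


@dataclass(frozen=True)
class GeneAssignment:
    """One (subject, gene, mechanism) unit of 'mutated gene'."""

    subject_id: str
    gene: str
    mechanism: str
    variants: tuple[str, ...]  # chrom:pos:ref:alt keys
    phase_status: str = "not_applicable"  # not_applicable | unknown | cis_excluded
    clinvar_terms: tuple[str, ...] = ()


@dataclass(frozen=True)
class PhaseEvidence:
    """Read-backed phase support for one het variant pair in one subject."""

    subject_id: str
    key1: str
    key2: str
    cis_support: int
    trans_support: int

    def pair(self) -> frozenset:
        return frozenset((self.key1, self.key2))


def read_phase_evidence(path) -> list[PhaseEvidence]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        PhaseEvidence(r.subject_id, r.key1, r.key2, int(r.cis_support), int(r.trans_support))
        for r in df.itertuples()
    ]


def _subject_sex(subjects: pd.DataFrame) -> dict[str, str]:
    return dict(zip(subjects["subject_id"], subjects["sex"]))


def _clinvar_by_key(group: pd.DataFrame, keys: list[str]) -> dict[str, str]:
    if "clinvar" not in group.columns:
        return {}
    return {
        k: str(t).strip()
        for k, t in zip(keys, group["clinvar"].fillna(""))
        if str(t).strip()
    }


def _terms_for(clinvar_map: dict[str, str], keys) -> tuple[str, ...]:
    return tuple(sorted({clinvar_map[k] for k in keys if k in clinvar_map}))


def assign_recessive(
    mutations: pd.DataFrame, subjects: pd.DataFrame
) -> list[GeneAssignment]:
    """Recessive gene assignment from a recessively-filtered mutation table.

    ``mutations`` carries core variant columns plus ``gene`` and one
    genotype column per subject.  Per (subject, gene): any homozygous
    mutation yields a ``hom`` assignment; otherwise >=2 distinct het
    mutations yield a ``chet`` assignment.  On chrX, males are hemizygous —
    a single variant call (het or hom on a diploid caller) assigns the
    gene; females follow the two-mutation rule.  Autosomal single hets
    yield nothing.  Assignment is invariant to row order.
    """
    sex = _subject_sex(subjects)
    out: list[GeneAssignment] = []
    if mutations.empty:
        return out
    work = mutations.dropna(subset=["gene"])
    for (gene, chrom), grp in sorted(
        work.groupby(["gene", "chrom"], sort=False), key=lambda kv: (kv[0][0], str(kv[0][1]))
    ):
        on_x = str(chrom) in X_CHROMS
        keys = [variant_key(c, p, r, a) for c, p, r, a in
                zip(grp["chrom"], grp["pos"], grp["ref"], grp["alt"])]
        clinvar_map = _clinvar_by_key(grp, keys)
        for sid in subjects["subject_id"]:
            if sid not in grp.columns:
                continue
            gts = grp[sid].to_numpy()
            hom_keys = sorted({k for k, g in zip(keys, gts) if g == GT_HOM_ALT})
            het_keys = sorted({k for k, g in zip(keys, gts) if g == GT_HET})
            if on_x:
                subj_sex = sex.get(sid)
                if subj_sex not in ("male", "female") and (hom_keys or het_keys):
                    raise ValueError(
                        f"subject {sid!r} carries chrX mutations but has no known sex"
                    )
                if subj_sex == "male":
                    if hom_keys or het_keys:
                        carried = tuple(sorted(hom_keys + het_keys)[:1])
                        out.append(GeneAssignment(
                            sid, gene, "hemizygous_x", carried,
                            "not_applicable", _terms_for(clinvar_map, carried),
                        ))
                    continue
            if hom_keys:
                out.append(GeneAssignment(
                    sid, gene, "hom", (hom_keys[0],), "not_applicable",
                    _terms_for(clinvar_map, (hom_keys[0],))))
            elif len(het_keys) >= 2:
                out.append(GeneAssignment(
                    sid, gene, "chet", tuple(het_keys), "unknown",
                    _terms_for(clinvar_map, het_keys)))
    return out


def assign_dominant(mutations: pd.DataFrame, subjects: pd.DataFrame) -> list[GeneAssignment]:
    """Dominant assignment: one qualifying rare variant suffices.

    Input must already have passed the dominant-model frequency filter.
    """
    out: list[GeneAssignment] = []
    if mutations.empty:
        return out
    work = mutations.dropna(subset=["gene"])
    for gene, grp in sorted(work.groupby("gene", sort=False), key=lambda kv: str(kv[0])):
        keys = [variant_key(c, p, r, a) for c, p, r, a in
                zip(grp["chrom"], grp["pos"], grp["ref"], grp["alt"])]
        clinvar_map = _clinvar_by_key(grp, keys)
        for sid in subjects["subject_id"]:
            if sid not in grp.columns:
                continue
            gts = grp[sid].to_numpy()
            carried = tuple(sorted({k for k, g in zip(keys, gts) if g in (GT_HET, GT_HOM_ALT)}))
            if carried:
                out.append(GeneAssignment(
                    sid, gene, "dominant_het", carried, "not_applicable",
                    _terms_for(clinvar_map, carried)))
    return out


def phase_exclude(
    assignments: list[GeneAssignment],
    evidence: list[PhaseEvidence],
    min_cis_reads: int = 1,
) -> tuple[list[GeneAssignment], list[GeneAssignment]]:
    """Drop compound-het assignments whose variants are definitely in cis.

    A chet assignment is excluded when *every* pair of its het variants has
    ``cis_support >= min_cis_reads`` and ``trans_support == 0`` — i.e. read
    evidence places all mutations on the same haplotype, so the second gene
    copy is intact.  Pairs with no spanning fragments leave the assignment
    retained with phase 'unknown'.  Non-chet assignments pass through.

    Returns ``(retained, cis_excluded)``.
    """
    known_keys = {k for a in assignments for k in a.variants}
    by_subject: dict[str, dict[frozenset, PhaseEvidence]] = {}
    for ev in evidence:
        if ev.key1 not in known_keys or ev.key2 not in known_keys:
            log.warning("phase evidence references unknown variant keys: %s/%s",
                        ev.key1, ev.key2)
            continue
        by_subject.setdefault(ev.subject_id, {})[ev.pair()] = ev

    retained, excluded = [], []
    for a in assignments:
        if a.mechanism != "chet":
            retained.append(a)
            continue
        pairs = list(itertools.combinations(sorted(a.variants), 2))
        emap = by_subject.get(a.subject_id, {})
        all_cis = bool(pairs)
        for k1, k2 in pairs:
            ev = emap.get(frozenset((k1, k2)))
            if ev is None or ev.cis_support < min_cis_reads or ev.trans_support > 0:
                all_cis = False
                break
        if all_cis:
            excluded.append(replace(a, phase_status="cis_excluded"))
        else:
            retained.append(a)
    return retained, excluded


def genes_of(assignments: list[GeneAssignment]) -> set[str]:
    return {a.gene for a in assignments}


def control_exclude(
    case_assignments: list[GeneAssignment],
    control_assignments: list[GeneAssignment],
) -> tuple[list[GeneAssignment], list[str]]:
    """Remove genes mutated in any control from all case assignment lists.

    This strips likely technical artifacts and variants that are common in
    the population but unannotated in frequency databases.  Returns the
    filtered case assignments and the sorted excluded gene list.
    """
    control_genes = genes_of(control_assignments)
    excluded = sorted(genes_of(case_assignments) & control_genes)
    kept = [a for a in case_assignments if a.gene not in control_genes]
    return kept, excluded


def mirror_exclude(
    control_assignments: list[GeneAssignment],
    case_assignments: list[GeneAssignment],
) -> tuple[list[GeneAssignment], list[str]]:
    """Mirror of :func:`control_exclude`: drop case genes from control lists."""
    return control_exclude(control_assignments, case_assignments)


def assignments_frame(assignments: list[GeneAssignment]) -> pd.DataFrame:
    """Tabular view mirroring the per-subject report columns."""
    return pd.DataFrame(
        [
            {
                "subject_id": a.subject_id,
                "type": a.mechanism,
                "gene": a.gene,
                "variants": ";".join(a.variants),
                "phase_status": a.phase_status,
                "clinvar": " | ".join(a.clinvar_terms),
            }
            for a in assignments
        ],
        columns=["subject_id", "type", "gene", "variants", "phase_status", "clinvar"],
    )
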