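"""End-to-end orchestration: QC → filters → inheritance models → ClinVar
matching → enrichment → handedness test → SV screen.

All stage outputs are pure functions of (inputs, config); the run manifest
records inputs, thresholds and seed so any run can be reproduced.  Record
counts in and out of every filter are logged, making narrative numbers
(e.g. how many genes the control overlap excluded) auditable from logs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .deleterious import (
    FilterModelConfig,
    attach_annotations,
    deleteriousness_pipeline,
    read_annotations,
)
from .enrichment import (
    MAX_SET_SIZE,
    MIN_INTERSECT,
    MIN_SET_SIZE,
    SIGNIFICANCE_CUTOFF,
    control_mirror_gsea,
    read_gmt,
    results_frame,
)
from .handedness import HandednessCount, binomial_upper_tail, tabulate_handedness
from .inheritance import (
    assign_dominant,
    assign_recessive,
    assignments_frame,
    control_exclude,
    mirror_exclude,
    phase_exclude,
    read_phase_evidence,
)
from .matching import (
    DEFAULT_QUERY_GROUPS,
    candidate_list_match,
    classification_frame,
    classify_cohort,
    load_query_groups,
    match_terms,
    read_candidate_list,
)
from .sv_screen import (
    DEFAULT_RECIPROCAL_OVERLAP,
    mean_genes_per_subject,
    quality_filter_svs,
    read_gene_bed,
    read_sv_calls,
    subtract_control_svs,
    sv_gene_hits,
)
from .variant_io import read_cohort, site_quality_filter

log = logging.getLogger(__name__)

EXIT_CONFIG_ERROR = 2
EXIT_DATA_ERROR = 3
EXIT_STAGE_FAILURE = 4

CASE_GROUPS = ("si_pcd", "si_nonpcd")


@dataclass
class RunConfig:
    """Validated paths and thresholds for one pipeline run."""

    vcf: Path
    subjects: Path
    annotations: Path
    genesets: Path
    out_dir: Path
    phase_evidence: Path | None = None
    genes_bed: Path | None = None
    svs: Path | None = None
    candidates: Path | None = None
    query_groups: Path | None = None
    tranche_cut: float = 99.9
    qd_min: float = 9.0
    call_rate_min: float = 0.8
    recessive_max_af: float = 0.005
    dominant_max_af: float = 5e-5
    min_cis_reads: int = 1
    enrichment_method: str = "bonferroni"
    enrichment_n_perm: int = 1000
    min_set_size: int = MIN_SET_SIZE
    max_set_size: int = MAX_SET_SIZE
    min_intersect: int = MIN_INTERSECT
    sv_min_reciprocal_overlap: float = DEFAULT_RECIPROCAL_OVERLAP
    population_left_rate: float = 0.10
    seed: int = 0

    _PATH_FIELDS = ("vcf", "subjects", "annotations", "genesets", "phase_evidence",
                    "genes_bed", "svs", "candidates", "query_groups")

    def __post_init__(self):
        for name in self._PATH_FIELDS + ("out_dir",):
            val = getattr(self, name)
            if val is not None:
                setattr(self, name, Path(val))
        missing = [
            name for name in self._PATH_FIELDS
            if getattr(self, name) is not None and not getattr(self, name).exists()
        ]
        if missing:
            raise FileNotFoundError(
                "config references missing input files: "
                + ", ".join(f"{n}={getattr(self, n)}" for n in missing)
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = Path(path).parent
        for key in cls._PATH_FIELDS:
            if raw.get(key):
                p = Path(raw[key])
                raw[key] = p if p.is_absolute() else base / p
        if "out_dir" in raw:
            p = Path(raw["out_dir"])
            raw["out_dir"] = p if p.is_absolute() else base / p
        return cls(**raw)


@dataclass
class RunResult:
    """In-memory bundle of everything the pipeline computed."""

    classifications: list
    subject_report: pd.DataFrame
    recessive_case_assignments: list
    recessive_control_assignments: list
    dominant_case_assignments: list
    cis_excluded: list
    control_excluded_genes: list
    dominant_excluded_genes: list
    gene_lists: dict
    enrichment: dict
    enrichment_report: pd.DataFrame
    handedness: dict
    handedness_report: pd.DataFrame
    candidate_hits_unsolved: list
    sv_hits: pd.DataFrame
    sv_mean_genes: float
    manifest: dict


def _stage(name):
    log.info("stage: %s", name)


def run(config: RunConfig) -> RunResult:
    """Execute the full analysis and write the report bundle to out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    _stage("read inputs")
    variants, subjects = read_cohort(config.vcf, config.subjects)
    log.info("read %d decomposed variant records, %d subjects", len(variants), len(subjects))

    _stage("site quality filter")
    qc = site_quality_filter(variants, config.tranche_cut, config.qd_min, config.call_rate_min)
    log.info("site QC: %d -> %d records", len(variants), len(qc))

    _stage("annotation")
    ann = attach_annotations(qc, read_annotations(config.annotations))

    case_ids = subjects.loc[subjects["group"].isin(CASE_GROUPS), "subject_id"].tolist()
    cases = subjects[subjects["group"].isin(CASE_GROUPS)]
    controls = subjects[subjects["group"] == "control"]

    _stage("recessive model")
    rec = deleteriousness_pipeline(ann, FilterModelConfig("recessive", config.recessive_max_af))
    log.info("recessive deleteriousness filters: %d -> %d records", len(ann), len(rec))
    rec_case = assign_recessive(rec, cases)
    rec_ctrl = assign_recessive(rec, controls)
    log.info("recessive assignments: %d in cases, %d in controls", len(rec_case), len(rec_ctrl))

    _stage("phase exclusion")
    evidence = read_phase_evidence(config.phase_evidence) if config.phase_evidence else []
    rec_case, cis_excluded = phase_exclude(rec_case, evidence, config.min_cis_reads)
    log.info("phase exclusion dropped %d compound-het assignments", len(cis_excluded))

    _stage("control exclusion")
    rec_case_pre = rec_case
    rec_case, excluded_genes = control_exclude(rec_case, rec_ctrl)
    # mirror removes every gene mutated in cases, leaving the genes
    # exclusively mutated in controls
    rec_ctrl_mirrored, mirror_excluded = mirror_exclude(rec_ctrl, rec_case_pre)
    log.info("control exclusion removed %d genes from case lists; mirror removed %d",
             len(excluded_genes), len(mirror_excluded))

    _stage("dominant model")
    dom = deleteriousness_pipeline(ann, FilterModelConfig("dominant", config.dominant_max_af))
    log.info("dominant deleteriousness filters: %d -> %d records", len(ann), len(dom))
    dom_case = assign_dominant(dom, cases)
    dom_ctrl = assign_dominant(dom, controls)
    dom_case_pre = dom_case
    dom_case, dom_excluded = control_exclude(dom_case, dom_ctrl)
    dom_ctrl_mirrored, _ = mirror_exclude(dom_ctrl, dom_case_pre)
    log.info("dominant control exclusion removed %d genes", len(dom_excluded))

    _stage("clinvar matching and classification")
    groups = load_query_groups(config.query_groups) if config.query_groups \
        else DEFAULT_QUERY_GROUPS
    matched = match_terms(rec_case, groups)
    classifications = classify_cohort(subjects, matched)
    report = classification_frame(classifications)

    _stage("candidate-gene screen of unsolved cases")
    unsolved_ids = {c.subject_id for c in classifications if c.status == "unsolved"}
    candidate_hits: list = []
    if config.candidates:
        candidates = read_candidate_list(config.candidates)
        unsolved_assign = [a for a in rec_case if a.subject_id in unsolved_ids]
        unsolved_dom = [a for a in dom_case if a.subject_id in unsolved_ids]
        candidate_hits = candidate_list_match(unsolved_assign + unsolved_dom, candidates)
        log.info("candidate-list hits in unsolved cases: %d", len(candidate_hits))

    _stage("gene set enrichment")
    schema = read_gmt(config.genesets)
    by_subject: dict[str, set] = {}
    for a in rec_case:
        by_subject.setdefault(a.subject_id, set()).add(a.gene)
    nonpcd_ids = subjects.loc[subjects["group"] == "si_nonpcd", "subject_id"].tolist()
    pcd_ids = subjects.loc[subjects["group"] == "si_pcd", "subject_id"].tolist()
    left_ids = {
        c.subject_id for c in classifications
        if c.group == "si_nonpcd" and c.natural_handedness == "left"
    }

    def union_genes(ids, source):
        return sorted(set().union(*[source.get(i, set()) for i in ids]) if ids else set())

    dom_by_subject: dict[str, set] = {}
    for a in dom_case:
        dom_by_subject.setdefault(a.subject_id, set()).add(a.gene)

    gene_lists = {
        "pcd": union_genes(pcd_ids, by_subject),
        "nonpcd": union_genes(nonpcd_ids, by_subject),
        "nonpcd_lefthanded": union_genes(sorted(left_ids), by_subject),
        "unsolved": union_genes(sorted(unsolved_ids), by_subject),
        "dominant_nonpcd": union_genes(nonpcd_ids, dom_by_subject),
        "dominant_unsolved": union_genes(sorted(unsolved_ids), dom_by_subject),
        "dominant_nonpcd_lefthanded": union_genes(sorted(left_ids), dom_by_subject),
    }
    control_genes = sorted({a.gene for a in rec_ctrl_mirrored}
                           | {a.gene for a in dom_ctrl_mirrored})
    enr = control_mirror_gsea(
        gene_lists, control_genes, schema,
        method=config.enrichment_method, rng=rng, n_perm=config.enrichment_n_perm,
        min_set=config.min_set_size, max_set=config.max_set_size,
        min_intersect=config.min_intersect,
    )
    enr_report = results_frame(enr)

    _stage("handedness")
    counts = tabulate_handedness(subjects, config.population_left_rate)
    hand_rows = []
    for group in sorted(counts):
        c = counts[group]
        p = binomial_upper_tail(c) if c.n_total >= 1 else float("nan")
        hand_rows.append({"group": group, "n_left": c.n_left, "n_total": c.n_total,
                          "p0": c.p0, "p_binomial_upper": p})
    hand_report = pd.DataFrame(hand_rows)

    _stage("SV screen")
    sv_hits = pd.DataFrame(columns=["subject_id", "gene", "in_candidate_list"])
    sv_mean = float("nan")
    if config.svs and config.genes_bed:
        svs = quality_filter_svs(read_sv_calls(config.svs))
        case_svs = [s for s in svs if s.subject_id in set(case_ids)]
        ctrl_svs = [s for s in svs if s.subject_id not in set(case_ids)]
        retained = subtract_control_svs(case_svs, ctrl_svs, config.sv_min_reciprocal_overlap)
        log.info("SV control subtraction: %d -> %d case SVs", len(case_svs), len(retained))
        gene_ivs = read_gene_bed(config.genes_bed)
        cand = read_candidate_list(config.candidates) if config.candidates else []
        sv_hits = sv_gene_hits(retained, gene_ivs, cand)
        sv_mean = mean_genes_per_subject(sv_hits, case_ids)

    _stage("reports")
    report.to_csv(out / "subject_report.tsv", sep="\t", index=False)
    assignments_frame(rec_case).to_csv(out / "recessive_assignments.tsv", sep="\t", index=False)
    assignments_frame(dom_case).to_csv(out / "dominant_assignments.tsv", sep="\t", index=False)
    pd.DataFrame({"excluded_gene": excluded_genes}).to_csv(
        out / "control_excluded_genes.tsv", sep="\t", index=False)
    enr_report.to_csv(out / "enrichment_report.tsv", sep="\t", index=False)
    hand_report.to_csv(out / "handedness_report.tsv", sep="\t", index=False)
    sv_hits.to_csv(out / "sv_gene_hits.tsv", sep="\t", index=False)
    with open(out / "gene_lists.json", "w") as fh:
        json.dump({k: list(v) for k, v in gene_lists.items()}
                  | {"controls_mirrored": control_genes}, fh, indent=1, sort_keys=True)

    manifest = {
        "situscan_version": __version__,
        "inputs": {k: str(getattr(config, k)) for k in RunConfig._PATH_FIELDS
                   if getattr(config, k) is not None},
        "thresholds": {
            "tranche_cut": config.tranche_cut, "qd_min": config.qd_min,
            "call_rate_min": config.call_rate_min,
            "recessive_max_af": config.recessive_max_af,
            "dominant_max_af": config.dominant_max_af,
            "min_cis_reads": config.min_cis_reads,
            "enrichment_method": config.enrichment_method,
            "min_set_size": config.min_set_size, "max_set_size": config.max_set_size,
            "min_intersect": config.min_intersect,
            "significance_cutoff": SIGNIFICANCE_CUTOFF,
            "sv_min_reciprocal_overlap": config.sv_min_reciprocal_overlap,
            "population_left_rate": config.population_left_rate,
        },
        "seed": config.seed,
        "counts": {
            "variants_read": int(len(variants)),
            "variants_post_qc": int(len(qc)),
            "recessive_case_assignments": len(rec_case),
            "cis_excluded": len(cis_excluded),
            "control_excluded_genes": len(excluded_genes),
            "dominant_excluded_genes": len(dom_excluded),
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)

    return RunResult(
        classifications=classifications,
        subject_report=report,
        recessive_case_assignments=rec_case,
        recessive_control_assignments=rec_ctrl_mirrored,
        dominant_case_assignments=dom_case,
        cis_excluded=cis_excluded,
        control_excluded_genes=excluded_genes,
        dominant_excluded_genes=dom_excluded,
        gene_lists=gene_lists,
        enrichment=enr,
        enrichment_report=enr_report,
        handedness=counts,
        handedness_report=hand_report,
        candidate_hits_unsolved=candidate_hits,
        sv_hits=sv_hits,
        sv_mean_genes=sv_mean,
        manifest=manifest,
    )


def run_on_bundle(bundle: dict, out_dir: str | Path, **overrides) -> RunResult:
    """Convenience: run the pipeline on a generator file map."""
    cfg = RunConfig(
        vcf=bundle["vcf"], subjects=bundle["subjects"],
        annotations=bundle["annotations"], genesets=bundle["genesets"],
        phase_evidence=bundle.get("phase_evidence"),
        genes_bed=bundle.get("genes_bed"), svs=bundle.get("svs"),
        candidates=bundle.get("candidates"), out_dir=Path(out_dir), **overrides,
    )
    return run(cfg)
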