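"""Self-contained synthetic cohorts for end-to-end testing of the pipeline.

Emits a complete input bundle — multi-sample VCF, annotation sidecar,
subject metadata, read-backed phase evidence, GMT gene-set schema, gene
BED, SV calls, candidate list — plus a truth table of every planted
(subject, gene, mechanism), so each analysis stage can be validated
without access to real genomes.

What it emulates: a 30-subject cohort (15 situs-inversus cases of which 6
PCD-like, 15 controls) with planted causal genes per inheritance mechanism
(homozygous, compound-het, hemizygous-X, dominant), per-subject background
rare deleterious mutations at the 5–15 recessively-mutated-genes-per-
subject scale, shared case/control artifact genes driving the control
exclusion, cis compound-het decoys with read-backed phase evidence, and
filter-exercising noise (failing tranches, low QD, low call rate, common
alleles, synonymous and benign/tolerated calls).  Same spec + seed gives
byte-identical files.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CHROM_ORDER = [str(i) for i in range(1, 23)] + ["X"]

#: laterality/PCD disease genes available for causal planting: symbol -> (chrom, clinvar)
DISEASE_GENES = {
    "DNAH5": ("5", "Kartagener"),
    "DNAH11": ("7", "PCD"),
    "DNAAF1": ("16", "Kartagener"),
    "CCDC114": ("19", "Kartagener"),
    "CCDC151": ("19", "Kartagener"),
    "LRRC6": ("8", "Kartagener"),
    "PKD1L1": ("7", "SA | SI"),
    "CFAP52": ("17", "SI"),
    "MMP21": ("10", "HTX"),
    "NME7": ("1", "SI"),
    "CCDC11": ("18", "HTX | SI"),
    "ZIC3": ("X", "HTX | SI"),
    "RAI2": ("X", "SI"),
    "ROCK2": ("2", "laterality"),
}

#: default planting: every mechanism exercised across the 15 cases
DEFAULT_PLANTED = (
    ("SI01", "DNAH5", "hom"),
    ("SI02", "DNAAF1", "chet"),
    ("SI03", "CCDC114", "hom"),
    ("SI04", "LRRC6", "chet"),
    ("SI05", "DNAH11", "hom"),
    ("SI06", "DNAH5", "chet"),
    ("SI07", "CCDC151", "hom"),
    ("SI08", "DNAH5", "chet"),
    ("SI09", "PKD1L1", "hom"),
    ("SI10", "CFAP52", "chet"),
    ("SI11", "ZIC3", "hemizygous_x"),
    ("SI12", "ROCK2", "dominant_het"),
)

#: default cis compound-het decoy: dropped by phase exclusion downstream
DEFAULT_PLANTED_CIS = (("SI13", "MMP21"),)


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic cohort."""

    n_cases: int = 15
    n_pcd_cases: int = 6
    n_controls: int = 15
    seed: int = 0
    planted: tuple = DEFAULT_PLANTED
    planted_cis: tuple = DEFAULT_PLANTED_CIS
    planted_sv: tuple = ()  # (subject_id, gene) candidate-gene deletions
    # per-subject background recessively-mutated gene count band; the upper
    # bound leaves room for one planted causal gene within the 5-15 scale
    background_band: tuple = (5, 14)
    af_absent_mass: float = 0.3
    af_beta: tuple = (1.2, 600.0)
    # with a 2000-gene background pool, planted shared-artifact genes
    # (15 cases * ~9.5 genes * 0.05) plus chance case/control overlap
    # (~142*142/2000) put the control exclusion near the real-data scale
    # of ~17 genes
    shared_artifact_rate: float = 0.05
    n_background_genes: int = 2000
    n_noise_variants: int = 108
    n_gene_sets: int = 40
    set_size_range: tuple = (15, 50)
    n_filler_genes: int = 300
    sv_share_rate: float = 0.4

    def case_ids(self) -> list[str]:
        return [f"SI{i + 1:02d}" for i in range(self.n_cases)]

    def control_ids(self) -> list[str]:
        return [f"C{i + 1:02d}" for i in range(self.n_controls)]

    def subject_ids(self) -> list[str]:
        return self.case_ids() + self.control_ids()

    def sex_of(self, subject_id: str) -> str:
        ids = self.subject_ids()
        return "male" if ids.index(subject_id) % 2 == 0 else "female"

    def validate(self) -> None:
        ids = set(self.subject_ids())
        for sid, gene, mech in self.planted:
            if sid not in ids:
                raise ValueError(f"planted subject {sid!r} not in cohort")
            if gene not in DISEASE_GENES:
                raise ValueError(f"planted gene {gene!r} is not a known disease gene")
            if mech not in ("hom", "chet", "hemizygous_x", "dominant_het"):
                raise ValueError(f"unknown mechanism {mech!r}")
            chrom = DISEASE_GENES[gene][0]
            if mech == "hemizygous_x":
                if chrom != "X":
                    raise ValueError(f"hemizygous_x planting needs a chrX gene, got {gene}")
                if self.sex_of(sid) != "male":
                    raise ValueError(f"female subject {sid} cannot be hemizygous for {gene}")
        for sid, gene in self.planted_cis:
            if sid not in ids:
                raise ValueError(f"cis planting subject {sid!r} not in cohort")
        if not 1 <= self.background_band[0] <= self.background_band[1]:
            raise ValueError(f"bad background band {self.background_band}")
        if self.n_pcd_cases > self.n_cases:
            raise ValueError("n_pcd_cases exceeds n_cases")


class _Genome:
    """Deterministic gene layout: intervals and fresh variant positions."""

    def __init__(self, background_genes, noise_genes):
        self.intervals = {}  # gene -> (chrom, start0, end0), BED half-open
        cursors = {c: 1_000_000 for c in CHROM_ORDER}
        order = list(DISEASE_GENES) + list(background_genes) + list(noise_genes)
        chrom_cycle = itertools.cycle([c for c in CHROM_ORDER if c != "X"])
        for gene in order:
            chrom = DISEASE_GENES[gene][0] if gene in DISEASE_GENES else next(chrom_cycle)
            start = cursors[chrom]
            self.intervals[gene] = (chrom, start, start + 100_000)
            cursors[chrom] = start + 300_000
        self._next_pos = {g: iv[1] + 1_000 for g, iv in self.intervals.items()}

    def new_site(self, gene) -> tuple[str, int]:
        chrom, _, end = self.intervals[gene]
        pos0 = self._next_pos[gene]
        self._next_pos[gene] = pos0 + 977  # keep sites inside the interval
        if pos0 >= end:
            raise RuntimeError(f"gene {gene} ran out of variant positions")
        return chrom, pos0 + 1  # 1-based VCF position


def _draw_af(rng: np.random.Generator, spec: CohortSpec, max_af: float | None = None):
    """Background AF law: point mass at 'absent from databases' + low Beta tail."""
    if rng.random() < spec.af_absent_mass:
        return None
    a, b = spec.af_beta
    af = float(rng.beta(a, b))
    if max_af is not None:
        while af >= max_af:
            af = float(rng.beta(a, b))
    return round(af, 6)


_DELETERIOUS_CONSEQUENCES = (
    ("stop_gained", "unknown", "unknown"),
    ("splice_donor_variant", "unknown", "unknown"),
    ("frameshift_variant", "unknown", "unknown"),
    ("splice_acceptor_variant", "unknown", "unknown"),
    ("missense_variant", "probably_damaging", "deleterious"),
    ("missense_variant", "probably_damaging", "unknown"),
)


class _CohortBuilder:
    def __init__(self, spec: CohortSpec):
        spec.validate()
        self.spec = spec
        self.rng = np.random.default_rng(spec.seed)
        self.bg_genes = [f"BG{i + 1:03d}" for i in range(spec.n_background_genes)]
        self.noise_genes = [f"NOI{i + 1:03d}" for i in range(spec.n_noise_variants)]
        self.genome = _Genome(self.bg_genes, self.noise_genes)
        self.subjects = spec.subject_ids()
        self.variants: list[dict] = []  # row dicts incl. genotype map
        self.phase_rows: list[dict] = []
        self.truth_rows: list[dict] = []

    # -- variant fabrication -------------------------------------------------

    def _add_variant(self, gene, genotypes: dict, consequence, polyphen, sift,
                     af, clinvar="", vqsr="PASS", qd=None, missing_in=()):
        chrom, pos = self.genome.new_site(gene)
        ref, alt = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")][pos % 4]
        if consequence in ("frameshift_variant", "inframe_deletion"):
            ref, alt = ref + "CT", ref
        elif consequence == "inframe_insertion":
            ref, alt = ref, ref + "GTC"
        gts = {s: "0/0" for s in self.subjects}
        gts.update(genotypes)
        for s in missing_in:
            gts[s] = "./."
        self.variants.append(
            {
                "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                "vqsr": vqsr,
                "qd": round(float(qd if qd is not None else 15 + 20 * self.rng.random()), 2),
                "gts": gts, "gene": gene, "consequence": consequence,
                "polyphen": polyphen, "sift": sift, "af": af, "clinvar": clinvar,
            }
        )
        return f"{chrom}:{pos}:{ref}:{alt}"

    def _deleterious(self):
        return _DELETERIOUS_CONSEQUENCES[int(self.rng.integers(len(_DELETERIOUS_CONSEQUENCES)))]

    def _plant_causal(self):
        for sid, gene, mech in self.spec.planted:
            clinvar = DISEASE_GENES[gene][1]
            if mech == "hom":
                cons, pp, sf = self._deleterious()
                self._add_variant(gene, {sid: "1/1"}, cons, pp, sf,
                                  _draw_af(self.rng, self.spec, 0.005), clinvar)
                n = 1
            elif mech == "chet":
                keys = []
                for _ in range(2):
                    cons, pp, sf = self._deleterious()
                    keys.append(self._add_variant(
                        gene, {sid: "0/1"}, cons, pp, sf,
                        _draw_af(self.rng, self.spec, 0.005), clinvar))
                self.phase_rows.append(
                    {"subject_id": sid, "key1": keys[0], "key2": keys[1],
                     "cis_support": 0, "trans_support": int(self.rng.integers(1, 6))})
                n = 2
            elif mech == "hemizygous_x":
                cons, pp, sf = self._deleterious()
                self._add_variant(gene, {sid: "0/1"}, cons, pp, sf,
                                  _draw_af(self.rng, self.spec, 0.005), clinvar)
                n = 1
            else:  # dominant_het: must survive the 5e-5 threshold
                cons, pp, sf = self._deleterious()
                self._add_variant(gene, {sid: "0/1"}, cons, pp, sf, None, clinvar)
                n = 1
            self.truth_rows.append(
                {"subject_id": sid, "gene": gene, "mechanism": mech,
                 "kind": "causal", "n_variants": n})

    def _plant_cis_decoys(self):
        for sid, gene in self.spec.planted_cis:
            clinvar = DISEASE_GENES.get(gene, ("", ""))[1]
            keys = []
            for _ in range(2):
                cons, pp, sf = self._deleterious()
                keys.append(self._add_variant(
                    gene, {sid: "0/1"}, cons, pp, sf,
                    _draw_af(self.rng, self.spec, 0.005), clinvar))
            self.phase_rows.append(
                {"subject_id": sid, "key1": keys[0], "key2": keys[1],
                 "cis_support": int(self.rng.integers(2, 8)), "trans_support": 0})
            self.truth_rows.append(
                {"subject_id": sid, "gene": gene, "mechanism": "chet",
                 "kind": "cis_artifact", "n_variants": 2})

    def _plant_background(self):
        lo, hi = self.spec.background_band
        controls = self.spec.control_ids()
        for sid in self.subjects:
            k = int(self.rng.integers(lo, hi + 1))
            genes = list(self.rng.choice(self.bg_genes, size=k, replace=False))
            for gene in genes:
                mech = "hom" if self.rng.random() < 0.4 else "chet"
                self._plant_recessive_background(sid, gene, mech, kind="background")
                shared = (
                    sid not in controls
                    and self.rng.random() < self.spec.shared_artifact_rate
                )
                if shared:
                    ctrl = controls[int(self.rng.integers(len(controls)))]
                    self._plant_recessive_background(ctrl, gene, "hom", kind="control_shared")

    def _plant_recessive_background(self, sid, gene, mech, kind):
        if mech == "hom":
            cons, pp, sf = self._deleterious()
            self._add_variant(gene, {sid: "1/1"}, cons, pp, sf,
                              _draw_af(self.rng, self.spec, 0.005))
            n = 1
        else:
            for _ in range(2):
                cons, pp, sf = self._deleterious()
                self._add_variant(gene, {sid: "0/1"}, cons, pp, sf,
                                  _draw_af(self.rng, self.spec, 0.005))
            n = 2
        self.truth_rows.append(
            {"subject_id": sid, "gene": gene, "mechanism": mech,
             "kind": kind, "n_variants": n})

    def _random_carriers(self, prob, het="0/1"):
        carriers = [s for s in self.subjects if self.rng.random() < prob]
        if not carriers:
            carriers = [self.subjects[int(self.rng.integers(len(self.subjects)))]]
        return {s: het for s in carriers}

    def _plant_noise(self):
        """Filter-exercising background: every removal branch gets traffic."""
        categories = [
            "tranche", "low_qd", "low_callrate", "common", "synonymous",
            "benign_medium", "tolerated_medium", "rescued_medium", "mid_freq",
        ]
        for i, gene in enumerate(self.noise_genes):
            cat = categories[i % len(categories)]
            gts = self._random_carriers(0.15)
            if cat == "tranche":
                self._add_variant(gene, gts, "missense_variant", "probably_damaging",
                                  "deleterious", None,
                                  vqsr="VQSRTrancheSNP99.90to100.00")
            elif cat == "low_qd":
                self._add_variant(gene, gts, "stop_gained", "unknown", "unknown",
                                  None, qd=4.0)
            elif cat == "low_callrate":
                n_missing = int(np.ceil(0.25 * len(self.subjects)))
                missing = list(self.rng.choice(self.subjects, size=n_missing, replace=False))
                self._add_variant(gene, gts, "stop_gained", "unknown", "unknown",
                                  None, missing_in=missing)
            elif cat == "common":
                self._add_variant(gene, self._random_carriers(0.5),
                                  "missense_variant", "probably_damaging",
                                  "deleterious", round(0.01 + 0.3 * self.rng.random(), 4))
            elif cat == "synonymous":
                self._add_variant(gene, gts, "synonymous_variant", "unknown",
                                  "unknown", None)
            elif cat == "benign_medium":
                self._add_variant(gene, gts, "missense_variant", "benign",
                                  "unknown", None)
            elif cat == "tolerated_medium":
                self._add_variant(gene, gts, "missense_variant",
                                  "possibly_damaging", "tolerated", None)
            elif cat == "rescued_medium":
                # benign by PolyPhen but rescued by a deleterious SIFT call
                self._add_variant(gene, gts, "missense_variant", "benign",
                                  "deleterious", None)
            else:  # mid_freq: kept recessive, removed dominant (5e-5 < af < 0.005)
                self._add_variant(gene, gts, "missense_variant",
                                  "probably_damaging", "deleterious",
                                  round(float(self.rng.uniform(2e-4, 4e-3)), 6))

    # -- metadata, schema, SVs ----------------------------------------------

    def _subject_meta(self) -> pd.DataFrame:
        rows = []
        case_ids = self.spec.case_ids()
        for sid in self.subjects:
            is_case = sid in case_ids
            group = (
                "si_pcd" if is_case and case_ids.index(sid) < self.spec.n_pcd_cases
                else "si_nonpcd" if is_case else "control"
            )
            # cosmetic draws; only the sign of the EHI matters downstream
            ehi = round(float(self.rng.uniform(0.55, 1.0)), 2)
            if self.rng.random() < 0.3:
                ehi = -ehi
            rows.append(
                {
                    "subject_id": sid, "group": group, "sex": self.spec.sex_of(sid),
                    "ehi": ehi,
                    "forced_switch": bool(self.rng.random() < 0.05),
                    "daily_wet_cough": "yes" if group == "si_pcd" else "no",
                    "chd": bool(self.rng.random() < 0.15),
                }
            )
        return pd.DataFrame(rows)

    def _schema_lines(self) -> list[str]:
        filler = [f"GOF{i + 1:03d}" for i in range(self.spec.n_filler_genes)]
        universe = sorted(set(DISEASE_GENES) | set(self.bg_genes) | set(filler))
        pcd_genes = sorted(g for g, (_, cv) in DISEASE_GENES.items()
                           if "Kartagener" in cv or "PCD" in cv)
        lat_genes = sorted(set(DISEASE_GENES) - set(pcd_genes))
        lo, hi = self.spec.set_size_range
        lines = []
        pad = [g for g in filler if g not in pcd_genes]
        cilia = pcd_genes + pad[: max(lo - len(pcd_genes), 0)]
        lines.append("GS0001\tcilium movement\t" + "\t".join(sorted(cilia)))
        lat = lat_genes + pad[len(cilia): len(cilia) + max(lo - len(lat_genes), 0)]
        lines.append("GS0002\tleft-right axis determination\t" + "\t".join(sorted(lat)))
        for i in range(3, self.spec.n_gene_sets + 1):
            size = int(self.rng.integers(lo, hi + 1))
            members = sorted(self.rng.choice(universe, size=size, replace=False))
            lines.append(f"GS{i:04d}\trandom process {i}\t" + "\t".join(members))
        return lines

    def _sv_rows(self) -> list[dict]:
        rows = []
        controls = self.spec.control_ids()
        genes = list(self.genome.intervals)
        for sid in self.subjects:
            for _ in range(int(self.rng.integers(2, 6))):
                gene = genes[int(self.rng.integers(len(genes)))]
                chrom, gstart, gend = self.genome.intervals[gene]
                start = max(0, gstart - int(self.rng.integers(0, 50_000)))
                end = gend + int(self.rng.integers(200_000, 1_500_000))
                sv_type = "DEL" if self.rng.random() < 0.6 else "DUP"
                qpass = bool(self.rng.random() < 0.9)
                rows.append({"subject_id": sid, "chrom": chrom, "start": start,
                             "end": end, "sv_type": sv_type, "quality_pass": qpass})
                if sid not in controls and self.rng.random() < self.spec.sv_share_rate:
                    ctrl = controls[int(self.rng.integers(len(controls)))]
                    rows.append({"subject_id": ctrl, "chrom": chrom, "start": start,
                                 "end": end, "sv_type": sv_type, "quality_pass": True})
        for sid, gene in self.spec.planted_sv:
            chrom, gstart, gend = self.genome.intervals[gene]
            rows.append({"subject_id": sid, "chrom": chrom, "start": gstart,
                         "end": gend, "sv_type": "DEL", "quality_pass": True})
            self.truth_rows.append({"subject_id": sid, "gene": gene,
                                    "mechanism": "sv_del", "kind": "causal_sv",
                                    "n_variants": 1})
        rows.sort(key=lambda r: (r["subject_id"], CHROM_ORDER.index(r["chrom"]),
                                 r["start"], r["end"], r["sv_type"]))
        return rows

    # -- emission ------------------------------------------------------------

    def build(self, out_dir: str | Path) -> dict:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self._plant_causal()
        self._plant_cis_decoys()
        self._plant_background()
        self._plant_noise()
        sv_rows = self._sv_rows()
        meta = self._subject_meta()

        self.variants.sort(key=lambda v: (CHROM_ORDER.index(v["chrom"]), v["pos"]))

        vcf_path = out / "cohort.vcf"
        with open(vcf_path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">\n')
            fh.write('##FILTER=<ID=VQSRTrancheSNP99.90to100.00,Description="tranche">\n')
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            for c in CHROM_ORDER:
                fh.write(f"##contig=<ID={c}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(self.subjects) + "\n")
            for v in self.variants:
                gts = "\t".join(v["gts"][s] for s in self.subjects)
                fh.write(
                    f"{v['chrom']}\t{v['pos']}\t.\t{v['ref']}\t{v['alt']}\t100\t"
                    f"{v['vqsr']}\tQD={v['qd']}\tGT\t{gts}\n"
                )

        ann_rows = []
        for v in self.variants:
            af = v["af"]
            # spread known frequencies across the consulted databases
            dbs = {"af_gnomad": "", "af_esp": "", "af_kg1000": "", "af_exac": ""}
            if af is not None:
                dbs["af_gnomad"] = af
                if v["pos"] % 3 == 0:
                    dbs["af_exac"] = af
            ann_rows.append(
                {"chrom": v["chrom"], "pos": v["pos"], "ref": v["ref"],
                 "alt": v["alt"], "gene": v["gene"], "consequence": v["consequence"],
                 "polyphen": v["polyphen"], "sift": v["sift"], **dbs,
                 "clinvar": v["clinvar"], "aac": ""}
            )
        pd.DataFrame(ann_rows).to_csv(out / "annotations.tsv", sep="\t", index=False)

        meta.to_csv(out / "subjects.tsv", sep="\t", index=False)
        pd.DataFrame(
            self.phase_rows,
            columns=["subject_id", "key1", "key2", "cis_support", "trans_support"],
        ).to_csv(out / "phase_evidence.tsv", sep="\t", index=False)

        (out / "genesets.gmt").write_text("\n".join(self._schema_lines()) + "\n")

        bed_rows = sorted(
            ((c, s, e, g) for g, (c, s, e) in self.genome.intervals.items()),
            key=lambda r: (CHROM_ORDER.index(r[0]), r[1]),
        )
        with open(out / "genes.bed", "w") as fh:
            for c, s, e, g in bed_rows:
                fh.write(f"{c}\t{s}\t{e}\t{g}\n")

        pd.DataFrame(sv_rows).to_csv(out / "svs.tsv", sep="\t", index=False)

        candidates = sorted(DISEASE_GENES)
        (out / "candidates.txt").write_text(
            "# candidate laterality/ciliopathy genes\n" + "\n".join(candidates) + "\n"
        )

        truth = pd.DataFrame(
            self.truth_rows,
            columns=["subject_id", "gene", "mechanism", "kind", "n_variants"],
        ).sort_values(["subject_id", "gene", "mechanism"], kind="stable")
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)

        return {
            "vcf": vcf_path,
            "subjects": out / "subjects.tsv",
            "annotations": out / "annotations.tsv",
            "phase_evidence": out / "phase_evidence.tsv",
            "genesets": out / "genesets.gmt",
            "genes_bed": out / "genes.bed",
            "svs": out / "svs.tsv",
            "candidates": out / "candidates.txt",
            "truth": out / "truth.tsv",
        }


def generate(spec: CohortSpec, out_dir: str | Path) -> dict:
    """Generate a full synthetic cohort bundle; returns the file map."""
    return _CohortBuilder(spec).build(out_dir)


# ---------------------------------------------------------------------------
# Published worked example: the fifteen situs inversus subjects, their most
# likely causal recessive mutations, and their handedness records, encoded
# as pipeline input files.  Positions and alleles follow GRCh37.
# ---------------------------------------------------------------------------

# subject_id, group, sex, age, ehi, forced_switch, chd, daily_wet_cough
_T1_SUBJECTS = [
    ("SI02", "si_nonpcd", "male", 50, 0.9, False, False, "unknown"),
    ("SI03", "si_nonpcd", "female", 26, -0.8, False, False, "yes"),
    ("SI04", "si_nonpcd", "male", 23, -1.0, False, True, "no"),
    ("SI05", "si_nonpcd", "male", 27, 0.9, False, False, "no"),
    ("SI07", "si_nonpcd", "female", 35, 0.9, False, True, "unknown"),
    ("SI09", "si_nonpcd", "female", 36, 0.7, True, False, "no"),
    ("SI12", "si_nonpcd", "female", 40, 0.9, False, False, "no"),
    ("SI14", "si_nonpcd", "male", 18, -0.8, False, True, "no"),
    ("SI16", "si_nonpcd", "male", 21, -1.0, False, False, "no"),
    ("SI06", "si_pcd", "male", 46, 1.0, False, False, "yes"),
    ("SI08", "si_pcd", "female", 23, 0.9, False, False, "yes"),
    ("SI11", "si_pcd", "female", 32, 0.9, False, False, "yes"),
    ("SI13", "si_pcd", "male", 48, 0.6, True, False, "yes"),
    ("SI15", "si_pcd", "female", 31, 0.7, False, False, "yes"),
    ("SI17", "si_pcd", "male", 39, 0.5, False, False, "yes"),
]

# subject, type, gene, chrom, pos, ref, alt, MAF (None = absent from
# databases), clinvar annotation, consequence
_T1_VARIANTS = [
    ("SI02", "hom", "PKD1L1", "7", 47870810, "TTCA", "T", 0.00109, "SA | SI",
     "splice_donor_variant"),
    ("SI12", "chet", "DNAH5", "5", 13900415, "A", "C", None, "Kartagener",
     "stop_gained"),
    ("SI12", "chet", "DNAH5", "5", 13769691, "G", "GC", 0.00002, "Kartagener",
     "frameshift_variant"),
    ("SI14", "chet", "CFAP52", "17", 9489207, "T", "A", 0.00066, "SI",
     "missense_variant"),
    ("SI14", "chet", "CFAP52", "17", 9536224, "C", "T", 0.00012, "SI",
     "stop_gained"),
    ("SI16", "hom", "CCDC151", "19", 11533429, "TTCT", "T", 0.00011, "Kartagener",
     "inframe_deletion"),
    ("SI06", "hom", "LRRC6", "8", 133687728, "T", "C", 0.00017, "Kartagener",
     "splice_donor_variant"),
    ("SI08", "hom", "DNAH11", "7", 21659620, "A", "C", 0.00006, "PCD",
     "stop_gained"),
    ("SI11", "chet", "DNAAF1", "16", 84203963, "C", "T", None, "Kartagener",
     "splice_donor_variant"),
    ("SI11", "chet", "DNAAF1", "16", 84193302, "G", "C", 0.00023, "Kartagener",
     "missense_variant"),
    ("SI13", "hom", "CCDC114", "19", 48814907, "C", "CACG", 0.00093,
     "Kartagener", "inframe_insertion"),
    ("SI15", "chet", "DNAH5", "5", 13786289, "A", "T", None, "Kartagener",
     "stop_gained"),
    ("SI15", "chet", "DNAH5", "5", 13753397, "G", "GA", 0.00034, "Kartagener",
     "frameshift_variant"),
    ("SI17", "chet", "DNAH5", "5", 13839638, "C", "T", 0.00021, "Kartagener",
     "splice_acceptor_variant"),
    ("SI17", "chet", "DNAH5", "5", 13753597, "T", "C", 0.00004, "Kartagener",
     "missense_variant"),
]


def make_table1_fixture(out_dir: str | Path) -> dict:
    """Emit the published worked example as a deterministic input bundle.

    Fifteen SI subjects (six PCD, nine non-PCD) with their reported causal
    hom/chet mutations, EHI scores, forced-switch flags and CHD status,
    plus fifteen handedness-matched controls carrying no rare variants.
    Missense rows carry damaging PolyPhen/SIFT calls, as retained variants
    must have had.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    case_rows = list(_T1_SUBJECTS)
    subjects = [sid for sid, *_ in case_rows]
    controls = [f"C{i + 1:02d}" for i in range(15)]
    meta_rows = [
        {"subject_id": sid, "group": group, "sex": sex, "ehi": ehi,
         "forced_switch": fs, "daily_wet_cough": cough, "chd": chd, "age": age}
        for sid, group, sex, age, ehi, fs, chd, cough in case_rows
    ]
    # controls matched for sex and handedness; cosmetic fixed values
    for i, (sid, group, sex, age, ehi, fs, chd, cough) in enumerate(case_rows):
        meta_rows.append(
            {"subject_id": controls[i], "group": "control", "sex": sex,
             "ehi": ehi, "forced_switch": fs, "daily_wet_cough": "no",
             "chd": False, "age": age}
        )
    meta = pd.DataFrame(meta_rows)
    meta.to_csv(out / "subjects.tsv", sep="\t", index=False)

    all_subjects = subjects + controls
    variants = sorted(_T1_VARIANTS, key=lambda v: (CHROM_ORDER.index(v[3]), v[4]))
    with open(out / "cohort.vcf", "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in CHROM_ORDER:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(all_subjects) + "\n")
        for sid, typ, gene, chrom, pos, ref, alt, maf, clinvar, cons in variants:
            gt = "1/1" if typ == "hom" else "0/1"
            gts = "\t".join(gt if s == sid else "0/0" for s in all_subjects)
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t100\tPASS\tQD=20.0\tGT\t{gts}\n")

    ann_rows = []
    for sid, typ, gene, chrom, pos, ref, alt, maf, clinvar, cons in variants:
        damaging = cons == "missense_variant"
        ann_rows.append(
            {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt, "gene": gene,
             "consequence": cons,
             "polyphen": "probably_damaging" if damaging else "unknown",
             "sift": "deleterious" if damaging else "unknown",
             "af_gnomad": "" if maf is None else maf,
             "af_esp": "", "af_kg1000": "", "af_exac": "",
             "clinvar": clinvar, "aac": ""}
        )
    pd.DataFrame(ann_rows).to_csv(out / "annotations.tsv", sep="\t", index=False)

    pd.DataFrame(
        columns=["subject_id", "key1", "key2", "cis_support", "trans_support"]
    ).to_csv(out / "phase_evidence.tsv", sep="\t", index=False)

    # small schema so enrichment can run end to end on the fixture
    genes = sorted({v[2] for v in _T1_VARIANTS})
    filler = [f"GOF{i + 1:03d}" for i in range(60)]
    gmt = [
        "GS0001\tcilium movement\t" + "\t".join(genes + filler[:10]),
        "GS0002\trandom process\t" + "\t".join(filler[10:40]),
        "GS0003\tanother process\t" + "\t".join(filler[30:60]),
    ]
    (out / "genesets.gmt").write_text("\n".join(gmt) + "\n")

    with open(out / "genes.bed", "w") as fh:
        seen = set()
        for sid, typ, gene, chrom, pos, *_ in variants:
            if gene in seen:
                continue
            seen.add(gene)
            fh.write(f"{chrom}\t{max(pos - 50_000, 0)}\t{pos + 50_000}\t{gene}\n")

    pd.DataFrame(
        columns=["subject_id", "chrom", "start", "end", "sv_type", "quality_pass"]
    ).to_csv(out / "svs.tsv", sep="\t", index=False)

    candidates = sorted(set(genes) | {
        "ZIC3", "CCDC11", "NME7", "MMP21", "ROCK2", "RAI2", "KIF3A", "KIF3B",
        "MYO1D", "MYO1C", "SLC6A4", "SLC18A2",
    })
    (out / "candidates.txt").write_text(
        "# candidate laterality/ciliopathy genes\n" + "\n".join(candidates) + "\n"
    )

    truth = pd.DataFrame(
        [
            {"subject_id": sid, "gene": gene, "mechanism": typ, "kind": "causal",
             "n_variants": 1 if typ == "hom" else 2}
            for sid, typ, gene, *_ in _T1_VARIANTS
        ]
    ).drop_duplicates().sort_values(["subject_id", "gene"], kind="stable")
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)

    return {
        "vcf": out / "cohort.vcf",
        "subjects": out / "subjects.tsv",
        "annotations": out / "annotations.tsv",
        "phase_evidence": out / "phase_evidence.tsv",
        "genesets": out / "genesets.gmt",
        "genes_bed": out / "genes.bed",
        "svs": out / "svs.tsv",
        "candidates": out / "candidates.txt",
        "truth": out / "truth.tsv",
    }
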