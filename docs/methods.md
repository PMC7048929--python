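# Methods

## The analysis model

`situscan` formalizes a case/control interpretation procedure for small
whole-genome cohorts with a suspected monogenic phenotype (here: *situs
inversus*, with and without primary ciliary dyskinesia). Its core
assumptions:

* **Variant calling is upstream.** The pipeline consumes a jointly-called
  multi-sample VCF with VQSR FILTER labels and QD, plus an annotation
  sidecar (gene, consequence, impact, PolyPhen/SIFT, per-database allele
  frequencies, ClinVar phenotype strings). It never computes alignments,
  calls, or functional annotations.
* **Monogenic, highly penetrant causes.** A recessive cause is a gene
  with two disabled copies in one subject — one homozygous mutation, or
  ≥ 2 distinct heterozygous mutations *in trans*. Compound-het pairs with
  unknown phase are retained as "possible" compound heterozygotes; only
  pairs that read evidence places definitely on the same haplotype
  (cis support ≥ `min_cis_reads` spanning fragments and zero trans
  fragments) are discarded, since the second gene copy is then intact.
* **Controls as a technical filter.** Any gene recessively (or, under the
  dominant model, dominantly) mutated in an unaffected control is removed
  from every case list. This is deliberately aggressive: it removes
  recurrent caller artifacts and variants common in the population but
  missing from frequency databases, at the cost of occasionally removing
  a true cause that a control happens to share. The exclusion is mirrored
  (case genes removed from control lists) before control enrichment is
  tested, so the control list contains genes exclusively mutated in
  controls.
* **Interpretation by annotation, not assertion.** A case is "solved"
  only when a surviving assignment's ClinVar strings match the phenotype
  queries; PCD-gene matches outrank situs-inversus/heterotaxy matches
  because PCD genes remain the likely cause even in cases without a PCD
  diagnosis (reduced penetrance). Everything else is reported unsolved.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| `tranche_cut` | 99.9 | VQSR sensitivity % | discard tranche ≥ 99.9 (closed bound); PASS always kept |
| `qd_min` | 9 | QD | remove QD ≤ 9; missing QD kept with a warning |
| `call_rate_min` | 0.8 | fraction | remove call rate ≤ 0.8 |
| `recessive_max_af` | 0.005 | allele frequency | exclude AF ≥ 0.005 in any consulted database |
| `dominant_max_af` | 5 × 10⁻⁵ | allele frequency | keep AF ≤ threshold (inclusive); see below |
| `min_cis_reads` | 1 | fragments | one definite cis fragment with zero trans suffices to discard a chet pair |
| enrichment bounds | 15 / 500 / 2 | genes | min set, max set, min intersection |
| significance | 0.01 | adjusted p | per-list correction, then fixed cutoff |
| `sv_min_reciprocal_overlap` | 0.5 | fraction | control subtraction; BND by ±500 bp breakpoint proximity |
| `p0` | 0.10 | rate | population rate of left-handedness |
| EHI ambidexterity bound | 0.5 | \|EHI\| | strict: \|EHI\| < 0.5 excluded, a printed 0.5 still counts |

Boundary semantics are exactly as stated: site filters remove the closed
bound (≤ 9, ≤ 0.8, ≥ 99.9); the recessive AF rule excludes at ≥ 0.005.
The dominant rule is phrased in the literature as a "maximum threshold",
which we read inclusively (keep at AF = 5 × 10⁻⁵) for symmetry with the
recessive exclusion written on the excluded side. Variants with no
frequency in any database always pass both AF filters — novel variants
are the ones a rare-disease screen must keep.

The consequence→impact mapping (VEP/Gemini-style severity classes) ships
as `data/impact_map.tsv` and can be overridden; an annotation with an
unmapped consequence passes impact selection only if it carries an
explicit impact value. PolyPhen `possibly_damaging` counts as non-benign
but does not rescue a SIFT-tolerated call; unknown predictions neither
remove nor rescue.

## Multiple-testing correction

The hierarchical set-aware correction used by g:Profiler (gSCS) is
proprietary; we provide Bonferroni (over all size-eligible sets, not just
those reaching the intersection bound), Benjamini–Hochberg, and
`empirical_sets`: a resampling estimate of the family-wise null that
draws random same-size queries from the background and records the
minimum raw p per draw; the adjusted value is the (plus-one) fraction of
null minima at or below the observed p. Published adjusted values from
hierarchical methods are therefore not expected to be matched
numerically, only qualitatively. Optional parent–child pruning
(`prune_hierarchy`, off by default) keeps the most significant of
directly related tested sets, approximating "moderate" hierarchical
redundancy filtering when an ontology edge file is supplied.

## The synthetic cohort generator

`CohortSpec` defaults encode the study conditions the pipeline targets:
15 cases (6 PCD-like, 9 non-PCD) and 15 controls; planted causal genes
covering every mechanism (hom, chet, hemizygous-X, dominant het) in real
laterality/PCD gene symbols with appropriate ClinVar strings; one planted
*cis* compound-het decoy with definite-cis read evidence; per-subject
background rare deleterious mutations with the recessively-mutated gene
count drawn uniformly from 5–14 (so that, with at most one planted
causal gene, per-subject totals stay in the 5–15 range reported for real
data); and filter-exercising noise — failing tranches, low QD, low call
rate, common alleles, synonymous calls, and every branch of the
PolyPhen/SIFT cross-rules.

Background allele frequencies follow a mixture: 0.3 point mass at
"absent from every database" plus a Beta(1.2, 600) low-frequency
component, so both AF thresholds and the unknown-AF path carry traffic.
With a 2000-gene background pool and a shared-artifact rate of 0.05, the
expected number of control-excluded genes (planted shared artifacts plus
chance case/control overlap) sits near the ~17 observed at real-data
scale. SV calls (2–5 per subject, spans up to ~1.5 Mb, 40% duplicated
into a control) put the mean number of SV-affected genes per case near
the real-data scale of ~10.

Same spec and seed give byte-identical output files: all randomness runs
through one `numpy` Generator and files are written in deterministic
order.

What the generator does **not** emulate: linkage disequilibrium and
haplotype structure, read-level data (no FASTQ/BAM; phase evidence is
already summarized into cis/trans fragment counts), realistic gene
lengths and variant density, annotation disagreement between tools, and
population stratification. Passing tests on synthetic cohorts therefore
demonstrate the *logic* of filtering, assignment, exclusion and testing
— not robustness to the annotation noise and calling artifacts of real
genomes, which the control-exclusion step only partially addresses.

The published 15-subject table is also encoded as a deterministic
fixture (`make_table1_fixture`): subject metadata (group, sex, EHI,
forced-switch, CHD), each reported causal hom/chet mutation with its
printed position, MAF and ClinVar abbreviation, and 15 handedness-matched
controls carrying no rare variants. Missense rows are given damaging
PolyPhen/SIFT calls, as retained variants must have had; chromosomes for
the named genes follow GRCh37.

## Numerical choices and degenerate inputs

* The binomial upper tail is summed term-by-term with exact integer
  binomial coefficients (no normal approximation) and clamped to [0, 1];
  scipy's exact test serves as an independent cross-check in the tests.
* Hypergeometric tails come from `scipy.stats.hypergeom.sf`; the unit
  tests verify them against exhaustive enumeration of all draws on small
  backgrounds.
* Allele normalization trims shared trailing then leading bases (one
  anchor base kept for indels) and, given a reference window, left-aligns
  indels to the smallest admissible position; the operation is
  idempotent and never changes the edited haplotype.
* Ambidextrous subjects (|EHI| < 0.5) are excluded from handedness
  numerator and denominator; empty groups tabulate as (0, 0) with a
  warning and no test.
* Assignments are emitted in sorted (gene, subject) order and are
  invariant to input row order; classification tie-breaks are by gene
  symbol with an explicit `ambiguous` flag.
* Records missing QD or call rate are kept and logged, never crashed on;
  phase evidence referencing unknown variant keys is ignored with a
  warning; an invalid cohort spec fails before any file is written.

## Design choices where the design was open

* **Tranche parsing**: any FILTER other than PASS/"." is treated as a
  tranche label; its numeric lower bound (e.g. 99.9 from
  `VQSRTrancheSNP99.90to100.00`) is compared against the cut.
* **Gene identity is the symbol string**; annotation sources must be
  harmonized upstream (e.g. *CFAP52* vs *WDR16*).
* **X handling**: without a PAR definition the whole chromosome follows
  the X rule; males with any single qualifying X variant are hemizygous,
  and an X variant in a subject of unknown sex is a hard error.
* **Control exclusion counts any control assignment**, whether its chet
  phase is retained or unknown — the conservative reading for an
  artifact filter.
* **ClinVar matching** is case-insensitive substring for full phrases;
  short abbreviations (SI, SA, HTX, PCD) match only as whole
  `|`-separated tokens, because a bare substring "SI" over-matches.
* **Scale of the shipped analyses**: tests and the acceptance script run
  the full pipeline over 20 generator seeds and use a 500-gene, 40-set
  schema with 300 replicates for the type-I simulation — sizes chosen so
  the complete suite runs in well under a minute while every rate is
  estimated with usable binomial error.

## Known limitations

* The gene-level recessive rule cannot distinguish two hets in trans from
  two hets in cis when no spanning fragments exist; such genes stay
  "possible compound heterozygous", as they should.
* No trio or statistical phasing, no de-novo calling, no liftover, no
  non-coding interpretation beyond splice-site classes.
* Enrichment backgrounds are defined by the supplied GMT (union of set
  members); results are only as good as the schema.
* The control-exclusion step assumes cases and controls were jointly
  called; applying it across separately-called batches would remove far
  too much.
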