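# situscan

Rare-variant prioritization and interpretation for *situs inversus* (SI)
cohorts — small case/control whole-genome studies asking whether a mirror
reversal of the visceral organs has a monogenic cause, and whether the
mutated genes of a subject group share biology.

Roughly a quarter of people with SI have primary ciliary dyskinesia (PCD),
a recessive disorder of motile cilia; the genetics of the remaining
non-PCD SI majority is poorly understood. `situscan` implements the full
interpretation pipeline such a study needs, for geneticists working from a
jointly-called, annotated multi-sample VCF:

1. **Site QC** — discard VQSR tranches ≥ 99.9%, quality depth ≤ 9,
   call rate ≤ 0.8; decompose multi-allelics; minimal/left-aligned allele
   normalization.
2. **Deleteriousness filters** — keep coding MEDIUM/HIGH and non-coding
   HIGH impact variants; drop synonymous variants; drop MEDIUM variants
   called benign by PolyPhen (unless SIFT-deleterious) or tolerated by
   SIFT (unless PolyPhen probably-damaging).
3. **Frequency filters** — recessive model: exclude known population
   frequency ≥ 0.005 in gnomAD/ESP/1000G/ExAC; dominant model: keep only
   ≤ 5 × 10⁻⁵. Variants absent from every database are retained.
4. **Inheritance models** — a gene is *recessively mutated* in a subject
   when homozygous for one mutation or carrying ≥ 2 distinct heterozygous
   mutations (possible compound heterozygote, chet); on chromosome X
   females need two mutations, males one (hemizygous). Read-backed phase
   evidence discards chet pairs that are definitely *cis*. Any gene
   recessively mutated in a control is excluded from case lists (and
   mirrored back), stripping technical artifacts and unannotated common
   variants.
5. **Interpretation** — assigned genes are matched against ClinVar
   phenotype queries (*situs inversus*; heterotaxy/situs ambiguus;
   PCD/ciliary dyskinesia/Kartagener; left-right; asymmetry/laterality)
   and a candidate laterality gene list; each case is classified
   solved-via-PCD-gene / solved-via-laterality-gene / unsolved.
6. **Gene-set over-representation** — per subject group, hypergeometric
   upper-tail test of the mutated gene list against a GMT schema
   (set size 15–500, intersection ≥ 2), with Bonferroni, Benjamini–
   Hochberg or an empirical min-p resampling correction; significance at
   adjusted p < 0.01.
7. **SV screen** — control subtraction by reciprocal overlap, then gene
   and candidate-list intersection of the surviving structural variants.
8. **Handedness** — the exact one-tailed binomial test for an excess of
   natural left-handers (population rate p₀ = 0.10), with the Edinburgh
   Handedness Inventory forced-switch override:

   P(X ≥ k), X ~ Binomial(n, p₀) = Σⱼ₌ₖⁿ C(n, j) p₀ʲ (1 − p₀)ⁿ⁻ʲ

Because such cohorts are rarely shareable, the package ships a
**synthetic cohort generator** (`situscan.synthetic`) that emits a
complete input bundle — VCF, annotation sidecar, metadata, phase
evidence, GMT, gene BED, SV calls, candidate list — plus a truth table of
every planted causal (subject, gene, mechanism), so the whole pipeline is
testable end to end, and a deterministic fixture encoding a published
15-subject SI cohort.

## Worked example

The encoded 15-subject cohort (6 PCD, 9 non-PCD) runs in seconds:

```bash
situscan fixture-table1 --out fixture/
situscan run --config run.yaml   # pointing at the fixture files
```

which prints the per-subject report:

```
subject_id     group                 status mechanism    gene    clinvar natural_handedness
      SI02 si_nonpcd solved_laterality_gene       hom  PKD1L1    SA | SI              right
      SI03 si_nonpcd               unsolved                                            left
      ...
      SI16 si_nonpcd        solved_pcd_gene       hom CCDC151 Kartagener               left
      SI06    si_pcd        solved_pcd_gene       hom   LRRC6 Kartagener              right
      ...
```

All six PCD cases are solved through ClinVar-annotated PCD genes; among
the nine non-PCD cases two are solved through PCD genes (reduced
penetrance), two through non-PCD laterality genes (*PKD1L1*, *CFAP52*),
and five remain unsolved. Five of the nine non-PCD cases are naturally
left-handed (one right-hander was forced to switch from left in
childhood), and the handedness report gives the exact binomial tail:

```
$ situscan handedness 5 9 0.10
P(X >= 5 | n=9, p0=0.1) = 0.00089092
```

i.e. p ≈ 0.0009 against a 10% population rate of left-handedness.

Single stages run standalone on intermediate TSVs (`situscan filter`,
`assign`, `classify`, `enrich`, `sv-screen`), and `situscan generate
--seed N --out DIR` emits a synthetic cohort bundle.

## Layout

```
src/situscan/
  variant_io.py    VCF/metadata reading, site QC, allele normalization
  deleterious.py   impact classes, PolyPhen-SIFT cross-rules, AF thresholds
  inheritance.py   recessive/dominant/X-linked assignment, phase + control exclusion
  matching.py      ClinVar term queries, candidate list, case classification
  enrichment.py    GMT schema, hypergeometric ORA, corrections
  sv_screen.py     SV control subtraction and gene overlap
  handedness.py    exact binomial test, per-group tabulation
  synthetic.py     cohort generator and the published-table fixture
  pipeline.py      orchestration, reports, manifest
  cli.py           `situscan` command group
```

See `docs/methods.md` for the model, parameter defaults, and what the
synthetic cohorts do and do not emulate.
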