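# actscreen

Screening exome-sequenced cohorts for **medically actionable genotypes**, with
the population-genetic machinery needed when the cohort is a genetic isolate.

Research cohorts increasingly return clinically actionable findings to their
participants. The screen implemented here follows the genome-first approach
used for founder populations such as the Northern Isles of Scotland: variants
falling in genes on the ACMG secondary-findings list (v3.2, 81 genes) are
matched against ClinVar, kept when classified pathogenic or likely pathogenic
(P/LP) with review status of one star or higher, and converted into
*actionable genotypes* under per-gene rules — a single heterozygote suffices
for a dominant gene; recessive genes require a homozygote or a (putative)
compound heterozygote; hereditary hemochromatosis counts only `HFE`
p.Cys282Tyr homozygotes; and for `TTN` only truncating (LoF) variants are
reportable. Because founder cohorts carry drifted alleles at many times their
cosmopolitan frequency, the package also quantifies founder effects and the
carrier arithmetic they imply.

The package is aimed at researchers running or auditing return-of-results
pipelines, and at anyone who needs its components individually: a careful
variant matcher, an exact Hardy-Weinberg test, or a reproducible synthetic
founder-cohort generator.

## What it does

- **ClinVar I/O** (`actscreen.clinvar`) — parse `variant_summary.txt`-dialect
  tables, derive 0–4 star ratings from review status, filter to P/LP at a
  minimum star level, aggregate duplicate rows and drop
  pathogenic-versus-benign conflicts.
- **Variant matching** (`actscreen.variants`, `actscreen.merge`) — parsimony +
  left-alignment normalization so that indels in repeat context (e.g. a 5-bp
  deletion renderable as `GCCAAG[CTAAG/-]ACT` or `GCC[AAGCT/-]AAGACT`) join on
  coordinates, with a protein-level fallback merge (same gene, transcript and
  HGVS p. change) for renderings that differ genomically.
- **Genotype QC** (`actscreen.qc`) — removes monomorphic variants, variants
  with >2% missingness or Hardy-Weinberg exact p < 1e-6, and individuals with
  >3% missingness.
- **Actionability** (`actscreen.actionability`) — zygosity rules per gene,
  somatic-mosaic flagging from allelic read depths (VAF below threshold plus
  an exact binomial test against 0.5), co-occurrence detection, cohort tallies.
- **Founder genetics** (`actscreen.founder`) — subcohort allele frequencies,
  fold uplift versus a reference population, the drifted-variant filter
  (>50-fold uplift, minor-allele count ≥ 5, pre-1800 pedigree origin), carrier
  and affected expectations under random mating (2q(1−q), q², 1−(1−q)²),
  depletion and penetrance statistics.
- **Reporting** (`actscreen.reporting`) — clinical-review overrides, consent
  overlay, and a return-of-results summary that partitions every person with
  an actionable genotype into exactly one category.
- **Synthetic cohorts** (`actscreen.synth`) — a fully seeded generator of
  two-archipelago founder cohorts with planted drifted alleles, compound
  heterozygotes, a named-allele homozygote gene, singletons with external
  ancestry, one somatic mosaic, misrendered indels and QC failures, plus a
  truth table for exact scoring.

## Worked example

```python
import actscreen as acts

# generate a small synthetic founder cohort and screen it
bundle = acts.generate_cohort(acts.minimal_config(seed=1), out_dir="cohort")
res = acts.screen(bundle.paths["vcf"], bundle.paths["clinvar"],
                  bundle.paths["rules"], bundle.paths["reference"])
t = res.tally
print(t.n_individuals_with_actionable, t.n_actionable_genotypes,
      t.n_distinct_variants, t.n_genes, t.percent_of_cohort)
# -> 39 42 11 9 19.6

# carrier arithmetic: summed P/LP allele frequency 1.12% in one subcohort
g = acts.gene_risk_summary("ATP7B", "shetland", [0.0112], "AR")
print(g.carrier_one_in, g.affected_one_in)
# -> 45 8000
```

The first line says 39 of the 199 QC-passed synthetic individuals (19.6%)
carry 42 actionable genotypes at 11 variants in 9 genes — the generator
plants alleles at much higher frequencies than a real cohort so every rule
fires at desk scale. The second says that with a summed pathogenic allele
frequency of 1.12%, about 1 in 45 people are carriers and about 1 in 8,000
are expected to be homozygous or compound-heterozygous under random mating.

The same stages are available from the shell:

```bash
actscreen simulate --preset minimal --seed 1 --out cohort
actscreen screen --vcf cohort/cohort.vcf --clinvar cohort/clinvar.tsv \
    --rules cohort/gene_rules.tsv --reference cohort/reference.fa --out screen_out
actscreen report --findings screen_out/findings.tsv --consent consent.tsv
```

## Documentation

See `docs/methods.md` for the model and procedure, parameter defaults and
their rationale, what the synthetic generator does and does not emulate, and
known limitations.
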