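# Methods

This note documents the models and procedures implemented in `actscreen`,
the defaults chosen where the design was open, and the limits of what the
synthetic benchmarks demonstrate.

## The screening procedure

The screen converts a cohort VCF, a ClinVar-dialect classification table and
a gene-rules table into per-individual actionable genotypes.

**Classification filtering.** ClinVar rows are kept on the requested assembly
only. Review-status strings map to the standard 0–4 star scale
(practice guideline → 4; reviewed by expert panel → 3; criteria provided,
multiple submitters, no conflicts → 2; single submitter or conflicting → 1;
no assertion criteria → 0; unknown strings → 0 with a warning). Clinical
significance strings are lowercased and split on "/" so combined renderings
collapse onto {P, LP, P_LP, B, LB, VUS, conflicting, other}. The retained set
is P/LP/P_LP with ≥ 1 star (configurable). When several rows describe one
CHROM:POS:REF:ALT, the maximum star rating wins; if the pathogenic and benign
families each have support at ≥ 1 star the variant is excluded outright —
the star ladder itself treats conflict as disqualifying, and a screen that
returns results to people should be conservative. ClinVar's consequence is
not a column of the `variant_summary` dialect, so the molecular consequence
is derived from the HGVS strings in the Name field (fs → frameshift,
Ter → stop_gain, aa→aa → missense, intronic offsets ±1,2 → essential splice,
±3–8 → splice region); a cohort-side `CONSEQ` annotation always overrides
this derivation.

**Variant normalization and matching.** Both sides of the merge are
normalized before joining: shared trailing bases trimmed, the allele pair
left-shifted through any repeat run, shared leading bases trimmed to the
single indel anchor (the standard parsimony/left-alignment algorithm; SNVs
pass through; the operation is idempotent). A REF allele that disagrees with
the reference is a hard error since it indicates a build mismatch. The
coordinate join requires equality of all four of CHROM, POS, REF, ALT —
joins on rsid are unsafe because one rsid can cover several alleles.
Variants left unmatched go through the protein-level fallback: a match
requires the same gene, the same transcript accession (version-insensitive —
classification snapshots drift in versions, not numbering; never across
transcripts, because residue numbering is isoform-specific) and an identical
parsed protein change. The p. grammar covers substitutions, Ter (both
`p.Trp31134Ter` and the predicted form `p.(Trp31134*)`), frameshift (any
`fs`/`fsTer12` suffix collapses to `fs`), del/dup, `=` and `?`; strings
outside the grammar are counted, never silently dropped. Matches carry their
provenance ("coordinate" or "protein-level") through to the findings.

**Genotype QC.** Individuals with more than 3% missing calls are removed
first, then variants that are monomorphic, have more than 2% missing calls,
or fail the Hardy-Weinberg exact test at p < 1e-6, in that fixed order so the
recorded reason is deterministic. Thresholds are strict inequalities: a
variant at exactly 2% missingness survives. The HWE test is the exact
conditional test (two-sided by probability ordering over all heterozygote
counts compatible with the observed allele counts), not the chi-square
approximation — at the 1e-6 tail the asymptotic test is unreliable. The
filters are generic over any genotype matrix; in the source study they were
applied to array genotypes, and this package applies them to whatever matrix
it is given.

**Actionability rules.** Each gene's rule states inheritance (AD/AR/XL) and
the reportable variant classes: `all_P_LP`, `LoF_only` (stop-gain,
frameshift, essential splice donor/acceptor; splice-region changes are *not*
LoF), or `named_variant_hom_only` with an explicit allele. Dominant genes:
heterozygote → finding; homozygote → finding (counted once — strictly more
evidence than a heterozygote). Recessive genes: homozygote → finding; two or
more distinct P/LP heterozygous variants → one compound-heterozygote finding
per gene, explicitly labeled *putative* because short-read exomes cannot
phase distant variants (trans is assumed; downstream clinical verification
is the safeguard); a single heterozygote is recorded as carrier-only, never
a finding. Named-allele rules report only homozygotes for that allele and
ignore heterozygotes and other alleles of the gene. A matched variant whose
gene lacks a rule is a hard error. The packaged default rule table covers
the genes attested in the source cohort (23 genes); it is a convenience
default, not a reproduction of the full official 81-gene list — users supply
rows for further genes in the same dialect.

**Mosaic flagging.** A heterozygous call with allelic depths is flagged as a
probable somatic mosaic when its variant allele fraction is below 0.25 *and*
a two-sided exact binomial test rejects reads ~ Binomial(depth, 0.5) at
0.001. The double gate separates a genuinely skewed call (e.g. 13 alternate
of 85 reads, VAF 15%) from low-depth noise. Both knobs are configurable; the
threshold is a package default, since the observation that motivated it is a
single flagged call, not a stated universal cutoff. Flagged genotypes are
excluded from the actionable counts and reported separately.

**Tallies and return of results.** The cohort tally reports distinct
individuals, genotypes, variants and genes, and the percentage of the cohort
(one decimal, computed on the pre-supplemental individuals). "Supplemental"
individuals support post-hoc additions that extend the reportable set
without re-running the screen — the motivating case is males carrying a
dominant allele whose direct clinical action is female-specific, added after
an ethics amendment; each adds one person and one genotype. Review
overrides mark findings not returnable but never delete them (audit
preservation). The return-of-results summary assigns every person with an
actionable genotype to exactly one category: not-returnable takes precedence
only when *none* of the person's findings is returnable (if one is, a letter
can still be sent, so consent decides); then consented and consenting
next-of-kin count as letters sent, with no-reply, declined and
deceased-without-request as the remaining categories. The partition is
checked: category sums must equal the total.

## Founder-effect quantification

Per (variant, subcohort): minor-allele count, allele number (2 × non-missing
calls) and MAF, with minor-allele orientation fixed cohort-wide. Fold uplift
is MAF/reference-MAF; when the reference has seen no copies the ratio is
undefined and a lower bound MAF × reference-allele-number is reported
instead. A variant is *drifted* when the uplift exceeds 50-fold, the
minor-allele count is at least 5, and an externally supplied genealogy flag
places its origin before ~1800 CE — genealogy is an input, never inferred.
Frequencies are raw counts over all QC-passed individuals with no kinship
down-weighting; in a founder cohort with deep relatedness this overstates
the effective sample size, which matters for standard errors but not for the
point estimates reported here.

Carrier/risk arithmetic assumes random mating. For a recessive gene with
summed P/LP allele frequency q: carriers 2q(1−q), affected q². For dominant
genes the carrier frequency is 1−(1−q)², the proportion with at least one
copy — with this convention a 0.5% summed frequency prints as exactly
"1 in 100", without a 2q approximation. Printed "one in N" figures follow
the rounding conventions population summaries use — carrier reciprocals to
the nearest 5, recessive risk to the nearest 1000, dominant carriers to the
nearest 100 — and the raw reciprocals are always reported alongside.
`carrier_to_risk` inverts 2q(1−q) (smaller root); it and the forward
arithmetic are mutual inverses across q ∈ [0.001, 0.1], which the tests
check on the full grid. Depletion of a variant class is measured as a rate
ratio with a two-sided Fisher exact p (scipy); penetrance among carriers is
compared with background prevalence the same way.

## The synthetic cohort generator

The generator emulates the statistical structure the screen assumes, not the
biology underneath it. Two subcohorts ("orkney", "shetland") are drawn
binomially under Hardy-Weinberg at configured per-subcohort frequencies on
one artificial contig per gene (so no reference download is needed). On top
of the draws it plants: guaranteed compound heterozygotes; a named-allele
homozygote gene at high frequency (homozygotes arise from the draws, keeping
the site in HWE); singleton variants with exactly one carrier each, labeled
with recent external ancestry; one somatic mosaic whose read depths are
drawn at a true VAF of 0.15 and depth 85 (matching the read-depth scale of
the motivating data; ordinary calls draw depth ~ Poisson(85)); indels in
repeat context, a configurable fraction of which are *written to the VCF in
a non-left-aligned rendering*; one variant whose classification-table
coordinates deliberately differ from the cohort rendering while sharing the
protein change (a synthetic stand-in for the repeat-context deletions that
only the protein merge recovers); decoy classification rows (benign 3-star,
pathogenic 0-star, wrong assembly); and QC casualties (a ~5%-missing
variant, a zero-heterozygote excess-homozygote variant, a ~5%-missing
individual). Fifty neutral common SNVs pad the matrix so one missing call is
a realistically small fraction of an individual's genotypes.

All randomness flows through one seeded generator; the same seed regenerates
the bundle byte-for-byte. The truth table is derived from the *realized*
genotype matrix (not the plant list) by independent straight-line logic, so
chance events — an extra compound heterozygote from independent draws, a
singleton call lost to a planted QC failure — are scored correctly. The
`paper-mimic` preset uses subcohort sizes 2090/2108 and drifted-allele
frequencies shaped like the motivating study's founder-effect table; the
`minimal` preset exercises every behaviour at 100+100 individuals.

What the generator does **not** emulate: linkage disequilibrium and
relatedness (genotypes are independent across individuals and variants),
realistic site-frequency spectra, sequencing error, pedigree structure, and
sample mix-ups (the source study's sex-concordance checks are out of scope).
Passing the end-to-end benchmarks therefore demonstrates the correctness of
the matching, QC and rule logic under the stated sampling model — not
robustness to annotation errors or cryptic relatedness in real data.

## Numerical choices

- HWE exact test: log-space weights normalized within the support; the
  p-value sums configurations with probability ≤ observed × (1 + 1e-12), the
  usual guard against float ties.
- Exact binomial and Fisher tests come from scipy (`binomtest`,
  `fisher_exact`); the test suite checks both against integer-exact
  enumeration oracles on all small tables.
- Reciprocal rounding uses round-half-to-even at the stated granularity and
  never rounds to zero (a nonzero frequency cannot print as "1 in 0").
- Monomorphic sites short-circuit to p = 1; an all-zero genotype table is an
  error, not a p-value.
- Problem sizes in the test suite and acceptance script (100-seed end-to-end
  runs at 60+60 individuals; drifted-flag Monte-Carlo at 2000-individual
  subcohorts, expected minor-allele count 20) were chosen so each property is
  measured at the scale where its expected behaviour is unambiguous.

## Known limitations

- The screen consumes consequence and protein annotations from the VCF INFO
  field (`GENE`, `CONSEQ`, `TX`, `HGVSC`, `HGVSP`, per-ALT); it does not run
  an annotator. Wrong annotations propagate.
- Compound heterozygotes are unphased by construction; some will be cis.
- ClinVar content is snapshot-dependent; the same cohort screened against a
  later table can yield different findings. The package records counts of
  every exclusion class so runs can be compared.
- The "known pathogenicity" requirement is interpreted as germline P/LP
  classification; somatic and drug-response assertions are not considered.
- Manual curation of borderline variants cannot be automated; it enters the
  pipeline only as the review-override table.
- X-linked rules are structurally supported but untested against real
  hemizygous data (the motivating cohort had no X-linked findings).
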