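"""From matched P/LP genotypes to actionable genotypes and cohort tallies.

An *actionable variant* is a classified P/LP allele in a gene on the
secondary-findings list; an *actionable genotype* is the configuration that
makes it reportable for a person: one copy suffices in a dominant gene, while
recessive genes require two copies — a homozygote or a (putative, unphased)
compound heterozygote — and the hemochromatosis special case requires
homozygosity for one named allele.  Single heterozygotes in recessive genes
are carriers, never findings.  Read-depth-skewed heterozygotes are flagged as
probable somatic mosaics and excluded from the counts.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from scipy.stats import binomtest

from .matrix import ALT_HOM, HET, MISSING, GenotypeMatrix
from .merge import Match
from .rules import GeneRule, rules_by_gene
from .variants import VariantKey

log = logging.getLogger(__name__)

ZYGOSITY_PATTERNS = (
    "dominant_het",
    "dominant_hom",
    "recessive_hom",
    "compound_het_putative",
)


@dataclass(frozen=True)
class ActionableGenotype:
    individual_id: str
    gene_symbol: str
    variants: tuple[VariantKey, ...]
    zygosity_pattern: str
    provenance: tuple[str, ...]
    returnable: bool = True
    mosaic_flag: bool = False

    def __post_init__(self) -> None:
        if self.zygosity_pattern not in ZYGOSITY_PATTERNS:
            raise ValueError(f"unknown zygosity pattern {self.zygosity_pattern!r}")
        if self.zygosity_pattern == "compound_het_putative" and len(self.variants) < 2:
            raise ValueError("compound het requires at least two distinct variants")
        if self.zygosity_pattern != "compound_het_putative" and len(self.variants) != 1:
            raise ValueError("single-variant pattern carries exactly one variant")


@dataclass(frozen=True)
class CarrierOnly:
    """A single recessive-acting P/LP copy: informative, not actionable."""

    individual_id: str
    gene_symbol: str
    variant: VariantKey


@dataclass(frozen=True)
class MosaicCall:
    individual_id: str
    gene_symbol: str
    variant: VariantKey
    vaf: float
    ref_reads: int
    alt_reads: int


def flag_mosaic(
    ref_reads: int,
    alt_reads: int,
    vaf_threshold: float = 0.25,
    binomial_alpha: float = 0.001,
) -> tuple[float, bool]:
    """Variant-allele fraction of a het call, and whether it looks mosaic.

    Flagged iff the VAF is below ``vaf_threshold`` *and* a two-sided exact
    binomial test rejects reads ~ Binomial(depth, 0.5) at ``binomial_alpha``;
    the double gate avoids flagging low-depth noise on the threshold alone.
    """
    depth = ref_reads + alt_reads
    if depth < 1:
        raise ValueError("zero total read depth")
    vaf = alt_reads / depth
    if vaf >= vaf_threshold:
        return vaf, False
    p = binomtest(alt_reads, depth, 0.5).pvalue
    return vaf, bool(p < binomial_alpha)


@dataclass
class ActionabilityResult:
    findings: list[ActionableGenotype]
    carrier_only: list[CarrierOnly]
    mosaics: list[MosaicCall]


def call_actionable_genotypes(
    genotypes: GenotypeMatrix,
    matches: Sequence[Match],
    rules: Iterable[GeneRule],
    vaf_threshold: float = 0.25,
    binomial_alpha: float = 0.001,
) -> ActionabilityResult:
    """Apply the gene rules to per-individual genotypes at matched variants.

    ``genotypes`` is the QC-passed matrix restricted (at least) to the matched
    variants; a matched variant whose gene has no rule is a hard error — the
    rule table is incomplete, silence would misclassify.
    """
    rule_map = rules_by_gene(rules)
    index = genotypes.variant_index()
    by_variant: dict[VariantKey, Match] = {m.variant: m for m in matches}

    findings: list[ActionableGenotype] = []
    carriers: list[CarrierOnly] = []
    mosaics: list[MosaicCall] = []

    # per-individual, per-gene accumulation of het/hom calls
    for m in matches:
        if m.variant not in index:
            continue  # removed by QC
        gene = m.record.gene_symbol
        if gene not in rule_map:
            raise ValueError(
                f"matched variant {m.variant} maps to gene {gene!r} absent from the rule table"
            )

    per_ind: dict[str, dict[str, list[tuple[VariantKey, int, str]]]] = {}
    for m in matches:
        j = index.get(m.variant)
        if j is None:
            continue
        gene = m.record.gene_symbol
        for si, ind in enumerate(genotypes.individuals):
            call = int(genotypes.calls[si, j])
            if call in (HET, ALT_HOM):
                if call == HET and genotypes.ref_depth is not None:
                    rd = int(genotypes.ref_depth[si, j])
                    ad = int(genotypes.alt_depth[si, j])
                    if rd != MISSING and ad != MISSING and rd + ad >= 1:
                        vaf, flagged = flag_mosaic(rd, ad, vaf_threshold, binomial_alpha)
                        if flagged:
                            mosaics.append(MosaicCall(ind, gene, m.variant, vaf, rd, ad))
                            continue
                per_ind.setdefault(ind, {}).setdefault(gene, []).append(
                    (m.variant, call, m.provenance)
                )

    for ind in genotypes.individuals:
        genes = per_ind.get(ind)
        if not genes:
            continue
        for gene, calls in sorted(genes.items()):
            rule = rule_map[gene]
            calls = sorted(calls)
            if rule.actionable_classes == "named_variant_hom_only":
                named = rule.named_variant
                for variant, zyg, prov in calls:
                    if variant == named and zyg == ALT_HOM:
                        findings.append(
                            ActionableGenotype(ind, gene, (variant,), "recessive_hom", (prov,))
                        )
                # hets and other alleles of the gene are deliberately ignored
                continue
            if rule.inheritance in ("AD", "XL"):
                for variant, zyg, prov in calls:
                    pattern = "dominant_het" if zyg == HET else "dominant_hom"
                    findings.append(
                        ActionableGenotype(ind, gene, (variant,), pattern, (prov,))
                    )
                continue
            # autosomal recessive
            homs = [(v, p) for v, z, p in calls if z == ALT_HOM]
            hets = [(v, p) for v, z, p in calls if z == HET]
            for v, p in homs:
                findings.append(
                    ActionableGenotype(ind, gene, (v,), "recessive_hom", (p,))
                )
            if len(hets) >= 2:
                findings.append(
                    ActionableGenotype(
                        ind,
                        gene,
                        tuple(v for v, _ in hets),
                        "compound_het_putative",
                        tuple(p for _, p in hets),
                    )
                )
            elif len(hets) == 1 and not homs:
                carriers.append(CarrierOnly(ind, gene, hets[0][0]))
    return ActionabilityResult(findings, carriers, mosaics)


def detect_cooccurrences(
    findings: Sequence[ActionableGenotype],
) -> list[tuple[str, list[tuple[str, str]]]]:
    """Individuals with actionable genotypes in two or more distinct genes,
    with every gene pair listed."""
    genes_by_ind: dict[str, set[str]] = {}
    for f in findings:
        genes_by_ind.setdefault(f.individual_id, set()).add(f.gene_symbol)
    out = []
    for ind in sorted(genes_by_ind):
        genes = sorted(genes_by_ind[ind])
        if len(genes) >= 2:
            out.append((ind, list(itertools.combinations(genes, 2))))
    return out


def expected_cooccurrence(
    genotype_frequencies: Mapping[str, float], n: int, higher_order: bool = False
) -> float:
    """Expected count of multi-gene individuals under independence:
    n * sum over unordered gene pairs of f_i * f_j (pairs only by default)."""
    freqs = list(genotype_frequencies.values())
    for f in freqs:
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"frequency {f} outside [0, 1]")
    total = sum(fi * fj for fi, fj in itertools.combinations(freqs, 2))
    if higher_order:
        total += sum(
            fi * fj * fk for fi, fj, fk in itertools.combinations(freqs, 3)
        )
    return n * total


@dataclass(frozen=True)
class CohortTally:
    n_individuals_with_actionable: int
    n_actionable_genotypes: int
    n_distinct_variants: int
    n_genes: int
    percent_of_cohort: float
    n_carrier_only: int

    def __post_init__(self) -> None:
        if self.n_individuals_with_actionable > self.n_actionable_genotypes:
            raise ValueError("more individuals than genotypes is impossible")


def tally_cohort(
    findings: Sequence[ActionableGenotype],
    carrier_only: Sequence[CarrierOnly],
    cohort_size: int,
    supplemental_individuals: int = 0,
) -> CohortTally:
    """Cohort-level accounting.

    ``supplemental_individuals`` supports post-hoc additions that extend the
    reportable set without re-running the screen (e.g. males carrying a
    dominant allele whose direct action is female-specific): they increment
    both the genotype and the people counts, one genotype per person.
    ``percent_of_cohort`` is computed on the pre-supplemental individuals,
    matching how the headline percentage is defined.
    """
    if cohort_size <= 0:
        raise ValueError("cohort_size must be positive")
    inds = {f.individual_id for f in findings}
    variants = {v for f in findings for v in f.variants}
    genes = {f.gene_symbol for f in findings}
    percent = round(100.0 * len(inds) / cohort_size, 1)
    return CohortTally(
        n_individuals_with_actionable=len(inds) + supplemental_individuals,
        n_actionable_genotypes=len(findings) + supplemental_individuals,
        n_distinct_variants=len(variants),
        n_genes=len(genes),
        percent_of_cohort=percent,
        n_carrier_only=len({(c.individual_id, c.gene_symbol) for c in carrier_only}),
    )


def tally_validation(attempted: int, failed: int) -> float:
    """Percent of attempted verifications that succeeded, to one decimal."""
    if attempted <= 0:
        raise ValueError("attempted must be positive")
    if failed > attempted or failed < 0:
        raise ValueError("failed must be between 0 and attempted")
    return round(100.0 * (attempted - failed) / attempted, 1)
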