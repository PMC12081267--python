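"""Founder-effect quantification and Hardy-Weinberg carrier/risk arithmetic.

In a young founder isolate, a handful of pathogenic alleles can drift to many
times their frequency in the source population.  This module measures that:
per-subcohort minor-allele frequencies, fold uplift against a reference
population, a drifted-variant filter (fold > 50, minor-allele count >= 5, and
a documented pedigree origin before ~1800 CE), and the random-mating
arithmetic that turns a summed pathogenic allele frequency q into carrier and
affected expectations (2q(1-q) and q**2 for recessive genes, 1-(1-q)**2 for
dominant ones).  Reciprocals are additionally rounded the way population
summaries print them ("about 1 in 45"), with the raw values always kept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import fisher_exact

from .matrix import ALT_HOM, HET, MISSING, GenotypeMatrix
from .variants import VariantKey

SUBCOHORTS = ("orkney", "shetland", "other")


@dataclass(frozen=True)
class FoldUplift:
    """Ratio of subcohort to reference MAF; undefined when the reference has
    seen no copies, in which case a lower bound from the reference allele
    number is reported instead."""

    value: float | None
    lower_bound: float | None = None

    @property
    def defined(self) -> bool:
        return self.value is not None

    def exceeds(self, threshold: float) -> bool:
        if self.value is not None:
            return self.value > threshold
        return self.lower_bound is not None and self.lower_bound > threshold


def fold_uplift(
    maf: float, ref_maf: float, ref_allele_number: int | None = None
) -> FoldUplift:
    if not (0 <= maf <= 1 and 0 <= ref_maf <= 1):
        raise ValueError("frequencies must lie in [0, 1]")
    if ref_maf > 0:
        return FoldUplift(maf / ref_maf)
    if maf == 0:
        return FoldUplift(0.0)
    if ref_allele_number:
        return FoldUplift(None, lower_bound=maf * ref_allele_number)
    return FoldUplift(None)


@dataclass(frozen=True)
class FrequencyRecord:
    variant: VariantKey
    subcohort: str
    allele_count: int
    allele_number: int
    maf: float
    ref_maf: float | None = None
    ref_allele_number: int | None = None
    origin_pre1800: bool | None = None
    gene_symbol: str | None = None

    def __post_init__(self) -> None:
        if self.subcohort not in SUBCOHORTS:
            raise ValueError(f"unknown subcohort {self.subcohort!r}")
        if self.allele_number <= 0:
            raise ValueError("allele_number must be positive")
        if not 0 <= self.allele_count <= self.allele_number:
            raise ValueError("allele_count outside [0, allele_number]")

    @property
    def uplift(self) -> FoldUplift | None:
        if self.ref_maf is None:
            return None
        return fold_uplift(self.maf, self.ref_maf, self.ref_allele_number)


def subcohort_frequencies(
    genotypes: GenotypeMatrix,
    subcohort_labels: Mapping[str, str],
    gene_of: Mapping[VariantKey, str] | None = None,
    ref_freqs: Mapping[VariantKey, tuple[float, int | None]] | None = None,
    origin_flags: Mapping[VariantKey, bool] | None = None,
) -> list[FrequencyRecord]:
    """Per (variant, subcohort) allele counts and MAF.

    Minor-allele orientation is fixed cohort-wide: a variant whose ALT allele
    is the majority across all labeled individuals is counted on its REF
    allele in every subcohort.  Subcohorts with no called genotypes for a
    variant are omitted (with the reason implicit in the missing row).
    """
    gene_of = gene_of or {}
    ref_freqs = ref_freqs or {}
    origin_flags = origin_flags or {}
    labels = [subcohort_labels.get(ind, "other") for ind in genotypes.individuals]
    for lab in labels:
        if lab not in SUBCOHORTS:
            raise ValueError(f"unknown subcohort label {lab!r}")
    lab_arr = np.array(labels)
    out: list[FrequencyRecord] = []
    for j, variant in enumerate(genotypes.variants):
        col = genotypes.calls[:, j]
        called = col != MISSING
        alt_total = int(col[called].sum())  # codes 0/1/2 == alt copies
        an_total = int(2 * called.sum())
        minor_is_alt = an_total == 0 or alt_total <= an_total - alt_total
        for sub in SUBCOHORTS:
            mask = called & (lab_arr == sub)
            an = int(2 * mask.sum())
            if an == 0:
                continue
            alt = int(col[mask].sum())
            ac = alt if minor_is_alt else an - alt
            ref = ref_freqs.get(variant)
            out.append(
                FrequencyRecord(
                    variant=variant,
                    subcohort=sub,
                    allele_count=ac,
                    allele_number=an,
                    maf=ac / an,
                    ref_maf=None if ref is None else ref[0],
                    ref_allele_number=None if ref is None else ref[1],
                    origin_pre1800=origin_flags.get(variant),
                    gene_symbol=gene_of.get(variant),
                )
            )
    return out


def is_drifted(
    rec: FrequencyRecord, fold_threshold: float = 50.0, min_mac: int = 5
) -> tuple[bool, str | None]:
    """Drifted-variant filter: uplift above threshold, minor-allele count at
    least ``min_mac``, and an externally supplied pre-1800 pedigree origin.
    A missing genealogy flag fails with reason "genealogy unknown"."""
    if rec.allele_count < min_mac:
        return False, f"minor-allele count {rec.allele_count} < {min_mac}"
    up = rec.uplift
    if up is None:
        return False, "no reference frequency"
    if not up.exceeds(fold_threshold):
        return False, f"fold uplift not above {fold_threshold}"
    if rec.origin_pre1800 is None:
        return False, "genealogy unknown"
    if not rec.origin_pre1800:
        return False, "origin after 1800"
    return True, None


def _round_to(x: float, base: int) -> int:
    return int(base * round(x / base)) or base


@dataclass(frozen=True)
class GeneRiskSummary:
    gene_symbol: str
    subcohort: str
    inheritance: str
    q: float
    carrier_freq: float
    carrier_one_in: int | None
    carrier_one_in_raw: float | None
    affected_freq: float | None
    affected_one_in: int | None
    affected_one_in_raw: float | None


def gene_risk_summary(
    gene_symbol: str,
    subcohort: str,
    mafs: Sequence[float],
    inheritance: str,
) -> GeneRiskSummary:
    """Random-mating expectations for one gene's summed P/LP allele frequency.

    AR: carriers 2q(1-q) (one-in rounded to the nearest 5), affected q**2
    (one-in rounded to the nearest 1000).  AD: carriers 1-(1-q)**2, i.e. the
    proportion with at least one copy (one-in rounded to the nearest 100);
    affected fields are not defined at this level for dominant disease.
    """
    q = float(sum(mafs))
    if q > 0.5:
        raise ValueError(f"summed pathogenic allele frequency {q} > 0.5 is implausible")
    if inheritance == "AR":
        carrier = 2 * q * (1 - q)
        affected = q * q
        return GeneRiskSummary(
            gene_symbol,
            subcohort,
            inheritance,
            q,
            carrier,
            _round_to(1 / carrier, 5) if carrier > 0 else None,
            1 / carrier if carrier > 0 else None,
            affected,
            _round_to(1 / affected, 1000) if affected > 0 else None,
            1 / affected if affected > 0 else None,
        )
    if inheritance in ("AD", "XL"):
        carrier = 1 - (1 - q) ** 2
        return GeneRiskSummary(
            gene_symbol,
            subcohort,
            inheritance,
            q,
            carrier,
            _round_to(1 / carrier, 100) if carrier > 0 else None,
            1 / carrier if carrier > 0 else None,
            None,
            None,
            None,
        )
    raise ValueError(f"unknown inheritance {inheritance!r}")


@dataclass(frozen=True)
class CarrierRisk:
    q: float
    carrier_one_in: int
    affected_one_in: int


def carrier_to_risk(carrier_freq: float) -> CarrierRisk:
    """Invert carrier frequency 2q(1-q) to the allele frequency q (smaller
    root) and the implied recessive risk; rounding as in
    :func:`gene_risk_summary`."""
    if not 0 < carrier_freq < 0.5:
        raise ValueError("carrier frequency must lie in (0, 0.5)")
    disc = 1 - 2 * carrier_freq
    if disc < 0:
        raise ValueError("no real root for the given carrier frequency")
    q = (1 - math.sqrt(disc)) / 2
    return CarrierRisk(
        q=q,
        carrier_one_in=_round_to(1 / carrier_freq, 5),
        affected_one_in=_round_to(1 / (q * q), 1000),
    )


def depletion_test(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """How much rarer a carrier class is in cohort 1 than in reference 2.

    Returns (fold_lower, p) where fold_lower = (k2/n2)/(k1/n1) and p is the
    two-sided Fisher exact probability on the 2x2 of carriers/non-carriers.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("denominators must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("carrier counts must not exceed totals")
    if k1 == 0:
        raise ValueError("zero carriers in cohort 1: fold is unbounded")
    fold = (k2 / n2) / (k1 / n1)
    _, p = fisher_exact([[k1, n1 - k1], [k2, n2 - k2]], alternative="two-sided")
    return fold, float(p)


@dataclass(frozen=True)
class PenetranceSummary:
    penetrance_percent: float
    prevalence_percent: float
    enrichment_fold: float
    fisher_p: float
    n_carriers: int
    n_affected_carriers: int


def penetrance_tally(
    carrier_flags: Sequence[bool],
    noncarrier_affected: int,
    noncarrier_total: int,
) -> PenetranceSummary:
    """Nominal penetrance among carriers versus background prevalence.

    ``carrier_flags`` marks, per carrier, whether a linked health-record
    condition is present.  Enrichment is the penetrance/prevalence ratio and
    the Fisher exact p tests the 2x2 of affected/unaffected by carrier status.
    """
    n_car = len(carrier_flags)
    if n_car == 0:
        raise ValueError("no carriers")
    if noncarrier_total <= 0:
        raise ValueError("noncarrier_total must be positive")
    aff = int(sum(bool(f) for f in carrier_flags))
    pen = 100.0 * aff / n_car
    prev = 100.0 * noncarrier_affected / noncarrier_total
    enrich = pen / prev if prev > 0 else math.inf
    _, p = fisher_exact(
        [[aff, n_car - aff], [noncarrier_affected, noncarrier_total - noncarrier_affected]]
    )
    return PenetranceSummary(pen, prev, enrich, float(p), n_car, aff)


ANCESTRY_LABELS = ("nonislander_parent", "nonislander_grandparent", "full_islander")


@dataclass(frozen=True)
class SingletonAncestry:
    counts: dict
    percent_external: int  # >= one-quarter non-isles ancestry, nearest integer


def singleton_ancestry_breakdown(labels: Sequence[str]) -> SingletonAncestry:
    """Breakdown of singleton-variant carriers by recent external ancestry."""
    if not labels:
        raise ValueError("no singletons supplied")
    counts = {lab: 0 for lab in ANCESTRY_LABELS}
    for lab in labels:
        if lab not in counts:
            raise ValueError(f"unlabeled or unknown ancestry label {lab!r}")
        counts[lab] += 1
    external = counts["nonislander_parent"] + counts["nonislander_grandparent"]
    return SingletonAncestry(
        counts=counts,
        percent_external=int(round(100.0 * external / len(labels))),
    )
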