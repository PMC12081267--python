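"""Genotype-level quality control and the Hardy-Weinberg exact test.

Variants failing any of three checks are removed, in a fixed order so the
recorded reason is deterministic: monomorphic, call missingness above 2%,
Hardy-Weinberg exact p below 1e-6.  Individuals with more than 3% missing
calls are removed first (thresholds and order are configurable; all
thresholds are strict inequalities, so a variant at exactly 2% missingness
survives).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .matrix import GenotypeMatrix, MISSING


def hwe_exact_test(n_ref_hom: int, n_het: int, n_alt_hom: int) -> float:
    """Two-sided exact test of Hardy-Weinberg proportions.

    Conditions on the observed allele counts: over every heterozygote count
    consistent with the margins, the probability of the configuration under
    random mating is computed, and the p-value sums those configurations no
    more probable than the observed one.  Monomorphic input gives p = 1.
    """
    a, h, b = int(n_ref_hom), int(n_het), int(n_alt_hom)
    if a < 0 or h < 0 or b < 0:
        raise ValueError("genotype counts must be non-negative")
    n = a + h + b
    if n == 0:
        raise ValueError("at least one genotype count must be nonzero")
    n_minor = min(2 * a + h, 2 * b + h)
    if n_minor == 0:
        return 1.0
    hs = np.arange(n_minor % 2, n_minor + 1, 2)
    # log P(h | n, n_minor) up to a shared constant
    aa = (n_minor - hs) // 2
    bb = n - aa - hs
    logp = hs * np.log(2.0) - gammaln(aa + 1) - gammaln(hs + 1) - gammaln(bb + 1)
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(hs, h)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


@dataclass(frozen=True)
class VariantQC:
    variant_index: int
    passed: bool
    reason: str | None
    missingness: float
    hwe_p: float | None


def variant_qc(
    matrix: GenotypeMatrix,
    max_missing: float = 0.02,
    hwe_alpha: float = 1e-6,
) -> list[VariantQC]:
    """Per-variant pass/fail with the first failing reason recorded."""
    out: list[VariantQC] = []
    miss = matrix.variant_missingness()
    for j in range(matrix.n_variants):
        a, h, b = matrix.genotype_counts(j)
        called = a + h + b
        monomorphic = called == 0 or min(2 * a + h, 2 * b + h) == 0
        hwe_p = hwe_exact_test(a, h, b) if called else None
        if monomorphic:
            out.append(VariantQC(j, False, "monomorphic", float(miss[j]), hwe_p))
        elif miss[j] > max_missing:
            out.append(VariantQC(j, False, "missingness", float(miss[j]), hwe_p))
        elif hwe_p is not None and hwe_p < hwe_alpha:
            out.append(VariantQC(j, False, "hwe", float(miss[j]), hwe_p))
        else:
            out.append(VariantQC(j, True, None, float(miss[j]), hwe_p))
    return out


def sample_qc(matrix: GenotypeMatrix, max_missing: float = 0.03) -> list[bool]:
    """Per-individual pass flags; strictly-greater-than semantics."""
    return [bool(f <= max_missing) for f in matrix.sample_missingness()]


@dataclass
class QCResult:
    matrix: GenotypeMatrix
    variant_report: pd.DataFrame
    sample_report: pd.DataFrame
    excluded_individuals: list[str]
    excluded_variants: list


def apply_qc(
    matrix: GenotypeMatrix,
    max_variant_missing: float = 0.02,
    max_sample_missing: float = 0.03,
    hwe_alpha: float = 1e-6,
    samples_first: bool = True,
) -> QCResult:
    """Run sample then variant QC (order configurable) and return the filtered
    matrix plus tab-ready reports.  Reports reflect the matrix each pass
    actually ran on (after-filter recomputation, not stale denominators)."""

    def samples_pass(m: GenotypeMatrix):
        flags = sample_qc(m, max_sample_missing)
        report = pd.DataFrame(
            {
                "individual_id": m.individuals,
                "missingness": m.sample_missingness(),
                "passed": flags,
            }
        )
        kept = m.subset(individual_idx=[i for i, ok in enumerate(flags) if ok])
        excluded = [ind for ind, ok in zip(m.individuals, flags) if not ok]
        return kept, report, excluded

    def variants_pass(m: GenotypeMatrix):
        qcs = variant_qc(m, max_variant_missing, hwe_alpha)
        report = pd.DataFrame(
            {
                "variant": [str(m.variants[q.variant_index]) for q in qcs],
                "passed": [q.passed for q in qcs],
                "reason": [q.reason or "" for q in qcs],
                "missingness": [q.missingness for q in qcs],
                "hwe_p": [q.hwe_p if q.hwe_p is not None else np.nan for q in qcs],
            }
        )
        kept = m.subset(variant_idx=[q.variant_index for q in qcs if q.passed])
        excluded = [m.variants[q.variant_index] for q in qcs if not q.passed]
        return kept, report, excluded

    if samples_first:
        work, sample_report, bad_inds = samples_pass(matrix)
        work, variant_report, bad_vars = variants_pass(work)
    else:
        work, variant_report, bad_vars = variants_pass(matrix)
        work, sample_report, bad_inds = samples_pass(work)
    return QCResult(work, variant_report, sample_report, bad_inds, bad_vars)
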