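"""Genotype-level actionability calls, mosaic flagging, and cohort tallies."""

import numpy as np
import pytest

from actscreen.actionability import (
    ActionableGenotype,
    CarrierOnly,
    call_actionable_genotypes,
    detect_cooccurrences,
    expected_cooccurrence,
    flag_mosaic,
    tally_cohort,
    tally_validation,
)
from actscreen.clinvar import ClinVarRecord
from actscreen.matrix import ALT_HOM, HET, REF_HOM, GenotypeMatrix
from actscreen.merge import Match
from actscreen.rules import GeneRule
from actscreen.variants import VariantKey


def _cv(gene, chrom, pos):
    return ClinVarRecord(
        gene_symbol=gene, assembly="GRCh38", chrom=chrom, pos=pos, ref="A", alt="G",
        clinical_significance="P", review_status="reviewed by expert panel", stars=3,
        molecular_consequence="missense",
    )


@pytest.fixture()
def small_cohort():
    """Five individuals exercising every zygosity rule.

    variants: v_ad (AD gene), v_ar1/v_ar2 (AR gene), v_named (hom-only gene)
    """
    v_ad = VariantKey("AD1", 10, "A", "G", normalized=True)
    v_ar1 = VariantKey("AR1", 10, "A", "G", normalized=True)
    v_ar2 = VariantKey("AR1", 50, "A", "G", normalized=True)
    v_named = VariantKey("HFE", 10, "A", "G", normalized=True)
    keys = [v_ad, v_ar1, v_ar2, v_named]
    #            v_ad      v_ar1     v_ar2     v_named
    calls = np.array([
        [HET,      REF_HOM,  REF_HOM,  REF_HOM],   # dominant het
        [REF_HOM,  HET,      REF_HOM,  REF_HOM],   # AR carrier only
        [REF_HOM,  HET,      HET,      REF_HOM],   # compound het
        [REF_HOM,  ALT_HOM,  REF_HOM,  HET],       # recessive hom; named-het ignored
        [ALT_HOM,  REF_HOM,  REF_HOM,  ALT_HOM],   # dominant hom; named hom
    ], dtype=np.int8)
    matrix = GenotypeMatrix([f"I{i}" for i in range(5)], keys, calls)
    matches = [
        Match(v_ad, _cv("GAD", "AD1", 10), "coordinate"),
        Match(v_ar1, _cv("GAR", "AR1", 10), "coordinate"),
        Match(v_ar2, _cv("GAR", "AR1", 50), "protein-level"),
        Match(v_named, _cv("GHOM", "HFE", 10), "coordinate"),
    ]
    rules = [
        GeneRule("GAD", "d", "cancer", "AD", "all_P_LP"),
        GeneRule("GAR", "d", "metabolic", "AR", "all_P_LP"),
        GeneRule("GHOM", "d", "metabolic", "AR", "named_variant_hom_only", v_named),
    ]
    return matrix, matches, rules


def test_zygosity_rules(small_cohort):
    matrix, matches, rules = small_cohort
    res = call_actionable_genotypes(matrix, matches, rules)
    got = {(f.individual_id, f.gene_symbol, f.zygosity_pattern) for f in res.findings}
    assert got == {
        ("I0", "GAD", "dominant_het"),
        ("I2", "GAR", "compound_het_putative"),
        ("I3", "GAR", "recessive_hom"),
        ("I4", "GAD", "dominant_hom"),
        ("I4", "GHOM", "recessive_hom"),
    }
    assert {(c.individual_id, c.gene_symbol) for c in res.carrier_only} == {("I1", "GAR")}
    compound = next(f for f in res.findings if f.zygosity_pattern == "compound_het_putative")
    assert len(compound.variants) == 2
    assert set(compound.provenance) == {"coordinate", "protein-level"}


def test_named_variant_heterozygote_is_silently_ignored(small_cohort):
    matrix, matches, rules = small_cohort
    res = call_actionable_genotypes(matrix, matches, rules)
    named_people = {f.individual_id for f in res.findings if f.gene_symbol == "GHOM"}
    assert named_people == {"I4"}
    assert not any(c.gene_symbol == "GHOM" for c in res.carrier_only)


def test_gene_without_rule_is_a_hard_error(small_cohort):
    matrix, matches, rules = small_cohort
    with pytest.raises(ValueError, match="absent from the rule table"):
        call_actionable_genotypes(matrix, matches, rules[:1])


def test_carrier_and_finding_sets_are_disjoint(small_cohort):
    matrix, matches, rules = small_cohort
    res = call_actionable_genotypes(matrix, matches, rules)
    find_pairs = {(f.individual_id, f.gene_symbol) for f in res.findings}
    carrier_pairs = {(c.individual_id, c.gene_symbol) for c in res.carrier_only}
    assert not find_pairs & carrier_pairs


# --- mosaic flagging ---------------------------------------------------------


@pytest.mark.parametrize(
    "ref,alt,vaf,flagged",
    [
        (72, 13, 0.153, True),  # the blood mosaic: 15% allele distribution
        (19, 1, 0.05, True),
        (50, 48, 0.49, False),
        (3, 1, 0.25, False),  # low depth: binomial cannot reject
    ],
)
def test_flag_mosaic(ref, alt, vaf, flagged):
    got_vaf, got_flag = flag_mosaic(ref, alt)
    assert got_vaf == pytest.approx(vaf, abs=5e-3)
    assert got_flag is flagged


def test_flag_mosaic_zero_depth_errors():
    with pytest.raises(ValueError):
        flag_mosaic(0, 0)


def test_mosaic_type_one_error_controlled_on_balanced_hets():
    rng = np.random.default_rng(5)
    depth = 85
    alts = rng.binomial(depth, 0.5, size=2000)
    flags = [flag_mosaic(depth - a, a)[1] for a in alts]
    assert np.mean(flags) <= 0.001


# --- co-occurrences and tallies ---------------------------------------------


def _finding(ind, gene, pos=10):
    return ActionableGenotype(
        ind, gene, (VariantKey(gene, pos, "A", "G"),), "dominant_het", ("coordinate",)
    )


def test_cooccurrence_pairs():
    findings = [
        _finding("I1", "BRCA1"), _finding("I1", "PMS2"),
        _finding("I2", "MSH6"),
        _finding("I3", "A"), _finding("I3", "B"), _finding("I3", "C"),
    ]
    out = dict(detect_cooccurrences(findings))
    assert set(out) == {"I1", "I3"}
    assert out["I1"] == [("BRCA1", "PMS2")]
    assert len(out["I3"]) == 3


def test_expected_cooccurrence_closed_form_and_edge_cases():
    assert expected_cooccurrence({"a": 0.01, "b": 0.01}, 10_000) == pytest.approx(1.0)
    assert expected_cooccurrence({"a": 0.3}, 1000) == 0.0
    with pytest.raises(ValueError):
        expected_cooccurrence({"a": 1.5}, 10)


def test_expected_cooccurrence_matches_monte_carlo():
    """Planted independent per-gene frequencies: the observed multi-gene count
    over many simulated cohorts stays within sampling error of the pairwise
    expectation."""
    rng = np.random.default_rng(17)
    freqs = {"g1": 0.02, "g2": 0.015, "g3": 0.01}
    n, reps = 2000, 1000
    expect = expected_cooccurrence(freqs, n)
    counts = []
    for _ in range(reps):
        hits = np.zeros(n, dtype=int)
        for f in freqs.values():
            hits += rng.random(n) < f
        counts.append((hits >= 2).sum())
    mean = np.mean(counts)
    se = np.std(counts) / np.sqrt(reps)
    assert abs(mean - expect) < max(4 * se, 0.05 * expect)


def test_tally_reproduces_headline_accounting():
    # 104 individuals, 4 of whom have findings in two genes -> 108 genotypes
    findings = []
    for i in range(100):
        findings.append(_finding(f"P{i}", "BRCA1"))
    for i in range(4):
        findings.append(_finding(f"D{i}", "BRCA2"))
        findings.append(_finding(f"D{i}", "GAA", pos=30))
    t = tally_cohort(findings, [], cohort_size=4198)
    assert t.n_individuals_with_actionable == 104
    assert t.n_actionable_genotypes == 108
    assert t.percent_of_cohort == 2.5
    assert t.n_actionable_genotypes - t.n_individuals_with_actionable == 4
    # adding the 13 dominant-allele males moves 108 -> 121 genotypes, 117 people
    t2 = tally_cohort(findings, [], cohort_size=4198, supplemental_individuals=13)
    assert t2.n_actionable_genotypes == 121
    assert t2.n_individuals_with_actionable == 117


def test_tally_empty_and_errors():
    t = tally_cohort([], [], cohort_size=100)
    assert (t.n_individuals_with_actionable, t.n_actionable_genotypes) == (0, 0)
    with pytest.raises(ValueError):
        tally_cohort([], [], cohort_size=0)


@pytest.mark.parametrize(
    "attempted,failed,expected",
    [(149, 2, 98.7), (10, 0, 100.0), (3, 1, 66.7)],
)
def test_validation_percentage(attempted, failed, expected):
    assert tally_validation(attempted, failed) == expected


def test_validation_zero_attempts_errors():
    with pytest.raises(ValueError):
        tally_validation(0, 0)
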