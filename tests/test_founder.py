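"""Founder-drift quantification and Hardy-Weinberg risk arithmetic."""

import itertools
import math

import numpy as np
import pytest

from actscreen.founder import (
    FrequencyRecord,
    carrier_to_risk,
    depletion_test,
    fold_uplift,
    gene_risk_summary,
    is_drifted,
    penetrance_tally,
    singleton_ancestry_breakdown,
    subcohort_frequencies,
)
from actscreen.matrix import ALT_HOM, HET, MISSING, REF_HOM, GenotypeMatrix
from actscreen.variants import VariantKey


def _freq_rec(maf=0.00478, ac=20, an=4180, ref_maf=0.00478 / 470, origin=True):
    return FrequencyRecord(
        variant=VariantKey("17", 100, "A", "G"),
        subcohort="orkney",
        allele_count=ac,
        allele_number=an,
        maf=maf,
        ref_maf=ref_maf,
        ref_allele_number=917_682,
        origin_pre1800=origin,
    )


def test_subcohort_counting_matches_direct_tally():
    # 20 minor alleles among 4,180 called alleles -> maf 0.00478
    n = 2090
    calls = np.zeros((n, 1), dtype=np.int8)
    calls[:18, 0] = HET
    calls[18, 0] = ALT_HOM
    m = GenotypeMatrix(
        [f"O{i}" for i in range(n)], [VariantKey("17", 100, "A", "G")], calls
    )
    labels = {f"O{i}": "orkney" for i in range(n)}
    recs = subcohort_frequencies(m, labels)
    assert len(recs) == 1
    rec = recs[0]
    assert (rec.allele_count, rec.allele_number) == (20, 4180)
    assert rec.maf == pytest.approx(0.00478, abs=5e-6)


def test_minor_allele_orientation_is_cohort_wide():
    calls = np.full((10, 1), ALT_HOM, dtype=np.int8)
    calls[0, 0] = HET
    m = GenotypeMatrix([f"I{i}" for i in range(10)], [VariantKey("c", 1, "A", "G")], calls)
    rec = subcohort_frequencies(m, {f"I{i}": "shetland" for i in range(10)})[0]
    # ALT is the major allele here, so the minor count is on REF
    assert rec.allele_count == 1
    assert rec.maf == pytest.approx(0.05)


def test_all_missing_subcohort_is_omitted():
    calls = np.array([[HET], [MISSING]], dtype=np.int8)
    m = GenotypeMatrix(["a", "b"], [VariantKey("c", 1, "A", "G")], calls)
    recs = subcohort_frequencies(m, {"a": "orkney", "b": "shetland"})
    assert [r.subcohort for r in recs] == ["orkney"]


def test_fold_uplift_definition_and_sentinels():
    assert fold_uplift(0.00478, 0.00478 / 470).value == pytest.approx(470)
    up = fold_uplift(0.0038, 0.0, ref_allele_number=917_682)
    assert up.value is None
    assert up.lower_bound == pytest.approx(0.0038 * 917_682)
    assert up.exceeds(50)
    assert fold_uplift(0.0, 0.1).value == 0.0
    with pytest.raises(ValueError):
        fold_uplift(1.2, 0.1)


def test_fold_uplift_scale_invariance():
    rng = np.random.default_rng(3)
    for _ in range(50):
        a, b = rng.uniform(1e-5, 0.4, size=2)
        c = rng.uniform(0.1, 2.0)
        assert fold_uplift(min(c * a, 1), min(c * b, 1)).value == pytest.approx(
            fold_uplift(a, b).value, rel=1e-9
        )


@pytest.mark.parametrize(
    "rec,expected,reason_part",
    [
        (_freq_rec(), True, None),
        (_freq_rec(ac=4), False, "count"),
        (_freq_rec(maf=0.00478, ref_maf=0.00478 / 40), False, "fold"),
        (_freq_rec(origin=None), False, "genealogy"),
        (_freq_rec(origin=False), False, "1800"),
    ],
)
def test_drifted_filter(rec, expected, reason_part):
    flag, reason = is_drifted(rec)
    assert flag is expected
    if reason_part:
        assert reason_part in reason


def test_recessive_risk_arithmetic_prints_like_the_field():
    g = gene_risk_summary("ATP7B", "shetland", [0.008, 0.0032], "AR")
    assert g.q == pytest.approx(0.0112)
    assert g.carrier_freq == pytest.approx(2 * 0.0112 * (1 - 0.0112))
    assert g.carrier_one_in == 45
    assert g.affected_one_in == 8000
    assert g.carrier_one_in_raw == pytest.approx(1 / g.carrier_freq)


def test_dominant_risk_uses_at_least_one_copy():
    g = gene_risk_summary("TTN", "shetland", [0.0038, 0.0007, 0.0005], "AD")
    assert g.carrier_freq == pytest.approx(1 - (1 - 0.005) ** 2)
    assert g.carrier_one_in == 100
    assert g.affected_one_in is None


def test_risk_summary_edge_cases():
    g = gene_risk_summary("X", "orkney", [], "AR")
    assert g.q == 0 and g.carrier_one_in is None and g.affected_one_in is None
    with pytest.raises(ValueError, match="implausible"):
        gene_risk_summary("X", "orkney", [0.3, 0.3], "AR")


def test_carrier_to_risk_reproduces_reported_rounding():
    r = carrier_to_risk(0.029)
    assert r.carrier_one_in == 35
    assert r.affected_one_in == 5000
    assert r.q == pytest.approx(0.014716, abs=1e-5)


def test_carrier_to_risk_inverts_gene_risk_on_the_q_grid():
    for q in np.arange(0.001, 0.1001, 0.001):
        carrier = 2 * q * (1 - q)
        r = carrier_to_risk(carrier)
        assert r.q == pytest.approx(q, rel=1e-9)
        g = gene_risk_summary("G", "orkney", [q], "AR")
        assert g.carrier_one_in == r.carrier_one_in
        assert g.affected_one_in == r.affected_one_in


def test_carrier_to_risk_small_q_limit():
    r = carrier_to_risk(1e-4)
    assert r.q == pytest.approx(5e-5, rel=1e-3)


def fisher_oracle(k1, n1, k2, n2):
    """Exact two-sided Fisher probability by full enumeration over tables
    with the observed margins (integer arithmetic throughout)."""
    total, col1 = n1 + n2, k1 + k2

    def weight(x):
        return math.comb(n1, x) * math.comb(n2, col1 - x)

    lo, hi = max(0, col1 - n2), min(n1, col1)
    weights = {x: weight(x) for x in range(lo, hi + 1)}
    denom = sum(weights.values())
    obs = weights[k1]
    return sum(w for w in weights.values() if w <= obs) / denom


def test_depletion_against_reference_rates():
    fold, p = depletion_test(1, 4198, 1, 288)
    assert fold == pytest.approx(14.58, abs=0.01)
    assert fold > 10
    assert p == pytest.approx(fisher_oracle(1, 4198, 1, 288), rel=1e-6)


def test_depletion_identical_rates():
    fold, p = depletion_test(5, 100, 5, 100)
    assert fold == 1.0
    assert p == 1.0


def test_depletion_matches_enumeration_on_small_tables():
    for n1, n2 in itertools.product(range(1, 9), range(1, 9)):
        for k1 in range(1, n1 + 1):
            for k2 in range(0, n2 + 1):
                _, p = depletion_test(k1, n1, k2, n2)
                assert p == pytest.approx(fisher_oracle(k1, n1, k2, n2), rel=1e-8)


def test_penetrance_enrichment():
    flags = [True] * 4 + [False] * 12
    s = penetrance_tally(flags, noncarrier_affected=281, noncarrier_total=4133)
    assert s.penetrance_percent == pytest.approx(25.0)
    assert s.prevalence_percent == pytest.approx(6.8, abs=0.05)
    assert s.enrichment_fold == pytest.approx(25.0 / 6.8, rel=1e-3)
    assert 0 < s.fisher_p < 1
    zero = penetrance_tally([False] * 5, 10, 100)
    assert zero.penetrance_percent == 0.0
    with pytest.raises(ValueError):
        penetrance_tally([], 10, 100)


def test_singleton_ancestry_breakdown():
    labels = (
        ["nonislander_parent"] * 13 + ["nonislander_grandparent"] * 4 + ["full_islander"] * 10
    )
    s = singleton_ancestry_breakdown(labels)
    assert s.percent_external == 63
    assert s.counts["nonislander_parent"] == 13
    assert singleton_ancestry_breakdown(["full_islander"] * 5).percent_external == 0
    assert singleton_ancestry_breakdown(["nonislander_parent"] * 3).percent_external == 100
    with pytest.raises(ValueError):
        singleton_ancestry_breakdown(["martian"])
    with pytest.raises(ValueError):
        singleton_ancestry_breakdown([])
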