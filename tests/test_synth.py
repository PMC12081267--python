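"""Synthetic founder-cohort generator: determinism, round trips, plants."""

import numpy as np
import pytest

import actscreen as acts
from actscreen.matrix import MISSING, read_vcf
from actscreen.synth import (
    PlantedVariant,
    QCPlants,
    SyntheticCohortConfig,
    generate_cohort,
    minimal_config,
)


def test_same_seed_regenerates_byte_identical_bundle(tmp_path):
    d1, d2 = tmp_path / "a", tmp_path / "b"
    b1 = generate_cohort(minimal_config(99), out_dir=d1)
    b2 = generate_cohort(minimal_config(99), out_dir=d2)
    for name in ("vcf", "reference", "clinvar", "rules", "samples", "ref_freqs", "truth"):
        assert (d1 / f"{b1.paths[name].split('/')[-1]}").read_bytes() == (
            d2 / f"{b2.paths[name].split('/')[-1]}"
        ).read_bytes(), name
    assert b1.truth.findings == b2.truth.findings


def test_different_seeds_differ():
    b1 = generate_cohort(minimal_config(1))
    b2 = generate_cohort(minimal_config(2))
    assert not (b1.matrix.calls == b2.matrix.calls).all()


def test_vcf_round_trip_preserves_calls_and_depths(minimal_bundle):
    b = minimal_bundle
    back, annotations = read_vcf(b.paths["vcf"])
    assert back.individuals == b.matrix.individuals
    # written keys may be alternative renderings; map back
    rendered = {b.rendered_keys.get(k, k): k for k in b.matrix.variants}
    idx_orig = b.matrix.variant_index()
    grouped = {k for g in b.multiallelic_groups for k in g}
    for j, key in enumerate(back.variants):
        orig = rendered[key]
        jo = idx_orig[orig]
        assert (back.calls[:, j] == b.matrix.calls[:, jo]).all(), key
        if b.matrix.ref_depth is not None and orig not in grouped:
            called = back.calls[:, j] != MISSING
            assert (back.ref_depth[called, j] == b.matrix.ref_depth[called, jo]).all()
            assert (back.alt_depth[called, j] == b.matrix.alt_depth[called, jo]).all()


def test_clinvar_table_round_trips(minimal_bundle):
    records = acts.parse_clinvar_summary(minimal_bundle.paths["clinvar"])
    originals = acts.clinvar.aggregate_records(minimal_bundle.clinvar_records)
    on_38 = [r for r in originals if r.assembly == "GRCh38"]
    assert len(records) == len(on_38)
    assert {(r.chrom, r.pos, r.ref, r.alt) for r in records} == {
        (r.chrom, r.pos, r.ref, r.alt) for r in on_38
    }


def test_multiallelic_row_decomposes_like_the_hand_expansion(tmp_path):
    """A handwritten two-ALT VCF row must come back as two biallelic keys
    with the per-ALT genotypes worked out by hand."""
    vcf = tmp_path / "multi.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        '##contig=<ID=c,length=1000>\n'
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\tS4\n"
        "c\t100\t.\tA\tG,C\t.\t.\t.\tGT\t0/1\t1/2\t2/2\t./.\n"
    )
    m, _ = read_vcf(vcf)
    assert [str(v) for v in m.variants] == ["c:100:A:G", "c:100:A:C"]
    g = {(str(v), ind): int(m.calls[i, j]) for j, v in enumerate(m.variants)
         for i, ind in enumerate(m.individuals)}
    assert g[("c:100:A:G", "S1")] == 1 and g[("c:100:A:C", "S1")] == 0
    assert g[("c:100:A:G", "S2")] == 1 and g[("c:100:A:C", "S2")] == 1
    assert g[("c:100:A:G", "S3")] == 0 and g[("c:100:A:C", "S3")] == 2
    assert g[("c:100:A:G", "S4")] == MISSING and g[("c:100:A:C", "S4")] == MISSING


def test_truth_table_contains_planted_structures(minimal_bundle):
    truth = minimal_bundle.truth
    patterns = {z for _, _, _, z in truth.findings}
    assert "compound_het_putative" in patterns
    assert "dominant_het" in patterns
    genes = {g for _, g, _, _ in truth.findings}
    assert "GENHOM" in genes or not any(
        z == "recessive_hom" and g == "GENHOM" for _, g, _, z in truth.findings
    )
    assert len(truth.mosaics) == 1
    assert truth.qc_failed_individuals == ["ORK00000"]
    assert any(v.startswith("QCMISS") for v in truth.qc_failed_variants)
    assert any(v.startswith("QCHWE") for v in truth.qc_failed_variants)


def test_planted_hwe_violation_always_removed():
    for seed in range(10):
        b = generate_cohort(minimal_config(seed))
        assert any(v.startswith("QCHWE") for v in b.truth.qc_failed_variants), seed


def test_misrendered_indel_is_written_non_left_aligned(minimal_bundle):
    b = minimal_bundle
    assert b.rendered_keys, "preset must perturb at least one indel rendering"
    for norm, rendered in b.rendered_keys.items():
        assert (norm.pos, norm.ref, norm.alt) != (rendered.pos, rendered.ref, rendered.alt)
        assert acts.normalize_variant(rendered, b.reference) == norm


def test_inconsistent_config_is_a_hard_error():
    with pytest.raises(ValueError, match="compound-het"):
        SyntheticCohortConfig(
            seed=1, n_orkney=10, n_shetland=10,
            planted=[PlantedVariant("G", "AR", "missense", 0.1, 0.1)],
            compound_het_genes=["G"],
        )
    with pytest.raises(ValueError, match="ancestry"):
        SyntheticCohortConfig(
            seed=1, n_orkney=10, n_shetland=10, planted=[],
            n_singletons=3, singleton_ancestry=(1, 1, 0),
        )
    with pytest.raises(ValueError, match="frequency"):
        PlantedVariant("G", "AD", "missense", 0.7, 0.0)


def test_null_cohort_yields_empty_findings(tmp_path):
    cfg = SyntheticCohortConfig(
        seed=4, n_orkney=30, n_shetland=30, planted=[],
        mosaic=None, qc=QCPlants(False, False, False),
        plant_multiallelic=False, decoy_clinvar=False,
        n_background_variants=5,
    )
    b = generate_cohort(cfg, out_dir=tmp_path)
    assert b.truth.findings == set()
    res = acts.screen(b.paths["vcf"], b.paths["clinvar"], b.paths["rules"], b.paths["reference"])
    assert res.findings == []


def test_sampled_mafs_converge_to_configured_frequencies():
    """At n = 10^4 every planted frequency is recovered within 3 binomial SE."""
    cfg = SyntheticCohortConfig(
        seed=8, n_orkney=5000, n_shetland=5000,
        planted=[
            PlantedVariant("G1", "AD", "missense", 0.02, 0.005),
            PlantedVariant("G2", "AR", "missense", 0.05, 0.1),
        ],
        mosaic=None, qc=QCPlants(False, False, False),
        plant_multiallelic=False, decoy_clinvar=False,
        n_background_variants=0, emit_depths=False,
    )
    b = generate_cohort(cfg)
    labels = dict(zip(b.sample_metadata.individual_id, b.sample_metadata.subcohort))
    recs = acts.subcohort_frequencies(b.matrix, labels)
    by = {(str(r.variant), r.subcohort): r for r in recs}
    for key, pv in b.variant_info.items():
        for sub, f, n2 in (("orkney", pv.freq_orkney, 10000), ("shetland", pv.freq_shetland, 10000)):
            if f == 0:
                continue
            rec = by[(str(key), sub)]
            se = np.sqrt(f * (1 - f) / rec.allele_number)
            assert abs(rec.maf - f) < 3 * se, (key, sub)
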