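"""ClinVar dialect parsing, star derivation, and pathogenic filtering."""

from collections import Counter

import pytest

from actscreen.clinvar import (
    ClinVarRecord,
    aggregate_records,
    classify_significance,
    filter_pathogenic,
    parse_clinvar_summary,
    star_rating,
    write_clinvar_table,
)

# Independent lookup-table oracle over the canonical review-status ladder.
STATUS_ORACLE = {
    "practice guideline": 4,
    "reviewed by expert panel": 3,
    "criteria provided, multiple submitters, no conflicts": 2,
    "criteria provided, single submitter": 1,
    "criteria provided, conflicting classifications": 1,
    "no assertion criteria provided": 0,
}


@pytest.mark.parametrize("status,stars", sorted(STATUS_ORACLE.items()))
def test_star_rating_matches_canonical_ladder(status, stars):
    assert star_rating(status) == stars
    assert star_rating(status.upper()) == stars
    assert star_rating("  " + status.replace(", ", ",  ") + " ") == stars


def test_unknown_review_status_is_zero_stars():
    assert star_rating("somebody's uncle vouched for it") == 0


@pytest.mark.parametrize(
    "text,code",
    [
        ("Pathogenic", "P"),
        ("Likely pathogenic", "LP"),
        ("Pathogenic/Likely pathogenic", "P_LP"),
        ("Benign", "B"),
        ("Benign/Likely benign", "LB"),
        ("Uncertain significance", "VUS"),
        ("Conflicting classifications of pathogenicity", "conflicting"),
        ("drug response", "other"),
    ],
)
def test_significance_normalization(text, code):
    assert classify_significance(text) == code


def _rec(**kw):
    base = dict(
        gene_symbol="BRCA1",
        assembly="GRCh38",
        chrom="17",
        pos=43063903,
        ref="A",
        alt="G",
        clinical_significance="P",
        review_status="reviewed by expert panel",
        stars=3,
        hgvs_c="c.5207T>C",
        hgvs_p="p.Val1736Ala",
        transcript="NM_007294.4",
        molecular_consequence="missense",
    )
    base.update(kw)
    return ClinVarRecord(**base)


@pytest.fixture()
def summary_file(tmp_path):
    path = tmp_path / "variant_summary.txt"
    rows = [
        _rec(),
        _rec(pos=43064001, alt="C", clinical_significance="LP", stars=2,
             review_status="criteria provided, multiple submitters, no conflicts"),
        _rec(pos=43064100, clinical_significance="B", stars=3),
        _rec(pos=43064200, clinical_significance="P", stars=0,
             review_status="no assertion criteria provided"),
    ]
    write_clinvar_table(rows, path)
    # append degenerate rows below the serializer: GRCh37 and a non-ACGT allele
    with open(path, "a") as fh:
        fh.write(
            "BRCA1\tPathogenic\treviewed by expert panel\tGRCh37\t17\t43063903\tA\tG\t"
            "NM_007294.4(BRCA1):c.5207T>C (p.Val1736Ala)\tmissense\n"
        )
        fh.write(
            "BRCA1\tPathogenic\treviewed by expert panel\tGRCh38\t17\t43064300\tA\tN\t"
            "NM_007294.4(BRCA1):c.1A>N\tmissense\n"
        )
    return path


def test_parse_filters_assembly_and_degenerate_alleles(summary_file):
    tally = Counter()
    records = parse_clinvar_summary(summary_file, assembly="GRCh38", tally=tally)
    assert len(records) == 4
    assert tally["other_assembly"] == 1
    assert tally["non_ACGT_allele_or_bad_coordinates"] == 1
    expert = next(r for r in records if r.pos == 43063903)
    assert expert.clinical_significance == "P"
    assert expert.stars == 3
    assert expert.hgvs_p == "p.Val1736Ala"
    assert expert.transcript == "NM_007294.4"


def test_parse_then_serialize_is_lossless(summary_file, tmp_path):
    records = parse_clinvar_summary(summary_file)
    out = tmp_path / "round.tsv"
    write_clinvar_table(records, out)
    assert parse_clinvar_summary(out) == records


def test_missing_mandatory_column_and_empty_file_are_hard_errors(tmp_path):
    bad = tmp_path / "bad.tsv"
    bad.write_text("GeneSymbol\tClinicalSignificance\nBRCA1\tPathogenic\n")
    with pytest.raises(ValueError, match="ReviewStatus"):
        parse_clinvar_summary(bad)
    empty = tmp_path / "empty.tsv"
    empty.write_text("\n")
    with pytest.raises(Exception):
        parse_clinvar_summary(empty)


def test_filter_keeps_one_star_or_higher_pathogenic_only():
    records = [
        _rec(stars=2, review_status="criteria provided, multiple submitters, no conflicts"),
        _rec(pos=2, stars=0, review_status="no assertion criteria provided"),
        _rec(pos=3, clinical_significance="B", stars=3),
        _rec(pos=4, clinical_significance="P_LP", stars=1,
             review_status="criteria provided, single submitter"),
    ]
    tally = Counter()
    kept = filter_pathogenic(records, min_stars=1, tally=tally)
    assert {r.pos for r in kept} == {43063903, 4}
    assert tally == Counter({"not_pathogenic": 1, "below_min_stars": 1})
    # idempotence and monotonicity
    assert filter_pathogenic(kept) == kept
    assert len(kept) <= len(records)


def test_duplicate_rows_aggregate_to_max_stars():
    dups = [
        _rec(stars=1, review_status="criteria provided, single submitter"),
        _rec(stars=3, review_status="reviewed by expert panel"),
    ]
    out = aggregate_records(dups)
    assert len(out) == 1 and out[0].stars == 3


def test_pathogenic_benign_conflict_at_one_star_each_is_excluded():
    conflict = [
        _rec(stars=2, review_status="criteria provided, multiple submitters, no conflicts"),
        _rec(clinical_significance="B", stars=1,
             review_status="criteria provided, single submitter"),
    ]
    tally = Counter()
    assert aggregate_records(conflict, tally) == []
    assert tally["significance_conflict"] == 1
    # a zero-star benign dissent does not suppress a starred pathogenic record
    weak = [
        _rec(stars=2, review_status="criteria provided, multiple submitters, no conflicts"),
        _rec(clinical_significance="B", stars=0,
             review_status="no assertion criteria provided"),
    ]
    assert len(aggregate_records(weak)) == 1
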