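"""End-to-end screen: VCF + ClinVar table + gene rules -> actionable genotypes.

Order of operations mirrors the analysis this package implements:

1. parse and filter the classification table (P/LP, >= 1 star, one aggregated
   record per variant, requested assembly only);
2. read cohort genotypes, decompose multiallelic rows, normalize every variant
   (and every classification record) against the reference;
3. coordinate merge, then protein-level fallback merge;
4. drop matches whose molecular consequence is not reportable for the gene;
5. sample then variant QC;
6. call actionable genotypes (mosaic flagging via allelic depths), carriers,
   co-occurrences, and the cohort tally.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .actionability import (
    ActionabilityResult,
    CohortTally,
    call_actionable_genotypes,
    detect_cooccurrences,
    tally_cohort,
)
from .clinvar import ClinVarRecord, filter_pathogenic, parse_clinvar_summary
from .matrix import GenotypeMatrix, read_vcf
from .merge import Match, two_stage_merge
from .qc import QCResult, apply_qc
from .rules import GeneRule, load_gene_rules, rules_by_gene, variant_class_allowed
from .variants import (
    VariantKey,
    load_fasta,
    normalize_variant,
    parse_protein_change,
)

log = logging.getLogger(__name__)


@dataclass
class ScreenResult:
    matrix: GenotypeMatrix  # QC-passed, normalized keys
    matches: list[Match]
    result: ActionabilityResult
    cooccurrences: list
    tally: CohortTally
    qc: QCResult
    exclusion_tally: Counter
    unmatched: list[VariantKey]

    @property
    def findings(self):
        return self.result.findings


def screen(
    vcf_path: str | Path,
    clinvar_path: str | Path,
    rules_path: str | Path,
    reference_path: str | Path,
    min_stars: int = 1,
    assembly: str = "GRCh38",
    max_variant_missing: float = 0.02,
    max_sample_missing: float = 0.03,
    hwe_alpha: float = 1e-6,
    vaf_threshold: float = 0.25,
    binomial_alpha: float = 0.001,
    out_dir: str | Path | None = None,
) -> ScreenResult:
    """Run the whole screen from files on disk; see module docstring."""
    tally: Counter = Counter()
    rules = load_gene_rules(rules_path)
    reference = load_fasta(str(reference_path))
    records = parse_clinvar_summary(clinvar_path, assembly=assembly, tally=tally)
    records = filter_pathogenic(records, min_stars=min_stars, tally=tally)
    records = _normalize_records(records, reference, tally)

    raw_matrix, annotations = read_vcf(vcf_path)
    mapping = {}
    for key in raw_matrix.variants:
        mapping[key] = normalize_variant(key, reference)
    matrix = raw_matrix.rename_variants(mapping)
    annotations = {mapping[k]: v for k, v in annotations.items()}

    cohort = []
    for key in matrix.variants:
        ann = annotations.get(key)
        pc = None
        if ann and ann.hgvs_p and ann.gene and ann.transcript:
            pc = parse_protein_change(ann.hgvs_p, ann.gene, ann.transcript)
        cohort.append((key, pc))
    matches, unmatched = two_stage_merge(cohort, records, tally)

    # variant-class gate: consequence from cohort annotation, else ClinVar
    rule_map = rules_by_gene(rules)
    kept_matches: list[Match] = []
    for m in matches:
        gene = m.record.gene_symbol
        rule = rule_map.get(gene)
        if rule is None:
            raise ValueError(
                f"matched variant {m.variant} in gene {gene!r} has no rule; "
                "supply a complete gene-rules table"
            )
        ann = annotations.get(m.variant)
        conseq = (ann.consequence if ann and ann.consequence else None) or (
            m.record.molecular_consequence
        )
        if variant_class_allowed(rule, conseq):
            kept_matches.append(m)
        else:
            tally["variant_class_not_actionable"] += 1

    qc = apply_qc(
        matrix,
        max_variant_missing=max_variant_missing,
        max_sample_missing=max_sample_missing,
        hwe_alpha=hwe_alpha,
    )
    result = call_actionable_genotypes(
        qc.matrix,
        kept_matches,
        rules,
        vaf_threshold=vaf_threshold,
        binomial_alpha=binomial_alpha,
    )
    cooc = detect_cooccurrences(result.findings)
    cohort_tally = tally_cohort(
        result.findings, result.carrier_only, cohort_size=qc.matrix.n_individuals
    )
    out = ScreenResult(
        matrix=qc.matrix,
        matches=kept_matches,
        result=result,
        cooccurrences=cooc,
        tally=cohort_tally,
        qc=qc,
        exclusion_tally=tally,
        unmatched=unmatched,
    )
    if out_dir is not None:
        write_screen_outputs(out, out_dir)
    return out


def _normalize_records(
    records: list[ClinVarRecord], reference, tally: Counter
) -> list[ClinVarRecord]:
    out = []
    for rec in records:
        if rec.chrom not in reference:
            tally["clinvar_contig_absent_from_reference"] += 1
            continue
        try:
            key = normalize_variant(rec.key, reference)
        except ValueError:
            tally["clinvar_ref_mismatch"] += 1
            continue
        if (key.pos, key.ref, key.alt) != (rec.pos, rec.ref, rec.alt):
            rec = ClinVarRecord(
                **{
                    **rec.__dict__,
                    "pos": key.pos,
                    "ref": key.ref,
                    "alt": key.alt,
                }
            )
        out.append(rec)
    return out


def write_screen_outputs(res: ScreenResult, out_dir: str | Path) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    findings_df = pd.DataFrame(
        [
            {
                "individual_id": f.individual_id,
                "gene": f.gene_symbol,
                "variants": ";".join(str(v) for v in f.variants),
                "zygosity": f.zygosity_pattern,
                "provenance": ";".join(f.provenance),
                "returnable": f.returnable,
            }
            for f in res.result.findings
        ]
    )
    carriers_df = pd.DataFrame(
        [
            {"individual_id": c.individual_id, "gene": c.gene_symbol, "variant": str(c.variant)}
            for c in res.result.carrier_only
        ]
    )
    mosaics_df = pd.DataFrame(
        [
            {
                "individual_id": mc.individual_id,
                "gene": mc.gene_symbol,
                "variant": str(mc.variant),
                "vaf": mc.vaf,
                "ref_reads": mc.ref_reads,
                "alt_reads": mc.alt_reads,
            }
            for mc in res.result.mosaics
        ]
    )
    cooc_df = pd.DataFrame(
        [
            {"individual_id": ind, "gene_pair": f"{a}+{b}"}
            for ind, pairs in res.cooccurrences
            for a, b in pairs
        ]
    )
    findings_df.to_csv(out / "findings.tsv", sep="\t", index=False)
    carriers_df.to_csv(out / "carriers.tsv", sep="\t", index=False)
    mosaics_df.to_csv(out / "mosaics.tsv", sep="\t", index=False)
    cooc_df.to_csv(out / "cooccurrences.tsv", sep="\t", index=False)
    res.qc.variant_report.to_csv(out / "qc_variants.tsv", sep="\t", index=False)
    res.qc.sample_report.to_csv(out / "qc_samples.tsv", sep="\t", index=False)
    with open(out / "tally.json", "w") as fh:
        json.dump(
            {
                "n_individuals_with_actionable": res.tally.n_individuals_with_actionable,
                "n_actionable_genotypes": res.tally.n_actionable_genotypes,
                "n_distinct_variants": res.tally.n_distinct_variants,
                "n_genes": res.tally.n_genes,
                "percent_of_cohort": res.tally.percent_of_cohort,
                "n_carrier_only": res.tally.n_carrier_only,
                "exclusions": dict(res.exclusion_tally),
            },
            fh,
            indent=1,
        )
    return {"out_dir": str(out)}
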