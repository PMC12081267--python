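"""Self-contained synthetic founder-cohort generator.

Emulates the statistical structure the screen assumes: two archipelago
subcohorts with drifted pathogenic alleles drawn binomially under
Hardy-Weinberg at configured per-subcohort frequencies, multi-allele
recessive genes (with guaranteed compound heterozygotes), a named-allele
homozygote gene, singleton variants carried by individuals with recent
external ancestry, one somatic mosaic with skewed read depths, deliberately
non-left-aligned indel renderings, a protein-level-only match, and planted
QC failures (a high-missingness variant, a Hardy-Weinberg-violating variant
and a high-missingness individual).

Everything is synthetic: contigs are one artificial sequence per gene so no
reference download is needed, and every genotype, depth and label is drawn
from one seeded generator (the same seed regenerates the bundle
bit-identically).  The truth table is derived from the realized genotype
matrix — not merely the plant list — with its own inline rule logic, so the
screen can be scored for exact recovery (precision = recall = 1) against it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .clinvar import ClinVarRecord, star_rating, write_clinvar_table
from .matrix import (
    ALT_HOM,
    HET,
    MISSING,
    REF_HOM,
    GenotypeMatrix,
    VariantAnnotation,
    write_fasta,
    write_vcf,
)
from .rules import GeneRule, write_gene_rules
from .variants import VariantKey, equivalent_renderings, normalize_variant

CONSENT_STATUSES = (
    "consented",
    "no_reply",
    "declined",
    "deceased_no_request",
    "deceased_next_of_kin_consented",
)

_DEL_CTX = "GCCAAGCTAAGACT"  # 5-bp deletion in repeat context; two renderings
_INS_CTX = "TCATCTA"  # CT insertion nameable at three offsets


@dataclass
class PlantedVariant:
    """One planted allele and how it should behave downstream."""

    gene: str
    inheritance: str  # AD | AR
    consequence: str
    freq_orkney: float
    freq_shetland: float
    ref_maf: float = 0.0
    ref_allele_number: int = 1_000_000
    significance: str = "Pathogenic"
    review_status: str = "criteria provided, multiple submitters, no conflicts"
    kind: str = "snv"  # snv | del | ins
    lof_only_gene: bool = False
    named_hom_only: bool = False
    protein_fallback: bool = False  # ClinVar row gets different coordinates
    misrender: bool = False  # emit a non-left-aligned rendering in the VCF
    origin_pre1800: bool = True
    intended_drifted: bool = False
    category: str = "other"
    disease: str = "synthetic condition"

    def __post_init__(self) -> None:
        for f in (self.freq_orkney, self.freq_shetland):
            if not 0.0 <= f <= 0.5:
                raise ValueError(f"planted frequency {f} outside [0, 0.5]")


@dataclass
class MosaicSpec:
    depth: int = 85
    true_vaf: float = 0.15


@dataclass
class QCPlants:
    missing_variant: bool = True  # ~5% missing calls
    hwe_variant: bool = True  # excess homozygotes, zero hets
    missing_individual: bool = True  # ~5% missing calls in one person


@dataclass
class SyntheticCohortConfig:
    seed: int
    n_orkney: int
    n_shetland: int
    planted: list[PlantedVariant]
    n_singletons: int = 0
    singleton_ancestry: tuple[int, int, int] = (0, 0, 0)  # parent, grandparent, islander
    compound_het_genes: list[str] = field(default_factory=list)
    mosaic: MosaicSpec | None = None
    qc: QCPlants = field(default_factory=QCPlants)
    consent_probs: dict = field(
        default_factory=lambda: {
            "consented": 0.57,
            "no_reply": 0.28,
            "declined": 0.03,
            "deceased_no_request": 0.10,
            "deceased_next_of_kin_consented": 0.02,
        }
    )
    emit_depths: bool = True
    mean_depth: int = 85
    plant_multiallelic: bool = True
    decoy_clinvar: bool = True
    #: neutral common SNVs padding the matrix, so that one missing call is a
    #: realistic (small) fraction of an individual's total genotypes
    n_background_variants: int = 50
    background_freq: float = 0.2

    def __post_init__(self) -> None:
        if self.n_singletons and sum(self.singleton_ancestry) != self.n_singletons:
            raise ValueError("singleton ancestry counts must sum to n_singletons")
        for gene in self.compound_het_genes:
            alleles = [p for p in self.planted if p.gene == gene and p.inheritance == "AR"]
            if len(alleles) < 2:
                raise ValueError(
                    f"compound-het gene {gene!r} needs >= 2 planted recessive alleles"
                )


@dataclass
class TruthTable:
    """Ground truth for scoring: every actionable genotype present in the
    realized matrix among QC-surviving individuals and variants."""

    findings: set  # (individual, gene, sorted-variant-str-tuple, zygosity)
    carrier_only: set  # (individual, gene)
    mosaics: set  # (individual, variant-str)
    qc_failed_individuals: list
    qc_failed_variants: list  # variant-str
    consent: dict
    drifted_variants: set  # variant-str with intended_drifted


@dataclass
class CohortBundle:
    config: SyntheticCohortConfig
    reference: dict
    matrix: GenotypeMatrix
    annotations: dict
    rendered_keys: dict
    multiallelic_groups: list
    clinvar_records: list
    gene_rules: list
    sample_metadata: pd.DataFrame
    ref_freq_table: pd.DataFrame
    origin_flags: dict
    truth: TruthTable
    variant_info: dict  # VariantKey -> PlantedVariant
    paths: dict = field(default_factory=dict)


def _seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _transcript(idx: int) -> str:
    return f"NM_{900000 + idx}.2"


def _protein(consequence: str, residue: int) -> str | None:
    if consequence == "missense":
        return f"p.Ala{residue}Val"
    if consequence == "stop_gain":
        return f"p.Gln{residue}Ter"
    if consequence == "frameshift":
        return f"p.Trp{residue}fs"
    return None  # splice changes have no residue-level rendering


def _place_variant(
    rng: np.random.Generator,
    reference: dict,
    gene: str,
    slot: int,
    kind: str,
) -> tuple[VariantKey, VariantKey | None]:
    """Plant one variant on the gene's contig; returns (normalized key,
    alternative non-normalized rendering or None)."""
    seq = reference[gene]
    pos = 101 + 40 * slot  # 1-based anchor region start
    if kind == "snv":
        ref = seq[pos - 1]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        key = VariantKey(gene, pos, ref, str(alt), normalized=True)
        return key, None
    if kind == "del":
        ctx = _DEL_CTX
        reference[gene] = seq[: pos - 1] + ctx + seq[pos - 1 + len(ctx) :]
        raw = VariantKey(gene, pos + 5, reference[gene][pos + 4 : pos + 10], reference[gene][pos + 4])
    elif kind == "ins":
        ctx = _INS_CTX
        reference[gene] = seq[: pos - 1] + ctx + seq[pos - 1 + len(ctx) :]
        anchor = reference[gene][pos + 4]
        raw = VariantKey(gene, pos + 5, anchor, anchor + "CT")
    else:
        raise ValueError(f"unknown variant kind {kind!r}")
    norm = normalize_variant(raw, reference)
    others = [r for r in equivalent_renderings(norm, reference) if r != VariantKey(
        norm.chrom, norm.pos, norm.ref, norm.alt
    )]
    alt_rendering = others[-1] if others else None
    return norm, alt_rendering


def generate_cohort(
    config: SyntheticCohortConfig, out_dir: str | Path | None = None
) -> CohortBundle:
    """Build the full fixture bundle; write files under ``out_dir`` if given."""
    rng = np.random.default_rng(config.seed)
    n_ork, n_shet = config.n_orkney, config.n_shetland
    n = n_ork + n_shet
    individuals = [f"ORK{i:05d}" for i in range(n_ork)] + [
        f"SHE{i:05d}" for i in range(n_shet)
    ]
    subcohort = ["orkney"] * n_ork + ["shetland"] * n_shet

    # --- assemble the variant roster -------------------------------------
    planted = list(config.planted)
    singleton_plants: list[PlantedVariant] = []
    for k in range(config.n_singletons):
        singleton_plants.append(
            PlantedVariant(
                gene=f"SING{k:02d}",
                inheritance="AD",
                consequence="missense",
                freq_orkney=0.0,
                freq_shetland=0.0,
                significance="Pathogenic",
            )
        )
    roster = planted + singleton_plants

    reference: dict = {}
    gene_slots: dict[str, int] = {}
    keys: list[VariantKey] = []
    rendered: dict[VariantKey, VariantKey] = {}
    variant_info: dict[VariantKey, PlantedVariant] = {}
    annotations: dict[VariantKey, VariantAnnotation] = {}
    gene_tx: dict[str, str] = {}
    clinvar_rows: list[ClinVarRecord] = []

    for pv in roster:
        if pv.gene not in reference:
            reference[pv.gene] = _seq(rng, 600)
            gene_tx[pv.gene] = _transcript(len(gene_tx))
        slot = gene_slots.get(pv.gene, 0)
        gene_slots[pv.gene] = slot + 1
        key, alt_rendering = _place_variant(rng, reference, pv.gene, slot, pv.kind)
        keys.append(key)
        variant_info[key] = pv
        if pv.misrender and alt_rendering is not None:
            rendered[key] = alt_rendering
        residue = 100 + 10 * slot
        hgvs_p = _protein(pv.consequence, residue)
        hgvs_c = _hgvs_c(pv, key, slot)
        annotations[key] = VariantAnnotation(
            gene=pv.gene,
            consequence=pv.consequence,
            transcript=gene_tx[pv.gene],
            hgvs_c=hgvs_c,
            hgvs_p=hgvs_p,
        )
        cv_key = key
        if pv.protein_fallback:
            cv_key = _shifted_clinvar_key(reference, key)
        clinvar_rows.append(
            ClinVarRecord(
                gene_symbol=pv.gene,
                assembly="GRCh38",
                chrom=cv_key.chrom,
                pos=cv_key.pos,
                ref=cv_key.ref,
                alt=cv_key.alt,
                clinical_significance=_sig_code(pv.significance),
                review_status=pv.review_status,
                stars=star_rating(pv.review_status),
                hgvs_c=hgvs_c,
                hgvs_p=hgvs_p,
                transcript=gene_tx[pv.gene],
                molecular_consequence=pv.consequence,
            )
        )

    # --- neutral / decoy variants ----------------------------------------
    multiallelic_groups: list[list[VariantKey]] = []
    neutral_keys: list[VariantKey] = []
    if config.plant_multiallelic:
        host = next((k for k in keys if k.is_snv), None)
        if host is not None:
            other_alt = next(
                b for b in "ACGT" if b not in (host.ref, host.alt)
            )
            partner = VariantKey(host.chrom, host.pos, host.ref, other_alt, normalized=True)
            neutral_keys.append(partner)
            annotations[partner] = VariantAnnotation(gene=host.chrom, consequence="other")
            multiallelic_groups.append([host, partner])
            if config.decoy_clinvar:
                clinvar_rows.append(
                    ClinVarRecord(
                        gene_symbol=variant_info[host].gene,
                        assembly="GRCh38",
                        chrom=partner.chrom,
                        pos=partner.pos,
                        ref=partner.ref,
                        alt=partner.alt,
                        clinical_significance="B",
                        review_status="reviewed by expert panel",
                        stars=3,
                        molecular_consequence="missense",
                    )
                )
    if config.n_background_variants:
        reference["BGCTG"] = _seq(rng, 200 + 40 * config.n_background_variants)
        for b in range(config.n_background_variants):
            pos = 101 + 40 * b
            ref = reference["BGCTG"][pos - 1]
            alt = next(x for x in "ACGT" if x != ref)
            k = VariantKey("BGCTG", pos, ref, alt, normalized=True)
            neutral_keys.append(k)
            annotations[k] = VariantAnnotation(gene="BGCTG", consequence="other")
    qc_variants: dict[str, VariantKey] = {}
    for name, flag in (
        ("QCMISS", config.qc.missing_variant),
        ("QCHWE", config.qc.hwe_variant),
    ):
        if not flag:
            continue
        reference[name] = _seq(rng, 300)
        ref = reference[name][100]
        alt = next(b for b in "ACGT" if b != ref)
        k = VariantKey(name, 101, ref, alt, normalized=True)
        qc_variants[name] = k
        neutral_keys.append(k)
        annotations[k] = VariantAnnotation(gene=name, consequence="other")
    if config.decoy_clinvar and keys:
        # pathogenic but 0-star: must be filtered before matching
        host = keys[0]
        reference.setdefault("DECOY", _seq(rng, 300))
        ref = reference["DECOY"][100]
        alt = next(b for b in "ACGT" if b != ref)
        decoy = VariantKey("DECOY", 101, ref, alt, normalized=True)
        neutral_keys.append(decoy)
        annotations[decoy] = VariantAnnotation(gene="DECOY", consequence="missense")
        clinvar_rows.append(
            ClinVarRecord(
                gene_symbol="DECOY",
                assembly="GRCh38",
                chrom="DECOY",
                pos=101,
                ref=ref,
                alt=alt,
                clinical_significance="P",
                review_status="no assertion criteria provided",
                stars=0,
                molecular_consequence="missense",
            )
        )
        clinvar_rows.append(  # wrong assembly: excluded at parse time
            ClinVarRecord(
                gene_symbol="DECOY",
                assembly="GRCh37",
                chrom="DECOY",
                pos=151,
                ref="A",
                alt="T",
                clinical_significance="P",
                review_status="reviewed by expert panel",
                stars=3,
                molecular_consequence="missense",
            )
        )

    all_keys = keys + neutral_keys
    calls = np.zeros((n, len(all_keys)), dtype=np.int8)
    col = {k: j for j, k in enumerate(all_keys)}

    # --- binomial genotype draws under HWE --------------------------------
    for key in keys:
        pv = variant_info[key]
        j = col[key]
        for sl, f in (
            (slice(0, n_ork), pv.freq_orkney),
            (slice(n_ork, n), pv.freq_shetland),
        ):
            if f > 0:
                calls[sl, j] = rng.binomial(2, f, size=sl.stop - sl.start)
    for k in neutral_keys:
        if k.chrom.startswith(("QC", "DECOY")):
            continue
        f = config.background_freq if k.chrom == "BGCTG" else 0.05
        calls[:, col[k]] = rng.binomial(2, f, size=n)
    if config.plant_multiallelic and multiallelic_groups:
        host, partner = multiallelic_groups[0]
        calls[:, col[partner]] = rng.binomial(2, 0.04, size=n)
        # a sample cannot carry 4 alleles at one site: thin impossible overlaps
        both = (calls[:, col[host]] + calls[:, col[partner]]) > 2
        calls[both, col[partner]] = 0
    if "DECOY" in reference and any(k.chrom == "DECOY" for k in neutral_keys):
        jd = col[next(k for k in neutral_keys if k.chrom == "DECOY")]
        calls[:, jd] = rng.binomial(2, 0.05, size=n)

    # --- deterministic plants ---------------------------------------------
    for gene in config.compound_het_genes:
        alleles = [k for k in keys if variant_info[k].gene == gene][:2]
        ind = int(rng.integers(0, n))
        for k in alleles:
            calls[ind, col[k]] = HET

    singleton_carriers: list[int] = []
    for key in keys:
        if variant_info[key].gene.startswith("SING"):
            jcol = col[key]
            calls[:, jcol] = REF_HOM
            carrier = int(rng.integers(0, n))
            while carrier in singleton_carriers:
                carrier = int(rng.integers(0, n))
            calls[carrier, jcol] = HET
            singleton_carriers.append(carrier)

    mosaic_cell: tuple[int, int] | None = None
    mosaic_alt_reads = 0
    if config.mosaic is not None:
        target = next(
            (k for k in keys if variant_info[k].inheritance == "AD"
             and not variant_info[k].gene.startswith("SING")),
            None,
        )
        if target is None:
            raise ValueError("mosaic plant needs at least one dominant planted variant")
        ind = int(rng.integers(0, n))
        calls[ind, col[target]] = HET
        mosaic_cell = (ind, col[target])
        mosaic_alt_reads = int(rng.binomial(config.mosaic.depth, config.mosaic.true_vaf))

    # --- QC plants ---------------------------------------------------------
    if "QCHWE" in qc_variants:
        j = col[qc_variants["QCHWE"]]
        calls[:, j] = REF_HOM
        n_homs = max(6, int(0.02 * n))
        hom_rows = rng.choice(n, size=n_homs, replace=False)
        calls[hom_rows, j] = ALT_HOM
    if "QCMISS" in qc_variants:
        j = col[qc_variants["QCMISS"]]
        calls[:, j] = rng.binomial(2, 0.1, size=n)
        miss_rows = rng.choice(n, size=max(1, int(math.ceil(0.05 * n))), replace=False)
        calls[miss_rows, j] = MISSING
    failing_individual: int | None = None
    if config.qc.missing_individual:
        failing_individual = 0
        k_miss = max(1, int(math.ceil(0.05 * len(all_keys))))
        miss_cols = rng.choice(len(all_keys), size=k_miss, replace=False)
        calls[failing_individual, miss_cols] = MISSING
    # a site-level GT is shared across decomposed ALTs: synchronize missingness
    for group in multiallelic_groups:
        cols = [col[k] for k in group]
        any_missing = (calls[:, cols] == MISSING).any(axis=1)
        for c in cols:
            calls[any_missing, c] = MISSING

    # --- read depths --------------------------------------------------------
    ref_depth = alt_depth = None
    if config.emit_depths:
        depth = rng.poisson(config.mean_depth, size=calls.shape).astype(np.int32)
        depth = np.maximum(depth, 10)
        ref_depth = np.full(calls.shape, MISSING, dtype=np.int32)
        alt_depth = np.full(calls.shape, MISSING, dtype=np.int32)
        het_mask = calls == HET
        alt_counts = rng.binomial(depth, 0.5)
        ref_depth[het_mask] = depth[het_mask] - alt_counts[het_mask]
        alt_depth[het_mask] = alt_counts[het_mask]
        ref_depth[calls == REF_HOM] = depth[calls == REF_HOM]
        alt_depth[calls == REF_HOM] = 0
        ref_depth[calls == ALT_HOM] = 0
        alt_depth[calls == ALT_HOM] = depth[calls == ALT_HOM]
        if mosaic_cell is not None:
            i, j = mosaic_cell
            ref_depth[i, j] = config.mosaic.depth - mosaic_alt_reads
            alt_depth[i, j] = mosaic_alt_reads

    matrix = GenotypeMatrix(individuals, all_keys, calls, ref_depth, alt_depth)

    # --- metadata ------------------------------------------------------------
    statuses = list(config.consent_probs)
    probs = np.array([config.consent_probs[s] for s in statuses], dtype=float)
    probs /= probs.sum()
    consent = rng.choice(statuses, size=n, p=probs)
    ancestry = np.array(["full_islander"] * n, dtype=object)
    a_par, a_gp, a_full = config.singleton_ancestry
    anc_labels = (
        ["nonislander_parent"] * a_par
        + ["nonislander_grandparent"] * a_gp
        + ["full_islander"] * a_full
    )
    rng.shuffle(anc_labels)
    for carrier, lab in zip(singleton_carriers, anc_labels):
        ancestry[carrier] = lab
    metadata = pd.DataFrame(
        {
            "individual_id": individuals,
            "subcohort": subcohort,
            "consent_status": consent,
            "ancestry": ancestry,
        }
    )

    ref_rows = []
    origin_flags: dict[VariantKey, bool] = {}
    for key in keys:
        pv = variant_info[key]
        if pv.gene.startswith("SING"):
            continue
        ref_rows.append(
            {
                "CHROM": key.chrom,
                "POS": key.pos,
                "REF": key.ref,
                "ALT": key.alt,
                "ref_maf": pv.ref_maf,
                "ref_allele_number": pv.ref_allele_number,
                "origin_pre1800": pv.origin_pre1800,
            }
        )
        origin_flags[key] = pv.origin_pre1800
    ref_freq_table = pd.DataFrame(
        ref_rows,
        columns=["CHROM", "POS", "REF", "ALT", "ref_maf", "ref_allele_number", "origin_pre1800"],
    )

    gene_rules = _build_rules(roster, keys, variant_info)
    truth = _derive_truth(config, matrix, variant_info, gene_rules, consent, individuals)

    bundle = CohortBundle(
        config=config,
        reference=reference,
        matrix=matrix,
        annotations=annotations,
        rendered_keys=rendered,
        multiallelic_groups=multiallelic_groups,
        clinvar_records=clinvar_rows,
        gene_rules=gene_rules,
        sample_metadata=metadata,
        ref_freq_table=ref_freq_table,
        origin_flags=origin_flags,
        truth=truth,
        variant_info=variant_info,
    )
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


def _hgvs_c(pv: PlantedVariant, key: VariantKey, slot: int) -> str:
    base = 300 + 10 * slot
    if pv.consequence == "splice_acceptor":
        return f"c.{base}-2A>G"
    if pv.consequence == "splice_donor":
        return f"c.{base}+2T>C"
    if pv.consequence == "splice_region":
        return f"c.{base}+3G>C"
    if pv.kind == "del":
        return f"c.{base}_{base + len(key.ref) - len(key.alt) - 1}del"
    if pv.kind == "ins":
        return f"c.{base}_{base + 1}insTC"
    return f"c.{base}{key.ref}>{key.alt}"


def _sig_code(text: str) -> str:
    t = text.strip().lower()
    if t in ("p", "pathogenic"):
        return "P"
    if t in ("lp", "likely pathogenic"):
        return "LP"
    if t in ("p/lp", "p_lp", "pathogenic/likely pathogenic"):
        return "P_LP"
    return text


def _shifted_clinvar_key(reference: dict, key: VariantKey) -> VariantKey:
    """A coordinate-distinct stand-in for a database rendering that only the
    protein-level merge can recover (synthetic by construction)."""
    seq = reference[key.chrom]
    pos = key.pos + 25
    ref = seq[pos - 1 : pos - 1 + len(key.ref)]
    alt = ref[: len(key.alt)]
    if ref == alt or len(set(ref)) == 1:
        pos += 3
        ref = seq[pos - 1 : pos - 1 + len(key.ref)]
        alt = ref[: len(key.alt)]
    return VariantKey(key.chrom, pos, ref, alt)


def _build_rules(
    roster: Sequence[PlantedVariant],
    keys: Sequence[VariantKey],
    variant_info: dict,
) -> list[GeneRule]:
    rules: dict[str, GeneRule] = {}
    for key in keys:
        pv = variant_info[key]
        if pv.gene in rules:
            continue
        if pv.named_hom_only:
            klass, named = "named_variant_hom_only", key
        elif pv.lof_only_gene:
            klass, named = "LoF_only", None
        else:
            klass, named = "all_P_LP", None
        rules[pv.gene] = GeneRule(
            gene_symbol=pv.gene,
            disease_name=pv.disease,
            category=pv.category if pv.category in ("cancer", "metabolic", "cardiovascular") else "other",
            inheritance="AD" if pv.inheritance == "AD" else "AR",
            actionable_classes=klass,
            named_variant=named,
        )
    return list(rules.values())


def _derive_truth(
    config: SyntheticCohortConfig,
    matrix: GenotypeMatrix,
    variant_info: dict,
    gene_rules: Sequence[GeneRule],
    consent: np.ndarray,
    individuals: Sequence[str],
) -> TruthTable:
    """Inline re-derivation of the actionable set from the realized matrix.

    Intentionally written as straight-line logic independent of the screening
    modules (shared helpers are limited to the HWE test and the mosaic
    binomial, whose own correctness is covered by enumeration oracles).
    """
    from .qc import hwe_exact_test

    rule_map = {r.gene_symbol: r for r in gene_rules}
    calls = matrix.calls
    n, m = calls.shape

    # QC-failed individuals: > 3% missing
    sm = (calls == MISSING).mean(axis=1)
    bad_inds = [i for i in range(n) if sm[i] > 0.03]
    keep = np.array([i for i in range(n) if i not in bad_inds])
    sub = calls[keep]

    bad_vars: list[int] = []
    for j in range(m):
        colv = sub[:, j]
        called = colv != MISSING
        a = int((colv == REF_HOM).sum())
        h = int((colv == HET).sum())
        b = int((colv == ALT_HOM).sum())
        if called.sum() == 0 or min(2 * a + h, 2 * b + h) == 0:
            bad_vars.append(j)
        elif (colv == MISSING).mean() > 0.02:
            bad_vars.append(j)
        elif hwe_exact_test(a, h, b) < 1e-6:
            bad_vars.append(j)

    findings: set = set()
    carriers: set = set()
    mosaics: set = set()
    pathogenic_cols = {}
    for j, key in enumerate(matrix.variants):
        pv = variant_info.get(key)
        if pv is None or j in bad_vars:
            continue
        if _sig_code(pv.significance) not in ("P", "LP", "P_LP"):
            continue
        if star_rating(pv.review_status) < 1:
            continue
        rule = rule_map[pv.gene]
        if rule.actionable_classes == "LoF_only" and pv.consequence not in (
            "stop_gain",
            "frameshift",
            "splice_donor",
            "splice_acceptor",
        ):
            continue
        pathogenic_cols[j] = (key, pv, rule)

    for i in range(n):
        if i in bad_inds:
            continue
        by_gene: dict[str, list[tuple[VariantKey, int]]] = {}
        for j, (key, pv, rule) in pathogenic_cols.items():
            z = int(calls[i, j])
            if z not in (HET, ALT_HOM):
                continue
            if z == HET and matrix.ref_depth is not None:
                rd, ad = int(matrix.ref_depth[i, j]), int(matrix.alt_depth[i, j])
                if rd != MISSING and ad != MISSING and rd + ad >= 1:
                    vaf = ad / (rd + ad)
                    if vaf < 0.25 and binomtest(ad, rd + ad, 0.5).pvalue < 0.001:
                        mosaics.add((individuals[i], str(key)))
                        continue
            by_gene.setdefault(pv.gene, []).append((key, z))
        for gene, zygs in by_gene.items():
            rule = rule_map[gene]
            if rule.actionable_classes == "named_variant_hom_only":
                for key, z in zygs:
                    if key == rule.named_variant and z == ALT_HOM:
                        findings.add(
                            (individuals[i], gene, (str(key),), "recessive_hom")
                        )
                continue
            if rule.inheritance == "AD":
                for key, z in zygs:
                    pat = "dominant_het" if z == HET else "dominant_hom"
                    findings.add((individuals[i], gene, (str(key),), pat))
                continue
            homs = [key for key, z in zygs if z == ALT_HOM]
            hets = [key for key, z in zygs if z == HET]
            for key in homs:
                findings.add((individuals[i], gene, (str(key),), "recessive_hom"))
            if len(hets) >= 2:
                findings.add(
                    (
                        individuals[i],
                        gene,
                        tuple(str(k) for k in sorted(hets)),
                        "compound_het_putative",
                    )
                )
            elif len(hets) == 1 and not homs:
                carriers.add((individuals[i], gene))

    drifted = {
        str(k) for k, pv in variant_info.items() if pv.intended_drifted
    }
    return TruthTable(
        findings=findings,
        carrier_only=carriers,
        mosaics=mosaics,
        qc_failed_individuals=[individuals[i] for i in bad_inds],
        qc_failed_variants=[str(matrix.variants[j]) for j in bad_vars],
        consent={ind: str(c) for ind, c in zip(individuals, consent)},
        drifted_variants=drifted,
    )


def write_bundle(bundle: CohortBundle, out_dir: str | Path) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "cohort.vcf",
        "reference": out / "reference.fa",
        "clinvar": out / "clinvar.tsv",
        "rules": out / "gene_rules.tsv",
        "samples": out / "samples.tsv",
        "ref_freqs": out / "ref_freqs.tsv",
        "truth": out / "truth.json",
    }
    write_vcf(
        bundle.matrix,
        paths["vcf"],
        reference=bundle.reference,
        annotations=bundle.annotations,
        rendered_keys=bundle.rendered_keys,
        multiallelic_groups=bundle.multiallelic_groups,
    )
    write_fasta(bundle.reference, paths["reference"])
    write_clinvar_table(bundle.clinvar_records, paths["clinvar"])
    write_gene_rules(bundle.gene_rules, paths["rules"])
    bundle.sample_metadata.to_csv(paths["samples"], sep="\t", index=False)
    bundle.ref_freq_table.to_csv(paths["ref_freqs"], sep="\t", index=False)
    truth = bundle.truth
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "findings": sorted([list(f[:2]) + [list(f[2]), f[3]] for f in truth.findings]),
                "carrier_only": sorted([list(c) for c in truth.carrier_only]),
                "mosaics": sorted([list(mc) for mc in truth.mosaics]),
                "qc_failed_individuals": truth.qc_failed_individuals,
                "qc_failed_variants": truth.qc_failed_variants,
                "consent": truth.consent,
                "drifted_variants": sorted(truth.drifted_variants),
            },
            fh,
            indent=1,
        )
    bundle.paths = {k: str(v) for k, v in paths.items()}
    return bundle.paths


# --- presets -----------------------------------------------------------------


def minimal_config(seed: int, n_orkney: int = 100, n_shetland: int = 100) -> SyntheticCohortConfig:
    """Small, feature-complete cohort: every screening behaviour is exercised
    at desk scale (drifted AD allele, LoF-only gene with a misrendered indel
    and a class-filtered missense, a two-allele recessive gene with a planted
    compound het, a named-allele homozygote gene, a protein-level-only match,
    a mosaic, singletons and QC plants)."""
    planted = [
        PlantedVariant("GENEA", "AD", "missense", 0.02, 0.0, ref_maf=2e-4,
                       intended_drifted=True, category="cancer"),
        PlantedVariant("GENLOF", "AD", "stop_gain", 0.0, 0.02, ref_maf=1e-4,
                       lof_only_gene=True, category="cardiovascular"),
        PlantedVariant("GENLOF", "AD", "frameshift", 0.0, 0.03, ref_maf=1e-4,
                       lof_only_gene=True, kind="del", misrender=True,
                       category="cardiovascular"),
        PlantedVariant("GENLOF", "AD", "missense", 0.05, 0.05, ref_maf=1e-3,
                       lof_only_gene=True, category="cardiovascular"),
        PlantedVariant("GENAR", "AR", "missense", 0.06, 0.06, ref_maf=1e-3,
                       category="metabolic"),
        PlantedVariant("GENAR", "AR", "frameshift", 0.05, 0.05, ref_maf=1e-3,
                       kind="ins", category="metabolic"),
        PlantedVariant("GENHOM", "AR", "missense", 0.15, 0.15, ref_maf=0.05,
                       named_hom_only=True, category="metabolic"),
        PlantedVariant("GENPF", "AD", "frameshift", 0.03, 0.03, ref_maf=1e-4,
                       kind="del", protein_fallback=True),
        PlantedVariant("GENCAR", "AR", "missense", 0.02, 0.02, ref_maf=1e-3),
    ]
    return SyntheticCohortConfig(
        seed=seed,
        n_orkney=n_orkney,
        n_shetland=n_shetland,
        planted=planted,
        n_singletons=3,
        singleton_ancestry=(1, 1, 1),
        compound_het_genes=["GENAR"],
        mosaic=MosaicSpec(),
    )


def paper_mimic_config(seed: int, scale: float = 1.0) -> SyntheticCohortConfig:
    """Two archipelagos at the study's QC-passed sizes with drifted-variant
    frequencies shaped like the published founder-effect table."""
    n_ork = max(20, int(round(2090 * scale)))
    n_shet = max(20, int(round(2108 * scale)))
    t4 = [
        # gene, inherit, conseq, f_ork, f_shet, fold (vs reference), kind, lof
        ("BRCA1", "AD", "missense", 0.00478, 0.0, 470, "snv", False),
        ("BRCA2", "AD", "splice_acceptor", 0.0, 0.00237, 155, "snv", False),
        ("ATP7B", "AR", "frameshift", 0.0, 0.00475, 180, "del", False),
        ("ATP7B", "AR", "missense", 0.0, 0.00356, 350, "snv", False),
        ("ATP7B", "AR", "missense", 0.00215, 0.0, 600, "snv", False),
        ("TTN", "AD", "frameshift", 0.0, 0.0038, 3700, "del", True),
        ("TTN", "AD", "stop_gain", 0.00048, 0.00071, 470, "snv", True),
        ("KCNH2", "AD", "missense", 0.0, 0.0011, 90, "snv", False),
        ("MUTYH", "AR", "missense", 0.0043, 0.00047, 170, "snv", False),
        ("GAA", "AR", "missense", 0.0028, 0.0, 740, "snv", False),
    ]
    planted = [
        PlantedVariant(
            gene, inh, cq, fo, fs,
            ref_maf=max(fo, fs) / fold,
            kind=kind,
            lof_only_gene=lof,
            intended_drifted=True,
            misrender=(kind != "snv"),
            category="cardiovascular" if gene in ("TTN", "KCNH2") else
            ("cancer" if gene in ("BRCA1", "BRCA2", "MUTYH") else "metabolic"),
        )
        for gene, inh, cq, fo, fs, fold, kind, lof in t4
    ]
    planted += [
        # non-drifted alleles completing the summed gene frequencies
        PlantedVariant("ATP7B", "AR", "missense", 0.0005, 0.00145, ref_maf=1.4e-3),
        PlantedVariant("ATP7B", "AR", "missense", 0.0005, 0.00144, ref_maf=1.4e-3),
        PlantedVariant("TTN", "AD", "stop_gain", 0.0, 0.0007, ref_maf=7e-4, lof_only_gene=True),
        PlantedVariant("MUTYH", "AR", "missense", 0.0052, 0.001, ref_maf=5e-3),
        PlantedVariant("MUTYH", "AR", "missense", 0.0052, 0.001, ref_maf=5e-3),
        PlantedVariant("HFE", "AR", "missense", 0.08, 0.08, ref_maf=0.077, named_hom_only=True),
        PlantedVariant("BTD", "AR", "missense", 0.004, 0.004, ref_maf=3e-3),
        PlantedVariant("CASQ2", "AR", "missense", 0.002, 0.002, ref_maf=2e-3),
        PlantedVariant("RPE65", "AR", "missense", 0.002, 0.002, ref_maf=2e-3),
    ]
    return SyntheticCohortConfig(
        seed=seed,
        n_orkney=n_ork,
        n_shetland=n_shet,
        planted=planted,
        n_singletons=27,
        singleton_ancestry=(13, 4, 10),
        compound_het_genes=["MUTYH", "ATP7B"],
        mosaic=MosaicSpec(depth=85, true_vaf=0.15),
    )
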