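"""Parsing and filtering of ClinVar ``variant_summary.txt``-dialect tables.

ClinVar assigns every classified variant a clinical significance and a review
status; the review status maps onto the familiar 0-4 star scale.  The screen
keeps only pathogenic / likely-pathogenic records with at least one star —
i.e. at least "criteria provided" by a submitter — and aggregates duplicate
rows describing the same genomic variant, dropping variants whose submissions
conflict between the pathogenic and benign families at comparable support.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import pandas as pd

from .variants import (
    ProteinChange,
    VariantKey,
    infer_consequence,
    parse_protein_change,
)

log = logging.getLogger(__name__)

SIGNIFICANCES = ("P", "LP", "P_LP", "B", "LB", "VUS", "conflicting", "other")
PATHOGENIC = frozenset({"P", "LP", "P_LP"})
_BENIGN = frozenset({"B", "LB"})

#: Canonical review-status -> star mapping (case/whitespace-insensitive).
STAR_MAP = {
    "practice guideline": 4,
    "reviewed by expert panel": 3,
    "criteria provided, multiple submitters, no conflicts": 2,
    "criteria provided, multiple submitters": 2,
    "criteria provided, single submitter": 1,
    "criteria provided, conflicting classifications": 1,
    "criteria provided, conflicting interpretations": 1,
    "no assertion criteria provided": 0,
    "no classification provided": 0,
    "no classification for the single variant": 0,
    "no classifications from unflagged records": 0,
    "no assertion provided": 0,
}

MANDATORY_COLUMNS = [
    "GeneSymbol",
    "ClinicalSignificance",
    "ReviewStatus",
    "Assembly",
    "Chromosome",
    "PositionVCF",
    "ReferenceAlleleVCF",
    "AlternateAlleleVCF",
    "Name",
]

_NAME_RE = re.compile(
    r"^(?P<tx>[A-Z]{2}_\d+(?:\.\d+)?)\((?P<gene>[^)]+)\):(?P<c>c\.[^ ]+)"
    r"(?:\s+\((?P<p>p\.[^)]*)\))?"
)


@dataclass(frozen=True)
class ClinVarRecord:
    gene_symbol: str
    assembly: str
    chrom: str
    pos: int
    ref: str
    alt: str
    clinical_significance: str
    review_status: str
    stars: int
    hgvs_c: str | None = None
    hgvs_p: str | None = None
    transcript: str | None = None
    molecular_consequence: str = "other"

    @property
    def key(self) -> VariantKey:
        return VariantKey(self.chrom, self.pos, self.ref, self.alt)

    @property
    def protein_change(self) -> ProteinChange | None:
        if not self.hgvs_p or not self.transcript:
            return None
        return parse_protein_change(self.hgvs_p, self.gene_symbol, self.transcript)


def star_rating(review_status: str) -> int:
    norm = " ".join(review_status.strip().lower().split())
    stars = STAR_MAP.get(norm)
    if stars is None:
        log.warning("unknown ClinVar review status %r -> 0 stars", review_status)
        return 0
    return stars


def classify_significance(text: str) -> str:
    """Collapse a ClinicalSignificance string onto the closed vocabulary.

    Lowercased and split on "/" and ";" so combined renderings such as
    "Pathogenic/Likely pathogenic" map to P_LP.
    """
    tokens = {t.strip() for t in re.split(r"[/;]", text.strip().lower()) if t.strip()}
    has_p = "pathogenic" in tokens
    has_lp = "likely pathogenic" in tokens
    has_b = "benign" in tokens
    has_lb = "likely benign" in tokens
    if any("conflicting" in t for t in tokens):
        return "conflicting"
    if (has_p or has_lp) and not (has_b or has_lb):
        if has_p and has_lp:
            return "P_LP"
        return "P" if has_p else "LP"
    if (has_b or has_lb) and not (has_p or has_lp):
        if has_b and has_lb:
            return "LB"
        return "B" if has_b else "LB"
    if "uncertain significance" in tokens:
        return "VUS"
    return "other"


def _parse_name(name: str) -> tuple[str | None, str | None, str | None]:
    m = _NAME_RE.match(name.strip())
    if m is None:
        return None, None, None
    return m.group("tx"), m.group("c"), m.group("p")


def parse_clinvar_summary(
    path: str | Path,
    assembly: str = "GRCh38",
    tally: Counter | None = None,
) -> list[ClinVarRecord]:
    """Parse a variant_summary-dialect table (gzip-aware) for one assembly.

    Rows on other assemblies, or with unparseable coordinates or non-ACGT
    alleles, are counted into ``tally`` (by reason) and skipped.  Duplicate
    rows for one CHROM:POS:REF:ALT are aggregated: the maximum star rating
    wins; a pathogenic/benign conflict at >=1 star on both sides excludes the
    variant outright.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, compression="infer", keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"ClinVar table {path} is empty") from exc
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"ClinVar table missing mandatory column(s): {missing}")
    if df.empty:
        log.warning("ClinVar table %s has a header but no rows", path)
    tally = tally if tally is not None else Counter()
    records: list[ClinVarRecord] = []
    for _, row in df.iterrows():
        if row["Assembly"].strip() != assembly:
            tally["other_assembly"] += 1
            continue
        try:
            pos = int(row["PositionVCF"])
        except ValueError:
            tally["unparseable_position"] += 1
            continue
        ref = row["ReferenceAlleleVCF"].strip().upper()
        alt = row["AlternateAlleleVCF"].strip().upper()
        try:
            key = VariantKey(row["Chromosome"].strip(), pos, ref, alt)
        except ValueError:
            tally["non_ACGT_allele_or_bad_coordinates"] += 1
            continue
        tx, hgvs_c, hgvs_p = _parse_name(row["Name"])
        conseq = row.get("MolecularConsequence", "").strip() or infer_consequence(
            hgvs_c, hgvs_p
        )
        records.append(
            ClinVarRecord(
                gene_symbol=row["GeneSymbol"].strip(),
                assembly=assembly,
                chrom=key.chrom,
                pos=key.pos,
                ref=key.ref,
                alt=key.alt,
                clinical_significance=classify_significance(row["ClinicalSignificance"]),
                review_status=row["ReviewStatus"].strip(),
                stars=star_rating(row["ReviewStatus"]),
                hgvs_c=hgvs_c,
                hgvs_p=hgvs_p,
                transcript=tx,
                molecular_consequence=conseq,
            )
        )
    return aggregate_records(records, tally)


def aggregate_records(
    records: Iterable[ClinVarRecord], tally: Counter | None = None
) -> list[ClinVarRecord]:
    """One record per CHROM:POS:REF:ALT; max stars; conflicted variants dropped."""
    tally = tally if tally is not None else Counter()
    by_key: dict[VariantKey, list[ClinVarRecord]] = {}
    for rec in records:
        by_key.setdefault(rec.key, []).append(rec)
    out: list[ClinVarRecord] = []
    for key, group in by_key.items():
        if len(group) == 1:
            out.append(group[0])
            continue
        path_stars = max(
            (r.stars for r in group if r.clinical_significance in PATHOGENIC), default=-1
        )
        benign_stars = max(
            (r.stars for r in group if r.clinical_significance in _BENIGN), default=-1
        )
        if path_stars >= 1 and benign_stars >= 1:
            log.info("excluding %s: pathogenic/benign conflict at >=1 star each", key)
            tally["significance_conflict"] += 1
            continue
        best = max(group, key=lambda r: r.stars)
        out.append(best)
    return out


def filter_pathogenic(
    records: Iterable[ClinVarRecord],
    min_stars: int = 1,
    tally: Counter | None = None,
) -> list[ClinVarRecord]:
    """Keep P / LP / P_LP records with at least ``min_stars`` stars."""
    tally = tally if tally is not None else Counter()
    kept: list[ClinVarRecord] = []
    for rec in records:
        if rec.clinical_significance not in PATHOGENIC:
            tally["not_pathogenic"] += 1
        elif rec.stars < min_stars:
            tally["below_min_stars"] += 1
        else:
            kept.append(rec)
    return kept


_SIG_RENDER = {
    "P": "Pathogenic",
    "LP": "Likely pathogenic",
    "P_LP": "Pathogenic/Likely pathogenic",
    "B": "Benign",
    "LB": "Likely benign",
    "VUS": "Uncertain significance",
    "conflicting": "Conflicting classifications of pathogenicity",
    "other": "other",
}


def write_clinvar_table(records: Iterable[ClinVarRecord], path: str | Path) -> None:
    """Serialize records back into the variant_summary dialect (round-trips
    through :func:`parse_clinvar_summary` for the retained fields)."""
    rows = []
    for r in records:
        name = ""
        if r.transcript and r.hgvs_c:
            name = f"{r.transcript}({r.gene_symbol}):{r.hgvs_c}"
            if r.hgvs_p:
                name += f" ({r.hgvs_p})"
        rows.append(
            {
                "GeneSymbol": r.gene_symbol,
                "ClinicalSignificance": _SIG_RENDER[r.clinical_significance],
                "ReviewStatus": r.review_status,
                "Assembly": r.assembly,
                "Chromosome": r.chrom,
                "PositionVCF": r.pos,
                "ReferenceAlleleVCF": r.ref,
                "AlternateAlleleVCF": r.alt,
                "Name": name,
                "MolecularConsequence": r.molecular_consequence,
            }
        )
    columns = MANDATORY_COLUMNS + ["MolecularConsequence"]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)
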