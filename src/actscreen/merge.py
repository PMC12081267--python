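"""Two-stage matching of cohort variants against classified variants.

Stage one joins on the normalized four-column key (CHROM, POS, REF, ALT); this
is the only safe genomic join — rsid-keyed merges conflate multiallelic sites.
Stage two rescues indels whose genomic renderings genuinely differ but whose
annotated protein consequence is identical on the same transcript (the classic
case: a repeat-context deletion rendered at different offsets that the
annotation pipeline and the classification database spelled differently).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

from .clinvar import ClinVarRecord
from .variants import ProteinChange, VariantKey

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Match:
    """One cohort variant resolved to one aggregated ClinVar record."""

    variant: VariantKey
    record: ClinVarRecord
    provenance: str  # "coordinate" | "protein-level"


def merge_by_coordinates(
    cohort_variants: list[VariantKey],
    clinvar: list[ClinVarRecord],
) -> tuple[list[Match], list[VariantKey]]:
    """Exact join on chrom/pos/ref/alt.  Both sides must be normalized against
    the same reference; unmatched cohort variants pass through for the
    protein-level fallback."""
    for key in cohort_variants:
        if not key.normalized:
            raise ValueError(f"cohort variant {key} is not normalized")
    index: dict[tuple, ClinVarRecord] = {}
    for rec in clinvar:
        k = (rec.chrom, rec.pos, rec.ref, rec.alt)
        if k in index:
            raise ValueError(f"ClinVar input not aggregated: duplicate key {k}")
        index[k] = rec
    matches: list[Match] = []
    unmatched: list[VariantKey] = []
    for key in cohort_variants:
        rec = index.get((key.chrom, key.pos, key.ref, key.alt))
        if rec is None:
            unmatched.append(key)
        else:
            matches.append(Match(key, rec, "coordinate"))
    return matches, unmatched


def merge_by_protein_change(
    unmatched: list[tuple[VariantKey, ProteinChange | None]],
    clinvar: list[ClinVarRecord],
    tally: Counter | None = None,
) -> list[Match]:
    """Fallback join on (gene, transcript, protein change).

    Transcript accessions are compared version-insensitively but never across
    transcripts: residue numbering is isoform-specific.  ClinVar records whose
    p. string falls outside the supported grammar are counted, not dropped
    silently; cohort variants without protein annotation are skipped likewise.
    """
    tally = tally if tally is not None else Counter()
    index: dict[tuple, ClinVarRecord] = {}
    for rec in clinvar:
        pc = rec.protein_change
        if rec.hgvs_p and pc is None:
            tally["clinvar_unparseable_hgvs_p"] += 1
            continue
        if pc is None:
            continue
        k = (pc.gene_symbol, pc.transcript_base, pc.residue_pos, pc.ref_aa, pc.alt_aa)
        # first record wins; coordinate-distinct records with one protein
        # rendering are expected (that is the point of this merge)
        index.setdefault(k, rec)
    matches: list[Match] = []
    for key, pc in unmatched:
        if pc is None:
            tally["cohort_missing_protein_annotation"] += 1
            continue
        rec = index.get(
            (pc.gene_symbol, pc.transcript_base, pc.residue_pos, pc.ref_aa, pc.alt_aa)
        )
        if rec is not None:
            matches.append(Match(key, rec, "protein-level"))
    return matches


def two_stage_merge(
    cohort: list[tuple[VariantKey, ProteinChange | None]],
    clinvar: list[ClinVarRecord],
    tally: Counter | None = None,
) -> tuple[list[Match], list[VariantKey]]:
    """Coordinate join, then protein fallback on the remainder.

    Returns (matches, still-unmatched).  The union of matched and unmatched
    variants equals the input set — nothing is lost or duplicated.
    """
    keys = [k for k, _ in cohort]
    annot = dict(zip(keys, (pc for _, pc in cohort)))
    matches, unmatched = merge_by_coordinates(keys, clinvar)
    fallback = merge_by_protein_change(
        [(k, annot[k]) for k in unmatched], clinvar, tally
    )
    matched_keys = {m.variant for m in fallback}
    remaining = [k for k in unmatched if k not in matched_keys]
    return matches + fallback, remaining
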