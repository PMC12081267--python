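"""Return-of-results accounting: clinical-review overrides, consent overlay,
and per-individual structured reports.

Genetics and governance stay separable: the screen never deletes a finding.
A clinical-review override marks a variant's findings not returnable (audit
preserved); the cohort summary then assigns every person with an actionable
genotype to exactly one category — not returnable taking precedence, then
their consent status — so the categories partition the people and their sum
equals the total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .actionability import ActionableGenotype
from .founder import FrequencyRecord
from .rules import GeneRule
from .variants import VariantKey

log = logging.getLogger(__name__)

CONSENT_STATUSES = (
    "consented",
    "no_reply",
    "declined",
    "deceased_no_request",
    "deceased_next_of_kin_consented",
)


@dataclass(frozen=True)
class ConsentRecord:
    individual_id: str
    status: str

    def __post_init__(self) -> None:
        if self.status not in CONSENT_STATUSES:
            raise ValueError(f"unknown consent status {self.status!r}")


@dataclass(frozen=True)
class ReviewOverride:
    variant: VariantKey
    returnable: bool
    reason: str = ""


def apply_review_overrides(
    findings: Sequence[ActionableGenotype],
    overrides: Sequence[ReviewOverride],
    known_variants: Iterable[VariantKey] | None = None,
) -> list[ActionableGenotype]:
    """Set returnable flags from a clinical-review override table.

    A finding is not returnable if any of its variants is overridden to not
    returnable.  Overrides naming variants absent from the screen are warned
    about and ignored.
    """
    known = set(known_variants) if known_variants is not None else {
        v for f in findings for v in f.variants
    }
    by_variant = {}
    for ov in overrides:
        if ov.variant not in known:
            log.warning("override for unknown variant %s ignored", ov.variant)
            continue
        by_variant[ov.variant] = ov
    out = []
    n_affected = 0
    for f in findings:
        flags = [by_variant[v].returnable for v in f.variants if v in by_variant]
        if flags and not all(flags):
            out.append(replace(f, returnable=False))
            n_affected += 1
        else:
            out.append(f)
    if by_variant:
        log.info(
            "review overrides: %d variant(s) overridden affecting %d finding(s)",
            len(by_variant),
            n_affected,
        )
    return out


@dataclass(frozen=True)
class RorSummary:
    letters_sent: int
    not_consented_no_reply: int
    deceased_no_request: int
    declined: int
    not_returnable_by_clinical_review: int
    total_people: int

    def __post_init__(self) -> None:
        total = (
            self.letters_sent
            + self.not_consented_no_reply
            + self.deceased_no_request
            + self.declined
            + self.not_returnable_by_clinical_review
        )
        if total != self.total_people:
            raise ValueError(
                f"category sum {total} does not equal total_people {self.total_people}"
            )


def ror_summary(
    findings: Sequence[ActionableGenotype],
    consent: Sequence[ConsentRecord],
    supplemental_individuals: Sequence[str] = (),
) -> RorSummary:
    """Assign every person with an actionable genotype to one category.

    A person with no returnable finding at all falls under clinical review;
    anyone with at least one returnable finding is categorized by consent
    (a letter can still be sent about the returnable one).  Letters go to the
    consented and to consenting next of kin.  ``supplemental_individuals``
    adds people outside the findings list (e.g. the dominant-allele males
    added after an ethics amendment); they must hold consent records too.
    """
    by_ind: dict[str, list[ActionableGenotype]] = {}
    for f in findings:
        by_ind.setdefault(f.individual_id, []).append(f)
    for ind in supplemental_individuals:
        by_ind.setdefault(ind, [])
    consent_map = {c.individual_id: c.status for c in consent}
    missing = [
        ind
        for ind, fs in sorted(by_ind.items())
        if (not fs or any(f.returnable for f in fs)) and ind not in consent_map
    ]
    if missing:
        raise ValueError(f"missing consent record(s) for: {missing}")
    counts = {
        "letters_sent": 0,
        "not_consented_no_reply": 0,
        "deceased_no_request": 0,
        "declined": 0,
        "not_returnable_by_clinical_review": 0,
    }
    for ind, fs in by_ind.items():
        if fs and not any(f.returnable for f in fs):
            counts["not_returnable_by_clinical_review"] += 1
            continue
        status = consent_map[ind]
        if status in ("consented", "deceased_next_of_kin_consented"):
            counts["letters_sent"] += 1
        elif status == "no_reply":
            counts["not_consented_no_reply"] += 1
        elif status == "declined":
            counts["declined"] += 1
        else:
            counts["deceased_no_request"] += 1
    return RorSummary(total_people=len(by_ind), **counts)


@dataclass(frozen=True)
class IndividualReport:
    """Machine-readable per-finding report record; no clinical free text."""

    individual_id: str
    gene_symbol: str
    disease_name: str
    inheritance: str
    variants_vcf: tuple[str, ...]
    variants_hgvs: tuple[str, ...]
    zygosity_pattern: str
    phase_unconfirmed: bool
    provenance: tuple[str, ...]
    subcohort: str | None
    cohort_maf: float | None


def individual_report(
    finding: ActionableGenotype,
    rule: GeneRule,
    frequency: FrequencyRecord | None = None,
    hgvs: Mapping[VariantKey, str] | None = None,
) -> IndividualReport:
    if finding.mosaic_flag:
        raise ValueError("mosaic-flagged findings are not reportable")
    if not finding.returnable:
        raise ValueError("finding is marked not returnable by clinical review")
    hgvs = hgvs or {}
    return IndividualReport(
        individual_id=finding.individual_id,
        gene_symbol=finding.gene_symbol,
        disease_name=rule.disease_name,
        inheritance=rule.inheritance,
        variants_vcf=tuple(str(v) for v in finding.variants),
        variants_hgvs=tuple(hgvs.get(v, "") for v in finding.variants),
        zygosity_pattern=finding.zygosity_pattern,
        phase_unconfirmed=finding.zygosity_pattern == "compound_het_putative",
        provenance=finding.provenance,
        subcohort=frequency.subcohort if frequency else None,
        cohort_maf=frequency.maf if frequency else None,
    )
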