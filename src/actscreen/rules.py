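"""ACMG actionability rules: which genes, inheritance modes and variant
classes make a finding reportable.

Each gene on the secondary-findings list carries a contract: the disease, the
inheritance mode (AD / AR / XL), and which variant classes count as actionable
— every P/LP variant, only loss-of-function (truncating) variants, or, in the
hemochromatosis special case, only homozygotes for one named allele.  A default
table covering the genes attested in the source cohort ships with the package;
any other gene is supplied by the user in the same tab-delimited dialect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

from .variants import CONSEQUENCES, VariantKey

log = logging.getLogger(__name__)

INHERITANCES = ("AD", "AR", "XL")
ACTIONABLE_CLASSES = ("all_P_LP", "LoF_only", "named_variant_hom_only")
CATEGORIES = ("cancer", "metabolic", "cardiovascular", "other")

#: Truncating classes accepted by LoF_only rules (TTN-style).
LOF_CONSEQUENCES = frozenset({"stop_gain", "frameshift", "splice_donor", "splice_acceptor"})

RULE_COLUMNS = [
    "gene_symbol",
    "disease",
    "category",
    "inheritance",
    "actionable_classes",
    "named_variant",
    "notes",
]


@dataclass(frozen=True)
class GeneRule:
    gene_symbol: str
    disease_name: str
    category: str
    inheritance: str
    actionable_classes: str
    named_variant: VariantKey | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        if self.inheritance not in INHERITANCES:
            raise ValueError(
                f"{self.gene_symbol}: inheritance must be one of {INHERITANCES}, "
                f"got {self.inheritance!r}"
            )
        if self.actionable_classes not in ACTIONABLE_CLASSES:
            raise ValueError(
                f"{self.gene_symbol}: unknown actionable class {self.actionable_classes!r}"
            )
        if self.category not in CATEGORIES:
            raise ValueError(f"{self.gene_symbol}: unknown category {self.category!r}")
        if self.actionable_classes == "named_variant_hom_only" and self.named_variant is None:
            raise ValueError(
                f"{self.gene_symbol}: named_variant_hom_only rule requires a named variant"
            )


def variant_class_allowed(rule: GeneRule, consequence: str) -> bool:
    """Whether ``consequence`` is a reportable class under ``rule``.

    Total over the closed consequence vocabulary.  For a named-variant rule
    the class gate is permissive — the decision is made at genotype level by
    exact allele match, so no consequence is refused here.
    """
    if consequence not in CONSEQUENCES:
        raise ValueError(f"consequence {consequence!r} outside the closed vocabulary")
    if rule.actionable_classes == "LoF_only":
        return consequence in LOF_CONSEQUENCES
    return True


def load_gene_rules(path: str | Path) -> list[GeneRule]:
    """Load a tab-delimited gene-rules table (header mandatory, one row/gene)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False).fillna("")
    if "named_variant" not in df.columns:
        df["named_variant"] = ""
    if "notes" not in df.columns:
        df["notes"] = ""
    missing = [c for c in RULE_COLUMNS if c not in df.columns and c != "notes"]
    if missing:
        raise ValueError(f"gene-rules table missing column(s): {missing}")
    rules: list[GeneRule] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        gene = row["gene_symbol"].strip()
        if gene in seen:
            raise ValueError(f"duplicate gene symbol {gene!r} at row {i + 2}")
        seen.add(gene)
        named = row.get("named_variant", "").strip()
        try:
            rules.append(
                GeneRule(
                    gene_symbol=gene,
                    disease_name=row["disease"].strip(),
                    category=row["category"].strip(),
                    inheritance=row["inheritance"].strip(),
                    actionable_classes=row["actionable_classes"].strip(),
                    named_variant=VariantKey.parse(named) if named else None,
                    notes=str(row.get("notes", "")).strip(),
                )
            )
        except ValueError as exc:
            raise ValueError(f"gene-rules row {i + 2} ({gene}): {exc}") from exc
    if not rules:
        log.warning("gene-rules table %s contains no rules", path)
    log.info("loaded %d gene rules from %s", len(rules), path)
    return rules


def write_gene_rules(rules: Iterable[GeneRule], path: str | Path) -> None:
    rows = [
        {
            "gene_symbol": r.gene_symbol,
            "disease": r.disease_name,
            "category": r.category,
            "inheritance": r.inheritance,
            "actionable_classes": r.actionable_classes,
            "named_variant": str(r.named_variant) if r.named_variant else "",
            "notes": r.notes,
        }
        for r in rules
    ]
    pd.DataFrame(rows, columns=RULE_COLUMNS).to_csv(path, sep="\t", index=False)


def default_gene_rules() -> list[GeneRule]:
    """The packaged rule set for the genes attested in the source cohort."""
    with resources.as_file(
        resources.files("actscreen.data").joinpath("default_gene_rules.tsv")
    ) as p:
        return load_gene_rules(p)


def rules_by_gene(rules: Iterable[GeneRule]) -> dict[str, GeneRule]:
    return {r.gene_symbol: r for r in rules}
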