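"""In-memory genotype matrix and VCF round-trip.

Calls are coded ref_hom=0, het=1, alt_hom=2, missing=-1 in an int8 array of
shape (individuals, variants); optional per-call allelic read depths ride
along in two parallel int32 arrays (-1 where absent).  Multiallelic VCF rows
are decomposed into biallelic keys on read, since the four-column coordinate
join is only sound on biallelic records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pysam

from .variants import VariantKey

REF_HOM, HET, ALT_HOM, MISSING = 0, 1, 2, -1

ZYGOSITY_NAMES = {REF_HOM: "ref_hom", HET: "het", ALT_HOM: "alt_hom", MISSING: "missing"}


@dataclass(frozen=True)
class VariantAnnotation:
    """Cohort-side annotation carried in VCF INFO (GENE, CONSEQ, TX, HGVSC, HGVSP)."""

    gene: str | None = None
    consequence: str | None = None
    transcript: str | None = None
    hgvs_c: str | None = None
    hgvs_p: str | None = None


@dataclass
class GenotypeMatrix:
    individuals: list[str]
    variants: list[VariantKey]
    calls: np.ndarray  # int8, (n_individuals, n_variants)
    ref_depth: np.ndarray | None = None
    alt_depth: np.ndarray | None = None

    def __post_init__(self) -> None:
        n, m = len(self.individuals), len(self.variants)
        if self.calls.shape != (n, m):
            raise ValueError(f"calls shape {self.calls.shape} != ({n}, {m})")
        if not np.isin(self.calls, [REF_HOM, HET, ALT_HOM, MISSING]).all():
            raise ValueError("calls outside the closed zygosity vocabulary")
        for d in (self.ref_depth, self.alt_depth):
            if d is not None:
                if d.shape != (n, m):
                    raise ValueError("depth array shape mismatch")
                if (d[d != MISSING] < 0).any():
                    raise ValueError("allelic depths must be non-negative")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_missingness(self) -> np.ndarray:
        return (self.calls == MISSING).mean(axis=0)

    def sample_missingness(self) -> np.ndarray:
        return (self.calls == MISSING).mean(axis=1)

    def genotype_counts(self, j: int) -> tuple[int, int, int]:
        col = self.calls[:, j]
        return (
            int((col == REF_HOM).sum()),
            int((col == HET).sum()),
            int((col == ALT_HOM).sum()),
        )

    def variant_index(self) -> dict[VariantKey, int]:
        return {v: j for j, v in enumerate(self.variants)}

    def subset(
        self,
        individual_idx: Sequence[int] | None = None,
        variant_idx: Sequence[int] | None = None,
    ) -> "GenotypeMatrix":
        ii = np.arange(self.n_individuals) if individual_idx is None else np.asarray(individual_idx)
        jj = np.arange(self.n_variants) if variant_idx is None else np.asarray(variant_idx)
        sub = lambda a: None if a is None else a[np.ix_(ii, jj)]
        return GenotypeMatrix(
            [self.individuals[i] for i in ii],
            [self.variants[j] for j in jj],
            self.calls[np.ix_(ii, jj)],
            sub(self.ref_depth),
            sub(self.alt_depth),
        )

    def rename_variants(self, mapping: Mapping[VariantKey, VariantKey]) -> "GenotypeMatrix":
        """Relabel variant keys (e.g. with their normalized renderings)."""
        return GenotypeMatrix(
            self.individuals,
            [mapping.get(v, v) for v in self.variants],
            self.calls,
            self.ref_depth,
            self.alt_depth,
        )


def read_vcf(path: str | Path) -> tuple[GenotypeMatrix, dict[VariantKey, VariantAnnotation]]:
    """Read genotypes (GT) and allelic depths (AD) from a VCF.

    Multiallelic rows are decomposed: each ALT becomes its own biallelic key,
    the genotype w.r.t. that ALT counting only copies of that allele, and the
    AD pair taking the REF and that ALT's depth.  Keys are returned as written
    (unnormalized); normalization is the caller's job.
    """
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        keys: list[VariantKey] = []
        annotations: dict[VariantKey, VariantAnnotation] = {}
        calls_cols: list[np.ndarray] = []
        rd_cols: list[np.ndarray] = []
        ad_cols: list[np.ndarray] = []
        any_depth = False
        for rec in vf:
            alts = rec.alts or ()
            for ai, alt in enumerate(alts, start=1):
                if alt is None:
                    continue
                try:
                    key = VariantKey(rec.chrom, rec.pos, rec.ref, alt)
                except ValueError:
                    continue  # symbolic or degenerate allele
                gt_col = np.full(len(samples), MISSING, dtype=np.int8)
                rd_col = np.full(len(samples), MISSING, dtype=np.int32)
                ad_col = np.full(len(samples), MISSING, dtype=np.int32)
                for si, sample in enumerate(samples):
                    sd = rec.samples[sample]
                    gt = sd.get("GT")
                    if gt is None or any(a is None for a in gt):
                        continue
                    gt_col[si] = min(2, sum(1 for a in gt if a == ai))
                    ad = sd.get("AD")
                    if ad is not None and len(ad) > ai and ad[0] is not None and ad[ai] is not None:
                        rd_col[si], ad_col[si] = ad[0], ad[ai]
                        any_depth = True
                keys.append(key)
                annotations[key] = VariantAnnotation(
                    gene=_info_str(rec, "GENE", ai),
                    consequence=_info_str(rec, "CONSEQ", ai),
                    transcript=_info_str(rec, "TX", ai),
                    hgvs_c=_info_str(rec, "HGVSC", ai),
                    hgvs_p=_info_str(rec, "HGVSP", ai),
                )
                calls_cols.append(gt_col)
                rd_cols.append(rd_col)
                ad_cols.append(ad_col)
    calls = np.column_stack(calls_cols) if calls_cols else np.zeros((len(samples), 0), np.int8)
    rd = np.column_stack(rd_cols) if (rd_cols and any_depth) else None
    ad = np.column_stack(ad_cols) if (ad_cols and any_depth) else None
    return GenotypeMatrix(samples, keys, calls.astype(np.int8), rd, ad), annotations


def _info_str(rec, tag: str, ai: int = 1) -> str | None:
    """Per-ALT INFO value (Number=A); ``ai`` is the 1-based ALT index."""
    if tag not in rec.header.info:
        return None
    val = rec.info.get(tag)
    if val is None:
        return None
    if isinstance(val, tuple):
        val = val[ai - 1] if len(val) >= ai else val[0]
    if val is None:
        return None
    return str(val) if val not in ("", ".") else None


_GT_RENDER = {REF_HOM: (0, 0), HET: (0, 1), ALT_HOM: (1, 1), MISSING: (None, None)}


def write_vcf(
    matrix: GenotypeMatrix,
    path: str | Path,
    reference: Mapping[str, str] | None = None,
    annotations: Mapping[VariantKey, VariantAnnotation] | None = None,
    rendered_keys: Mapping[VariantKey, VariantKey] | None = None,
    multiallelic_groups: Sequence[Sequence[VariantKey]] | None = None,
) -> None:
    """Write a VCF v4.2 with GT (and AD when present).

    ``rendered_keys`` lets the caller emit a variant under an equivalent
    non-normalized rendering; ``multiallelic_groups`` lists sets of matrix
    keys to be folded back into a single multi-ALT row (they must share the
    rendered CHROM/POS/REF).
    """
    annotations = annotations or {}
    rendered_keys = rendered_keys or {}
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    if matrix.ref_depth is not None:
        header.add_line(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">'
        )
    for tag, desc in (
        ("GENE", "Gene symbol"),
        ("CONSEQ", "Molecular consequence"),
        ("TX", "Transcript accession"),
        ("HGVSC", "HGVS cDNA change"),
        ("HGVSP", "HGVS protein change"),
    ):
        header.add_line(f'##INFO=<ID={tag},Number=A,Type=String,Description="{desc}">')
    contigs = {}
    for v in matrix.variants:
        rk = rendered_keys.get(v, v)
        end = rk.pos + len(rk.ref)
        contigs[rk.chrom] = max(contigs.get(rk.chrom, 0), end + 100)
    if reference is not None:
        for chrom in reference:
            contigs[chrom] = len(reference[chrom])
    for chrom, length in contigs.items():
        header.add_line(f"##contig=<ID={chrom},length={length}>")
    for ind in matrix.individuals:
        header.add_sample(ind)

    index = matrix.variant_index()
    grouped: dict[VariantKey, list[VariantKey]] = {}
    in_group: set[VariantKey] = set()
    for group in multiallelic_groups or ():
        grouped[group[0]] = list(group)
        in_group.update(group)

    with pysam.VariantFile(str(path), "w", header=header) as out:
        order = sorted(
            (v for v in matrix.variants if v not in in_group or v in grouped),
            key=lambda v: (rendered_keys.get(v, v).chrom, rendered_keys.get(v, v).pos),
        )
        for v in order:
            members = grouped.get(v, [v])
            rks = [rendered_keys.get(m, m) for m in members]
            if len({(k.chrom, k.pos, k.ref) for k in rks}) != 1:
                raise ValueError("multiallelic group members must share chrom/pos/ref")
            rec = out.new_record(
                contig=rks[0].chrom,
                start=rks[0].pos - 1,
                alleles=tuple([rks[0].ref] + [k.alt for k in rks]),
            )
            anns = [annotations.get(m) for m in members]
            for tag, getter in (
                ("GENE", lambda a: a.gene),
                ("CONSEQ", lambda a: a.consequence),
                ("TX", lambda a: a.transcript),
                ("HGVSC", lambda a: a.hgvs_c),
                ("HGVSP", lambda a: a.hgvs_p),
            ):
                vals = tuple(
                    (getter(a) if a is not None and getter(a) is not None else ".")
                    for a in anns
                )
                if any(v != "." for v in vals):
                    rec.info[tag] = vals
            cols = [index[m] for m in members]
            for si in range(matrix.n_individuals):
                gts = [int(matrix.calls[si, j]) for j in cols]
                rec.samples[si]["GT"] = _combine_gt(gts)
                if matrix.ref_depth is not None:
                    rds = [int(matrix.ref_depth[si, j]) for j in cols]
                    ads = [int(matrix.alt_depth[si, j]) for j in cols]
                    if any(d != MISSING for d in rds + ads):
                        rec.samples[si]["AD"] = tuple(
                            [max(rds[0], 0)] + [max(a, 0) for a in ads]
                        )
            out.write(rec)


def _combine_gt(gts: list[int]) -> tuple[int | None, int | None]:
    """Fold per-ALT zygosities into one GT tuple over ALT indices 1..k.

    A site-level GT cannot be missing for one ALT and called for another, so
    any missing member renders the whole call missing.
    """
    if any(g == MISSING for g in gts):
        return (None, None)
    alleles: list[int] = []
    for ai, g in enumerate(gts, start=1):
        if g == HET:
            alleles.append(ai)
        elif g == ALT_HOM:
            alleles.extend([ai, ai])
    while len(alleles) < 2:
        alleles.insert(0, 0)
    return tuple(alleles[:2])


def write_fasta(reference: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sorted(reference):
            fh.write(f">{name}\n")
            seq = reference[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
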