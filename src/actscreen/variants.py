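"""Genomic variant keys, indel normalization, and protein-level change parsing.

A :class:`VariantKey` is the four-column identity (CHROM, POS, REF, ALT) used to
join cohort calls against a classification table.  Indels sitting in repeat or
homopolymer context can be rendered at several positions; :func:`normalize_variant`
collapses every equivalent rendering to a single canonical key (parsimonious,
left-aligned), so that the coordinate join is sound.  Where the genomic
renderings differ but the predicted protein consequence is identical, the
fallback join is keyed on :class:`ProteinChange`, parsed from HGVS p. notation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

_ACGT = set("ACGT")

AA3 = {
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
    "Sec", "Pyl", "Xaa",
}


@dataclass(frozen=True, order=True)
class VariantKey:
    """One biallelic variant in VCF convention (1-based POS, anchored indels).

    Equality and ordering are on the four coordinates only; the ``normalized``
    flag records provenance and never distinguishes two keys.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    normalized: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"POS must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("REF and ALT must be non-empty")
        if set(self.ref) - _ACGT or set(self.alt) - _ACGT:
            raise ValueError(f"non-ACGT allele in {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError("REF and ALT are identical")

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @classmethod
    def parse(cls, text: str, normalized: bool = False) -> "VariantKey":
        chrom, pos, ref, alt = text.strip().split(":")
        return cls(chrom, int(pos), ref.upper(), alt.upper(), normalized)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


def _contig(reference: Mapping[str, str], chrom: str) -> str:
    try:
        seq = reference[chrom]
    except KeyError as exc:
        raise KeyError(f"contig {chrom!r} absent from reference") from exc
    return str(seq).upper()


def normalize_variant(key: VariantKey, reference: Mapping[str, str]) -> VariantKey:
    """Return the canonical (trimmed, left-aligned) rendering of ``key``.

    Standard parsimony/left-alignment: shared trailing bases are trimmed, the
    allele pair is shifted left through any repeat run it sits in, and shared
    leading bases beyond the single indel anchor are trimmed.  SNVs pass
    through unchanged and the operation is idempotent.

    ``reference`` maps contig name to its full sequence (a plain dict or any
    mapping, e.g. one built from a FASTA).  A REF allele that disagrees with
    the reference is a hard error: it signals a wrong genome build or a
    corrupt input, not something to paper over.
    """
    seq = _contig(reference, key.chrom)
    pos, ref, alt = key.pos, key.ref.upper(), key.alt.upper()
    if seq[pos - 1 : pos - 1 + len(ref)] != ref:
        raise ValueError(
            f"REF mismatch at {key.chrom}:{pos}: expected {ref!r}, "
            f"reference has {seq[pos - 1 : pos - 1 + len(ref)]!r}"
        )
    if key.is_snv:
        return replace(key, normalized=True)
    changed = True
    while changed:
        changed = False
        if ref and alt and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
            changed = True
        if not ref or not alt:
            if pos == 1:
                raise ValueError(f"cannot left-extend past contig start for {key}")
            pad = seq[pos - 2]
            ref, alt, pos = pad + ref, pad + alt, pos - 1
            changed = True
    while len(ref) >= 2 and len(alt) >= 2 and ref[0] == alt[0]:
        ref, alt, pos = ref[1:], alt[1:], pos + 1
    return VariantKey(key.chrom, pos, ref, alt, normalized=True)


def equivalent_renderings(
    key: VariantKey, reference: Mapping[str, str], flank: int = 20
) -> list[VariantKey]:
    """Enumerate every rendering of ``key`` within ``flank`` bases that spells
    the same alternate haplotype.

    Brute force over candidate start positions in the local window: a candidate
    (pos', ref', alt') is equivalent iff substituting it into the reference
    window reproduces the same edited sequence.  Used by the synthetic
    generator to emit deliberately non-left-aligned indels; SNVs have exactly
    one rendering.
    """
    seq = _contig(reference, key.chrom)
    lo = max(0, key.pos - 1 - flank)
    hi = min(len(seq), key.pos - 1 + len(key.ref) + flank)
    ref_win = seq[lo:hi]
    off = key.pos - 1 - lo
    alt_win = ref_win[:off] + key.alt + ref_win[off + len(key.ref) :]
    out: list[VariantKey] = []
    L, A = len(key.ref), len(key.alt)
    for s in range(0, len(ref_win) - L + 1):
        tail = len(ref_win) - s - L
        if ref_win[:s] != alt_win[:s]:
            continue
        if tail and ref_win[len(ref_win) - tail :] != alt_win[len(alt_win) - tail :]:
            continue
        cand_ref = ref_win[s : s + L]
        cand_alt = alt_win[s : len(alt_win) - tail if tail else len(alt_win)]
        if cand_ref == cand_alt:
            continue
        try:
            out.append(VariantKey(key.chrom, lo + s + 1, cand_ref, cand_alt))
        except ValueError:
            continue
    return sorted(set(out))


# --- protein-level changes ---------------------------------------------------

#: Closed vocabulary for non-substitution outcomes.
SPECIAL_ALT = {"Ter", "fs", "del", "dup", "=", "?"}

_PC_RE = re.compile(
    r"^p\.\(?"
    r"(?P<ref>[A-Z][a-z]{2})"
    r"(?P<pos>\d+)"
    r"(?P<alt>[A-Z][a-z]{2}|Ter|\*|=|del|dup|fs(?:Ter\d*|\*\d*)?|\?)"
    r"\)?$"
)


@dataclass(frozen=True, order=True)
class ProteinChange:
    """A protein-level consequence parsed from HGVS p. notation.

    ``alt_aa`` is either a 3-letter amino-acid code or one of the special
    tokens Ter (stop), fs (frameshift), del, dup, "=" (synonymous) or "?".
    Transcript comparison ignores the accession version: classification
    snapshots drift in versions, not in residue numbering.
    """

    gene_symbol: str
    transcript: str
    residue_pos: int
    ref_aa: str
    alt_aa: str

    def __post_init__(self) -> None:
        if self.residue_pos < 1:
            raise ValueError("residue_pos must be >= 1")
        if self.ref_aa not in AA3:
            raise ValueError(f"unknown reference amino acid {self.ref_aa!r}")
        if self.alt_aa not in AA3 and self.alt_aa not in SPECIAL_ALT:
            raise ValueError(f"unknown alternate token {self.alt_aa!r}")

    @property
    def transcript_base(self) -> str:
        return self.transcript.split(".", 1)[0]

    def same_change(self, other: "ProteinChange") -> bool:
        """Version-insensitive equality used by the fallback merge."""
        return (
            self.gene_symbol == other.gene_symbol
            and self.transcript_base == other.transcript_base
            and self.residue_pos == other.residue_pos
            and self.ref_aa == other.ref_aa
            and self.alt_aa == other.alt_aa
        )

    def render(self) -> str:
        return f"p.{self.ref_aa}{self.residue_pos}{self.alt_aa}"


def parse_protein_change(
    hgvs_p: str, gene_symbol: str, transcript: str
) -> ProteinChange | None:
    """Parse an HGVS p. string into a :class:`ProteinChange`.

    Accepts both plain and parenthesized predicted forms ("p.Trp31134Ter" and
    "p.(Trp31134*)" parse identically); "*" maps to Ter and any "fsTer12"-style
    suffix collapses to the bare frameshift token.  Returns None for strings
    outside the grammar (e.g. "p.?"), which callers count rather than drop
    silently.
    """
    m = _PC_RE.match(hgvs_p.strip())
    if m is None:
        return None
    alt = m.group("alt")
    if alt == "*":
        alt = "Ter"
    elif alt.startswith("fs"):
        alt = "fs"
    try:
        return ProteinChange(gene_symbol, transcript, int(m.group("pos")), m.group("ref"), alt)
    except ValueError:
        return None


#: Closed consequence vocabulary shared with the gene-rule layer.
CONSEQUENCES = (
    "missense",
    "stop_gain",
    "frameshift",
    "splice_donor",
    "splice_acceptor",
    "splice_region",
    "synonymous_splice",
    "inframe_indel",
    "other",
)

_C_SPLICE_RE = re.compile(r"^c\.[-*]?\d+(?:_[-*]?\d+)?(?:(?P<sign>[+-])(?P<off>\d+))")


def infer_consequence(hgvs_c: str | None, hgvs_p: str | None) -> str:
    """Best-effort molecular consequence from HGVS strings.

    Protein notation dominates (fs -> frameshift, Ter -> stop_gain, aa->aa ->
    missense, "=" -> synonymous); intronic offsets in the cDNA name classify
    essential-splice (+/-1,2) versus splice-region (+/-3..8) changes.  Anything
    unrecognized is "other"; callers may override with an annotation column.
    """
    if hgvs_p:
        pc = parse_protein_change(hgvs_p, "_", "_")
        if pc is not None:
            if pc.alt_aa == "fs":
                return "frameshift"
            if pc.alt_aa == "Ter":
                return "stop_gain"
            if pc.alt_aa in ("del", "dup"):
                return "inframe_indel"
            if pc.alt_aa == "=":
                return "synonymous_splice" if _has_splice_offset(hgvs_c) else "other"
            if pc.alt_aa in AA3:
                return "missense"
    if hgvs_c:
        m = _C_SPLICE_RE.match(hgvs_c.strip())
        if m and m.group("off"):
            off = int(m.group("off"))
            if off <= 2:
                return "splice_donor" if m.group("sign") == "+" else "splice_acceptor"
            if off <= 8:
                return "splice_region"
    return "other"


def _has_splice_offset(hgvs_c: str | None) -> bool:
    if not hgvs_c:
        return False
    m = _C_SPLICE_RE.match(hgvs_c.strip())
    return bool(m and m.group("off"))


def load_fasta(path: str) -> dict[str, str]:
    """Read a FASTA file into a plain contig -> sequence dict."""
    from pysam import FastaFile

    with FastaFile(str(path)) as fa:
        return {name: fa.fetch(name).upper() for name in fa.references}
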