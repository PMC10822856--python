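"""HGVS consequence classification of KMT2D / KDM6A variants.

Patient-level variants are classified into six leaf categories —
nonsense, frameshift, splice_site, large_deletion, missense,
inframe_indel — from their HGVS protein (p.) and coding-DNA (c.)
strings.  Protein notation takes precedence: a premature stop (``Ter``
or ``*`` at the new residue) without a frameshift suffix is nonsense, a
``fs`` suffix is frameshift, a single residue substitution is missense
and a frame-preserving delins is an in-frame indel.  Records carrying
only cDNA notation are classified from it: intronic offsets adjacent to
exon boundaries mark splice-site variants, and the net length of a
del/dup/ins/delins decides frameshift vs in-frame.  Whole-exon loss
descriptions are large deletions.

Rollups: protein-truncating variants (PTV) are nonsense, frameshift,
splice_site and large_deletion; protein-altering variants (PAV) are
missense and inframe_indel; premature_stop is nonsense plus frameshift.
Percentages are integer-rounded (half away from zero) and always
recomputed from counts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "VariantRecord",
    "VariantClassificationError",
    "classify_variant",
    "summarize_variants",
    "read_variants",
    "CATEGORIES",
    "PTV_CATEGORIES",
    "PAV_CATEGORIES",
]

CATEGORIES = (
    "nonsense",
    "frameshift",
    "splice_site",
    "large_deletion",
    "missense",
    "inframe_indel",
)
PTV_CATEGORIES = ("nonsense", "frameshift", "splice_site", "large_deletion")
PAV_CATEGORIES = ("missense", "inframe_indel")


class VariantClassificationError(ValueError):
    """Unparseable HGVS or structural variant description."""


@dataclass
class VariantRecord:
    """One patient-level variant observation."""

    gene: str
    protein_hgvs: str = ""
    cdna_hgvs: str = ""
    exon: int | None = None
    multiplicity: int = 1
    category: str = ""   # derived via classify_variant, never an input

    def __post_init__(self):
        if self.gene not in ("KMT2D", "KDM6A"):
            raise ValueError(f"gene must be KMT2D or KDM6A, got {self.gene!r}")
        if not (self.protein_hgvs or self.cdna_hgvs):
            raise ValueError("need a protein, cDNA or structural description")
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")

    @property
    def is_ptv(self) -> bool:
        return self.category in PTV_CATEGORIES


_AA3 = "Ala|Arg|Asn|Asp|Cys|Gln|Glu|Gly|His|Ile|Leu|Lys|Met|Phe|Pro|Ser|Thr|Trp|Tyr|Val|Ter|Sec"
_RE_NONSENSE = re.compile(rf"^p\.\(?({_AA3})(\d+)(\*|Ter)\)?$", re.I)
_RE_FRAMESHIFT = re.compile(rf"^p\.\(?({_AA3})(\d+)({_AA3})?fs", re.I)
_RE_MISSENSE = re.compile(rf"^p\.\(?({_AA3})(\d+)({_AA3})\)?$", re.I)
_RE_PROT_DELINS = re.compile(r"^p\.", re.I)

_RE_INTRONIC = re.compile(r"^c\.\d+[+-]\d+", re.I)
_RE_INTRONIC_RANGE = re.compile(r"^c\.\d+[+-]\d+_\d+[+-]\d+", re.I)
_RE_EXON_DEL = re.compile(r"exon", re.I)
_RE_SUB = re.compile(r"^c\.\d+[A-Z]>[A-Z]$", re.I)
_RE_SPAN = re.compile(r"^c\.(\d+)(?:_(\d+))?(del|dup|ins|delins)([ACGT]*)$", re.I)


def _cdna_net_length(cdna: str) -> int | None:
    """Net inserted-minus-deleted length of a simple c. del/dup/ins/delins."""
    m = _RE_SPAN.match(cdna.strip())
    if not m:
        return None
    start = int(m.group(1))
    end = int(m.group(2)) if m.group(2) else start
    kind = m.group(3).lower()
    seq = m.group(4) or ""
    span = end - start + 1
    if kind == "del":
        return -span
    if kind == "dup":
        return span
    if kind == "ins":
        return len(seq) if seq else 1
    if kind == "delins":
        return len(seq) - span
    return None


def classify_variant(rec: VariantRecord) -> str:
    """Derive the consequence category of one variant record.

    Protein notation rules when present; cDNA-only records fall back to
    intronic-offset (splice) and reading-frame rules; whole-exon loss
    text is a large deletion.  Case-insensitive on the ``p.``/``c.``
    prefixes.  Raises :class:`VariantClassificationError` when nothing
    parses.
    """
    prot = (rec.protein_hgvs or "").strip()
    cdna = (rec.cdna_hgvs or "").strip()

    if prot and _RE_EXON_DEL.search(prot) or cdna and _RE_EXON_DEL.search(cdna):
        return "large_deletion"

    if prot:
        if _RE_FRAMESHIFT.match(prot):
            return "frameshift"
        if _RE_NONSENSE.match(prot):
            return "nonsense"
        m = _RE_MISSENSE.match(prot)
        if m:
            if m.group(3).lower() == "ter":
                return "nonsense"
            # a substitution-shaped protein string can accompany an
            # indel-type cDNA (several residues replaced); the reading
            # frame of the nucleotide change decides the category then
            net = _cdna_net_length(cdna) if cdna else None
            if net is not None:
                return "frameshift" if net % 3 != 0 else "inframe_indel"
            return "missense"
        if re.search(r"delins|del|ins|dup", prot.lower()):
            net = _cdna_net_length(cdna) if cdna else None
            if net is not None and net % 3 != 0:
                return "frameshift"
            return "inframe_indel"
        raise VariantClassificationError(f"cannot classify protein HGVS {prot!r}")

    if cdna:
        if _RE_INTRONIC.match(cdna) or _RE_INTRONIC_RANGE.match(cdna):
            return "splice_site"
        net = _cdna_net_length(cdna)
        if net is not None:
            return "frameshift" if net % 3 != 0 else "inframe_indel"
        if _RE_SUB.match(cdna):
            raise VariantClassificationError(
                f"cDNA substitution {cdna!r} without protein consequence"
            )
        raise VariantClassificationError(f"cannot classify cDNA HGVS {cdna!r}")

    raise VariantClassificationError("record has no classifiable notation")


def _round_half_away(x: float) -> int:
    return int(x + 0.5) if x >= 0 else -int(-x + 0.5)


def summarize_variants(records: Sequence[VariantRecord]) -> pd.DataFrame:
    """Patient-level counts and integer percentages per gene.

    Classifies every record (filling ``category``), then reports, per
    gene, the patient count and percentage of each leaf category, the
    PTV/PAV rollups and the premature-stop rollup (nonsense plus
    frameshift), plus each gene's share among all genotyped patients.
    Percentages are recomputed from counts with half-away-from-zero
    rounding.
    """
    for rec in records:
        rec.category = classify_variant(rec)
    rows = []
    total_all = sum(r.multiplicity for r in records)
    for gene in ("KMT2D", "KDM6A"):
        recs = [r for r in records if r.gene == gene]
        n_gene = sum(r.multiplicity for r in recs)
        if n_gene == 0:
            continue

        def count(cats: Iterable[str]) -> int:
            cats = set(cats)
            return sum(r.multiplicity for r in recs if r.category in cats)

        entries = {c: count([c]) for c in CATEGORIES}
        entries["PTV"] = count(PTV_CATEGORIES)
        entries["PAV"] = count(PAV_CATEGORIES)
        entries["premature_stop"] = count(("nonsense", "frameshift"))
        for name, cnt in entries.items():
            rows.append({
                "gene": gene, "category": name, "n": cnt,
                "percent": _round_half_away(100.0 * cnt / n_gene),
            })
        rows.append({
            "gene": gene, "category": "total", "n": n_gene,
            "percent": _round_half_away(100.0 * n_gene / total_all),
        })
    return pd.DataFrame(rows)


def read_variants(path) -> list[VariantRecord]:
    """Read a variant CSV (gene, protein_hgvs, cdna_hgvs, exon, multiplicity)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    out = []
    for rec in df.to_dict("records"):
        out.append(
            VariantRecord(
                gene=rec["gene"],
                protein_hgvs=rec.get("protein_hgvs", ""),
                cdna_hgvs=rec.get("cdna_hgvs", ""),
                exon=int(rec["exon"]) if rec.get("exon") else None,
                multiplicity=int(rec.get("multiplicity") or 1),
            )
        )
    return out
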