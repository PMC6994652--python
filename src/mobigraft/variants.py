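"""Sequence variants: the unit filtered and applied during reference correction.

Variants are stored left-anchored in the VCF convention: a SNP has
``|ref| == |alt| == 1``; an insertion carries one anchor base (``ref="A"``,
``alt="ACT"``); a deletion likewise (``ref="ACT"``, ``alt="A"``).  ``position``
is 1-based and points at the anchor base.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

SNP = "SNP"
INS = "INS"
DEL = "DEL"


class VariantError(ValueError):
    """Raised for malformed variant records."""


@dataclass(frozen=True)
class SequenceVariant:
    contig: str
    position: int  # 1-based anchor position
    ref: str
    alt: str
    depth: int = 0
    alt_support: int = 0
    quality: float = 0.0

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise VariantError(
                f"{self.contig}:{self.position}: empty allele (ref={self.ref!r}, "
                f"alt={self.alt!r}); use anchored representation"
            )
        if len(self.ref) > 1 and len(self.alt) > 1:
            raise VariantError(
                f"{self.contig}:{self.position}: complex allele pair "
                f"{self.ref}>{self.alt} not supported (left-anchored SNP/INS/DEL only)"
            )
        if self.depth < self.alt_support:
            raise VariantError(
                f"{self.contig}:{self.position}: depth {self.depth} < "
                f"alt support {self.alt_support}"
            )

    @property
    def kind(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return SNP
        return INS if len(self.alt) > len(self.ref) else DEL

    @property
    def zygosity_fraction(self) -> float:
        return self.alt_support / self.depth if self.depth else 0.0

    @property
    def length_change(self) -> int:
        return len(self.alt) - len(self.ref)

    @property
    def ref_span(self) -> tuple[int, int]:
        """1-based inclusive interval of reference bases consumed."""
        return self.position, self.position + len(self.ref) - 1


def left_align(contig_seq: str, position: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Normalise an anchored indel to its left-most equivalent representation.

    Standard VCF left-alignment: while the trailing base of both alleles is
    equal, drop it and prepend the reference base preceding the anchor.  SNPs
    are returned unchanged.  ``contig_seq`` is the full contig, ``position``
    1-based.
    """
    if len(ref) == 1 and len(alt) == 1:
        return position, ref, alt
    pos, r, a = position, ref, alt
    while len(r) > 1 and len(a) > 1 and r[-1] == a[-1] and r[:-1] != a[: len(r) - 1]:
        r, a = r[:-1], a[:-1]
    while pos > 1 and r[-1] == a[-1] and (len(r) > 1) != (len(a) > 1):
        prev = contig_seq[pos - 2]
        r = prev + r[:-1]
        a = prev + a[:-1]
        pos -= 1
    return pos, r, a


# ----------------------------------------------------------------------- I/O
_TABLE_COLUMNS = [
    "contig", "position", "ref", "alt", "kind",
    "depth", "alt_support", "zygosity_fraction", "quality",
]


def variants_to_frame(variants: Iterable[SequenceVariant]) -> pd.DataFrame:
    rows = [
        (v.contig, v.position, v.ref, v.alt, v.kind,
         v.depth, v.alt_support, round(v.zygosity_fraction, 6), v.quality)
        for v in variants
    ]
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)


def write_variant_table(variants: Iterable[SequenceVariant], path: str | Path) -> None:
    variants_to_frame(variants).to_csv(path, sep="\t", index=False)


def read_variant_table(path: str | Path) -> list[SequenceVariant]:
    df = pd.read_csv(path, sep="\t", dtype={"contig": str, "ref": str, "alt": str})
    return [
        SequenceVariant(
            contig=row.contig, position=int(row.position), ref=row.ref, alt=row.alt,
            depth=int(row.depth), alt_support=int(row.alt_support),
            quality=float(row.quality),
        )
        for row in df.itertuples()
    ]


def read_vcf(path: str | Path) -> list[SequenceVariant]:
    """Load variants from a VCF 4.x file (first ALT allele of each record).

    The VCF ``QUAL`` field is used directly as the variant quality; ``DP`` and
    ``AD``/``DP4`` INFO fields populate depth and alt support when present,
    otherwise depth defaults to 0 (records from a VCF are assumed
    pre-filtered by the producer when support fields are absent).
    """
    import pysam

    out: list[SequenceVariant] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if not rec.alts:
                continue
            alt = rec.alts[0]
            try:
                depth = int(rec.info.get("DP", 0))
            except ValueError:  # DP absent from the header
                depth = 0
            support = depth
            try:
                ad = rec.info.get("AD")
            except ValueError:
                ad = None
            if ad is not None and len(ad) >= 2:
                support = int(ad[1])
            out.append(
                SequenceVariant(
                    contig=rec.chrom, position=rec.pos, ref=rec.ref, alt=alt,
                    depth=depth, alt_support=support,
                    quality=float(rec.qual) if rec.qual is not None else 0.0,
                )
            )
    return out
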