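"""Variant records and allele normalization.

Variant identity throughout the package is (chrom, pos, ref, alt) after
left-alignment against the reference, with multi-allelic records split into
biallelics before any filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional


@dataclass(frozen=True)
class Variant:
    """A called variant with genotype and quality annotations.

    ``pos`` is 1-based as in VCF.  ``genotype`` is a pair of allele indices
    (0 = ref, 1 = alt); ``qd`` (quality by depth) and ``dp`` (read depth) may
    be absent.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    genotype: tuple[Optional[int], Optional[int]] = (None, None)
    qd: Optional[float] = None
    dp: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("ref and alt alleles must be non-empty")
        if self.qd is not None and self.qd < 0:
            raise ValueError("QD must be >= 0")
        if self.dp is not None and self.dp < 0:
            raise ValueError("DP must be >= 0")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_hom_alt(self) -> bool:
        return self.genotype == (1, 1)

    @property
    def is_het(self) -> bool:
        return None not in self.genotype and set(self.genotype) == {0, 1}

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 == len(self.alt)

    @property
    def is_deletion(self) -> bool:
        return len(self.ref) > len(self.alt)

    def deleted_interval(self) -> tuple[int, int]:
        """0-based half-open genomic interval removed by a deletion.

        Assumes the standard anchored representation (alt is a prefix of ref).
        """
        if not self.is_deletion:
            raise ValueError("not a deletion")
        start0 = self.pos - 1 + len(self.alt)
        return start0, self.pos - 1 + len(self.ref)


def trim_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Remove shared suffix then shared prefix bases (keeping one anchor)."""
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def left_align(variant: Variant, reference: str) -> Variant:
    """Left-align an indel against the reference contig sequence.

    Implements the standard normalization: trim shared flanks, then while the
    alleles end with the same base, shift one base leftward, prepending the
    reference base.  SNVs are returned trimmed only.
    """
    pos, ref, alt = trim_alleles(variant.pos, variant.ref, variant.alt)
    if len(ref) != len(alt):
        while pos > 1 and ref[-1] == alt[-1]:
            prev = reference[pos - 2]
            ref = prev + ref[:-1]
            alt = prev + alt[:-1]
            pos -= 1
        pos, ref, alt = trim_alleles(pos, ref, alt)
    if (pos, ref, alt) == (variant.pos, variant.ref, variant.alt):
        return variant
    return replace(variant, pos=pos, ref=ref, alt=alt)


def split_multiallelic(
    chrom: str,
    pos: int,
    ref: str,
    alts: list[str],
    genotype: tuple[Optional[int], Optional[int]],
    qd: Optional[float] = None,
    dp: Optional[int] = None,
) -> list[Variant]:
    """Split one multi-allelic site into biallelic records.

    Each split record keeps the site QD/DP; genotype allele indices map to
    1 for the kept alt, 0 otherwise.
    """
    out = []
    for ai, alt in enumerate(alts, start=1):
        gt = tuple((1 if a == ai else 0) if a is not None else None for a in genotype)
        out.append(Variant(chrom, pos, ref, alt, gt, qd, dp))
    return out
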