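"""Gene models and coordinate arithmetic.

A :class:`GeneModel` is an exon/intron structure on a genomic contig together
with the CDS location on the spliced transcript.  All internal coordinates are
0-based, half-open; VCF-facing code converts to 1-based at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

Interval = tuple[int, int]

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GeneModelError(ValueError):
    """Raised when a gene model violates its structural invariants."""


@dataclass(frozen=True)
class GeneModel:
    """Exon/intron structure of one protein-coding transcript.

    Parameters
    ----------
    exons:
        Genomic intervals in transcription order (ascending genomic
        coordinates on '+', descending on '-'), 0-based half-open.
    cds_start, cds_end:
        CDS location in *transcript* coordinates, half-open; the interval
        includes the stop codon, so its length is divisible by three.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[Interval, ...]
    cds_start: int
    cds_end: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise GeneModelError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise GeneModelError("gene model needs at least one exon")
        for s, e in self.exons:
            if e <= s:
                raise GeneModelError(f"empty or inverted exon ({s}, {e})")
        genomic_order = sorted(self.exons) if self.strand == "+" else sorted(self.exons, reverse=True)
        if tuple(genomic_order) != self.exons:
            raise GeneModelError("exons must be given in transcription order")
        ordered = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
            if s2 < e1:
                raise GeneModelError("exons overlap")
        if not (0 <= self.cds_start < self.cds_end <= self.transcript_length):
            raise GeneModelError("CDS must lie within the spliced transcript")
        if (self.cds_end - self.cds_start) % 3 != 0:
            raise GeneModelError("CDS length must be divisible by 3")

    # -- basic geometry ----------------------------------------------------

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def exon_lengths(self) -> tuple[int, ...]:
        return tuple(e - s for s, e in self.exons)

    @property
    def transcript_length(self) -> int:
        return sum(self.exon_lengths)

    @property
    def start(self) -> int:
        """Genomic start of the gene body (leftmost exon base)."""
        return min(s for s, _ in self.exons)

    @property
    def end(self) -> int:
        """Genomic end of the gene body (half-open)."""
        return max(e for _, e in self.exons)

    @property
    def introns(self) -> tuple[Interval, ...]:
        """Genomic intron intervals in transcription order."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                out.append((e1, s2))
            else:
                out.append((e2, s1))
        return tuple(out)

    def intron_lengths(self) -> tuple[int, ...]:
        return tuple(e - s for s, e in self.introns)

    def contains(self, genomic_pos: int) -> bool:
        """True if the position lies within the gene body (exons or introns)."""
        return self.start <= genomic_pos < self.end

    # -- coordinate mapping ------------------------------------------------

    def genomic_to_transcript(self, pos: int) -> int | None:
        """Map a genomic position to a transcript offset, or None if intronic."""
        offset = 0
        for s, e in self.exons:
            if s <= pos < e:
                if self.strand == "+":
                    return offset + (pos - s)
                return offset + (e - 1 - pos)
            offset += e - s
        return None

    def transcript_to_genomic(self, t: int) -> int:
        if not (0 <= t < self.transcript_length):
            raise GeneModelError(f"transcript coordinate {t} out of range")
        offset = 0
        for s, e in self.exons:
            length = e - s
            if t < offset + length:
                if self.strand == "+":
                    return s + (t - offset)
                return e - 1 - (t - offset)
            offset += length
        raise AssertionError("unreachable")

    # -- sequences ---------------------------------------------------------

    def exon_sequence(self, genome: str, i: int) -> str:
        s, e = self.exons[i]
        seq = genome[s:e]
        return reverse_complement(seq) if self.strand == "-" else seq

    def intron_sequence(self, genome: str, i: int) -> str:
        s, e = self.introns[i]
        seq = genome[s:e]
        return reverse_complement(seq) if self.strand == "-" else seq

    def spliced_sequence(self, genome: str) -> str:
        return "".join(self.exon_sequence(genome, i) for i in range(self.n_exons))

    def cds_sequence(self, genome: str) -> str:
        return self.spliced_sequence(genome)[self.cds_start : self.cds_end]

    def pre_mrna_sequence(self, genome: str) -> str:
        seq = genome[self.start : self.end]
        return reverse_complement(seq) if self.strand == "-" else seq

    # -- CDS bookkeeping ---------------------------------------------------

    def cds_position_of_intron(self, intron_index: int) -> int:
        """CDS nucleotides upstream of intron ``intron_index`` (1-based intron).

        This is the number printed before the '+' in HGVS-style names such as
        c.614+1delG: the CDS coordinate of the last exonic base preceding the
        intron.  Raises if the intron lies outside the CDS.
        """
        if not (1 <= intron_index <= self.n_exons - 1):
            raise GeneModelError(f"intron index {intron_index} out of range")
        t_end = sum(self.exon_lengths[:intron_index])  # transcript offset of donor
        cds_pos = t_end - self.cds_start
        if not (0 < cds_pos <= self.cds_end - self.cds_start):
            raise GeneModelError(
                f"intron {intron_index} does not follow a coding exon position"
            )
        return cds_pos

    def intron_of_position(self, pos: int) -> int | None:
        """1-based index of the intron containing a genomic position, else None."""
        for i, (s, e) in enumerate(self.introns, start=1):
            if s <= pos < e:
                return i
        return None
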