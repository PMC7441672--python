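"""Splice-site consequence modelling: classification, intron retention,
translation to the premature stop, C-terminus accounting and in-silico PCR.

The central mechanism modelled here is failure of donor-site recognition
after deletion of the essential +1 G, leading to intron retention: the
mutant transcript carries the (G-deleted) intron, translation runs into the
intron in the post-junction frame, appends a short run of novel residues and
terminates at a premature stop.  The wild-type and mutant C-termini are then
compared residue-class-wise (basic K/R/H vs acidic D/E), since the charge of
the troponin T C-terminal tail governs its calcium-dependent interaction
with tropomyosin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqUtils import molecular_weight

from .models import GeneModel, reverse_complement
from .variants import Variant

BASIC_RESIDUES = frozenset("KRH")
ACIDIC_RESIDUES = frozenset("DE")

CONSEQUENCE_TERMS = (
    "splice_donor_variant",
    "splice_acceptor_variant",
    "stop_gained",
    "frameshift_variant",
    "missense_variant",
    "synonymous_variant",
    "intron_variant",
    "intergenic_variant",
)

# fixed 4-class severity table used for candidate ranking
SEVERITY_CLASS = {
    "splice_donor_variant": 0,
    "splice_acceptor_variant": 0,
    "stop_gained": 1,
    "frameshift_variant": 1,
    "missense_variant": 2,
    "synonymous_variant": 2,
    "intron_variant": 3,
    "intergenic_variant": 3,
}


@dataclass(frozen=True)
class ConsequenceRecord:
    variant: Variant
    term: str
    gene_id: Optional[str] = None
    intron_index: Optional[int] = None  # 1-based, for splice/intron terms
    exon_index: Optional[int] = None  # 1-based, for exonic terms
    hgvs_c: Optional[str] = None

    def __post_init__(self) -> None:
        if self.term not in CONSEQUENCE_TERMS:
            raise ValueError(f"unknown consequence term {self.term!r}")

    @property
    def severity_class(self) -> int:
        return SEVERITY_CLASS[self.term]


@dataclass(frozen=True)
class ProteinReport:
    """Wild-type vs mutant protein comparison after a splicing defect."""

    wt_protein: str
    mut_protein: str
    replaced_tail_length: int
    novel_tail_length: int
    basic_count_wt: int
    basic_count_mut: int
    acidic_count_wt: int
    acidic_count_mut: int
    wt_mass_kda: float
    mut_mass_kda: float

    @property
    def wt_length(self) -> int:
        return len(self.wt_protein)

    @property
    def mut_length(self) -> int:
        return len(self.mut_protein)

    def to_dict(self) -> dict:
        return {
            "wt_length": self.wt_length,
            "mut_length": self.mut_length,
            "replaced_tail_length": self.replaced_tail_length,
            "novel_tail_length": self.novel_tail_length,
            "basic_count_wt": self.basic_count_wt,
            "basic_count_mut": self.basic_count_mut,
            "acidic_count_wt": self.acidic_count_wt,
            "acidic_count_mut": self.acidic_count_mut,
            "wt_mass_kda": round(self.wt_mass_kda, 4),
            "mut_mass_kda": round(self.mut_mass_kda, 4),
        }


# ---------------------------------------------------------------------------
# classification


def _splice_site_term(gene: GeneModel, affected: Sequence[int]) -> Optional[tuple[str, int]]:
    """Check whether any affected genomic position hits a donor/acceptor +-1-2."""
    for idx, (s, e) in enumerate(gene.introns, start=1):
        if gene.strand == "+":
            donor = {s, s + 1}
            acceptor = {e - 2, e - 1}
        else:
            donor = {e - 1, e - 2}
            acceptor = {s, s + 1}
        for pos in affected:
            if pos in donor:
                return "splice_donor_variant", idx
            if pos in acceptor:
                return "splice_acceptor_variant", idx
    return None


def _hgvs_donor_deletion(gene: GeneModel, intron_index: int, offset: int,
                         deleted: str) -> str:
    cds_pos = gene.cds_position_of_intron(intron_index)
    return f"c.{cds_pos}+{offset}del{deleted}"


def classify_variant(
    variant: Variant, genes: Sequence[GeneModel], genome: str
) -> ConsequenceRecord:
    """Assign exactly one consequence term against the given gene models.

    The variant must already be normalized (left-aligned).  Precedence:
    splice donor/acceptor (+-2 intronic bases) > coding-exon effect >
    intron > intergenic.  Non-coding exonic (UTR) positions are reported in
    the lowest in-gene class (intron_variant).
    """
    if not (1 <= variant.pos <= len(genome)):
        raise ValueError(f"variant position {variant.pos} outside the contig")

    if variant.is_deletion:
        span = variant.deleted_interval()
        affected = list(range(span[0], span[1]))
    elif len(variant.alt) > len(variant.ref):  # insertion: anchor base only
        affected = [variant.pos - 1]
    else:
        affected = [variant.pos - 1 + i for i in range(len(variant.ref))]

    overlapping = [g for g in genes if any(g.contains(p) for p in affected)]
    if not overlapping:
        return ConsequenceRecord(variant=variant, term="intergenic_variant")
    gene = overlapping[0]

    hit = _splice_site_term(gene, affected)
    if hit is not None:
        term, idx = hit
        hgvs = None
        if term == "splice_donor_variant" and variant.is_deletion:
            s, _ = gene.introns[idx - 1]
            try:
                offset = (affected[0] - s + 1) if gene.strand == "+" else 1
                hgvs = _hgvs_donor_deletion(
                    gene, idx, offset, genome[affected[0] : affected[-1] + 1]
                )
            except Exception:
                hgvs = None
        return ConsequenceRecord(
            variant=variant, term=term, gene_id=gene.gene_id,
            intron_index=idx, hgvs_c=hgvs,
        )

    t_positions = [gene.genomic_to_transcript(p) for p in affected]
    exonic = [t for t in t_positions if t is not None]
    if not exonic:
        idx = gene.intron_of_position(affected[0])
        return ConsequenceRecord(
            variant=variant, term="intron_variant", gene_id=gene.gene_id,
            intron_index=idx,
        )

    exon_index = None
    offset = 0
    for i, length in enumerate(gene.exon_lengths, start=1):
        if offset <= exonic[0] < offset + length:
            exon_index = i
            break
        offset += length

    in_cds = [t for t in exonic if gene.cds_start <= t < gene.cds_end]
    if not in_cds:
        # UTR exon: coarse-grained into the lowest in-gene severity class
        return ConsequenceRecord(
            variant=variant, term="intron_variant", gene_id=gene.gene_id,
            exon_index=exon_index,
        )

    if len(variant.ref) != len(variant.alt):
        indel_len = abs(len(variant.ref) - len(variant.alt))
        term = "frameshift_variant" if indel_len % 3 else "missense_variant"
        return ConsequenceRecord(
            variant=variant, term=term, gene_id=gene.gene_id, exon_index=exon_index
        )

    # SNV (or MNV, classified by its first base) in the CDS
    t = in_cds[0]
    cds_off = t - gene.cds_start
    codon_idx = cds_off // 3
    cds = gene.cds_sequence(genome)
    codon = cds[3 * codon_idx : 3 * codon_idx + 3]
    within = cds_off % 3
    base = variant.alt[0]
    if gene.strand == "-":
        base = reverse_complement(base)
    mut_codon = codon[:within] + base + codon[within + 1 :]
    table = CodonTable.unambiguous_dna_by_id[1]
    wt_aa = "*" if codon in table.stop_codons else str(Seq(codon).translate())
    mut_aa = "*" if mut_codon in table.stop_codons else str(Seq(mut_codon).translate())
    if mut_aa == "*" and wt_aa != "*":
        term = "stop_gained"
    elif mut_aa == wt_aa:
        term = "synonymous_variant"
    else:
        term = "missense_variant"
    return ConsequenceRecord(
        variant=variant, term=term, gene_id=gene.gene_id, exon_index=exon_index
    )


# ---------------------------------------------------------------------------
# intron retention and translation


def model_intron_retention(
    gene: GeneModel,
    cdna: str,
    genome: str,
    intron_index: int,
    donor_deletion: bool = False,
) -> str:
    """Mutant transcript with the given intron retained.

    By default the full intron is inserted at the exon k / k+1 junction, so
    the mutant length is cdna_length + intron_length.  With
    ``donor_deletion=True`` the retained intron lacks its +1 donor base,
    modelling the transcript of a donor +1 deletion allele (one base
    shorter).
    """
    if not (1 <= intron_index <= gene.n_exons - 1):
        raise ValueError(f"intron index {intron_index} out of range")
    junction = sum(gene.exon_lengths[:intron_index])
    intron = gene.intron_sequence(genome, intron_index - 1)
    if donor_deletion:
        intron = intron[1:]
    return cdna[:junction] + intron + cdna[junction:]


def translate_to_stop(cds: str) -> tuple[str, bool]:
    """Translate from the first codon to the first stop.

    Returns ``(residues, stop_found)``; when no stop codon occurs in frame,
    the full translation is returned flagged ``stop_found=False``.  Sequences
    shorter than one codon yield an empty peptide with the flag unset.
    """
    if len(cds) < 3:
        return "", False
    usable = len(cds) - len(cds) % 3
    full = str(Seq(cds[:usable]).translate())
    stop = full.find("*")
    if stop == -1:
        return full, False
    return full[:stop], True


def protein_mass_kda(protein: str) -> float:
    """Average (not monoisotopic) molecular mass of a peptide, in kDa."""
    if not protein:
        raise ValueError("empty protein sequence")
    for aa in protein:
        if aa not in "ACDEFGHIKLMNPQRSTVWY":
            raise ValueError(f"unknown residue symbol {aa!r}")
    return molecular_weight(protein, seq_type="protein", monoisotopic=False) / 1000.0


def compare_termini(wt_protein: str, mut_protein: str) -> ProteinReport:
    """Compare C-termini after the longest common prefix.

    The replaced tail is the wild-type sequence beyond the shared prefix; the
    novel tail is the mutant sequence beyond it.  Basic (K/R/H) and acidic
    (D/E) residues are counted within each compared tail.
    """
    if not wt_protein or not mut_protein:
        raise ValueError("both protein sequences must be non-empty")
    prefix = 0
    for a, b in zip(wt_protein, mut_protein):
        if a != b:
            break
        prefix += 1
    wt_tail = wt_protein[prefix:]
    mut_tail = mut_protein[prefix:]
    return ProteinReport(
        wt_protein=wt_protein,
        mut_protein=mut_protein,
        replaced_tail_length=len(wt_tail),
        novel_tail_length=len(mut_tail),
        basic_count_wt=sum(aa in BASIC_RESIDUES for aa in wt_tail),
        basic_count_mut=sum(aa in BASIC_RESIDUES for aa in mut_tail),
        acidic_count_wt=sum(aa in ACIDIC_RESIDUES for aa in wt_tail),
        acidic_count_mut=sum(aa in ACIDIC_RESIDUES for aa in mut_tail),
        wt_mass_kda=protein_mass_kda(wt_protein),
        mut_mass_kda=protein_mass_kda(mut_protein),
    )


def build_protein_report(
    gene: GeneModel, genome: str, intron_index: int
) -> ProteinReport:
    """Predict the intron-retention protein and compare it with wild-type.

    The mutant CDS is the wild-type CDS with the (donor-G-deleted) retained
    intron spliced in at the junction; translation stops at the first
    premature stop in the new frame.
    """
    cdna = gene.spliced_sequence(genome)
    cds = gene.cds_sequence(genome)
    junction_t = sum(gene.exon_lengths[:intron_index])
    junction_cds = junction_t - gene.cds_start
    if not (0 < junction_cds < len(cds)):
        raise ValueError("retained intron does not interrupt the CDS")
    intron = gene.intron_sequence(genome, intron_index - 1)
    mut_cds = cds[:junction_cds] + intron[1:] + cds[junction_cds:]
    wt_protein, _ = translate_to_stop(cds)
    mut_protein, _ = translate_to_stop(mut_cds)
    return compare_termini(wt_protein, mut_protein)


# ---------------------------------------------------------------------------
# in-silico PCR


def insilico_pcr(template: str, fwd_primer: str, rev_primer: str) -> list[int]:
    """Exact-match PCR product sizes from a primer pair on a template.

    The forward primer anneals on the sense strand, the reverse primer as its
    reverse complement downstream.  Returns the outer-span lengths (primers
    inclusive) of every fwd/rev combination, sorted; an empty list means no
    product.  Multiple hits of either primer yield all products.
    """
    if len(fwd_primer) < 10 or len(rev_primer) < 10:
        raise ValueError("primers must be at least 10 nt")
    fwd = fwd_primer.upper()
    rev_rc = reverse_complement(rev_primer.upper())
    template = template.upper()

    def all_hits(needle: str) -> list[int]:
        hits, start = [], 0
        while True:
            i = template.find(needle, start)
            if i == -1:
                return hits
            hits.append(i)
            start = i + 1

    products = []
    for f in all_hits(fwd):
        for r in all_hits(rev_rc):
            end = r + len(rev_rc)
            if end > f + len(fwd) and r >= f:
                products.append(end - f)
    return sorted(products)
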