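"""Forge a TNNT1-like gene model with a controllable intron-retention frame.

The forged gene emulates the ovine slow skeletal troponin T locus: a
multi-exon transcript whose translation starts after one or more 5'UTR exons
and terminates in the penultimate exon, with one designated intron whose
retention (after deletion of its +1 donor G) appends a configurable number of
novel sense codons followed by a premature stop.

All introns carry the canonical GT donor and AG acceptor dinucleotides.  The
sequence content is random given the seed, except at the retention junction,
where a handful of codons are fixed so that the retained-intron reading frame
is guaranteed to (a) diverge from the wild-type protein at the first
post-junction residue and (b) terminate after exactly the configured number
of novel amino acids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ..models import GeneModel

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"
SENSE_CODONS = tuple(
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
)
_T_SENSE_CODONS = tuple(c for c in SENSE_CODONS if c[0] == "T")
_SENSE_NOT_G_END = tuple(c for c in SENSE_CODONS if c[2] != "G")


class InfeasibleGeneConfig(ValueError):
    """Raised when a gene-forging configuration cannot be realized."""


@dataclass(frozen=True)
class GeneForgeConfig:
    """Configuration of the forged gene.

    Defaults reproduce the ovine TNNT1 structure: a 1001-nt cDNA over 15
    exons, a 263-residue protein whose translation starts in exon 2 and
    terminates in exon 14, and intron 13 (810 nt in the wild-type allele)
    as the retention target, with its donor pinned at CDS position 614 so
    the planted deletion is named c.614+1delG.
    """

    n_exons: int = 15
    cdna_length: int = 1001
    cds_start_exon: int = 2
    cds_end_exon: int = 14
    target_protein_length: int = 263
    retained_intron_index: int = 13
    novel_aa_before_stop: int = 12
    intron_lengths: Optional[tuple[int, ...]] = None
    donor_cds_position: Optional[int] = 614
    atg_offset: int = 10
    utr_exon_length: int = 50
    last_exon_length: int = 51
    exon_lengths: Optional[tuple[int, ...]] = None
    contig_length: int = 2_000_000
    chrom: str = "chr1"
    gene_id: str = "TNNT1L"
    seed: int = 0

    @property
    def cds_length(self) -> int:
        return 3 * (self.target_protein_length + 1)

    def resolved_intron_lengths(self) -> tuple[int, ...]:
        if self.intron_lengths is not None:
            ils = tuple(self.intron_lengths)
            if len(ils) != self.n_exons - 1:
                raise InfeasibleGeneConfig(
                    f"need {self.n_exons - 1} intron lengths, got {len(ils)}"
                )
            return ils
        return tuple(
            810 if i == self.retained_intron_index else 300
            for i in range(1, self.n_exons)
        )


@dataclass(frozen=True)
class ForgedGene:
    """A forged gene model plus its sequences and retention bookkeeping."""

    model: GeneModel
    genome: str
    cdna: str
    config: GeneForgeConfig
    donor_pos: int  # 0-based genomic coordinate of the retained intron's +1 G
    junction_cds: int  # CDS nucleotides upstream of the retained intron

    @property
    def chrom(self) -> str:
        return self.model.chrom

    @property
    def contig_length(self) -> int:
        return len(self.genome)

    @property
    def retained_intron_length(self) -> int:
        return self.model.intron_lengths()[self.config.retained_intron_index - 1]

    def wildtype_cds(self) -> str:
        return self.model.cds_sequence(self.genome)

    def mutant_cds(self) -> str:
        """CDS-through-intron sequence of the disease allele.

        The retained intron lacks its +1 donor G (the planted deletion), so
        the insert is one base shorter than the wild-type intron.
        """
        k = self.config.retained_intron_index
        intron = self.model.intron_sequence(self.genome, k - 1)
        cds = self.wildtype_cds()
        j = self.junction_cds
        return cds[:j] + intron[1:] + cds[j:]


def _layout_exons(cfg: GeneForgeConfig) -> tuple[int, ...]:
    """Derive exon lengths honouring the CDS span and optional donor pin."""
    n = cfg.n_exons
    if cfg.exon_lengths is not None:
        lens = tuple(cfg.exon_lengths)
        if len(lens) != n or sum(lens) != cfg.cdna_length:
            raise InfeasibleGeneConfig("explicit exon lengths must sum to cdna_length")
        return lens
    if not (1 <= cfg.cds_start_exon <= cfg.cds_end_exon <= n):
        raise InfeasibleGeneConfig("CDS exon span out of range")
    n_utr5_exons = cfg.cds_start_exon - 1
    n_utr3_exons = n - cfg.cds_end_exon
    len_a = n_utr5_exons * cfg.utr_exon_length
    len_c = n_utr3_exons * cfg.last_exon_length
    total_b = cfg.cdna_length - len_a - len_c
    min_b = cfg.atg_offset + cfg.cds_length
    if total_b < min_b + (0 if n_utr3_exons else 0):
        raise InfeasibleGeneConfig(
            f"cDNA too short: coding block needs >= {min_b} nt, has {total_b} "
            "(CDS longer than cDNA allows)"
        )
    q = cfg.cds_end_exon - cfg.cds_start_exon + 1
    tail3 = total_b - cfg.atg_offset - cfg.cds_length  # 3'UTR inside last coding exon

    def even(total: int, parts: int) -> list[int]:
        base, rem = divmod(total, parts)
        return [base + (1 if i < rem else 0) for i in range(parts)]

    k = cfg.retained_intron_index
    pin = cfg.donor_cds_position
    if pin is not None:
        if not (cfg.cds_start_exon <= k < cfg.cds_end_exon):
            raise InfeasibleGeneConfig(
                "donor_cds_position requires the retained intron inside the CDS span"
            )
        if not (0 < pin <= cfg.cds_length - 3):
            raise InfeasibleGeneConfig(
                "donor_cds_position must precede the stop codon"
            )
        q1 = k - cfg.cds_start_exon + 1
        t1 = cfg.atg_offset + pin
        t2 = total_b - t1
        q2 = q - q1
        if t1 < q1 or t2 < q2:
            raise InfeasibleGeneConfig("donor_cds_position leaves an empty exon")
        b_lens = even(t1, q1) + even(t2, q2)
    else:
        b_lens = even(total_b, q)
    lens = (
        [cfg.utr_exon_length] * n_utr5_exons + b_lens + [cfg.last_exon_length] * n_utr3_exons
    )
    if any(l <= 0 for l in lens):
        raise InfeasibleGeneConfig("layout produced an empty exon")
    if b_lens[0] <= cfg.atg_offset:
        raise InfeasibleGeneConfig("start exon shorter than the 5'UTR offset")
    if b_lens[-1] <= tail3:
        raise InfeasibleGeneConfig("CDS does not terminate in cds_end_exon")
    return tuple(lens)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    lookup = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lookup[rng.integers(0, 4, n)].tobytes().decode("ascii")


def forge_gene_model(cfg: GeneForgeConfig) -> ForgedGene:
    """Forge the gene model, its genomic contig and its cDNA.

    Deterministic given ``cfg.seed``.  Raises :class:`InfeasibleGeneConfig`
    naming the violated constraint when the configuration cannot be realized.
    """
    if cfg.novel_aa_before_stop < 1:
        raise InfeasibleGeneConfig("novel_aa_before_stop must be >= 1")
    if cfg.target_protein_length < 2:
        raise InfeasibleGeneConfig("target_protein_length must be >= 2")
    exon_lens = _layout_exons(cfg)
    intron_lens = cfg.resolved_intron_lengths()
    if any(l < 4 for l in intron_lens):
        raise InfeasibleGeneConfig("introns must be at least 4 nt (GT..AG)")

    n = cfg.n_exons
    k = cfg.retained_intron_index
    if not (1 <= k <= n - 1):
        raise InfeasibleGeneConfig("retained_intron_index out of range")
    m = cfg.novel_aa_before_stop
    p = cfg.target_protein_length
    cds_len = cfg.cds_length

    # transcript coordinate of the ATG and of the retention junction
    cum = np.cumsum((0,) + exon_lens)
    u = int(cum[cfg.cds_start_exon - 1]) + cfg.atg_offset
    junction_cds = int(cum[k]) - u
    if not (0 < junction_cds <= cds_len - 3):
        raise InfeasibleGeneConfig(
            "retained intron junction must lie within the CDS before the stop codon"
        )
    r = junction_cds % 3
    prefix_codons = junction_cds // 3
    if r > 0 and prefix_codons == 0:
        raise InfeasibleGeneConfig("retention junction falls inside the initiator codon")
    if r == 0 and junction_cds < 6:
        raise InfeasibleGeneConfig("retention junction too close to the initiator codon")

    needed = 3 * (m + 1) - r  # intron nucleotides consumed by novel codons + stop
    retained_len = intron_lens[k - 1]
    if retained_len - 1 < needed + 2:
        raise InfeasibleGeneConfig(
            f"retained intron ({retained_len} nt) too short for "
            f"{m} novel codons plus stop (needs >= {needed + 3})"
        )

    rng = np.random.default_rng(cfg.seed)

    # --- wild-type CDS -----------------------------------------------------
    codons = ["ATG"] + list(rng.choice(SENSE_CODONS, p - 1)) + ["TAA"]
    if r > 0:
        codons[prefix_codons] = "AAA"  # junction-straddling codon; see below
    else:
        codons[prefix_codons] = "AAA"  # first codon downstream of the junction
        # keep the exonic base 5' of the donor unambiguous (not a G), so the
        # planted donor-G deletion left-aligns to the canonical +1 position
        codons[prefix_codons - 1] = str(rng.choice(_SENSE_NOT_G_END))
    cds = "".join(codons)
    assert len(cds) == cds_len

    # --- cDNA --------------------------------------------------------------
    utr5 = _random_seq(rng, u)
    utr3 = _random_seq(rng, cfg.cdna_length - u - cds_len)
    cdna = utr5 + cds + utr3
    assert len(cdna) == cfg.cdna_length

    # --- introns -----------------------------------------------------------
    introns: list[str] = []
    for i in range(1, n):
        length = intron_lens[i - 1]
        if i == k:
            # design the post-deletion reading frame: D is the retained
            # (G-deleted) intron as seen by the ribosome
            novel: list[str] = []
            if r == 2:
                first = "AAT"  # 'AA' from the exon + intron 'T' -> Asn != Lys
                d = "T"
            elif r == 1:
                z = str(rng.choice(list("ACGT")))
                first = "A" + "T" + z  # Ile/Met != Lys
                d = "T" + z
            else:
                first = str(rng.choice(_T_SENSE_CODONS))
                d = first
            novel.append(first)
            for _ in range(m - 1):
                c = str(rng.choice(SENSE_CODONS))
                novel.append(c)
                d += c
            d += "TAA"
            filler = retained_len - 1 - len(d) - 2
            d += _random_seq(rng, filler) + "AG"
            intron = "G" + d
            assert intron.startswith("GT") and intron.endswith("AG")
            assert len(intron) == retained_len
        else:
            intron = "GT" + _random_seq(rng, length - 4) + "AG"
        introns.append(intron)

    # --- genomic assembly --------------------------------------------------
    gene_seq_parts = []
    pos = 0
    exon_coords: list[tuple[int, int]] = []
    gene_span = cfg.cdna_length + sum(intron_lens)
    if cfg.contig_length < gene_span + 2:
        raise InfeasibleGeneConfig("contig shorter than the gene span")
    gene_start = (cfg.contig_length - gene_span) // 2
    cursor = gene_start
    t = 0
    for i in range(n):
        exon_seq = cdna[t : t + exon_lens[i]]
        exon_coords.append((cursor, cursor + exon_lens[i]))
        gene_seq_parts.append(exon_seq)
        cursor += exon_lens[i]
        t += exon_lens[i]
        if i < n - 1:
            gene_seq_parts.append(introns[i])
            cursor += len(introns[i])
    gene_seq = "".join(gene_seq_parts)

    flank_left = _random_seq(rng, gene_start)
    flank_right = _random_seq(rng, cfg.contig_length - gene_start - gene_span)
    genome = flank_left + gene_seq + flank_right
    assert len(genome) == cfg.contig_length

    model = GeneModel(
        gene_id=cfg.gene_id,
        chrom=cfg.chrom,
        strand="+",
        exons=tuple(exon_coords),
        cds_start=u,
        cds_end=u + cds_len,
        name=cfg.gene_id,
    )
    donor_pos = model.introns[k - 1][0]

    forged = ForgedGene(
        model=model, genome=genome, cdna=cdna, config=cfg,
        donor_pos=donor_pos, junction_cds=junction_cds,
    )
    # structural self-checks; cheap relative to sequence generation
    assert model.spliced_sequence(genome) == cdna
    assert genome[donor_pos] == "G" and genome[donor_pos + 1] == "T"
    assert forged.wildtype_cds() == cds
    return forged
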