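"""Consequence classification, intron retention, translation, termini, PCR."""

import numpy as np
import pytest

from ocpmd.models import GeneModel, reverse_complement
from ocpmd.splice import (
    SEVERITY_CLASS,
    build_protein_report,
    classify_variant,
    compare_termini,
    insilico_pcr,
    model_intron_retention,
    protein_mass_kda,
    translate_to_stop,
)
from ocpmd.synthetic import GeneForgeConfig, forge_gene_model
from ocpmd.synthetic.cohort import planted_variant_record
from ocpmd.variants import Variant

# ---------------------------------------------------------------------------
# a tiny hand-built gene for exact-codon assertions
#
# genome: 10-nt flank | exon1 ATGAAACGT | intron GTCCCCAG | exon2 GAATAATT | flank
# CDS = ATG AAA CGT GAA TAA (Met Lys Arg Glu stop), 2-nt 3'UTR in exon 2.

FLANK = "TTTTTTTTTT"
EXON1 = "ATGAAACGT"
INTRON = "GTCCCCAG"
EXON2 = "GAATAATT"
TOY_GENOME = FLANK + EXON1 + INTRON + EXON2 + FLANK
TOY = GeneModel(
    gene_id="TOY", chrom="1", strand="+",
    exons=((10, 19), (27, 35)), cds_start=0, cds_end=15,
)


def snv(pos0, alt, ref=None):
    return Variant(
        chrom="1", pos=pos0 + 1, ref=ref or TOY_GENOME[pos0], alt=alt, genotype=(1, 1)
    )


class TestClassifyToyGene:
    def test_intergenic(self):
        assert classify_variant(snv(2, "G"), [TOY], TOY_GENOME).term == "intergenic_variant"

    def test_donor_plus_one_and_two(self):
        assert classify_variant(snv(19, "A"), [TOY], TOY_GENOME).term == "splice_donor_variant"
        assert classify_variant(snv(20, "A"), [TOY], TOY_GENOME).term == "splice_donor_variant"

    def test_acceptor_minus_two_and_one(self):
        assert classify_variant(snv(25, "C"), [TOY], TOY_GENOME).term == "splice_acceptor_variant"
        assert classify_variant(snv(26, "C"), [TOY], TOY_GENOME).term == "splice_acceptor_variant"

    def test_deep_intron(self):
        rec = classify_variant(snv(22, "A"), [TOY], TOY_GENOME)
        assert rec.term == "intron_variant"
        assert rec.intron_index == 1

    def test_synonymous(self):
        # AAA -> AAG, both Lys (codon 2 at cds 3..6, genomic 13..16)
        assert classify_variant(snv(15, "G"), [TOY], TOY_GENOME).term == "synonymous_variant"

    def test_missense(self):
        # AAA -> ACA (Lys -> Thr)
        assert classify_variant(snv(14, "C"), [TOY], TOY_GENOME).term == "missense_variant"

    def test_stop_gained(self):
        # GAA -> TAA at codon 4 (exon 2, genomic 27)
        assert classify_variant(snv(27, "T"), [TOY], TOY_GENOME).term == "stop_gained"

    def test_frameshift_deletion_in_cds(self):
        var = Variant(chrom="1", pos=13, ref="GA", alt="G", genotype=(1, 1))
        assert classify_variant(var, [TOY], TOY_GENOME).term == "frameshift_variant"

    def test_utr_position_in_lowest_gene_class(self):
        rec = classify_variant(snv(34, "A"), [TOY], TOY_GENOME)  # 3'UTR base
        assert rec.term == "intron_variant"

    def test_outside_contig_raises(self):
        far = Variant(chrom="1", pos=1000, ref="A", alt="T", genotype=(1, 1))
        with pytest.raises(ValueError, match="outside"):
            classify_variant(far, [TOY], TOY_GENOME)


def test_forged_donor_deletion_named_c614(forged_default):
    chrom, pos, ref, alt = planted_variant_record(forged_default)
    var = Variant(chrom=chrom, pos=pos, ref=ref, alt=alt, genotype=(1, 1))
    rec = classify_variant(var, [forged_default.model], forged_default.genome)
    assert rec.term == "splice_donor_variant"
    assert rec.intron_index == 13
    assert rec.hgvs_c == "c.614+1delG"


def test_classification_exhaustive_and_single_valued(forged_default):
    """Every position in a lattice tiling the gene gets exactly one term."""
    g = forged_default
    start, end = g.model.start, g.model.end
    positions = list(range(start - 5, start + 50)) + list(
        range(g.donor_pos - 5, g.donor_pos + 10)
    ) + list(range(end - 50, end + 5))
    for pos0 in positions:
        ref = g.genome[pos0]
        alt = "A" if ref != "A" else "C"
        rec = classify_variant(snv_at(g, pos0, alt), [g.model], g.genome)
        assert rec.term in SEVERITY_CLASS


def snv_at(g, pos0, alt):
    return Variant(chrom=g.chrom, pos=pos0 + 1, ref=g.genome[pos0], alt=alt,
                   genotype=(1, 1))


# ---------------------------------------------------------------------------
# intron retention


def test_retention_length_arithmetic(forged_default):
    g = forged_default
    mut = model_intron_retention(g.model, g.cdna, g.genome, 13)
    assert len(mut) == 1001 + 810  # the ~1.8 kb product
    assert len(mut) - len(g.cdna) == g.retained_intron_length


def test_single_intron_retention_equals_premrna():
    cfg = GeneForgeConfig(
        n_exons=2, cdna_length=60, cds_start_exon=1, cds_end_exon=2,
        target_protein_length=10, retained_intron_index=1,
        novel_aa_before_stop=3, intron_lengths=(40,),
        donor_cds_position=None, atg_offset=3, contig_length=500,
    )
    g = forge_gene_model(cfg)
    mut = model_intron_retention(g.model, g.cdna, g.genome, 1)
    assert mut == g.model.pre_mrna_sequence(g.genome)


@pytest.mark.parametrize("seed", range(4))
def test_retention_length_property_random_genes(seed):
    cfg = GeneForgeConfig(seed=seed, contig_length=50_000)
    g = forge_gene_model(cfg)
    for k in (1, 7, 13):
        mut = model_intron_retention(g.model, g.cdna, g.genome, k)
        assert len(mut) - len(g.cdna) == g.model.intron_lengths()[k - 1]


def test_retention_with_donor_deletion_one_shorter(forged_default):
    g = forged_default
    full = model_intron_retention(g.model, g.cdna, g.genome, 13)
    deleted = model_intron_retention(g.model, g.cdna, g.genome, 13, donor_deletion=True)
    assert len(full) - len(deleted) == 1


# ---------------------------------------------------------------------------
# translation

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R", "AGT": "S",
    "AGC": "S", "AGA": "R", "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G",
    "GGG": "G", "TAA": "*", "TAG": "*", "TGA": "*",
}


def oracle_translate(seq):
    out = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        aa = CODON_TABLE[seq[i : i + 3]]
        if aa == "*":
            return "".join(out), True
        out.append(aa)
    return "".join(out), False


def test_translate_single_codon_then_stop():
    assert translate_to_stop("ATGTAA") == ("M", True)


def test_translate_no_stop_flagged():
    peptide, stop = translate_to_stop("ATGAAA")
    assert peptide == "MK"
    assert stop is False


def test_translate_too_short():
    assert translate_to_stop("AT") == ("", False)


def test_translate_matches_codon_table_oracle():
    rng = np.random.default_rng(1)
    for _ in range(50):
        seq = "".join(rng.choice(list("ACGT"), size=300))
        assert translate_to_stop(seq) == oracle_translate(seq)


# ---------------------------------------------------------------------------
# termini comparison and masses


def test_compare_termini_hand_example():
    rep = compare_termini("MKKR", "MKDE")
    assert rep.replaced_tail_length == 2
    assert rep.novel_tail_length == 2
    assert rep.basic_count_wt == 2
    assert rep.basic_count_mut == 0
    assert rep.acidic_count_wt == 0
    assert rep.acidic_count_mut == 2


def test_compare_termini_identical_proteins():
    rep = compare_termini("MKVL", "MKVL")
    assert rep.replaced_tail_length == 0
    assert rep.novel_tail_length == 0


def test_protein_report_invariant_across_seeds():
    """mut_length == wt_length - replaced + novel, for every forged gene."""
    for seed in range(5):
        g = forge_gene_model(GeneForgeConfig(seed=seed, contig_length=50_000))
        rep = build_protein_report(g.model, g.genome, g.config.retained_intron_index)
        assert rep.mut_length == rep.wt_length - rep.replaced_tail_length + rep.novel_tail_length
        assert rep.novel_tail_length == g.config.novel_aa_before_stop
        assert rep.basic_count_wt <= rep.replaced_tail_length
        assert rep.basic_count_mut <= rep.novel_tail_length


def test_single_residue_masses():
    assert protein_mass_kda("G") == pytest.approx(0.07507, abs=1e-4)
    assert protein_mass_kda("GG") == pytest.approx(0.13212, abs=1e-4)


def test_unknown_residue_raises():
    with pytest.raises(ValueError, match="X"):
        protein_mass_kda("GXG")


# ---------------------------------------------------------------------------
# in-silico PCR


def test_full_span_product():
    rng = np.random.default_rng(2)
    template = "".join(rng.choice(list("ACGT"), size=500))
    fwd = template[:20]
    rev = reverse_complement(template[-20:])
    assert insilico_pcr(template, fwd, rev) == [500]


def test_absent_primer_no_product():
    template = "A" * 200
    assert insilico_pcr(template, "GATTACAGATTACA", "TTGGCCAATTGGCC") == []


def test_retained_intron_shifts_product_by_intron_length(forged_default):
    g = forged_default
    mut = model_intron_retention(g.model, g.cdna, g.genome, 13)
    fwd = g.cdna[:20]
    rev = reverse_complement(g.cdna[-20:])
    (wt_size,) = insilico_pcr(g.cdna, fwd, rev)
    (mut_size,) = insilico_pcr(mut, fwd, rev)
    assert wt_size == 1001
    assert mut_size - wt_size == 810


def test_multiple_hits_reported_all():
    unit = "ACGTACGTACGTACGTACGT"  # 20 nt
    spacer = "CCCCCCCCCCCC"
    template = unit + spacer + unit + spacer + "TTTTTGGGGGTTTTTGGGGG"
    rev = reverse_complement("TTTTTGGGGGTTTTTGGGGG")
    products = insilico_pcr(template, unit, rev)
    assert len(products) >= 2


def test_short_primer_rejected():
    with pytest.raises(ValueError, match="10 nt"):
        insilico_pcr("ACGT" * 50, "ACGT", "ACGTACGTACGT")


def test_pcr_matches_substring_scan_oracle():
    rng = np.random.default_rng(3)
    for _ in range(10):
        template = "".join(rng.choice(list("ACGT"), size=1000))
        i, j = sorted(rng.integers(0, 950, size=2))
        j = max(j, i + 60)
        fwd = template[i : i + 15]
        rev = reverse_complement(template[j : j + 15])
        got = insilico_pcr(template, fwd, rev)
        # oracle: scan every start for exact matches
        rc = template[j : j + 15]
        fwd_hits = [k for k in range(len(template) - 14) if template[k : k + 15] == fwd]
        rc_hits = [k for k in range(len(template) - 14) if template[k : k + 15] == rc]
        want = sorted(
            k2 + 15 - k1 for k1 in fwd_hits for k2 in rc_hits if k2 >= k1 and k2 + 15 > k1 + 15
        )
        assert got == want
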