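"""Readers and writers for the standard formats the pipeline speaks.

FASTA goes through Biopython, GFF3 reading through gffutils, VCF reading
through pysam.  Emission of GFF3/VCF/PED/MAP/TSV is plain-text writing of
formats this package itself defines the content of.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import GeneModel
from .variants import Variant

# ---------------------------------------------------------------------------
# FASTA


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# GFF3


def write_gff3(genes: Sequence[GeneModel], path: str | Path, source: str = "ocpmd") -> None:
    """Write gene/mRNA/exon/CDS features for each model (1-based inclusive)."""
    lines = ["##gff-version 3"]
    for gene in genes:
        gid = gene.gene_id
        attrs_gene = f"ID=gene:{gid};Name={gene.name or gid};biotype=protein_coding"
        lines.append(
            "\t".join(
                [gene.chrom, source, "gene", str(gene.start + 1), str(gene.end), ".",
                 gene.strand, ".", attrs_gene]
            )
        )
        mid = f"transcript:{gid}.t1"
        lines.append(
            "\t".join(
                [gene.chrom, source, "mRNA", str(gene.start + 1), str(gene.end), ".",
                 gene.strand, ".", f"ID={mid};Parent=gene:{gid}"]
            )
        )
        for i, (s, e) in enumerate(gene.exons, start=1):
            lines.append(
                "\t".join(
                    [gene.chrom, source, "exon", str(s + 1), str(e), ".", gene.strand,
                     ".", f"ID=exon:{gid}.{i};Parent={mid};rank={i}"]
                )
            )
        # CDS pieces: intersect CDS transcript interval with exons
        offset = 0
        phase = 0
        for i, (s, e) in enumerate(gene.exons, start=1):
            length = e - s
            lo = max(gene.cds_start, offset)
            hi = min(gene.cds_end, offset + length)
            if lo < hi:
                if gene.strand == "+":
                    gs, ge = s + (lo - offset), s + (hi - offset)
                else:
                    gs, ge = e - (hi - offset), e - (lo - offset)
                lines.append(
                    "\t".join(
                        [gene.chrom, source, "CDS", str(gs + 1), str(ge), ".",
                         gene.strand, str(phase), f"ID=cds:{gid};Parent={mid}"]
                    )
                )
                phase = (3 - ((hi - gene.cds_start) % 3)) % 3
            offset += length
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Load protein-coding gene models from a GFF3 file via gffutils."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        gid = g.id.split(":", 1)[-1]
        mrnas = list(db.children(g, featuretype="mRNA"))
        if not mrnas:
            continue
        m = mrnas[0]
        exons = sorted(
            ((f.start - 1, f.end) for f in db.children(m, featuretype="exon")),
        )
        cds_parts = sorted(
            ((f.start - 1, f.end) for f in db.children(m, featuretype="CDS")),
        )
        if g.strand == "-":
            exons = sorted(exons, reverse=True)
        exons_t = tuple(exons)
        transcript_length = sum(e - s for s, e in exons_t)

        def to_transcript(pos: int) -> int:
            offset = 0
            for s, e in exons_t:
                if s <= pos < e:
                    return offset + (pos - s if g.strand == "+" else e - 1 - pos)
                offset += e - s
            raise ValueError(f"CDS bound {pos} not exonic in {gid}")

        # CDS in transcript coordinates
        if cds_parts:
            if g.strand == "+":
                cds_first, cds_last = cds_parts[0][0], cds_parts[-1][1] - 1
            else:
                cds_first, cds_last = cds_parts[-1][1] - 1, cds_parts[0][0]
            cds_start, cds_end = to_transcript(cds_first), to_transcript(cds_last) + 1
        else:
            cds_start, cds_end = 0, transcript_length
        genes.append(
            GeneModel(
                gene_id=gid, chrom=g.seqid, strand=g.strand, exons=exons_t,
                cds_start=cds_start, cds_end=cds_end,
                name=g.attributes.get("Name", [gid])[0],
            )
        )
    return genes


# ---------------------------------------------------------------------------
# VCF


def write_vcf(
    sample: str,
    variants: Sequence[Variant],
    contigs: Mapping[str, int],
    path: str | Path,
) -> None:
    """Write a single-sample VCF 4.2 with QD/DP INFO keys and GT in FORMAT."""
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">',
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for name, length in contigs.items():
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample
    )
    for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
        info_parts = []
        if v.qd is not None:
            info_parts.append(f"QD={v.qd:.2f}")
        if v.dp is not None:
            info_parts.append(f"DP={v.dp}")
        info = ";".join(info_parts) or "."
        gt = "/".join(str(a) for a in v.genotype)
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{info}\tGT\t{gt}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> tuple[str, list[Variant]]:
    """Read a single-sample VCF via pysam; returns (sample, variants)."""
    import pysam

    vf = pysam.VariantFile(str(path))
    sample = list(vf.header.samples)[0]
    variants = []
    for rec in vf:
        qd = rec.info.get("QD")
        dp = rec.info.get("DP")
        gt = rec.samples[sample]["GT"]
        for ai, alt in enumerate(rec.alts or (), start=1):
            mapped = tuple(
                (1 if a == ai else 0) if a is not None else None for a in gt
            )
            variants.append(
                Variant(
                    chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt,
                    genotype=mapped,
                    qd=float(qd) if qd is not None else None,
                    dp=int(dp) if dp is not None else None,
                )
            )
    return sample, variants


# ---------------------------------------------------------------------------
# Tabular formats


def write_pileups(pileups: pd.DataFrame, path: str | Path) -> None:
    cols = ["sample", "chrom", "pos", "ref_reads", "alt_reads"]
    pileups[cols].to_csv(path, sep="\t", index=False)


def read_pileups(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str})


def write_status(statuses: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"sample": list(statuses), "status": list(statuses.values())}
    ).to_csv(path, sep="\t", index=False)


def read_status(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["sample"], df["status"]))


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# PED / MAP

GENO_MISSING = -1  # array no-call
GENO_HOM_A = 0
GENO_HET = 1
GENO_HOM_B = 2


def write_ped_map(
    genotypes: Mapping[str, Sequence[int]],
    marker_ids: Sequence[str],
    chroms: Sequence[str],
    positions: Sequence[int],
    ped_path: str | Path,
    map_path: str | Path,
    phenotypes: Mapping[str, int] | None = None,
) -> None:
    """Write PLINK-style text PED/MAP.

    Genotypes are coded 0/1/2 (hom allele 1 / het / hom allele 2), -1 missing;
    alleles are written as '1' and '2', missing as '0 0'.
    """
    allele_pairs = {
        GENO_HOM_A: ("1", "1"),
        GENO_HET: ("1", "2"),
        GENO_HOM_B: ("2", "2"),
        GENO_MISSING: ("0", "0"),
    }
    ped_lines = []
    for sample, genos in genotypes.items():
        pheno = str((phenotypes or {}).get(sample, 0))
        fields = ["FAM1", sample, "0", "0", "0", pheno]
        for g in genos:
            fields.extend(allele_pairs[int(g)])
        ped_lines.append(" ".join(fields))
    Path(ped_path).write_text("\n".join(ped_lines) + "\n")

    map_lines = [
        f"{c}\t{mid}\t0\t{pos}" for c, mid, pos in zip(chroms, marker_ids, positions)
    ]
    Path(map_path).write_text("\n".join(map_lines) + "\n")


def read_ped_map(
    ped_path: str | Path, map_path: str | Path
) -> tuple[dict[str, list[int]], pd.DataFrame]:
    """Read PED/MAP back into 0/1/2/-1 genotype codes and a marker table."""
    marker_df = pd.read_csv(
        map_path, sep=r"\s+", header=None,
        names=["chrom", "marker_id", "cm", "pos"], dtype={"chrom": str},
    )
    n_markers = len(marker_df)
    genotypes: dict[str, list[int]] = {}
    for line in Path(ped_path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.split()
        sample = fields[1]
        alleles = fields[6:]
        if len(alleles) != 2 * n_markers:
            raise ValueError(
                f"sample {sample}: expected {2 * n_markers} alleles, got {len(alleles)}"
            )
        genos = []
        for a1, a2 in zip(alleles[::2], alleles[1::2]):
            if a1 == "0" or a2 == "0":
                genos.append(GENO_MISSING)
            elif a1 == a2:
                genos.append(GENO_HOM_A if a1 == "1" else GENO_HOM_B)
            else:
                genos.append(GENO_HET)
        genotypes[sample] = genos
    return genotypes, marker_df
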