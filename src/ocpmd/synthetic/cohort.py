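"""Simulate a pedigree-structured sequencing cohort around a forged gene.

The cohort mirrors the discovery design: two deep-coverage affected samples
with per-sample VCFs, low-coverage (~5x) affected and unrelated control
samples summarized as per-locus read counts, and optional carriers.  A single
causal variant — deletion of the +1 donor G of the configured intron — is
planted homozygous in all affected, heterozygous in carriers and absent from
controls.  Background variants are drawn as a Poisson process along the
contig with Hardy-Weinberg genotypes independent of disease status.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ..models import GeneModel
from ..variants import Variant, left_align
from .gene import ForgedGene


@dataclass(frozen=True)
class CohortConfig:
    """Cohort structure and sequencing-noise parameters.

    Defaults follow the study design: two affected sequenced deep (50x),
    four additional affected and eight unrelated controls at low coverage
    (Poisson mean 5 reads), and a background variant rate chosen to yield
    on the order of 200 background variants on the default 2-Mb contig.
    """

    n_affected_hi: int = 2
    n_affected_lo: int = 4
    n_controls_lo: int = 8
    n_carriers: int = 2
    background_variant_rate: float = 0.1  # per kb
    mean_depth_lo: float = 5.0
    mean_depth_hi: float = 50.0
    qd_mean: float = 30.0
    qd_sd: float = 4.0
    qd_min_guarantee: float = 20.0  # planted-variant calls exceed these
    dp_min_guarantee: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_affected_hi", "n_affected_lo", "n_controls_lo", "n_carriers"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.mean_depth_lo <= 0:
            raise ValueError("mean_depth_lo must be > 0")
        if self.background_variant_rate < 0:
            raise ValueError("background_variant_rate must be >= 0")


@dataclass
class CohortResult:
    deep_variants: dict[str, list[Variant]]  # per deep-affected sample
    pileups: pd.DataFrame  # sample, chrom, pos, ref_reads, alt_reads
    truth: dict
    statuses: dict[str, str]  # sample -> affected_hi|affected_lo|control|carrier
    background: list[tuple[int, str, str, float]]  # pos0, ref, alt, allele freq

    @property
    def controls(self) -> list[str]:
        return [s for s, st in self.statuses.items() if st == "control"]

    @property
    def extra_affected(self) -> list[str]:
        return [s for s, st in self.statuses.items() if st == "affected_lo"]

    @property
    def carriers(self) -> list[str]:
        return [s for s, st in self.statuses.items() if st == "carrier"]


def _hwe_genotype(rng: np.random.Generator, freq: float) -> tuple[int, int]:
    return (int(rng.random() < freq), int(rng.random() < freq))


def planted_variant_record(forged: ForgedGene) -> tuple[str, int, str, str]:
    """Left-aligned anchored VCF representation of the planted donor deletion."""
    g = forged.donor_pos
    raw = Variant(
        chrom=forged.chrom,
        pos=g,  # 1-based position of the base before the deleted G
        ref=forged.genome[g - 1 : g + 1],
        alt=forged.genome[g - 1],
        genotype=(1, 1),
    )
    v = left_align(raw, forged.genome)
    return (v.chrom, v.pos, v.ref, v.alt)


def simulate_cohort(forged: ForgedGene, cfg: CohortConfig) -> CohortResult:
    """Simulate deep VCF calls, low-coverage pileups and the truth record."""
    rng = np.random.default_rng(cfg.seed)
    genome = forged.genome
    chrom = forged.chrom
    contig_len = len(genome)

    chrom_, pos_, ref_, alt_ = planted_variant_record(forged)

    # --- background variants ----------------------------------------------
    n_bg = int(rng.poisson(cfg.background_variant_rate * contig_len / 1000.0))
    background: list[tuple[int, str, str, float]] = []
    if n_bg > 0:
        forbidden = set(range(forged.donor_pos - 3, forged.donor_pos + 4))
        positions = np.sort(rng.choice(contig_len - 2, size=n_bg, replace=False)) + 1
        for p0 in positions:
            p0 = int(p0)
            if p0 in forbidden:
                continue
            ref = genome[p0]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            freq = float(rng.uniform(0.1, 0.9))
            background.append((p0, ref, alt, freq))

    # --- sample naming ------------------------------------------------------
    statuses: dict[str, str] = {}
    for i in range(cfg.n_affected_hi):
        statuses[f"AF_HI_{i + 1}"] = "affected_hi"
    for i in range(cfg.n_affected_lo):
        statuses[f"AF_LO_{i + 1}"] = "affected_lo"
    for i in range(cfg.n_controls_lo):
        statuses[f"CTRL_{i + 1}"] = "control"
    for i in range(cfg.n_carriers):
        statuses[f"CAR_{i + 1}"] = "carrier"

    # --- deep-coverage VCFs -------------------------------------------------
    def draw_qd() -> float:
        return float(max(rng.normal(cfg.qd_mean, cfg.qd_sd), 0.0))

    def draw_guaranteed_qd() -> float:
        while True:
            q = float(rng.normal(cfg.qd_mean, cfg.qd_sd))
            if q > cfg.qd_min_guarantee:
                return q

    def draw_guaranteed_dp() -> int:
        while True:
            d = int(rng.poisson(cfg.mean_depth_hi))
            if d > cfg.dp_min_guarantee:
                return d

    deep_variants: dict[str, list[Variant]] = {}
    for sample, status in statuses.items():
        if status != "affected_hi":
            continue
        records = [
            Variant(
                chrom=chrom_, pos=pos_, ref=ref_, alt=alt_, genotype=(1, 1),
                qd=draw_guaranteed_qd(), dp=draw_guaranteed_dp(),
            )
        ]
        for p0, ref, alt, freq in background:
            gt = _hwe_genotype(rng, freq)
            if gt == (0, 0):
                continue
            records.append(
                Variant(
                    chrom=chrom, pos=p0 + 1, ref=ref, alt=alt,
                    genotype=tuple(sorted(gt)),
                    qd=draw_qd(), dp=int(rng.poisson(cfg.mean_depth_hi)),
                )
            )
        records.sort(key=lambda v: v.pos)
        deep_variants[sample] = records

    # --- low-coverage pileups ----------------------------------------------
    loci: list[tuple[int, tuple[int, int] | None, float | None]] = [
        (pos_, None, None)  # planted: genotype depends on status
    ]
    for p0, ref, alt, freq in background:
        loci.append((p0 + 1, None, freq))

    rows = []
    planted_gt_by_status = {
        "affected_lo": (1, 1),
        "control": (0, 0),
        "carrier": (0, 1),
        "affected_hi": (1, 1),
    }
    for sample, status in statuses.items():
        if status == "affected_hi":
            continue
        for pos, _, freq in loci:
            depth = int(rng.poisson(cfg.mean_depth_lo))
            if freq is None:
                gt = planted_gt_by_status[status]
            else:
                gt = _hwe_genotype(rng, freq)
            n_alt_alleles = gt[0] + gt[1]
            if n_alt_alleles == 0:
                ref_reads, alt_reads = depth, 0
            elif n_alt_alleles == 2:
                ref_reads, alt_reads = 0, depth
            else:
                alt_reads = int(rng.binomial(depth, 0.5))
                ref_reads = depth - alt_reads
            rows.append((sample, chrom, pos, ref_reads, alt_reads))
    pileups = pd.DataFrame(
        rows, columns=["sample", "chrom", "pos", "ref_reads", "alt_reads"]
    )

    truth = {
        "chrom": chrom_,
        "pos": pos_,
        "ref": ref_,
        "alt": alt_,
        "deleted_base_pos0": forged.donor_pos,
        "intron_index": forged.config.retained_intron_index,
        "gene_id": forged.model.gene_id,
        "n_background_variants": len(background),
        "seed": cfg.seed,
    }
    return CohortResult(
        deep_variants=deep_variants,
        pileups=pileups,
        truth=truth,
        statuses=statuses,
        background=background,
    )


def make_decoy_genes(
    forged: ForgedGene, n: int = 5, seed: int = 0
) -> list[GeneModel]:
    """Scatter simple two-exon decoy protein-coding genes along the contig.

    Decoys give the genic filter something non-trivial to do; their sequence
    content is whatever the contig already carries.
    """
    rng = np.random.default_rng(seed)
    contig_len = forged.contig_length
    gene_lo, gene_hi = forged.model.start, forged.model.end
    decoys: list[GeneModel] = []
    span = 3000  # exon1 300 + intron 2400 + exon2 300
    attempts = 0
    while len(decoys) < n and attempts < 100 * n:
        attempts += 1
        start = int(rng.integers(1000, contig_len - span - 1000))
        end = start + span
        if not (end <= gene_lo or start >= gene_hi):
            continue
        if any(not (end <= d.start or start >= d.end) for d in decoys):
            continue
        exons = ((start, start + 300), (end - 300, end))
        decoys.append(
            GeneModel(
                gene_id=f"DECOY{len(decoys) + 1}",
                chrom=forged.chrom,
                strand="+",
                exons=exons,
                cds_start=30,
                cds_end=570,
                name=f"DECOY{len(decoys) + 1}",
            )
        )
    return sorted(decoys, key=lambda g: g.start)
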