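"""Simulate SNP-array genotypes with a planted autozygous block.

Markers are placed at a fixed spacing along the contig with per-marker
population allele frequencies.  Inside a configurable window containing the
causal locus, all affected individuals are homozygous for one shared
(identical-by-descent) haplotype; carriers carry the shared haplotype plus a
population haplotype; controls follow Hardy-Weinberg everywhere.  No meiosis
or recombination is modelled beyond this single planted block.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

from ..io import GENO_HET, GENO_HOM_A, GENO_HOM_B
from .gene import ForgedGene


@dataclass(frozen=True)
class SNPArrayConfig:
    marker_spacing: int = 20_000
    window_halfwidth: int = 600_000  # 0 disables the autozygous block
    maf_low: float = 0.2
    maf_high: float = 0.8
    include_causal_marker: bool = True
    missing_rate: float = 0.0
    seed: int = 0


@dataclass
class SNPArrayResult:
    genotypes: dict[str, list[int]]  # 0/1/2 codes, -1 missing
    marker_ids: list[str]
    chroms: list[str]
    positions: list[int]
    window: tuple[int, int]  # 1-based inclusive bounds of the autozygous block
    causal_index: Optional[int]


def simulate_snp_array(
    forged: ForgedGene,
    statuses: Mapping[str, str],
    cfg: SNPArrayConfig,
) -> SNPArrayResult:
    """Generate PED/MAP-style genotypes for the cohort; seeded and repeatable."""
    from .cohort import planted_variant_record

    rng = np.random.default_rng(cfg.seed)
    contig_len = forged.contig_length
    # marker sits at the causal locus as represented in the VCF (the
    # left-aligned anchored position of the donor-G deletion)
    causal_pos = planted_variant_record(forged)[1]

    window = (causal_pos - cfg.window_halfwidth, causal_pos + cfg.window_halfwidth)
    if cfg.window_halfwidth > 0 and (window[0] < 1 or window[1] > contig_len):
        raise ValueError(
            f"autozygous window {window} extends outside the map extent (1..{contig_len})"
        )

    positions = list(range(cfg.marker_spacing, contig_len, cfg.marker_spacing))
    causal_index: Optional[int] = None
    if cfg.include_causal_marker:
        import bisect

        causal_index = bisect.bisect_left(positions, causal_pos)
        if causal_index < len(positions) and positions[causal_index] == causal_pos:
            pass
        else:
            positions.insert(causal_index, causal_pos)
    n_markers = len(positions)
    marker_ids = [f"SNP{i + 1}" for i in range(n_markers)]
    chroms = [forged.chrom] * n_markers

    freqs = rng.uniform(cfg.maf_low, cfg.maf_high, n_markers)  # freq of allele B
    in_window = np.array(
        [cfg.window_halfwidth > 0 and window[0] <= p <= window[1] for p in positions]
    )
    # the shared IBD haplotype inside the block
    shared = (rng.random(n_markers) < freqs).astype(int)  # 0 = allele A, 1 = allele B

    def hwe(i: int) -> int:
        a1 = int(rng.random() < freqs[i])
        a2 = int(rng.random() < freqs[i])
        return a1 + a2  # 0 -> hom A, 1 -> het, 2 -> hom B

    genotypes: dict[str, list[int]] = {}
    for sample, status in statuses.items():
        affected = status.startswith("affected")
        carrier = status == "carrier"
        genos = []
        for i in range(n_markers):
            if causal_index is not None and i == causal_index:
                if affected:
                    g = GENO_HOM_B
                elif carrier:
                    g = GENO_HET
                else:
                    g = GENO_HOM_A
            elif in_window[i] and affected:
                g = GENO_HOM_B if shared[i] else GENO_HOM_A
            elif in_window[i] and carrier:
                other = int(rng.random() < freqs[i])
                g = int(shared[i]) + other
            else:
                g = hwe(i)
            if cfg.missing_rate > 0 and rng.random() < cfg.missing_rate:
                g = -1
            genos.append(g)
        genotypes[sample] = genos

    return SNPArrayResult(
        genotypes=genotypes,
        marker_ids=marker_ids,
        chroms=chroms,
        positions=positions,
        window=window,
        causal_index=causal_index,
    )
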