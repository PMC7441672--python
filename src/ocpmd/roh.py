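"""Runs-of-homozygosity calling and carrier-weighted region ranking.

A run is a maximal marker window free of heterozygous calls except for a
configurable allowance, trimmed so it starts and ends on a homozygous call;
overlapping maximal windows are resolved by greedy leftmost selection so the
segments reported for one individual never overlap.  Missing genotypes
neither break a run nor count toward the minimum marker requirement.

Candidate regions are the intersections of runs across affected individuals,
down-weighted when carriers share them and discarded when homozygous only in
carriers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .io import GENO_HET, GENO_MISSING

EVIDENCE_ORDER = {"affected_only": 0, "shared_with_carriers": 1, "excluded": 2}


@dataclass(frozen=True)
class ROHParams:
    min_snps: int = 20
    min_length_bp: int = 1_000_000
    max_het: int = 1


@dataclass(frozen=True)
class ROHSegment:
    individual: str
    chrom: str
    start: int  # bp, half-open on marker positions
    end: int
    n_snps: int
    n_het_exceptions: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("segment end must exceed start")


@dataclass(frozen=True)
class CandidateRegion:
    chrom: str
    start: int
    end: int
    evidence_class: str
    supporting: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.evidence_class not in EVIDENCE_ORDER:
            raise ValueError(f"unknown evidence class {self.evidence_class!r}")


def call_roh(
    individual: str,
    chrom: str,
    positions: Sequence[int],
    genotypes: Sequence[int],
    params: ROHParams = ROHParams(),
) -> list[ROHSegment]:
    """Call ROH segments for one individual on one chromosome.

    ``genotypes`` use the 0/1/2 coding (1 = het) with -1 for missing calls.
    Markers must be position-sorted; an all-missing individual yields an
    empty list.
    """
    n = len(positions)
    if len(genotypes) != n:
        raise ValueError("positions and genotypes must have equal length")
    if any(positions[i] >= positions[i + 1] for i in range(n - 1)):
        raise ValueError("marker positions must be strictly increasing")

    hom = [g not in (GENO_HET, GENO_MISSING) for g in genotypes]
    het = [g == GENO_HET for g in genotypes]

    # maximal windows with <= max_het embedded hets (two-pointer sweep)
    windows: list[tuple[int, int]] = []  # inclusive marker index ranges
    left = 0
    het_count = 0
    prev_left = -1
    for right in range(n):
        if het[right]:
            het_count += 1
        while het_count > params.max_het:
            if het[left]:
                het_count -= 1
            left += 1
        if right == n - 1 or (het[right + 1] and het_count == params.max_het):
            if left > prev_left:
                windows.append((left, right))
                prev_left = left
    if n == 0:
        return []

    segments: list[ROHSegment] = []
    last_end_idx = -1
    for lo, hi in windows:
        # trim to homozygous endpoints
        while lo <= hi and not hom[lo]:
            lo += 1
        while hi >= lo and not hom[hi]:
            hi -= 1
        if lo > hi:
            continue
        if lo <= last_end_idx:  # greedy non-overlap resolution
            lo = last_end_idx + 1
            while lo <= hi and not hom[lo]:
                lo += 1
            if lo > hi:
                continue
        n_snps = sum(1 for i in range(lo, hi + 1) if genotypes[i] != GENO_MISSING)
        n_het = sum(1 for i in range(lo, hi + 1) if het[i])
        start, end = positions[lo], positions[hi] + 1
        if n_snps >= params.min_snps and (end - start) >= params.min_length_bp:
            segments.append(
                ROHSegment(
                    individual=individual, chrom=chrom, start=start, end=end,
                    n_snps=n_snps, n_het_exceptions=n_het,
                )
            )
            last_end_idx = hi
    return segments


def call_roh_cohort(
    genotypes: Mapping[str, Sequence[int]],
    marker_df: pd.DataFrame,
    params: ROHParams = ROHParams(),
) -> dict[str, list[ROHSegment]]:
    """Call ROH for every individual, per chromosome, from PED/MAP content."""
    out: dict[str, list[ROHSegment]] = {}
    chrom_groups = [
        (chrom, df.index.to_list())
        for chrom, df in marker_df.groupby("chrom", sort=False)
    ]
    for sample, genos in genotypes.items():
        segs: list[ROHSegment] = []
        for chrom, idx in chrom_groups:
            positions = marker_df.loc[idx, "pos"].to_list()
            sub = [genos[i] for i in idx]
            segs.extend(call_roh(sample, str(chrom), positions, sub, params))
        out[sample] = segs
    return out


def rank_regions(
    roh_by_individual: Mapping[str, Sequence[ROHSegment]],
    statuses: Mapping[str, str],
) -> list[CandidateRegion]:
    """Intersect affected ROH and classify regions by carrier sharing.

    Regions homozygous in every affected individual are candidates:
    ``affected_only`` when no carrier shares them, ``shared_with_carriers``
    (ranked below) when at least one does.  Regions homozygous only in
    carriers are ``excluded``.
    """
    affected = [s for s, st in statuses.items() if st.startswith("affected")]
    carriers = [s for s, st in statuses.items() if st == "carrier"]
    relevant = affected + carriers
    segs = [
        seg
        for s in relevant
        for seg in roh_by_individual.get(s, [])
    ]
    if not segs:
        return []

    regions: list[CandidateRegion] = []
    for chrom in sorted({seg.chrom for seg in segs}):
        chrom_segs = [seg for seg in segs if seg.chrom == chrom]
        points = sorted({p for seg in chrom_segs for p in (seg.start, seg.end)})
        pending: CandidateRegion | None = None
        for lo, hi in zip(points, points[1:]):
            aff_cover = {
                seg.individual for seg in chrom_segs
                if seg.individual in affected and seg.start <= lo and seg.end >= hi
            }
            car_cover = {
                seg.individual for seg in chrom_segs
                if seg.individual in carriers and seg.start <= lo and seg.end >= hi
            }
            if affected and aff_cover == set(affected):
                cls = "affected_only" if not car_cover else "shared_with_carriers"
                support = tuple(sorted(aff_cover | car_cover))
            elif not aff_cover and car_cover:
                cls = "excluded"
                support = tuple(sorted(car_cover))
            else:
                cls = None
                support = ()
            if cls is None:
                if pending is not None:
                    regions.append(pending)
                    pending = None
                continue
            if (
                pending is not None
                and pending.evidence_class == cls
                and pending.supporting == support
                and pending.end == lo
            ):
                pending = CandidateRegion(chrom, pending.start, hi, cls, support)
            else:
                if pending is not None:
                    regions.append(pending)
                pending = CandidateRegion(chrom, lo, hi, cls, support)
        if pending is not None:
            regions.append(pending)

    regions.sort(key=lambda r: (EVIDENCE_ORDER[r.evidence_class], r.chrom, r.start))
    return regions


def segments_to_bed(segments: Sequence[ROHSegment]) -> str:
    lines = [
        f"{s.chrom}\t{s.start}\t{s.end}\t{s.individual}\t{s.n_snps}\t{s.n_het_exceptions}"
        for s in segments
    ]
    return "\n".join(lines) + ("\n" if lines else "")


def regions_to_table(regions: Sequence[CandidateRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "evidence_class": r.evidence_class,
                "supporting": ",".join(r.supporting),
            }
            for r in regions
        ],
        columns=["chrom", "start", "end", "evidence_class", "supporting"],
    )
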