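"""The variant-prioritization cascade.

From per-sample deep-coverage variant calls and low-coverage read-support
summaries to a ranked candidate table: hard quality filtering of homozygous
calls (QD > 20, DP > 10, strict), intersection across affected samples,
restriction to gene bodies, adjudication against low-coverage cohorts, and
severity-ranked output.  Every stage reports input/output counts, which are
non-increasing through the cascade.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .models import GeneModel
from .splice import ConsequenceRecord, SEVERITY_CLASS, classify_variant
from .variants import Variant

VERDICTS = (
    "supported",
    "refuted_control_alt",
    "refuted_affected_ref",
    "insufficient_coverage",
)


@dataclass(frozen=True)
class HardFilterThresholds:
    qd_min: float = 20.0
    dp_min: int = 10


@dataclass
class FilterStats:
    n_input: int = 0
    n_passed: int = 0
    n_not_hom_alt: int = 0
    n_below_threshold: int = 0
    n_missing_fields: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass(frozen=True)
class SupportVerdict:
    chrom: str
    pos: int
    verdict: str
    n_controls_covered: int
    n_extra_affected_covered: int

    def __post_init__(self) -> None:
        if self.verdict not in VERDICTS:
            raise ValueError(f"unknown verdict {self.verdict!r}")


def hard_filter(
    variants: Sequence[Variant],
    thresholds: HardFilterThresholds = HardFilterThresholds(),
) -> tuple[list[Variant], FilterStats]:
    """Keep homozygous-alt calls with QD and DP strictly above threshold.

    Records missing QD or DP are excluded and tallied, not raised.
    """
    stats = FilterStats(n_input=len(variants))
    passed: list[Variant] = []
    for v in variants:
        if not v.is_hom_alt:
            stats.n_not_hom_alt += 1
            continue
        if v.qd is None or v.dp is None:
            stats.n_missing_fields += 1
            continue
        if v.qd > thresholds.qd_min and v.dp > thresholds.dp_min:
            passed.append(v)
        else:
            stats.n_below_threshold += 1
    stats.n_passed = len(passed)
    return passed, stats


def intersect_homozygous(
    set_a: Sequence[Variant], set_b: Sequence[Variant]
) -> list[Variant]:
    """Variants with identical (chrom, pos, ref, alt) homozygous in both sets."""
    keys_b = {v.key for v in set_b if v.is_hom_alt}
    return [v for v in set_a if v.is_hom_alt and v.key in keys_b]


def genic_filter(
    variants: Sequence[Variant], genes: Sequence[GeneModel]
) -> list[Variant]:
    """Keep variants whose position falls within any gene body.

    Gene bodies span exons and introns inclusive; UTR exons count as exons.
    """
    out = []
    for v in variants:
        pos0 = v.pos - 1
        if any(g.chrom == v.chrom and g.contains(pos0) for g in genes):
            out.append(v)
    return out


def lowcov_adjudicate(
    locus: tuple[str, int],
    pileups: pd.DataFrame,
    controls: Sequence[str],
    extra_affected: Sequence[str],
    min_depth: int = 1,
    min_fraction: float = 0.75,
) -> SupportVerdict:
    """Support or refute a candidate locus with low-coverage read counts.

    A single alt read in any control refutes (the variant cannot be the
    private recessive allele); a single ref read in any additional affected
    refutes (affected must be homozygous).  Refutation is evaluated before
    the coverage requirement: at least ``ceil(min_fraction * subset)``
    samples of each subset must have ``min_depth`` reads at the locus,
    otherwise the verdict is ``insufficient_coverage``.
    """
    if len(controls) == 0 or len(extra_affected) == 0:
        raise ValueError("control and extra-affected subsets must be non-empty")
    chrom, pos = locus
    sub = pileups[(pileups["chrom"] == chrom) & (pileups["pos"] == pos)]
    counts = {
        row["sample"]: (int(row["ref_reads"]), int(row["alt_reads"]))
        for _, row in sub.iterrows()
    }

    def depth(sample: str) -> int:
        r, a = counts.get(sample, (0, 0))
        return r + a

    n_ctrl_cov = sum(depth(s) >= min_depth for s in controls)
    n_aff_cov = sum(depth(s) >= min_depth for s in extra_affected)

    if any(counts.get(s, (0, 0))[1] >= 1 for s in controls):
        verdict = "refuted_control_alt"
    elif any(counts.get(s, (0, 0))[0] >= 1 for s in extra_affected):
        verdict = "refuted_affected_ref"
    elif (
        n_ctrl_cov < math.ceil(min_fraction * len(controls))
        or n_aff_cov < math.ceil(min_fraction * len(extra_affected))
    ):
        verdict = "insufficient_coverage"
    else:
        verdict = "supported"
    return SupportVerdict(
        chrom=chrom, pos=pos, verdict=verdict,
        n_controls_covered=n_ctrl_cov, n_extra_affected_covered=n_aff_cov,
    )


def prioritize(
    annotated: Sequence[tuple[Variant, ConsequenceRecord, SupportVerdict]],
) -> pd.DataFrame:
    """Rank supported candidates by severity class, ties broken by position.

    Severity classes: splice donor/acceptor > stop-gain/frameshift > other
    coding > intronic/intergenic.  Only variants with verdict ``supported``
    appear in the output.
    """
    rows = []
    for variant, cons, verdict in annotated:
        if verdict.verdict != "supported":
            continue
        rows.append(
            {
                "chrom": variant.chrom,
                "pos": variant.pos,
                "ref": variant.ref,
                "alt": variant.alt,
                "gene": cons.gene_id or "",
                "consequence": cons.term,
                "severity_class": cons.severity_class,
                "hgvs_c": cons.hgvs_c or "",
                "verdict": verdict.verdict,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt", "gene", "consequence",
            "severity_class", "hgvs_c", "verdict",
        ],
    )
    df = df.sort_values(
        ["severity_class", "chrom", "pos"], kind="mergesort"
    ).reset_index(drop=True)
    df.insert(0, "rank", range(1, len(df) + 1))
    return df


def run_cascade(
    deep_variants: Mapping[str, Sequence[Variant]],
    pileups: pd.DataFrame,
    genes: Sequence[GeneModel],
    genome: str,
    controls: Sequence[str],
    extra_affected: Sequence[str],
    thresholds: HardFilterThresholds = HardFilterThresholds(),
    min_depth: int = 1,
    min_fraction: float = 0.75,
) -> tuple[pd.DataFrame, dict]:
    """Run the full cascade; returns the ranked table and stage counts."""
    samples = list(deep_variants)
    if len(samples) < 2:
        raise ValueError("cascade needs at least two deep-coverage samples")
    counts: dict = {"deep_samples": samples}

    filtered: list[list[Variant]] = []
    for sample in samples:
        passed, stats = hard_filter(list(deep_variants[sample]), thresholds)
        counts[f"hard_filter[{sample}]"] = stats.as_dict()
        filtered.append(passed)

    shared = filtered[0]
    for other in filtered[1:]:
        shared = intersect_homozygous(shared, other)
    counts["shared_hom_alt"] = len(shared)

    genic = genic_filter(shared, genes)
    counts["genic"] = len(genic)

    annotated = []
    for v in genic:
        cons = classify_variant(v, genes, genome)
        verdict = lowcov_adjudicate(
            (v.chrom, v.pos), pileups, controls, extra_affected,
            min_depth=min_depth, min_fraction=min_fraction,
        )
        annotated.append((v, cons, verdict))
    counts["supported"] = sum(1 for _, _, w in annotated if w.verdict == "supported")

    table = prioritize(annotated)
    counts["ranked"] = len(table)
    return table, counts
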