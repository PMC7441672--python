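"""End-to-end orchestration: simulate -> ROH -> prioritize -> consequence,
and the contractility analysis chain, each driven by a single RunConfig.
"""

from __future__ import annotations

import dataclasses
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import io as ocio
from .contractility import compare_groups, fit_fibre_table
from .prioritize import HardFilterThresholds, run_cascade
from .roh import ROHParams, call_roh_cohort, rank_regions, regions_to_table, segments_to_bed
from .splice import build_protein_report
from .synthetic import (
    CohortConfig,
    FibreSimConfig,
    GeneForgeConfig,
    SNPArrayConfig,
    forge_gene_model,
    make_decoy_genes,
    simulate_cohort,
    simulate_force_pca,
    simulate_snp_array,
)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and counts so far."""

    def __init__(self, stage: str, counts: dict, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.counts = counts


@dataclass
class RunConfig:
    """Per-module parameter blocks plus a master seed and output directory.

    When ``seed`` is set it overrides the per-block seeds deterministically
    (block seeds are derived as small offsets of the master seed).
    """

    gene: GeneForgeConfig = field(default_factory=GeneForgeConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    snp_array: SNPArrayConfig = field(default_factory=SNPArrayConfig)
    roh: ROHParams = field(default_factory=ROHParams)
    thresholds: HardFilterThresholds = field(default_factory=HardFilterThresholds)
    fibre: FibreSimConfig = field(default_factory=FibreSimConfig)
    n_decoy_genes: int = 5
    seed: Optional[int] = None
    outdir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.seed is not None:
            base = int(self.seed) % (2**31 - 10)
            self.gene = dataclasses.replace(self.gene, seed=base)
            self.cohort = dataclasses.replace(self.cohort, seed=base + 1)
            self.snp_array = dataclasses.replace(self.snp_array, seed=base + 2)
            self.fibre = dataclasses.replace(self.fibre, seed=base + 3)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        block_types = {
            "gene": GeneForgeConfig,
            "cohort": CohortConfig,
            "snp_array": SNPArrayConfig,
            "roh": ROHParams,
            "thresholds": HardFilterThresholds,
            "fibre": FibreSimConfig,
        }
        for key, typ in block_types.items():
            if key in raw:
                block = dict(raw[key])
                for name in ("intron_lengths", "exon_lengths", "pca_grid"):
                    if name in block and block[name] is not None:
                        block[name] = tuple(block[name])
                kwargs[key] = typ(**block)
        for key in ("n_decoy_genes", "seed", "outdir"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


@dataclass
class DiscoveryReport:
    candidates: pd.DataFrame
    counts: dict
    roh_regions: pd.DataFrame
    consequence: dict
    protein_report: Optional[dict]
    truth: dict

    @property
    def top_is_truth(self) -> bool:
        if self.candidates.empty:
            return False
        top = self.candidates.iloc[0]
        return (
            top["chrom"] == self.truth["chrom"]
            and int(top["pos"]) == int(self.truth["pos"])
            and top["ref"] == self.truth["ref"]
            and top["alt"] == self.truth["alt"]
        )


def _log(msg: str) -> None:
    print(msg, file=sys.stderr)


def run_discovery(config: RunConfig, write: bool = True) -> DiscoveryReport:
    """Simulate a cohort and run the full discovery chain over it.

    Stage order: gene forging, cohort simulation, SNP-array simulation and
    ROH ranking, the variant-prioritization cascade, and consequence /
    protein modelling of the top candidate.  Writes TSV/JSON outputs (plus
    FASTA/GFF3/VCF/PED/MAP inputs) under ``config.outdir`` when requested.
    """
    counts: dict = {"seed": config.seed}
    stage = "forge_gene"
    try:
        forged = forge_gene_model(config.gene)
        decoys = make_decoy_genes(forged, n=config.n_decoy_genes,
                                  seed=config.gene.seed + 7)
        genes = [forged.model] + decoys
        _log(f"[{stage}] gene span {forged.model.start}-{forged.model.end}, "
             f"{len(decoys)} decoy genes")

        stage = "simulate_cohort"
        cohort = simulate_cohort(forged, config.cohort)
        counts["n_background_variants"] = cohort.truth["n_background_variants"]
        _log(f"[{stage}] {counts['n_background_variants']} background variants")

        stage = "roh"
        array = simulate_snp_array(forged, cohort.statuses, config.snp_array)
        marker_df = pd.DataFrame(
            {"chrom": array.chroms, "marker_id": array.marker_ids,
             "pos": array.positions}
        )
        roh = call_roh_cohort(array.genotypes, marker_df, config.roh)
        regions = rank_regions(roh, cohort.statuses)
        counts["n_roh_regions"] = len(regions)
        _log(f"[{stage}] {len(regions)} candidate regions")

        stage = "prioritize"
        table, cascade_counts = run_cascade(
            cohort.deep_variants, cohort.pileups, genes, forged.genome,
            controls=cohort.controls, extra_affected=cohort.extra_affected,
            thresholds=config.thresholds,
        )
        counts.update(cascade_counts)
        _log(f"[{stage}] {len(table)} ranked candidates")

        stage = "consequence"
        consequence: dict = {}
        protein: Optional[dict] = None
        if not table.empty:
            top = table.iloc[0]
            consequence = {
                "chrom": top["chrom"], "pos": int(top["pos"]),
                "ref": top["ref"], "alt": top["alt"],
                "term": top["consequence"], "hgvs_c": top["hgvs_c"],
                "gene": top["gene"],
            }
            if top["consequence"] in ("splice_donor_variant", "splice_acceptor_variant") \
                    and top["gene"] == forged.model.gene_id:
                report = build_protein_report(
                    forged.model, forged.genome,
                    config.gene.retained_intron_index,
                )
                protein = report.to_dict()
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise StageError(stage, counts, exc) from exc

    report = DiscoveryReport(
        candidates=table, counts=counts, roh_regions=regions_to_table(regions),
        consequence=consequence, protein_report=protein, truth=cohort.truth,
    )

    if write and config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _write_simulation(outdir, forged, cohort, array)
        report.candidates.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
        report.roh_regions.to_csv(outdir / "roh_regions.tsv", sep="\t", index=False)
        ocio.write_json(
            {
                "counts": report.counts,
                "consequence": report.consequence,
                "protein_report": report.protein_report,
                "top_is_truth": report.top_is_truth,
            },
            outdir / "report.json",
        )
        for sample, segs in roh.items():
            (outdir / f"roh_{sample}.bed").write_text(segments_to_bed(segs))
    return report


def _write_simulation(outdir: Path, forged, cohort, array) -> None:
    ocio.write_fasta({forged.chrom: forged.genome}, outdir / "genome.fa")
    ocio.write_fasta({f"{forged.model.gene_id}_cdna": forged.cdna}, outdir / "cdna.fa")
    decoys = []
    ocio.write_gff3([forged.model], outdir / "genes.gff3")
    contigs = {forged.chrom: forged.contig_length}
    for sample, variants in cohort.deep_variants.items():
        ocio.write_vcf(sample, variants, contigs, outdir / f"{sample}.vcf")
    ocio.write_pileups(cohort.pileups, outdir / "pileups.tsv")
    ocio.write_status(cohort.statuses, outdir / "status.tsv")
    ocio.write_json(cohort.truth, outdir / "truth.json")
    phenos = {
        s: (2 if st.startswith("affected") else 1)
        for s, st in cohort.statuses.items()
    }
    ocio.write_ped_map(
        array.genotypes, array.marker_ids, array.chroms, array.positions,
        outdir / "cohort.ped", outdir / "cohort.map", phenotypes=phenos,
    )


def run_contractility(
    config: RunConfig,
    measurements: Optional[pd.DataFrame] = None,
    geometry: Optional[pd.DataFrame] = None,
    pooled: bool = False,
) -> tuple[pd.DataFrame, Optional[pd.DataFrame]]:
    """Fit per-fibre Hill curves and compare groups.

    Uses the provided force-pCa table or simulates one from the config.
    Returns (fits, comparison); the comparison is None (with a warning) when
    only one group is present.
    """
    if measurements is None:
        measurements, geometry = simulate_force_pca(config.fibre)
    if measurements.empty:
        raise ValueError("empty force-pCa table: nothing to fit")
    fits = fit_fibre_table(measurements, pooled=pooled)
    metrics = ["pCa50", "pCa20", "pCa10", "nH", "Ca50_mM", "Ca20_mM", "Ca10_mM"]
    if geometry is not None and not geometry.empty:
        from .contractility import elliptical_csa

        geo = geometry.copy()
        geo["CSA_um2"] = [
            elliptical_csa(
                (r["width1"], r["width2"], r["width3"]),
                (r["depth1"], r["depth2"], r["depth3"]),
            )
            for _, r in geo.iterrows()
        ]
        geo["specific_force"] = geo["max_force"] / geo["CSA_um2"]
        fits = fits.merge(
            geo[["fibre_id", "CSA_um2", "specific_force"]],
            left_on="fit_id", right_on="fibre_id", how="left",
        ).drop(columns=["fibre_id"])
        if fits["CSA_um2"].notna().all():
            metrics = metrics + ["CSA_um2", "specific_force"]

    groups = fits["group"].unique()
    if len(groups) < 2:
        _log("single group present; skipping group comparison")
        comparison = None
    else:
        comparison = compare_groups(fits, metrics)
        for _, row in comparison.iterrows():
            _log(f"[compare] {row['metric']}: t={row['t']:.3f} p={row['p']:.3g}")
    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fits.to_csv(outdir / "fibre_fits.tsv", sep="\t", index=False)
        if comparison is not None:
            comparison.to_csv(outdir / "group_comparison.tsv", sep="\t", index=False)
    return fits, comparison
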