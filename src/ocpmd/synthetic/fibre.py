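"""Simulate single-myofibre force-pCa measurements from the Hill model.

Each fibre's normalized steady-state force at grid pCa values is the Hill
closed form at the group's generative (pCa50, nH) plus truncated Gaussian
noise, re-normalized to the measurement at saturating calcium (pCa 4.5).
Fibre geometry (width/depth at three points) and maximal absolute force are
also drawn so that cross-sectional area and specific force comparisons can
be exercised; both groups share the same geometry distribution, matching the
observation that these did not differ between genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from ..contractility import hill_force

DEFAULT_PCA_GRID = (9.0, 6.4, 6.2, 6.0, 5.8, 5.6, 5.4, 5.2, 5.0, 4.5)


@dataclass(frozen=True)
class FibreSimConfig:
    """Generative parameters for two-group force-pCa simulation.

    Defaults are the study conditions: ten fibres per group on a pCa grid
    spanning 4.5-9.0, wild-type pCa50 5.804 vs affected 6.056, Hill
    coefficient 2.0, measurement noise 2% of maximal force.
    """

    n_fibres_per_group: int = 10
    pca_grid: tuple[float, ...] = DEFAULT_PCA_GRID
    pca50_true: Mapping[str, float] = field(
        default_factory=lambda: {"WT": 5.804, "AF": 6.056}
    )
    nh_true: float = 2.0
    noise_sd: float = 0.02
    mean_width_um: float = 65.0
    sd_width_um: float = 6.0
    mean_specific_force: float = 120.0  # arbitrary stress units per CSA
    sd_specific_force: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if min(self.pca_grid) > 4.5 or max(self.pca_grid) < 9.0:
            raise ValueError("pca_grid must span at least [4.5, 9.0]")
        if 4.5 not in self.pca_grid:
            raise ValueError("pca_grid must include the normalization point pCa 4.5")


def simulate_force_pca(cfg: FibreSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-fibre force-pCa curves.

    Returns ``(measurements, geometry)``: measurements has one row per
    (fibre, pCa) with the re-normalized force; geometry has per-fibre width
    and depth triples (um) and the maximal absolute force.
    """
    rng = np.random.default_rng(cfg.seed)
    grid = np.asarray(cfg.pca_grid, dtype=float)
    i_max = int(np.argmin(np.abs(grid - 4.5)))

    meas_rows = []
    geom_rows = []
    for group, pca50 in cfg.pca50_true.items():
        for i in range(cfg.n_fibres_per_group):
            fibre_id = f"{group}_f{i + 1}"
            forces = hill_force(grid, pca50, cfg.nh_true)
            if cfg.noise_sd > 0:
                forces = forces + rng.normal(0.0, cfg.noise_sd, grid.size)
            forces = np.clip(forces, 0.0, None)
            if forces[i_max] <= 0:
                raise RuntimeError("degenerate fibre: zero force at pCa 4.5")
            forces = forces / forces[i_max]

            widths = rng.normal(cfg.mean_width_um, cfg.sd_width_um, 3)
            depths = rng.normal(cfg.mean_width_um, cfg.sd_width_um, 3)
            widths = np.clip(widths, 5.0, None)
            depths = np.clip(depths, 5.0, None)
            csa = float(
                np.mean(np.pi * (widths / 2.0) * (depths / 2.0))
            )
            specific = float(rng.normal(cfg.mean_specific_force, cfg.sd_specific_force))
            max_force = specific * csa

            for pca, f in zip(grid, forces):
                meas_rows.append((fibre_id, group, float(pca), float(f)))
            geom_rows.append(
                (fibre_id, group, *widths, *depths, max_force)
            )

    measurements = pd.DataFrame(
        meas_rows, columns=["fibre_id", "group", "pCa", "force"]
    )
    geometry = pd.DataFrame(
        geom_rows,
        columns=[
            "fibre_id", "group",
            "width1", "width2", "width3",
            "depth1", "depth2", "depth3",
            "max_force",
        ],
    )
    return measurements, geometry
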