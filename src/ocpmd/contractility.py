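"""Force-pCa analysis: fibre geometry, normalization, Hill fits, group tests.

The force-pCa relation of a permeabilized myofibre is modelled in pCa space
with a unit plateau (forces are normalized to the measurement at saturating
calcium, pCa 4.5)::

    F(pCa) = 1 / (1 + 10 ** (nH * (pCa - pCa50)))

where pCa = -log10 of the molar free Ca2+ concentration, pCa50 is the pCa at
half-maximal force, and nH (the Hill coefficient) indexes myofilament
cooperativity.  Derived submaximal points follow in closed form:
pCa_x = pCa50 + log10((1 - x) / x) / nH.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

PCA50_BOUNDS = (4.5, 7.5)
NH_BOUNDS = (0.1, 10.0)


def hill_force(pca, pca50: float, nh: float):
    """Normalized Hill force at the given pCa value(s)."""
    pca = np.asarray(pca, dtype=float)
    return 1.0 / (1.0 + 10.0 ** (nh * (pca - pca50)))


class HillFitError(RuntimeError):
    """Raised when the least-squares Hill fit fails to converge."""


@dataclass(frozen=True)
class FibreGeometry:
    """Width/depth (um) at three points along the fibre and the derived CSA."""

    widths: tuple[float, float, float]
    depths: tuple[float, float, float]

    @property
    def csa(self) -> float:
        return elliptical_csa(self.widths, self.depths)


@dataclass(frozen=True)
class HillFit:
    """Fitted Hill parameters and derived submaximal calcium sensitivities."""

    pca50: float
    nh: float
    residual: float  # sum of squared residuals
    n_points: int

    def __post_init__(self) -> None:
        if self.nh <= 0:
            raise ValueError("nH must be > 0")

    @property
    def pca10(self) -> float:
        return pca_at_fraction(self, 0.10)[0]

    @property
    def pca20(self) -> float:
        return pca_at_fraction(self, 0.20)[0]

    def calcium_at_fraction(self, fraction: float) -> float:
        """Free [Ca2+] (mM) needed to reach the given force fraction."""
        return pca_at_fraction(self, fraction)[1]


def elliptical_csa(widths: Sequence[float], depths: Sequence[float]) -> float:
    """Cross-sectional area (um^2) assuming an elliptical cross-section.

    The CSA is the mean over measurement points of pi * (width/2) * (depth/2).
    """
    w = np.asarray(widths, dtype=float)
    d = np.asarray(depths, dtype=float)
    if w.shape != d.shape or w.size == 0:
        raise ValueError("widths and depths must be equal-length, non-empty")
    if np.any(w <= 0) or np.any(d <= 0):
        raise ValueError("fibre dimensions must be positive")
    return float(np.mean(np.pi * (w / 2.0) * (d / 2.0)))


def normalize_curve(
    pca: Sequence[float], force: Sequence[float], atol: float = 1e-9
) -> np.ndarray:
    """Normalize raw forces to the measurement at pCa 4.5.

    The relaxing-solution baseline (pCa 9.0) is retained as data, not
    subtracted.  Raises if no measurement at pCa 4.5 exists.
    """
    pca = np.asarray(pca, dtype=float)
    force = np.asarray(force, dtype=float)
    mask = np.isclose(pca, 4.5, atol=atol)
    if not mask.any():
        raise ValueError("no measurement at pCa 4.5; cannot normalize")
    fmax = float(np.mean(force[mask]))
    if fmax <= 0:
        raise ValueError("non-positive force at pCa 4.5")
    return force / fmax


def fit_hill(pca: Sequence[float], force: Sequence[float]) -> HillFit:
    """Least-squares Hill fit of a normalized force-pCa curve.

    Initialized at nH=2 with pCa50 at the grid point whose force is nearest
    0.5; bounded pCa50 in [4.5, 7.5], nH in [0.1, 10].
    """
    pca = np.asarray(pca, dtype=float)
    force = np.asarray(force, dtype=float)
    if np.unique(pca).size < 4:
        raise ValueError("need at least 4 distinct pCa points to fit")
    p0_pca50 = float(np.clip(pca[np.argmin(np.abs(force - 0.5))], *PCA50_BOUNDS))
    p0 = (p0_pca50, 2.0)
    bounds = ([PCA50_BOUNDS[0], NH_BOUNDS[0]], [PCA50_BOUNDS[1], NH_BOUNDS[1]])
    try:
        popt, _ = optimize.curve_fit(
            hill_force, pca, force, p0=p0, bounds=bounds, maxfev=10000
        )
    except RuntimeError as exc:
        raise HillFitError(
            f"Hill fit did not converge (init={p0}, bounds={bounds}): {exc}"
        ) from exc
    resid = float(np.sum((hill_force(pca, *popt) - force) ** 2))
    return HillFit(pca50=float(popt[0]), nh=float(popt[1]), residual=resid,
                   n_points=int(pca.size))


def pca_at_fraction(fit: HillFit, fraction: float) -> tuple[float, float]:
    """pCa and free [Ca2+] (mM) at which force reaches the given fraction.

    Closed form: pCa_x = pCa50 + log10((1 - x) / x) / nH.  The calcium
    concentration is 10**(-pCa_x) mol/L expressed in mM.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    pca_x = fit.pca50 + np.log10((1.0 - fraction) / fraction) / fit.nh
    calcium_mm = 10.0 ** (-pca_x) * 1000.0
    return float(pca_x), float(calcium_mm)


def fit_fibre_table(measurements: pd.DataFrame, pooled: bool = False) -> pd.DataFrame:
    """Fit the Hill model per fibre (default) or pooled per group.

    ``measurements`` needs columns fibre_id, group, pCa, force (force already
    normalized).  Returns one row per fit with pCa50, nH, pCa10/20 and their
    mM equivalents.
    """
    rows = []
    if pooled:
        groups = measurements.groupby("group", sort=False)
        for group, df in groups:
            fit = fit_hill(df["pCa"].to_numpy(), df["force"].to_numpy())
            rows.append(_fit_row(group, group, fit))
    else:
        for fibre_id, df in measurements.groupby("fibre_id", sort=False):
            group = df["group"].iloc[0]
            fit = fit_hill(df["pCa"].to_numpy(), df["force"].to_numpy())
            rows.append(_fit_row(fibre_id, group, fit))
    return pd.DataFrame(rows)


def _fit_row(fit_id: str, group: str, fit: HillFit) -> dict:
    row = {
        "fit_id": fit_id,
        "group": group,
        "pCa50": fit.pca50,
        "nH": fit.nh,
        "residual": fit.residual,
    }
    for frac, label in ((0.5, "50"), (0.2, "20"), (0.1, "10")):
        pca_x, ca_mm = pca_at_fraction(fit, frac)
        row[f"pCa{label}"] = pca_x
        row[f"Ca{label}_mM"] = ca_mm
    return row


def compare_groups(
    values: pd.DataFrame,
    metrics: Iterable[str],
    group_col: str = "group",
    equal_var: bool = True,
) -> pd.DataFrame:
    """Two-tailed unpaired t-test per metric between exactly two groups.

    Welch's correction is applied when ``equal_var`` is False.  Raises if a
    group has fewer than two observations.
    """
    groups = list(dict.fromkeys(values[group_col]))
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    g1, g2 = groups
    rows = []
    for metric in metrics:
        a = values.loc[values[group_col] == g1, metric].to_numpy(dtype=float)
        b = values.loc[values[group_col] == g2, metric].to_numpy(dtype=float)
        if a.size < 2 or b.size < 2:
            raise ValueError(f"metric {metric}: each group needs >= 2 observations")
        if np.var(a, ddof=1) == 0.0 and np.var(b, ddof=1) == 0.0:
            # degenerate zero-variance groups: the t statistic is defined by
            # its limit (0 for equal means, +/-inf otherwise)
            if np.mean(a) == np.mean(b):
                t, p = 0.0, 1.0
            else:
                t = np.inf if np.mean(a) > np.mean(b) else -np.inf
                p = 0.0
        else:
            t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        rows.append(
            {
                "metric": metric,
                f"mean_{g1}": float(np.mean(a)),
                f"sd_{g1}": float(np.std(a, ddof=1)),
                f"mean_{g2}": float(np.mean(b)),
                f"sd_{g2}": float(np.std(b, ddof=1)),
                "t": float(t),
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)
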