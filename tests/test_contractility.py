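"""Fibre geometry, curve normalization, Hill fitting and group comparison."""

import numpy as np
import pytest

from ocpmd.contractility import (
    HillFit,
    compare_groups,
    elliptical_csa,
    fit_hill,
    hill_force,
    normalize_curve,
    pca_at_fraction,
)

GRID = np.array([9.0, 6.4, 6.2, 6.0, 5.8, 5.6, 5.4, 5.2, 5.0, 4.5])


# ---------------------------------------------------------------------------
# geometry


def test_csa_circle():
    assert elliptical_csa([50, 50, 50], [50, 50, 50]) == pytest.approx(1963.50, abs=0.01)


def test_csa_hand_mean():
    got = elliptical_csa([40, 50, 60], [40, 50, 60])
    assert got == pytest.approx((1256.64 + 1963.50 + 2827.43) / 3, abs=0.01)


def test_csa_dimensional_homogeneity():
    base = elliptical_csa([40, 50, 60], [30, 45, 55])
    scaled = elliptical_csa([80, 100, 120], [60, 90, 110])
    assert scaled == pytest.approx(4 * base, rel=1e-12)


def test_csa_rejects_nonpositive():
    with pytest.raises(ValueError, match="positive"):
        elliptical_csa([50, 0, 50], [50, 50, 50])


# ---------------------------------------------------------------------------
# normalization


def test_normalize_simple_ratio():
    out = normalize_curve([4.5, 6.0], [120.0, 60.0])
    assert out.tolist() == [1.0, 0.5]


def test_normalize_all_equal():
    out = normalize_curve([4.5, 6.0, 9.0], [5.0, 5.0, 5.0])
    assert np.allclose(out, 1.0)


def test_normalize_missing_pca45_raises():
    with pytest.raises(ValueError, match="4.5"):
        normalize_curve([5.0, 6.0], [1.0, 0.5])


def test_normalize_idempotent():
    raw = hill_force(GRID, 6.0, 2.0) * 137.0
    once = normalize_curve(GRID, raw)
    twice = normalize_curve(GRID, once)
    assert np.allclose(once, twice)


def test_noiseless_curve_equals_hill_form():
    raw = hill_force(GRID, 5.9, 2.3) * 55.0
    out = normalize_curve(GRID, raw)
    expect = hill_force(GRID, 5.9, 2.3) / hill_force(4.5, 5.9, 2.3)
    assert np.allclose(out, expect)


# ---------------------------------------------------------------------------
# Hill fit


def test_noiseless_recovery():
    force = hill_force(GRID, 6.0, 2.0)
    fit = fit_hill(GRID, force)
    assert fit.pca50 == pytest.approx(6.0, abs=1e-6)
    assert fit.nh == pytest.approx(2.0, abs=1e-6)


def test_too_few_points_rejected():
    with pytest.raises(ValueError, match="4 distinct"):
        fit_hill([4.5, 5.0, 6.0], [1.0, 0.9, 0.2])


def test_fit_agrees_with_grid_search_oracle():
    rng = np.random.default_rng(5)
    force = np.clip(hill_force(GRID, 5.9, 2.2) + rng.normal(0, 0.02, GRID.size), 0, None)
    force = force / force[-1]
    fit = fit_hill(GRID, force)
    # coarse 2-D grid search over (pCa50, nH)
    pgrid = np.arange(5.5, 6.3, 0.01)
    ngrid = np.arange(1.0, 4.0, 0.05)
    best, best_sse = None, np.inf
    for p in pgrid:
        for h in ngrid:
            sse = float(np.sum((hill_force(GRID, p, h) - force) ** 2))
            if sse < best_sse:
                best, best_sse = (p, h), sse
    assert fit.pca50 == pytest.approx(best[0], abs=0.011)
    assert fit.nh == pytest.approx(best[1], abs=0.051)


def test_parameter_recovery_over_seeds():
    """Median absolute error < 0.03 pCa (pCa50) and < 0.3 (nH) at 2% noise."""
    rng = np.random.default_rng(10)
    err_p, err_n = [], []
    for _ in range(50):
        force = np.clip(
            hill_force(GRID, 5.804, 2.0) + rng.normal(0, 0.02, GRID.size), 0, None
        )
        force = force / force[-1]
        fit = fit_hill(GRID, force)
        err_p.append(abs(fit.pca50 - 5.804))
        err_n.append(abs(fit.nh - 2.0))
    assert np.median(err_p) < 0.03
    assert np.median(err_n) < 0.3


# ---------------------------------------------------------------------------
# derived quantities


def test_fraction_half_is_pca50():
    fit = HillFit(pca50=6.1, nh=1.8, residual=0.0, n_points=10)
    pca, ca = pca_at_fraction(fit, 0.5)
    assert pca == pytest.approx(6.1)
    assert ca == pytest.approx(10 ** -6.1 * 1000)


def test_fraction_tenth_closed_form():
    fit = HillFit(pca50=6.0, nh=2.0, residual=0.0, n_points=10)
    pca, _ = pca_at_fraction(fit, 0.1)
    assert pca == pytest.approx(6.0 + np.log10(9) / 2.0, abs=1e-12)
    assert pca == pytest.approx(6.4771, abs=1e-4)


def test_pca_ordering_and_calcium_monotonicity():
    fit = HillFit(pca50=5.9, nh=2.4, residual=0.0, n_points=10)
    assert fit.pca10 >= fit.pca20 >= fit.pca50
    fracs = np.linspace(0.05, 0.95, 19)
    cas = [pca_at_fraction(fit, f)[1] for f in fracs]
    assert all(a < b for a, b in zip(cas, cas[1:]))  # strictly increasing in fraction


def test_fraction_bounds():
    fit = HillFit(pca50=6.0, nh=2.0, residual=0.0, n_points=10)
    for bad in (0.0, 1.0, -0.1, 1.5):
        with pytest.raises(ValueError):
            pca_at_fraction(fit, bad)


# ---------------------------------------------------------------------------
# group comparison


import pandas as pd


def _frame(a, b):
    return pd.DataFrame(
        {"group": ["X"] * len(a) + ["Y"] * len(b), "m": list(a) + list(b)}
    )


def test_identical_groups():
    out = compare_groups(_frame([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]), ["m"])
    assert out.loc[0, "t"] == 0.0
    assert out.loc[0, "p"] == 1.0


def test_textbook_t_example():
    out = compare_groups(_frame([1, 2, 3], [4, 5, 6]), ["m"])
    assert out.loc[0, "t"] == pytest.approx(-3.674, abs=1e-3)
    assert out.loc[0, "p"] == pytest.approx(0.0213, abs=1e-3)


def test_welch_option_runs():
    out = compare_groups(_frame([1, 2, 3, 4], [4, 5, 6]), ["m"], equal_var=False)
    assert np.isfinite(out.loc[0, "p"])


def test_small_group_rejected():
    with pytest.raises(ValueError, match=">= 2"):
        compare_groups(_frame([1.0], [2.0, 3.0]), ["m"])
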