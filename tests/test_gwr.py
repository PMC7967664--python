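"""GWR/MGWR: kernels, limits, bandwidth search, backfitting, summaries."""

import numpy as np
import pandas as pd
import pytest

from conftest import lattice_coords
from geodrivers.errors import NumericalError, ValidationError
from geodrivers.gwr import (KernelSpec, compare_models, fit_gwr, fit_mgwr,
                            kernel_weights, regional_mean_coefficients,
                            select_bandwidth, _aicc)


@pytest.fixture(scope="module")
def small_design():
    rng = np.random.default_rng(11)
    n = 50
    coords = rng.uniform(0, 100, (n, 2))
    X = rng.normal(size=(n, 2))
    y = 1.0 + 2.0 * X[:, 0] - 1.5 * X[:, 1] + rng.normal(0, 0.5, n)
    return coords, y, X


# ---------------------------------------------------------------------------
# kernels


def test_kernel_closed_form_values():
    spec = KernelSpec("fixed", 10.0)
    w = kernel_weights([0.0, 10.0], spec)
    assert w[0] == 1.0
    assert w[1] == pytest.approx(np.exp(-1), abs=1e-12)


def test_kernel_strictly_decreasing():
    d = np.linspace(0, 50, 200)
    w = kernel_weights(d, KernelSpec("fixed", 12.0))
    assert (np.diff(w) < 0).all()


def test_adaptive_kernel_uses_kth_neighbor_distance():
    d = np.array([0.0, 1.0, 2.0, 4.0, 8.0])
    w = kernel_weights(d, KernelSpec("adaptive", 3))
    # bandwidth = 3rd smallest distance = 2.0
    assert w[2] == pytest.approx(np.exp(-1), abs=1e-12)


def test_kernel_validation():
    with pytest.raises(ValueError):
        KernelSpec("fixed", -1.0)
    with pytest.raises(ValueError):
        kernel_weights([-1.0], KernelSpec("fixed", 1.0))


# ---------------------------------------------------------------------------
# GWR


def test_gwr_with_huge_bandwidth_is_ols(small_design):
    coords, y, X = small_design
    D = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
    fit = fit_gwr(coords, y, X, KernelSpec("fixed", 1e6 * D.max()))
    A = np.column_stack([np.ones(len(y)), X])
    ols = np.linalg.lstsq(A, y, rcond=None)[0]
    assert np.allclose(fit.params, ols[None, :], rtol=1e-6)
    assert fit.enp == pytest.approx(3.0, abs=1e-6)


def test_gwr_recovers_constant_coefficients(small_design):
    coords, y, X = small_design
    fit = fit_gwr(coords, y, X, KernelSpec("adaptive", 45))
    # generous bandwidth: surfaces flat within noise
    assert fit.params[:, 1].std() < 0.2
    assert fit.params[:, 1].mean() == pytest.approx(2.0, abs=0.2)
    assert fit.params[:, 2].mean() == pytest.approx(-1.5, abs=0.2)


def test_hat_matrix_reproduces_fit(small_design):
    coords, y, X = small_design
    fit = fit_gwr(coords, y, X, KernelSpec("adaptive", 20))
    assert np.allclose(fit.hat @ y, fit.fitted, atol=1e-10)
    assert fit.rss == pytest.approx(float(fit.residuals @ fit.residuals))
    assert fit.enp >= 3.0 - 1e-9


def test_gwr_equivariant_to_rigid_motion(small_design):
    coords, y, X = small_design
    theta = 0.7
    R = np.array([[np.cos(theta), -np.sin(theta)],
                  [np.sin(theta), np.cos(theta)]])
    moved = coords @ R.T + np.array([1000.0, -500.0])
    a = fit_gwr(coords, y, X, KernelSpec("adaptive", 20))
    b = fit_gwr(moved, y, X, KernelSpec("adaptive", 20))
    assert np.allclose(a.params, b.params, atol=1e-8)


def test_gwr_singular_design_message():
    rng = np.random.default_rng(0)
    coords = lattice_coords(6, 6, 10.0)
    X = np.column_stack([rng.normal(size=36),
                         np.zeros(36)])  # rank-deficient locally & globally
    y = rng.normal(size=36)
    with pytest.raises((NumericalError, np.linalg.LinAlgError)):
        fit_gwr(coords, y, X, KernelSpec("adaptive", 6))


def test_aicc_closed_form_reimplementation(rng):
    # independent recomputation from the published closed form
    for _ in range(50):
        n = int(rng.integers(20, 200))
        rss = float(rng.uniform(0.5, 50))
        trS = float(rng.uniform(3, min(15, n - 3)))
        sigma_ml = np.sqrt(rss / n)
        oracle = (n * np.log(2 * np.pi * sigma_ml ** 2)
                  + n * (n + trS) / (n - 2 - trS))
        assert _aicc(n, rss, trS) == pytest.approx(oracle, abs=1e-9)


# ---------------------------------------------------------------------------
# bandwidth selection


def test_selected_bandwidth_is_local_optimum(small_design):
    coords, y, X = small_design
    res = select_bandwidth(coords, y, X, mode="adaptive")
    evaluated = dict((int(b), a) for b, a in res.trace)
    b = int(res.bandwidth)
    for nb in (b - 1, b + 1):
        if nb in evaluated:
            assert evaluated[b] <= evaluated[nb] + 1e-9


def test_search_agrees_with_exhaustive_scan(small_design):
    coords, y, X = small_design
    res = select_bandwidth(coords, y, X, mode="adaptive")
    from geodrivers.gwr import _gwr_aicc_only, _distance_matrix
    D = _distance_matrix(coords)
    Xd = np.column_stack([np.ones(len(y)), X])
    lo, hi = X.shape[1] + 3, len(y)
    scan = {b: _gwr_aicc_only(D, y, Xd, KernelSpec("adaptive", float(b)))
            for b in range(lo, hi + 1)}
    best = min(scan, key=lambda b: (scan[b], b))
    assert res.aicc == pytest.approx(scan[best], abs=1e-6)


def test_fine_variation_selects_smaller_bandwidth():
    rng = np.random.default_rng(5)
    coords = lattice_coords(12, 12, 10.0)
    u = coords[:, 0] / coords[:, 0].max()
    v = coords[:, 1] / coords[:, 1].max()
    x = rng.normal(size=144)
    noise = rng.normal(0, 0.3, 144)
    beta_coarse = np.full(144, 2.0)
    beta_fine = 1.0 + 1.5 * np.sin(2 * np.pi * u) * np.cos(2 * np.pi * v)
    y_coarse = beta_coarse * x + noise
    y_fine = beta_fine * x + noise
    bc = select_bandwidth(coords, y_coarse, x[:, None], mode="adaptive").bandwidth
    bf = select_bandwidth(coords, y_fine, x[:, None], mode="adaptive").bandwidth
    assert bf < bc


# ---------------------------------------------------------------------------
# MGWR


def test_forced_common_bandwidth_matches_gwr(small_design):
    coords, y, X = small_design
    D = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
    b = 20.0 * D.max()    # generous common bandwidth
    g = fit_gwr(coords, y, X, KernelSpec("fixed", b), standardize=True)
    m = fit_mgwr(coords, y, X, mode="fixed", bandwidths=[b, b, b],
                 standardize=True, tol=1e-10, max_iter=1000)
    assert m.converged
    assert np.allclose(m.params, g.params, atol=1e-4)
    assert m.enp == pytest.approx(g.enp, abs=1e-3)


def test_mgwr_per_term_enp_sums_to_total(small_design):
    coords, y, X = small_design
    m = fit_mgwr(coords, y, X, standardize=True)
    assert m.enp_terms.sum() == pytest.approx(m.enp, abs=1e-3)
    assert np.allclose(m.hat @ ((y - y.mean()) / y.std()), m.fitted, atol=1e-8)


def test_mgwr_constant_vs_varying_bandwidth_ordering():
    rng = np.random.default_rng(8)
    coords = lattice_coords(15, 15, 10.0)
    n = 225
    u = coords[:, 0] / coords[:, 0].max()
    v = coords[:, 1] / coords[:, 1].max()
    X = rng.normal(size=(n, 2))
    beta_const = np.full(n, 2.0)
    beta_vary = 1.0 + np.sin(4 * np.pi * u) * np.cos(4 * np.pi * v)
    y = 1.0 + beta_const * X[:, 0] + beta_vary * X[:, 1] + rng.normal(0, 0.3, n)
    m = fit_mgwr(coords, y, X, standardize=True)
    # the constant-coefficient covariate gets the wider kernel
    assert m.bandwidths[1] > m.bandwidths[2]


def test_mgwr_score_trace_decreases(small_design):
    coords, y, X = small_design
    m = fit_mgwr(coords, y, X, standardize=True)
    scores = [s for _, s in m.trace]
    if len(scores) > 2:
        assert all(s2 <= s1 * 1.5 for s1, s2 in zip(scores[1:], scores[2:]))
        assert scores[-1] < scores[1]


def test_mgwr_nonconvergence_flag(small_design):
    coords, y, X = small_design
    m = fit_mgwr(coords, y, X, standardize=True, max_iter=1, tol=1e-12)
    assert not m.converged


def test_raw_params_back_transform_roundtrip(small_design):
    coords, y, X = small_design
    m = fit_mgwr(coords, y, X, standardize=True)
    raw = m.raw_params()
    Xd = np.column_stack([np.ones(len(y)), X])
    yhat_raw = (Xd * raw).sum(axis=1)
    yhat_std = m.fitted * y.std() + y.mean()
    assert np.allclose(yhat_raw, yhat_std, atol=1e-8)


# ---------------------------------------------------------------------------
# summaries


def test_compare_models_layout(small_design):
    coords, y, X = small_design
    g = fit_gwr(coords, y, X, KernelSpec("adaptive", 30), standardize=True)
    m = fit_mgwr(coords, y, X, standardize=True)
    tab = compare_models(g, m)
    assert list(tab.index) == ["Residual Squares", "Effective Number",
                               "Sigma", "AICc", "R2", "R2Adjusted"]
    assert tab.loc["Residual Squares", "GWR"] == pytest.approx(g.rss)
    assert tab.loc["AICc", "MGWR"] == pytest.approx(m.aicc)
    # self-comparison is symmetric
    self_tab = compare_models(g, m)
    pd.testing.assert_frame_equal(tab, self_tab)


def test_regional_means_match_groupby_oracle(small_design):
    coords, y, X = small_design
    m = fit_mgwr(coords, y, X, standardize=True)
    groups = np.repeat(["north", "south"], [20, 30])
    tab = regional_mean_coefficients(m, groups)
    for g in ("north", "south"):
        sel = groups == g
        for j, name in enumerate(m.names[1:], start=1):
            assert tab.loc[g, name] == pytest.approx(
                m.params[sel, j].mean(), abs=1e-12)
    # strongest = argmax |mean| over covariates
    for g in ("north", "south"):
        means = {n: abs(tab.loc[g, n]) for n in m.names[1:]}
        assert tab.loc[g, "strongest"] == max(means, key=means.get)


def test_regional_means_single_group_and_errors(small_design):
    coords, y, X = small_design
    m = fit_mgwr(coords, y, X, standardize=True)
    tab = regional_mean_coefficients(m, np.repeat("all", 50))
    assert tab.loc["all", m.names[1]] == pytest.approx(m.params[:, 1].mean())
    with pytest.raises(ValidationError):
        regional_mean_coefficients(m, np.repeat("x", 10))
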