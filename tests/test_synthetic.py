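"""Synthetic-panel generators: determinism, spatial structure, ground truth."""

import numpy as np
import pytest

from geodrivers.errors import ValidationError
from geodrivers.geodetector import factor_q
from geodrivers.moran import global_moran
from geodrivers.screening import vif
from geodrivers.synthetic import (CovariateSpec, SurfaceSpec, SyntheticSpec,
                                  default_study_spec, generate_city_lattice,
                                  generate_covariates, generate_panel,
                                  generate_response, generate_strata_scene,
                                  multiscale_recovery_spec)


def small_spec(**kw):
    base = dict(rows=5, cols=5, spacing_km=10.0,
                covariates=[CovariateSpec("x1", range_km=5.0)],
                surfaces={"x1": SurfaceSpec(kind="constant", level=2.0)},
                noise_sd=0.5, seed=3)
    base.update(kw)
    return SyntheticSpec(**base)


def test_lattice_counts_and_queen_corners():
    panel, w, geoms = generate_city_lattice(small_spec())
    assert panel.n_units == 25
    corner = w.units.index("u0000")
    assert w.neighbor_counts()[corner] == 3
    assert np.array_equal(w.W, w.W.T)
    assert w.current_islands() == []


def test_group_partition_sums_to_n():
    panel, _, _ = generate_city_lattice(default_study_spec())
    counts = panel.data["group"].value_counts()
    assert counts.tolist() == [31, 27, 17]
    assert counts.sum() == 75


def test_same_seed_byte_identical_panel(tmp_path):
    from geodrivers.panel import write_panel
    a, _, _, _ = generate_panel(small_spec())
    b, _, _, _ = generate_panel(small_spec())
    pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
    write_panel(a, pa)
    write_panel(b, pb)
    assert pa.read_text() == pb.read_text()


def test_different_seed_differs():
    a, _, _, _ = generate_panel(small_spec(seed=1))
    b, _, _, _ = generate_panel(small_spec(seed=2))
    assert not np.allclose(a.response(), b.response())


def test_spec_yaml_roundtrip(tmp_path):
    spec = default_study_spec(seed=9)
    path = tmp_path / "spec.yaml"
    spec.to_yaml(path)
    again = SyntheticSpec.from_yaml(path)
    assert again == spec


def test_short_range_covariate_is_white_noise():
    spec = small_spec(rows=8, cols=8,
                      covariates=[CovariateSpec("x1", range_km=0.01)])
    panel, w, _ = generate_city_lattice(spec)
    panel = generate_covariates(panel, spec)
    res = global_moran(panel.data["x1"].to_numpy(), w)
    assert abs(res.Z) < 3.0  # no detectable structure


def test_long_range_covariate_is_smooth():
    spec = small_spec(rows=8, cols=8,
                      covariates=[CovariateSpec("x1", range_km=200.0)])
    panel, w, _ = generate_city_lattice(spec)
    panel = generate_covariates(panel, spec)
    res = global_moran(panel.data["x1"].to_numpy(), w)
    assert res.I > 0 and res.Z > 2.58


def test_injected_correlation_reproduces_target_vif():
    spec = small_spec(
        rows=20, cols=20,
        covariates=[CovariateSpec("x1", range_km=0.01),
                    CovariateSpec("x2", range_km=0.01,
                                  correlate_with="x1", rho=0.9)])
    panel, _, _ = generate_city_lattice(spec)
    panel = generate_covariates(panel, spec)
    tab = vif(panel.data, ["x1", "x2"])
    assert tab["VIFs"].iloc[0] == pytest.approx(1 / (1 - 0.81), rel=0.25)


def test_noiseless_constant_response_is_exactly_linear():
    spec = small_spec(noise_sd=0.0,
                      surfaces={"intercept": SurfaceSpec("constant", level=5.0),
                                "x1": SurfaceSpec("constant", level=2.0)})
    panel, w, geoms = generate_city_lattice(spec)
    panel = generate_covariates(panel, spec)
    panel, truth = generate_response(panel, spec)
    X = np.column_stack([np.ones(25), panel.X()])
    beta = np.linalg.lstsq(X, panel.response(), rcond=None)[0]
    assert np.allclose(beta, [5.0, 2.0], atol=1e-10)
    assert truth.shape == (25, 2)  # intercept + 1 covariate, one row per unit


def test_residual_variance_matches_noise_sd():
    spec = small_spec(rows=25, cols=25, noise_sd=0.7)
    panel, _, _, truth = generate_panel(spec)
    X = np.column_stack([np.ones(625), panel.X()])
    beta = np.linalg.lstsq(X, panel.response(), rcond=None)[0]
    resid = panel.response() - X @ beta
    assert resid.std() == pytest.approx(0.7, rel=0.15)


def test_unknown_surface_name_raises():
    spec = small_spec(surfaces={"nope": SurfaceSpec("constant", level=1.0)})
    panel, _, _ = generate_city_lattice(spec)
    panel = generate_covariates(panel, spec)
    with pytest.raises(ValidationError, match="nope"):
        generate_response(panel, spec)


def test_strata_scene_limits_and_self_consistency(rng):
    # zero within-variance -> q exactly 1
    spec = small_spec(strata_L=4, strata_between_sd=2.0, strata_within_sd=0.0,
                      strata_n=200)
    y, strata, true_q = generate_strata_scene(spec)
    assert true_q == pytest.approx(1.0)
    assert factor_q(y, strata).q == pytest.approx(1.0)

    # no between-variance -> q near 0 at large n
    spec = small_spec(strata_L=4, strata_between_sd=0.0, strata_within_sd=1.0,
                      strata_n=20000)
    y, strata, true_q = generate_strata_scene(spec)
    assert factor_q(y, strata).q < 0.01

    # realized truth equals the detector output exactly (same formula)
    spec = small_spec(strata_L=5, strata_between_sd=1.0, strata_within_sd=0.5,
                      strata_n=500)
    y, strata, true_q = generate_strata_scene(spec)
    assert factor_q(y, strata).q == pytest.approx(true_q, abs=1e-12)


def test_strata_q_recovery_at_large_n():
    # q -> 1 - within/(within+between) as n grows
    spec = small_spec(strata_L=8, strata_between_sd=1.0, strata_within_sd=0.5,
                      strata_n=20000, seed=12)
    y, strata, true_q = generate_strata_scene(spec)
    got = factor_q(y, strata).q
    assert got == pytest.approx(true_q, abs=1e-12)
    # variance-share recovery: q ≈ 1 - σ_w²/σ̂_t² with the realized total
    # variance (the drawn stratum means set the between part)
    theory = 1.0 - 0.25 / np.var(y)
    assert got == pytest.approx(theory, abs=0.02)


def test_time_panel_has_all_slices():
    spec = default_study_spec(seed=4)
    panel, w, geoms, truth = generate_panel(spec)
    assert panel.times == ["2015", "2016", "2017", "2018"]
    assert len(panel.data) == 75 * 4
    s = panel.slice_time("2016")
    assert s.n_units == 75


def test_recovery_fixture_shape():
    spec = multiscale_recovery_spec()
    panel, w, geoms, truth = generate_panel(spec)
    assert panel.n_units == 400
    assert list(truth.columns) == ["intercept", "x1", "x2"]
    # constant, gradient, sinusoid
    assert truth["intercept"].std() == 0.0
    assert truth["x1"].std() > 0
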