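"""Spatial Durbin estimation and the specification battery."""

import numpy as np
import pandas as pd
import pytest

import tricoord as tc
from tricoord import sdm as sdmod
from tricoord.errors import EstimationError, InvalidConfigError


@pytest.fixture(scope="module")
def panel_X(w_dist_mod):
    rng = np.random.default_rng(7)
    idx = pd.MultiIndex.from_product([w_dist_mod.ids, range(2013, 2024)],
                                     names=["unit", "year"])
    return pd.DataFrame({"x1": rng.normal(size=len(idx)),
                         "x2": rng.normal(size=len(idx))}, index=idx)


@pytest.fixture(scope="module")
def w_dist_mod():
    cent, _ = tc.default_geography()
    return tc.from_centroids(cent, kind="inverse_distance")


def test_reduces_to_ols_when_rho_zero(w_dist_mod, panel_X):
    y, _ = tc.generate_sdm_outcome(w_dist_mod, panel_X, 0.0, [1.0, -0.5],
                                   [0.0, 0.0], 1e-9, seed=1)
    res = sdmod.fit_sdm(panel_X, y, w_dist_mod, effects="pooled", model="sar")
    Z = np.column_stack([np.ones(len(y)),
                         panel_X.reindex(y.index).to_numpy()])
    ols, *_ = np.linalg.lstsq(Z, y.to_numpy(), rcond=None)
    np.testing.assert_allclose(res.params[["const", "x1", "x2"]], ols, atol=1e-6)
    assert abs(res.rho) < 1e-6


def test_rho_recovery_monte_carlo(w_dist_mod, panel_X):
    rhos = []
    for rep in range(30):
        y, _ = tc.generate_sdm_outcome(w_dist_mod, panel_X, 0.4, [1.0, -0.5],
                                       [0.5, 0.2], 0.1, seed=200 + rep)
        rhos.append(sdmod.fit_sdm(panel_X, y, w_dist_mod,
                                  effects="pooled").rho)
    assert abs(np.mean(rhos) - 0.4) < 0.05


def test_noise_scale_does_not_bias_rho(w_dist_mod, panel_X):
    """Doubling sigma leaves the rho-hat distribution centered at truth."""
    means = []
    for sigma in (0.1, 0.2):
        rhos = [sdmod.fit_sdm(panel_X,
                              tc.generate_sdm_outcome(
                                  w_dist_mod, panel_X, 0.4, [1.0, -0.5],
                                  [0.5, 0.2], sigma, seed=500 + rep)[0],
                              w_dist_mod, effects="pooled").rho
                for rep in range(20)]
        means.append(np.mean(rhos))
    assert abs(means[0] - 0.4) < 0.06 and abs(means[1] - 0.4) < 0.06


def test_loglik_at_optimum_beats_rho_zero(w_dist_mod, panel_X):
    y, _ = tc.generate_sdm_outcome(w_dist_mod, panel_X, 0.3, [1.0, -0.5],
                                   [0.5, 0.2], 0.2, seed=9)
    est = tc.SpatialDurbinRegressor(weights=w_dist_mod, effects="pooled")
    est.fit(panel_X, y)
    res = est.result_
    eig = np.linalg.eigvals(w_dist_mod.matrix).real
    assert 1.0 / eig.min() < res.rho < 1.0
    # refitting with the spatial term suppressed cannot improve the fit
    res0 = sdmod.fit_sdm(panel_X, y, w_dist_mod, effects="pooled", model="sar")
    assert res.llf >= res0.llf - 1e-8


def test_concentrated_likelihood_matches_grid_search():
    """Tiny panel: scalar optimum agrees with a dense rho grid (step 1e-3)."""
    rng = np.random.default_rng(3)
    cent = pd.DataFrame({"x": rng.uniform(size=6), "y": rng.uniform(size=6)},
                        index=[f"u{i}" for i in range(6)])
    w = tc.from_centroids(cent, kind="inverse_distance")
    idx = pd.MultiIndex.from_product([w.ids, [2013, 2014, 2015]],
                                     names=["unit", "year"])
    X = pd.DataFrame({"x": rng.normal(size=len(idx))}, index=idx)
    y, _ = tc.generate_sdm_outcome(w, X, 0.35, [1.0], [0.4], 0.3, seed=5)
    est = tc.SpatialDurbinRegressor(weights=w, effects="pooled").fit(X, y)

    from tricoord.sdm import panel_arrays, _per_period, _ols, _log_jacobian
    yv, Xv, T, _ = panel_arrays(X, y, w)
    eig = np.linalg.eigvals(w.matrix).real
    WX = _per_period(w.matrix, Xv, w.n, T)
    Wy = _per_period(w.matrix, yv[:, None], w.n, T).ravel()
    Z = np.column_stack([np.ones_like(yv), Xv, WX])
    _, e0 = _ols(yv, Z)
    _, e1 = _ols(Wy, Z)
    N = w.n * T

    def ll(rho):
        e = e0 - rho * e1
        s2 = e @ e / N
        return -0.5 * N * (np.log(2 * np.pi * s2) + 1) + T * _log_jacobian(rho, eig)

    grid = np.arange(1.0 / eig.min() + 1e-3, 1.0 - 1e-3, 1e-3)
    best = grid[np.argmax([ll(r) for r in grid])]
    assert abs(est.rho_ - best) <= 1e-3


def test_estimates_invariant_under_unit_permutation(w_dist_mod, panel_X):
    y, _ = tc.generate_sdm_outcome(w_dist_mod, panel_X, 0.3, [1.0, -0.5],
                                   [0.5, 0.2], 0.2, seed=11)
    res = sdmod.fit_sdm(panel_X, y, w_dist_mod, effects="pooled")
    rng = np.random.default_rng(0)
    order = list(rng.permutation(w_dist_mod.ids))
    wp = w_dist_mod.permute(order)
    resp = sdmod.fit_sdm(panel_X, y, wp, effects="pooled")
    np.testing.assert_allclose(resp.params, res.params, atol=1e-10)


def test_fixed_and_random_effects_run(w_dist_mod, panel_X):
    rng = np.random.default_rng(13)
    # add genuine unit effects so FE/RE have something to absorb
    effects = pd.Series(rng.normal(0, 0.5, size=w_dist_mod.n),
                        index=w_dist_mod.ids)
    y, _ = tc.generate_sdm_outcome(w_dist_mod, panel_X, 0.3, [1.0, -0.5],
                                   [0.5, 0.2], 0.2, seed=13)
    y = y + effects.reindex(y.index.get_level_values("unit")).to_numpy()
    fe = sdmod.fit_sdm(panel_X, y, w_dist_mod, effects="fixed")
    re = sdmod.fit_sdm(panel_X, y, w_dist_mod, effects="random")
    for res in (fe, re):
        assert abs(res.rho - 0.3) < 0.12
        np.testing.assert_allclose(res.params[["x1", "x2"]], [1.0, -0.5],
                                   atol=0.1)


def test_rank_deficient_regressors_rejected(w_dist_mod, panel_X):
    X = panel_X.assign(x3=panel_X["x1"] * 2.0)
    y = pd.Series(np.arange(len(X), dtype=float), index=X.index)
    with pytest.raises(EstimationError):
        sdmod.fit_sdm(X, y, w_dist_mod, effects="pooled")


# ----------------------------------------------------------------------- VIF

def test_vif_orthogonal_and_collinear(rng):
    n = 200
    X = pd.DataFrame({"a": np.repeat([1.0, -1.0], n // 2),
                      "b": np.tile([1.0, -1.0], n // 2)})
    v, mean = sdmod.vif(X)
    np.testing.assert_allclose(v, 1.0, atol=1e-10)
    X2 = pd.DataFrame({"a": rng.normal(size=n)})
    X2["b"] = X2["a"] + rng.normal(scale=1e-3, size=n)
    v2, _ = sdmod.vif(X2)
    assert (v2 > 10).all()
    X3 = X2.assign(c=2 * X2["a"])
    with pytest.raises(EstimationError, match="c"):
        sdmod.vif(X3)


def test_vif_matches_auxiliary_regression_oracle(rng):
    X = pd.DataFrame(rng.normal(size=(60, 4)), columns=list("abcd"))
    X["b"] += 0.8 * X["a"]
    v, mean = sdmod.vif(X)
    import statsmodels.api as sm
    for col in X.columns:
        others = sm.add_constant(X.drop(columns=col))
        r2 = sm.OLS(X[col], others).fit().rsquared
        assert v[col] == pytest.approx(1 / (1 - r2), abs=1e-10)
    assert mean == pytest.approx(v.mean())


# ------------------------------------------------------------------ LM tests

def test_lm_lag_has_power_under_strong_rho(w_dist_mod, panel_X):
    hits = 0
    for rep in range(20):
        y, _ = tc.generate_sdm_outcome(w_dist_mod, panel_X, 0.5, [1.0, -0.5],
                                       [0.0, 0.0], 0.3, seed=700 + rep)
        t = sdmod.lm_tests(panel_X, y, w_dist_mod)
        assert t.lm_lag >= 0 and t.lm_error >= 0
        assert t.robust_lm_lag >= 0 and t.robust_lm_error >= 0
        hits += t.lm_lag_p < 0.05
    assert hits >= 19


# -------------------------------------------------------- LR / Wald / Hausman

def test_identical_models_have_zero_lr():
    res_ll = 123.45
    assert 2 * (res_ll - res_ll) == 0.0


def test_lr_wald_battery_under_sdm_dgp(w_dist_mod, panel_X):
    y, _ = tc.generate_sdm_outcome(w_dist_mod, panel_X, 0.4, [1.0, -0.5],
                                   [0.6, 0.3], 0.2, seed=21)
    tests, fits = sdmod.lr_wald_hausman(panel_X, y, w_dist_mod,
                                        effects="pooled")
    # a true SDM rejects both the SAR and SEM simplifications
    assert tests.lr_lag > 0 and tests.lr_lag_p < 0.05
    assert tests.lr_error > 0 and tests.lr_error_p < 0.05
    assert tests.wald_lag >= 0 and tests.wald_error >= 0
    assert tests.hausman >= 0
    assert fits["sdm"].llf >= fits["sar"].llf - 1e-8
    assert fits["sdm"].llf >= fits["sem"].llf - 1e-8


def test_lr_lag_size_under_sar_dgp(w_dist_mod, panel_X):
    """Under a SAR generating process the SDM-vs-SAR LR rarely rejects."""
    rejections = 0
    for rep in range(15):
        y, _ = tc.generate_sdm_outcome(w_dist_mod, panel_X, 0.4, [1.0, -0.5],
                                       [0.0, 0.0], 0.3, seed=900 + rep)
        tests, _ = sdmod.lr_wald_hausman(panel_X, y, w_dist_mod,
                                         effects="pooled")
        rejections += tests.lr_lag_p < 0.05
    assert rejections <= 4


def test_hausman_accepts_random_effects_when_consistent(w_dist_mod, panel_X):
    """Effects uncorrelated with X: Hausman should not rush to reject."""
    rng = np.random.default_rng(31)
    pvals = []
    for rep in range(5):
        eff = pd.Series(rng.normal(0, 0.3, size=w_dist_mod.n),
                        index=w_dist_mod.ids)
        y, _ = tc.generate_sdm_outcome(w_dist_mod, panel_X, 0.3, [1.0, -0.5],
                                       [0.5, 0.2], 0.3, seed=1100 + rep)
        y = y + eff.reindex(y.index.get_level_values("unit")).to_numpy()
        tests, _ = sdmod.lr_wald_hausman(panel_X, y, w_dist_mod,
                                         effects="random")
        pvals.append(tests.hausman_p)
    assert np.median(pvals) > 0.01


# --------------------------------------------------------------- robustness

def test_robustness_suite_contract(w_dist_mod, panel_X):
    y, _ = tc.generate_sdm_outcome(w_dist_mod, panel_X, 0.4, [1.0, -0.5],
                                   [0.5, 0.2], 0.2, seed=41)
    y_alt = y * 1.05  # proxy alternative outcome sharing the spatial signal
    out = sdmod.robustness_suite(panel_X, y, w_dist_mod, y_alternative=y_alt,
                                 exclude=[w_dist_mod.ids[0], w_dist_mod.ids[5]],
                                 effects="pooled")
    assert np.sign(out["alternative_outcome"].rho) == np.sign(out["baseline"].rho)
    w_sub = w_dist_mod.subset([u for u in w_dist_mod.ids
                               if u not in (w_dist_mod.ids[0], w_dist_mod.ids[5])])
    np.testing.assert_allclose(w_sub.matrix.sum(axis=1), 1.0, atol=1e-12)
    assert out["subset"].n == w_dist_mod.n - 2
    # empty exclusion list reproduces the baseline exactly
    out2 = sdmod.robustness_suite(panel_X, y, w_dist_mod, exclude=[],
                                  effects="pooled")
    np.testing.assert_allclose(out2["baseline"].params,
                               out["baseline"].params, atol=0)
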