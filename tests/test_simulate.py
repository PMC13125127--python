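"""Synthetic panel generator: structure, determinism, ground truth."""

import numpy as np
import pandas as pd
import pytest

import tricoord as tc
from tricoord.composite import IndicatorSchema
from tricoord.errors import InvalidConfigError
from tricoord.simulate import child_seed, default_schema_table


def small_config(**kw):
    schema = pd.DataFrame({
        "indicator": ["h1", "h2"],
        "subsystem": ["healthcare", "healthcare"],
        "dimension": ["d", "d"],
        "direction": ["+", "-"],
    })
    defaults = dict(
        n_units=4, n_years=3, indicator_schema=schema,
        region_assignment={"u1": "east", "u2": "east",
                           "u3": "central", "u4": "west"},
        seed=0)
    defaults.update(kw)
    return tc.SimulationConfig(**defaults)


def test_row_count_arithmetic():
    panel, _ = tc.generate_indicator_panel(small_config())
    assert len(panel) == 4 * 3 * 2


def test_default_conditions_are_the_study_panel():
    cfg = tc.SimulationConfig(seed=0)
    assert cfg.n_units == 31 and cfg.n_years == 11
    assert len(cfg.indicator_schema) == 29
    regions = pd.Series(cfg.region_assignment).value_counts()
    assert regions["east"] == 11 and regions["central"] == 8 and regions["west"] == 12


def test_invalid_config_rejected():
    with pytest.raises(InvalidConfigError):
        small_config(n_units=0)
    with pytest.raises(InvalidConfigError):
        small_config(n_years=-1)
    with pytest.raises(InvalidConfigError):
        small_config(noise_sd=-0.1)


def test_noiseless_series_monotone_in_year():
    cfg = small_config(noise_sd=0.0)
    panel, _ = tc.generate_indicator_panel(cfg)
    wide = panel.pivot_table(index="year", columns=["unit", "indicator"],
                             values="value")
    diffs = wide.diff().dropna()
    for (unit, ind) in wide.columns:
        col = diffs[(unit, ind)]
        if ind == "h1":      # positive direction rises with latent quality
            assert (col > 0).all()
        else:                # negative direction falls as quality rises
            assert (col < 0).all()


def test_same_seed_reproduces_identical_panels():
    p1, _ = tc.generate_indicator_panel(small_config())
    p2, _ = tc.generate_indicator_panel(small_config())
    pd.testing.assert_frame_equal(p1, p2)
    c1 = tc.generate_covariates(small_config())
    c2 = tc.generate_covariates(small_config())
    pd.testing.assert_frame_equal(c1, c2)


def test_region_ordering_of_subsystem_scores():
    cfg = tc.SimulationConfig(seed=2, noise_sd=0.01)
    panel, gt = tc.generate_indicator_panel(cfg)
    schema = IndicatorSchema(cfg.indicator_schema)
    scores = tc.SubsystemIndex(schema).fit(panel).scores_
    reg = pd.Series(cfg.region_assignment)
    by_region = scores.join(reg.rename("region"), on="unit") \
                      .groupby("region").mean()
    for sub in scores.columns:
        assert by_region.loc["east", sub] > by_region.loc["central", sub] \
            > by_region.loc["west", sub]
    # recorded latent region means respect the same ordering
    for sub, means in gt.region_means.items():
        assert means["east"] > means["central"] > means["west"]


def test_csv_round_trip_is_lossless(tmp_path):
    panel, _ = tc.generate_indicator_panel(small_config())
    path = tmp_path / "panel.csv"
    panel.to_csv(path, index=False)
    back = pd.read_csv(path)
    np.testing.assert_allclose(back["value"], panel["value"], rtol=1e-12)
    assert (back[["unit", "year", "indicator"]].values
            == panel[["unit", "year", "indicator"]].values).all()


def test_covariates_respect_ranges_and_vary_within_units():
    cfg = tc.SimulationConfig(seed=3)
    cov = tc.generate_covariates(cfg)
    for name, (lo, hi) in cfg.covariate_ranges.items():
        assert cov[name].between(lo, hi).all()
    within = cov.groupby(level="unit")["Old"].nunique()
    assert (within > 1).all()


def test_ground_truth_round_trips_exactly(tmp_path):
    gt = tc.GroundTruth(true_rho=0.4, true_betas=[1.0, -0.5],
                        true_theta=[0.5, 0.2], true_sigma=0.1,
                        true_gamma=15.06, true_regime_betas=[0.006, 0.011])
    path = tmp_path / "gt.json"
    gt.to_json(path)
    back = tc.GroundTruth.from_json(path)
    assert back == gt


def test_child_seeds_are_stable_and_stage_specific():
    assert child_seed(7, "sdm_dgp") == child_seed(7, "sdm_dgp")
    assert child_seed(7, "sdm_dgp") != child_seed(7, "threshold_dgp")
    assert 0 <= child_seed(123456, "x") < 2 ** 31


# ------------------------------------------------------------- DGP outcomes

def test_sdm_outcome_degenerate_cases(w_dist, rng):
    idx = pd.MultiIndex.from_product([w_dist.ids, [2013, 2014]],
                                     names=["unit", "year"])
    X = pd.DataFrame({"x": rng.normal(size=len(idx))}, index=idx)
    y, gt = tc.generate_sdm_outcome(w_dist, X, 0.0, [2.0], [0.0], 0.0, seed=0)
    np.testing.assert_allclose(y.sort_index(), 2.0 * X["x"].sort_index(),
                               atol=1e-12)
    assert gt.true_rho == 0.0
    # a zero weight matrix makes y independent of rho
    w0 = tc.SpatialWeights(np.zeros((3, 3)), ["a", "b", "c"], kind="contiguity")
    idx3 = pd.MultiIndex.from_product([["a", "b", "c"], [2013]],
                                      names=["unit", "year"])
    X3 = pd.DataFrame({"x": [1.0, 2.0, 3.0]}, index=idx3)
    y1, _ = tc.generate_sdm_outcome(w0, X3, 0.0, [1.0], [0.5], 0.0, seed=1)
    y2, _ = tc.generate_sdm_outcome(w0, X3, 0.8, [1.0], [0.5], 0.0, seed=1)
    pd.testing.assert_series_equal(y1, y2)


def test_sdm_outcome_singularity_names_rho(w_dist, rng):
    idx = pd.MultiIndex.from_product([w_dist.ids, [2013]],
                                     names=["unit", "year"])
    X = pd.DataFrame({"x": rng.normal(size=len(idx))}, index=idx)
    with pytest.raises(InvalidConfigError, match="rho=1.0"):
        tc.generate_sdm_outcome(w_dist, X, 1.0, [1.0], [0.0], 0.1, seed=0)


def test_sdm_outcome_with_positive_rho_is_spatially_autocorrelated(w_queen):
    """Monte-Carlo: the panel-mean Moran's I of y (n=31, T=11) is positive
    in at least 95 of 100 replicates under rho = 0.4."""
    years = range(2013, 2024)
    idx = pd.MultiIndex.from_product([w_queen.ids, years],
                                     names=["unit", "year"])
    X = pd.DataFrame({"x": np.zeros(len(idx))}, index=idx)
    hits = 0
    for rep in range(100):
        y, _ = tc.generate_sdm_outcome(w_queen, X, 0.4, [0.0], [0.0], 1.0,
                                       seed=1000 + rep)
        mean_i = np.mean([
            tc.global_moran(y.xs(t, level="year").reindex(w_queen.ids),
                            w_queen).I
            for t in years])
        hits += mean_i > 0
    assert hits >= 95


def test_threshold_outcome_contract(rng):
    idx = pd.MultiIndex.from_product([[f"u{i}" for i in range(10)],
                                      range(2013, 2019)],
                                     names=["unit", "year"])
    q = pd.Series(rng.uniform(5, 30, size=len(idx)), index=idx)
    with pytest.raises(InvalidConfigError, match="outside"):
        tc.generate_threshold_outcome(q, 100.0, 0.1, 0.2, None, 0.1, seed=0)
    y1, gt = tc.generate_threshold_outcome(q, 15.0, 0.1, 0.3, None, 0.0,
                                           seed=4, unit_effect_sd=0.0)
    # noiseless outcome is exactly piecewise linear in q
    expect = np.where(q <= 15.0, 0.1 * q, 0.3 * q)
    np.testing.assert_allclose(y1.to_numpy(), expect, atol=1e-12)
    assert gt.true_gamma == 15.0 and gt.true_regime_betas == [0.1, 0.3]
    y2, _ = tc.generate_threshold_outcome(q, 15.0, 0.1, 0.3, None, 0.2, seed=9)
    y3, _ = tc.generate_threshold_outcome(q, 15.0, 0.1, 0.3, None, 0.2, seed=9)
    pd.testing.assert_series_equal(y2, y3)
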