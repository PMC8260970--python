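"""Synthetic cohort generator: determinism, calibration, and oracle accuracy."""

import numpy as np
import pandas as pd
import pytest

import threshcurve as tc
from threshcurve.errors import ConfigurationError
from threshcurve.scores import tb_bin_index
from threshcurve.simulate import COHORT_COLUMNS


def test_deterministic_under_fixed_seed():
    cfg = tc.SimulationConfig.cirrhosis_like(n=1000, seed=1)
    a = tc.generate_cohort(cfg)
    b = tc.generate_cohort(cfg)
    pd.testing.assert_frame_equal(a, b)
    assert len(a) == 1000
    assert list(a.columns) == COHORT_COLUMNS


def test_different_seeds_differ():
    a = tc.generate_cohort(tc.SimulationConfig.cirrhosis_like(n=500, seed=1))
    b = tc.generate_cohort(tc.SimulationConfig.cirrhosis_like(n=500, seed=2))
    assert not a["tb"].equals(b["tb"])


def test_death_flag_conservation(cirrhosis_cohort):
    df = cirrhosis_cohort
    assert (df["death_28"] <= df["death_90"]).all()
    assert df["death_28"].sum() <= df["death_90"].sum() <= len(df)
    assert (df["tb"].dropna() >= 0).all()
    assert df["he_grade"].isin([0, 2, 3, 4]).all()
    lt = df[df["lt_within_90"] == 1]
    assert (lt["lt_day"] <= 90).all()


def test_flat_link_mortality_independent_of_tb():
    """With a flat link, bin-level mortality differs only by sampling noise
    and the (weak) confounder-TB dependence built into complications."""
    cfg = tc.SimulationConfig.cirrhosis_like(
        n=20_000,
        seed=7,
        link=tc.TBLink("flat", {"level": 0.0}),
        beta={},  # remove confounder effects to isolate the link
        missingness={},
    )
    df = tc.generate_cohort(cfg)
    bins = np.asarray(tb_bin_index(df["tb"].to_numpy()))
    rates = [df["death_90"][bins == b].mean() for b in range(7)]
    p = df["death_90"].mean()
    se = np.sqrt(p * (1 - p) / min(np.bincount(bins)))
    assert max(rates) - min(rates) < 6 * se


def test_cirrhosis_calibration_overall_mortality():
    """Default cirrhosis-like config lands near 16.6% 90-day mortality."""
    df = tc.generate_cohort(tc.SimulationConfig.cirrhosis_like(seed=5))
    assert df["death_90"].mean() == pytest.approx(0.166, abs=0.02)


def test_config_validation_names_field():
    with pytest.raises(ConfigurationError, match="baseline_hazard"):
        tc.SimulationConfig.cirrhosis_like(baseline_hazard=-1.0).validate()
    with pytest.raises(ConfigurationError, match="scale"):
        tc.TBLink("sigmoid", {"amplitude": 1, "center": 10, "scale": 0}).validate()
    with pytest.raises(ConfigurationError, match="threshold"):
        tc.TBLink("hinge", {"threshold": 60, "slope": 0.1}).validate()
    with pytest.raises(ConfigurationError):
        tc.SimulationConfig.cirrhosis_like(n=0).validate()


def test_true_curve_flat_and_hinge_shapes():
    flat = tc.SimulationConfig.cirrhosis_like(seed=3, link=tc.TBLink("flat", {"level": 0.5}))
    c = tc.true_curve(flat, grid=np.linspace(0, 50, 26), n_mc=20_000)
    assert np.ptp(c.adjusted_mortality) < 1e-12  # exactly constant in TB

    hinge = tc.SimulationConfig.fibrosis_like(seed=3)
    g = np.linspace(0, 12, 13)
    ch = tc.true_curve(hinge, grid=g, n_mc=20_000)
    assert np.ptp(ch.adjusted_mortality) < 1e-12  # flat below the threshold


def test_true_curve_sigmoid_monotone():
    cfg = tc.SimulationConfig.cirrhosis_like(seed=3)
    c = tc.true_curve(cfg, n_mc=50_000)
    assert np.all(np.diff(c.adjusted_mortality) >= -1e-12)
    assert c.adjusted_mortality.min() >= 0 and c.adjusted_mortality.max() <= 1


def test_true_curve_validates_inputs():
    cfg = tc.SimulationConfig.cirrhosis_like(seed=1)
    with pytest.raises(ConfigurationError):
        tc.true_curve(cfg, horizon=0)
    with pytest.raises(ConfigurationError):
        tc.true_curve(cfg, grid=[-1, 10])


def test_empirical_bins_match_closed_form_oracle():
    """Empirical bin mortality at n=50,000 tracks each patient's closed-form
    death probability within Monte-Carlo error in every TB bin.

    The oracle conditions on each patient's own covariates (complication
    rates depend on the TB bin, so the bin-level observed mortality is the
    bin-conditional expectation, not the marginal true_curve value)."""
    from threshcurve.simulate import _covariate_log_hazard

    cfg = tc.SimulationConfig.cirrhosis_like(n=50_000, seed=11, missingness={}, lt_rate=0.0)
    df = tc.generate_cohort(cfg)
    bins = np.asarray(tb_bin_index(df["tb"].to_numpy()))
    eta = _covariate_log_hazard(cfg, df) + cfg.link(df["tb"].to_numpy())
    p_death = 1.0 - np.exp(
        -cfg.baseline_hazard * np.exp(eta) * 90.0**cfg.weibull_shape
    )
    for b in range(7):
        m = bins == b
        n_b = int(m.sum())
        emp = df["death_90"][m].mean()
        exp = p_death[m].mean()
        se = np.sqrt(np.mean(p_death[m] * (1 - p_death[m]))) / np.sqrt(n_b)
        assert abs(emp - exp) < 3.5 * se, f"bin {b}: {emp:.4f} vs {exp:.4f}"


def test_calibrate_baseline_hazard_solves_target():
    from dataclasses import replace

    cfg = tc.SimulationConfig.cirrhosis_like(n=20_000, seed=2)
    lam = tc.calibrate_baseline_hazard(cfg, 0.10, n_mc=50_000)
    df = tc.generate_cohort(replace(cfg, baseline_hazard=lam))
    assert df["death_90"].mean() == pytest.approx(0.10, abs=0.01)
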