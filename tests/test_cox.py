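"""Cox model: closed-form and brute-force oracles, recovery, trend test."""

import numpy as np
import pandas as pd
import pytest

import threshcurve as tc
from threshcurve.errors import NoEventsError

from conftest import make_toy_cohort


def efron_neg_log_partial_likelihood(beta, durations, events, x):
    """Independent single-covariate Efron partial likelihood (brute force)."""
    nll = 0.0
    risk = np.exp(beta * x)
    for t in np.unique(durations[events == 1]):
        at_risk = durations >= t
        dead = (durations == t) & (events == 1)
        d = int(dead.sum())
        sum_risk = risk[at_risk].sum()
        sum_dead = risk[dead].sum()
        nll -= beta * x[dead].sum()
        for j in range(d):
            nll += np.log(sum_risk - j / d * sum_dead)
    return nll


def test_coefficient_matches_brute_force_grid_search():
    """On a tiny tied dataset the fitted coefficient equals the brute-force
    partial-likelihood argmin to 1e-3."""
    durations = np.array([3, 3, 5, 7, 7, 7, 9, 12], dtype=float)
    events = np.array([1, 1, 1, 0, 1, 1, 0, 1])
    x = np.array([1, 0, 1, 1, 0, 1, 0, 0], dtype=float)
    grid = np.arange(-3, 3, 1e-4)
    nll = [efron_neg_log_partial_likelihood(b, durations, events, x) for b in grid]
    beta_star = grid[int(np.argmin(nll))]

    toy = make_toy_cohort(
        tb=x, death_90=events, time_to_death=durations
    )
    res = tc.TBCoxModel(toy, exposure_mode="continuous", adjusted=False).fit()
    assert res.coefs["tb"] == pytest.approx(beta_star, abs=1e-3)


def test_two_group_proportional_hazards_oracle():
    """Group with exactly double the hazard: HR estimate ~2 within its CI."""
    rng = np.random.default_rng(5)
    n = 5000
    grp = rng.integers(0, 2, n).astype(float)
    t = np.ceil(rng.exponential(1.0 / (0.01 * np.exp(np.log(2.0) * grp))))
    toy = make_toy_cohort(
        tb=grp, death_90=(t <= 90).astype(int), time_to_death=t
    )
    res = tc.TBCoxModel(toy, exposure_mode="continuous", adjusted=False).fit()
    assert res.ci_lower["tb"] < 2.0 < res.ci_upper["tb"]
    assert res.hazard_ratios["tb"] == pytest.approx(2.0, rel=0.08)


def test_all_censored_raises_no_events():
    toy = make_toy_cohort(tb=[1.0, 2.0, 3.0], death_90=[0, 0, 0])
    with pytest.raises(NoEventsError):
        tc.TBCoxModel(toy, exposure_mode="continuous", adjusted=False)


def test_continuous_recovery_on_linear_link():
    """Cohort simulated with true log-HR 0.06/mg/dL: adjusted estimate lands
    in [1.04, 1.08]."""
    cfg = tc.SimulationConfig.cirrhosis_like(
        seed=11, link=tc.TBLink("linear", {"slope": 0.06})
    )
    analysis, _ = tc.apply_exclusions(tc.generate_cohort(cfg))
    res = tc.TBCoxModel(analysis, exposure_mode="continuous", adjusted=True).fit()
    assert 1.04 <= res.hazard_ratios["tb"] <= 1.08


def test_hr_equals_exp_coef_and_ci_order(cirrhosis_analysis):
    res = tc.TBCoxModel(cirrhosis_analysis, exposure_mode="categorical").fit()
    for term in res.terms:
        assert res.hazard_ratios[term] == pytest.approx(np.exp(res.coefs[term]), rel=1e-9)
        assert res.ci_lower[term] <= res.hazard_ratios[term] <= res.ci_upper[term]
    assert res.n_events <= res.n_used
    assert res.reference_bin == "0-2"
    tab = res.summary(exposure_only=True)
    assert list(tab["term"]) == [f"tb_bin[{b}]" for b in ("2-5", "5-8", "8-12", "12-16", "16-20", ">20")]


def test_trend_detects_monotone_effect(cirrhosis_analysis):
    p = tc.trend_test(cirrhosis_analysis)
    assert p < 0.05


def test_trend_requires_bin_variation():
    toy = make_toy_cohort(tb=np.full(60, 1.0), death_90=np.tile([1, 0, 0], 20))
    with pytest.raises(ValueError, match="two occupied TB bins"):
        tc.TBCoxModel(toy, exposure_mode="categorical", adjusted=False).trend_test()


def test_trend_type_I_error_under_flat_link():
    """Adjusted trend test keeps ~5% false-positive rate on null cohorts."""
    reps, alpha_hits = 120, 0
    for seed in range(300, 300 + reps):
        cfg = tc.SimulationConfig.cirrhosis_like(
            n=2000, seed=seed, link=tc.TBLink("flat", {"level": 0.0})
        )
        analysis, _ = tc.apply_exclusions(tc.generate_cohort(cfg))
        alpha_hits += tc.trend_test(analysis) < 0.05
    rate = alpha_hits / reps
    assert 0.005 <= rate <= 0.11  # ~2.6 binomial SE around 0.05


def test_time_shift_beyond_horizon_is_invariant(cirrhosis_analysis):
    res1 = tc.TBCoxModel(cirrhosis_analysis, exposure_mode="continuous").fit()
    shifted = cirrhosis_analysis.copy()
    beyond = shifted["time_to_death"] > 90
    shifted.loc[beyond, "time_to_death"] += 1000.0
    res2 = tc.TBCoxModel(shifted, exposure_mode="continuous").fit()
    assert res1.coefs["tb"] == pytest.approx(res2.coefs["tb"], abs=1e-12)


def test_empty_bin_dropped_with_warning():
    rng = np.random.default_rng(0)
    tb = np.r_[rng.uniform(0, 2, 150), rng.uniform(2, 5, 150)]  # only two bins
    deaths = (rng.uniform(size=300) < 0.2).astype(int)
    toy = make_toy_cohort(tb=tb, death_90=deaths)
    with pytest.warns(UserWarning, match="empty"):
        res = tc.TBCoxModel(toy, exposure_mode="categorical", adjusted=False).fit()
    assert res.exposure_terms() == ["tb_bin[2-5]"]
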