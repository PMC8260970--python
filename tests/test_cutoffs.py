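"""Acceleration analysis: differentiation oracles and cutoff detection."""

import numpy as np
import pytest

import threshcurve as tc
from threshcurve.cutoffs import EDGE_TRIM, _curve_spline
from threshcurve.riskcurve import RiskCurve, default_grid

from conftest import make_toy_cohort

GRID = default_grid()


def logistic_curve(center=15.0, scale=3.0, top=0.6):
    return RiskCurve(
        horizon=90,
        grid=GRID,
        adjusted_mortality=top / (1.0 + np.exp(-(GRID - center) / scale)),
    )


def logistic_second_derivative(x, center=15.0, scale=3.0, top=0.6):
    s = 1.0 / (1.0 + np.exp(-(x - center) / scale))
    return top * s * (1 - s) * (1 - 2 * s) / scale**2


class TestSecondDerivative:
    def test_linear_curve_zero_acceleration(self):
        c = RiskCurve(horizon=90, grid=GRID, adjusted_mortality=0.01 + 0.005 * GRID)
        acc = tc.second_derivative(c)
        assert np.max(np.abs(acc.acceleration)) < 1e-6

    def test_quadratic_curve_constant_acceleration(self):
        c = RiskCurve(horizon=90, grid=GRID, adjusted_mortality=1e-4 * GRID**2)
        acc = tc.second_derivative(c)
        assert acc.acceleration == pytest.approx(np.full_like(acc.grid, 2e-4), abs=1e-6)

    def test_logistic_closed_form_oracle(self):
        acc = tc.second_derivative(logistic_curve())
        expected = logistic_second_derivative(acc.grid)
        assert np.max(np.abs(acc.acceleration - expected)) < 1e-4

    def test_boundary_trim(self):
        acc = tc.second_derivative(logistic_curve())
        span = GRID[-1] - GRID[0]
        assert acc.grid[0] >= GRID[0] + EDGE_TRIM * span
        assert acc.grid[-1] <= GRID[-1] - EDGE_TRIM * span

    def test_too_few_points_rejected(self):
        c = RiskCurve(horizon=90, grid=np.linspace(0, 50, 5), adjusted_mortality=np.full(5, 0.1))
        with pytest.raises(ValueError):
            tc.second_derivative(c)

    def test_internal_fd_crosscheck_on_fitted_curves(self, curve90, curve28):
        # second_derivative raises NumericalError if the analytic spline
        # derivative disagrees with dense central differences beyond 1e-4
        for curve in (curve90, curve28):
            acc = tc.second_derivative(curve)
            assert np.all(np.isfinite(acc.acceleration))


class TestInflections:
    def test_logistic_peak_and_valley_closed_form(self):
        acc = tc.second_derivative(logistic_curve())
        peak, valley = tc.find_inflections(acc)
        # analytic argmax of the logistic acceleration: 15 - 3*ln((3+sqrt3)/(3-sqrt3))
        assert peak == pytest.approx(11.049, abs=0.11)
        assert valley == pytest.approx(18.951, abs=0.11)

    def test_linear_curve_has_no_inflections(self):
        c = RiskCurve(horizon=90, grid=GRID, adjusted_mortality=0.01 + 0.005 * GRID)
        peak, valley = tc.find_inflections(tc.second_derivative(c))
        assert peak is None and valley is None

    def test_valley_is_above_peak(self, curve90):
        peak, valley = tc.find_inflections(tc.second_derivative(curve90))
        assert peak is not None
        if valley is not None:
            assert valley > peak


class TestClinicalCutoff:
    def test_logistic_analytic_inversion(self):
        cut = tc.clinical_cutoff(logistic_curve(), level=0.15)
        assert cut == pytest.approx(15 - 3 * np.log(3), abs=5e-3)

    def test_constant_curve_never_reaches_level(self):
        c = RiskCurve(horizon=28, grid=GRID, adjusted_mortality=np.full_like(GRID, 0.05))
        assert tc.clinical_cutoff(c, level=0.15) is None

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError):
            tc.clinical_cutoff(logistic_curve(), level=1.5)

    def test_curve_value_at_returned_cutoff_equals_level(self, curve28):
        cut = tc.clinical_cutoff(curve28, level=0.15)
        assert cut is not None
        val = float(_curve_spline(curve28)(cut))
        assert val == pytest.approx(0.15, abs=1e-6)


class TestSummarize:
    def test_toy_exceedance_hand_count(self):
        cohort = make_toy_cohort(tb=np.arange(1.0, 11.0), death_90=np.zeros(10, dtype=int))
        rep = tc.summarize_cutoffs(cohort, None, None, {"mathematical": 5.0}, group="toy")
        (entry,) = rep.entries
        assert entry.exceed_fraction == 0.5
        assert entry.n_exceed == 5
        assert entry.mortality28_at is None

    def test_cutoff_above_grid_yields_absent_values(self, curve90):
        cohort = make_toy_cohort(tb=np.arange(1.0, 11.0), death_90=np.zeros(10, dtype=int))
        rep = tc.summarize_cutoffs(cohort, None, curve90, {"clinical": 60.0})
        (entry,) = rep.entries
        assert entry.exceed_fraction == 0.0
        assert entry.mortality90_at is None

    def test_absent_cutoffs_skipped(self):
        cohort = make_toy_cohort(tb=np.arange(1.0, 5.0), death_90=np.zeros(4, dtype=int))
        rep = tc.summarize_cutoffs(cohort, None, None, {"mathematical": None, "valley": None})
        assert rep.entries == []
        assert rep.mathematical_cutoff is None

    def test_exceedance_matches_mixture_tail(self, cirrhosis_analysis, curve28, curve90):
        """Recovered-cutoff exceedance tracks the generator's TB tail mass."""
        peak, _ = tc.find_inflections(tc.second_derivative(curve90))
        rep = tc.summarize_cutoffs(
            cirrhosis_analysis, curve28, curve90, {"mathematical": peak}, group="cirrhosis"
        )
        (entry,) = rep.entries
        tb = cirrhosis_analysis["tb"].dropna()
        assert entry.exceed_fraction == pytest.approx((tb > peak).mean(), abs=1e-12)
        frame = rep.to_frame()
        assert frame.loc[0, "tb_mg_dl"] == peak
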