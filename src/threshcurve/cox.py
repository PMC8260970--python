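"""Multivariable Cox proportional-hazards analysis of TB and 90-day
transplantation-free mortality.

``TBCoxModel`` is built from a (filtered, scored) cohort table and fits a
partial-likelihood Cox model with Efron tie handling — event times are
day-resolution, so ties are heavy.  TB enters either as a continuous
exposure (hazard ratio per mg/dL) or as the seven-bin categorical exposure
with the lowest bin (TB <= 2 mg/dL) as reference.  The adjusted model uses
the standard confounder set (see ``_design``); GI bleeding is dropped from
the advanced-fibrosis adjustment set.  The categorical trend test refits the
adjusted model with the ordinal bin index (1..7) as a single continuous
covariate and reports its Wald p-value.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

from ._design import complete_cases, confounder_design, drop_invariant
from .errors import NoEventsError
from .scores import TB_BIN_LABELS, tb_bin_index

__all__ = ["TBCoxModel", "CoxResults", "trend_test"]

HORIZON = 90.0


class TBCoxModel:
    """Cox model of 90-day transplantation-free mortality on TB.

    Parameters
    ----------
    cohort : patient-level table (post-filter); needs ``time_to_death`` and
        ``death_90`` plus the exposure and (if adjusted) the confounders.
    exposure_mode : "continuous" or "categorical".
    adjusted : include the confounder set; unadjusted fits TB alone.
    include_gib : keep gastrointestinal bleeding among the confounders.
    """

    def __init__(
        self,
        cohort: pd.DataFrame,
        exposure_mode: str = "continuous",
        adjusted: bool = True,
        include_gib: bool = True,
    ):
        if exposure_mode not in ("continuous", "categorical"):
            raise ValueError(f"unknown exposure_mode {exposure_mode!r}")
        self.exposure_mode = exposure_mode
        self.adjusted = adjusted
        self.include_gib = include_gib
        self.reference_bin = TB_BIN_LABELS[0]

        extra = ["tb", "time_to_death", "death_90"]
        data = (
            complete_cases(cohort, extra, include_gib)
            if adjusted
            else cohort.dropna(subset=extra)
        )
        self.data = data
        self.n_used = len(data)
        self.n_events = int(data["death_90"].sum())
        if self.n_events < 2:
            raise NoEventsError(
                f"need >= 2 death events, found {self.n_events}"
            )

    # -- design -----------------------------------------------------------

    def _exposure_design(self) -> tuple[pd.DataFrame, list[str]]:
        data = self.data
        if self.exposure_mode == "continuous":
            return pd.DataFrame({"tb": data["tb"].astype(float)}, index=data.index), ["tb"]
        idx = np.asarray(tb_bin_index(data["tb"].to_numpy(dtype=float)))
        X = pd.DataFrame(index=data.index)
        kept = []
        for b, label in enumerate(TB_BIN_LABELS):
            if b == 0:
                continue  # reference
            col = (idx == b).astype(float)
            name = f"tb_bin[{label}]"
            if col.sum() == 0:
                warnings.warn(f"TB bin {label} is empty and was dropped from the fit")
                continue
            X[name] = col
            kept.append(name)
        return X, kept

    def _full_design(self) -> pd.DataFrame:
        X, _ = self._exposure_design()
        if self.adjusted:
            X = pd.concat(
                [X, drop_invariant(confounder_design(self.data, self.include_gib))],
                axis=1,
            )
        X["duration"] = np.minimum(
            self.data["time_to_death"].astype(float), HORIZON
        )
        X["event"] = self.data["death_90"].astype(int)
        n_terms = X.shape[1] - 2
        if self.n_used < 10 * n_terms:
            warnings.warn(
                f"only {self.n_used} complete cases for {n_terms} terms "
                "(< 10 per term); estimates may be unstable"
            )
        return X

    # -- fitting ----------------------------------------------------------

    #: fallback L2 penalizer when the unpenalized Newton step hits a
    #: singular Hessian (monotone likelihood in a rare dummy)
    RIDGE_FALLBACK = 1e-3

    @classmethod
    def _fit_lifelines(cls, X: pd.DataFrame) -> CoxPHFitter:
        from lifelines.exceptions import ConvergenceError

        try:
            cph = CoxPHFitter()
            cph.fit(X, duration_col="duration", event_col="event")
            return cph
        except ConvergenceError:
            warnings.warn(
                "unpenalized Cox fit hit a singular Hessian; "
                f"refitting with ridge penalizer {cls.RIDGE_FALLBACK}"
            )
            cph = CoxPHFitter(penalizer=cls.RIDGE_FALLBACK, l1_ratio=0.0)
            cph.fit(X, duration_col="duration", event_col="event")
            return cph

    def fit(self) -> "CoxResults":
        X = self._full_design()
        return CoxResults(self, self._fit_lifelines(X))

    def trend_test(self) -> float:
        """Wald p-value of the ordinal TB-bin index in the adjusted model."""
        data = self.data
        ordinal = np.asarray(tb_bin_index(data["tb"].to_numpy(dtype=float))) + 1.0
        if len(np.unique(ordinal)) < 2:
            raise ValueError("trend test needs at least two occupied TB bins")
        X = pd.DataFrame({"tb_ordinal": ordinal}, index=data.index)
        if self.adjusted:
            X = pd.concat(
                [X, drop_invariant(confounder_design(data, self.include_gib))], axis=1
            )
        X["duration"] = np.minimum(data["time_to_death"].astype(float), HORIZON)
        X["event"] = data["death_90"].astype(int)
        cph = self._fit_lifelines(X)
        return float(cph.summary.loc["tb_ordinal", "p"])


class CoxResults:
    """Coefficients, hazard ratios, CIs and p-values of a fitted Cox model."""

    def __init__(self, model: TBCoxModel, fitter: CoxPHFitter):
        self.model = model
        self._fitter = fitter
        s = fitter.summary
        self.terms = list(s.index)
        self.coefs = s["coef"].to_dict()
        self.hazard_ratios = s["exp(coef)"].to_dict()
        self.ci_lower = s["exp(coef) lower 95%"].to_dict()
        self.ci_upper = s["exp(coef) upper 95%"].to_dict()
        self.p_values = s["p"].to_dict()
        self.n_used = model.n_used
        self.n_events = model.n_events
        self.exposure_mode = model.exposure_mode
        self.reference_bin = (
            model.reference_bin if model.exposure_mode == "categorical" else None
        )
        self._trend_p: float | None = None

    @property
    def log_likelihood(self) -> float:
        return float(self._fitter.log_likelihood_)

    @property
    def trend_p(self) -> float | None:
        """Trend-test p-value (computed lazily, categorical mode only)."""
        if self.exposure_mode != "categorical":
            return None
        if self._trend_p is None:
            self._trend_p = self.model.trend_test()
        return self._trend_p

    def exposure_terms(self) -> list[str]:
        return [t for t in self.terms if t == "tb" or t.startswith("tb_bin[")]

    def summary(self, exposure_only: bool = False) -> pd.DataFrame:
        """Tidy table: term, coefficient, HR, 95% CI, p-value."""
        terms = self.exposure_terms() if exposure_only else self.terms
        return pd.DataFrame(
            {
                "term": terms,
                "coef": [self.coefs[t] for t in terms],
                "hazard_ratio": [self.hazard_ratios[t] for t in terms],
                "ci_lower": [self.ci_lower[t] for t in terms],
                "ci_upper": [self.ci_upper[t] for t in terms],
                "p": [self.p_values[t] for t in terms],
            }
        )


def trend_test(cohort: pd.DataFrame, include_gib: bool = True) -> float:
    """Convenience wrapper: adjusted ordinal-bin trend test on a cohort."""
    return TBCoxModel(
        cohort, exposure_mode="categorical", adjusted=True, include_gib=include_gib
    ).trend_test()
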