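"""Delayed-entry Kaplan–Meier estimation and the cumulative-hazard offset.

With age as the timescale, cohort members enter observation in middle age
already disease-free, so the product-limit convention S = 1 at the first
event age is wrong: the cohort has already accrued cumulative hazard

    H(t) = H1 + Hhat(t),   H1 = integral of h over [0, t1),

where t1 is the first observed event age and Hhat is what the Kaplan–Meier
estimator actually measures.  Given a fitted parametric model for H, the
offset is estimated by averaging over the n observed event ages,

    H1 ~= (1/n) * sum_i (H(t_i) - Hhat(t_i)),

which introduces no additional free parameters, and the corrected survival
curve is S(t) = exp(-H1) * Shat(t).  Without this correction, age-timescale
incidence curves look far flatter than they are and multistage (log-log
linear) behaviour is hidden.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "KaplanMeierCurve",
    "AdjustedKMCurve",
    "kaplan_meier_delayed_entry",
    "estimate_H1",
    "adjust_km",
]


@dataclass(frozen=True)
class KaplanMeierCurve:
    """Product-limit estimator on distinct event ages, with Greenwood variance."""

    times: np.ndarray        # distinct event ages, increasing
    n_risk: np.ndarray       # risk-set size just before each event age
    n_events: np.ndarray     # events at each age
    survival: np.ndarray     # right-continuous step value at each age
    variance: np.ndarray     # Greenwood variance of survival at each age

    @property
    def cumulative_hazard(self) -> np.ndarray:
        return -np.log(self.survival)

    def survival_at(self, t) -> np.ndarray:
        """Step-function value at arbitrary ages (1 before the first event)."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right") - 1
        s = np.where(idx >= 0, self.survival[np.clip(idx, 0, None)], 1.0)
        return s

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age": self.times,
                "n_risk": self.n_risk,
                "n_events": self.n_events,
                "S_hat": self.survival,
                "var": self.variance,
            }
        )


@dataclass(frozen=True)
class AdjustedKMCurve:
    """KM curve multiplied by exp(-H1); variances scaled by exp(-2*H1)."""

    base: KaplanMeierCurve
    H1: float

    @property
    def times(self) -> np.ndarray:
        return self.base.times

    @property
    def survival(self) -> np.ndarray:
        return np.exp(-self.H1) * self.base.survival

    @property
    def variance(self) -> np.ndarray:
        return np.exp(-2.0 * self.H1) * self.base.variance

    @property
    def cumulative_hazard(self) -> np.ndarray:
        return self.H1 + self.base.cumulative_hazard

    def to_frame(self) -> pd.DataFrame:
        df = self.base.to_frame()
        df["S_adj"] = self.survival
        df["var_adj"] = self.variance
        df["H1"] = self.H1
        return df


def kaplan_meier_delayed_entry(
    entry_age, exit_age, status
) -> KaplanMeierCurve:
    """Kaplan–Meier estimator with risk sets honouring delayed entry.

    A subject is at risk at age t if entry < t <= exit; events at t are
    subjects with exit == t and status == 1.
    """
    entry = np.asarray(entry_age, dtype=float)
    exit_ = np.asarray(exit_age, dtype=float)
    delta = np.asarray(status).astype(int)
    if np.any(exit_ < entry):
        raise ValueError("exit_age < entry_age")
    ev = exit_[delta == 1]
    if ev.size == 0:
        raise ValueError("no events: Kaplan-Meier estimator undefined")

    times, d = np.unique(ev, return_counts=True)
    entry_sorted = np.sort(entry)
    exit_sorted = np.sort(exit_)
    # at risk just before t: entered strictly before t and not yet exited
    n_in = np.searchsorted(entry_sorted, times, side="left")
    n_out = np.searchsorted(exit_sorted, times, side="left")
    n_risk = n_in - n_out
    if np.any(n_risk < d):
        raise ValueError("empty or deficient risk set at an event age")

    frac = 1.0 - d / n_risk
    surv = np.cumprod(frac)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n_risk > d, d / (n_risk * (n_risk - d)), np.inf)
        var = surv**2 * np.cumsum(terms)
    var = np.where(np.isfinite(var), var, 0.0)  # variance undefined once S hits 0
    return KaplanMeierCurve(times, n_risk, d, surv, var)


def estimate_H1(model, km: KaplanMeierCurve, x=None, eta: float | None = None) -> float:
    """Offset H1 = mean over event observations of H_model(t_i) - Hhat(t_i).

    ``model`` is any object with a ``cumulative_hazard(t, ...)`` method
    (a fitted WeibullPH or NSM).  The average runs over the observed events
    (tied event ages weighted by their multiplicity); censored rows do not
    enter the sum.
    """
    if km.times.size == 0:
        raise ValueError("no event ages")
    kwargs = {}
    if eta is not None:
        kwargs["eta"] = eta
    elif x is not None:
        kwargs["x"] = x
    H_model = np.asarray(model.cumulative_hazard(km.times, **kwargs), dtype=float)
    with np.errstate(divide="ignore"):
        H_km = km.cumulative_hazard
    w = km.n_events.astype(float)
    # Hhat is undefined where the product-limit estimate hits 0 (risk set
    # exhausted at the last event age); such points cannot enter the average
    ok = np.isfinite(H_km)
    if not ok.any():
        raise ValueError("no event age with a defined cumulative hazard")
    return float(np.sum(w[ok] * (H_model[ok] - H_km[ok])) / np.sum(w[ok]))


def adjust_km(km: KaplanMeierCurve, H1: float) -> AdjustedKMCurve:
    """Apply the offset: S(t) = exp(-H1) * Shat(t), Var scaled by exp(-2 H1)."""
    if not np.isfinite(H1):
        raise ValueError("H1 must be finite")
    return AdjustedKMCurve(base=km, H1=float(H1))
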