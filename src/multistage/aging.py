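"""Relative aging rates, effective ages, and group comparisons.

In the proportional-hazards Weibull model the cumulative hazard can be
written H(t) = (t * exp(eta/m) / L)^m, so a risk profile with linear
predictor eta multiplies age by the **relative aging rate** exp(eta/m):
a person aged t carries the baseline risk of a person aged t * exp(eta/m).
Because the exponent divides by m, risk factors move the effective age of
low-m (sporadic) diseases much more than of high-m (late-onset) ones, even
at equal relative risk exp(eta).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .assess import fdr_adjust

__all__ = [
    "relative_aging_rate",
    "relative_risk",
    "effective_age",
    "equivalent_screening_age",
    "expected_first_disease_age",
    "compare_groups",
    "aging_rate_table",
    "DegenerateVarianceError",
]

log = logging.getLogger(__name__)


class DegenerateVarianceError(ValueError):
    """Both groups have zero variance but different means: t-test undefined."""


def relative_risk(eta: float) -> float:
    """Hazard ratio exp(eta) relative to baseline."""
    return float(np.exp(eta))


def relative_aging_rate(eta: float, m: float) -> float:
    """exp(eta / m): the factor multiplying age to give effective age.

    Equals 1 at baseline; the influence of risk factors on the aging rate is
    suppressed by 1/m, so high-m diseases have rates near 1.
    """
    if m <= 0:
        raise ValueError("m must be > 0")
    return float(np.exp(eta / m))


def effective_age(t: float, rar: float) -> float:
    """Effective age t * exp(eta/m) given a relative aging rate."""
    if t < 0:
        raise ValueError("age must be >= 0")
    if rar <= 0:
        raise ValueError("relative aging rate must be > 0")
    return t * rar


def equivalent_screening_age(
    reference_age: float, rar_reference: float, rar_target: float
) -> float:
    """Age at which the target group matches the reference group's risk.

    Cumulative hazards equal when t_target * rar_target equals
    t_ref * rar_ref, so t_target = reference_age * rar_reference / rar_target.
    """
    if rar_reference <= 0 or rar_target <= 0:
        raise ValueError("aging rates must be > 0")
    return reference_age * rar_reference / rar_target


def expected_first_disease_age(
    baseline_age: float, baseline_disease_free_years: float, rar: float
) -> tuple[int, int]:
    """Expected age at first disease and disease-free years under a rate.

    A person who at ``baseline_age`` would, at baseline risk, expect
    ``baseline_disease_free_years`` more disease-free years, instead reaches
    effective-age parity at (baseline_age + Y) / rar.  Values are reported
    rounded to whole years.
    """
    if baseline_disease_free_years <= 0:
        raise ValueError("baseline disease-free years must be > 0")
    if rar <= 0:
        raise ValueError("relative aging rate must be > 0")
    age = (baseline_age + baseline_disease_free_years) / rar
    dfy = age - baseline_age
    if dfy < 0:
        log.warning("negative disease-free years (%.1f): extreme aging rate", dfy)
    return int(round(age)), int(round(dfy))


def aging_rate_table(results) -> pd.DataFrame:
    """Long-format RR / RAR table, one row per non-baseline covariate level."""
    rows = []
    for name, b in results.beta.items():
        rows.append(
            {
                "level": name,
                "beta": float(b),
                "relative_risk": relative_risk(b),
                "relative_aging_rate": relative_aging_rate(b, results.m),
            }
        )
    return pd.DataFrame(rows)


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = a.mean() - b.mean()
    if va == 0 and vb == 0:
        if diff == 0:
            return 0.0, 0.0, 1.0
        raise DegenerateVarianceError(
            "zero within-group variance with unequal means"
        )
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(diff), float(t), float(p)


def compare_groups(sporadic: pd.DataFrame, late_onset: pd.DataFrame) -> pd.DataFrame:
    """Per-covariate-level Welch t-tests of sporadic vs late-onset diseases.

    Inputs are long-format tables with columns ``level`` and value columns
    ``relative_aging_rate`` and ``relative_risk`` (one row per disease x
    level).  Returns one row per (level, measure) with the mean difference
    (sporadic minus late-onset), Welch t, p, and BH q across rows.
    """
    rows = []
    for measure in ("relative_aging_rate", "relative_risk"):
        for level in sorted(set(sporadic["level"]) & set(late_onset["level"])):
            a = sporadic.loc[sporadic["level"] == level, measure].to_numpy(dtype=float)
            b = late_onset.loc[late_onset["level"] == level, measure].to_numpy(dtype=float)
            if a.size < 2 or b.size < 2:
                raise ValueError(f"need >= 2 diseases per group for level {level!r}")
            diff, t, p = _welch(a, b)
            rows.append(
                {
                    "measure": measure,
                    "level": level,
                    "mean_sporadic": a.mean(),
                    "mean_late_onset": b.mean(),
                    "mean_difference": diff,
                    "t": t,
                    "p": p,
                }
            )
    out = pd.DataFrame(rows)
    out["q"] = fdr_adjust(out["p"].to_numpy())
    return out
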