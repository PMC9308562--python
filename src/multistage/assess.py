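"""Goodness-of-fit screening and inclusion rules.

A fitted parametric curve is screened against the offset-adjusted
Kaplan–Meier estimate with a chi-square statistic over the event-age grid,

    X2 = sum_j (S_model(t_j) - S_adj(t_j))^2 / Var_adj(t_j),

using only the Kaplan–Meier variance (not the fit's), which makes the screen
deliberately strict.  Degrees of freedom equal the number of evaluation
points, uncorrected for estimated parameters — conservative by design;
subtract the parameter count from ``df`` if a classical correction is
preferred.  Diseases are excluded from downstream analysis when the
Benjamini–Hochberg-adjusted GOF q-value falls below the FDR level, or when
the estimated effective number of steps is below 0.8 (incidence nearly flat
in age, outside the multistage regime of interest).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .km import AdjustedKMCurve

__all__ = ["GofResult", "chisq_gof", "fdr_adjust", "inclusion_filter"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GofResult:
    statistic: float
    df: int
    pvalue: float
    qvalue: float | None = None
    included: bool | None = None
    reason: str = "none"

    def __post_init__(self) -> None:
        if self.statistic < 0:
            raise ValueError("chi-square statistic must be >= 0")


def chisq_gof(model, adjusted: AdjustedKMCurve, x=None, eta: float | None = None) -> GofResult:
    """Chi-square comparison of a parametric survival curve with the adjusted KM.

    Evaluation points are the distinct event ages with positive Kaplan–Meier
    variance (zero-variance points are skipped and logged); p-value from the
    chi-square law with df = number of points used.
    """
    t = adjusted.times
    var = adjusted.variance
    ok = var > 0
    n_skipped = int((~ok).sum())
    if n_skipped:
        log.info("chisq_gof: %d zero-variance points skipped", n_skipped)
    if ok.sum() < 2:
        raise ValueError("need >= 2 event-age points with positive KM variance")
    kwargs = {}
    if eta is not None:
        kwargs["eta"] = eta
    elif x is not None:
        kwargs["x"] = x
    S_model = np.asarray(model.survival(t[ok], **kwargs), dtype=float)
    resid = S_model - adjusted.survival[ok]
    statistic = float(np.sum(resid**2 / var[ok]))
    df = int(ok.sum())
    pvalue = float(stats.chi2.sf(statistic, df))
    return GofResult(statistic=statistic, df=df, pvalue=pvalue)


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values across diseases."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def inclusion_filter(
    m_hat: float,
    gof: GofResult,
    m_threshold: float = 0.8,
    fdr_level: float = 0.05,
) -> GofResult:
    """Apply the inclusion rules; returns the GofResult with flag and reason.

    Excluded iff the FDR-adjusted GOF q-value signals misfit (q < level) or
    the estimated effective number of steps falls below the threshold.
    ``gof.qvalue`` must already be set (ensemble-level BH adjustment).
    """
    if gof.qvalue is None:
        raise ValueError("qvalue not set; run fdr_adjust across diseases first")
    if m_hat < m_threshold:
        return replace(gof, included=False, reason="m_below_threshold")
    if gof.qvalue < fdr_level:
        return replace(gof, included=False, reason="gof")
    return replace(gof, included=True, reason="none")
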