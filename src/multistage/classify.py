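"""Sporadic vs late-onset classification by extrapolated risk.

A fitted parametric model can be extrapolated to compare disease risk at
ages 50 and 100: F(50) measures risk accrued while young, and the relative
increase (F(100) - F(50)) / F(50) measures how steeply risk grows with age.
The product F(50) * F(50)/F(100) — large when early risk is appreciable and
grows slowly — scores how "sporadic" a disease is; its ensemble tertiles
give the sporadic / mid-range / late-onset labels.  Extrapolation is at the
baseline covariate profile (eta = 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RiskProfile",
    "risk_profile",
    "sporadic_score",
    "classify_tertiles",
    "chapter_composition",
    "TERTILE_LABELS",
]

log = logging.getLogger(__name__)

TERTILE_LABELS = ("sporadic", "mid-range", "late-onset")


@dataclass(frozen=True)
class RiskProfile:
    F50: float
    F100: float
    relative_increase: float
    flagged: bool = False  # F50 == 0: relative increase undefined


def risk_profile(model, age_young: float = 50.0, age_old: float = 100.0) -> RiskProfile:
    """F at the two reference ages and the relative increase between them."""
    S50 = float(model.survival(age_young))
    S100 = float(model.survival(age_old))
    F50, F100 = 1.0 - S50, 1.0 - S100
    if F50 <= 0.0:
        log.warning("F(%g) = 0: relative increase undefined", age_young)
        return RiskProfile(F50=F50, F100=F100, relative_increase=np.nan, flagged=True)
    return RiskProfile(F50=F50, F100=F100, relative_increase=(F100 - F50) / F50)


def sporadic_score(F50: float, F100: float) -> float:
    """F(50)^2 / F(100); larger for more sporadic diseases, in [0, F50]."""
    if F100 <= 0:
        raise ValueError("F100 must be > 0")
    return F50 * F50 / F100


def classify_tertiles(scores) -> np.ndarray:
    """Tertile labels by sporadic score; boundaries at the 1/3 and 2/3 quantiles.

    The top tertile is "sporadic", the bottom "late-onset"; boundary values go
    to the lower tertile.  A fully degenerate ensemble (all scores equal) is
    labelled mid-range and logged.
    """
    s = np.asarray(scores, dtype=float)
    if s.size < 3:
        raise ValueError("need >= 3 diseases to form tertiles")
    q1, q2 = np.quantile(s, [1.0 / 3.0, 2.0 / 3.0])
    if q1 == q2:
        if np.all(s == s[0]):
            log.info("all sporadic scores equal; labelling all mid-range")
            return np.full(s.size, "mid-range", dtype=object)
    labels = np.where(s > q2, "sporadic", np.where(s > q1, "mid-range", "late-onset"))
    return labels.astype(object)


def chapter_composition(labels, chapters) -> pd.DataFrame:
    """Cross-tabulation of tertile label by ICD-10 chapter (counts)."""
    df = pd.DataFrame({"tertile": list(labels), "chapter": list(chapters)})
    tab = pd.crosstab(df["chapter"], df["tertile"])
    for lab in TERTILE_LABELS:
        if lab not in tab.columns:
            tab[lab] = 0
    return tab[list(TERTILE_LABELS)]


def classification_table(fits: pd.DataFrame) -> pd.DataFrame:
    """Add F50/F100/relative_increase/score/tertile columns to a fit table.

    ``fits`` needs columns disease, chapter, m, L (one row per included
    disease); the Weibull closed form is used for extrapolation.
    """
    from .families import WeibullPH

    rows = []
    for _, r in fits.iterrows():
        rp = risk_profile(WeibullPH(m=r["m"], L=r["L"]))
        rows.append(
            {
                "disease": r["disease"],
                "chapter": r["chapter"],
                "F50": rp.F50,
                "F100": rp.F100,
                "relative_increase": rp.relative_increase,
                "score": sporadic_score(rp.F50, rp.F100) if rp.F100 > 0 else np.nan,
                "flagged": rp.flagged,
            }
        )
    out = pd.DataFrame(rows)
    if len(out) >= 3:
        out["tertile"] = classify_tertiles(out["score"].to_numpy())
    else:
        out["tertile"] = pd.NA
    return out
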