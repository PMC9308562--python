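"""Maximum-likelihood fitting of multistage models to cohort data.

The entry point is :class:`MultistageModel`, built from a survival table
(one row per subject: ``entry_age``, ``exit_age``, ``status`` and optional
categorical covariate columns) in the statsmodels spirit: ``fit()`` returns a
:class:`MultistageResults` carrying point estimates, delta-method standard
errors, the log-likelihood, convergence diagnostics and a ``summary()``
table, with the downstream analyses (offset-adjusted Kaplan–Meier, the
chi-square screen, risk profiles and relative aging rates) hanging off the
results object.

The log-likelihood honours left truncation at entry and right censoring:

    ll = sum_i [ delta_i log f(t_i | x_i) + (1 - delta_i) log S(t_i | x_i)
                 - log S(t0_i | x_i) ] .

Optimization is over (log m, log L, beta) so the positivity constraints are
implicit; standard errors come from the inverse observed information at the
optimum, mapped to the natural scale by the delta method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.tools.numdiff import approx_hess1

from .families import NSM, Covariate, CovariateSchema, WeibullPH
from .km import AdjustedKMCurve, adjust_km, estimate_H1, kaplan_meier_delayed_entry

__all__ = ["MultistageModel", "MultistageResults", "initial_values"]

log = logging.getLogger(__name__)

_REQUIRED = ("entry_age", "exit_age", "status")


def _design_matrix(data: pd.DataFrame, schema: CovariateSchema) -> np.ndarray:
    cols = []
    for cov in schema:
        lv = data[cov.name].astype(str)
        unknown = set(lv.unique()) - set(cov.levels)
        if unknown:
            raise ValueError(f"unknown levels {unknown} for covariate {cov.name!r}")
        for level in cov.levels:
            if level != cov.baseline:
                cols.append((lv == level).to_numpy(dtype=float))
    return np.column_stack(cols) if cols else np.empty((len(data), 0))


def _schema_from_data(data: pd.DataFrame, covariates: Sequence[str]) -> CovariateSchema:
    covs = []
    for name in covariates:
        levels = tuple(sorted(data[name].astype(str).unique()))
        covs.append(Covariate(name, levels, baseline=levels[0]))
    return CovariateSchema(tuple(covs))


class MultistageModel:
    """Parametric multistage survival model for a left-truncated cohort.

    Parameters
    ----------
    data : DataFrame with entry_age, exit_age, status columns (status 1=event).
    family : "weibull" (proportional-hazards Weibull) or "nsm".
    covariates : names of categorical covariate columns (Weibull only);
        the baseline level of each is its alphabetically first level unless a
        full schema is supplied.
    schema : optional explicit CovariateSchema overriding the inferred one.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        family: str = "weibull",
        covariates: Sequence[str] | None = None,
        schema: CovariateSchema | None = None,
    ) -> None:
        if family not in ("weibull", "nsm"):
            raise ValueError(f"unknown family {family!r}")
        for c in _REQUIRED:
            if c not in data:
                raise ValueError(f"data lacks required column {c!r}")
        if family == "nsm" and covariates:
            raise ValueError("the NSM family is fitted without covariates")
        data = data.dropna(subset=list(_REQUIRED) + list(covariates or ())).reset_index(
            drop=True
        )  # complete-case analysis
        if (data["exit_age"] < data["entry_age"]).any():
            raise ValueError("exit_age < entry_age")
        self.data = data
        self.family = family
        self.covariate_names = tuple(covariates or ())
        self.schema = (
            schema
            if schema is not None
            else _schema_from_data(data, self.covariate_names)
        )

        self.entry = data["entry_age"].to_numpy(dtype=float)
        self.exit = data["exit_age"].to_numpy(dtype=float)
        self.status = data["status"].to_numpy(dtype=int)
        self.X = _design_matrix(data, self.schema)
        self.n_events = int(self.status.sum())
        self.nobs = len(data)
        self.k_beta = self.X.shape[1]
        self.param_names = ["m", "L"] + self.schema.design_columns
        # precomputed pieces of the Weibull likelihood
        self._log_t = np.log(np.where(self.exit > 0, self.exit, 1.0))
        self._t0_pos = self.entry > 0
        self._log_t0 = np.log(np.where(self._t0_pos, self.entry, 1.0))

    @classmethod
    def from_dataframe(cls, data, family="weibull", covariates=None, schema=None):
        return cls(data, family=family, covariates=covariates, schema=schema)

    # -- likelihood --------------------------------------------------------
    def loglike(self, params: np.ndarray) -> float:
        """Log-likelihood at transformed params (log m, log L, beta...)."""
        if self.family == "weibull":
            return self._loglike_weibull(params)
        return self._loglike_nsm(params)

    def _loglike_weibull(self, params) -> float:
        logm, logL = params[0], params[1]
        beta = np.asarray(params[2:], dtype=float)
        m = np.exp(logm)
        eta = self.X @ beta if beta.size else 0.0
        z = m * (self._log_t - logL)
        with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
            H = np.exp(eta + z)
            H0 = np.where(self._t0_pos, np.exp(eta + m * (self._log_t0 - logL)), 0.0)
            d = self.status
            if np.any(self.exit[d == 1] <= 0):
                return -np.inf  # density undefined at t=0
            ll = np.sum(d * (logm - self._log_t + eta + z)) - np.sum(H - H0)
        if not np.isfinite(ll):
            return -np.inf
        return float(ll)

    def score(self, params: np.ndarray) -> np.ndarray:
        """Analytic gradient in the transformed parameterization (Weibull)."""
        if self.family != "weibull":
            raise NotImplementedError("analytic score implemented for Weibull only")
        logm, logL = params[0], params[1]
        beta = np.asarray(params[2:], dtype=float)
        m = np.exp(logm)
        eta = self.X @ beta if beta.size else np.zeros(self.nobs)
        lt, lt0 = self._log_t, self._log_t0
        with np.errstate(over="ignore"):
            H = np.exp(eta + m * (lt - logL))
            H0 = np.where(self._t0_pos, np.exp(eta + m * (lt0 - logL)), 0.0)
        d = self.status
        dH = H - H0
        g_m = np.sum(d * (1.0 / m + (lt - logL))) - np.sum(
            H * (lt - logL) - H0 * np.where(self._t0_pos, lt0 - logL, 0.0)
        )
        g_logm = m * g_m
        g_logL = -m * np.sum(d) + m * np.sum(dH)
        grads = [g_logm, g_logL]
        if beta.size:
            r = d - dH
            grads.extend(self.X.T @ r)
        return np.asarray(grads, dtype=float)

    def _loglike_nsm(self, params) -> float:
        logm, logL = params[0], params[1]
        m, L = np.exp(logm), np.exp(logL)
        t, t0, d = self.exit, self.entry, self.status
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            q = np.log1p(-np.exp(-t / L))          # log(1 - e^{-t/L})
            logS = np.log(-np.expm1(m * q))
            logf = np.log(m / L) - t / L + (m - 1.0) * q
            q0 = np.where(t0 > 0, np.log1p(-np.exp(-t0 / L)), -np.inf)
            logS0 = np.where(t0 > 0, np.log(-np.expm1(m * q0)), 0.0)
            ll = np.sum(d * logf + (1 - d) * logS - logS0)
        if not np.isfinite(ll):
            return -np.inf
        return float(ll)

    # -- fitting -----------------------------------------------------------
    def fit(
        self,
        start_params: np.ndarray | None = None,
        fix: Mapping[str, float] | None = None,
        maxiter: int = 500,
        gtol: float = 1e-8,
        compute_se: bool = True,
        cox_start: bool = True,
    ) -> "MultistageResults":
        """Maximize the likelihood; returns a :class:`MultistageResults`.

        ``fix`` pins named parameters (e.g. ``{"m": 1.0}``) during
        optimization; fixed parameters get zero standard error.
        ``cox_start=False`` skips the semi-parametric fit for the starting
        beta (uses 0 instead) — useful in large simulation loops where the
        analytic-gradient optimizer converges regardless.
        """
        if self.n_events < 1:
            raise ValueError("no events: the likelihood carries no information")
        if start_params is None:
            start_params = initial_values(self, cox_start=cox_start)
        start_params = np.asarray(start_params, dtype=float)

        fix = dict(fix or {})
        fixed_idx, fixed_val = [], []
        for name, value in fix.items():
            i = self.param_names.index(name)
            fixed_idx.append(i)
            fixed_val.append(np.log(value) if i < 2 else float(value))
        free_idx = [i for i in range(len(self.param_names)) if i not in fixed_idx]

        def embed(free: np.ndarray) -> np.ndarray:
            full = np.empty(len(self.param_names))
            full[free_idx] = free
            full[fixed_idx] = fixed_val
            return full

        def nll(free):
            return -self.loglike(embed(free))

        use_jac = self.family == "weibull"

        def njac(free):
            return -self.score(embed(free))[free_idx]

        bounds = []
        for i in free_idx:
            if i == 0:
                bounds.append((np.log(1e-2), np.log(50.0)))
            elif i == 1:
                bounds.append((np.log(1e-3), np.log(1e8)))
            else:
                bounds.append((-20.0, 20.0))

        res = optimize.minimize(
            nll,
            start_params[free_idx],
            jac=njac if use_jac else None,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": gtol, "gtol": 1e-6},
        )
        if not res.success:
            log.warning("optimizer did not report convergence: %s", res.message)

        full = embed(res.x)
        llf = -res.fun

        cov_t = np.full((len(full), len(full)), np.nan)
        if compute_se and free_idx:
            try:
                H = approx_hess1(full[free_idx], lambda p: self.loglike(embed(p)))
                cov_free = np.linalg.inv(-H)
                if np.any(np.diag(cov_free) <= 0):
                    raise np.linalg.LinAlgError("non-positive variance")
                for a, ia in enumerate(free_idx):
                    for b, ib in enumerate(free_idx):
                        cov_t[ia, ib] = cov_free[a, b]
            except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate
                log.warning("observed information not invertible: %s", exc)
        for i in fixed_idx:
            cov_t[i, :] = 0.0
            cov_t[:, i] = 0.0

        return MultistageResults(
            model=self,
            params_transformed=full,
            cov_transformed=cov_t,
            llf=llf,
            converged=bool(res.success),
            message=str(res.message),
            start_params=start_params,
            n_iter=int(res.nit),
        )


def initial_values(model: MultistageModel, cox_start: bool = True) -> np.ndarray:
    """Starting parameters: PH fit for beta, log-log regression for (m, L).

    beta0 comes from a semi-parametric Cox proportional-hazards fit with
    delayed entry (falling back to 0 on a degenerate design); (m0, L0) from
    least squares of log cumulative hazard of the unadjusted delayed-entry
    product-limit estimator on log age.  For the NSM, m0 is taken from the
    same regression and L0 chosen so the NSM median matches the Weibull's.
    """
    beta0 = np.zeros(model.k_beta)
    if model.k_beta and cox_start:
        beta0 = _cox_beta(model)

    km = kaplan_meier_delayed_entry(model.entry, model.exit, model.status)
    with np.errstate(divide="ignore"):
        Hhat = km.cumulative_hazard
    ok = np.isfinite(Hhat) & (Hhat > 0) & (km.times > 0)
    if ok.sum() >= 2:
        slope, intercept = np.polyfit(np.log(km.times[ok]), np.log(Hhat[ok]), 1)
        m0 = float(np.clip(slope, 0.2, 20.0))
        L0 = float(np.exp(-intercept / m0))
    else:
        m0, L0 = 2.0, float(np.median(model.exit) * 2)
    L0 = float(np.clip(L0, 1e-2, 1e7))

    if model.family == "nsm":
        # match the Weibull-start median onset age
        t_med = L0 * np.log(2.0) ** (1.0 / m0)
        L0 = float(np.clip(-t_med / np.log1p(-0.5 ** (1.0 / m0)), 1e-2, 1e7))
        return np.array([np.log(m0), np.log(L0)])
    return np.concatenate([[np.log(m0), np.log(L0)], beta0])


def _cox_beta(model: MultistageModel) -> np.ndarray:
    from lifelines import CoxPHFitter

    df = pd.DataFrame(model.X, columns=model.schema.design_columns)
    # degenerate columns (no variation, or no events in a level) start at 0
    keep = []
    for j, col in enumerate(model.schema.design_columns):
        x = model.X[:, j]
        if x.std() == 0 or model.status[x == 1].sum() == 0 or model.status[x == 0].sum() == 0:
            log.warning("degenerate design for %s; beta0 set to 0", col)
        else:
            keep.append(j)
    beta0 = np.zeros(model.k_beta)
    if not keep:
        return beta0
    df = df.iloc[:, keep].copy()
    df["entry_age"] = model.entry
    df["exit_age"] = model.exit
    df["status"] = model.status
    try:
        cph = CoxPHFitter()
        cph.fit(
            df,
            duration_col="exit_age",
            event_col="status",
            entry_col="entry_age",
            show_progress=False,
        )
        for j, name in zip(keep, [model.schema.design_columns[j] for j in keep]):
            beta0[j] = float(cph.params_[name])
    except Exception as exc:  # pragma: no cover - lifelines internals
        log.warning("Cox initial values failed (%s); beta0 = 0", exc)
    return beta0


@dataclass
class MultistageResults:
    """Fit results: estimates, uncertainties, diagnostics, downstream analyses."""

    model: MultistageModel
    params_transformed: np.ndarray  # (log m, log L, beta...)
    cov_transformed: np.ndarray
    llf: float
    converged: bool
    message: str
    start_params: np.ndarray
    n_iter: int
    seed: int | None = None

    # -- parameter access --------------------------------------------------
    @property
    def m(self) -> float:
        return float(np.exp(self.params_transformed[0]))

    @property
    def L(self) -> float:
        return float(np.exp(self.params_transformed[1]))

    @property
    def beta(self) -> pd.Series:
        return pd.Series(
            self.params_transformed[2:], index=self.model.schema.design_columns
        )

    @property
    def params(self) -> pd.Series:
        return pd.Series(
            np.concatenate([[self.m, self.L], self.params_transformed[2:]]),
            index=self.model.param_names,
        )

    @property
    def bse(self) -> pd.Series:
        """Standard errors on the natural scale (delta method for m and L)."""
        se_t = np.sqrt(np.diag(self.cov_transformed))
        se = se_t.copy()
        se[0] *= self.m
        se[1] *= self.L
        return pd.Series(se, index=self.model.param_names)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """Wald intervals; m and L on the log scale, exponentiated."""
        z = stats.norm.ppf(1 - alpha / 2)
        se_t = np.sqrt(np.diag(self.cov_transformed))
        lo = self.params_transformed - z * se_t
        hi = self.params_transformed + z * se_t
        lo[:2], hi[:2] = np.exp(lo[:2]), np.exp(hi[:2])
        return pd.DataFrame(
            {"lower": lo, "upper": hi}, index=self.model.param_names
        )

    @property
    def dist(self) -> WeibullPH | NSM:
        """The fitted parametric family as a closed-form model object."""
        if self.model.family == "weibull":
            return WeibullPH(
                m=self.m,
                L=self.L,
                beta=dict(zip(self.model.schema.design_columns, self.params_transformed[2:])),
                schema=self.model.schema,
            )
        return NSM(m=self.m, L=self.L)

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def n_events(self) -> int:
        return self.model.n_events

    # -- downstream analyses ----------------------------------------------
    def adjusted_km(self) -> AdjustedKMCurve:
        """Offset-corrected Kaplan–Meier curve for this cohort and fit."""
        km = kaplan_meier_delayed_entry(
            self.model.entry, self.model.exit, self.model.status
        )
        # the KM curve is marginal over covariates; the offset uses the fitted
        # model at the baseline profile (eta = 0), exact for unadjusted fits
        H1 = estimate_H1(self.dist, km)
        return adjust_km(km, H1)

    def gof(self):
        from .assess import chisq_gof

        return chisq_gof(self.dist, self.adjusted_km())

    def risk_profile(self):
        from .classify import risk_profile

        return risk_profile(self.dist)

    def aging_rates(self) -> pd.DataFrame:
        from .aging import aging_rate_table

        return aging_rate_table(self)

    # -- reporting ---------------------------------------------------------
    def to_row(self) -> dict:
        row = {
            "family": self.model.family,
            "n": self.nobs,
            "n_events": self.n_events,
            "loglik": self.llf,
            "converged": self.converged,
            "m": self.m,
            "se_m": self.bse["m"],
            "L": self.L,
            "se_L": self.bse["L"],
        }
        for name in self.model.schema.design_columns:
            row[f"beta[{name}]"] = self.beta[name]
            row[f"se[{name}]"] = self.bse[name]
        return row

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            "Multistage survival model results",
            "=" * 64,
            f"Family:        {self.model.family:>8}    Subjects: {self.nobs}",
            f"Events:        {self.n_events:>8}    Log-likelihood: {self.llf:.3f}",
            f"Converged:     {str(self.converged):>8}    Iterations: {self.n_iter}",
            "-" * 64,
            f"{'param':<22}{'estimate':>12}{'std err':>10}{'[0.025':>10}{'0.975]':>10}",
        ]
        for name in self.model.param_names:
            lines.append(
                f"{name:<22}{self.params[name]:>12.4f}{self.bse[name]:>10.4f}"
                f"{ci.loc[name, 'lower']:>10.4f}{ci.loc[name, 'upper']:>10.4f}"
            )
        lines.append("=" * 64)
        return "\n".join(lines)
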