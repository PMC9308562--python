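"""Closed-form multistage survival families.

Two parametric families describe age-at-onset of a disease that requires
``m`` rate-limiting steps with a common timescale ``L`` (age-years):

* :class:`WeibullPH` — the sequential (Armitage–Doll-type) model, written as a
  proportional-hazards Weibull with cumulative hazard

  .. math:: H(t \\mid x) = e^{\\eta_x} (t/L)^m, \\qquad \\eta_x = \\sum_j \\beta_j x_j .

  On log–log axes ``log H`` is exactly linear in ``log t`` with slope ``m``;
  covariates displace the line vertically by ``eta`` without changing the
  slope, equivalently they rescale age by the relative aging rate
  ``exp(eta/m)``.

* :class:`NSM` — the non-sequential model in which all ``m`` constant-rate
  events must occur, in any order:

  .. math:: S(t) = 1 - (1 - e^{-t/L})^m .

``m`` is treated as a real-valued "effective number of steps" throughout; it
is an integer only in the classical time-homogeneous multistage model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Covariate",
    "CovariateSchema",
    "WeibullPH",
    "NSM",
    "model_from_text",
    "model_from_file",
]


@dataclass(frozen=True)
class Covariate:
    """A categorical covariate with a designated baseline level."""

    name: str
    levels: tuple[str, ...]
    baseline: str | None = None

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise ValueError(f"covariate {self.name!r} needs >= 2 levels")
        base = self.baseline if self.baseline is not None else self.levels[0]
        if base not in self.levels:
            raise ValueError(f"baseline {base!r} not among levels of {self.name!r}")
        object.__setattr__(self, "baseline", base)

    @property
    def design_columns(self) -> list[str]:
        """One indicator column per non-baseline level, ``name:level``."""
        return [f"{self.name}:{lv}" for lv in self.levels if lv != self.baseline]


@dataclass(frozen=True)
class CovariateSchema:
    """Ordered collection of categorical covariates defining the design matrix."""

    covariates: tuple[Covariate, ...] = ()

    def __post_init__(self) -> None:
        names = [c.name for c in self.covariates]
        if len(set(names)) != len(names):
            raise ValueError("duplicate covariate names in schema")

    def __iter__(self):
        return iter(self.covariates)

    def __len__(self) -> int:
        return len(self.covariates)

    @property
    def design_columns(self) -> list[str]:
        cols: list[str] = []
        for cov in self.covariates:
            cols.extend(cov.design_columns)
        return cols

    def encode(self, profile: Mapping[str, str]) -> np.ndarray:
        """Indicator vector for one covariate profile (dict name -> level)."""
        x = np.zeros(len(self.design_columns))
        cols = {c: i for i, c in enumerate(self.design_columns)}
        for cov in self.covariates:
            level = profile.get(cov.name, cov.baseline)
            if level not in cov.levels:
                raise ValueError(f"unknown level {level!r} for covariate {cov.name!r}")
            if level != cov.baseline:
                x[cols[f"{cov.name}:{level}"]] = 1.0
        return x


def _check_time(t, allow_zero: bool = True):
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("ages must be finite")
    if allow_zero:
        if np.any(t < 0):
            raise ValueError("ages must be >= 0")
    elif np.any(t <= 0):
        raise ValueError("ages must be > 0")
    return t


@dataclass(frozen=True)
class WeibullPH:
    """Proportional-hazards Weibull multistage model, H(t|x) = exp(eta)*(t/L)^m."""

    m: float
    L: float
    beta: dict[str, float] = field(default_factory=dict)
    schema: CovariateSchema | None = None

    def __post_init__(self) -> None:
        if not (self.m > 0 and np.isfinite(self.m)):
            raise ValueError("m must be finite and > 0")
        if not (self.L > 0 and np.isfinite(self.L)):
            raise ValueError("L must be finite and > 0")
        if self.schema is not None:
            expected = self.schema.design_columns
            if list(self.beta) != expected:
                raise ValueError(
                    f"beta keys {list(self.beta)} do not match schema columns {expected}"
                )

    # -- covariates -------------------------------------------------------
    def eta(self, x: Mapping[str, str] | Sequence[float] | None = None) -> float:
        """Linear predictor eta = sum_j beta_j x_j; 0 at baseline."""
        if x is None or not self.beta:
            return 0.0
        if isinstance(x, Mapping):
            if self.schema is None:
                raise ValueError("covariate profile given but model has no schema")
            x = self.schema.encode(x)
        x = np.asarray(x, dtype=float)
        b = np.array(list(self.beta.values()))
        if x.shape[-1] != b.size:
            raise ValueError(f"covariate vector length {x.shape[-1]} != {b.size}")
        return float(x @ b)

    # -- closed forms ------------------------------------------------------
    def cumulative_hazard(self, t, x=None, eta: float | None = None):
        """H(t) = exp(eta) * (t/L)^m = (t*exp(eta/m)/L)^m."""
        t = _check_time(t)
        e = self.eta(x) if eta is None else float(eta)
        return np.exp(e) * (t / self.L) ** self.m

    def survival(self, t, x=None, eta: float | None = None):
        return np.exp(-self.cumulative_hazard(t, x=x, eta=eta))

    def hazard(self, t, x=None, eta: float | None = None):
        """h(t) = (m/t) * exp(eta) * (t/L)^m; diverges at t=0 when m < 1."""
        t = _check_time(t, allow_zero=self.m >= 1)
        t = np.asarray(t, dtype=float)
        if self.m < 1 and np.any(t == 0):
            raise ValueError("hazard diverges at t=0 for m < 1")
        e = self.eta(x) if eta is None else float(eta)
        with np.errstate(divide="ignore", invalid="ignore"):
            h = np.where(t > 0, self.m / np.where(t > 0, t, 1.0)
                         * np.exp(e) * (t / self.L) ** self.m, 0.0)
        return h if h.ndim else float(h)

    def density(self, t, x=None, eta: float | None = None):
        """f(t) = h(t) * S(t); f/h = S exactly, so f ~ h while S ~ 1."""
        return self.hazard(t, x=x, eta=eta) * self.survival(t, x=x, eta=eta)

    def cumhaz_ratio(self, t1: float, t2: float) -> float:
        """H(t2)/H(t1) = (t2/t1)^m — independent of L and covariates."""
        if not (0 < t1 < t2):
            raise ValueError("need 0 < t1 < t2")
        return (t2 / t1) ** self.m

    # -- serialization -----------------------------------------------------
    def to_text(self) -> str:
        lines = ["family=weibull", f"m={float(self.m)!r}", f"L={float(self.L)!r}"]
        for k, v in self.beta.items():
            lines.append(f"beta.{k}={float(v)!r}")
        if self.schema is not None:
            for cov in self.schema:
                lines.append(
                    "covariate.%s=%s|baseline=%s"
                    % (cov.name, ",".join(cov.levels), cov.baseline)
                )
        return "\n".join(lines) + "\n"

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_text())

    def at_baseline(self) -> "WeibullPH":
        return replace(self, beta={k: 0.0 for k in self.beta})


@dataclass(frozen=True)
class NSM:
    """Non-sequential multistage model: S(t) = 1 - (1 - exp(-t/L))^m.

    All m events must occur, in any order, each at constant rate 1/L; the
    onset age is distributed as the maximum of m iid exponentials.  The
    optional ``eta`` argument of the hazard-scale methods applies a
    proportional-hazards multiplier exp(eta) to the cumulative hazard
    (off by default; the canonical model carries no covariates).
    """

    m: float
    L: float

    def __post_init__(self) -> None:
        if not (self.m > 0 and np.isfinite(self.m)):
            raise ValueError("m must be finite and > 0")
        if not (self.L > 0 and np.isfinite(self.L)):
            raise ValueError("L must be finite and > 0")

    def survival(self, t, eta: float = 0.0):
        t = _check_time(t)
        # S = -expm1(m * log1p(-exp(-t/L))) is stable for both tails
        with np.errstate(divide="ignore"):
            logF = self.m * np.log1p(-np.exp(-t / self.L))
        s = -np.expm1(logF)
        if eta != 0.0:
            s = np.exp(np.exp(eta) * np.log(np.clip(s, 1e-300, 1.0)))
        return s if np.ndim(s) else float(s)

    def cumulative_hazard(self, t, eta: float = 0.0):
        s = self.survival(t)
        h = -np.log(np.clip(s, 1e-300, None))
        return np.exp(eta) * h

    def density(self, t, eta: float = 0.0):
        """f(t) = (m/L) exp(-t/L) (1-exp(-t/L))^(m-1)."""
        t = _check_time(t, allow_zero=self.m >= 1)
        t = np.asarray(t, dtype=float)
        if self.m < 1 and np.any(t == 0):
            raise ValueError("density diverges at t=0 for m < 1")
        q = -np.expm1(-t / self.L)  # 1 - exp(-t/L)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (self.m / self.L) * np.exp(-t / self.L) * np.where(q > 0, q, 1.0) ** (self.m - 1)
            f = np.where((q == 0) & (self.m > 1), 0.0, f)
            f = np.where((q == 0) & (self.m == 1), 1.0 / self.L, f)
        if eta != 0.0:
            f = np.exp(eta) * f / self.survival(t) * self.survival(t, eta=eta)
        return f if f.ndim else float(f)

    def hazard(self, t, eta: float = 0.0):
        return self.density(t, eta=eta) / self.survival(t, eta=eta)

    def to_text(self) -> str:
        return f"family=nsm\nm={float(self.m)!r}\nL={float(self.L)!r}\n"

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_text())


def model_from_text(text: str) -> WeibullPH | NSM:
    """Inverse of ``to_text``; floats round-trip bit-exactly via repr."""
    fields: dict[str, str] = {}
    for line in text.strip().splitlines():
        if not line.strip():
            continue
        key, _, value = line.partition("=")
        fields[key.strip()] = value
    family = fields.pop("family", None)
    m = float(fields.pop("m"))
    L = float(fields.pop("L"))
    if family == "nsm":
        return NSM(m=m, L=L)
    if family != "weibull":
        raise ValueError(f"unknown family {family!r}")
    beta = {k[len("beta."):]: float(v) for k, v in fields.items() if k.startswith("beta.")}
    covs = []
    for k, v in fields.items():
        if k.startswith("covariate."):
            spec, _, base = v.partition("|baseline=")
            covs.append(Covariate(k[len("covariate."):], tuple(spec.split(",")), base or None))
    schema = CovariateSchema(tuple(covs)) if covs else None
    return WeibullPH(m=m, L=L, beta=beta, schema=schema)


def model_from_file(path) -> WeibullPH | NSM:
    with open(path) as fh:
        return model_from_text(fh.read())
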