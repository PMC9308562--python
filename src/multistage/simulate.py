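"""Synthetic cohorts with the statistical structure of a middle-aged biobank.

The generator emulates the features of hospital-episode cohort data that the
downstream analysis relies on: entry ages drawn from a Normal(57, 8) law
truncated to [49, 69] (the recruitment window of large UK cohorts), disease
onset ages from a known multistage model, left truncation at entry
(subjects are sampled conditionally on being disease-free at entry),
right censoring at study end, and optional censoring at an independently
drawn competing-cancer age.  Per-disease case counts land in the few-hundred
to few-thousand range at the default sizes.

Two brute-force multistage simulators serve as independent oracles for the
closed-form families:

* :func:`simulate_sequential_multistage` — onset is the sum of independent
  exponential stage waits (hypoexponential); its small-``t`` CDF approaches
  the Weibull form ``(prod(rates)) t^m / m!``.
* :func:`simulate_parallel_stages` — onset is the maximum of ``m`` iid
  exponential(1/L) waits, exactly the NSM law.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import linalg, stats

from .families import NSM, Covariate, CovariateSchema, WeibullPH

__all__ = [
    "EntryAgeLaw",
    "CovariateDesign",
    "GeneratorConfig",
    "sample_onset_weibull",
    "sample_onset_nsm",
    "generate_cohort",
    "simulate_sequential_multistage",
    "simulate_parallel_stages",
    "hypoexponential_cdf",
    "small_t_weibull_cdf",
    "DiseaseSpec",
    "generate_episode_table",
]


@dataclass(frozen=True)
class EntryAgeLaw:
    """Truncated-normal entry-age distribution; sd=0 degenerates to a point mass."""

    mean: float = 57.0
    sd: float = 8.0
    lower: float = 49.0
    upper: float = 69.0

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        u = rng.random(n)
        if self.sd == 0:
            return np.full(n, self.mean)
        a = (self.lower - self.mean) / self.sd
        b = (self.upper - self.mean) / self.sd
        # inverse-CDF sampling: deterministic given the uniform stream
        return stats.truncnorm.ppf(u, a, b, loc=self.mean, scale=self.sd)


@dataclass(frozen=True)
class CovariateDesign:
    """A covariate with level prevalences and true log-hazard-ratio per level.

    ``betas`` maps each non-baseline level to its true coefficient; the
    baseline (first level by default) has beta = 0.
    """

    name: str
    levels: tuple[str, ...]
    prevalences: tuple[float, ...]
    betas: dict[str, float] = field(default_factory=dict)
    baseline: str | None = None

    def __post_init__(self) -> None:
        if len(self.levels) != len(self.prevalences):
            raise ValueError(f"{self.name}: levels and prevalences differ in length")
        if abs(sum(self.prevalences) - 1.0) > 1e-9:
            raise ValueError(f"{self.name}: prevalences must sum to 1")
        object.__setattr__(
            self, "baseline", self.baseline if self.baseline is not None else self.levels[0]
        )

    def to_covariate(self) -> Covariate:
        return Covariate(self.name, self.levels, self.baseline)


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int
    n_subjects: int
    true_model: WeibullPH | NSM = WeibullPH(m=5.0, L=100.0)
    entry_age_law: EntryAgeLaw = EntryAgeLaw()
    followup_years: float = 10.0
    covariate_design: tuple[CovariateDesign, ...] = ()
    competing_cancer_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be > 0")
        if self.followup_years < 0:
            raise ValueError("followup_years must be >= 0")
        if self.competing_cancer_rate < 0:
            raise ValueError("competing_cancer_rate must be >= 0")

    def schema(self) -> CovariateSchema:
        return CovariateSchema(tuple(c.to_covariate() for c in self.covariate_design))

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["true_model"] = self.true_model.to_text()
        return yaml.safe_dump(d, sort_keys=False)


# ---------------------------------------------------------------------------
# conditional onset sampling (inverse-CDF, given survival to entry age t0)
# ---------------------------------------------------------------------------

def sample_onset_weibull(t0, model: WeibullPH, u, eta=0.0):
    """Onset age t solving S(t) = u * S(t0) for the Weibull family.

    t = L * ((t0/L)^m - exp(-eta) * log u)^(1/m) >= t0.
    """
    t0 = np.asarray(t0, dtype=float)
    u = np.asarray(u, dtype=float)
    if np.any((u <= 0) | (u >= 1)):
        raise ValueError("u must lie strictly in (0, 1)")
    if np.any(t0 < 0):
        raise ValueError("entry age must be >= 0")
    m, L = model.m, model.L
    t = L * ((t0 / L) ** m - np.exp(-np.asarray(eta, dtype=float)) * np.log(u)) ** (1.0 / m)
    return t if t.ndim else float(t)


def sample_onset_nsm(t0, model: NSM, u):
    """Onset age solving F(t) = F(t0) + u*(1 - F(t0)), F(t) = (1-exp(-t/L))^m."""
    t0 = np.asarray(t0, dtype=float)
    u = np.asarray(u, dtype=float)
    if np.any((u <= 0) | (u >= 1)):
        raise ValueError("u must lie strictly in (0, 1)")
    if np.any(t0 < 0):
        raise ValueError("entry age must be >= 0")
    m, L = model.m, model.L
    F0 = (-np.expm1(-t0 / L)) ** m
    Ft = F0 + u * (1.0 - F0)
    t = -L * np.log1p(-Ft ** (1.0 / m))
    return t if t.ndim else float(t)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _draw_covariates(config: GeneratorConfig, rng: np.random.Generator, n: int):
    """Covariate levels per subject and the implied linear predictor eta."""
    levels: dict[str, np.ndarray] = {}
    eta = np.zeros(n)
    for cov in config.covariate_design:
        idx = rng.choice(len(cov.levels), size=n, p=np.asarray(cov.prevalences))
        lv = np.asarray(cov.levels, dtype=object)[idx]
        levels[cov.name] = lv
        for level, b in cov.betas.items():
            eta += b * (lv == level)
    return levels, eta


def generate_cohort(
    config: GeneratorConfig, mode: str = "conditional"
) -> pd.DataFrame:
    """Simulate one left-truncated, right-censored cohort.

    Columns: subject_id, sex, entry_age, exit_age, status (1=event,
    0=censored), one column per covariate.  ``mode='conditional'`` samples
    onsets conditionally on being event-free at entry (exact truncated law);
    ``mode='rejection'`` draws unconditional onsets from age 0 and rejects
    subjects whose onset precedes entry — same law, used for validation.
    """
    if mode not in ("conditional", "rejection"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    model = config.true_model

    if mode == "conditional":
        entry = config.entry_age_law.sample(n, rng)
        levels, eta = _draw_covariates(config, rng, n)
        u = rng.random(n)
        onset = _onset(model, entry, u, eta)
    else:
        entry_l = []
        levels_l: list[dict] = []
        onset_l = []
        remaining = n
        while remaining > 0:
            k = max(remaining * 2, 100)
            e = config.entry_age_law.sample(k, rng)
            lv, et = _draw_covariates(config, rng, k)
            o = _onset(model, np.zeros(k), rng.random(k), et)
            keep = o > e
            take = min(int(keep.sum()), remaining)
            sel = np.flatnonzero(keep)[:take]
            entry_l.append(e[sel])
            onset_l.append(o[sel])
            levels_l.append({name: v[sel] for name, v in lv.items()})
            remaining -= take
        entry = np.concatenate(entry_l)
        onset = np.concatenate(onset_l)
        levels = {
            name: np.concatenate([d[name] for d in levels_l])
            for name in (levels_l[0] if levels_l else {})
        }

    end_age = entry + config.followup_years
    censor_age = end_age.copy()
    if config.competing_cancer_rate > 0:
        cancer_wait = rng.exponential(1.0 / config.competing_cancer_rate, size=n)
        censor_age = np.minimum(censor_age, entry + cancer_wait)

    status = (onset <= censor_age).astype(int)
    exit_age = np.where(status == 1, onset, censor_age)

    df = pd.DataFrame(
        {
            "subject_id": np.arange(n),
            "sex": np.where(rng.random(n) < 0.5, "F", "M"),
            "entry_age": entry,
            "exit_age": exit_age,
            "status": status,
        }
    )
    for name, lv in levels.items():
        df[name] = lv
    df.attrs["seed"] = config.seed
    df.attrs["config"] = config
    return df


def _onset(model, t0, u, eta):
    if isinstance(model, WeibullPH):
        return sample_onset_weibull(t0, model, u, eta=eta)
    if isinstance(model, NSM):
        return sample_onset_nsm(t0, model, u)
    raise TypeError(f"unsupported model {type(model).__name__}")


# ---------------------------------------------------------------------------
# brute-force multistage oracles
# ---------------------------------------------------------------------------

def simulate_sequential_multistage(rates, n: int, seed: int) -> np.ndarray:
    """Onset ages of a sequential multistage process: sum of exponential waits."""
    rates = np.asarray(rates, dtype=float)
    if rates.size == 0:
        raise ValueError("need at least one stage rate")
    if np.any(rates <= 0):
        raise ValueError("all stage rates must be > 0")
    rng = np.random.default_rng(seed)
    waits = rng.exponential(1.0 / rates, size=(n, rates.size))
    return waits.sum(axis=1)


def simulate_parallel_stages(L: float, m: int, n: int, seed: int) -> np.ndarray:
    """Onset ages of the non-sequential model: max of m iid exponential(1/L)."""
    if int(m) != m or m < 1:
        raise ValueError("m must be an integer >= 1")
    rng = np.random.default_rng(seed)
    return rng.exponential(L, size=(n, int(m))).max(axis=1)


def hypoexponential_cdf(t, rates) -> np.ndarray:
    """Exact CDF of a sum of independent exponentials (any rates, ties allowed).

    Computed from the phase-type representation: F(t) = 1 - alpha expm(Q t) 1
    with Q the bidiagonal generator of the sequential chain.  Robust to
    repeated rates, unlike the partial-fraction formula.
    """
    rates = np.asarray(rates, dtype=float)
    k = rates.size
    Q = np.zeros((k, k))
    Q[np.arange(k), np.arange(k)] = -rates
    Q[np.arange(k - 1), np.arange(1, k)] = rates[:-1]
    t = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.empty_like(t)
    for i, ti in enumerate(t):
        out[i] = 1.0 - linalg.expm(Q * ti)[0].sum()
    return out


def small_t_weibull_cdf(t, rates) -> np.ndarray:
    """Small-t Weibull approximation F(t) ~ (prod rates) t^m / m! = (t/L)^m."""
    rates = np.asarray(rates, dtype=float)
    m = rates.size
    L = (math.factorial(m) / np.prod(rates)) ** (1.0 / m)
    return (np.asarray(t, dtype=float) / L) ** m


# ---------------------------------------------------------------------------
# episode-table fixtures with known ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiseaseSpec:
    """One synthetic disease: an ICD-10 code and its true onset model."""

    code: str
    model: WeibullPH | NSM
    primary_fraction: float = 1.0  # fraction of its episodes flagged primary


def generate_episode_table(
    config: GeneratorConfig,
    diseases: tuple[DiseaseSpec, ...],
    pre_entry_cancer_prob: float = 0.0,
    pre_entry_nmsc_prob: float = 0.0,
):
    """Synthetic hospital-episode table plus its ground truth.

    Returns ``(subjects, episodes, truth)``: subjects carry entry/end ages and
    covariates; episodes one row per (subject, age, icd10, primary) with
    onsets drawn unconditionally from age 0 so pre-entry events exercise the
    first-event and exclusion rules; truth records, per subject, the exclusion
    flag (a pre-entry C00–C97 cancer other than C44) and each disease onset.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    entry = config.entry_age_law.sample(n, rng)
    levels, eta = _draw_covariates(config, rng, n)
    end_age = entry + config.followup_years

    subjects = pd.DataFrame(
        {
            "subject_id": np.arange(n),
            "sex": np.where(rng.random(n) < 0.5, "F", "M"),
            "entry_age": entry,
            "end_age": end_age,
        }
    )
    for name, lv in levels.items():
        subjects[name] = lv

    rows = []
    truth_rows = []
    for spec in diseases:
        onset = _onset(spec.model, np.zeros(n), rng.random(n), eta)
        primary = rng.random(n) < spec.primary_fraction
        observed = onset <= end_age
        for i in np.flatnonzero(observed):
            rows.append((i, float(onset[i]), spec.code, bool(primary[i])))
        for i in range(n):
            truth_rows.append((i, spec.code, float(onset[i]), bool(observed[i])))

    excluded = np.zeros(n, dtype=bool)
    if pre_entry_cancer_prob > 0:
        hit = rng.random(n) < pre_entry_cancer_prob
        ages = entry * rng.random(n)
        for i in np.flatnonzero(hit):
            rows.append((i, float(ages[i]), "C50.9", True))
        excluded |= hit
    if pre_entry_nmsc_prob > 0:
        hit = rng.random(n) < pre_entry_nmsc_prob
        ages = entry * rng.random(n)
        for i in np.flatnonzero(hit):
            rows.append((i, float(ages[i]), "C44.1", True))
        # non-melanoma skin cancer never excludes

    episodes = pd.DataFrame(rows, columns=["subject_id", "age", "icd10", "primary"])
    episodes = episodes.sort_values(["subject_id", "age"], kind="mergesort").reset_index(drop=True)
    truth = pd.DataFrame(truth_rows, columns=["subject_id", "code", "onset_age", "observed"])
    truth["excluded"] = truth["subject_id"].map(pd.Series(excluded)).astype(bool)
    return subjects, episodes, truth
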