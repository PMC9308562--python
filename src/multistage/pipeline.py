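"""End-to-end orchestration: cohort → fits → screening → classification.

``run_pipeline`` sequences the stages for a set of diseases, each defined by
one or more ICD-10 codes, on either supplied subject/episode tables or a
synthetic cohort, and writes delimited result tables plus a JSON manifest
(seed, versions, per-stage counts, exclusions with reasons) so a run is
reproducible from its artifacts alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aging import aging_rate_table, compare_groups
from .assess import chisq_gof, fdr_adjust, inclusion_filter
from .classify import classification_table
from .families import NSM, WeibullPH, model_from_text
from .icd import icd10_chapter
from .km import adjust_km, estimate_H1, kaplan_meier_delayed_entry
from .model import MultistageModel
from .prepare import (
    apply_baseline_exclusions,
    build_disease_dataset,
    first_event_per_chapter,
)
from .simulate import (
    CovariateDesign,
    DiseaseSpec,
    EntryAgeLaw,
    GeneratorConfig,
    generate_episode_table,
)

__all__ = ["PipelineConfig", "DiseaseDef", "run_pipeline", "stratified_comparison"]

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


class DataError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class DiseaseDef:
    name: str
    codes: tuple[str, ...]


@dataclass
class PipelineConfig:
    diseases: tuple[DiseaseDef, ...]
    out_dir: str
    seed: int = 0
    subjects_path: str | None = None
    episodes_path: str | None = None
    generator: GeneratorConfig | None = None
    synthetic_diseases: tuple[DiseaseSpec, ...] = ()
    covariates: tuple[str, ...] = ()
    family: str = "weibull"  # weibull | nsm | both
    fdr_level: float = 0.05
    m_threshold: float = 0.8
    min_events: int = 10

    def __post_init__(self) -> None:
        has_paths = self.subjects_path is not None and self.episodes_path is not None
        has_gen = self.generator is not None
        if has_paths == has_gen:
            raise ConfigError("exactly one of input paths / generator config required")
        if self.family not in ("weibull", "nsm", "both"):
            raise ConfigError(f"unknown family {self.family!r}")
        if not (0 < self.fdr_level < 1):
            raise ConfigError("fdr_level must lie in (0, 1)")
        if self.m_threshold < 0:
            raise ConfigError("m_threshold must be >= 0")
        if not self.diseases:
            raise ConfigError("no diseases configured")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        diseases = tuple(
            DiseaseDef(d["name"], tuple(d["codes"])) for d in raw.get("diseases", [])
        )
        gen = None
        synth: tuple[DiseaseSpec, ...] = ()
        if "generator" in raw:
            g = dict(raw["generator"])
            synth = tuple(
                DiseaseSpec(
                    code=s["code"],
                    model=model_from_text(s["model"])
                    if isinstance(s["model"], str)
                    else WeibullPH(m=s["model"]["m"], L=s["model"]["L"]),
                )
                for s in g.pop("diseases", [])
            )
            covs = tuple(
                CovariateDesign(
                    name=c["name"],
                    levels=tuple(c["levels"]),
                    prevalences=tuple(c["prevalences"]),
                    betas=dict(c.get("betas", {})),
                )
                for c in g.pop("covariate_design", [])
            )
            entry = EntryAgeLaw(**g.pop("entry_age_law", {}))
            tm = g.pop("true_model", None)
            model = (
                model_from_text(tm)
                if isinstance(tm, str)
                else WeibullPH(m=5.0, L=100.0)
            )
            gen = GeneratorConfig(
                true_model=model, entry_age_law=entry, covariate_design=covs, **g
            )
        return cls(
            diseases=diseases,
            out_dir=raw["out_dir"],
            seed=int(raw.get("seed", 0)),
            subjects_path=raw.get("subjects_path"),
            episodes_path=raw.get("episodes_path"),
            generator=gen,
            synthetic_diseases=synth,
            covariates=tuple(raw.get("covariates", ())),
            family=raw.get("family", "weibull"),
            fdr_level=float(raw.get("fdr_level", 0.05)),
            m_threshold=float(raw.get("m_threshold", 0.8)),
            min_events=int(raw.get("min_events", 10)),
        )


def _families(config: PipelineConfig) -> tuple[str, ...]:
    return ("weibull", "nsm") if config.family == "both" else (config.family,)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns a bundle of DataFrames and writes artifacts."""
    t_start = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # ------------------------------------------------------------------ data
    if config.generator is not None:
        subjects, episodes, _truth = generate_episode_table(
            config.generator, config.synthetic_diseases
        )
    else:
        try:
            subjects = pd.read_csv(config.subjects_path)
            episodes = pd.read_csv(config.episodes_path)
        except (OSError, ValueError) as exc:
            raise DataError(f"reading input tables failed: {exc}") from exc
    n_before = len(subjects)
    subjects = apply_baseline_exclusions(subjects, episodes)
    firsts = first_event_per_chapter(subjects, episodes)

    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "n_subjects_input": int(n_before),
        "n_subjects_after_exclusions": int(len(subjects)),
        "stages": [],
        "exclusions": [],
    }

    # ------------------------------------------------------------------ fits
    fit_rows = []
    gofs: dict[tuple[str, str], object] = {}
    results: dict[tuple[str, str], object] = {}
    skipped: list[str] = []
    for dd in config.diseases:
        t0 = time.time()
        ds = build_disease_dataset(
            dd.codes, subjects, firsts, episodes, covariates=config.covariates
        )
        n_ev = int(ds["status"].sum())
        if n_ev < config.min_events:
            skipped.append(dd.name)
            manifest["exclusions"].append(
                {"disease": dd.name, "rule": "too_few_events", "n_events": n_ev}
            )
            log.warning("%s skipped: %d events < %d", dd.name, n_ev, config.min_events)
            continue
        for family in _families(config):
            model = MultistageModel(
                ds,
                family=family,
                covariates=config.covariates if family == "weibull" else None,
            )
            try:
                res = model.fit()
            except Exception as exc:
                raise ConvergenceError(f"fit stage failed for {dd.name}: {exc}") from exc
            adj = res.adjusted_km()
            gof = chisq_gof(res.dist, adj)
            key = (dd.name, family)
            results[key] = res
            gofs[key] = gof
            row = {"disease": dd.name, "chapter": icd10_chapter(dd.codes[0]), **res.to_row()}
            row.update(
                {
                    "H1": adj.H1,
                    "gof_stat": gof.statistic,
                    "gof_df": gof.df,
                    "gof_p": gof.pvalue,
                }
            )
            fit_rows.append(row)
            adj.to_frame().to_csv(out / f"curve_{dd.name}_{family}.csv", index=False)
        manifest["stages"].append(
            {"disease": dd.name, "seconds": round(time.time() - t0, 3), "n_events": n_ev}
        )
    if not fit_rows:
        raise DataError("no disease could be fitted")
    fits = pd.DataFrame(fit_rows)

    # ----------------------------------------------------------- assessment
    fits["gof_q"] = np.nan
    fits["included"] = False
    fits["exclusion_reason"] = ""
    for family in _families(config):
        mask = fits["family"] == family
        q = fdr_adjust(fits.loc[mask, "gof_p"].to_numpy())
        fits.loc[mask, "gof_q"] = q
        inc, reason = [], []
        for (_, row), qi in zip(fits.loc[mask].iterrows(), q):
            g = dataclasses.replace(gofs[(row["disease"], family)], qvalue=float(qi))
            g = inclusion_filter(
                row["m"], g, m_threshold=config.m_threshold, fdr_level=config.fdr_level
            )
            inc.append(g.included)
            reason.append(g.reason)
            if not g.included:
                manifest["exclusions"].append(
                    {"disease": row["disease"], "family": family, "rule": g.reason}
                )
        fits.loc[mask, "included"] = inc
        fits.loc[mask, "exclusion_reason"] = reason

    # ------------------------------------------------------- classification
    report_family = "weibull" if config.family in ("weibull", "both") else "nsm"
    cls_in = fits[(fits["family"] == report_family) & fits["included"].astype(bool)]
    classification = (
        classification_table(cls_in) if len(cls_in) else pd.DataFrame()
    )

    # ---------------------------------------------------------- aging rates
    rates = pd.DataFrame()
    comparison = pd.DataFrame()
    if config.covariates and report_family == "weibull":
        rate_rows = []
        for _, row in cls_in.iterrows():
            res = results[(row["disease"], report_family)]
            tab = aging_rate_table(res)
            tab.insert(0, "disease", row["disease"])
            rate_rows.append(tab)
        if rate_rows:
            rates = pd.concat(rate_rows, ignore_index=True)
            if len(classification):
                tert = classification.set_index("disease")["tertile"]
                rates["tertile"] = rates["disease"].map(tert)
                spor = rates[rates["tertile"] == "sporadic"]
                late = rates[rates["tertile"] == "late-onset"]
                enough = (
                    spor.groupby("level").size().ge(2).all()
                    and late.groupby("level").size().ge(2).all()
                    and len(spor)
                    and len(late)
                )
                if enough:
                    comparison = compare_groups(spor, late)

    # -------------------------------------------------------------- outputs
    fits.to_csv(out / "fits.csv", index=False)
    if len(classification):
        classification.to_csv(out / "classification.csv", index=False)
    if len(rates):
        rates.to_csv(out / "aging_rates.csv", index=False)
    if len(comparison):
        comparison.to_csv(out / "group_comparison.csv", index=False)

    n_diseases = len(config.diseases)
    n_rows = int((fits["family"] == report_family).sum())
    n_included = int(
        fits[(fits["family"] == report_family)]["included"].astype(bool).sum()
    )
    manifest["counts"] = {
        "diseases_in": n_diseases,
        "skipped_no_events": len(skipped),
        "fitted": n_rows,
        "included": n_included,
        "excluded": n_rows - n_included,
    }
    manifest["seconds_total"] = round(time.time() - t_start, 3)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return {
        "fits": fits,
        "classification": classification,
        "aging_rates": rates,
        "group_comparison": comparison,
        "manifest": manifest,
        "results": results,
    }


def stratified_comparison(
    data: pd.DataFrame,
    stratifier: str,
    family: str = "weibull",
    ref_age: float = 60.0,
    min_events: int = 10,
) -> pd.DataFrame:
    """Unadjusted per-stratum fits with vertical-displacement and slope deltas.

    Fits the chosen family separately in each level of ``stratifier`` and
    reports, against the first (baseline) stratum, the change in
    log cumulative hazard at ``ref_age`` (vertical displacement on the
    log–log plot) and the change in slope m, each with a delta-method SE.
    """
    if stratifier not in data:
        raise ValueError(f"stratifier {stratifier!r} not in data")
    if data[stratifier].isna().any():
        raise ValueError("stratifier must be present for all subjects")
    rows = []
    base = None
    for level, sub in data.groupby(stratifier, sort=True):
        n_ev = int(sub["status"].sum())
        if n_ev < min_events:
            log.warning("stratum %r skipped: %d events", level, n_ev)
            continue
        res = MultistageModel(sub, family=family).fit()
        logm, logL = res.params_transformed[:2]
        m = res.m
        logH = m * (np.log(ref_age) - logL)
        grad = np.array([logH, -m])  # d logH / d(log m, log L)
        var_logH = float(grad @ res.cov_transformed[:2, :2] @ grad)
        row = {
            "stratum": level,
            "n": res.nobs,
            "n_events": res.n_events,
            "m": m,
            "se_m": res.bse["m"],
            "L": res.L,
            "logH_ref": logH,
            "se_logH_ref": np.sqrt(var_logH),
        }
        if base is None:
            base = row
            row["delta_m"] = 0.0
            row["se_delta_m"] = 0.0
            row["delta_logH"] = 0.0
            row["se_delta_logH"] = 0.0
        else:
            row["delta_m"] = m - base["m"]
            row["se_delta_m"] = float(np.hypot(row["se_m"], base["se_m"]))
            row["delta_logH"] = logH - base["logH_ref"]
            row["se_delta_logH"] = float(
                np.hypot(row["se_logH_ref"], base["se_logH_ref"])
            )
        rows.append(row)
    if not rows:
        raise ValueError("no stratum had enough events")
    return pd.DataFrame(rows)
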