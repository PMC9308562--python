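"""From hospital-episode tables to per-disease survival datasets.

The analysis design takes, for every subject, the first primary hospital
admission in each ICD-10 chapter, so that each chapter contributes at most
one event per subject and events are unconfounded by earlier disease in the
same chapter.  Subjects with a pre-entry cancer other than non-melanoma skin
cancer are excluded entirely; post-entry cancers censor follow-up.

Input schemas (delimited text, one row per record):

* subjects: ``subject_id, sex, entry_age, end_age`` plus covariate columns.
* episodes: ``subject_id, age, icd10, primary`` (primary a boolean flag).

Output per disease: ``subject_id, entry_age, exit_age, status`` plus the
covariates — a left-truncated, right-censored survival table.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .icd import icd10_chapter, is_cancer, normalize_code

__all__ = [
    "apply_baseline_exclusions",
    "first_event_per_chapter",
    "build_disease_dataset",
]

log = logging.getLogger(__name__)


def _validated_episodes(episodes: pd.DataFrame) -> pd.DataFrame:
    ep = episodes.copy()
    if (ep["age"] < 0).any():
        raise ValueError("episode ages must be >= 0")
    ep["icd10"] = ep["icd10"].map(normalize_code)
    return ep


def apply_baseline_exclusions(
    subjects: pd.DataFrame, episodes: pd.DataFrame
) -> pd.DataFrame:
    """Drop subjects with a C00–C97 (except C44) episode strictly before entry."""
    if "entry_age" not in subjects:
        raise ValueError("subjects table lacks entry_age")
    ep = _validated_episodes(episodes)
    ep = ep.merge(subjects[["subject_id", "entry_age"]], on="subject_id", how="inner")
    cancer = ep["icd10"].map(lambda c: is_cancer(c)).to_numpy()
    pre_entry = ep["age"].to_numpy() < ep["entry_age"].to_numpy()
    bad = set(ep.loc[cancer & pre_entry, "subject_id"])
    kept = subjects[~subjects["subject_id"].isin(bad)].reset_index(drop=True)
    log.info("baseline exclusions: %d of %d subjects removed", len(bad), len(subjects))
    return kept


def first_event_per_chapter(
    subjects: pd.DataFrame, episodes: pd.DataFrame
) -> pd.DataFrame:
    """Earliest primary episode at/after entry, per (subject, chapter).

    Ties at identical age within a chapter keep the lowest code (logged).
    Returns columns ``subject_id, chapter, age, icd10``.
    """
    ep = _validated_episodes(episodes)
    ep = ep[ep["primary"].astype(bool)]
    ep = ep.merge(subjects[["subject_id", "entry_age"]], on="subject_id", how="inner")
    ep = ep[ep["age"] >= ep["entry_age"]]
    if ep.empty:
        return pd.DataFrame(columns=["subject_id", "chapter", "age", "icd10"])
    ep = ep.assign(chapter=ep["icd10"].map(icd10_chapter))
    # stable sort by (age, code) then take the head of each group: the
    # deterministic tie rule "lowest code wins at equal age"
    ep = ep.sort_values(["subject_id", "chapter", "age", "icd10"], kind="mergesort")
    ties = ep.duplicated(subset=["subject_id", "chapter", "age"], keep=False)
    firsts = ep.groupby(["subject_id", "chapter"], as_index=False).first()
    n_ties = int(ties.sum())
    if n_ties:
        log.info("first_event_per_chapter: %d same-age ties resolved by code order", n_ties)
    return firsts[["subject_id", "chapter", "age", "icd10"]].reset_index(drop=True)


def _matches(code: str, code_set: Sequence[str]) -> bool:
    """A normalized episode code matches a set entry exactly or by stem prefix."""
    for c in code_set:
        if code == c or code.startswith(c):
            return True
    return False


def build_disease_dataset(
    code_set: Iterable[str],
    subjects: pd.DataFrame,
    first_events: pd.DataFrame,
    episodes: pd.DataFrame | None = None,
    covariates: Sequence[str] = (),
) -> pd.DataFrame:
    """Survival table for one disease defined by a set of ICD-10 codes.

    Event: the subject's chapter-first event falls in the code set.  Censoring
    age is the earliest of: study end, first post-entry cancer other than
    non-melanoma skin cancer (needs ``episodes``), or the chapter-first event
    for a *different* disease in the same chapter (the chapter is then
    "used up" and the subject leaves the risk set).
    """
    code_set = [normalize_code(c) for c in code_set]
    if not code_set:
        raise ValueError("empty disease code set")
    chapters = {icd10_chapter(c) for c in code_set}
    if len(chapters) > 1:
        raise ValueError(f"disease code set spans chapters {sorted(chapters)}")
    chapter = chapters.pop()

    subj = subjects.set_index("subject_id")
    fe = first_events[first_events["chapter"] == chapter].set_index("subject_id")

    entry = subj["entry_age"].to_numpy(dtype=float)
    exit_age = subj["end_age"].to_numpy(dtype=float)
    status = np.zeros(len(subj), dtype=int)

    # competing within-chapter first events and matching events
    fe_age = fe["age"].reindex(subj.index)
    fe_code = fe["icd10"].reindex(subj.index)
    has_fe = fe_age.notna().to_numpy()
    is_match = np.array(
        [(_matches(c, code_set) if isinstance(c, str) else False) for c in fe_code],
        dtype=bool,
    )

    # post-entry cancer censoring
    if episodes is not None:
        ep = _validated_episodes(episodes)
        ep = ep.merge(
            subjects[["subject_id", "entry_age"]], on="subject_id", how="inner"
        )
        cancer = ep["icd10"].map(lambda c: is_cancer(c)).to_numpy()
        post = ep["age"].to_numpy() >= ep["entry_age"].to_numpy()
        ca = (
            ep[cancer & post]
            .groupby("subject_id")["age"]
            .min()
            .reindex(subj.index)
            .to_numpy(dtype=float)
        )
        # cancers that are themselves the matching event must not censor
        ca_applies = ~(has_fe & is_match & (fe_age.to_numpy() >= ca))
        with np.errstate(invalid="ignore"):
            exit_age = np.where(
                ~np.isnan(ca) & (ca < exit_age) & ca_applies, ca, exit_age
            )

    competing = has_fe & ~is_match
    comp_age = fe_age.to_numpy(dtype=float)
    exit_age = np.where(competing & (comp_age < exit_age), comp_age, exit_age)

    event = has_fe & is_match & (fe_age.to_numpy() <= exit_age)
    status[event] = 1
    exit_age = np.where(event, fe_age.to_numpy(), exit_age)

    out = pd.DataFrame(
        {
            "subject_id": subj.index.to_numpy(),
            "entry_age": entry,
            "exit_age": exit_age,
            "status": status,
        }
    )
    for c in covariates:
        out[c] = subj[c].to_numpy()
    if (out["exit_age"] < out["entry_age"]).any():
        raise ValueError("exit_age < entry_age after censoring rules — data inconsistency")
    return out
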