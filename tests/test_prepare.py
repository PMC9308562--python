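"""First-event-per-chapter extraction and per-disease survival datasets."""

import numpy as np
import pandas as pd
import pytest

from multistage.icd import CHAPTERS, icd10_chapter, is_cancer, normalize_code
from multistage.prepare import (
    apply_baseline_exclusions,
    build_disease_dataset,
    first_event_per_chapter,
)
from multistage.simulate import DiseaseSpec, GeneratorConfig, generate_episode_table
from multistage import WeibullPH


class TestChapterMap:
    @pytest.mark.parametrize(
        "code, chapter",
        [
            ("C34", "II"),     # lung cancer -> Neoplasms
            ("D12", "II"),     # benign bowel -> Neoplasms (C00-D48)
            ("D50", "III"),
            ("K52", "XI"),     # digestive
            ("I21", "IX"),     # circulatory
            ("I25.1", "IX"),
            ("H59", "VII"),
            ("H60", "VIII"),
            ("T98", "XIX"),
            ("Z99", "XXI"),
        ],
    )
    def test_known_codes(self, code, chapter):
        assert icd10_chapter(code) == chapter

    def test_ranges_are_disjoint_and_ordered(self):
        stems = [(lo, hi) for _, lo, hi, _ in CHAPTERS]
        for (lo, hi) in stems:
            assert lo <= hi
        s = sorted(stems)
        for (_, hi), (lo2, _) in zip(s, s[1:]):
            assert hi < lo2

    def test_invalid_code_rejected(self):
        for bad in ("123", "CA4", "C3", ""):
            with pytest.raises(ValueError):
                icd10_chapter(bad)

    def test_normalize_strips_decimal(self):
        assert normalize_code("i25.1") == "I251"

    def test_cancer_predicate(self):
        assert is_cancer("C50.9")
        assert not is_cancer("C44.1")       # non-melanoma skin cancer exempt
        assert is_cancer("C44.1", include_nmsc=True)
        assert not is_cancer("D12")


def _subjects(rows):
    return pd.DataFrame(rows, columns=["subject_id", "entry_age", "end_age"])


def _episodes(rows):
    return pd.DataFrame(rows, columns=["subject_id", "age", "icd10", "primary"])


class TestBaselineExclusions:
    def test_pre_entry_cancer_excludes(self):
        subj = _subjects([(1, 50.0, 60.0)])
        ep = _episodes([(1, 48.0, "C50", True)])
        assert len(apply_baseline_exclusions(subj, ep)) == 0

    def test_pre_entry_nmsc_retained(self):
        subj = _subjects([(1, 50.0, 60.0)])
        ep = _episodes([(1, 48.0, "C44", True)])
        assert len(apply_baseline_exclusions(subj, ep)) == 1

    def test_post_entry_cancer_retained(self):
        subj = _subjects([(1, 50.0, 60.0)])
        ep = _episodes([(1, 55.0, "C50", True)])
        assert len(apply_baseline_exclusions(subj, ep)) == 1


class TestFirstEventPerChapter:
    def test_earliest_per_chapter(self):
        subj = _subjects([(1, 50.0, 62.0)])
        ep = _episodes(
            [(1, 55.0, "I21", True), (1, 57.0, "I25.1", True), (1, 58.0, "K52", True)]
        )
        fe = first_event_per_chapter(subj, ep)
        got = {(r.chapter, r.age) for r in fe.itertuples()}
        assert got == {("IX", 55.0), ("XI", 58.0)}

    def test_non_primary_ignored(self):
        subj = _subjects([(1, 50.0, 62.0)])
        ep = _episodes([(1, 55.0, "I21", False)])
        assert first_event_per_chapter(subj, ep).empty

    def test_pre_entry_episode_ignored(self):
        subj = _subjects([(1, 50.0, 62.0)])
        ep = _episodes([(1, 45.0, "I21", True), (1, 55.0, "I25", True)])
        fe = first_event_per_chapter(subj, ep)
        assert list(fe["age"]) == [55.0]

    def test_tie_at_same_age_keeps_lowest_code(self):
        # exhaustive over orderings of the tied pair
        for order in ([("I25", "I21")], [("I21", "I25")]):
            subj = _subjects([(1, 50.0, 62.0)])
            rows = [(1, 55.0, c, True) for c in order[0]]
            fe = first_event_per_chapter(subj, _episodes(rows))
            assert list(fe["icd10"]) == ["I21"]


class TestBuildDiseaseDataset:
    subj = _subjects([(1, 50.0, 60.0)])

    def _fe(self, episodes):
        return first_event_per_chapter(self.subj, episodes)

    def test_matching_event(self):
        ep = _episodes([(1, 55.0, "I21", True)])
        ds = build_disease_dataset(["I21"], self.subj, self._fe(ep), ep)
        assert ds.iloc[0]["status"] == 1 and ds.iloc[0]["exit_age"] == 55.0

    def test_competing_first_event_censors_chapter(self):
        # chapter IX already "used" by I21 at 55 -> censored for I25.1
        ep = _episodes([(1, 55.0, "I21", True), (1, 57.0, "I25.1", True)])
        ds = build_disease_dataset(["I25.1"], self.subj, self._fe(ep), ep)
        assert ds.iloc[0]["status"] == 0 and ds.iloc[0]["exit_age"] == 55.0

    def test_post_entry_cancer_censors_other_chapters(self):
        ep = _episodes([(1, 55.0, "C50", True)])
        ds = build_disease_dataset(["K52"], self.subj, self._fe(ep), ep)
        assert ds.iloc[0]["status"] == 0 and ds.iloc[0]["exit_age"] == 55.0

    def test_cancer_disease_is_not_self_censored(self):
        ep = _episodes([(1, 55.0, "C50", True)])
        ds = build_disease_dataset(["C50"], self.subj, self._fe(ep), ep)
        assert ds.iloc[0]["status"] == 1 and ds.iloc[0]["exit_age"] == 55.0

    def test_empty_code_set_rejected(self):
        with pytest.raises(ValueError):
            build_disease_dataset([], self.subj, self._fe(_episodes([])), None)

    def test_four_digit_definition_matches_stem(self):
        ep = _episodes([(1, 55.0, "I21.4", True)])
        ds = build_disease_dataset(["I21"], self.subj, self._fe(ep), ep)
        assert ds.iloc[0]["status"] == 1


class TestAgainstGeneratorGroundTruth:
    def test_extraction_matches_reference_implementation(self):
        cfg = GeneratorConfig(seed=33, n_subjects=300, true_model=WeibullPH(m=5, L=100),
                              followup_years=12.0)
        diseases = (
            DiseaseSpec("I21", WeibullPH(m=5.0, L=95.0)),
            DiseaseSpec("I50", WeibullPH(m=5.0, L=100.0)),
            DiseaseSpec("K52", WeibullPH(m=4.0, L=110.0)),
        )
        subjects, episodes, truth = generate_episode_table(
            cfg, diseases, pre_entry_cancer_prob=0.1
        )
        kept = apply_baseline_exclusions(subjects, episodes)
        excluded_truth = set(truth.loc[truth["excluded"], "subject_id"])
        assert set(subjects["subject_id"]) - set(kept["subject_id"]) == excluded_truth

        fe = first_event_per_chapter(kept, episodes)
        # reference: slow pure-python first-event scan
        entry = subjects.set_index("subject_id")["entry_age"]
        expect = {}
        for r in episodes.itertuples():
            if not r.primary or r.subject_id in excluded_truth:
                continue
            if r.age < entry.loc[r.subject_id]:
                continue
            ch = icd10_chapter(r.icd10)
            key = (r.subject_id, ch)
            cur = expect.get(key)
            if cur is None or (r.age, r.icd10) < cur:
                expect[key] = (r.age, r.icd10)
        got = {(r.subject_id, r.chapter): (r.age, r.icd10) for r in fe.itertuples()}
        assert got == expect

    def test_dataset_invariants(self):
        cfg = GeneratorConfig(seed=34, n_subjects=500, true_model=WeibullPH(m=5, L=100))
        diseases = (DiseaseSpec("I21", WeibullPH(m=5.0, L=100.0)),)
        subjects, episodes, _ = generate_episode_table(cfg, diseases)
        fe = first_event_per_chapter(subjects, episodes)
        ds = build_disease_dataset(["I21"], subjects, fe, episodes)
        assert ds["subject_id"].is_unique
        assert (ds["exit_age"] >= ds["entry_age"]).all()
        assert len(ds) == len(subjects)
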