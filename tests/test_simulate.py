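"""Synthetic-cohort generator and brute-force multistage oracles."""

import numpy as np
import pytest
from scipy import stats

from multistage import (
    NSM,
    EntryAgeLaw,
    GeneratorConfig,
    WeibullPH,
    generate_cohort,
    sample_onset_nsm,
    sample_onset_weibull,
    simulate_parallel_stages,
    simulate_sequential_multistage,
)
from multistage.simulate import (
    DiseaseSpec,
    generate_episode_table,
    hypoexponential_cdf,
    small_t_weibull_cdf,
)


class TestConditionalOnsetSampling:
    def test_exponential_median(self):
        t = sample_onset_weibull(0.0, WeibullPH(m=1.0, L=100.0), 0.5)
        assert t == pytest.approx(100 * np.log(2), rel=1e-9)  # 69.3147

    def test_u_near_one_returns_entry(self):
        t0 = 55.0
        t = sample_onset_weibull(t0, WeibullPH(m=5.0, L=100.0), 1 - 1e-12)
        assert t == pytest.approx(t0, abs=1e-6)

    def test_onset_never_precedes_entry(self):
        rng = np.random.default_rng(0)
        t0 = rng.uniform(40, 70, 1000)
        t = sample_onset_weibull(t0, WeibullPH(m=3.0, L=90.0), rng.random(1000))
        assert np.all(t >= t0)

    def test_invalid_u_rejected(self):
        with pytest.raises(ValueError):
            sample_onset_weibull(0.0, WeibullPH(m=1.0, L=100.0), 1.0)
        with pytest.raises(ValueError):
            sample_onset_nsm(0.0, NSM(m=1.0, L=100.0), 0.0)

    def test_weibull_conditional_draws_match_closed_form(self):
        model = WeibullPH(m=5.0, L=100.0)
        rng = np.random.default_rng(1)
        n = 100_000
        draws = sample_onset_weibull(np.full(n, 50.0), model, rng.random(n))

        def cdf(t):
            return 1.0 - model.survival(t) / model.survival(50.0)

        d, _ = stats.kstest(draws, cdf)
        assert d < 1.36 / np.sqrt(n)

    def test_nsm_exponential_case_matches_weibull(self):
        t = sample_onset_nsm(0.0, NSM(m=1.0, L=100.0), 0.5)
        assert t == pytest.approx(100 * np.log(2), rel=1e-9)

    def test_nsm_inverts_survival_example(self):
        # S(100) = 1 - (1-e^{-1})^2 => F(100) ~ 0.39958
        model = NSM(m=2.0, L=100.0)
        u = 1.0 - model.survival(100.0)
        assert sample_onset_nsm(0.0, model, u) == pytest.approx(100.0, rel=1e-9)

    def test_nsm_conditional_draws_match_closed_form(self):
        model = NSM(m=4.0, L=60.0)
        rng = np.random.default_rng(2)
        n = 100_000
        draws = sample_onset_nsm(np.full(n, 50.0), model, rng.random(n))

        def cdf(t):
            return 1.0 - model.survival(t) / model.survival(50.0)

        d, _ = stats.kstest(draws, cdf)
        assert d < 1.36 / np.sqrt(n)


class TestGenerateCohort:
    def test_zero_followup_all_censored(self, true_model):
        cfg = GeneratorConfig(seed=0, n_subjects=500, true_model=true_model,
                              followup_years=0.0)
        df = generate_cohort(cfg)
        assert df["status"].sum() == 0
        np.testing.assert_allclose(df["exit_age"], df["entry_age"])

    def test_seed_determinism(self, true_model):
        cfg = GeneratorConfig(seed=42, n_subjects=2_000, true_model=true_model)
        a, b = generate_cohort(cfg), generate_cohort(cfg)
        assert a.equals(b)

    def test_entry_ages_within_recruitment_window(self, plain_cohort):
        assert plain_cohort["entry_age"].between(49, 69).all()
        # trunc-normal(57, 8, [49, 69]) has mean 57 + 8*(phi(-1)-phi(1.5))/(Phi(1.5)-Phi(-1)) ~ 58.16
        mean = stats.truncnorm.mean(-1.0, 1.5, loc=57.0, scale=8.0)
        se = 8.0 / np.sqrt(len(plain_cohort))
        assert abs(plain_cohort["entry_age"].mean() - mean) < 4 * se

    def test_event_fraction_matches_closed_form(self, plain_cohort, true_model):
        """Observed event rate vs 1 - E[S(t0+10)/S(t0)] over the entry law."""
        t0 = plain_cohort["entry_age"].to_numpy()
        p = 1.0 - true_model.survival(t0 + 10.0) / true_model.survival(t0)
        expected = p.mean()
        n = len(plain_cohort)
        observed = plain_cohort["status"].mean()
        sd = np.sqrt(expected * (1 - expected) / n)
        assert abs(observed - expected) < 3 * sd

    def test_competing_cancer_censoring_shortens_followup(self, true_model):
        base = GeneratorConfig(seed=5, n_subjects=5_000, true_model=true_model)
        comp = GeneratorConfig(seed=5, n_subjects=5_000, true_model=true_model,
                               competing_cancer_rate=0.1)
        a, b = generate_cohort(base), generate_cohort(comp)
        assert b["exit_age"].mean() < a["exit_age"].mean()
        assert b["status"].sum() < a["status"].sum()

    def test_rejection_mode_matches_conditional_law(self, true_model):
        cfg = GeneratorConfig(seed=9, n_subjects=20_000, true_model=true_model)
        cond = generate_cohort(cfg, mode="conditional")
        rej = generate_cohort(cfg, mode="rejection")
        # same truncated onset law: compare event-age distributions
        a = cond.loc[cond["status"] == 1, "exit_age"]
        b = rej.loc[rej["status"] == 1, "exit_age"]
        _, p = stats.ks_2samp(a, b)
        assert p > 0.001
        assert abs(cond["status"].mean() - rej["status"].mean()) < 0.01

    def test_degenerate_config_rejected(self, true_model):
        with pytest.raises(ValueError):
            GeneratorConfig(seed=0, n_subjects=0, true_model=true_model)


class TestSequentialOracle:
    def test_single_stage_is_exponential(self):
        ages = simulate_sequential_multistage([0.01], n=50_000, seed=3)
        assert ages.mean() == pytest.approx(100.0, rel=0.03)
        d, _ = stats.kstest(ages, stats.expon(scale=100).cdf)
        assert d < 1.36 / np.sqrt(50_000)

    def test_mean_is_sum_of_stage_means(self):
        rates = [0.01, 0.02, 0.05]
        ages = simulate_sequential_multistage(rates, n=100_000, seed=4)
        expected = sum(1 / r for r in rates)
        se = ages.std() / np.sqrt(ages.size)
        assert abs(ages.mean() - expected) < 3 * se

    def test_exact_two_stage_cdf(self):
        # two equal stages lambda=0.01: F(10) = 1 - e^{-0.1}(1.1)
        exact = hypoexponential_cdf(10.0, [0.01, 0.01])[0]
        assert exact == pytest.approx(1 - np.exp(-0.1) * 1.1, rel=1e-9)  # 0.004679

    def test_small_t_weibull_form(self):
        # L = (m!/prod)^{1/m} = sqrt(20000) ~ 141.42; F ~ (10/141.42)^2 = 0.005
        approx = small_t_weibull_cdf(10.0, [0.01, 0.01])
        assert approx == pytest.approx(0.005, rel=1e-9)

    def test_cdf_ratio_converges_at_small_t(self):
        rates = [0.01, 0.01]
        L = np.sqrt(2 / (0.01 * 0.01))
        ratios = []
        for frac in (0.1, 0.05, 0.01):
            t = frac * L
            ratios.append(hypoexponential_cdf(t, rates)[0] / small_t_weibull_cdf(t, rates))
        # deviation from 1 shrinks monotonically as t -> 0
        devs = np.abs(np.array(ratios) - 1.0)
        assert np.all(np.diff(devs) < 0)
        assert devs[-1] < 0.02

    def test_empty_rates_rejected(self):
        with pytest.raises(ValueError):
            simulate_sequential_multistage([], n=10, seed=0)


class TestParallelOracle:
    def test_m1_is_exponential(self):
        ages = simulate_parallel_stages(L=100.0, m=1, n=50_000, seed=6)
        d, _ = stats.kstest(ages, stats.expon(scale=100).cdf)
        assert d < 1.36 / np.sqrt(50_000)

    def test_survival_matches_nsm_at_reference_age(self):
        ages = simulate_parallel_stages(L=100.0, m=2, n=100_000, seed=7)
        p = NSM(m=2.0, L=100.0).survival(100.0)  # ~0.60042
        emp = (ages > 100.0).mean()
        assert abs(emp - p) < 3 * np.sqrt(p * (1 - p) / ages.size)

    def test_distribution_equals_nsm_closed_form(self):
        model = NSM(m=5.0, L=80.0)
        ages = simulate_parallel_stages(L=80.0, m=5, n=100_000, seed=8)
        d, _ = stats.kstest(ages, lambda t: 1.0 - model.survival(t))
        assert d < 1.36 / np.sqrt(ages.size)

    def test_non_integer_m_rejected(self):
        with pytest.raises(ValueError):
            simulate_parallel_stages(L=10.0, m=0, n=5, seed=0)


def test_raising_one_stage_rate_lifts_curve_and_lowers_slope():
    """A 100x faster stage raises incidence but removes a rate-limiting step."""
    from multistage.model import MultistageModel
    import pandas as pd

    def fit_onsets(ages, horizon=120.0):
        df = pd.DataFrame(
            {
                "entry_age": 0.0,
                "exit_age": np.minimum(ages, horizon),
                "status": (ages <= horizon).astype(int),
            }
        )
        return MultistageModel(df).fit()

    base = simulate_sequential_multistage([0.01] * 5, n=100_000, seed=10)
    fast = simulate_sequential_multistage([0.01] * 4 + [1.0], n=100_000, seed=11)
    rb, rf = fit_onsets(base), fit_onsets(fast)
    assert rf.m < rb.m  # step effectively removed
    H_b = rb.dist.cumulative_hazard(60.0)
    H_f = rf.dist.cumulative_hazard(60.0)
    assert H_f > H_b  # curve displaced upwards


class TestEpisodeTable:
    cfg = GeneratorConfig(seed=21, n_subjects=400, true_model=WeibullPH(m=5, L=100))
    diseases = (
        DiseaseSpec("I21", WeibullPH(m=5.0, L=110.0)),
        DiseaseSpec("K52", WeibullPH(m=4.0, L=130.0)),
    )

    def test_determinism(self):
        a = generate_episode_table(self.cfg, self.diseases, pre_entry_cancer_prob=0.05)
        b = generate_episode_table(self.cfg, self.diseases, pre_entry_cancer_prob=0.05)
        for x, y in zip(a, b):
            assert x.equals(y)

    def test_ground_truth_consistency(self):
        subjects, episodes, truth = generate_episode_table(
            self.cfg, self.diseases, pre_entry_cancer_prob=0.1
        )
        # every observed truth onset appears as an episode row
        obs = truth[truth["observed"]]
        merged = obs.merge(
            episodes, left_on=["subject_id", "code"], right_on=["subject_id", "icd10"]
        )
        assert len(merged) == len(obs)
        np.testing.assert_allclose(merged["onset_age"], merged["age"])

    def test_excluded_subjects_have_pre_entry_cancer(self):
        subjects, episodes, truth = generate_episode_table(
            self.cfg, self.diseases, pre_entry_cancer_prob=0.2
        )
        excluded = set(truth.loc[truth["excluded"], "subject_id"])
        cancer_rows = episodes[episodes["icd10"].str.startswith("C50")]
        entry = subjects.set_index("subject_id")["entry_age"]
        pre = set(
            cancer_rows.loc[
                cancer_rows["age"].to_numpy()
                < entry.loc[cancer_rows["subject_id"]].to_numpy(),
                "subject_id",
            ]
        )
        assert excluded == pre
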