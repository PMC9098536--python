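"""Statistical stage: t tests, ROC/AUC, Youden cutoffs, combination,
decision rule and confusion metrics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.optimize import brentq

from gliomet import (
    apply_decision_rule,
    binormal_auc,
    combine_classifiers,
    confusion_metrics,
    default_decision_rule,
    roc_analysis,
    two_sample_t_test,
)
from gliomet.stats import DecisionRule, bootstrap_auc_ci
from gliomet.synthetic import CohortSpec, default_cohort_spec, sample_feature_cohort


def _pooled_t_closed_form(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    df = na + nb - 2
    p = 2 * sps.t.sf(abs(t), df)
    return t, df, p


class TestTTest:
    def test_identical_groups(self):
        res = two_sample_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(0.0) and res.p == pytest.approx(1.0)

    def test_separation_limit(self):
        a = np.array([1.0, 2.0, 3.0])
        res = two_sample_t_test(a, a + 100.0 * a.std(ddof=1))
        assert res.p < 1e-6

    def test_pooled_matches_closed_form(self):
        a, b = [1.0, 2.0, 4.0], [2.5, 3.0, 5.5]
        res = two_sample_t_test(a, b, variant="pooled")
        t, df, p = _pooled_t_closed_form(a, b)
        assert res.t == pytest.approx(t, abs=1e-12)
        assert res.df == pytest.approx(df)
        assert res.p == pytest.approx(p, abs=1e-12)

    def test_welch_df_below_pooled(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([10.0, 30.0, 50.0, 70.0, 90.0])
        res = two_sample_t_test(a, b, variant="welch")
        assert res.df < a.size + b.size - 2

    def test_zero_variance_equal_means(self):
        res = two_sample_t_test([2.0, 2.0], [2.0, 2.0])
        assert res.t == 0.0 and res.p == 1.0

    def test_zero_variance_unequal_means_flagged(self):
        with pytest.raises(ValueError, match="zero variance"):
            two_sample_t_test([2.0, 2.0], [3.0, 3.0])

    def test_study_sized_cohorts_separate_lesion_adc(self):
        """Lesion ADC separates study-sized cohorts (20 vs 21) at p < 0.001
        at a rate matching the noncentral-t power of the sampled law."""
        spec = default_cohort_spec()
        small = CohortSpec(
            features={"lesion_adc_mean": dict(spec.features["lesion_adc_mean"])},
            n_gb=20, n_bm=21,
        )
        hits = 0
        n_cohorts = 500
        for seed in range(n_cohorts):
            df = sample_feature_cohort(small, seed=seed)
            vals = df["lesion_adc_mean"].to_numpy()
            gb = vals[df.group.to_numpy() == "GB"]
            bm = vals[df.group.to_numpy() == "BM"]
            if two_sample_t_test(gb, bm).p < 1e-3:
                hits += 1
        rate = hits / n_cohorts
        # analytic oracle: Welch power with the truncated-normal moments
        mu_g, sd_g = 0.71e-3, 0.33e-3
        mu_b, sd_b = 1.13e-3, 0.21e-3
        tg = sps.truncnorm(a=-mu_g / sd_g, b=np.inf, loc=mu_g, scale=sd_g)
        n_g, n_b = 20, 21
        v_g, v_b = tg.var() / n_g, sd_b**2 / n_b
        ncp = (mu_b - tg.mean()) / np.sqrt(v_g + v_b)
        df_w = (v_g + v_b) ** 2 / (v_g**2 / (n_g - 1) + v_b**2 / (n_b - 1))
        t_crit = sps.t.isf(5e-4, df_w)
        power = float(sps.nct.sf(t_crit, df_w, ncp))
        se = np.sqrt(power * (1 - power) / n_cohorts)
        assert abs(rate - power) <= 4 * se
        assert rate >= 0.85  # strong separation at study size


def _auc_brute_force(scores, labels):
    """Pairwise Mann-Whitney count with half credit for ties."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (pos.size * neg.size)


class TestRoc:
    def test_perfect_separation(self):
        scores = np.r_[np.zeros(10), np.ones(10)]
        labels = np.r_[np.zeros(10), np.ones(10)].astype(bool)
        assert roc_analysis(scores, labels).auc == 1.0

    def test_null_auc_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.standard_normal(100_000)
        labels = rng.integers(0, 2, 100_000).astype(bool)
        assert roc_analysis(scores, labels).auc == pytest.approx(0.5, abs=0.01)

    def test_matches_pairwise_oracle_with_ties(self):
        rng = np.random.default_rng(1)
        scores = rng.integers(0, 5, 60).astype(float)  # heavy ties
        labels = rng.integers(0, 2, 60).astype(bool)
        if labels.min() == labels.max():
            labels[0] = ~labels[0]
        got = roc_analysis(scores, labels).auc
        assert got == pytest.approx(_auc_brute_force(scores, labels.astype(int)), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(0, 1, 500)
        labels = rng.integers(0, 2, 500).astype(bool)
        a = roc_analysis(scores, labels).auc
        b = roc_analysis(np.exp(scores), labels).auc
        assert a == b

    def test_less_is_positive_direction(self):
        scores = np.array([0.5, 0.6, 1.2, 1.4])
        labels = np.array([True, True, False, False])  # low score = positive
        roc = roc_analysis(scores, labels, "less_is_positive")
        assert roc.auc == 1.0
        assert 0.6 <= roc.optimal_cutoff <= 1.2

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis(np.arange(5.0), np.ones(5, bool))

    def test_roc_point_reproduced_by_confusion_metrics(self):
        rng = np.random.default_rng(3)
        scores = np.r_[rng.normal(1, 1, 300), rng.normal(0, 1, 300)]
        labels = np.array(["GB"] * 300 + ["BM"] * 300, dtype=object)
        roc = roc_analysis(scores, labels)
        for k in (5, 50, 250):
            thr = roc.thresholds[k]
            predicted = np.where(scores >= thr, "GB", "BM").astype(object)
            cm = confusion_metrics(predicted, labels)
            assert cm["sensitivity"] == pytest.approx(roc.sensitivity[k], abs=1e-12)
            assert cm["specificity"] == pytest.approx(roc.specificity[k], abs=1e-12)


class TestYoudenCutoff:
    def test_separated_clusters_cutoff_between(self):
        scores = np.r_[np.full(20, 1.0), np.full(20, 3.0)]
        labels = np.r_[np.zeros(20), np.ones(20)].astype(bool)
        roc = roc_analysis(scores, labels)
        assert 1.0 < roc.optimal_cutoff <= 3.0

    def test_monotone_transform_preserves_operating_point(self):
        rng = np.random.default_rng(4)
        scores = np.r_[rng.normal(2, 1, 400), rng.normal(0, 1, 400)]
        labels = np.r_[np.ones(400), np.zeros(400)].astype(bool)
        roc = roc_analysis(scores, labels)
        roc_t = roc_analysis(np.exp(scores), labels)
        sens = (scores[labels] >= roc.optimal_cutoff).mean()
        sens_t = (np.exp(scores[labels]) >= roc_t.optimal_cutoff).mean()
        assert sens_t == pytest.approx(sens, abs=1e-12)
        assert roc_t.optimal_cutoff == pytest.approx(np.exp(roc.optimal_cutoff), rel=1e-9)

    def test_adc_cutoff_converges_to_density_crossing(self, large_cohort):
        """The empirical Youden cutoff for lesion ADC approaches the
        equal-density crossing of the two (truncated) Gaussians."""
        vals = large_cohort["lesion_adc_mean"].to_numpy()
        labels = large_cohort["group"].to_numpy(dtype=object)
        roc = roc_analysis(vals, labels, "less_is_positive")
        mu_g, sd_g = 0.71e-3, 0.33e-3
        mu_b, sd_b = 1.13e-3, 0.21e-3
        gb = sps.truncnorm(a=-mu_g / sd_g, b=np.inf, loc=mu_g, scale=sd_g)
        bm = sps.truncnorm(a=-mu_b / sd_b, b=np.inf, loc=mu_b, scale=sd_b)
        crossing = brentq(lambda x: gb.pdf(x) - bm.pdf(x), 0.75e-3, 1.1e-3)
        assert roc.optimal_cutoff == pytest.approx(crossing, abs=0.05e-3)


class TestBinormalAuc:
    def test_equal_means_is_half(self):
        assert binormal_auc(1.0, 0.5, 1.0, 2.0) == pytest.approx(0.5)

    def test_study_rcbv_value(self):
        auc = binormal_auc(2.63, 1.72, 1.21, 0.64)
        assert auc == pytest.approx(sps.norm.cdf(1.42 / np.hypot(1.72, 0.64)), abs=1e-12)
        assert auc == pytest.approx(0.78, abs=0.005)

    def test_monotone_in_separation(self):
        aucs = [binormal_auc(d, 1.0, 0.0, 1.0) for d in np.linspace(0, 10, 30)]
        assert np.all(np.diff(aucs) > 0)
        assert aucs[-1] > 0.999

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            binormal_auc(1.0, 0.0, 0.0, 1.0)

    def test_empirical_auc_matches_binormal(self, large_cohort):
        labels = large_cohort["group"].to_numpy(dtype=object)
        spec = default_cohort_spec()
        for name, direction in (
            ("perilesional_rcbv_max", "greater_is_positive"),
            ("psr_percent", "greater_is_positive"),
            ("lesion_adc_mean", "less_is_positive"),
        ):
            (mu_g, sd_g), (mu_b, sd_b) = spec.features[name]["GB"], spec.features[name]["BM"]
            emp = roc_analysis(large_cohort[name].to_numpy(), labels, direction).auc
            assert emp == pytest.approx(binormal_auc(mu_g, sd_g, mu_b, sd_b), abs=0.01), name


class TestCombineClassifiers:
    def test_single_feature_preserves_auc(self):
        rng = np.random.default_rng(5)
        x = np.r_[rng.normal(1, 1, 500), rng.normal(0, 1, 500)][:, None]
        labels = np.r_[np.ones(500), np.zeros(500)].astype(bool)
        single = roc_analysis(x[:, 0], labels).auc
        _, combined = combine_classifiers(x, labels)
        assert combined.auc == pytest.approx(single, abs=1e-9)

    def test_two_independent_features_beat_each_alone(self):
        rng = np.random.default_rng(6)
        n = 20_000
        x = np.c_[
            np.r_[rng.normal(1, 1, n), rng.normal(0, 1, n)],
            np.r_[rng.normal(1, 1, n), rng.normal(0, 1, n)],
        ]
        labels = np.r_[np.ones(n), np.zeros(n)].astype(bool)
        auc1 = roc_analysis(x[:, 0], labels).auc
        _, combined = combine_classifiers(x, labels)
        assert combined.auc > auc1
        # binormal closed form for two independent unit-d' features
        assert combined.auc == pytest.approx(sps.norm.cdf(np.sqrt(2.0) / np.sqrt(2.0) * 1.0), abs=0.01)

    def test_trio_matches_independence_bound(self, large_cohort):
        """Combined AUC of the three biomarkers ~ Phi(sqrt(sum a_i^2))."""
        labels = large_cohort["group"].to_numpy(dtype=object)
        cols = ["lesion_adc_mean", "perilesional_rcbv_max", "psr_percent"]
        _, combined = combine_classifiers(large_cohort[cols], labels)
        spec = default_cohort_spec()
        a2 = 0.0
        for name in cols:
            (mu_g, sd_g), (mu_b, sd_b) = spec.features[name]["GB"], spec.features[name]["BM"]
            a2 += ((mu_g - mu_b) / np.hypot(sd_g, sd_b)) ** 2
        assert combined.auc == pytest.approx(sps.norm.cdf(np.sqrt(a2)), abs=0.01)

    def test_perfect_separation_falls_back_to_lda(self):
        x = np.r_[np.full(20, 5.0), np.zeros(20)][:, None] + \
            np.linspace(0, 0.1, 40)[:, None]
        labels = np.r_[np.ones(20), np.zeros(20)].astype(bool)
        scores, combined = combine_classifiers(x, labels)
        assert np.all(np.isfinite(scores))
        assert combined.auc == 1.0


class TestDecisionRule:
    def test_gb_group_mean_profile(self):
        df = pd.DataFrame([{
            "perilesional_rcbv_max": 2.63, "psr_percent": 84.59, "lesion_adc_mean": 0.71e-3,
        }])
        assert apply_decision_rule(df, default_decision_rule())[0] == "GB"

    def test_bm_group_mean_profile(self):
        df = pd.DataFrame([{
            "perilesional_rcbv_max": 1.21, "psr_percent": 71.14, "lesion_adc_mean": 1.13e-3,
        }])
        assert apply_decision_rule(df, default_decision_rule())[0] == "BM"

    @pytest.mark.parametrize("mode", ["all", "any", "majority"])
    def test_boundary_profile_is_bm_in_every_mode(self, mode):
        df = pd.DataFrame([{
            "perilesional_rcbv_max": 1.37, "psr_percent": 75.0, "lesion_adc_mean": 1.0e-3,
        }])
        assert apply_decision_rule(df, default_decision_rule(mode))[0] == "BM"

    def test_missing_feature_value_undetermined(self):
        df = pd.DataFrame([{
            "perilesional_rcbv_max": np.nan, "psr_percent": 84.0, "lesion_adc_mean": 0.7e-3,
        }])
        assert apply_decision_rule(df, default_decision_rule())[0] == "undetermined"

    def test_combination_modes_differ(self):
        # satisfies 2 of 3 criteria
        df = pd.DataFrame([{
            "perilesional_rcbv_max": 2.0, "psr_percent": 80.0, "lesion_adc_mean": 1.5e-3,
        }])
        assert apply_decision_rule(df, default_decision_rule("all"))[0] == "BM"
        assert apply_decision_rule(df, default_decision_rule("any"))[0] == "GB"
        assert apply_decision_rule(df, default_decision_rule("majority"))[0] == "GB"

    def test_absent_column_rejected(self):
        df = pd.DataFrame([{"psr_percent": 80.0}])
        with pytest.raises(ValueError, match="perilesional_rcbv_max"):
            apply_decision_rule(df, default_decision_rule())


class TestConfusionMetrics:
    def test_perfect_prediction(self):
        truth = np.array(["GB", "BM", "GB", "BM"], dtype=object)
        m = confusion_metrics(truth.copy(), truth)
        assert (m["sensitivity"], m["specificity"], m["accuracy"]) == (1.0, 1.0, 1.0)

    def test_inverted_prediction(self):
        truth = np.array(["GB", "BM", "GB", "BM"], dtype=object)
        inv = np.where(truth == "GB", "BM", "GB").astype(object)
        m = confusion_metrics(inv, truth)
        assert (m["sensitivity"], m["specificity"], m["accuracy"]) == (0.0, 0.0, 0.0)

    def test_undetermined_excluded_and_counted(self):
        truth = np.array(["GB", "GB", "BM"], dtype=object)
        pred = np.array(["GB", "undetermined", "BM"], dtype=object)
        m = confusion_metrics(pred, truth)
        assert m["n_undetermined"] == 1 and m["sensitivity"] == 1.0

    def test_adc_rule_sensitivity_matches_analytic(self, large_cohort):
        """Single-feature ADC rule at 1.0e-3: sensitivity ~ the truncated-
        normal tail probability (~0.81 for the study parameters)."""
        vals = large_cohort["lesion_adc_mean"].to_numpy()
        truth = large_cohort["group"].to_numpy(dtype=object)
        predicted = np.where(vals < 1.0e-3, "GB", "BM").astype(object)
        m = confusion_metrics(predicted, truth)
        mu, sd = 0.71e-3, 0.33e-3
        gb_law = sps.truncnorm(a=-mu / sd, b=np.inf, loc=mu, scale=sd)
        assert m["sensitivity"] == pytest.approx(gb_law.cdf(1.0e-3), abs=0.01)
        assert m["sensitivity"] == pytest.approx(0.81, abs=0.015)


class TestBootstrapCi:
    def test_ci_brackets_auc_and_is_deterministic(self):
        rng = np.random.default_rng(7)
        scores = np.r_[rng.normal(1, 1, 400), rng.normal(0, 1, 400)]
        labels = np.r_[np.ones(400), np.zeros(400)].astype(bool)
        auc = roc_analysis(scores, labels).auc
        lo, hi = bootstrap_auc_ci(scores, labels, n_resamples=300, seed=1)
        assert lo < auc < hi
        assert (lo, hi) == bootstrap_auc_ci(scores, labels, n_resamples=300, seed=1)
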