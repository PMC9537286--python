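"""Discrimination, calibration and stratification statistics."""

import numpy as np
import pandas as pd
import pytest

import rgx
from rgx.errors import ModelError
from rgx.evaluation import _f1, f1_reference_value
from rgx.transforms import TransformParams


class TestAUC:
    def test_perfect_ordering(self):
        rep = rgx.roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], n_boot=50, seed=0)
        assert rep.aux["observed"] == 1.0

    def test_all_tied_scores_give_half(self):
        rep = rgx.roc_auc(np.ones(40), np.r_[np.ones(20), np.zeros(20)], n_boot=50, seed=0)
        assert rep.aux["observed"] == pytest.approx(0.5)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        rep = rgx.roc_auc(rng.normal(0, 1, 200), rng.integers(0, 2, 200), n_boot=100, seed=1)
        assert rep.point == pytest.approx(0.5, abs=0.08)

    def test_single_class_rejected(self):
        with pytest.raises(ModelError):
            rgx.roc_auc([0.1, 0.9], [1, 1])

    def test_bootstrap_deterministic_and_ci_shrinks_with_n(self):
        rng = np.random.default_rng(3)
        widths = []
        for n in (50, 200, 800):
            scores = rng.normal(0, 1, n)
            labels = (scores + rng.normal(0, 1, n) > 0).astype(int)
            r1 = rgx.roc_auc(scores, labels, n_boot=200, seed=7)
            r2 = rgx.roc_auc(scores, labels, n_boot=200, seed=7)
            assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)
            widths.append(r1.ci_high - r1.ci_low)
        assert widths[0] > widths[1] > widths[2]

    def test_reduces_to_c_index_on_binary_uncensored(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(0, 1, 100)
        labels = rng.integers(0, 2, 100)
        auc = rgx.roc_auc(scores, labels, n_boot=50, seed=0).aux["observed"]
        # encode the label as (reversed) time: events first
        time = np.where(labels == 1, 1.0, 2.0)
        c = rgx.concordance(scores, time, np.ones(100, int), n_boot=50, seed=0)
        assert auc == pytest.approx(c.aux["observed"], abs=1e-12)


class TestF1Cutoff:
    def test_reference_value_equals_always_positive_f1(self):
        rng = np.random.default_rng(0)
        labels = (rng.uniform(size=500) < 0.2).astype(int)
        pi = labels.mean()
        always_pos = _f1(np.ones(500), labels, cutoff=0.0)
        assert f1_reference_value(pi) == pytest.approx(always_pos, abs=1e-12)
        assert f1_reference_value(0.2) == pytest.approx(1 / 3)

    def test_perfect_separation_reaches_one(self):
        scores = np.r_[np.full(30, 0.1), np.full(30, 0.9)]
        labels = np.r_[np.zeros(30, int), np.ones(30, int)]
        cutoff, rep = rgx.f1_with_cutoff(scores, labels, "fit", n_boot=100, seed=0)
        assert 0.1 < cutoff < 0.9
        assert rep.point == 1.0

    def test_apply_mode_reuses_stored_cutoff(self):
        rng = np.random.default_rng(1)
        scores = rng.uniform(size=100)
        labels = (scores + rng.normal(0, 0.3, 100) > 0.5).astype(int)
        cutoff, _ = rgx.f1_with_cutoff(scores, labels, "fit", n_boot=100, seed=0)
        new_scores = rng.uniform(size=60)
        new_labels = rng.integers(0, 2, 60)
        out_cut, rep = rgx.f1_with_cutoff(
            new_scores, new_labels, "apply", cutoff=cutoff, n_boot=100, seed=0
        )
        assert out_cut == cutoff  # nothing refitted on the new data
        assert rep.aux["cutoff"] == cutoff

    def test_uninformative_scores_flagged(self):
        rng = np.random.default_rng(2)
        scores = rng.uniform(size=80)
        labels = rng.integers(0, 2, 80)
        with pytest.warns(UserWarning, match="reference"):
            rgx.f1_with_cutoff(scores, np.zeros(80, int) + labels * 0, "fit", n_boot=50, seed=0)


class TestConcordance:
    def test_three_patient_hand_enumeration(self):
        perfect = rgx.concordance([3, 2, 1], [1, 2, 3], [1, 1, 1], n_boot=50, seed=0)
        assert perfect.aux["observed"] == 1.0
        reversed_ = rgx.concordance([1, 2, 3], [1, 2, 3], [1, 1, 1], n_boot=50, seed=0)
        assert reversed_.aux["observed"] == 0.0

    def test_random_risk_near_half(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10, 200)
        e = rng.integers(0, 2, 200)
        e[0] = 1
        rep = rgx.concordance(rng.normal(0, 1, 200), t, e, n_boot=100, seed=0)
        assert rep.point == pytest.approx(0.5, abs=0.05)


class TestHosmerLemeshow:
    def test_flat_probabilities_perfectly_calibrated(self):
        chi2, p = rgx.hosmer_lemeshow(np.full(100, 0.5), np.r_[np.ones(50), np.zeros(50)])
        assert chi2 == pytest.approx(0.0)
        assert p == 1.0

    def test_shifted_probabilities_rejected(self):
        rng = np.random.default_rng(0)
        p_true = rng.uniform(0.1, 0.7, 1000)
        y = (rng.uniform(size=1000) < p_true).astype(int)
        _, p_ok = rgx.hosmer_lemeshow(p_true, y)
        _, p_bad = rgx.hosmer_lemeshow(np.clip(p_true + 0.2, 0, 1), y)
        assert p_bad < 0.01 < p_ok

    def test_sample_size_guard(self):
        with pytest.raises(ModelError):
            rgx.hosmer_lemeshow([0.5] * 10, [1] * 10, g=10)


class TestGND:
    @staticmethod
    def _cohort(n=300, seed=0, rate=0.03):
        rng = np.random.default_rng(seed)
        lp = rng.normal(0, 0.7, n)
        t_ev = rng.exponential(1 / (rate * np.exp(lp)))
        c = rng.uniform(0, 80, n)
        t, e = np.minimum(t_ev, c), (t_ev <= c).astype(int)
        s_pred = np.exp(-rate * 24.0 * np.exp(lp))
        return s_pred, t, e

    def test_well_calibrated_model_accepted(self):
        s_pred, t, e = self._cohort()
        chi2, p, table = rgx.gnd_calibration(s_pred, t, e, horizon=24.0)
        assert p > 0.01
        assert (table["n"] > 0).all()

    def test_doubled_hazard_rejected(self):
        s_pred, t, e = self._cohort(seed=1)
        chi2_bad, p_bad, _ = rgx.gnd_calibration(s_pred**2, t, e, horizon=24.0)
        assert p_bad < 0.01

    def test_single_group_undefined(self):
        s_pred, t, e = self._cohort(n=60, seed=2)
        with pytest.raises(ModelError):
            rgx.gnd_calibration(s_pred, t, e, groups=np.zeros(60, int), horizon=24.0)

    def test_no_events_before_horizon_rejected(self):
        with pytest.raises(ModelError):
            rgx.gnd_calibration(
                np.full(50, 0.9), np.full(50, 100.0), np.ones(50, int), horizon=24.0
            )


class TestKMLogrank:
    def test_identical_groups_give_zero_statistic(self):
        t = np.r_[np.arange(1, 21), np.arange(1, 21)]
        e = np.ones(40, int)
        g = np.r_[np.zeros(20, int), np.ones(20, int)]
        _, chi2, p = rgx.km_logrank(t, e, g)
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_no_events_curve_stays_at_one(self):
        curves, _, _ = rgx.km_logrank(
            np.r_[np.arange(1, 11), np.arange(1, 11)],
            np.zeros(20, int),
            np.r_[np.zeros(10, int), np.ones(10, int)],
        )
        for kmf in curves.values():
            assert float(kmf.survival_function_.iloc[-1]) == 1.0

    def test_rate_ratio_two_is_detected(self):
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(50):
            t = np.r_[rng.exponential(10, 200), rng.exponential(20, 200)]
            g = np.r_[np.zeros(200, int), np.ones(200, int)]
            _, _, p = rgx.km_logrank(t, np.ones(400, int), g)
            ps.append(p)
        assert np.median(ps) < 0.01


class TestStratification:
    def test_bimodal_risks_split_at_the_gap(self):
        # risk clusters around 1 and 2 with disjoint survival-time ranges:
        # any split inside the risk gap separates survival perfectly, so the
        # optimal threshold must fall there
        rng = np.random.default_rng(0)
        risk = np.r_[rng.normal(1, 0.1, 100), rng.normal(2, 0.1, 100)]
        t = np.r_[rng.uniform(30, 60, 100), rng.uniform(1, 10, 100)]
        e = np.ones(200, int)
        rule, p = rgx.stratification_threshold(risk, t, e, "fit")
        assert (risk[:100] <= rule.threshold).all()
        assert (risk[100:] > rule.threshold).all()
        assert p < 1e-6

    def test_stored_threshold_splits_example_scores(self):
        rule = rgx.StratificationRule(1.502)
        groups = (np.array([1.4, 1.6]) > rule.threshold).astype(int)
        assert groups.tolist() == [0, 1]

    def test_apply_does_not_refit(self):
        rng = np.random.default_rng(1)
        risk_d = rng.uniform(0, 2, 150)
        t_d = rng.exponential(20 / (1 + risk_d))
        rule, _ = rgx.stratification_threshold(risk_d, t_d, np.ones(150, int), "fit")
        risk_v = rng.uniform(0, 2, 100)
        t_v = rng.exponential(15, 100)
        rule2, p_v = rgx.stratification_threshold(
            risk_v, t_v, np.ones(100, int), "apply", rule
        )
        assert rule2.threshold == rule.threshold

    def test_constant_risks_rejected(self):
        with pytest.raises(ModelError):
            rgx.stratification_threshold(
                np.ones(30), np.arange(1, 31), np.ones(30, int), "fit"
            )


class TestSchoenfeld:
    @staticmethod
    def _fit(n=200, beta_t=False, seed=0):
        rng = np.random.default_rng(seed)
        if beta_t:
            # piecewise hazard whose log-hazard ratio flips sign at t = 8
            x = np.r_[np.zeros(n // 2), np.ones(n // 2)]
            t1 = rng.exponential(1 / (0.1 * np.exp(1.5 * x)))
            t2 = 8.0 + rng.exponential(1 / (0.1 * np.exp(-1.5 * x)))
            t_ev = np.where(t1 < 8.0, t1, t2)
        else:
            x = rng.normal(0, 1, n)
            t_ev = rng.exponential(1 / (0.05 * np.exp(0.5 * x)))
        c = rng.uniform(0, 60, n)
        t, e = np.minimum(t_ev, c), (t_ev <= c).astype(int)
        X = pd.DataFrame({"x": x})
        params = TransformParams(
            pd.DataFrame({"lam": 1.0, "shift": 0.0, "scale": 1.0}, index=["x"])
        )
        res = rgx.CoxPH(X, t, e, params).fit()
        return res, X, t, e

    def test_proportional_data_usually_accepted(self):
        res, X, t, e = self._fit()
        table = rgx.schoenfeld_ph_test(res, X, t, e)
        assert set(table.index) == {"x", "GLOBAL"}
        assert table.loc["x", "p"] > 0.01

    def test_sign_flipping_effect_detected(self):
        res, X, t, e = self._fit(beta_t=True, seed=3)
        table = rgx.schoenfeld_ph_test(res, X, t, e)
        assert table.loc["GLOBAL", "p"] < 0.05

    def test_matches_lifelines_km_transform(self):
        from lifelines.statistics import proportional_hazard_test

        for seed in range(5):
            res, X, t, e = self._fit(seed=seed)
            ours = rgx.schoenfeld_ph_test(res, X, t, e).loc["x", "p"]
            df = X.copy()
            df["time"], df["event"] = t, e
            ref = proportional_hazard_test(res._lifelines, df, time_transform="km")
            assert ours == pytest.approx(float(ref.p_value[0]), rel=1e-6)

    def test_more_covariates_than_events_rejected(self):
        X = pd.DataFrame({"a": np.arange(5.0), "b": np.arange(5.0) ** 2})
        with pytest.raises(ModelError):
            rgx.schoenfeld_ph_test(object(), X, np.arange(1, 6), np.array([1, 0, 0, 0, 0]))
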