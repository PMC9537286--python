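"""Feature selection, rank aggregation and the two model families."""

import warnings

import numpy as np
import pandas as pd
import pytest

import rgx
from rgx.errors import ModelError
from rgx.modeling import (
    _discretise_ef,
    _mi,
    enhanced_borda_scores,
    volume_correlation_filter,
)
from rgx.transforms import TransformParams, fit_transforms, apply_transforms
from oracles import complete_linkage_clusters, mrmr_greedy_oracle


def identity_params(names):
    """z-transform parameters that leave inputs unchanged (lam=1, shift=0, scale=1)."""
    return TransformParams(
        pd.DataFrame({"lam": 1.0, "shift": 0.0, "scale": 1.0}, index=list(names))
    )


class TestClusterRepresentatives:
    def test_duplicated_features_collapse(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, 60)
        df = pd.DataFrame({"a": base, "b": base * 3 + 1, "c": rng.normal(0, 1, 60)})
        reps, cmap = rgx.cluster_representatives(df)
        assert len(reps) == 2
        assert set(cmap[[r for r in reps if "c" != r][0]]) == {"a", "b"}

    def test_monotone_transform_joins_its_source(self):
        rng = np.random.default_rng(1)
        x = rng.gamma(2, 1, 80)
        df = pd.DataFrame({"x": x, "expx": np.exp(x), "other": rng.normal(0, 1, 80)})
        _, cmap = rgx.cluster_representatives(df)
        cluster_of = {m: rep for rep, members in cmap.items() for m in members}
        assert cluster_of["x"] == cluster_of["expx"]

    @pytest.mark.parametrize("seed", range(15))
    def test_partition_matches_naive_complete_linkage(self, seed):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(rng.normal(0, 1, (40, 5)), columns=list("abcde"))
        _, cmap = rgx.cluster_representatives(df)
        rho = df.corr(method="spearman").to_numpy()
        dist = 1 - np.abs(rho)
        np.fill_diagonal(dist, 0)
        oracle = complete_linkage_clusters(dist, 0.3)
        ours = sorted(
            sorted(df.columns.get_loc(m) for m in members)
            for members in cmap.values()
        )
        assert ours == sorted(sorted(c) for c in oracle)

    def test_volume_filter_drops_correlated(self):
        rng = np.random.default_rng(2)
        vol = pd.Series(rng.gamma(3, 10, 100))
        df = pd.DataFrame(
            {"vol_like": vol * 2 + rng.normal(0, 1, 100), "free": rng.normal(0, 1, 100)}
        )
        keep = volume_correlation_filter(df, vol)
        assert keep == ["free"]


class TestMRMR:
    def test_target_copy_selected_first(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 150)
        X = pd.DataFrame(
            {"noise": rng.normal(0, 1, 150), "copy_of_y": y + 0.0, "z": rng.normal(0, 1, 150)}
        )
        assert rgx.mrmr_rank(X, y)[0] == "copy_of_y"

    def test_redundant_twin_ranked_after_independent_signal(self):
        rng = np.random.default_rng(3)
        f1 = rng.normal(0, 1, 300)
        y = (f1 > 0).astype(int)
        X = pd.DataFrame(
            {
                "f1": f1,
                "f2": f1 + rng.normal(0, 0.05, 300),  # near-duplicate
                "f3": np.where(rng.uniform(size=300) < 0.7, y, 1 - y)
                + rng.normal(0, 0.01, 300),  # weaker but independent
            }
        )
        assert rgx.mrmr_rank(X, y) == ["f1", "f3", "f2"]

    @pytest.mark.parametrize("seed", range(10))
    def test_greedy_path_matches_exhaustive_criterion(self, seed):
        rng = np.random.default_rng(seed)
        n_feat = int(rng.integers(3, 7))
        X = pd.DataFrame(
            rng.normal(0, 1, (80, n_feat)), columns=[f"f{i}" for i in range(n_feat)]
        )
        y = (X["f0"] + rng.normal(0, 1, 80) > 0).astype(int).to_numpy()
        ours = rgx.mrmr_rank(X, y)
        oracle = mrmr_greedy_oracle(X, y, _mi, _discretise_ef)
        assert ours == oracle

    def test_truncation_warns(self):
        X = pd.DataFrame({"a": np.arange(20.0)})
        with pytest.warns(UserWarning, match="truncated"):
            rgx.mrmr_rank(X, np.arange(20) % 2, n_select=5)


class TestEnhancedBorda:
    def test_hand_computed_toy(self):
        # fold 1 selects (a, b); fold 2 selects (b,) out of 2 folds:
        # a: (2-1+1)/2 = 1 -> 0.5 ;  b: (2-2+1)/2 + (1-1+1)/1 = 1.5 -> 0.75
        scores = enhanced_borda_scores([["a", "b"], ["b"]])
        assert scores["a"] == pytest.approx(0.5)
        assert scores["b"] == pytest.approx(0.75)

    def test_unselected_features_score_zero(self):
        scores = enhanced_borda_scores([["a"]], n_folds=4)
        assert scores == {"a": pytest.approx(0.25)}

    def test_perfect_feature_dominates_cv(self):
        rng = np.random.default_rng(0)
        y = np.r_[np.zeros(30, int), np.ones(30, int)]
        X = pd.DataFrame(
            {
                "perfect": y + rng.normal(0, 0.01, 60),
                "junk1": rng.normal(0, 1, 60),
                "junk2": rng.normal(0, 1, 60),
            }
        )
        ranking = rgx.cv_rank_aggregate(X, y, reps=3, folds=3, seed=0, s_max=3)
        assert ranking.table.index[0] == "perfect"
        assert ranking.table.loc["perfect", "occurrence"] == 9

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 40)
        X = pd.DataFrame(rng.normal(0, 1, (40, 4)), columns=list("abcd"))
        r1 = rgx.cv_rank_aggregate(X, y, reps=2, folds=2, seed=5, s_max=3)
        r2 = rgx.cv_rank_aggregate(X, y, reps=2, folds=2, seed=5, s_max=3)
        pd.testing.assert_frame_equal(r1.table, r2.table)
        assert r1.median_size == r2.median_size

    def test_pure_noise_has_no_fixed_winner(self):
        winners = set()
        for seed in range(8):
            rng = np.random.default_rng(100 + seed)
            y = rng.integers(0, 2, 60)
            X = pd.DataFrame(rng.normal(0, 1, (60, 5)), columns=list("abcde"))
            r = rgx.cv_rank_aggregate(X, y, reps=2, folds=3, seed=seed, s_max=3)
            winners.add(r.table.index[0])
        assert len(winners) > 1


class TestLogistic:
    def test_published_model_probability_at_origin(self):
        # the final atypical model: z = (0, 0) -> p = 1 / (1 + e^0.968)
        params = TransformParams.from_dict(
            {
                "morph_vol_dens_aabb": {"lambda": -0.5, "shift": 0.246, "scale": 0.046},
                "szm_glnu": {"lambda": 0.0, "shift": 4.190, "scale": 0.669},
            }
        )
        model = rgx.FittedModel(
            model_kind="logistic_ova",
            features=["morph_vol_dens_aabb", "szm_glnu"],
            coefficients=pd.Series(
                {"morph_vol_dens_aabb": 0.114, "szm_glnu": -0.545}
            ),
            transform_params=params,
            intercept=-0.968,
        )
        from rgx.transforms import yeo_johnson_inverse

        raw = pd.DataFrame(
            {
                "morph_vol_dens_aabb": [yeo_johnson_inverse(np.array([0.246]), -0.5)[0]],
                "szm_glnu": [yeo_johnson_inverse(np.array([4.190]), 0.0)[0]],
            }
        )
        p = model.predict(raw)[0]
        assert p == pytest.approx(1 / (1 + np.exp(0.968)), abs=1e-9)
        assert p == pytest.approx(0.275, abs=5e-4)

    def test_negative_coefficient_is_monotone_decreasing(self):
        params = TransformParams.from_dict(
            {"szm_glnu": {"lambda": 0.0, "shift": 4.190, "scale": 0.669}}
        )
        model = rgx.FittedModel(
            model_kind="logistic_ova",
            features=["szm_glnu"],
            coefficients=pd.Series({"szm_glnu": -0.545}),
            transform_params=params,
            intercept=-0.968,
        )
        probs = model.predict(pd.DataFrame({"szm_glnu": [10.0, 65.0, 300.0]}))
        assert probs.is_monotonic_decreasing

    def test_null_model_recovers_zero(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(0, 1, (600, 2)), columns=["a", "b"])
        y = rng.integers(0, 2, 600)
        res = rgx.LogisticOVA(X, y, 1, identity_params(["a", "b"])).fit(penalty_grid=(0.0,))
        assert abs(res.intercept) < 0.2
        from sklearn.metrics import roc_auc_score

        auc = roc_auc_score(y, res.predict(X))
        assert auc == pytest.approx(0.5, abs=0.08)

    def test_separable_data_reaches_training_auc_one(self):
        X = pd.DataFrame({"x": np.r_[np.linspace(-2, -1, 20), np.linspace(1, 2, 20)]})
        y = np.r_[np.zeros(20, int), np.ones(20, int)]
        res = rgx.LogisticOVA(X, y, 1, identity_params(["x"])).fit(penalty_grid=(0.01,))
        from sklearn.metrics import roc_auc_score

        assert roc_auc_score(y, res.predict(X)) == 1.0

    def test_separation_with_zero_penalty_falls_back(self):
        X = pd.DataFrame({"x": np.r_[-np.ones(10), np.ones(10)]})
        y = np.r_[np.zeros(10, int), np.ones(10, int)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = rgx.LogisticOVA(X, y, 1, identity_params(["x"])).fit(
                penalty_grid=(0.0, 0.01)
            )
        assert np.isfinite(res.coefficients).all()

    def test_single_class_rejected(self):
        X = pd.DataFrame({"x": np.arange(10.0)})
        with pytest.raises(ModelError):
            rgx.LogisticOVA(X, np.ones(10, int), 1, identity_params(["x"]))


class TestCox:
    def test_published_model_risk_at_origin_and_hr(self):
        params = TransformParams.from_dict(
            {
                "GTV": {"lambda": 1.0, "shift": 0.170, "scale": 0.824},
                "log_stat_p90": {"lambda": 0.0, "shift": 1.256, "scale": 0.499},
                "E2F_targets": {"lambda": 1.0, "shift": -0.014, "scale": 0.416},
                "Hedgehog_signalling": {"lambda": 0.0, "shift": -0.055, "scale": 0.280},
            }
        )
        hrs = {
            "GTV": 1.196,
            "log_stat_p90": 1.393,
            "E2F_targets": 0.774,
            "Hedgehog_signalling": 1.329,
        }
        model = rgx.FittedModel(
            model_kind="cox",
            features=list(hrs),
            coefficients=pd.Series({f: np.log(h) for f, h in hrs.items()}),
            transform_params=params,
        )
        from rgx.transforms import yeo_johnson_inverse

        raw_z0 = pd.DataFrame(
            {
                f: [yeo_johnson_inverse(np.array([params.table.loc[f, "shift"]]),
                                        params.table.loc[f, "lam"])[0]]
                for f in hrs
            }
        )
        assert model.predict(raw_z0)[0] == pytest.approx(1.0, abs=1e-9)
        # one z-unit increase of log_stat_p90 multiplies the hazard by 1.393
        raw_z1 = raw_z0.copy()
        shift, scale = params.table.loc["log_stat_p90", ["shift", "scale"]]
        raw_z1["log_stat_p90"] = yeo_johnson_inverse(
            np.array([shift + scale]), 0.0
        )[0]
        ratio = model.predict(raw_z1)[0] / model.predict(raw_z0)[0]
        assert ratio == pytest.approx(1.393, abs=1e-9)
        assert model.hazard_ratios["log_stat_p90"] == pytest.approx(1.393, rel=1e-12)

    def test_hazard_ratio_two_recovered_on_average(self):
        rng = np.random.default_rng(0)
        hrs = []
        for _ in range(50):
            x = rng.integers(0, 2, 500).astype(float)
            t_event = rng.exponential(1 / (0.05 * np.exp(np.log(2) * x)))
            c = rng.uniform(0, 60, 500)
            t, e = np.minimum(t_event, c), (t_event <= c).astype(int)
            X = pd.DataFrame({"x": x})
            res = rgx.CoxPH(X, t, e, identity_params(["x"])).fit()
            hrs.append(float(res.hazard_ratios["x"]))
        assert 1.7 <= np.mean(hrs) <= 2.3

    def test_all_zero_coefficients_give_unit_risk(self):
        params = identity_params(["a", "b"])
        model = rgx.FittedModel(
            model_kind="cox",
            features=["a", "b"],
            coefficients=pd.Series({"a": 0.0, "b": 0.0}),
            transform_params=params,
        )
        risks = model.predict(pd.DataFrame({"a": [1.0, -2.0], "b": [0.5, 3.0]}))
        np.testing.assert_allclose(risks, 1.0)

    def test_no_events_rejected(self):
        X = pd.DataFrame({"x": np.arange(20.0)})
        with pytest.raises(ModelError):
            rgx.CoxPH(X, np.ones(20), np.zeros(20, int), identity_params(["x"]))

    def test_missing_feature_named_in_error(self):
        params = identity_params(["a"])
        model = rgx.FittedModel(
            model_kind="cox",
            features=["a"],
            coefficients=pd.Series({"a": 1.0}),
            transform_params=params,
        )
        with pytest.raises(ModelError, match="a"):
            model.predict(pd.DataFrame({"b": [1.0]}))


class TestPersistence:
    def test_json_round_trip_preserves_predictions(self, tmp_path):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"a": rng.gamma(2, 1, 100), "b": rng.normal(0, 1, 100)})
        y = (X["a"] > 2).astype(int).to_numpy()
        params = fit_transforms(X)
        res = rgx.LogisticOVA(apply_transforms(X, params), y, 1, params).fit(
            penalty_grid=(0.01,)
        )
        path = tmp_path / "model.json"
        res.to_json(path)
        back = rgx.FittedModel.from_json(path)
        np.testing.assert_allclose(
            res.predict(X).to_numpy(), back.predict(X).to_numpy(), atol=1e-12
        )
        assert back.model_kind == "logistic_ova"
        assert back.penalty == res.penalty


class TestLeakFreedom:
    def test_validation_mutation_changes_nothing_fitted(self, tiny_cohort):
        cohort = tiny_cohort
        disc = cohort.discovery_ids
        feats = cohort.features[["morph_volume", "stat_p90", "szm_glnu"]]
        clin = cohort.clinical.set_index("id")
        params = fit_transforms(feats.loc[disc])
        z = apply_transforms(feats.loc[disc], params)
        res = rgx.CoxPH(
            z, clin.loc[disc, "time_months"], clin.loc[disc, "event"], params
        ).fit()
        rule, _ = rgx.stratification_threshold(
            res.predict(feats.loc[disc]),
            clin.loc[disc, "time_months"],
            clin.loc[disc, "event"],
            "fit",
        )
        # mutate every validation value and refit everything from discovery
        feats2 = feats.copy()
        val = cohort.validation_ids
        feats2.loc[val] = feats2.loc[val] * 3 + 11
        params2 = fit_transforms(feats2.loc[disc])
        res2 = rgx.CoxPH(
            apply_transforms(feats2.loc[disc], params2),
            clin.loc[disc, "time_months"],
            clin.loc[disc, "event"],
            params2,
        ).fit()
        rule2, _ = rgx.stratification_threshold(
            res2.predict(feats2.loc[disc]),
            clin.loc[disc, "time_months"],
            clin.loc[disc, "event"],
            "fit",
        )
        pd.testing.assert_frame_equal(params.table, params2.table)
        pd.testing.assert_series_equal(res.coefficients, res2.coefficients)
        assert rule.threshold == rule2.threshold
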