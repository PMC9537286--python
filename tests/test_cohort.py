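"""Synthetic cohort generator: determinism, planted effects, round trips."""

import numpy as np
import pandas as pd
import pytest

import rgx
from rgx.cohort import E2F_SET, HEDGEHOG_SET
from rgx.errors import ConfigError, SizingError


class TestTumourVolume:
    def test_zero_noise_case_is_a_uniform_sphere(self):
        vol, mask = rgx.generate_tumour_volume(
            0.0, 0.0, 16.0, (1, 1, 1), seed=0, include_outliers=False
        )
        inside = vol.intensities[mask.morphological]
        assert len(np.unique(inside)) == 1
        # discrete sphere: voxel count close to (4/3) pi r^3
        analytic = 4 / 3 * np.pi * 8.0**3
        assert mask.morphological.sum() == pytest.approx(analytic, rel=0.05)

    def test_same_seed_identical_arrays(self):
        a = rgx.generate_tumour_volume(0.3, 0.5, 18.0, (1, 1, 2), seed=9)
        b = rgx.generate_tumour_volume(0.3, 0.5, 18.0, (1, 1, 2), seed=9)
        np.testing.assert_array_equal(a[0].intensities, b[0].intensities)
        np.testing.assert_array_equal(a[1].morphological, b[1].morphological)

    def test_mask_is_single_connected_component(self):
        from scipy import ndimage

        for seed in range(5):
            _, mask = rgx.generate_tumour_volume(0.9, 0.5, 16.0, (1, 1, 1), seed=seed)
            _, n = ndimage.label(mask.morphological)
            assert n == 1

    def test_inclusions_outside_hu_window(self):
        vol, mask = rgx.generate_tumour_volume(0.2, 0.3, 20.0, (1, 1, 1), seed=1)
        inside = vol.intensities[mask.morphological]
        assert inside.min() < -150
        assert inside.max() > 180

    def test_shape_irregularity_lowers_bounding_box_density(self):
        # planted-effect monotonicity via the feature extractor, 20 seeds
        def density(shape, seed):
            vol, mask = rgx.generate_tumour_volume(
                shape, 0.0, 18.0, (1, 1, 1), seed=seed, include_outliers=False
            )
            fv = rgx.extract_features(vol, None, mask)
            return fv.values["morph_vol_dens_aabb"]

        regular = [density(0.0, s) for s in range(20)]
        irregular = [density(0.8, s) for s in range(20)]
        assert np.mean(irregular) < np.mean(regular)

    def test_texture_raises_grey_level_nonuniformity(self):
        def glnu(texture, seed):
            vol, mask = rgx.generate_tumour_volume(
                0.0, texture, 18.0, (1, 1, 1), seed=seed, include_outliers=False
            )
            base, logv, mask_p = rgx.preprocess(vol, mask)
            return rgx.extract_features(base, logv, mask_p).values["szm_glnu"]

        smooth = [glnu(0.1, s) for s in range(20)]
        rough = [glnu(0.9, s) for s in range(20)]
        assert np.mean(rough) > np.mean(smooth)

    def test_degenerate_sizing_rejected(self):
        with pytest.raises(SizingError):
            rgx.generate_tumour_volume(0.2, 0.2, -5.0, (1, 1, 1), 0)
        with pytest.raises(SizingError):
            rgx.generate_tumour_volume(0.2, 0.2, 10.0, (0.0, 1, 1), 0)


class TestExpression:
    def test_noise_free_samples_correlate_perfectly(self, centroids):
        expr = rgx.generate_expression(4, centroids, list(centroids.columns), 0.0, seed=0)
        asg = rgx.assign_subtypes(expr, centroids)
        for i, c in enumerate(centroids.columns):
            assert asg.correlations.iloc[i][c] == pytest.approx(1.0)

    def test_batch_shift_visible_before_harmonisation(self, centroids):
        labels = ["basal"] * 40
        batches = ["a"] * 20 + ["b"] * 20
        expr = rgx.generate_expression(
            40, centroids, labels, 0.5,
            batch_labels=batches,
            batch_effects={"b": {"shift": 2.0, "scale": 1.0}},
            seed=1,
        )
        gap = expr.iloc[:, 20:].mean(axis=1) - expr.iloc[:, :20].mean(axis=1)
        assert gap.mean() == pytest.approx(2.0, abs=0.1)

    def test_label_count_mismatch_rejected(self, centroids):
        with pytest.raises(ConfigError):
            rgx.generate_expression(3, centroids, ["basal"], 0.1, seed=0)

    def test_unknown_label_rejected(self, centroids):
        with pytest.raises(ConfigError):
            rgx.generate_expression(1, centroids, ["weird"], 0.1, seed=0)


class TestOutcomes:
    def test_no_censoring_all_events(self):
        rng = np.random.default_rng(0)
        design = pd.DataFrame({"f": rng.normal(0, 1, 200)})
        out = rgx.generate_outcomes(design, {"f": 0.3}, 0.02, 0.0, seed=1)
        assert (out["event"] == 1).all()
        assert (out["time_months"] > 0).all()

    def test_censoring_rate_calibrated(self):
        rng = np.random.default_rng(1)
        design = pd.DataFrame({"f": rng.normal(0, 1, 3000)})
        out = rgx.generate_outcomes(design, {"f": 0.0}, 0.02, 0.4, seed=2)
        assert 1 - out["event"].mean() == pytest.approx(0.4, abs=0.03)

    def test_unit_coefficient_recovered_by_cox(self):
        from rgx.transforms import TransformParams

        rng = np.random.default_rng(2)
        params = TransformParams(
            pd.DataFrame({"lam": 1.0, "shift": 0.0, "scale": 1.0}, index=["f"])
        )
        betas = []
        for rep in range(20):
            design = pd.DataFrame({"f": rng.normal(0, 1, 500)})
            out = rgx.generate_outcomes(design, {"f": 1.0}, 0.02, 0.2, seed=rep)
            res = rgx.CoxPH(design, out["time_months"], out["event"], params).fit()
            betas.append(float(res.coefficients["f"]))
        assert np.mean(betas) == pytest.approx(1.0, abs=0.1)

    def test_null_model_logrank_type_one_error(self):
        # with all hazard coefficients zero, a median split of any feature
        # gives uniform log-rank p-values: ~5% rejections at alpha = 0.05
        rng = np.random.default_rng(3)
        rejections = 0
        reps = 200
        for rep in range(reps):
            design = pd.DataFrame({"f": rng.normal(0, 1, 100)})
            out = rgx.generate_outcomes(design, {"f": 0.0}, 0.03, 0.2, seed=500 + rep)
            groups = (design["f"] > design["f"].median()).astype(int)
            _, _, p = rgx.km_logrank(out["time_months"], out["event"], groups)
            rejections += p < 0.05
        assert 0.02 <= rejections / reps <= 0.08

    def test_missing_coefficient_name_rejected(self):
        design = pd.DataFrame({"f": [1.0, 2.0]})
        with pytest.raises(ConfigError):
            rgx.generate_outcomes(design, {"g": 1.0}, 0.02, 0.2, seed=0)
        with pytest.raises(ConfigError):
            rgx.generate_outcomes(design, {"f": 1.0}, -0.1, 0.2, seed=0)


class TestFullCohort:
    def test_split_sizes_match_design(self, tiny_cohort):
        clin = tiny_cohort.clinical
        assert (clin["split"] == "discovery").sum() == 18
        assert (clin["split"] == "validation").sum() == 12
        assert clin["event"].isin([0, 1]).all()
        assert (clin["time_months"] > 0).all()

    def test_deterministic_regeneration(self, tiny_cohort):
        again = rgx.generate_cohort(tiny_cohort.config)
        pd.testing.assert_frame_equal(tiny_cohort.expression, again.expression)
        pd.testing.assert_frame_equal(tiny_cohort.features, again.features)
        pd.testing.assert_frame_equal(tiny_cohort.clinical, again.clinical)
        for pid in tiny_cohort.ids[:3]:
            np.testing.assert_array_equal(
                tiny_cohort.volumes[pid][0].intensities,
                again.volumes[pid][0].intensities,
            )

    def test_seed_changes_noise_not_layout(self, tiny_cohort):
        import dataclasses

        cfg2 = dataclasses.replace(tiny_cohort.config, seed=43)
        other = rgx.generate_cohort(cfg2)
        assert list(other.expression.index) == list(tiny_cohort.expression.index)
        assert list(other.expression.columns) == list(tiny_cohort.expression.columns)
        assert not np.allclose(
            other.expression.to_numpy(), tiny_cohort.expression.to_numpy()
        )

    def test_written_layout_round_trips(self, tiny_cohort, tmp_path):
        from rgx import io as rgx_io

        rgx_io.write_cohort(tiny_cohort, tmp_path)
        back = rgx_io.read_cohort_tables(tmp_path)
        pd.testing.assert_frame_equal(
            back["expression"], tiny_cohort.expression, check_names=False
        )
        pd.testing.assert_frame_equal(back["clinical"], tiny_cohort.clinical)
        vol, mask = rgx_io.load_patient_image(tmp_path, tiny_cohort.ids[0])
        orig_vol, orig_mask = tiny_cohort.volumes[tiny_cohort.ids[0]]
        np.testing.assert_allclose(vol.intensities, orig_vol.intensities, atol=1e-5)
        np.testing.assert_array_equal(mask.morphological, orig_mask.morphological)
        assert vol.spacing == pytest.approx(orig_vol.spacing)

    def test_truth_contains_planted_structure(self, tiny_cohort):
        truth = tiny_cohort.truth
        assert set(truth["signature_classes"]) == {HEDGEHOG_SET, E2F_SET}
        assert set(truth["subtype"].unique()) <= {
            "atypical", "basal", "classical", "mesenchymal", "unclassified"
        }
        assert len(truth["lp_true"]) == 30

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigError):
            rgx.CohortConfig(n_discovery=0)
        with pytest.raises(ConfigError):
            rgx.CohortConfig(subtype_proportions=(0.5, 0.5, 0.5, 0.5))
        with pytest.raises(ConfigError):
            rgx.CohortConfig(censoring_rate=1.5)
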