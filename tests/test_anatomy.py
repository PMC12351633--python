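import numpy as np
import pandas as pd
import pytest

from tesgroup.anatomy import (
    feature_diffs,
    features_table,
    fit_feature_regression,
    geodesic_distance,
    geodesic_perimeters,
    loso_predict,
)
from tesgroup.cohort import CohortSpec, generate_cohort
from tesgroup.geometry import CorticalSurface, icosphere


def _uv_sphere(radius: float, lat: int = 17, lon: int = 24) -> CorticalSurface:
    """UV sphere with exact pole and equator vertices (via trimesh)."""
    import trimesh

    m = trimesh.creation.uv_sphere(radius=radius, count=(lat, lon))
    return CorticalSurface(np.asarray(m.vertices), np.asarray(m.faces))


class TestGeodesics:
    def test_great_circle_arcs_within_half_percent(self, rng):
        surf = icosphere(3, 92.0)
        dirs = surf.unit_directions()
        for _ in range(15):
            i, j = rng.integers(0, surf.n_nodes, 2)
            if i == j:
                continue
            theta = np.arccos(np.clip(dirs[i] @ dirs[j], -1, 1))
            d = geodesic_distance(surf, int(i), int(j))
            assert d == pytest.approx(92.0 * theta, rel=0.005)

    def test_coincident_landmarks_give_zero(self, sphere642):
        assert geodesic_distance(sphere642, 10, 10) == 0.0

    def test_sagittal_chain_is_half_circumference(self):
        surf = _uv_sphere(92.0)
        dirs = surf.unit_directions()
        landmarks = {
            "Nz": int(np.argmax(dirs @ [0, 1, 0])),
            "Iz": int(np.argmax(dirs @ [0, -1, 0])),
            "LPA": int(np.argmax(dirs @ [-1, 0, 0])),
            "RPA": int(np.argmax(dirs @ [1, 0, 0])),
            "Cz": int(np.argmax(dirs @ [0, 0, 1])),
        }
        perims = geodesic_perimeters(surf, landmarks)

        def arc(a, b):
            return 92.0 * np.arccos(np.clip(dirs[landmarks[a]] @ dirs[landmarks[b]], -1, 1))

        # expected chains from the snapped landmark nodes (two half-great-circle
        # chains and the three-quarter axial chain, up to landmark snapping)
        assert perims["sagittal_perimeter"] == pytest.approx(
            arc("Nz", "Cz") + arc("Cz", "Iz"), rel=0.005
        )
        assert perims["coronal_distance"] == pytest.approx(
            arc("LPA", "Cz") + arc("Cz", "RPA"), rel=0.005
        )
        assert perims["axial_perimeter"] == pytest.approx(
            arc("Nz", "LPA") + arc("LPA", "Iz") + arc("Iz", "RPA"), rel=0.005
        )
        # and the idealised values hold up to the landmark snapping error
        assert perims["sagittal_perimeter"] == pytest.approx(np.pi * 92.0, rel=0.07)
        assert perims["axial_perimeter"] == pytest.approx(1.5 * np.pi * 92.0, rel=0.07)

    def test_perimeters_scale_linearly_with_coordinates(self):
        surf = icosphere(2, 1.0)
        big = CorticalSurface(surf.nodes * 92.0, surf.triangles)
        d_unit = geodesic_distance(surf, 3, 100)
        d_big = geodesic_distance(big, 3, 100)
        assert d_big == pytest.approx(92.0 * d_unit, rel=1e-9)

    def test_missing_landmark_is_an_error(self, sphere642):
        with pytest.raises(ValueError, match="missing landmarks"):
            geodesic_perimeters(sphere642, {"Nz": 0, "Iz": 1})


class TestFeatureTables:
    def test_normalized_features_sum_to_one(self, featured_cohort):
        table = features_table(featured_cohort)
        dist_norm = table[
            ["axial_perimeter_norm", "sagittal_perimeter_norm", "coronal_distance_norm"]
        ].sum(axis=1)
        np.testing.assert_allclose(dist_norm, 1.0)
        vol_norm = table[[c for c in table.columns if c.endswith("_vol_norm")]].sum(axis=1)
        np.testing.assert_allclose(vol_norm, 1.0)

    def test_diffs_are_antisymmetric(self, featured_cohort):
        d01 = feature_diffs(featured_cohort, featured_cohort[0].subject_id)
        d10 = feature_diffs(featured_cohort, featured_cohort[1].subject_id)
        s0, s1 = featured_cohort[0].subject_id, featured_cohort[1].subject_id
        np.testing.assert_allclose(d01.loc[s1], -d10.loc[s0], atol=1e-12)

    def test_template_excluded_from_diffs(self, featured_cohort):
        tid = featured_cohort[0].subject_id
        assert tid not in feature_diffs(featured_cohort, tid).index

    def test_zero_jitter_cohort_has_zero_diffs(self):
        cohort = generate_cohort(
            CohortSpec(
                n_subjects=3, seed=1, radius_jitter=0.0,
                surface_subdivisions=2, tet_subdivisions=1,
            )
        )
        diffs = feature_diffs(cohort, cohort[0].subject_id)
        np.testing.assert_allclose(diffs.to_numpy(), 0.0, atol=1e-9)

    def test_missing_features_are_an_error(self, cohort6):
        with pytest.raises(ValueError, match="no features"):
            features_table(cohort6)


def _diff_frame(rng, n=54, p=5):
    return pd.DataFrame(
        rng.normal(0, 1, (n, p)), columns=[f"f{i}" for i in range(p)],
        index=[f"s{i}" for i in range(n)],
    )


class TestFeatureRegression:
    def test_exact_linear_response_has_r2_one(self, rng):
        X = _diff_frame(rng)
        y = 2.0 * X["f1"] - 0.5 * X["f3"]
        fit = fit_feature_regression(X, y, order=1)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.coefficients["f1"] == pytest.approx(2.0, abs=1e-9)

    def test_pure_noise_has_low_median_r2(self, rng):
        r2 = []
        for _ in range(200):
            X = _diff_frame(rng, n=100)
            y = rng.normal(0, 1, 100)
            r2.append(fit_feature_regression(X, y, order=1).r_squared)
        assert np.median(r2) < 0.1

    def test_second_order_recovery_within_2_se(self, rng):
        X = _diff_frame(rng, n=200, p=3)
        y = 1.5 * X["f0"] + 2.0 * X["f0"] * X["f1"] + rng.normal(0, 0.3, 200)
        fit = fit_feature_regression(X, y, order=2)
        assert abs(fit.coefficients["f0"] - 1.5) < 2 * fit.bse["f0"]
        assert abs(fit.coefficients["f0 f1"] - 2.0) < 2 * fit.bse["f0 f1"]
        misfit = fit_feature_regression(X, y, order=1)
        assert misfit.r_squared < fit.r_squared - 0.1

    def test_rank_deficiency_suggests_pca(self, rng):
        X = _diff_frame(rng, n=30, p=4)
        X["f4"] = X["f0"] + X["f1"]  # exactly collinear
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_feature_regression(X, rng.normal(0, 1, 30), order=1)
        fit = fit_feature_regression(X, rng.normal(0, 1, 30), order=1, use_pca=True,
                                     pca_components=3)
        assert fit.n_components == 3

    def test_pca_cv_selects_valid_component_count(self, rng):
        X = _diff_frame(rng, n=25, p=4)
        y = X["f0"] + rng.normal(0, 0.1, 25)
        fit = fit_feature_regression(X, y, order=1, use_pca=True, pca_components="cv")
        assert 1 <= fit.n_components <= 4

    def test_overparameterised_without_pca_is_an_error(self, rng):
        X = _diff_frame(rng, n=10, p=5)
        with pytest.raises(ValueError, match="PCA"):
            fit_feature_regression(X, rng.normal(0, 1, 10), order=2)


class TestLosoPredict:
    def test_noiseless_linear_response_predicts_perfectly(self, rng):
        X = _diff_frame(rng)
        y = 3.0 * X["f0"] - 1.0 * X["f2"] + 0.5
        preds, obs, r2 = loso_predict(X, y, order=1)
        assert r2 == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(preds, obs, atol=1e-9)

    def test_prediction_is_independent_of_own_response(self, rng):
        X = _diff_frame(rng, n=20)
        y = (X["f0"] + rng.normal(0, 0.2, 20)).to_numpy()
        preds_a, _, _ = loso_predict(X, y, order=1)
        y2 = y.copy()
        y2[5] += 100.0  # only subject 5's own response changes
        preds_b, _, _ = loso_predict(X, y2, order=1)
        assert preds_a[5] == pytest.approx(preds_b[5], rel=1e-12)

    def test_loso_r2_below_insample_r2(self, rng):
        worse = 0
        for rep in range(20):
            X = _diff_frame(rng, n=30)
            y = X["f0"] + rng.normal(0, 1.0, 30)
            fit = fit_feature_regression(X, y, order=1)
            _, _, r2 = loso_predict(X, y, order=1)
            worse += r2 <= fit.r_squared
        assert worse >= 19  # held-out fit cannot beat in-sample, bar rare ties

    def test_recovers_planted_signal_to_noise(self, rng):
        # R^2 of a linear signal with noise concentrates near var_s/(var_s+var_n)
        r2s = []
        for _ in range(50):
            X = _diff_frame(rng, n=54, p=3)
            y = X["f0"] + rng.normal(0, 0.5, 54)
            _, _, r2 = loso_predict(X, y, order=1)
            r2s.append(r2)
        expected = 1.0 / (1.0 + 0.25)
        assert np.median(r2s) == pytest.approx(expected, abs=0.08)

    def test_feature_subset_restriction(self, rng):
        X = _diff_frame(rng, n=20)
        y = X["f1"]
        _, _, r2 = loso_predict(X, y, order=1, feature_subset=["f1"])
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_needs_three_subjects(self, rng):
        X = _diff_frame(rng, n=2)
        with pytest.raises(ValueError, match="at least 3"):
            loso_predict(X, [0.0, 1.0])
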