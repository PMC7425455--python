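import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vrfmed.glm import StatMap, build_design, fit_ancova, fit_glm, t_to_z


@pytest.fixture
def toy_cohort(rng):
    n = 40
    return pd.DataFrame(
        {
            "subject_id": [f"S{i}" for i in range(n)],
            "group": np.repeat(["CN", "EMCI", "LMCI", "AD"], n // 4),
            "vrf_score": rng.integers(0, 6, n).astype(float),
            "mmse": rng.normal(27, 2, n),
            "age": rng.normal(72, 6, n),
            "gender": rng.integers(0, 2, n).astype(float),
            "education_years": rng.normal(16, 2, n),
            "apoe": rng.integers(0, 2, n).astype(float),
        }
    )


def toy_images(rng, n, shape=(6, 6, 6)):
    return rng.normal(size=(n,) + shape)


class TestBuildDesign:
    def test_six_columns_with_four_covariates(self, toy_cohort):
        d = build_design(toy_cohort, "vrf_score", ["age", "gender", "education_years", "apoe"])
        assert d.p == 6
        assert d.names[:2] == ["intercept", "vrf_score"]

    def test_group_dummies_add_three(self, toy_cohort):
        d = build_design(
            toy_cohort, "vrf_score", ["age", "gender", "education_years", "apoe", "group"]
        )
        assert d.p == 9
        assert sum(n.startswith("group_") for n in d.names) == 3

    def test_constant_predictor_rank_error(self, toy_cohort):
        toy_cohort = toy_cohort.assign(const=1.0)
        with pytest.raises(ValueError, match="rank deficient"):
            build_design(toy_cohort, "const", ["age"])

    def test_collinear_columns_named(self, toy_cohort):
        toy_cohort = toy_cohort.assign(age2=toy_cohort["age"] * 2.0)
        with pytest.raises(ValueError, match="age2"):
            build_design(toy_cohort, "vrf_score", ["age", "age2"])

    def test_predictor_swap_same_shape(self, toy_cohort):
        covs = ["age", "gender", "education_years", "apoe"]
        d1 = build_design(toy_cohort, "vrf_score", covs)
        d2 = build_design(toy_cohort, "mmse", covs)
        assert d1.X.shape == d2.X.shape

    def test_missing_column_errors(self, toy_cohort):
        with pytest.raises(ValueError, match="not in cohort"):
            build_design(toy_cohort, "nope", [])


class TestFitGlm:
    def test_exact_linear_construction(self, toy_cohort):
        n = len(toy_cohort)
        x = toy_cohort["vrf_score"].to_numpy()
        images = np.empty((n, 5, 5, 5))
        images[:] = (3.0 + 2.0 * x)[:, None, None, None]
        mask = np.ones((5, 5, 5), dtype=bool)
        design = build_design(toy_cohort, "vrf_score", [])
        res = fit_glm(images, mask, design)
        np.testing.assert_allclose(res.beta.data[mask], 2.0, atol=1e-10)
        # zero residual variance everywhere: flagged, t = +inf
        assert res.flagged_voxels[mask].all()
        assert np.isposinf(res.t.data[mask]).all()

    def test_normal_equations_oracle(self, rng, toy_cohort):
        # independent brute-force (X'X)^-1 X'y per voxel
        n = len(toy_cohort)
        images = toy_images(rng, n)
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[1:5, 1:5, 1:5] = True
        design = build_design(toy_cohort, "vrf_score", ["age", "gender", "apoe"])
        res = fit_glm(images, mask, design)
        X = design.X
        for idx in np.argwhere(mask)[::7]:
            y = images[:, idx[0], idx[1], idx[2]]
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            resid = y - X @ beta
            se = np.sqrt(
                resid @ resid / (n - X.shape[1]) * np.linalg.inv(X.T @ X)[1, 1]
            )
            assert res.beta.data[tuple(idx)] == pytest.approx(beta[1], abs=1e-10)
            assert res.t.data[tuple(idx)] == pytest.approx(beta[1] / se, abs=1e-8)

    def test_permutation_null_calibration(self):
        rng = np.random.default_rng(123)
        n = 40
        images = rng.normal(size=(n, 10, 10, 10))  # 1000 voxels
        mask = np.ones((10, 10, 10), dtype=bool)
        cohort = pd.DataFrame({"x": rng.permutation(np.linspace(0, 5, n))})
        design = build_design(cohort, "x", [])
        res = fit_glm(images, mask, design)
        p = 2 * stats.t.sf(np.abs(res.t.data[mask]), res.df_resid)
        frac = (p < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_covariate_centering_invariance(self, rng, toy_cohort):
        images = toy_images(rng, len(toy_cohort))
        mask = np.ones((6, 6, 6), dtype=bool)
        d1 = build_design(toy_cohort, "vrf_score", ["age"])
        centered = toy_cohort.assign(age=toy_cohort["age"] - toy_cohort["age"].mean())
        d2 = build_design(centered, "vrf_score", ["age"])
        r1 = fit_glm(images, mask, d1)
        r2 = fit_glm(images, mask, d2)
        np.testing.assert_allclose(r1.beta.data, r2.beta.data, atol=1e-10)

    def test_intensity_rescaling(self, rng, toy_cohort):
        images = toy_images(rng, len(toy_cohort))
        mask = np.ones((6, 6, 6), dtype=bool)
        d = build_design(toy_cohort, "vrf_score", ["age"])
        r1 = fit_glm(images, mask, d)
        r2 = fit_glm(images * 10.0, mask, d)
        np.testing.assert_allclose(r2.beta.data, 10.0 * r1.beta.data, atol=1e-8)
        np.testing.assert_allclose(r2.t.data, r1.t.data, atol=1e-8)

    def test_single_predictor_matches_pearson_t(self, rng):
        n = 30
        x = rng.normal(size=n)
        images = rng.normal(size=(n, 2, 2, 2))
        mask = np.ones((2, 2, 2), dtype=bool)
        design = build_design(pd.DataFrame({"x": x}), "x", [])
        res = fit_glm(images, mask, design)
        for idx in np.argwhere(mask):
            y = images[:, idx[0], idx[1], idx[2]]
            r, _ = stats.pearsonr(x, y)
            t_ref = r * np.sqrt((n - 2) / (1 - r**2))
            assert res.t.data[tuple(idx)] == pytest.approx(t_ref, abs=1e-8)

    def test_row_mismatch_errors(self, rng, toy_cohort):
        design = build_design(toy_cohort, "vrf_score", [])
        with pytest.raises(ValueError, match="design rows"):
            fit_glm(toy_images(rng, 10), np.ones((6, 6, 6), dtype=bool), design)


class TestTtoZ:
    def test_probability_preserving(self):
        for t_val, df in [(1.3, 10), (-2.1, 30), (3.7, 5)]:
            z = t_to_z(np.array([t_val]), df)[0]
            assert stats.norm.sf(abs(z)) == pytest.approx(
                stats.t.sf(abs(t_val), df), rel=1e-10
            )
            assert np.sign(z) == np.sign(t_val)

    def test_large_df_z_close_to_t(self):
        t_vals = np.linspace(-4, 4, 17)
        z = t_to_z(t_vals, df=500)
        nonzero = t_vals != 0
        assert np.all(np.abs(z[nonzero] - t_vals[nonzero]) / np.abs(t_vals[nonzero]) < 0.02)

    def test_infinite_t_passes_through(self):
        z = t_to_z(np.array([np.inf, -np.inf]), 10)
        assert np.isposinf(z[0]) and np.isneginf(z[1])


class TestAncova:
    def test_no_group_effect_f_zero(self):
        rng = np.random.default_rng(3)
        n = 24
        age = rng.normal(size=n)
        images = np.empty((n, 4, 4, 4))
        images[:] = (1.0 + 0.5 * age)[:, None, None, None]  # covariate effect only
        mask = np.ones((4, 4, 4), dtype=bool)
        labels = np.repeat(list("abcd"), 6)
        fmap = fit_ancova(images, mask, labels, age)
        assert np.all(fmap.data[mask] < 1e-10)

    def test_constructed_group_effect_detected(self):
        rng = np.random.default_rng(4)
        n = 40
        noise_sd = 0.1
        images = rng.normal(0, noise_sd, size=(n, 8, 8, 8))
        labels = np.repeat(list("abcd"), 10)
        roi = np.zeros((8, 8, 8), dtype=bool)
        roi[2:5, 2:5, 2:5] = True
        sel = labels == "d"
        lowered = images[sel]
        lowered[:, roi] -= 5 * noise_sd
        images[sel] = lowered
        mask = np.ones((8, 8, 8), dtype=bool)
        fmap = fit_ancova(images, mask, labels, None)
        crit = stats.f.ppf(0.999, *fmap.df)
        assert fmap.data[roi].min() > crit

    def test_nested_rss_oracle(self, rng):
        n = 30
        images = rng.normal(size=(n, 5, 5, 5))
        labels = np.repeat(["x", "y", "z"], 10)
        covs = rng.normal(size=(n, 2))
        mask = np.ones((5, 5, 5), dtype=bool)
        fmap = fit_ancova(images, mask, labels, covs)
        dummies = np.column_stack([(labels == "y").astype(float), (labels == "z").astype(float)])
        X_red = np.column_stack([np.ones(n), covs])
        X_full = np.column_stack([X_red, dummies])
        for idx in np.argwhere(mask)[::13]:
            y = images[:, idx[0], idx[1], idx[2]]
            rss_f = np.sum((y - X_full @ np.linalg.lstsq(X_full, y, rcond=None)[0]) ** 2)
            rss_r = np.sum((y - X_red @ np.linalg.lstsq(X_red, y, rcond=None)[0]) ** 2)
            f_ref = ((rss_r - rss_f) / 2) / (rss_f / (n - X_full.shape[1]))
            assert fmap.data[tuple(idx)] == pytest.approx(f_ref, abs=1e-9)
        assert fmap.df == (2.0, float(n - X_full.shape[1]))

    def test_small_group_rejected(self, rng):
        images = rng.normal(size=(5, 3, 3, 3))
        with pytest.raises(ValueError, match="n >= 2"):
            fit_ancova(images, np.ones((3, 3, 3), bool), ["a", "a", "a", "a", "b"], None)


def test_statmap_shape_check():
    with pytest.raises(ValueError, match="shapes differ"):
        StatMap(np.zeros((3, 3, 3)), "t", (10.0,), np.ones((4, 4, 4), dtype=bool))
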