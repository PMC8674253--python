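"""Classic SMOTE and the Gaussian centroid-interpolation variant."""

import numpy as np
import pytest
from scipy import stats
from scipy.spatial.distance import cdist

from normsmote import (
    NormalSmoteConfig,
    SmoteConfig,
    ValidationError,
    expand,
    imbalance_ratio,
    knn_minority_neighbors,
    minority_center,
    minority_feature_stds,
    minority_profile,
    normal_smote_generate,
    normalize,
    partition_by_class,
    required_synthetic_count,
    smote_generate,
)


class TestMinorityProfile:
    def test_center_single_sample(self):
        np.testing.assert_array_equal(
            minority_center(np.array([[0.2, 0.8]])), [0.2, 0.8]
        )

    def test_center_is_columnwise_mean(self):
        rng = np.random.default_rng(1)
        m = rng.uniform(size=(100, 4))
        # independent oracle: explicit per-column summation
        oracle = np.array([sum(m[i, j] for i in range(100)) / 100 for j in range(4)])
        np.testing.assert_allclose(minority_center(m), oracle, atol=1e-12)

    def test_center_midpoint(self):
        np.testing.assert_array_equal(
            minority_center(np.array([[0.0, 0.0], [1.0, 1.0]])), [0.5, 0.5]
        )

    def test_std_uses_n_minus_1(self):
        m = np.array([[0.0], [1.0]])
        np.testing.assert_allclose(minority_feature_stds(m), [np.sqrt(0.5)])

    def test_std_constant_feature_is_zero(self):
        m = np.array([[0.3, 0.1], [0.3, 0.9], [0.3, 0.5]])
        stds = minority_feature_stds(m)
        assert stds[0] == 0.0 and stds[1] > 0.0

    def test_std_is_consistent_estimator(self):
        rng = np.random.default_rng(7)
        m = rng.normal(0.5, 0.1, size=(2000, 1))
        assert abs(minority_feature_stds(m)[0] - 0.1) < 0.01

    def test_std_requires_two_samples(self):
        with pytest.raises(ValidationError):
            minority_feature_stds(np.array([[0.1, 0.2]]))


class TestRequiredCount:
    @pytest.mark.parametrize(
        "n_min,n_maj,target,expected",
        [
            (268, 500, 0.7, 82),
            (45, 149, 0.7, 60),
            (400, 500, 0.7, 0),
            (0, 10, 0.5, 5),
            (212, 357, 0.7, 38),
        ],
    )
    def test_counts(self, n_min, n_maj, target, expected):
        assert required_synthetic_count(n_min, n_maj, target) == expected

    @pytest.mark.parametrize("n_min,n_maj", [(268, 500), (45, 149), (126, 225), (3, 97)])
    def test_minimality(self, n_min, n_maj):
        target = 0.7
        c = required_synthetic_count(n_min, n_maj, target)
        assert (n_min + c) / n_maj >= target
        if c > 0:
            assert (n_min + c - 1) / n_maj < target


class TestKnn:
    def test_colinear_points(self):
        m = np.array([[0.0], [1.0], [10.0]])
        np.testing.assert_array_equal(
            knn_minority_neighbors(m, 1).ravel(), [1, 0, 1]
        )

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        m = rng.uniform(size=(6, 2))
        got = knn_minority_neighbors(m, 2)
        d = cdist(m, m)
        for i in range(6):
            order = sorted(range(6), key=lambda j: (d[i, j], j))
            expected = [j for j in order if j != i][:2]
            assert got[i].tolist() == expected

    def test_duplicate_point_wins_tie_by_lower_index(self):
        m = np.array([[0.0], [0.0], [0.0], [2.0]])
        nb = knn_minority_neighbors(m, 2)
        assert nb[0].tolist() == [1, 2]
        assert nb[2].tolist() == [0, 1]

    def test_k_out_of_range(self):
        with pytest.raises(ValidationError):
            knn_minority_neighbors(np.zeros((3, 1)), 3)


class TestClassicSmote:
    def test_points_lie_on_segment(self):
        rng = np.random.default_rng(2)
        m = rng.uniform(size=(20, 3))
        syn = smote_generate(m, SmoteConfig(k=3, seed=4), 200)
        # every synthetic row must sit inside the bounding box of some pair
        lo, hi = m.min(axis=0), m.max(axis=0)
        assert np.all(syn >= lo - 1e-12) and np.all(syn <= hi + 1e-12)

    def test_recovered_u_in_unit_interval_and_uniform(self):
        # two-point minority set: every draw interpolates the same segment,
        # so the coefficient u is recoverable exactly
        m = np.array([[0.0, 0.0], [1.0, 1.0]])
        syn = smote_generate(m, SmoteConfig(k=1, seed=3), 1000)
        u = syn[:, 0]
        np.testing.assert_allclose(syn[:, 0], syn[:, 1], atol=1e-12)
        assert np.all((u >= 0.0) & (u <= 1.0))
        assert stats.kstest(u, "uniform").pvalue > 0.01

    def test_zero_count(self):
        m = np.array([[0.0], [1.0]])
        assert smote_generate(m, SmoteConfig(seed=0), 0).shape == (0, 1)

    def test_needs_two_samples(self):
        with pytest.raises(ValidationError):
            smote_generate(np.array([[0.0]]), SmoteConfig(seed=0), 5)


class TestNormalSmote:
    def test_interpolation_arithmetic(self):
        # x' = 0.2, center = 0.6, f = 1.1 -> 0.2 + 1.1 * 0.4 = 0.64
        x, center, f = 0.2, 0.6, 1.1
        assert x + f * (center - x) == pytest.approx(0.64)

    def test_source_equal_to_center_yields_center(self):
        # a source point sitting exactly at the centroid is fixed for any f
        m = np.array([[0.1, 0.9], [0.9, 0.1], [0.5, 0.5]])
        profile = minority_profile(m)  # center (0.5, 0.5), non-zero stds
        source = np.tile(profile.center, (2, 1))
        syn = normal_smote_generate(
            source, profile, NormalSmoteConfig(sigma_scale=1.0, seed=0), 10
        )
        np.testing.assert_allclose(syn, np.tile(profile.center, (10, 1)), atol=1e-12)

    def test_centroid_preservation(self):
        # E[p] = center since E[f] = 1; check the Monte-Carlo mean from one
        # fixed source point against the standard-error bound
        rng = np.random.default_rng(9)
        m = rng.uniform(size=(30, 3))
        profile = minority_profile(m)
        source = np.tile(m[0], (2, 1))  # single source repeated to satisfy n >= 2
        n_draws = 10_000
        syn = normal_smote_generate(
            source, profile, NormalSmoteConfig(sigma_scale=1.0, seed=13), n_draws
        )
        se = profile.stds * np.abs(profile.center - m[0]) / np.sqrt(n_draws)
        assert np.all(np.abs(syn.mean(axis=0) - profile.center) < 3 * np.maximum(se, 1e-12) + 1e-12)

    def test_coverage_probabilities_at_one_third_scale(self):
        # with spread sigma0/3 the factor lands within +-sigma0 of 1 w.p.
        # ~0.9974 and within +-sigma0/3 w.p. ~0.6826
        sigma0 = 0.12
        rng = np.random.default_rng(21)
        f = rng.normal(1.0, sigma0 / 3, size=1_000_000)
        assert abs(np.mean(np.abs(f - 1) <= sigma0) - 0.9974) < 0.002
        assert abs(np.mean(np.abs(f - 1) <= sigma0 / 3) - 0.6826) < 0.002

    def test_monotone_concentration_in_sigma_scale(self):
        rng = np.random.default_rng(30)
        m = rng.uniform(size=(40, 4))
        profile = minority_profile(m)
        mean_dists = []
        for scale in (1 / 3, 2 / 3, 1.0):
            syn = normal_smote_generate(
                m, profile, NormalSmoteConfig(sigma_scale=scale, seed=17), 10_000
            )
            mean_dists.append(np.linalg.norm(syn - profile.center, axis=1).mean())
        assert mean_dists[0] < mean_dists[1] < mean_dists[2]

    def test_all_constant_minority_warns_and_copies_center(self):
        m = np.tile([0.4, 0.6], (5, 1))
        profile = minority_profile(m)
        with pytest.warns(UserWarning, match="constant"):
            syn = normal_smote_generate(m, profile, NormalSmoteConfig(seed=0), 4)
        np.testing.assert_allclose(syn, np.tile([0.4, 0.6], (4, 1)), atol=1e-12)

    def test_clip_to_unit(self):
        rng = np.random.default_rng(3)
        m = rng.uniform(size=(10, 2))
        profile = minority_profile(m)
        syn = normal_smote_generate(
            m, profile, NormalSmoteConfig(sigma_scale=50.0, clip_to_unit=True, seed=1), 500
        )
        assert syn.min() >= 0.0 and syn.max() <= 1.0


class TestExpand:
    @pytest.mark.parametrize(
        "fixture_name,expected_synth,expected_n",
        [("pima_shaped", 82, 850), ("wpbc_shaped", 60, 254)],
    )
    @pytest.mark.parametrize("method", ["normal", "smote"])
    def test_stopping_rule(self, request, fixture_name, expected_synth, expected_n, method):
        d = request.getfixturevalue(fixture_name)
        cfg = (
            NormalSmoteConfig(seed=5)
            if method == "normal"
            else SmoteConfig(seed=5)
        )
        result = expand(d, method, cfg)
        assert result.synthetic.shape[0] == expected_synth
        assert result.fused.n == expected_n
        achieved = imbalance_ratio(result.fused)
        assert achieved >= 0.7
        # one fewer row would miss the target
        assert (result.fused.n_minority - 1) / result.fused.n_majority < 0.7

    def test_already_balanced_dataset_unchanged(self):
        rng = np.random.default_rng(8)
        from normsmote import Dataset

        feats = rng.uniform(size=(20, 2))
        labels = np.array(["pos"] * 10 + ["neg"] * 10)
        d = Dataset(feats, labels, "pos")
        result = expand(d, "normal", NormalSmoteConfig(seed=1))
        assert result.synthetic.shape[0] == 0
        norm, _ = normalize(d)
        np.testing.assert_array_equal(result.fused.features, norm.features)

    def test_determinism(self, wpbc_shaped):
        a = expand(wpbc_shaped, "normal", NormalSmoteConfig(sigma_scale=2 / 3, seed=99))
        b = expand(wpbc_shaped, "normal", NormalSmoteConfig(sigma_scale=2 / 3, seed=99))
        np.testing.assert_array_equal(a.synthetic, b.synthetic)
        np.testing.assert_array_equal(a.fused.features, b.fused.features)
        assert a.provenance == b.provenance

    def test_synthetic_rows_carry_minority_label(self, wpbc_shaped):
        result = expand(wpbc_shaped, "normal", NormalSmoteConfig(seed=2))
        assert np.all(result.fused.labels[-result.synthetic.shape[0]:] == "pos")

    def test_original_rows_unchanged(self, wpbc_shaped):
        result = expand(wpbc_shaped, "smote", SmoteConfig(seed=2))
        norm, _ = normalize(wpbc_shaped)
        np.testing.assert_array_equal(result.fused.features[: wpbc_shaped.n], norm.features)

    def test_provenance_counts(self, wpbc_shaped):
        prov = expand(wpbc_shaped, "normal", NormalSmoteConfig(seed=0)).provenance
        assert prov["n_synthetic"] == 60
        assert prov["n_minority_after"] == 105
        assert prov["achieved_ratio"] >= prov["target_ratio"]
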