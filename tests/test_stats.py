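import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mtbm.errors import DomainError, ValidationError
from mtbm.stats import (
    CorrelationMap,
    combine_structures,
    detj_ratio_map,
    hotelling_t2,
    hotelling_t2_f_pvalue,
    residualize,
    score_correlation_map,
    structurewise_correction,
    validate_cohort,
    vertexwise_permutation_test,
    volume_permutation_ttest,
)

LAB = np.array([True] * 10 + [False] * 13)


class TestResidualize:
    def test_exactly_linear_in_age_gives_zero(self, rng):
        ages = rng.uniform(9, 15, 23)
        feats = 2.0 + 0.3 * ages[:, None, None] * np.ones((23, 50, 4))
        resid = residualize(feats, ages)
        assert np.abs(resid).max() < 1e-10

    def test_residuals_orthogonal_to_age_and_centered(self, rng):
        ages = rng.uniform(9, 15, 23)
        feats = rng.normal(size=(23, 40, 4))
        resid = residualize(feats, ages)
        flat = resid.reshape(23, -1)
        assert np.abs(ages @ flat).max() < 1e-10
        assert np.abs(flat.mean(axis=0)).max() < 1e-10

    def test_age_independent_features_reduce_to_centering(self, rng):
        n = 200
        ages = rng.uniform(9, 15, n)
        feats = rng.normal(size=(n, 30))
        resid = residualize(feats, ages)
        centered = feats - feats.mean(axis=0)
        r = np.corrcoef(resid.ravel(), centered.ravel())[0, 1]
        assert r > 0.99

    def test_constant_ages_rejected(self):
        with pytest.raises(DomainError):
            residualize(np.zeros((5, 3)), np.full(5, 12.0))


class TestHotellingT2:
    def test_equal_means_give_zero(self, rng):
        a = rng.normal(size=(8, 4))
        perm = a[rng.permutation(8)]
        assert hotelling_t2(a, perm) < 1e-12

    def test_one_channel_reduces_to_t_squared(self, rng):
        a = rng.normal(size=(10, 1))
        b = rng.normal(size=(13, 1)) + 0.4
        t, _ = sps.ttest_ind(a[:, 0], b[:, 0])
        assert hotelling_t2(a, b) == pytest.approx(t**2, abs=1e-10)

    def test_matches_direct_formula_oracle(self, rng):
        a = rng.normal(size=(10, 4)) + [0.5, 0, 0, 0]
        b = rng.normal(size=(13, 4))
        d = a.mean(axis=0) - b.mean(axis=0)
        S = (np.cov(a.T) * 9 + np.cov(b.T) * 12) / 21
        expected = 10 * 13 / 23 * d @ np.linalg.inv(S) @ d
        assert hotelling_t2(a, b) == pytest.approx(expected, rel=1e-10)

    def test_affine_invariance(self, rng):
        a = rng.normal(size=(10, 4))
        b = rng.normal(size=(13, 4)) + 0.3
        L = rng.normal(size=(4, 4)) + 2 * np.eye(4)
        shift = rng.normal(size=4)
        assert hotelling_t2(a @ L + shift, b @ L + shift) == pytest.approx(
            hotelling_t2(a, b), rel=1e-8
        )

    def test_small_group_rejected(self, rng):
        with pytest.raises(ValidationError):
            hotelling_t2(rng.normal(size=(1, 4)), rng.normal(size=(5, 4)))


class TestVertexwisePermutation:
    def test_determinism_same_seed_bit_identical(self, rng):
        X = rng.normal(size=(23, 50, 4))
        a = vertexwise_permutation_test(X, LAB, n_perm=200, seed=7)
        b = vertexwise_permutation_test(X, LAB, n_perm=200, seed=7)
        assert np.array_equal(a.stat, b.stat)
        assert np.array_equal(a.p, b.p)
        assert a.corrected_p == b.corrected_p

    def test_p_floor_is_one_over_nperm_plus_one(self, rng):
        X = rng.normal(size=(23, 5, 4))
        X[:10] += 50.0  # overwhelming effect: observed beats every shuffle
        sm = vertexwise_permutation_test(X, LAB, n_perm=200, seed=3)
        assert np.all(sm.p == 1 / 201)

    def test_p_never_zero_and_in_range(self, rng):
        X = rng.normal(size=(23, 100, 4))
        sm = vertexwise_permutation_test(X, LAB, n_perm=150, seed=0)
        assert (sm.p > 0).all() and (sm.p <= 1).all()

    def test_tiny_cohort_enumerates_all_assignments(self, rng):
        X = rng.normal(size=(8, 10, 2))
        lab = np.array([True] * 4 + [False] * 4)
        sm = vertexwise_permutation_test(X, lab, n_perm=100, seed=0)
        assert sm.n_perm == 70  # C(8, 4)
        assert any("enumeration" in n for n in sm.notes)

    def test_corrected_p_at_least_min_vertex_p(self, rng):
        for shift in (0.0, 2.0):
            X = rng.normal(size=(23, 80, 4))
            X[:10, :20] += shift
            sm = vertexwise_permutation_test(X, LAB, n_perm=300, seed=1)
            assert sm.corrected_p >= sm.p.min() - 1e-12

    def test_structurewise_correction_consistent_with_archive(self, rng):
        X = rng.normal(size=(23, 60, 4))
        sm, arch = vertexwise_permutation_test(
            X, LAB, n_perm=200, seed=5, return_archive=True
        )
        assert structurewise_correction(sm, arch, 0.05) == sm.corrected_p

    def test_no_significant_vertices_gives_corrected_one(self, rng):
        X = rng.normal(size=(23, 5, 4))
        sm, arch = vertexwise_permutation_test(
            X, LAB, n_perm=150, seed=2, return_archive=True
        )
        # alpha below the permutation resolution: no vertex can be significant
        assert structurewise_correction(sm, arch, alpha_vertex=1e-6) == 1.0

    def test_bad_alpha_rejected(self, rng):
        X = rng.normal(size=(23, 5, 4))
        sm, arch = vertexwise_permutation_test(
            X, LAB, n_perm=150, seed=2, return_archive=True
        )
        with pytest.raises(ValidationError):
            structurewise_correction(sm, arch, alpha_vertex=1.5)


class TestCombineStructures:
    def test_schedule_mismatch_rejected(self, rng):
        X = rng.normal(size=(23, 20, 4))
        a = vertexwise_permutation_test(X, LAB, n_perm=150, seed=1)
        b = vertexwise_permutation_test(X, LAB, n_perm=150, seed=2)
        with pytest.raises(ValidationError):
            combine_structures([a, b])

    def test_zero_significant_on_both_sides_gives_one(self, rng):
        X = rng.normal(size=(23, 5, 4))
        Y = rng.normal(size=(23, 5, 4))
        a = vertexwise_permutation_test(X, LAB, n_perm=150, seed=9, alpha_vertex=1e-9)
        with pytest.raises(ValidationError):
            # alpha outside permutation resolution is caught upstream
            vertexwise_permutation_test(X, LAB, n_perm=150, seed=9, alpha_vertex=0)
        b = vertexwise_permutation_test(Y, LAB, n_perm=150, seed=9, alpha_vertex=1e-9)
        assert combine_structures([a, b]) == 1.0

    def test_combined_lies_between_for_unilateral_effect(self, rng):
        strong = rng.normal(size=(23, 60, 4))
        strong[:10, :30] += 1.5
        null = rng.normal(size=(23, 60, 4))
        a = vertexwise_permutation_test(strong, LAB, n_perm=400, seed=4)
        b = vertexwise_permutation_test(null, LAB, n_perm=400, seed=4)
        c = combine_structures([a, b])
        assert a.corrected_p <= c <= b.corrected_p


class TestVolumeTest:
    def test_equal_group_means_give_p_one(self):
        # observed t = 0: every shuffled |t| ties or beats it
        v = np.concatenate([np.tile([4.0, 6.0], 5), np.full(13, 5.0)])
        v[10:12] = [4.0, 6.0]
        assert volume_permutation_ttest(v, LAB, n_perm=300, seed=0) == 1.0

    def test_constant_volumes_warn_and_give_p_one(self):
        with pytest.warns(UserWarning, match="equal"):
            p = volume_permutation_ttest(np.full(23, 7.0), LAB, n_perm=200, seed=0)
        assert p == 1.0

    def test_agrees_with_analytic_t_for_gaussian_data(self, rng):
        v = rng.normal(5000, 400, size=23)
        p_perm = volume_permutation_ttest(v, LAB, n_perm=10_000, seed=8)
        _, p_t = sps.ttest_ind(v[:10], v[10:])
        assert abs(p_perm - p_t) < 0.01

    def test_type_one_error_calibrated(self, rng):
        rej = 0
        n_sim = 400
        for k in range(n_sim):
            v = rng.normal(size=23)
            rej += volume_permutation_ttest(v, LAB, n_perm=500, seed=k) < 0.05
        assert 0.02 <= rej / n_sim <= 0.08


class TestRatioMap:
    def test_identical_groups_ratio_one(self, rng):
        d = rng.uniform(0.9, 1.1, size=(5, 40))
        assert np.abs(detj_ratio_map(d, d) - 1.0).max() < 1e-12

    def test_scaled_group_gives_squared_scale(self, rng):
        low = np.ones((5, 40))
        high = np.full((4, 40), 1.21)
        assert np.abs(detj_ratio_map(high, low) - 1.21).max() < 1e-12

    def test_zero_denominator_flagged_nan(self):
        high = np.ones((3, 4))
        low = np.ones((3, 4))
        low[:, 2] = 0.0
        out = detj_ratio_map(high, low)
        assert np.isnan(out[2]) and np.isfinite(out[[0, 1, 3]]).all()


class TestScoreCorrelation:
    def test_exact_linear_relation_gives_unit_r(self, rng):
        detj = rng.uniform(0.8, 1.2, size=(23, 10))
        scores = 3.0 + 2.0 * detj[:, 4]
        cm = score_correlation_map(detj, scores, n_perm=200, seed=0)
        assert cm.r[4] == pytest.approx(1.0, abs=1e-12)

    def test_negative_slope_gives_negative_r(self, rng):
        detj = rng.uniform(0.8, 1.2, size=(23, 3))
        scores = 40.0 - 30.0 * detj[:, 1] + rng.normal(0, 0.01, 23)
        cm = score_correlation_map(detj, scores, n_perm=200, seed=0)
        assert cm.r[1] < -0.99

    def test_permutation_p_matches_analytic_t_distribution(self, rng):
        detj = rng.uniform(0.9, 1.1, size=(23, 1))
        scores = 35 - 20 * detj[:, 0] + rng.normal(0, 1.0, 23)
        cm = score_correlation_map(detj, scores, n_perm=10_000, seed=6)
        _, p_analytic = sps.pearsonr(detj[:, 0], scores)
        assert abs(cm.p[0] - p_analytic) < 0.01

    def test_null_p_values_roughly_uniform(self, rng):
        detj = rng.uniform(0.9, 1.1, size=(23, 2000))
        scores = rng.normal(size=23)
        cm = score_correlation_map(detj, scores, n_perm=1000, seed=3)
        frac = (cm.p < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_constant_scores_rejected(self, rng):
        with pytest.raises(ValidationError):
            score_correlation_map(
                rng.uniform(size=(23, 5)), np.full(23, 30.0), n_perm=200, seed=0
            )


class TestMonotonicity:
    def test_omnibus_count_grows_with_effect_size(self, rng):
        mean_counts = []
        for shift in (0.0, 0.8, 1.6):
            counts = []
            for rep in range(8):
                X = rng.normal(size=(23, 60, 4))
                X[:10, :20] += shift
                sm = vertexwise_permutation_test(X, LAB, n_perm=200, seed=rep)
                counts.append(sm.omnibus_count)
            mean_counts.append(np.mean(counts))
        assert mean_counts[0] <= mean_counts[1] <= mean_counts[2]


def test_cohort_table_validation():
    good = pd.DataFrame(
        {
            "id": ["a", "b", "c", "d"],
            "group": ["high", "high", "low", "low"],
            "age": [10.0, 11.0, 12.0, 13.0],
        }
    )
    validate_cohort(good)
    with pytest.raises(ValidationError):
        validate_cohort(good.assign(id=["a", "a", "c", "d"]))
    with pytest.raises(ValidationError):
        validate_cohort(good.assign(group=["hi", "hi", "lo", "lo"]))
    with pytest.raises(ValidationError):
        validate_cohort(good.assign(age=[-1.0, 11.0, 12.0, 13.0]))
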