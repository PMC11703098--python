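"""Profile statistics: cosine similarity, LDA, Hotelling's T2, ANOVA, PCA."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ajprofiler.stats import (
    cosine_similarity,
    fit_lda,
    group_compare_1d,
    hotelling_t2,
    pca_profiles,
    similarity_matrix,
)


class TestCosine:
    def test_known_values(self):
        assert cosine_similarity([0.5, 0.5], [0.5, 0.5]) == pytest.approx(1.0)
        assert cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)
        assert cosine_similarity([1, 2], [2, 1]) == pytest.approx(0.8)

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity([0, 0], [1, 0])

    @given(
        p=st.lists(st.floats(0.01, 10), min_size=2, max_size=6),
        a=st.floats(0.01, 100),
    )
    @settings(max_examples=60, deadline=None)
    def test_scale_invariance(self, p, a):
        q = list(reversed(p))
        s1 = cosine_similarity(np.array(p) * a, q)
        s2 = cosine_similarity(p, q)
        assert s1 == pytest.approx(s2, rel=1e-9)

    def test_matrix_matches_pairwise_calls(self):
        rng = np.random.default_rng(0)
        profs = [rng.random(5) for _ in range(3)]
        m = similarity_matrix(profs)
        assert np.array_equal(m, m.T)
        np.testing.assert_allclose(np.diag(m), 1.0)
        for i in range(3):
            for j in range(3):
                if i != j:
                    assert m[i, j] == pytest.approx(cosine_similarity(profs[i], profs[j]))


class TestLDA:
    def test_axis_aligned_separation(self):
        rng = np.random.default_rng(0)
        g1 = rng.normal(size=(50, 2)) * [0.3, 1.0]
        g2 = rng.normal(size=(50, 2)) * [0.3, 1.0] + [5, 0]
        model, Z = fit_lda(np.vstack([g1, g2]), [0] * 50 + [1] * 50, n_components=1)
        w = model.sk_model.scalings_[:, 0]
        assert abs(w[0] / np.linalg.norm(w)) >= 0.99
        assert abs(Z[:50].mean() - Z[50:].mean()) > 3 * Z[:50].std()

    def test_frozen_transform_idempotent(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 4))
        y = [0] * 20 + [1] * 20
        model, _ = fit_lda(X, y, n_components=1)
        new = rng.normal(size=(10, 4))
        np.testing.assert_array_equal(model.transform(new), model.transform(new))

    def test_single_dimension_reduction_for_three_groups(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(loc=i * 2, size=(15, 3)) for i in range(3)])
        y = np.repeat([0, 1, 2], 15)
        model, Z = fit_lda(X, y, n_components=1)
        assert Z.shape == (45, 1)
        anova, _ = group_compare_1d({i: Z[y == i, 0] for i in range(3)})
        assert anova.p_value < 0.01

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            fit_lda(np.zeros((10, 2)), [0] * 10)

    def test_explained_variance_ratios_bounded(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(loc=[i, 0, 0], size=(20, 3)) for i in range(3)])
        y = np.repeat([0, 1, 2], 20)
        model, _ = fit_lda(X, y, n_components=2)
        assert model.explained_variance_ratio.sum() <= 1.0 + 1e-9


class TestHotelling:
    def test_identical_samples(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(10, 2))
        r = hotelling_t2(A, A.copy())
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_univariate_equals_t_squared(self):
        from scipy import stats as sps

        rng = np.random.default_rng(1)
        a, b = rng.normal(size=(15, 1)), rng.normal(0.5, 1, size=(12, 1))
        r = hotelling_t2(a, b)
        t, p = sps.ttest_ind(a.ravel(), b.ravel())
        assert r.statistic == pytest.approx(t * t, rel=1e-10)
        assert r.p_value == pytest.approx(p, rel=1e-10)

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        A = rng.normal(size=(20, 2))
        B = rng.normal(0.5, 1, size=(20, 2))
        base = hotelling_t2(A, B).statistic
        for _ in range(5):
            M = rng.normal(size=(2, 2)) + np.eye(2) * 2
            shift = rng.normal(size=2)
            r = hotelling_t2(A @ M + shift, B @ M + shift)
            assert r.statistic == pytest.approx(base, abs=1e-8, rel=1e-8)

    def test_sample_size_guard(self):
        with pytest.raises(ValueError):
            hotelling_t2(np.zeros((2, 3)), np.zeros((10, 3)))


class TestGroupCompare:
    def test_identical_groups_give_zero_f(self):
        with pytest.warns(UserWarning):
            anova, _ = group_compare_1d({"a": [2.0, 2.0], "b": [2.0, 2.0]})
        assert anova.statistic == 0.0 and anova.p_value == 1.0

    def test_t_statistic_scalar_oracle(self):
        _, pairs = group_compare_1d({"a": [1, 2, 3], "b": [4, 5, 6]})
        assert abs(pairs[0]["t"]) == pytest.approx(3 / np.sqrt(2 / 3), rel=1e-12)

    def test_holm_adjustment_monotone_and_bounded(self):
        rng = np.random.default_rng(0)
        groups = {k: rng.normal(loc, 1, 8) for k, loc in zip("abcd", [0, 0.2, 1.5, 3.0])}
        _, pairs = group_compare_1d(groups)
        for p in pairs:
            assert p["p_holm"] >= p["p_raw"] and p["p_holm"] <= 1.0
        by_raw = sorted(pairs, key=lambda d: d["p_raw"])
        holms = [p["p_holm"] for p in by_raw]
        assert holms == sorted(holms)


class TestPCA:
    def test_rank_one_data(self):
        t = np.linspace(0, 1, 10)[:, None]
        X = t @ np.array([[1.0, 2.0, -1.0]])
        scores, evr = pca_profiles(X, n_components=2)
        assert evr[0] == pytest.approx(1.0, abs=1e-10)

    def test_eigenvalues_match_direct_decomposition(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(3, 3))
        _, evr = pca_profiles(X)
        cov = np.cov(X, rowvar=False)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        np.testing.assert_allclose(evr, eig[: len(evr)] / eig.sum(), atol=1e-10)

    def test_ratios_sum_to_one(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(12, 4))
        _, evr = pca_profiles(X)
        assert evr.sum() == pytest.approx(1.0, abs=1e-9)

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError):
            pca_profiles(np.zeros((3, 4)), n_components=5)
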