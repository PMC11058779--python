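"""Bray-Curtis, PAV isotonic regression, stress-1, and the NMDS optimizer."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform

from oracles import isotonic_bruteforce
from riverhealth.ordination import (
    NMDS,
    bray_curtis,
    nmds,
    orient_axes,
    pav_isotonic,
    range_standardize,
    stress1,
)


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        X = pd.DataFrame([[1, 2, 3], [1, 2, 3]], index=["a", "b"])
        assert bray_curtis(X).loc["a", "b"] == 0.0

    def test_disjoint_supports_one(self):
        X = pd.DataFrame([[2, 0], [0, 5]], index=["a", "b"])
        assert bray_curtis(X).loc["a", "b"] == pytest.approx(1.0)

    def test_hand_value(self):
        # (2,1) vs (1,3): 1 - 2*(1+1)/7 = 3/7
        X = pd.DataFrame([[2, 1], [1, 3]], index=["a", "b"])
        assert bray_curtis(X).loc["a", "b"] == pytest.approx(3 / 7)

    def test_matches_definition_on_random(self, rng):
        X = rng.integers(0, 20, size=(6, 9)).astype(float)
        X[:, 0] += 1
        D = bray_curtis(X).to_numpy()
        for i in range(6):
            for j in range(6):
                expected = 1 - 2 * np.minimum(X[i], X[j]).sum() / (X[i] + X[j]).sum()
                assert D[i, j] == pytest.approx(expected)
        assert np.allclose(D, D.T)
        assert np.all(np.diag(D) == 0)
        assert np.all((D >= 0) & (D <= 1))

    def test_errors(self):
        with pytest.raises(ValueError, match="non-negative"):
            bray_curtis(np.array([[1.0, -1.0], [0.0, 1.0]]))
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis(pd.DataFrame([[0, 0], [1, 2]], index=["empty", "b"]))


class TestPAV:
    def test_already_monotone_unchanged(self):
        y = np.array([1.0, 2.0, 2.0, 5.0])
        np.testing.assert_array_equal(pav_isotonic(y), y)

    def test_decreasing_pools_to_grand_mean(self):
        y = np.array([5.0, 3.0, 1.0])
        np.testing.assert_allclose(pav_isotonic(y), np.full(3, 3.0))

    def test_hand_case(self):
        np.testing.assert_allclose(pav_isotonic([3.0, 1.0, 2.0]), [2.0, 2.0, 2.0])

    def test_sum_preserved_and_monotone(self, rng):
        y = rng.normal(size=200)
        fit = pav_isotonic(y)
        assert np.all(np.diff(fit) >= -1e-12)
        assert fit.sum() == pytest.approx(y.sum())

    def test_matches_bruteforce_partition_optimum(self):
        # exhaustive over all length <= 8 sequences on a small value grid
        grid = [0.0, 1.0, 2.0]
        rng = np.random.default_rng(0)
        for n in range(1, 9):
            for _ in range(60):
                y = rng.choice(grid, size=n)
                np.testing.assert_allclose(
                    pav_isotonic(y), isotonic_bruteforce(y), atol=1e-12
                )

    def test_matches_sklearn_isotonic(self, rng):
        from sklearn.isotonic import IsotonicRegression

        y = rng.normal(size=60)
        ours = pav_isotonic(y)
        theirs = IsotonicRegression().fit_transform(np.arange(60), y)
        np.testing.assert_allclose(ours, theirs, atol=1e-10)


class TestStress1:
    def test_perfect_fit_zero(self):
        assert stress1([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_hand_value(self):
        assert stress1([1.0, 2.0], [1.5, 1.5]) == pytest.approx(np.sqrt(0.5 / 5.0))

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.01, 10), min_size=2, max_size=20))
    def test_property_matches_formula(self, d):
        d = np.array(d)
        dhat = d[::-1].copy()
        expected = np.sqrt(np.sum((d - dhat) ** 2) / np.sum(d**2))
        assert stress1(d, dhat) == pytest.approx(expected)

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            stress1([0.0, 0.0], [1.0, 1.0])


class TestNMDS:
    def test_equilateral_triangle_embeds_exactly(self):
        pts = np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2], [0.5, 0.29]])
        D = pd.DataFrame(squareform(pdist(pts)))
        res = nmds(D, n_starts=10, random_state=0)
        assert res.stress <= 1e-6

    def test_planted_2d_configuration_recovered(self, rng):
        X0 = rng.normal(size=(20, 2))
        D = pd.DataFrame(squareform(pdist(X0)))
        res = nmds(D, n_starts=20, random_state=0)
        assert res.stress <= 0.01
        r = np.corrcoef(pdist(X0), pdist(res.coordinates.to_numpy()))[0, 1]
        assert r >= 0.99

    def test_stress_trace_non_increasing(self, rng):
        X0 = rng.normal(size=(12, 3))
        D = pd.DataFrame(squareform(pdist(X0)))
        res = nmds(D, n_components=2, n_starts=3, random_state=1)
        trace = np.array(res.stress_trace)
        assert np.all(np.diff(trace) <= 1e-15)

    def test_scale_invariance(self, rng):
        X0 = rng.normal(size=(10, 2))
        D = squareform(pdist(X0))
        r1 = nmds(pd.DataFrame(D), n_starts=5, random_state=3)
        r2 = nmds(pd.DataFrame(7.3 * D), n_starts=5, random_state=3)
        assert r1.stress == pytest.approx(r2.stress, abs=1e-8)

    def test_permutation_equivariance(self, rng):
        # identical starting configurations mapped through the permutation
        # must yield identically permuted site scores
        X0 = rng.normal(size=(9, 2))
        D = squareform(pdist(X0))
        labels = [f"s{i}" for i in range(9)]
        perm = rng.permutation(9)
        inits = rng.uniform(-1, 1, size=(4, 9, 2))
        res1 = nmds(pd.DataFrame(D, index=labels, columns=labels), init=inits)
        Dp = D[np.ix_(perm, perm)]
        labp = [labels[i] for i in perm]
        res2 = nmds(pd.DataFrame(Dp, index=labp, columns=labp),
                    init=inits[:, perm, :])
        assert res1.stress == pytest.approx(res2.stress, abs=1e-10)
        np.testing.assert_allclose(
            res1.coordinates.loc[labp].to_numpy(),
            res2.coordinates.to_numpy(),
            atol=1e-8,
        )

    def test_too_few_sites_raises(self):
        D = pd.DataFrame(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            nmds(D, n_components=2)

    def test_beats_or_matches_sklearn_nonmetric_mds(self, rng):
        from sklearn.manifold import MDS

        X0 = rng.normal(size=(15, 4))
        D = squareform(pdist(X0))
        ours = nmds(pd.DataFrame(D), n_starts=10, random_state=0).stress
        theirs = MDS(
            n_components=2, metric=False, dissimilarity="precomputed",
            n_init=10, random_state=0, normalized_stress=True, max_iter=500,
        ).fit(D).stress_
        assert ours <= theirs + 0.02


class TestOrientAxes:
    def test_mirror_invariance(self, rng):
        X = rng.normal(size=(12, 2))
        out1 = orient_axes(X)
        out2 = orient_axes(X * np.array([-1.0, 1.0]))
        np.testing.assert_allclose(out1, out2, atol=1e-10)

    def test_rotation_invariance(self, rng):
        X = rng.normal(size=(12, 2))
        theta = 0.77
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        np.testing.assert_allclose(orient_axes(X), orient_axes(X @ R), atol=1e-8)

    def test_axis1_carries_most_variance(self, rng):
        X = rng.normal(size=(30, 2)) * np.array([0.3, 2.0])
        out = orient_axes(X)
        assert out[:, 0].var() >= out[:, 1].var()
        # matches eigen-decomposition of the covariance
        eigvals = np.sort(np.linalg.eigvalsh(np.cov(X.T)))[::-1]
        np.testing.assert_allclose(
            [out[:, 0].var(ddof=1), out[:, 1].var(ddof=1)], eigvals, rtol=1e-8
        )

    def test_reference_fixes_sign(self, rng):
        X = rng.normal(size=(15, 2))
        ref = rng.normal(size=15)
        out = orient_axes(X, reference=ref)
        for j in range(2):
            assert np.dot(out[:, j] - out[:, j].mean(), ref - ref.mean()) >= 0


def test_range_standardize_bounds(rng):
    X = pd.DataFrame(rng.normal(size=(10, 4)) * 100)
    Xs = range_standardize(X)
    assert Xs.to_numpy().min() == pytest.approx(0.0)
    assert Xs.to_numpy().max() == pytest.approx(1.0)


def test_estimator_fit_transform(bundle):
    from riverhealth.guilds import EcologicalEntities, relative_abundance

    em = EcologicalEntities().fit(bundle.guilds).transform(bundle.abundance)
    ra = relative_abundance(em, scope="per_site", decimals=None)
    est = NMDS(n_starts=5, random_state=0)
    emb = est.fit_transform(ra)
    assert list(emb.columns) == ["NMDS1", "NMDS2"]
    assert est.stress_ < 0.3
    assert emb.index.equals(ra.index)
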