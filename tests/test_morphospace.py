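"""Size correction, PCA morphospace and packing metrics against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nichepack.morphospace import (
    centroid_distances,
    mcp_area,
    nn_distances,
    packing_metrics,
    run_pca,
    size_correct,
)


def make_residual_input(n=8, traits=("t1", "t2", "t3", "t4"), seed=0):
    rng = np.random.default_rng(seed)
    mass = pd.Series(rng.uniform(4, 40, n), index=[f"sp{i}" for i in range(n)])
    df = pd.DataFrame(
        {t: 3 + 0.4 * mass + rng.normal(0, 1.5, n) for t in traits}, index=mass.index
    )
    return df, mass


# --- independent oracles -------------------------------------------------

def ols_closed_form(x, y):
    """Two-parameter OLS by the closed-form normal equations."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    b = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
    a = y.mean() - b * x.mean()
    return a, b


def hull_half_plane(points):
    """Convex hull by the all-pairs half-plane test, area by shoelace fan."""
    P = np.asarray(points, float)
    n = len(P)
    on_hull = set()
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = P[j] - P[i]
            rel = P - P[i]
            cross = d[0] * rel[:, 1] - d[1] * rel[:, 0]
            if np.all(cross <= 1e-12) or np.all(cross >= -1e-12):
                on_hull.update((i, j))
    V = P[sorted(on_hull)]
    c = V.mean(axis=0)
    V = V[np.argsort(np.arctan2(V[:, 1] - c[1], V[:, 0] - c[0]))]
    x, y = V[:, 0], V[:, 1]
    return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


# --- size_correct --------------------------------------------------------

class TestSizeCorrect:
    def test_perfectly_allometric_trait_has_zero_residuals(self):
        mass = pd.Series([5.0, 10.0, 20.0, 40.0])
        df = pd.DataFrame({"t": 2 + 0.5 * mass})
        res = size_correct(df, mass, traits=("t",))
        assert np.allclose(res.residuals["t"], 0.0, atol=1e-10)
        assert res.fits.loc["t", "slope"] == pytest.approx(0.5)

    def test_constant_trait_gives_zero_slope_and_residuals(self):
        mass = pd.Series([5.0, 10.0, 20.0])
        df = pd.DataFrame({"t": [7.0, 7.0, 7.0]})
        res = size_correct(df, mass, traits=("t",))
        assert np.allclose(res.residuals["t"], 0.0)
        assert res.fits.loc["t", "slope"] == 0.0
        assert res.fits.loc["t", "intercept"] == 7.0

    def test_matches_closed_form_ols(self):
        mass = pd.Series([10.0, 20.0, 30.0])
        trait = np.array([5.0, 9.0, 10.0])
        df = pd.DataFrame({"t": trait})
        res = size_correct(df, mass, traits=("t",))
        a, b = ols_closed_form(mass, trait)
        assert res.fits.loc["t", "intercept"] == pytest.approx(a)
        assert res.fits.loc["t", "slope"] == pytest.approx(b)
        assert np.allclose(res.residuals["t"], trait - (a + b * mass))

    def test_residuals_centred_and_mass_orthogonal(self):
        df, mass = make_residual_input(n=12, seed=4)
        res = size_correct(df, mass, traits=tuple(df.columns))
        for t in df.columns:
            r = res.residuals[t].to_numpy()
            assert abs(r.sum()) < 1e-9 * max(1.0, np.abs(df[t]).sum())
            assert abs(np.cov(r, mass)[0, 1]) < 1e-8

    def test_residuals_invariant_to_trait_shift(self):
        df, mass = make_residual_input(seed=2)
        res1 = size_correct(df, mass, traits=tuple(df.columns))
        res2 = size_correct(df + 100.0, mass, traits=tuple(df.columns))
        pd.testing.assert_frame_equal(res1.residuals, res2.residuals)

    def test_too_few_pairs_names_the_trait(self):
        df, mass = make_residual_input(n=5, seed=1)
        df.loc[df.index[:3], "t2"] = np.nan
        with pytest.raises(ValueError, match="t2"):
            size_correct(df, mass, traits=tuple(df.columns))

    def test_zero_mass_variance_is_rejected(self):
        df = pd.DataFrame({"t": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="variance"):
            size_correct(df, pd.Series([10.0, 10.0, 10.0]), traits=("t",))


# --- run_pca -------------------------------------------------------------

class TestRunPCA:
    def test_collinear_data_loads_on_single_component(self):
        x = np.linspace(0, 5, 6)
        df = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.warns(UserWarning, match="rank-deficient"):
            coords = run_pca(df, k=2)
        assert coords.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_component_variances_conserve_total_variance(self):
        df, mass = make_residual_input(n=9, seed=7)
        resid = size_correct(df, mass, traits=tuple(df.columns))
        coords = run_pca(resid, k=4)
        total = resid.residuals.var(ddof=1).sum()
        assert coords.explained_variance.sum() == pytest.approx(total)
        assert coords.explained_variance_ratio.sum() == pytest.approx(1.0)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(42)
        X = pd.DataFrame(rng.normal(size=(6, 4)), columns=list("abcd"))
        coords = run_pca(X, k=4)
        C = np.cov((X - X.mean()).T, ddof=1)
        eigvals, eigvecs = np.linalg.eigh(C)
        order = np.argsort(eigvals)[::-1]
        eigvals, eigvecs = eigvals[order], eigvecs[:, order]
        for j in range(4):  # same deterministic sign convention
            i = np.argmax(np.abs(eigvecs[:, j]))
            if eigvecs[i, j] < 0:
                eigvecs[:, j] *= -1
        assert np.allclose(coords.explained_variance, eigvals)
        assert np.allclose(coords.loadings.to_numpy(), eigvecs, atol=1e-9)
        scores_oracle = (X - X.mean()).to_numpy() @ eigvecs
        assert np.allclose(coords.scores.to_numpy(), scores_oracle, atol=1e-9)

    def test_scores_are_mutually_uncorrelated(self):
        df, mass = make_residual_input(n=10, seed=3)
        coords = run_pca(size_correct(df, mass, traits=tuple(df.columns)), k=4)
        C = np.cov(coords.scores.to_numpy().T, ddof=1)
        assert np.allclose(C - np.diag(np.diag(C)), 0.0, atol=1e-9)

    def test_incomplete_species_dropped_with_warning(self):
        df, mass = make_residual_input(n=8, seed=5)
        df.loc["sp0", "t1"] = np.nan
        with pytest.warns(UserWarning, match="sp0"):
            coords = run_pca(df, k=3)
        assert "sp0" not in coords.scores.index

    def test_k_larger_than_rank_bound_is_rejected(self):
        df, _ = make_residual_input(n=4, seed=6)
        with pytest.raises(ValueError, match="k="):
            run_pca(df, k=4)  # n - 1 = 3 < 4


# --- distances and hull --------------------------------------------------

class TestPackingMetrics:
    def test_two_points_nn(self):
        nn, mean, sd = nn_distances(np.array([[0.0, 0.0], [3.0, 0.0]]))
        assert nn.tolist() == [3.0, 3.0]
        assert mean == 3.0 and sd == 0.0

    def test_nn_matches_all_pairs_minimum(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(8, 10))
        nn, _, _ = nn_distances(X)
        D = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        np.fill_diagonal(D, np.inf)
        assert np.allclose(nn, D.min(axis=1))

    def test_nn_needs_two_points(self):
        with pytest.raises(ValueError):
            nn_distances(np.array([[1.0, 2.0]]))

    def test_symmetric_cross_centroid_distances(self):
        X = np.array([[1.0, 0], [-1, 0], [0, 1], [0, -1]])
        d, mean, median = centroid_distances(X)
        assert np.allclose(d, 1.0)
        assert median == 1.0

    def test_single_point_centroid_distance_zero(self):
        d, mean, _ = centroid_distances(np.array([[4.0, 5.0, 6.0]]))
        assert d.tolist() == [0.0]

    def test_centroid_matches_direct_computation(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(10, 5))
        d, _, _ = centroid_distances(X)
        assert np.allclose(d, np.linalg.norm(X - X.mean(0), axis=1))

    def test_unit_square_hull_area(self):
        hull = mcp_area([[0, 0], [1, 0], [1, 1], [0, 1]])
        assert hull.area == pytest.approx(1.0)
        assert not hull.degenerate

    def test_collinear_points_degenerate(self):
        hull = mcp_area([[0, 0], [1, 1], [2, 2]])
        assert hull.area == 0.0
        assert hull.degenerate

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_hull_area_matches_half_plane_oracle(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.normal(size=(12, 2))
        assert mcp_area(P).area == pytest.approx(hull_half_plane(P))

    def test_interior_point_removal_leaves_area_unchanged(self):
        rng = np.random.default_rng(12)
        P = rng.normal(size=(12, 2))
        hull = mcp_area(P)
        vertex_rows = {tuple(v) for v in hull.vertices}
        interior = [i for i in range(len(P)) if tuple(P[i]) not in vertex_rows]
        assert interior, "instance should have interior points"
        reduced = np.delete(P, interior[0], axis=0)
        assert mcp_area(reduced).area == pytest.approx(hull.area)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(0.1, 10.0))
    def test_rigid_motion_and_scale_equivariance(self, seed, scale):
        """Distances are invariant under rotation+translation and scale by s;
        the 2-D hull area scales by s^2."""
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(7, 2))
        theta = rng.uniform(0, 2 * np.pi)
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        Y = scale * (X @ R.T) + rng.normal(size=2)
        nn_x, _, _ = nn_distances(X)
        nn_y, _, _ = nn_distances(Y)
        assert np.allclose(nn_y, scale * nn_x)
        cd_x, _, _ = centroid_distances(X)
        cd_y, _, _ = centroid_distances(Y)
        assert np.allclose(cd_y, scale * cd_x)
        assert mcp_area(Y).area == pytest.approx(scale**2 * mcp_area(X).area)

    def test_nn_bounded_by_centroid_triangle_inequality(self, fixture_report):
        for p in fixture_report.packing.values():
            assert (p.nn <= p.centroid + p.centroid.max() + 1e-9).all()

    def test_packing_metrics_bundle_consistency(self):
        rng = np.random.default_rng(3)
        scores = pd.DataFrame(rng.normal(size=(9, 4)), columns=["PC1", "PC2", "PC3", "PC4"])
        p = packing_metrics(scores)
        assert p.nn_mean == pytest.approx(p.nn.mean())
        assert p.centroid_median == pytest.approx(p.centroid.median())
        assert p.mcp_area >= 0
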