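import numpy as np
import pandas as pd
import pytest
from scipy.linalg import orthogonal_procrustes
from scipy.spatial.distance import pdist, squareform

from foresthab.census import PlotSpec, grid_stems
from foresthab.multivariate import (
    betadisper,
    bray_curtis,
    pcoa,
    rda_marginal,
    _marginal_fraction,
)
from .conftest import make_census


def qm_from_counts(counts, species=None):
    """Build a QuadratMatrix whose columns are the given count vectors."""
    counts = np.asarray(counts)
    S, Q = counts.shape
    rows = []
    # one plot wide enough for Q quadrats in a row
    plot = PlotSpec("P1", 10 * Q, 10, 10)
    species = species or [f"s{i}" for i in range(S)]
    for i, sp in enumerate(species):
        for j in range(Q):
            rows += [("P1", sp, "tree", 10 * j + 0.5, 0.5, 5.0)] * int(counts[i, j])
    return grid_stems(make_census(rows, [plot]))


class TestBrayCurtis:
    def test_identical_quadrats_zero(self):
        d = bray_curtis(qm_from_counts([[2, 2], [1, 1]]))
        assert d.iloc[0, 1] == pytest.approx(0.0)

    def test_disjoint_quadrats_one(self):
        d = bray_curtis(qm_from_counts([[3, 0], [0, 5]]))
        assert d.iloc[0, 1] == pytest.approx(1.0)

    def test_hand_value(self):
        # (2,1,0) vs (0,1,2): sum|a-b| = 4, sum(a+b) = 6
        d = bray_curtis(qm_from_counts([[2, 0], [1, 1], [0, 2]]))
        assert d.iloc[0, 1] == pytest.approx(4 / 6)

    def test_empty_pair_warns_and_is_zero(self):
        qm = qm_from_counts([[1, 0, 0], [2, 0, 0]])
        with pytest.warns(UserWarning, match="empty quadrats"):
            d = bray_curtis(qm)
        assert d.iloc[1, 2] == pytest.approx(0.0)


class TestPcoa:
    def test_recovers_euclidean_geometry(self, rng):
        pts = rng.normal(size=(12, 2))
        D = squareform(pdist(pts))
        coords, evals = pcoa(D)
        assert (evals[:2] > 0).all()
        rec = coords[:, :2]
        ptsc = pts - pts.mean(axis=0)
        R, _ = orthogonal_procrustes(rec, ptsc)
        assert np.abs(rec @ R - ptsc).max() < 1e-8

    def test_two_points(self):
        coords, evals = pcoa(np.array([[0.0, 2.0], [2.0, 0.0]]))
        assert np.abs(coords[:, 0]) == pytest.approx([1.0, 1.0])
        assert coords[0, 0] == pytest.approx(-coords[1, 0])

    def test_eigenvalue_sum_equals_centered_trace(self, rng):
        pts = rng.normal(size=(8, 3))
        D = squareform(pdist(pts)) ** 1.3  # non-Euclidean on purpose
        coords, evals = pcoa(D)
        n = D.shape[0]
        A = -0.5 * D**2
        J = np.eye(n) - np.ones((n, n)) / n
        assert evals.sum() == pytest.approx(np.trace(J @ A @ J))

    def test_rejects_asymmetric(self):
        with pytest.raises(ValueError, match="symmetric"):
            pcoa(np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_matches_scikit_bio(self, rng):
        """Independent cross-check of the embedding against scikit-bio."""
        skbio = pytest.importorskip("skbio")
        pts = rng.normal(size=(10, 3))
        D = squareform(pdist(pts))
        coords, evals = pcoa(D)
        ref = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(D))
        np.testing.assert_allclose(
            evals[: 3], ref.eigvals.to_numpy()[:3], atol=1e-8
        )
        np.testing.assert_allclose(
            np.abs(coords[:, 0]), np.abs(ref.samples.to_numpy()[:, 0]), atol=1e-8
        )


class TestBetadisper:
    def test_scaled_group_dispersion_ratio(self, rng):
        """Scaling one group's spread x3 scales centroid distances x3."""
        a = rng.normal(size=(20, 2))
        b = rng.normal(size=(20, 2)) * 3.0 + 10.0
        pts = np.vstack([a, b])
        D = squareform(pdist(pts))
        groups = ["a"] * 20 + ["b"] * 20
        res = betadisper(D, groups)
        means = res.group_means()
        # same generating spread up to the x3 factor; MC slack on the ratio
        assert means["b"] / means["a"] == pytest.approx(3.0, rel=0.35)

    def test_identical_points_degenerate(self):
        pts = np.array([[0, 0], [0, 0], [5, 5], [5, 5]], dtype=float)
        D = squareform(pdist(pts))
        res = betadisper(D, ["a", "a", "b", "b"])
        assert np.isnan(res.f_stat)
        assert res.p_anova == 1.0

    def test_singleton_group_excluded(self, rng):
        pts = rng.normal(size=(7, 2))
        D = squareform(pdist(pts))
        with pytest.warns(UserWarning, match="singleton"):
            res = betadisper(D, ["a", "a", "a", "b", "b", "b", "c"])
        assert set(res.groups) == {"a", "b"}

    def test_matches_vegan_convention_on_euclidean(self, rng):
        """On Euclidean distances, centroid distances are plain geometry."""
        pts = rng.normal(size=(10, 2))
        D = squareform(pdist(pts))
        groups = np.array(["a"] * 5 + ["b"] * 5)
        res = betadisper(D, groups)
        for g in "ab":
            m = groups == g
            cen = pts[m].mean(axis=0)
            expected = np.linalg.norm(pts[m] - cen, axis=1)
            assert np.sort(res.centroid_dist[m]) == pytest.approx(
                np.sort(expected), abs=1e-8
            )

    def test_permutation_p_reported(self, rng):
        pts = rng.normal(size=(16, 2))
        D = squareform(pdist(pts))
        res = betadisper(D, ["a"] * 8 + ["b"] * 8, n_perm=99, seed=1)
        assert res.p_perm is not None
        assert 1 / 100 <= res.p_perm <= 1.0


class TestRdaMarginal:
    def topo(self, qm, values):
        meta = qm.quadrat_meta
        return pd.DataFrame(
            {"plot": meta["plot"].to_numpy(),
             "cell_ix": meta["cell_ix"].to_numpy(),
             "cell_iy": meta["cell_iy"].to_numpy(),
             **values}
        )

    def test_orthogonal_covariate_near_zero(self):
        qm = qm_from_counts([[1, 1, 1, 1], [2, 2, 2, 2]])
        topo = self.topo(qm, {"elevation": [1.0, 2.0, 3.0, 4.0]})
        res = rda_marginal(qm, topo, n_perm=19, seed=0, transform=None)
        assert res.table["explained_pct"].iloc[0] == pytest.approx(0.0, abs=1e-8)

    def test_exact_linear_function_is_100(self):
        qm = qm_from_counts([[1, 2, 3, 4], [8, 6, 4, 2]])
        topo = self.topo(qm, {"elevation": [1.0, 2.0, 3.0, 4.0]})
        res = rda_marginal(qm, topo, n_perm=19, seed=0, transform=None)
        assert res.table["explained_pct"].iloc[0] == pytest.approx(100.0)

    def test_matches_per_column_regression_oracle(self, rng):
        counts = rng.integers(0, 9, size=(5, 8))
        counts[0, 0] += 1  # guard against an all-zero matrix
        qm = qm_from_counts(counts)
        x = rng.normal(size=8)
        topo = self.topo(qm, {"elevation": x})
        res = rda_marginal(qm, topo, n_perm=19, seed=0, transform=None)
        # oracle: per-column least squares, pooled SS ratio
        Y = counts.T.astype(float)
        Yc = Y - Y.mean(axis=0)
        xc = x - x.mean()
        ss_fit = 0.0
        for j in range(Y.shape[1]):
            beta = np.polyfit(xc, Yc[:, j], 1)[0]
            ss_fit += ((beta * xc) ** 2).sum()
        expected = 100.0 * ss_fit / (Yc**2).sum()
        assert res.table["explained_pct"].iloc[0] == pytest.approx(expected)

    def test_constant_covariate_warns_zero(self):
        qm = qm_from_counts([[1, 2, 3, 4]])
        topo = self.topo(qm, {"elevation": [7.0] * 4})
        with pytest.warns(UserWarning, match="constant"):
            res = rda_marginal(qm, topo, n_perm=9, seed=0)
        assert res.table["explained_pct"].iloc[0] == 0.0

    def test_orthogonal_design_fractions_add_up(self, rng):
        """On orthogonal covariates, marginal fractions sum to the joint fit."""
        n = 16
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        Y = np.outer(x1, rng.normal(size=3)) + np.outer(x2, rng.normal(size=3))
        Y += 0.01 * rng.normal(size=Y.shape)
        f1 = _marginal_fraction(Y, x1)
        f2 = _marginal_fraction(Y, x2)
        X = np.column_stack([x1, x2])
        beta, *_ = np.linalg.lstsq(X - X.mean(0), Y - Y.mean(0), rcond=None)
        joint = (((X - X.mean(0)) @ beta) ** 2).sum() / ((Y - Y.mean(0)) ** 2).sum()
        assert f1 + f2 == pytest.approx(joint, rel=1e-6)
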