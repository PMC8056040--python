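"""Composition-dissimilarity analyses.

Bray-Curtis dissimilarities between quadrats, principal coordinates analysis
(PCoA, with negative eigenvalues retained), a multivariate homogeneity-of-
dispersion test (distances to group centroids in the PCoA embedding, F-tested
by ANOVA and optionally by permutation), and marginal redundancy-analysis
variance fractions for per-quadrat topographic covariates.

Negative PCoA eigenvalues arise because Bray-Curtis is non-Euclidean; the
dispersion test combines real and imaginary axes as
``z = sqrt(max(0, d_real^2 - d_imag^2))``, the standard treatment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from scipy.spatial.distance import pdist, squareform

from .census import QuadratMatrix

__all__ = [
    "bray_curtis",
    "pcoa",
    "DispersionResult",
    "betadisper",
    "RdaResult",
    "rda_marginal",
]


def bray_curtis(qm: QuadratMatrix, *, drop_empty: bool = False) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between quadrat columns.

    ``d(a, b) = sum_i |a_i - b_i| / sum_i (a_i + b_i)``.  A pair of entirely
    empty quadrats has an undefined dissimilarity; it is defined as 0 here
    (with a warning) so the matrix stays valid.  Set ``drop_empty`` to
    exclude empty quadrats instead.
    """
    X = qm.abundance.to_numpy(dtype=float).T  # quadrats x species
    labels = list(qm.abundance.columns)
    empty = X.sum(axis=1) == 0
    if drop_empty:
        X = X[~empty]
        labels = [l for l, e in zip(labels, empty) if not e]
    elif empty.any():
        warnings.warn(
            f"{int(empty.sum())} empty quadrats: their mutual dissimilarity "
            "is defined as 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        D = squareform(pdist(X, metric="braycurtis"))
    D = np.nan_to_num(D, nan=0.0)
    return pd.DataFrame(D, index=labels, columns=labels)


def _check_square(d: pd.DataFrame | np.ndarray) -> np.ndarray:
    D = np.asarray(d, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be symmetric")
    return D


def pcoa(d: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal coordinates of a dissimilarity matrix.

    Eigendecomposition of the Gower double-centered matrix
    ``B = -1/2 J (D*D) J``; axes are ordered by descending eigenvalue and
    negative eigenvalues are retained (their coordinates are stored for the
    imaginary part of the embedding).  Returns ``(coords, eigenvalues)``
    where ``coords[:, k] = v_k * sqrt(|lambda_k|)``.
    """
    D = _check_square(d)
    n = D.shape[0]
    A = -0.5 * D**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ A @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    coords = evecs * np.sqrt(np.abs(evals))[None, :]
    return coords, evals


@dataclass
class DispersionResult:
    """Outcome of the multivariate dispersion (betadisper-style) test."""

    pcoa_coords: np.ndarray
    eigenvalues: np.ndarray
    groups: np.ndarray
    centroid_dist: np.ndarray
    f_stat: float
    p_anova: float
    p_perm: float | None = None

    def group_means(self) -> pd.Series:
        s = pd.Series(self.centroid_dist, index=self.groups)
        return s.groupby(level=0).mean()


def _centroid_distances(coords: np.ndarray, evals: np.ndarray,
                        groups: np.ndarray) -> np.ndarray:
    """Distance of each point to its own group centroid.

    Real axes (positive eigenvalues) contribute positively, imaginary axes
    (negative eigenvalues) negatively: ``z = sqrt(max(0, dr^2 - di^2))``.
    """
    pos = evals > 1e-12
    neg = evals < -1e-12
    z = np.empty(len(groups))
    for g in np.unique(groups):
        m = groups == g
        cen = coords[m].mean(axis=0)
        diff = coords[m] - cen
        dr2 = (diff[:, pos] ** 2).sum(axis=1)
        di2 = (diff[:, neg] ** 2).sum(axis=1)
        z[m] = np.sqrt(np.clip(dr2 - di2, 0.0, None))
    return z


def _anova_f(values: np.ndarray, groups: np.ndarray) -> float:
    grand = values.mean()
    ss_b = ss_w = 0.0
    k = 0
    for g in np.unique(groups):
        v = values[groups == g]
        ss_b += len(v) * (v.mean() - grand) ** 2
        ss_w += ((v - v.mean()) ** 2).sum()
        k += 1
    n = len(values)
    if ss_w <= 0:
        return np.inf if ss_b > 0 else np.nan
    return (ss_b / (k - 1)) / (ss_w / (n - k))


def betadisper(
    d: pd.DataFrame | np.ndarray,
    groups,
    *,
    n_perm: int = 0,
    seed: int | None = None,
) -> DispersionResult:
    """Homogeneity of multivariate dispersions across groups.

    Embeds the dissimilarity matrix by PCoA, computes each quadrat's
    distance to its own group centroid, and compares mean distances across
    groups with a one-way ANOVA F test (parametric p) and, when
    ``n_perm > 0``, a permutation test shuffling group labels.

    Groups of size 1 carry no dispersion information and are excluded with
    a warning.  If every within-group distance is identical the F statistic
    is degenerate and reported as NaN with p = 1.
    """
    D = _check_square(d)
    groups = np.asarray(groups)
    if len(groups) != D.shape[0]:
        raise ValueError("groups length must match matrix size")
    uniq, counts = np.unique(groups, return_counts=True)
    singletons = uniq[counts < 2]
    if len(singletons):
        warnings.warn(f"excluding singleton groups: {list(singletons)}", stacklevel=2)
        keep = ~np.isin(groups, singletons)
        D = D[np.ix_(keep, keep)]
        groups = groups[keep]
        uniq = uniq[counts >= 2]
    if len(uniq) < 2:
        raise ValueError("need at least two groups of size >= 2")
    coords, evals = pcoa(D)
    z = _centroid_distances(coords, evals, groups)
    # distances indistinguishable from numerical noise: degenerate by fiat
    if np.ptp(z) <= 1e-9 * max(1.0, D.max()):
        z = np.zeros_like(z)
    f = _anova_f(z, groups)
    if np.isnan(f) or np.isinf(f):
        p_anova = 1.0 if np.isnan(f) else 0.0
    else:
        k, n = len(uniq), len(z)
        p_anova = float(scipy.stats.f.sf(f, k - 1, n - k))
    p_perm = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            gp = rng.permutation(groups)
            zp = _centroid_distances(coords, evals, gp)
            fp = _anova_f(zp, gp)
            if not np.isnan(fp) and (np.isnan(f) or fp >= f):
                hits += 1
        p_perm = (hits + 1) / (n_perm + 1)
    return DispersionResult(
        pcoa_coords=coords,
        eigenvalues=evals,
        groups=groups,
        centroid_dist=z,
        f_stat=float(f),
        p_anova=p_anova,
        p_perm=p_perm,
    )


@dataclass
class RdaResult:
    """Per-covariate marginal explained variance with permutation p-values."""

    table: pd.DataFrame  # columns: covariate, explained_pct, p_perm

    def __repr__(self) -> str:  # pragma: no cover
        return f"RdaResult(\n{self.table}\n)"


def _marginal_fraction(Y: np.ndarray, x: np.ndarray) -> float:
    """Fraction of total (centered) species variance explained by x alone."""
    Yc = Y - Y.mean(axis=0)
    xc = x - x.mean()
    ss_tot = (Yc**2).sum()
    sxx = (xc**2).sum()
    if ss_tot <= 0 or sxx <= 0:
        return 0.0
    beta = Yc.T @ xc / sxx  # per-species slope
    ss_fit = (sxx * beta**2).sum()
    return float(ss_fit / ss_tot)


def rda_marginal(
    qm: QuadratMatrix,
    topo: pd.DataFrame,
    covariates: list[str] | None = None,
    *,
    n_perm: int = 999,
    seed: int | None = None,
    transform: str | None = "hellinger",
) -> RdaResult:
    """Marginal (each-covariate-alone) RDA variance fractions.

    For each covariate, every species column is regressed on it and the
    explained fraction is ``SS(fitted) / SS(total) * 100`` over the whole
    (column-centered) species matrix; the permutation p-value shuffles the
    covariate across quadrats.  ``topo`` must be indexed like the quadrat
    columns (``plot:ix:iy``) or carry ``plot, cell_ix, cell_iy`` columns.
    Aspect (circular, degrees) is expanded to a sin/cos pair internally and
    the pair's joint fit is reported under the original name.

    The species matrix is Hellinger-transformed by default (square root of
    relative abundance per quadrat), the standard pre-transformation for RDA
    on abundance data; pass ``transform=None`` for raw abundances.
    """
    if {"plot", "cell_ix", "cell_iy"}.issubset(topo.columns):
        idx = (
            topo["plot"].astype(str)
            + ":" + topo["cell_ix"].astype(int).astype(str)
            + ":" + topo["cell_iy"].astype(int).astype(str)
        )
        topo = topo.drop(columns=["plot", "cell_ix", "cell_iy"]).set_index(idx)
    topo = topo.loc[list(qm.abundance.columns)]
    if covariates is None:
        covariates = list(topo.columns)
    Y = qm.abundance.to_numpy(dtype=float).T  # quadrats x species
    if transform == "hellinger":
        rowsum = Y.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            Y = np.sqrt(np.where(rowsum > 0, Y / rowsum, 0.0))
    rng = np.random.default_rng(seed)
    rows = []
    for cov in covariates:
        x = topo[cov].to_numpy(dtype=float)
        if cov.lower().startswith("aspect"):
            rad = np.deg2rad(x)
            X = np.column_stack([np.sin(rad), np.cos(rad)])
            frac = _multi_fraction(Y, X)
            perm_frac = lambda p: _multi_fraction(Y, X[p])  # noqa: E731
        else:
            if np.ptp(x) == 0:
                warnings.warn(f"constant covariate {cov!r}: 0%", stacklevel=2)
                rows.append({"covariate": cov, "explained_pct": 0.0, "p_perm": 1.0})
                continue
            frac = _marginal_fraction(Y, x)
            perm_frac = lambda p: _marginal_fraction(Y, x[p])  # noqa: E731
        hits = 0
        for _ in range(n_perm):
            if perm_frac(rng.permutation(len(x))) >= frac:
                hits += 1
        rows.append(
            {
                "covariate": cov,
                "explained_pct": 100.0 * frac,
                "p_perm": (hits + 1) / (n_perm + 1),
            }
        )
    return RdaResult(table=pd.DataFrame(rows))


def _multi_fraction(Y: np.ndarray, X: np.ndarray) -> float:
    """Explained fraction for a small multi-column predictor block."""
    Yc = Y - Y.mean(axis=0)
    Xc = X - X.mean(axis=0)
    ss_tot = (Yc**2).sum()
    if ss_tot <= 0:
        return 0.0
    beta, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    ss_fit = ((Xc @ beta) ** 2).sum()
    return float(ss_fit / ss_tot)
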