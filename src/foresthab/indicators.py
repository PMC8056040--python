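"""IndVal indicator-species analysis with a permutation null.

For species s and site group g,

    A_gs = mean abundance of s in g / sum over groups of mean abundances
    B_gs = fraction of sites in g occupied by s
    IndVal_s = max_g sqrt(A_gs * B_gs)

A (specificity) is group-size equalized: group means, not raw sums, so
unequal numbers of quadrats per community do not bias it.  B is fidelity
(within-group occurrence frequency).  The p-value permutes site group
labels; by default it is reported per species for its best group only and
without multiple-testing correction, mirroring the usual indicator-table
layout (a Holm correction is available).
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
import pandas as pd

from .census import QuadratMatrix

__all__ = ["indval", "indval_stats"]


def _indval_components(X: np.ndarray, group_ids: np.ndarray, n_groups: int):
    """Return (A, B, indval) arrays of shape (n_groups, n_species)."""
    means = np.empty((n_groups, X.shape[1]))
    occ = np.empty((n_groups, X.shape[1]))
    for g in range(n_groups):
        m = group_ids == g
        means[g] = X[m].mean(axis=0)
        occ[g] = (X[m] > 0).mean(axis=0)
    denom = means.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        A = np.where(denom > 0, means / denom, 0.0)
    return A, occ, np.sqrt(A * occ)


def indval_stats(X: np.ndarray, group_ids: np.ndarray, n_groups: int) -> np.ndarray:
    """Per-species IndVal statistic: max over groups of sqrt(A * B)."""
    return _indval_components(X, group_ids, n_groups)[2].max(axis=0)


def indval(
    qm: QuadratMatrix,
    groups=None,
    *,
    n_perm: int | None = 999,
    seed: int | None = None,
    holm: bool = False,
) -> pd.DataFrame:
    """Indicator value of every species for its best community.

    ``groups`` defaults to the quadrat communities (plot labels).  With
    ``n_perm=None`` the permutation null is enumerated exhaustively over all
    distinct arrangements of the group labels (feasible for a handful of
    sites only); the p-value is then the exact fraction of arrangements,
    including the observed one, whose IndVal reaches the observed value.
    With Monte-Carlo permutations, ``p = (#(perm >= obs) + 1) / (n_perm + 1)``.

    Species absent from every site are excluded with a warning column-free;
    returns a tidy frame with ``species, life_form, best_group, A, B,
    indval, p`` (plus ``p_holm`` when requested), sorted by p then -indval.
    """
    if groups is None:
        groups = qm.quadrat_meta["plot"].to_numpy()
    groups = np.asarray(groups)
    X_df = qm.abundance
    present = X_df.sum(axis=1) > 0
    X_df = X_df.loc[present]
    X = X_df.to_numpy(dtype=float).T  # sites x species
    uniq = list(pd.unique(groups))
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    gid = np.array([uniq.index(g) for g in groups])
    A, B, iv = _indval_components(X, gid, len(uniq))
    best = iv.argmax(axis=0)
    sp_idx = np.arange(X.shape[1])
    obs = iv[best, sp_idx]

    if n_perm is None:
        # exhaustive: all distinct label arrangements
        seen = set()
        hits = np.zeros(X.shape[1])
        total = 0
        for perm in permutations(range(len(gid))):
            key = tuple(gid[list(perm)])
            if key in seen:
                continue
            seen.add(key)
            total += 1
            stat = indval_stats(X, np.array(key), len(uniq))
            hits += stat >= obs - 1e-12
        p = hits / total
    else:
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        hits = np.zeros(X.shape[1])
        for _ in range(n_perm):
            stat = indval_stats(X, rng.permutation(gid), len(uniq))
            hits += stat >= obs - 1e-12
        p = (hits + 1) / (n_perm + 1)

    life = qm.species_meta["life_form"].reindex(X_df.index)
    out = pd.DataFrame(
        {
            "species": X_df.index,
            "life_form": life.to_numpy(),
            "best_group": [uniq[b] for b in best],
            "A": A[best, sp_idx],
            "B": B[best, sp_idx],
            "indval": obs,
            "p": p,
        }
    )
    if holm:
        order = np.argsort(out["p"].to_numpy())
        m = len(out)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * out["p"].iloc[idx])
            adj[idx] = min(1.0, running)
        out["p_holm"] = adj
    return out.sort_values(["p", "indval"], ascending=[True, False]).reset_index(
        drop=True
    )
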