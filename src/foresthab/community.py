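"""Per-community composition summaries.

Importance values (IV), exact sample-based species-accumulation curves,
Kruskal-Wallis comparisons of richness/abundance, and occurrence-overlap
(Venn) counts across communities.

The importance value of a species in a community is

    IV = (relative abundance % + relative frequency % + relative basal area %) / 3

where relative frequency uses occupied-quadrat counts (denominator = the sum
of occupied-quadrat counts over all species, so the components each total
100% within a community) and basal area is pi * (dbh/2)^2 summed over stems.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats
from scipy.special import gammaln

from .census import CensusTable, QuadratMatrix

__all__ = [
    "importance_values",
    "AccumulationCurve",
    "species_accumulation",
    "kruskal_wallis",
    "occurrence_overlap",
]


def importance_values(
    qm: QuadratMatrix, census: CensusTable, community: str
) -> pd.DataFrame:
    """Importance-value table for one community (plot).

    Returns one row per species present in the community with columns
    ``abundance, mean_dbh, basal_area, rel_abundance, rel_frequency,
    rel_basal_area, iv``.  Basal area is in cm^2 (an extra ``basal_area_m2``
    column gives the same quantity in m^2).  IVs sum to 100 per community.
    """
    mask = qm.quadrat_meta["plot"].to_numpy() == community
    if not mask.any():
        raise KeyError(f"unknown community {community!r}")
    sub = qm.abundance.loc[:, mask]
    abund = sub.sum(axis=1)
    abund = abund[abund > 0]
    if abund.empty:
        raise ValueError(f"community {community!r} holds no stems")
    species = abund.index
    freq = (sub.loc[species] > 0).sum(axis=1).astype(float)

    stems = census.stems[census.stems["plot"] == community]
    ba = stems.assign(ba=np.pi * (stems["dbh"] / 2.0) ** 2).groupby("species")["ba"].sum()
    mean_dbh = stems.groupby("species")["dbh"].mean()
    ba = ba.reindex(species).fillna(0.0)
    mean_dbh = mean_dbh.reindex(species)

    rel_ab = 100.0 * abund / abund.sum()
    rel_fr = 100.0 * freq / freq.sum()
    rel_ba = 100.0 * ba / ba.sum() if ba.sum() > 0 else rel_ab * 0.0
    iv = (rel_ab + rel_fr + rel_ba) / 3.0
    out = pd.DataFrame(
        {
            "community": community,
            "abundance": abund.astype(int),
            "mean_dbh": mean_dbh,
            "basal_area": ba,
            "basal_area_m2": ba / 1e4,
            "rel_abundance": rel_ab,
            "rel_frequency": rel_fr,
            "rel_basal_area": rel_ba,
            "iv": iv,
        }
    )
    return out.sort_values("iv", ascending=False)


@dataclass
class AccumulationCurve:
    """Exact sample-based rarefaction curve.

    ``mean_richness[n-1]`` is the expected species count in a uniformly
    random subset of ``n`` of the ``T`` sites; ``sd_richness`` its exact
    standard deviation over subsets.
    """

    n_sites: np.ndarray
    mean_richness: np.ndarray
    sd_richness: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_sites": self.n_sites,
                "mean_richness": self.mean_richness,
                "sd_richness": self.sd_richness,
            }
        )


def _log_comb(n: np.ndarray | float, k: np.ndarray | float) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    out = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return np.where(k > n, -np.inf, out)


def species_accumulation(
    qm: QuadratMatrix, communities: list[str] | None = None
) -> AccumulationCurve:
    """Exact expected species-accumulation curve over quadrats.

    With ``T`` sites and species ``i`` occupying ``T_i`` of them, the
    probability a random ``n``-subset misses species ``i`` is
    ``C(T - T_i, n) / C(T, n)``, so

        E[S(n)] = S_obs - sum_i C(T - T_i, n) / C(T, n).

    The variance uses joint absence probabilities
    ``q_ij = C(T - |A_i u A_j|, n) / C(T, n)``:

        Var[S(n)] = sum_i p_i (1 - p_i) + 2 sum_{i<j} (q_ij - p_i p_j).

    Combinatorics are evaluated in log space.
    """
    if communities is not None:
        mask = qm.quadrat_meta["plot"].isin(set(communities)).to_numpy()
        ab = qm.abundance.loc[:, mask]
    else:
        ab = qm.abundance
    pres = (ab.to_numpy() > 0)
    pres = pres[pres.any(axis=1)]  # drop species absent from the subset
    S, T = pres.shape
    if T < 1:
        raise ValueError("need at least one site")
    occ = pres.sum(axis=1)  # T_i
    ns = np.arange(1, T + 1)
    logCTn = _log_comb(T, ns)
    # p[i, n]: absence probability of species i at sample size n
    with np.errstate(invalid="ignore"):
        p = np.exp(_log_comb((T - occ)[:, None], ns[None, :]) - logCTn[None, :])
    p = np.nan_to_num(p, nan=0.0)
    mean = S - p.sum(axis=0)

    # pairwise joint-absence site counts: T - |A_i u A_j|
    inter = pres.astype(np.int64) @ pres.T.astype(np.int64)
    union = occ[:, None] + occ[None, :] - inter
    absent_both = T - union
    var = (p * (1.0 - p)).sum(axis=0)
    iu, ju = np.triu_indices(S, k=1)
    if len(iu):
        with np.errstate(invalid="ignore"):
            q = np.exp(_log_comb(absent_both[iu, ju][:, None], ns[None, :])
                       - logCTn[None, :])
        q = np.nan_to_num(q, nan=0.0)
        var = var + 2.0 * (q - p[iu] * p[ju]).sum(axis=0)
    var = np.clip(var, 0.0, None)
    return AccumulationCurve(n_sites=ns, mean_richness=mean, sd_richness=np.sqrt(var))


def kruskal_wallis(samples: list[np.ndarray]) -> tuple[float, float]:
    """Kruskal-Wallis rank test across groups.

    Returns ``(H, p)`` with the tie-corrected statistic and the chi-square
    tail probability on ``len(samples) - 1`` df.  The degenerate case of all
    pooled values identical (tie correction divides by zero) is defined as
    ``H = 0, p = 1``.
    """
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(s, dtype=float) for s in samples]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("every group needs at least one value")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = scipy.stats.kruskal(*arrays)
    return float(h), float(p)


def occurrence_overlap(qm: QuadratMatrix) -> dict:
    """Venn-style occurrence counts of species across communities.

    Presence = total abundance > 0 in the community.  Returns
    ``{"subsets": {frozenset-of-communities as sorted tuple: count},
    "at_least": {k: count of species in >= k communities}}``; subset counts
    are exclusive (species counted in exactly that community set).
    """
    totals = qm.community_totals()
    comms = list(totals.columns)
    pres = totals > 0
    subsets: dict[tuple[str, ...], int] = {}
    for r in range(1, len(comms) + 1):
        for combo in combinations(comms, r):
            subsets[tuple(combo)] = 0
    at_least = {k: 0 for k in range(1, len(comms) + 1)}
    for sp in totals.index:
        present = tuple(c for c in comms if pres.at[sp, c])
        if not present:
            continue
        subsets[present] += 1
        for k in range(1, len(present) + 1):
            at_least[k] += 1
    return {"subsets": subsets, "at_least": at_least}
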