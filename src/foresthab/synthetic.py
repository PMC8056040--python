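"""Synthetic stem-mapped census generator.

Emulates a four-plot (1 ha each) stem-mapped census of woody plants: per
species x plot stem counts are Poisson, positions are either uniform
(complete spatial randomness) or a Thomas cluster process (Poisson parents,
isotropic Gaussian offsets), and DBH is lognormal truncated at the 1 cm
census minimum.  Species can be given a "community preference" — a fold-
change of expected abundance in one preferred plot relative to each other
plot — which is what the habitat-association machinery is meant to recover.

Randomness is hierarchical: one global seed spawns an independent stream per
(species, plot), so adding or removing a species does not perturb the stems
generated for the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .census import CensusTable, PlotSpec, STEM_COLUMNS

__all__ = [
    "ClusterSpec",
    "SyntheticConfig",
    "PreferenceSpec",
    "generate_census",
    "generate_null_census",
    "apply_preferences",
]


@dataclass(frozen=True)
class ClusterSpec:
    """Within-plot spatial structure of one species.

    ``kind`` is ``"uniform"`` (CSR) or ``"thomas"``.  For a Thomas process,
    ``kappa`` is the expected number of cluster parents per hectare and
    ``sigma`` the Gaussian offset scale in meters.  Offspring falling outside
    the plot are re-drawn (plots are physically bounded, not tori).
    """

    kind: str = "uniform"
    kappa: float = 10.0
    sigma: float = 2.0

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "thomas"):
            raise ValueError(f"unknown clustering kind {self.kind!r}")
        if self.kind == "thomas" and (self.kappa <= 0 or self.sigma <= 0):
            raise ValueError("thomas clustering needs kappa > 0 and sigma > 0")


@dataclass
class SyntheticConfig:
    """Full description of a synthetic census.

    ``intensity`` maps species -> {plot_id -> expected stem count}; the
    realized count is Poisson with that mean.  ``dbh_lognormal`` maps species
    to ``(mu_log, sigma_log)`` of the underlying normal on the cm scale; the
    default (1.5, 0.6) gives mean DBH around 5-6 cm with a realistic right
    tail, truncated at 1 cm.
    """

    species_pool: list[tuple[str, str]]  # (species, life_form)
    intensity: dict[str, dict[str, float]]
    n_plots: int = 4
    plot_size: float = 100.0
    quadrat: float = 10.0
    clustering: dict[str, ClusterSpec] = field(default_factory=dict)
    dbh_lognormal: dict[str, tuple[float, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for sp, row in self.intensity.items():
            for lam in row.values():
                if lam < 0:
                    raise ValueError(f"negative intensity for {sp!r}")

    @property
    def plot_ids(self) -> list[str]:
        return [f"P{i + 1}" for i in range(self.n_plots)]

    def plots(self) -> list[PlotSpec]:
        return [
            PlotSpec(pid, self.plot_size, self.plot_size, self.quadrat)
            for pid in self.plot_ids
        ]

    # -- serialization --------------------------------------------------
    def to_yaml(self) -> str:
        doc = {
            "n_plots": self.n_plots,
            "plot_size": self.plot_size,
            "quadrat": self.quadrat,
            "seed": self.seed,
            "species_pool": [list(t) for t in self.species_pool],
            "intensity": self.intensity,
            "clustering": {
                s: {"kind": c.kind, "kappa": c.kappa, "sigma": c.sigma}
                for s, c in self.clustering.items()
            },
            "dbh_lognormal": {s: list(v) for s, v in self.dbh_lognormal.items()},
        }
        return yaml.safe_dump(doc, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "SyntheticConfig":
        doc = yaml.safe_load(text)
        return cls(
            species_pool=[tuple(t) for t in doc["species_pool"]],
            intensity={s: dict(v) for s, v in doc["intensity"].items()},
            n_plots=doc.get("n_plots", 4),
            plot_size=doc.get("plot_size", 100.0),
            quadrat=doc.get("quadrat", 10.0),
            clustering={
                s: ClusterSpec(**v) for s, v in doc.get("clustering", {}).items()
            },
            dbh_lognormal={
                s: tuple(v) for s, v in doc.get("dbh_lognormal", {}).items()
            },
            seed=doc.get("seed", 0),
        )


@dataclass(frozen=True)
class PreferenceSpec:
    """A species' community preference as an intensity contrast.

    The preferred plot carries ``fold`` times the expected abundance of each
    other plot; the species' total expected abundance is preserved.
    """

    species: str
    preferred_plot: str
    fold: float

    def __post_init__(self) -> None:
        if self.fold < 1:
            raise ValueError("fold must be >= 1")


def apply_preferences(
    config: SyntheticConfig, prefs: list[PreferenceSpec]
) -> SyntheticConfig:
    """Rescale intensity rows to encode plot preferences.

    For ``P`` plots with total expected abundance ``L`` and fold ``f``, the
    non-preferred plots each get ``L / (f + P - 1)`` and the preferred plot
    ``f`` times that, so the total is exactly preserved.
    """
    intensity = {s: dict(v) for s, v in config.intensity.items()}
    plot_ids = config.plot_ids
    for p in prefs:
        if p.species not in intensity:
            raise KeyError(f"unknown species {p.species!r}")
        if p.preferred_plot not in plot_ids:
            raise KeyError(f"unknown plot {p.preferred_plot!r}")
        total = sum(intensity[p.species].get(pid, 0.0) for pid in plot_ids)
        base = total / (p.fold + len(plot_ids) - 1)
        intensity[p.species] = {
            pid: (p.fold * base if pid == p.preferred_plot else base)
            for pid in plot_ids
        }
    return replace(config, intensity=intensity)


def equalize_intensities(config: SyntheticConfig) -> SyntheticConfig:
    """Spread each species' total expected abundance evenly over plots."""
    plot_ids = config.plot_ids
    intensity = {
        s: {pid: sum(row.get(p, 0.0) for p in plot_ids) / len(plot_ids)
            for pid in plot_ids}
        for s, row in config.intensity.items()
    }
    return replace(config, intensity=intensity)


# ---------------------------------------------------------------------------
# Generation


def _species_plot_rng(seed: int, sp_index: int, plot_index: int) -> np.random.Generator:
    # hierarchical stream: stable under adding/removing other species
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(sp_index, plot_index))
    )


def _draw_positions(
    rng: np.random.Generator, n: int, size: float, cluster: ClusterSpec
) -> np.ndarray:
    if n == 0:
        return np.empty((0, 2))
    if cluster.kind == "uniform":
        return rng.uniform(0.0, size, size=(n, 2))
    # Thomas: Poisson number of parents over the plot area (kappa per ha)
    area_ha = size * size / 1e4
    n_parents = rng.poisson(cluster.kappa * area_ha)
    if n_parents == 0:
        n_parents = 1
    parents = rng.uniform(0.0, size, size=(n_parents, 2))
    assignment = rng.integers(0, n_parents, size=n)
    pos = np.empty((n, 2))
    for i, pa in enumerate(assignment):
        while True:
            p = parents[pa] + rng.normal(0.0, cluster.sigma, size=2)
            if 0.0 <= p[0] < size and 0.0 <= p[1] < size:
                pos[i] = p
                break
    return pos


def _draw_dbh(
    rng: np.random.Generator, n: int, mu_log: float, sigma_log: float, min_dbh: float
) -> np.ndarray:
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.lognormal(mu_log, sigma_log, size=max(n - filled, 16))
        ok = draw[draw >= min_dbh]
        take = min(len(ok), n - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


DEFAULT_DBH = (1.5, 0.6)


def generate_census(config: SyntheticConfig) -> CensusTable:
    """Draw one census realization; fully reproducible from ``config.seed``."""
    plots = config.plots()
    records = []
    lf = dict(config.species_pool)
    for si, (sp, _form) in enumerate(config.species_pool):
        row = config.intensity.get(sp, {})
        cluster = config.clustering.get(sp, ClusterSpec())
        mu_log, sigma_log = config.dbh_lognormal.get(sp, DEFAULT_DBH)
        for pi, pspec in enumerate(plots):
            lam = row.get(pspec.plot_id, 0.0)
            rng = _species_plot_rng(config.seed, si, pi)
            n = int(rng.poisson(lam)) if lam > 0 else 0
            if n == 0:
                continue
            pos = _draw_positions(rng, n, pspec.width, cluster)
            dbh = _draw_dbh(rng, n, mu_log, sigma_log, 1.0)
            for k in range(n):
                records.append(
                    (
                        f"{pspec.plot_id}-{sp}-{k}",
                        pspec.plot_id,
                        sp,
                        lf[sp],
                        float(pos[k, 0]),
                        float(pos[k, 1]),
                        float(dbh[k]),
                    )
                )
    stems = pd.DataFrame(records, columns=STEM_COLUMNS)
    return CensusTable(stems=stems, plots=plots)


def generate_null_census(config: SyntheticConfig) -> CensusTable:
    """A census with no habitat preference: equal intensity across plots.

    Used for type-I-error studies of the association machinery; everything
    else (clustering, DBH, seeding) is as in :func:`generate_census`.
    """
    return generate_census(equalize_intensities(config))


def default_species_pool(
    n_species: int = 20, frac_shrub: float = 0.35
) -> list[tuple[str, str]]:
    """A generic pool of labeled species, a mix of trees and shrubs."""
    n_shrub = int(round(n_species * frac_shrub))
    pool = []
    for i in range(n_species):
        form = "shrub" if i < n_shrub else "tree"
        pool.append((f"sp{i + 1:02d}", form))
    return pool


def default_config(
    n_species: int = 20,
    mean_abundance: float = 120.0,
    seed: int = 0,
    n_plots: int = 4,
) -> SyntheticConfig:
    """A four-plot census resembling a temperate mixed stand.

    Total expected abundance per species is lognormally ranked (a few
    dominants, many sparse species) around ``mean_abundance`` stems per
    species over all plots, spread evenly across plots until preferences
    are applied.
    """
    pool = default_species_pool(n_species)
    # deterministic rank-abundance: geometric series normalized to the mean
    ranks = np.arange(n_species)
    weights = 0.85 ** ranks
    totals = weights / weights.mean() * mean_abundance
    plot_ids = [f"P{i + 1}" for i in range(n_plots)]
    intensity = {
        sp: {pid: float(t) / n_plots for pid in plot_ids}
        for (sp, _), t in zip(pool, totals)
    }
    return SyntheticConfig(
        species_pool=pool,
        intensity=intensity,
        n_plots=n_plots,
        seed=seed,
    )
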