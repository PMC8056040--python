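"""Torus-translation test of species-habitat association.

The four 1-ha plots (the "habitats": four disturbance regimes) are
concatenated side by side into one 40 x 10 quadrat grid.  The observed
statistic for a species x habitat pair is the Harms-style relative density

    RD = (stems in habitat / habitat cell count)
         / (total stems / total cell count),

RD = 1 under no association.  The null distribution translates the habitat
map — not the stems — around the torus, in all (dx, dy) shifts of each of
four map variants (identity, 180-degree rotation, x-mirror, mirrored
rotation): 4 * 40 * 10 = 1,600 maps, the real one plus 1,599 translated
ones.  Shifting the map instead of the stems preserves both the stems'
spatial autocorrelation and the habitat patch structure.

A species is positively associated with a habitat when the observed RD sits
in the extreme upper tail of its null set (p_pos <= alpha/2), negatively in
the lower tail; ties count toward both tails and the observed map is a
member of its own null set, so p-values live on {1/1600, ..., 1}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .census import CensusTable, QuadratMatrix

__all__ = [
    "HabitatMap",
    "build_combined_map",
    "enumerate_null_maps",
    "relative_density",
    "torus_test",
]

VARIANTS = ("identity", "rot180", "mirror", "mirror_rot180")


@dataclass
class HabitatMap:
    """Toroidal grid of habitat labels over quadrat cells.

    ``codes[ix, iy]`` is an integer index into ``habitats``;
    ``cell_of_quadrat`` maps quadrat column labels (``plot:ix:iy``) to
    combined-grid cells.
    """

    codes: np.ndarray  # (nx, ny) int
    habitats: list[str]
    cell_of_quadrat: dict[str, tuple[int, int]]

    @property
    def nx(self) -> int:
        return self.codes.shape[0]

    @property
    def ny(self) -> int:
        return self.codes.shape[1]

    @property
    def n_cells(self) -> int:
        return self.codes.size

    def habitat_cell_counts(self) -> np.ndarray:
        return np.bincount(self.codes.ravel(), minlength=len(self.habitats))

    def cell_index(self, quadrat_label: str) -> int:
        ix, iy = self.cell_of_quadrat[quadrat_label]
        return ix * self.ny + iy


def build_combined_map(
    census: CensusTable, layout: list[str] | None = None
) -> HabitatMap:
    """Concatenate the plots along x into one toroidal habitat map.

    Each cell is labeled with its plot's community id.  ``layout`` fixes the
    left-to-right plot order (default: census plot order).  All plots must
    share the quadrat size and plot height.
    """
    plots = {p.plot_id: p for p in census.plots}
    if layout is None:
        layout = [p.plot_id for p in census.plots]
    if set(layout) != set(plots) or len(layout) != len(plots):
        raise ValueError("layout must be a permutation of the census plot ids")
    qs = {plots[pid].quadrat for pid in layout}
    hs = {plots[pid].ny for pid in layout}
    if len(qs) != 1 or len(hs) != 1:
        raise ValueError("plots must share quadrat size and height")
    ny = hs.pop()
    nx = sum(plots[pid].nx for pid in layout)
    codes = np.empty((nx, ny), dtype=np.int64)
    cell_of_quadrat: dict[str, tuple[int, int]] = {}
    habitats = list(layout)
    x0 = 0
    for h, pid in enumerate(layout):
        p = plots[pid]
        codes[x0 : x0 + p.nx, :] = h
        for ix in range(p.nx):
            for iy in range(ny):
                cell_of_quadrat[f"{pid}:{ix}:{iy}"] = (x0 + ix, iy)
        x0 += p.nx
    return HabitatMap(codes=codes, habitats=habitats, cell_of_quadrat=cell_of_quadrat)


def _variant(codes: np.ndarray, name: str) -> np.ndarray:
    if name == "identity":
        return codes
    if name == "rot180":
        return codes[::-1, ::-1]
    if name == "mirror":
        return codes[::-1, :]
    if name == "mirror_rot180":
        return codes[:, ::-1]
    raise ValueError(f"unknown variant {name!r}")


def transform_stack(hmap: HabitatMap) -> tuple[list[tuple[str, int, int]], np.ndarray]:
    """All 4 * nx * ny torus transforms of the map, the untransformed first.

    Returns ``(tags, stack)`` where ``tags[k] = (variant, dx, dy)`` and
    ``stack[k]`` is the flattened (nx * ny) label-code array of transform k.
    """
    nx, ny = hmap.nx, hmap.ny
    tags = []
    stack = np.empty((4 * nx * ny, nx * ny), dtype=np.int8)
    k = 0
    for name in VARIANTS:
        base = _variant(hmap.codes, name)
        for dx in range(nx):
            for dy in range(ny):
                tags.append((name, dx, dy))
                stack[k] = np.roll(base, (dx, dy), axis=(0, 1)).ravel()
                k += 1
    # move the untransformed original (identity, 0, 0) to the front
    assert tags[0] == ("identity", 0, 0)
    return tags, stack


def enumerate_null_maps(hmap: HabitatMap):
    """Yield the 4 * nx * ny - 1 transformed maps (the original excluded).

    Each item is ``((variant, dx, dy), codes)`` with ``codes`` shaped like
    the original grid.  Every habitat's cell count is preserved by every
    transform.
    """
    tags, stack = transform_stack(hmap)
    for tag, flat in zip(tags[1:], stack[1:]):
        yield tag, flat.reshape(hmap.nx, hmap.ny)


def relative_density(
    counts_per_cell: np.ndarray, codes_flat: np.ndarray, habitat_code: int
) -> float:
    """Harms relative density of one species in one habitat."""
    counts_per_cell = np.asarray(counts_per_cell, dtype=float)
    total = counts_per_cell.sum()
    if total <= 0:
        raise ValueError("species has no stems")
    in_h = codes_flat == habitat_code
    n_cells_h = int(in_h.sum())
    if n_cells_h == 0:
        raise ValueError("degenerate habitat with 0 cells")
    dens_h = counts_per_cell[in_h].sum() / n_cells_h
    dens_all = total / counts_per_cell.size
    return float(dens_h / dens_all)


def _species_cell_counts(qm: QuadratMatrix, hmap: HabitatMap) -> np.ndarray:
    """Species x combined-grid-cell abundance array aligned with the map."""
    S = qm.n_species
    counts = np.zeros((S, hmap.n_cells))
    for j, label in enumerate(qm.abundance.columns):
        counts[:, hmap.cell_index(label)] += qm.abundance.iloc[:, j].to_numpy()
    return counts


def torus_test(
    qm: QuadratMatrix,
    hmap: HabitatMap,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Torus-translation association test for every species x habitat pair.

    ``qm`` should already be abundance-filtered (the plot-census convention
    tests only species with at least five stems).  Returns a tidy table
    with columns ``species, life_form, habitat, observed_rd, p_pos, p_neg,
    class`` where class is ``positive`` (p_pos <= alpha/2), ``negative``
    (p_neg <= alpha/2) or ``none``.  The two classes are mutually exclusive
    for any alpha < 1 because the tails overlap only on ties.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    tags, stack = transform_stack(hmap)
    n_maps = stack.shape[0]
    counts = _species_cell_counts(qm, hmap)  # S x n_cells
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        absent = [s for s, t in zip(qm.abundance.index, totals) if t == 0]
        raise ValueError(f"species with no stems: {absent}")
    cell_counts = hmap.habitat_cell_counts()
    rows = []
    life = qm.species_meta["life_form"]
    for h, habitat in enumerate(hmap.habitats):
        in_h = (stack == h)  # n_maps x n_cells
        # stems of each species inside habitat h under every transform
        stems_h = counts @ in_h.T.astype(float)  # S x n_maps
        rd = (stems_h / cell_counts[h]) / (totals / hmap.n_cells)[:, None]
        obs = rd[:, 0]
        null = rd[:, 1:]
        ge = (null >= obs[:, None] - 1e-12).sum(axis=1)
        le = (null <= obs[:, None] + 1e-12).sum(axis=1)
        p_pos = (ge + 1) / n_maps
        p_neg = (le + 1) / n_maps
        for i, sp in enumerate(qm.abundance.index):
            if p_pos[i] <= alpha / 2:
                cls = "positive"
            elif p_neg[i] <= alpha / 2:
                cls = "negative"
            else:
                cls = "none"
            rows.append(
                {
                    "species": sp,
                    "life_form": life.loc[sp],
                    "habitat": habitat,
                    "observed_rd": obs[i],
                    "p_pos": p_pos[i],
                    "p_neg": p_neg[i],
                    "class": cls,
                }
            )
    return pd.DataFrame(rows)
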