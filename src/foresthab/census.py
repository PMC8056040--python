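"""Stem-mapped census data model, I/O and quadrat gridding.

A census is a table of mapped woody stems (one row per stem, with plot,
species, life form, x/y position in meters and DBH in cm) plus the geometry
of the plots it was mapped in.  All downstream analyses work either on the
stem table directly or on the species x quadrat abundance matrix obtained by
gridding each plot into square quadrats (10 m x 10 m by default, the
field-standard subplot size for 1-ha forest dynamics plots).

Conventions
-----------
* Coordinates are 0-based and half-open per axis: a stem at ``x == width``
  is outside the plot.  Quadrat index is ``floor(coord / quadrat_size)``.
* The minimum DBH for inclusion is 1 cm (stems below it are census errors).
* Species and plot labels are opaque strings; no taxonomic normalization.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PlotSpec",
    "CensusTable",
    "QuadratMatrix",
    "CensusFormatError",
    "read_census",
    "write_census",
    "grid_stems",
    "filter_min_abundance",
]

#: canonical column order of the stem CSV dialect
STEM_COLUMNS = ["stem_id", "plot", "species", "life_form", "x", "y", "dbh"]

LIFE_FORMS = ("tree", "shrub")


class CensusFormatError(ValueError):
    """Raised for malformed census files or invariant-violating rows."""


@dataclass(frozen=True)
class PlotSpec:
    """Geometry of one rectangular plot.

    Width and height must be integer multiples of the quadrat size so the
    plot grids exactly.
    """

    plot_id: str
    width: float = 100.0
    height: float = 100.0
    quadrat: float = 10.0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0 or self.quadrat <= 0:
            raise ValueError("plot dimensions and quadrat size must be positive")
        for dim in (self.width, self.height):
            n = dim / self.quadrat
            if abs(n - round(n)) > 1e-9:
                raise ValueError(
                    f"plot {self.plot_id!r}: dimension {dim} is not an integer "
                    f"multiple of quadrat size {self.quadrat}"
                )

    @property
    def nx(self) -> int:
        return int(round(self.width / self.quadrat))

    @property
    def ny(self) -> int:
        return int(round(self.height / self.quadrat))

    @property
    def n_quadrats(self) -> int:
        return self.nx * self.ny


@dataclass
class CensusTable:
    """A stem table plus the plots it lives in.

    ``stems`` is a DataFrame with the canonical columns
    ``stem_id, plot, species, life_form, x, y, dbh``.
    """

    stems: pd.DataFrame
    plots: list[PlotSpec] = field(default_factory=list)
    min_dbh: float = 1.0

    def __post_init__(self) -> None:
        missing = [c for c in STEM_COLUMNS if c not in self.stems.columns]
        if missing:
            raise CensusFormatError(f"stem table missing columns: {missing}")
        self.stems = self.stems[STEM_COLUMNS].reset_index(drop=True)
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        plot_ids = {p.plot_id for p in self.plots}
        bad = set(self.stems["plot"]) - plot_ids
        if bad:
            raise CensusFormatError(f"stems reference unknown plots: {sorted(bad)}")
        by_plot = {p.plot_id: p for p in self.plots}
        for row in self.stems.itertuples():
            spec = by_plot[row.plot]
            if not (0 <= row.x < spec.width and 0 <= row.y < spec.height):
                raise CensusFormatError(
                    f"stem {row.stem_id!r}: position ({row.x}, {row.y}) outside "
                    f"half-open plot [0, {spec.width}) x [0, {spec.height})"
                )
            if row.dbh < self.min_dbh:
                raise CensusFormatError(
                    f"stem {row.stem_id!r}: dbh {row.dbh} below census minimum "
                    f"{self.min_dbh} cm"
                )
            if row.life_form not in LIFE_FORMS:
                raise CensusFormatError(
                    f"stem {row.stem_id!r}: life_form {row.life_form!r} not in "
                    f"{LIFE_FORMS}"
                )

    @property
    def n_stems(self) -> int:
        return len(self.stems)

    @property
    def species(self) -> list[str]:
        return sorted(self.stems["species"].unique())

    def life_form_of(self) -> dict[str, str]:
        """Species -> life form mapping (first occurrence wins)."""
        return (
            self.stems.drop_duplicates("species")
            .set_index("species")["life_form"]
            .to_dict()
        )

    def subset_plots(self, plot_ids: list[str]) -> "CensusTable":
        keep = [p for p in self.plots if p.plot_id in set(plot_ids)]
        stems = self.stems[self.stems["plot"].isin(set(plot_ids))].reset_index(drop=True)
        return CensusTable(stems=stems, plots=keep, min_dbh=self.min_dbh)


@dataclass
class QuadratMatrix:
    """Species x quadrat abundance matrix.

    ``abundance`` rows are species, columns are quadrat labels of the form
    ``plot:ix:iy``.  ``quadrat_meta`` has one row per column with
    ``plot, cell_ix, cell_iy``; ``species_meta`` has one row per species with
    its life form.
    """

    abundance: pd.DataFrame
    quadrat_meta: pd.DataFrame
    species_meta: pd.DataFrame

    @property
    def n_species(self) -> int:
        return self.abundance.shape[0]

    @property
    def n_quadrats(self) -> int:
        return self.abundance.shape[1]

    @property
    def total(self) -> int:
        return int(self.abundance.to_numpy().sum())

    @property
    def communities(self) -> list[str]:
        return list(pd.unique(self.quadrat_meta["plot"]))

    def community_totals(self) -> pd.DataFrame:
        """Species x community abundance totals (collapses quadrats)."""
        groups = self.quadrat_meta["plot"].to_numpy()
        out = {}
        for c in self.communities:
            out[c] = self.abundance.loc[:, groups == c].sum(axis=1)
        return pd.DataFrame(out)

    def to_csv(self, path_or_buf) -> None:
        self.abundance.to_csv(path_or_buf, index_label="species")


def _quadrat_label(plot: str, ix: int, iy: int) -> str:
    return f"{plot}:{ix}:{iy}"


# ---------------------------------------------------------------------------
# I/O


def read_census(
    path,
    plots: list[PlotSpec] | None = None,
    *,
    plot_size: float = 100.0,
    quadrat: float = 10.0,
    min_dbh: float = 1.0,
) -> CensusTable:
    """Read a stem CSV into a :class:`CensusTable`.

    The canonical dialect is UTF-8, comma-separated, with a header row naming
    ``stem_id,plot,species,life_form,x,y,dbh``.  If ``plots`` is omitted,
    square plots of side ``plot_size`` are inferred from the plot labels
    present in the file.

    Rows violating invariants (coordinates outside the half-open plot
    rectangle, non-numeric fields, sub-minimum DBH) are rejected with
    row-numbered diagnostics.
    """
    try:
        df = pd.read_csv(path, dtype={"stem_id": str, "plot": str, "species": str,
                                      "life_form": str})
    except Exception as exc:  # pragma: no cover - delegated to pandas
        raise CensusFormatError(f"cannot parse census file: {exc}") from exc
    missing = [c for c in STEM_COLUMNS if c not in df.columns]
    if missing:
        raise CensusFormatError(f"census file missing required columns: {missing}")
    errors = []
    for col in ("x", "y", "dbh"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        for i in df.index[coerced.isna() & df[col].notna()]:
            errors.append(f"row {i + 2}: non-numeric {col}={df.at[i, col]!r}")
        df[col] = coerced
    if errors:
        raise CensusFormatError("; ".join(errors))
    if plots is None:
        plots = [
            PlotSpec(str(p), plot_size, plot_size, quadrat)
            for p in pd.unique(df["plot"])
        ]
    by_plot = {p.plot_id: p for p in plots}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        spec = by_plot.get(row.plot)
        if spec is None:
            errors.append(f"row {i}: unknown plot {row.plot!r}")
        elif not (0 <= row.x < spec.width and 0 <= row.y < spec.height):
            errors.append(
                f"row {i}: ({row.x}, {row.y}) outside [0, {spec.width}) x "
                f"[0, {spec.height})"
            )
        elif row.dbh < min_dbh:
            errors.append(f"row {i}: dbh {row.dbh} < minimum {min_dbh}")
    if errors:
        raise CensusFormatError("; ".join(errors))
    return CensusTable(stems=df, plots=plots, min_dbh=min_dbh)


def write_census(census: CensusTable, path_or_buf) -> None:
    """Write the canonical stem CSV (round-trips bit-identically)."""
    census.stems.to_csv(path_or_buf, index=False)


def census_to_string(census: CensusTable) -> str:
    buf = io.StringIO()
    write_census(census, buf)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Gridding and filtering


def grid_stems(census: CensusTable) -> QuadratMatrix:
    """Grid stems into quadrats; conserves the stem count exactly.

    A stem at ``(x, y)`` falls in cell ``(floor(x/q), floor(y/q))`` of its
    plot; columns are ordered plot-by-plot, x-major then y.
    """
    columns: list[str] = []
    meta_rows = []
    for p in census.plots:
        for ix in range(p.nx):
            for iy in range(p.ny):
                columns.append(_quadrat_label(p.plot_id, ix, iy))
                meta_rows.append({"plot": p.plot_id, "cell_ix": ix, "cell_iy": iy})
    quadrat_meta = pd.DataFrame(meta_rows, index=columns)
    species = census.species
    arr = np.zeros((len(species), len(columns)), dtype=np.int64)
    if len(census.stems):
        q = census.stems["plot"].map({p.plot_id: p.quadrat for p in census.plots})
        ix = np.floor(census.stems["x"].to_numpy() / q.to_numpy()).astype(int)
        iy = np.floor(census.stems["y"].to_numpy() / q.to_numpy()).astype(int)
        labels = (census.stems["plot"].astype(str) + ":" +
                  pd.Series(ix).astype(str) + ":" + pd.Series(iy).astype(str))
        col_pos = {c: j for j, c in enumerate(columns)}
        row_pos = {s: i for i, s in enumerate(species)}
        np.add.at(
            arr,
            (census.stems["species"].map(row_pos).to_numpy(),
             labels.map(col_pos).to_numpy()),
            1,
        )
    counts = pd.DataFrame(arr, index=species, columns=columns)
    lf = census.life_form_of()
    species_meta = pd.DataFrame(
        {"life_form": [lf.get(s, "tree") for s in species]}, index=species
    )
    return QuadratMatrix(abundance=counts, quadrat_meta=quadrat_meta,
                         species_meta=species_meta)


def filter_min_abundance(qm: QuadratMatrix, min_n: int = 5) -> QuadratMatrix:
    """Keep species whose total abundance is at least ``min_n``.

    The default of 5 reads the standard "more than four individuals"
    inclusion rule for plot-level association tests literally.
    An empty result is valid; downstream stages must cope with 0 species.
    """
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    totals = qm.abundance.sum(axis=1)
    keep = totals[totals >= min_n].index
    return QuadratMatrix(
        abundance=qm.abundance.loc[keep],
        quadrat_meta=qm.quadrat_meta,
        species_meta=qm.species_meta.loc[keep],
    )
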