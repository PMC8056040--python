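import numpy as np
import pandas as pd
import pytest

from foresthab.census import CensusTable, PlotSpec, STEM_COLUMNS, grid_stems


def make_census(rows, plots):
    """rows: (plot, species, life_form, x, y, dbh) tuples."""
    stems = pd.DataFrame(
        [(f"s{i}", *r) for i, r in enumerate(rows)], columns=STEM_COLUMNS
    )
    return CensusTable(stems=stems, plots=plots)


@pytest.fixture
def toy_census():
    """One 20 x 20 m plot, 4 quadrats, 3 species with fixed DBHs.

    Species A: 6 stems, B: 3 stems, C: 1 stem.
    """
    plot = PlotSpec("P1", 20, 20, 10)
    rows = []
    # A: 6 stems spread over 3 quadrats
    for x, y in [(1, 1), (2, 2), (3, 3), (11, 1), (12, 2), (1, 11)]:
        rows.append(("P1", "A", "tree", x, y, 10.0))
    # B: 3 stems in 2 quadrats
    for x, y in [(5, 5), (15, 5), (16, 6)]:
        rows.append(("P1", "B", "tree", x, y, 20.0))
    # C: 1 stem
    rows.append(("P1", "C", "shrub", 15, 15, 5.0))
    return make_census(rows, [plot])


@pytest.fixture
def toy_qm(toy_census):
    return grid_stems(toy_census)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def uniform_census(rng, n_stems=200, plots=None, species=("sp1",), forms=None):
    """CSR stems spread uniformly over the given plots."""
    if plots is None:
        plots = [PlotSpec("P1", 100, 100, 10)]
    if forms is None:
        forms = {s: "tree" for s in species}
    rows = []
    for s in species:
        for _ in range(n_stems):
            p = plots[rng.integers(len(plots))]
            rows.append(
                (p.plot_id, s, forms[s],
                 rng.uniform(0, p.width), rng.uniform(0, p.height), 5.0)
            )
    return make_census(rows, plots)
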