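import numpy as np
import pytest

from foresthab.census import PlotSpec, filter_min_abundance, grid_stems
from foresthab.habitat import (
    build_combined_map,
    enumerate_null_maps,
    relative_density,
    torus_test,
    transform_stack,
)
from .conftest import make_census, uniform_census


def four_plot_census(rng, n_stems=120):
    plots = [PlotSpec(f"P{i+1}", 100, 100, 10) for i in range(4)]
    return uniform_census(rng, n_stems=n_stems, plots=plots, species=("sp",))


class TestBuildCombinedMap:
    def test_forty_by_ten(self, rng):
        hmap = build_combined_map(four_plot_census(rng))
        assert (hmap.nx, hmap.ny) == (40, 10)
        assert list(hmap.habitat_cell_counts()) == [100] * 4

    def test_layout_permutation_preserves_areas(self, rng):
        census = four_plot_census(rng)
        hmap = build_combined_map(census, layout=["P3", "P1", "P4", "P2"])
        assert list(hmap.habitat_cell_counts()) == [100] * 4
        assert hmap.habitats == ["P3", "P1", "P4", "P2"]

    def test_single_plot(self, rng):
        census = uniform_census(rng, n_stems=10)
        hmap = build_combined_map(census)
        assert (hmap.nx, hmap.ny) == (10, 10)
        assert len(hmap.habitats) == 1

    def test_bad_layout_rejected(self, rng):
        with pytest.raises(ValueError, match="permutation"):
            build_combined_map(four_plot_census(rng), layout=["P1", "P2"])


class TestEnumerateNullMaps:
    @pytest.mark.parametrize(
        "nx, ny, expected", [(1, 1, 3), (2, 2, 15), (40, 10, 1599)]
    )
    def test_null_map_count(self, rng, nx, ny, expected):
        from foresthab.habitat import HabitatMap

        codes = (np.arange(nx * ny).reshape(nx, ny) % 2)
        hmap = HabitatMap(codes=codes, habitats=["a", "b"], cell_of_quadrat={})
        assert sum(1 for _ in enumerate_null_maps(hmap)) == expected

    def test_habitat_areas_conserved_on_all_1600(self, rng):
        hmap = build_combined_map(four_plot_census(rng))
        _, stack = transform_stack(hmap)
        assert stack.shape == (1600, 400)
        counts = np.stack([(stack == h).sum(axis=1) for h in range(4)])
        assert (counts == 100).all()


class TestRelativeDensity:
    def test_uniform_is_one(self):
        counts = np.ones(8)
        codes = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        assert relative_density(counts, codes, 0) == pytest.approx(1.0)
        assert relative_density(counts, codes, 1) == pytest.approx(1.0)

    def test_concentrated_in_quarter(self):
        counts = np.zeros(8)
        counts[:2] = 5
        codes = np.array([0, 0, 1, 1, 1, 1, 1, 1])
        assert relative_density(counts, codes, 0) == pytest.approx(4.0)

    def test_hand_value_eight_cells(self):
        counts = np.array([3, 1, 0, 0, 2, 0, 1, 1])
        codes = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        # habitat 0: 4 stems over 4 cells; overall: 8 stems over 8 cells
        assert relative_density(counts, codes, 0) == pytest.approx(
            (4 / 4) / (8 / 8)
        )

    def test_absent_species_raises(self):
        with pytest.raises(ValueError, match="no stems"):
            relative_density(np.zeros(4), np.array([0, 0, 1, 1]), 0)


def brute_force_torus(cell_counts, labels_2d, alpha=0.05):
    """Exhaustive torus-translation p-values, written with explicit loops.

    ``cell_counts[(ix, iy)]`` are stems of one species; ``labels_2d`` is the
    W x H habitat grid as nested lists.  Returns {habitat: (p_pos, p_neg)}.
    """
    W, H = len(labels_2d), len(labels_2d[0])
    n_cells = W * H

    def label_at(variant, dx, dy, ix, iy):
        jx, jy = (ix - dx) % W, (iy - dy) % H
        if variant == "identity":
            return labels_2d[jx][jy]
        if variant == "rot180":
            return labels_2d[W - 1 - jx][H - 1 - jy]
        if variant == "mirror":
            return labels_2d[W - 1 - jx][jy]
        return labels_2d[jx][H - 1 - jy]  # mirror_rot180

    habitats = sorted({l for col in labels_2d for l in col})
    total = sum(cell_counts.values())
    rd_by_map = {h: [] for h in habitats}
    for variant in ("identity", "rot180", "mirror", "mirror_rot180"):
        for dx in range(W):
            for dy in range(H):
                for h in habitats:
                    stems = cells = 0
                    for ix in range(W):
                        for iy in range(H):
                            if label_at(variant, dx, dy, ix, iy) == h:
                                stems += cell_counts.get((ix, iy), 0)
                                cells += 1
                    rd_by_map[h].append((stems / cells) / (total / n_cells))
    out = {}
    for h in habitats:
        rds = rd_by_map[h]
        obs = rds[0]  # identity, no shift
        null = rds[1:]
        p_pos = (sum(1 for v in null if v >= obs - 1e-12) + 1) / len(rds)
        p_neg = (sum(1 for v in null if v <= obs + 1e-12) + 1) / len(rds)
        out[h] = (p_pos, p_neg)
    return out


class TestTorusTest:
    def two_habitat_census(self):
        """Two 10 x 20 m plots -> combined 2 x 2 quadrat grid."""
        plots = [PlotSpec("A", 10, 20, 10), PlotSpec("B", 10, 20, 10)]
        rows = (
            [("A", "s1", "tree", 5.0, 5.0, 5.0)] * 4
            + [("A", "s1", "tree", 5.0, 15.0, 5.0)] * 2
            + [("B", "s1", "tree", 5.0, 5.0, 5.0)] * 1
            + [("A", "s2", "tree", 5.0, 5.0, 5.0)] * 1
            + [("B", "s2", "tree", 5.0, 5.0, 5.0)] * 3
            + [("B", "s2", "tree", 5.0, 15.0, 5.0)] * 2
        )
        return make_census(rows, plots)

    def test_matches_exhaustive_enumeration(self):
        census = self.two_habitat_census()
        qm = grid_stems(census)
        hmap = build_combined_map(census)
        table = torus_test(qm, hmap, alpha=0.05)
        labels_2d = [[hmap.habitats[hmap.codes[ix, iy]] for iy in range(hmap.ny)]
                     for ix in range(hmap.nx)]
        for sp in ("s1", "s2"):
            cell_counts = {}
            for label, (ix, iy) in hmap.cell_of_quadrat.items():
                cell_counts[(ix, iy)] = int(qm.abundance.at[sp, label])
            expected = brute_force_torus(cell_counts, labels_2d)
            for h, (p_pos, p_neg) in expected.items():
                row = table.query("species == @sp and habitat == @h").iloc[0]
                assert row["p_pos"] == pytest.approx(p_pos)
                assert row["p_neg"] == pytest.approx(p_neg)

    def test_p_values_on_discrete_grid(self):
        census = self.two_habitat_census()
        qm = grid_stems(census)
        table = torus_test(qm, build_combined_map(census))
        n_maps = 16
        ticks = np.round(table[["p_pos", "p_neg"]].to_numpy() * n_maps)
        assert np.allclose(table[["p_pos", "p_neg"]].to_numpy(),
                           ticks / n_maps)
        assert (table["p_pos"] + table["p_neg"] >= 1 + 1 / n_maps - 1e-12).all()

    def test_uniform_stems_never_significant(self):
        plots = [PlotSpec(f"P{i+1}", 20, 20, 10) for i in range(2)]
        rows = []
        for p in plots:
            for ix in range(2):
                for iy in range(2):
                    rows.append((p.plot_id, "s", "tree",
                                 10 * ix + 5.0, 10 * iy + 5.0, 5.0))
        census = make_census(rows, plots)
        table = torus_test(grid_stems(census), build_combined_map(census))
        assert (table["class"] == "none").all()
        assert table["observed_rd"].to_numpy() == pytest.approx([1.0, 1.0])

    def test_species_relabeling_permutes_rows_only(self, rng):
        census = four_plot_census(rng)
        stems = census.stems.copy()
        stems["species"] = "zz_" + stems["species"]
        relabeled = make_census(
            [tuple(r) for r in stems[["plot", "species", "life_form",
                                      "x", "y", "dbh"]].to_numpy()],
            census.plots,
        )
        t1 = torus_test(grid_stems(census), build_combined_map(census))
        t2 = torus_test(grid_stems(relabeled), build_combined_map(relabeled))
        np.testing.assert_allclose(
            t1[["observed_rd", "p_pos", "p_neg"]].to_numpy(),
            t2[["observed_rd", "p_pos", "p_neg"]].to_numpy(),
        )

    def test_preferred_species_detected(self, rng):
        """A strongly concentrated species comes out positive."""
        from foresthab.synthetic import (
            PreferenceSpec, apply_preferences, default_config, generate_census,
        )

        cfg = apply_preferences(
            default_config(n_species=1, mean_abundance=300, seed=42),
            [PreferenceSpec("sp01", "P3", 10.0)],
        )
        census = generate_census(cfg)
        qm = filter_min_abundance(grid_stems(census), 5)
        table = torus_test(qm, build_combined_map(census))
        row = table.query("habitat == 'P3'").iloc[0]
        assert row["class"] == "positive"
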