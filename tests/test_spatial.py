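"""Spatial statistics against brute-force oracles and hand-computed cases."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from tmespatial import io, spatial, synthetic
from tmespatial.errors import InputError
from conftest import brute_force_interactions, brute_force_nn, random_cell_table


def make_cells(points_by_phenotype):
    rows = []
    cid = 0
    for phenotype, pts in points_by_phenotype.items():
        for x, y in pts:
            rows.append({"cell_id": cid, "sample_id": "S", "x_um": x, "y_um": y,
                         "phenotype": phenotype})
            cid += 1
    return pd.DataFrame(rows)


class TestNNDistances:
    def test_pythagorean_case(self):
        cells = make_cells({"RC": [(0, 0)], "NC": [(3, 4), (6, 8)]})
        nnset = spatial.nn_distances(cells, "RC", "NC")
        assert nnset.distances_um[0] == pytest.approx(5.0)

    def test_no_neighbor_in_scope_gives_empty_set(self):
        cells = make_cells({"RC": [(0, 0), (1, 1)], "NC": [(5, 5)]})
        cells["region_label"] = ["IT", "IT", "PT"]
        nnset = spatial.nn_distances(cells, "RC", "NC", scope="IT")
        assert nnset.n_ref_total == 2
        assert nnset.n_ref_with_neighbor == 0
        assert len(nnset.distances_um) == 0
        assert np.isnan(nnset.median_um())

    def test_unknown_phenotype_rejected(self):
        cells = make_cells({"RC": [(0, 0)], "NC": [(1, 1)]})
        with pytest.raises(InputError, match="unknown phenotype"):
            spatial.nn_distances(cells, "RC", "NOPE")

    def test_multi_sample_table_rejected(self):
        cells = make_cells({"RC": [(0, 0)], "NC": [(1, 1)]})
        cells.loc[1, "sample_id"] = "S2"
        with pytest.raises(InputError, match="one sample"):
            spatial.nn_distances(cells, "RC", "NC")

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        cells = random_cell_table(rng, 800, ["A", "B", "C"])
        nnset = spatial.nn_distances(cells, "A", "B")
        ref = cells[cells["phenotype"] == "A"][["x_um", "y_um"]].to_numpy()
        nbr = cells[cells["phenotype"] == "B"][["x_um", "y_um"]].to_numpy()
        np.testing.assert_allclose(nnset.distances_um, brute_force_nn(ref, nbr))

    def test_scope_restricts_both_sides(self):
        cells = make_cells({"RC": [(1, 1), (50, 50)], "NC": [(2, 2), (51, 51)]})
        cells["region_label"] = ["IT", "PT", "IT", "PT"]
        nnset = spatial.nn_distances(cells, "RC", "NC", scope="IT")
        assert nnset.n_ref_total == 1
        assert nnset.distances_um[0] == pytest.approx(np.sqrt(2))


class TestProximityCurve:
    def test_coincident_pairs_give_p0_one(self):
        cells = make_cells({"RC": [(1, 1), (2, 2)], "NC": [(1, 1), (2, 2)]})
        curve = spatial.proximity_curve(spatial.nn_distances(cells, "RC", "NC"))
        assert curve.at(0.0) == 1.0

    def test_neighborless_refs_stay_in_denominator(self):
        cells = make_cells({"RC": [(0, 0), (500, 500)], "NC": [(0, 3)]})
        curve = spatial.proximity_curve(spatial.nn_distances(cells, "RC", "NC"))
        assert curve.at(5.0) == pytest.approx(0.5)
        # far RC's nearest NC is ~703 um away, beyond the 300 um grid
        assert curve.at(300.0) == pytest.approx(0.5)

    def test_endpoint_matches_direct_count(self, small_tissue):
        cells, _, _ = small_tissue
        nnset = spatial.nn_distances(cells, "CD8+Tim3-", "PanCK+G9+")
        curve = spatial.proximity_curve(nnset)
        direct = (nnset.distances_um <= 300.0).sum() / nnset.n_ref_total
        assert curve.at(300.0) == pytest.approx(direct)

    @pytest.mark.parametrize("seed", range(10))
    def test_curve_nondecreasing(self, seed):
        rng = np.random.default_rng(seed)
        cells = random_cell_table(rng, 200, ["A", "B"])
        curve = spatial.proximity_curve(spatial.nn_distances(cells, "A", "B"))
        assert (np.diff(curve.proportion) >= 0).all()
        assert ((curve.proportion >= 0) & (curve.proportion <= 1)).all()

    def test_bad_grid_rejected(self, small_tissue):
        cells, _, _ = small_tissue
        nnset = spatial.nn_distances(cells, "CD8+Tim3-", "PanCK+G9+")
        with pytest.raises(InputError, match="grid_step"):
            spatial.proximity_curve(nnset, grid_step_um=0.0)


class TestEffectiveStat:
    def test_composition_arithmetic(self):
        # 82 of 100 effective cells Tim3-, 18 Tim3+ -> 82% / 18%
        tim3neg = [(i, 0.0) for i in range(82)] + [(1000 + i, 500.0) for i in range(18)]
        tim3pos = [(i, 1.0) for i in range(18)] + [(2000 + i, 500.0) for i in range(82)]
        targets = [(i, 0.5) for i in range(101)]
        cells = make_cells({"Tim3-": tim3neg, "Tim3+": tim3pos, "T": targets})
        stat = spatial.effective_stat(cells, ["Tim3-", "Tim3+"], "T", radius_um=15.0)
        assert stat.composition_pct["Tim3-"] == pytest.approx(82.0)
        assert stat.composition_pct["Tim3+"] == pytest.approx(18.0)
        assert stat.effective_fraction_pct["Tim3-"] == pytest.approx(82.0)

    def test_no_effective_cells_flagged(self):
        cells = make_cells({"R": [(0, 0)], "T": [(500, 500)]})
        stat = spatial.effective_stat(cells, ["R"], "T", radius_um=15.0)
        assert stat.effective_fraction_pct["R"] == 0.0
        assert stat.composition_pct is None

    def test_negative_radius_rejected(self, small_tissue):
        cells, _, _ = small_tissue
        with pytest.raises(InputError, match="radius"):
            spatial.effective_stat(cells, ["CD8+Tim3-"], "PanCK+G9+", radius_um=-1.0)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_within_radius_scan(self, seed):
        rng = np.random.default_rng(seed)
        cells = random_cell_table(rng, 400, ["R1", "R2", "T"], width=300.0)
        stat = spatial.effective_stat(cells, ["R1", "R2"], "T", radius_um=25.0)
        xy = {p: cells[cells["phenotype"] == p][["x_um", "y_um"]].to_numpy()
              for p in ("R1", "R2", "T")}
        for sub in ("R1", "R2"):
            d = brute_force_nn(xy[sub], xy["T"])
            expected = 100.0 * (d <= 25.0).sum() / len(d)
            assert stat.effective_fraction_pct[sub] == pytest.approx(expected)

    def test_agrees_with_proximity_curve_at_300(self, small_tissue):
        cells, _, _ = small_tissue
        nnset = spatial.nn_distances(cells, "CD8+Tim3-", "PanCK+G9+")
        curve = spatial.proximity_curve(nnset)
        stat = spatial.effective_stat(cells, ["CD8+Tim3-"], "PanCK+G9+", radius_um=300.0)
        assert stat.effective_fraction_pct["CD8+Tim3-"] == pytest.approx(
            100.0 * curve.at(300.0)
        )


class TestInteractions:
    def test_two_cell_case(self):
        cells = make_cells({"A": [(0, 0)], "B": [(1, 0)]})
        im = spatial.nn_interactions(cells)
        assert im.to_frame().loc["A", "B"] == 1
        assert im.to_frame().loc["B", "A"] == 1

    def test_diagonal_always_zero(self, small_tissue):
        cells, _, _ = small_tissue
        im = spatial.nn_interactions(cells)
        assert (np.diag(im.matrix) == 0).all()

    def test_single_phenotype_warns_and_zeroes(self):
        cells = make_cells({"A": [(0, 0), (1, 1)]})
        with pytest.warns(UserWarning, match="fewer than two"):
            im = spatial.nn_interactions(cells)
        assert im.matrix.sum() == 0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(100 + seed)
        cells = random_cell_table(rng, 600, ["A", "B", "C", "D"])
        im = spatial.nn_interactions(cells, ["A", "B", "C", "D"])
        expected = brute_force_interactions(
            cells[["x_um", "y_um"]].to_numpy(),
            cells["phenotype"].to_numpy(),
            cells["cell_id"].to_numpy(),
            ["A", "B", "C", "D"],
        )
        np.testing.assert_array_equal(im.matrix, expected)

    def test_totals_invariant_under_relabeling(self):
        rng = np.random.default_rng(31)
        cells = random_cell_table(rng, 300, ["A", "B", "C"])
        im1 = spatial.nn_interactions(cells, ["A", "B", "C"])
        relabeled = cells.copy()
        relabeled["cell_id"] = rng.permutation(len(cells)) + 10_000
        im2 = spatial.nn_interactions(relabeled, ["A", "B", "C"])
        np.testing.assert_array_equal(im1.matrix.sum(axis=1), im2.matrix.sum(axis=1))


class TestDensity:
    def test_arithmetic(self):
        geom = io.RegionGeometry(
            "S", {"IT": box(0, 0, 1000, 500)}  # 0.5 mm^2
        )
        cells = make_cells({"G9+": [(i * 2.0 + 1, 100.0) for i in range(50)]})
        cells["region_label"] = "IT"
        assert spatial.phenotype_density(cells, geom, "G9+", "IT") == pytest.approx(100.0)

    def test_empty_phenotype_is_zero(self):
        geom = io.RegionGeometry("S", {"IT": box(0, 0, 1000, 1000)})
        cells = make_cells({"X": [(1, 1)]})
        cells["region_label"] = "IT"
        assert spatial.phenotype_density(cells, geom, "Y", "IT") == 0.0

    def test_zero_area_rejected(self):
        geom = io.RegionGeometry("S", {"IT": box(0, 0, 1000, 1000)})
        geom.polygons["PT"] = box(0, 0, 0, 0)
        cells = make_cells({"X": [(1, 1)]})
        cells["region_label"] = "IT"
        with pytest.raises(InputError, match="area"):
            spatial.phenotype_density(cells, geom, "X", "PT")

    def test_poisson_rate_recovered(self):
        config = synthetic.TissueConfig(
            nest_centers=((750.0, 750.0),), nest_radius_um=400.0,
            tumor_intensity_per_mm2=1500.0, p_g9_positive=1.0,
            immune_counts={}, seed=13,
        )
        cells, regions = synthetic.gen_tissue(config)
        cells = io.assign_phenotypes(cells)
        cells = io.assign_regions(cells, regions)
        density = spatial.phenotype_density(cells, regions, "PanCK+G9+", "IT")
        area = regions.areas_mm2["IT"]
        assert abs(density - 1500.0) < 3 * np.sqrt(1500.0 / area)


class TestDensityCorrelation:
    def test_perfect_anticorrelation(self):
        table = pd.DataFrame({"A": np.arange(10.0), "B": -np.arange(10.0)})
        res = spatial.density_correlation(table, ("A", "B"))
        assert res.r == pytest.approx(-1.0)

    def test_constant_vector_flagged_undefined(self):
        table = pd.DataFrame({"A": np.arange(5.0), "B": np.ones(5)})
        res = spatial.density_correlation(table, ("A", "B"))
        assert res.undefined
        assert np.isnan(res.r)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            x, y = rng.normal(size=(2, 12))
            table = pd.DataFrame({"A": x, "B": y})
            res = spatial.density_correlation(table, ("A", "B"), method="pearson")
            xm, ym = x - x.mean(), y - y.mean()
            longhand = (xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum())
            assert res.r == pytest.approx(longhand, abs=1e-12)
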