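import numpy as np
import pytest

from plelscape.plel_core import CategoricalRaster, NAME_TO_CODE
from plelscape import risk_index as rk


def bruteforce_patches(values, mask, code, connectivity=8):
    """Independent stack-based flood fill for patch counting."""
    h, w = values.shape
    seen = np.zeros((h, w), dtype=bool)
    if connectivity == 8:
        offs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        offs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    count = 0
    for r in range(h):
        for c in range(w):
            if seen[r, c] or not mask[r, c] or values[r, c] != code:
                continue
            count += 1
            stack = [(r, c)]
            seen[r, c] = True
            while stack:
                i, j = stack.pop()
                for di, dj in offs:
                    ni, nj = i + di, j + dj
                    if (
                        0 <= ni < h and 0 <= nj < w
                        and not seen[ni, nj] and mask[ni, nj]
                        and values[ni, nj] == code
                    ):
                        seen[ni, nj] = True
                        stack.append((ni, nj))
    return count


class TestVulnerabilityWeights:
    def test_default_ranking_reproduces_canonical_weights(self):
        f = rk.vulnerability_weights()
        expected = {
            "ULL": 0.03, "RLL": 0.06, "FEL": 0.08, "GEL": 0.11,
            "APL": 0.14, "WEL": 0.17, "IPL": 0.19, "OEL": 0.22,
        }
        for name, val in expected.items():
            assert f[name] == pytest.approx(val, abs=1e-12)
        assert f.sum() == pytest.approx(1.00, abs=1e-9)

    def test_single_class_gets_weight_one(self):
        f = rk.vulnerability_weights({"GEL": 5})
        assert f["GEL"] == pytest.approx(1.0)

    def test_non_positive_rank_rejected(self):
        with pytest.raises(ValueError):
            rk.vulnerability_weights({"GEL": 0, "APL": 1})


class TestBuildGrid:
    def test_fully_valid_raster_tiles_into_900_hm2_units(self):
        r = CategoricalRaster(values=np.ones((300, 300)), cell_size=30.0)
        grid = rk.build_grid(r, unit_edge=3000.0)
        assert len(grid) == 9
        assert all(u.area_hm2 == pytest.approx(900.0) for u in grid.units)

    def test_half_masked_edge_unit_has_half_area(self):
        r = CategoricalRaster(values=np.ones((100, 200)), cell_size=30.0)
        r.mask[:, 150:] = False  # right half of the second unit invalid
        grid = rk.build_grid(r, unit_edge=3000.0)
        areas = sorted(u.area_hm2 for u in grid.units)
        assert areas == [pytest.approx(450.0), pytest.approx(900.0)]

    def test_low_coverage_units_dropped(self):
        r = CategoricalRaster(values=np.ones((100, 200)), cell_size=30.0)
        r.mask[:, 105:] = False  # second unit has 5% valid cells
        grid = rk.build_grid(r, unit_edge=3000.0, min_coverage=0.1)
        assert len(grid) == 1

    def test_non_multiple_edge_rejected(self):
        r = CategoricalRaster(values=np.ones((100, 100)), cell_size=30.0)
        with pytest.raises(ValueError, match="multiple"):
            rk.build_grid(r, unit_edge=1000.0)


class TestLabelPatches:
    def test_constant_unit_is_one_patch(self):
        r = CategoricalRaster(values=np.full((10, 10), 6), cell_size=300.0)
        grid = rk.build_grid(r, unit_edge=3000.0)
        assert rk.label_patches(r, grid.units[0]) == {6: 1}

    def test_diagonal_cells_connectivity_convention(self):
        v = np.array([[1, 2], [2, 1]])
        r = CategoricalRaster(values=v, cell_size=1500.0)
        grid = rk.build_grid(r, unit_edge=3000.0)
        assert rk.label_patches(r, grid.units[0], connectivity=8)[1] == 1
        assert rk.label_patches(r, grid.units[0], connectivity=4)[1] == 2

    def test_absent_class_has_no_entry(self):
        r = CategoricalRaster(values=np.full((4, 4), 6), cell_size=750.0)
        grid = rk.build_grid(r, unit_edge=3000.0)
        assert 1 not in rk.label_patches(r, grid.units[0])

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_bruteforce_flood_fill(self, connectivity):
        rng = np.random.default_rng(42)
        for trial in range(5):
            v = rng.integers(1, 5, size=(20, 20))
            r = CategoricalRaster(values=v, cell_size=150.0)
            grid = rk.build_grid(r, unit_edge=3000.0)
            got = rk.label_patches(r, grid.units[0], connectivity=connectivity)
            for code in np.unique(v):
                assert got[code] == bruteforce_patches(
                    v, r.mask, code, connectivity
                )


class TestDominance:
    def test_single_unit_single_class_dominance_is_one(self):
        r = CategoricalRaster(values=np.full((30, 30), 6), cell_size=100.0)
        grid = rk.build_grid(r, unit_edge=3000.0)
        dom = rk.global_dominance(r, grid)
        assert dom.loc["GEL", "D"] == pytest.approx(1.0)

    def test_toy_landscape_hand_values(self, toy_unit_raster):
        grid = rk.build_grid(toy_unit_raster, unit_edge=3000.0)
        dom = rk.global_dominance(toy_unit_raster, grid)
        assert dom.loc["GEL", "D"] == pytest.approx(0.6833, abs=1e-4)
        assert dom.loc["APL", "D"] == pytest.approx(0.5667, abs=1e-4)

    def test_patch_and_area_shares_normalize(self):
        rng = np.random.default_rng(1)
        r = CategoricalRaster(values=rng.integers(1, 9, (60, 60)), cell_size=50.0)
        grid = rk.build_grid(r, unit_edge=1000.0)
        dom = rk.global_dominance(r, grid)
        assert dom["M"].sum() == pytest.approx(1.0)
        assert dom["L"].sum() == pytest.approx(1.0)
        assert ((dom[["Q", "M", "L"]] >= 0) & (dom[["Q", "M", "L"]] <= 1)).all().all()

    def test_empty_grid_rejected(self):
        r = CategoricalRaster(values=np.ones((10, 10)), cell_size=300.0)
        grid = rk.build_grid(r, unit_edge=3000.0)
        grid.units = []
        with pytest.raises(ValueError, match="empty"):
            rk.global_dominance(r, grid)


class TestUnitEri:
    def test_toy_unit_hand_calculation(self, toy_unit_raster):
        grid = rk.build_grid(toy_unit_raster, unit_edge=3000.0)
        dom = rk.global_dominance(toy_unit_raster, grid)
        rec = rk.unit_eri(
            toy_unit_raster, grid.units[0], dom, rk.vulnerability_weights()
        )
        assert rec["ERI"] == pytest.approx(0.017657, abs=1e-6)
        assert rec["U1"] == pytest.approx(0.006735, abs=1e-6)
        assert rec["U2"] == 0.0
        assert rec["U3"] == pytest.approx(0.010922, abs=1e-6)

    def test_single_class_unit_hand_calculation(self):
        r = CategoricalRaster(values=np.full((30, 30), 6), cell_size=100.0)
        grid = rk.build_grid(r, unit_edge=3000.0)
        dom = rk.global_dominance(r, grid)
        rec = rk.unit_eri(r, grid.units[0], dom, rk.vulnerability_weights())
        assert rec["ERI"] == pytest.approx(0.022611, abs=1e-6)

    def test_disturbance_weights_must_sum_to_one(self, toy_unit_raster):
        grid = rk.build_grid(toy_unit_raster, unit_edge=3000.0)
        dom = rk.global_dominance(toy_unit_raster, grid)
        with pytest.raises(ValueError, match="sum to 1"):
            rk.unit_eri(
                toy_unit_raster, grid.units[0], dom,
                rk.vulnerability_weights(), weights=(0.5, 0.3, 0.3),
            )

    def test_eri_equals_tier_partition_on_random_landscapes(self):
        rng = np.random.default_rng(7)
        for trial in range(3):
            v = rng.integers(1, 9, size=(40, 40))
            r = CategoricalRaster(values=v, cell_size=75.0)
            grid = rk.build_grid(r, unit_edge=1500.0)
            table = rk.compute_unit_table(r, grid)
            np.testing.assert_allclose(
                table["ERI"], table[["U1", "U2", "U3"]].sum(axis=1), atol=1e-12
            )

    def test_unit_areas_partition_unit(self):
        rng = np.random.default_rng(9)
        v = rng.integers(1, 9, size=(40, 40))
        r = CategoricalRaster(values=v, cell_size=75.0)
        grid = rk.build_grid(r, unit_edge=1500.0)
        table = rk.compute_unit_table(r, grid)
        area_cols = [c for c in table.columns if c.startswith("A_") and c != "A_k"]
        np.testing.assert_allclose(
            table[area_cols].sum(axis=1), table["A_k"], atol=1e-6
        )

    def test_splitting_a_patch_never_decreases_disturbance(self):
        # one 6x4 GEL patch inside an OEL unit vs the same area in two pieces
        gel, oel = NAME_TO_CODE["GEL"], NAME_TO_CODE["OEL"]
        v1 = np.full((20, 20), oel)
        v1[4:10, 8:12] = gel
        v2 = np.full((20, 20), oel)
        v2[2:5, 8:12], v2[12:15, 8:12] = gel, gel  # same 24 cells, 2 patches
        recs = []
        for v in (v1, v2):
            r = CategoricalRaster(values=v, cell_size=150.0)
            grid = rk.build_grid(r, unit_edge=3000.0)
            dom = rk.global_dominance(r, grid)
            recs.append(
                rk.unit_eri(r, grid.units[0], dom, rk.vulnerability_weights())
            )
        assert recs[1]["E_GEL"] >= recs[0]["E_GEL"]

    def test_mean_unit_eri_in_expected_band_on_synthetic(self, small_synth_series):
        series = small_synth_series["series"]
        grid = rk.build_grid(series[0], unit_edge=1500.0)
        table = rk.compute_unit_table(series[-1], grid)
        assert 0.001 <= table["ERI"].mean() <= 0.05

    def test_unit_scope_dominance_also_partitions(self, toy_unit_raster):
        grid = rk.build_grid(toy_unit_raster, unit_edge=3000.0)
        table = rk.compute_unit_table(
            toy_unit_raster, grid, dominance_scope="unit"
        )
        np.testing.assert_allclose(
            table["ERI"], table[["U1", "U2", "U3"]].sum(axis=1), atol=1e-12
        )
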