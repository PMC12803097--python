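import numpy as np
import pytest

from paleorealms.core import RealmSet
from paleorealms.dmm import (
    LatLonGrid,
    PaleoSnapshot,
    StratifiedDMM,
    build_stratified_dmm,
    extrapolate_realms,
    multipliers_from_distances,
    overwater_distance_matrix,
    preset_boundaries,
    read_dmm_stack,
    realm_centroids,
    write_dmm_stack,
)
from paleorealms.geo import haversine_km, spherical_centroid
from paleorealms.simulate import sim_paleogeography

# 100 km of longitude at the equator
DEG_100KM = np.degrees(100.0 / 6371.0088)


def row_grid(n_cells, water=None):
    lons = np.arange(n_cells) * DEG_100KM
    lats = np.array([0.0])
    w = np.ones((1, n_cells), dtype=bool) if water is None else np.asarray([water])
    return LatLonGrid(lons, lats, w)


class TestExtrapolation:
    def test_nearest_seed_labels(self):
        realms = RealmSet(("A", "B"))
        grid = row_grid(4)
        snap = PaleoSnapshot(0.0, [grid.lons[0], grid.lons[3]], [0.0, 0.0], ["A", "B"], grid)
        labels = extrapolate_realms(snap, realms)
        assert labels[0].tolist() == [0, 0, 1, 1]

    def test_equidistant_tie_goes_to_lower_realm_order(self):
        realms = RealmSet(("A", "B"))
        grid = row_grid(3)
        snap = PaleoSnapshot(0.0, [grid.lons[0], grid.lons[2]], [0.0, 0.0], ["B", "A"], grid)
        labels = extrapolate_realms(snap, realms)
        assert labels[0, 1] == 0  # middle cell ties; A (order 0) wins

    def test_identity_when_seeds_match_present_map(self):
        realms = RealmSet(("A", "B"))
        grid = row_grid(6)
        seeds_lon = grid.lons.tolist()
        seeds = ["A", "A", "A", "B", "B", "B"]
        snap = PaleoSnapshot(0.0, seeds_lon, [0.0] * 6, seeds, grid)
        labels = extrapolate_realms(snap, realms)
        assert labels[0].tolist() == [0, 0, 0, 1, 1, 1]

    def test_land_cells_unlabeled(self):
        realms = RealmSet(("A", "B"))
        grid = row_grid(4, water=[True, False, True, True])
        snap = PaleoSnapshot(0.0, [grid.lons[0], grid.lons[3]], [0.0, 0.0], ["A", "B"], grid)
        labels = extrapolate_realms(snap, realms)
        assert labels[0, 1] == -1


class TestCentroids:
    def test_single_cell_realm(self):
        realms = RealmSet(("A", "B"))
        grid = row_grid(2)
        labels = np.array([[0, 1]])
        cents = realm_centroids(labels, grid, realms)
        assert cents["A"] == pytest.approx((0.0, 0.0))

    def test_two_cells_midpoint(self):
        lon, lat = spherical_centroid([0.0, 10.0], [0.0, 0.0])
        assert (lon, lat) == (pytest.approx(5.0), pytest.approx(0.0))

    def test_antipodal_degenerate(self):
        with pytest.raises(ValueError, match="centroid"):
            spherical_centroid([0.0, 180.0], [0.0, 0.0])


class TestOverwaterDistances:
    def test_straight_row_path(self):
        realms = RealmSet(("A", "B"))
        grid = row_grid(5)
        cents = {"A": (grid.lons[0], 0.0), "B": (grid.lons[4], 0.0)}
        D = overwater_distance_matrix(cents, grid, realms)
        assert D[0, 1] == pytest.approx(400.0, rel=1e-3)
        assert D[0, 0] == 0.0
        assert D[0, 1] == D[1, 0]

    def test_disconnected_row_is_infinite(self):
        realms = RealmSet(("A", "B"))
        grid = row_grid(5, water=[True, True, False, True, True])
        cents = {"A": (grid.lons[0], 0.0), "B": (grid.lons[4], 0.0)}
        with pytest.warns(UserWarning, match="not connected"):
            D = overwater_distance_matrix(cents, grid, realms)
        assert np.isinf(D[0, 1])

    def test_detour_matches_brute_force(self):
        import networkx as nx

        realms = RealmSet(("A", "B"))
        lons = np.arange(5) * DEG_100KM
        lats = np.arange(3) * DEG_100KM
        water = np.ones((3, 5), dtype=bool)
        water[1, 2] = False  # 1-cell land pillar mid-row
        grid = LatLonGrid(lons, lats, water)
        cents = {"A": (lons[0], lats[1]), "B": (lons[4], lats[1])}
        D = overwater_distance_matrix(cents, grid, realms)

        G = nx.Graph()
        for y in range(3):
            for x in range(5):
                if not water[y, x]:
                    continue
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        ny, nx_ = y + dy, x + dx
                        if (dy, dx) != (0, 0) and 0 <= ny < 3 and 0 <= nx_ < 5 and water[ny, nx_]:
                            w = haversine_km(lons[x], lats[y], lons[nx_], lats[ny])
                            G.add_edge((y, x), (ny, nx_), weight=float(w))
        brute = nx.shortest_path_length(G, (1, 0), (1, 4), weight="weight")
        assert D[0, 1] == pytest.approx(brute, rel=1e-9)

    def test_path_never_beats_geodesic(self):
        rng = np.random.default_rng(1)
        realms = RealmSet(("A", "B"))
        for _ in range(10):
            water = rng.uniform(size=(4, 6)) > 0.2
            water[1, 0] = water[2, 5] = True
            grid = LatLonGrid(np.arange(6) * DEG_100KM, np.arange(4) * DEG_100KM, water)
            cents = {"A": (grid.lons[0], grid.lats[1]), "B": (grid.lons[5], grid.lats[2])}
            D = overwater_distance_matrix(cents, grid, realms)
            gc = haversine_km(*cents["A"], *cents["B"])
            assert D[0, 1] >= gc - 1e-6


class TestMultipliers:
    def test_minmax_arithmetic(self):
        D = np.array([[0.0, 50, 100], [50, 0.0, 75], [100, 75, 0.0]])
        M = multipliers_from_distances(D)
        assert M[0, 1] == pytest.approx(0.5)
        assert M[0, 2] == pytest.approx(0.0)
        assert M[1, 2] == pytest.approx(0.25)
        assert np.allclose(np.diag(M), 1.0)

    def test_two_realms_farthest_pair_zero_with_floor_option(self):
        D = np.array([[0.0, 123.0], [123.0, 0.0]])
        M = multipliers_from_distances(D, degenerate_to_ones=False)
        assert M[0, 1] == pytest.approx(0.0)
        M = multipliers_from_distances(D, degenerate_to_ones=False, floor=0.01)
        assert M[0, 1] == pytest.approx(0.01)

    def test_equal_distances_default_to_ones(self):
        D = np.full((3, 3), 80.0)
        np.fill_diagonal(D, 0.0)
        with pytest.warns(UserWarning, match="all-ones"):
            M = multipliers_from_distances(D)
        assert np.allclose(M, 1.0)

    def test_infinite_entries_replaced(self):
        D = np.array([[0.0, 100.0, np.inf], [100.0, 0.0, 50.0], [np.inf, 50.0, 0.0]])
        M = multipliers_from_distances(D)
        assert M[0, 2] == pytest.approx(0.0)  # 150/150 -> 0
        assert 0 < M[0, 1] < 1


class TestStratifiedStack:
    def test_preset_interval_counts(self):
        assert preset_boundaries("cetacean").size == 10
        assert preset_boundaries("other").size == 15

    def test_identical_snapshots_give_identical_matrices(self, marine_realms):
        realms = RealmSet(("A", "B", "C"))
        snaps = sim_paleogeography(realms, boundaries=[5.0, 10.0, 360.0],
                                   drift_deg_per_myr=0.0, seed=3)
        dmm = build_stratified_dmm(snaps, realms, boundaries=[5.0, 10.0, 360.0])
        assert dmm.n_epochs == 3
        for M in dmm.matrices[1:]:
            assert np.allclose(M, dmm.matrices[0])

    def test_invariants_on_built_stack(self):
        realms = RealmSet(("A", "B", "C", "D"))
        snaps = sim_paleogeography(realms, group="cetacean", seed=5,
                                   land_bars=[(20.0, 360.0, -30.0, -10.0)])
        dmm = build_stratified_dmm(snaps, realms, group="cetacean")
        assert dmm.n_epochs == 10
        for M in dmm.matrices:
            finite = ~np.isnan(M)
            assert (M[finite] >= -1e-12).all() and (M[finite] <= 1 + 1e-12).all()
            assert np.allclose(M, M.T, equal_nan=True)
            assert np.allclose(np.diag(M), 1.0)

    def test_epoch_lookup(self):
        realms = RealmSet(("A", "B"))
        dmm = StratifiedDMM.uniform(realms, boundaries=[5.0, 10.0, 360.0])
        assert dmm.epoch_index(0.0) == 0
        assert dmm.epoch_index(4.99) == 0
        assert dmm.epoch_index(5.0) == 1
        assert dmm.epoch_index(360.0) == 2

    def test_stack_text_roundtrip(self, tmp_path):
        realms = RealmSet(("A", "B", "C"))
        rng = np.random.default_rng(0)
        mats = []
        for _ in range(3):
            x = rng.uniform(0.1, 0.9, size=(3, 3))
            M = (x + x.T) / 2
            np.fill_diagonal(M, 1.0)
            mats.append(M)
        dmm = StratifiedDMM(realms, [5.0, 10.0, 360.0], mats)
        path = tmp_path / "stack.txt"
        write_dmm_stack(path, dmm)
        back = read_dmm_stack(path, realms)
        assert np.allclose(back.boundaries, dmm.boundaries)
        for A, B in zip(back.matrices, dmm.matrices):
            assert np.allclose(A, B, atol=1e-6)

    def test_boundary_validation(self):
        realms = RealmSet(("A", "B"))
        with pytest.raises(ValueError, match="increasing"):
            StratifiedDMM(realms, [10.0, 5.0], [np.ones((2, 2))] * 2)
        dmm = StratifiedDMM.uniform(realms, boundaries=[50.0])
        with pytest.raises(ValueError, match="root age"):
            dmm.validate_root_age(80.0)


class TestLandBarMonotonicity:
    def test_land_bar_increases_distance_decreases_multiplier(self):
        realms = RealmSet(("A", "B"))
        lons = np.arange(8) * DEG_100KM
        lats = np.arange(3) * DEG_100KM
        open_grid = LatLonGrid(lons, lats, np.ones((3, 8), dtype=bool))
        barred = np.ones((3, 8), dtype=bool)
        barred[:2, 4] = False  # partial land bar forces a detour
        bar_grid = LatLonGrid(lons, lats, barred)
        cents = {"A": (lons[1], lats[1]), "B": (lons[6], lats[1])}
        D_open = overwater_distance_matrix(cents, open_grid, realms)
        D_bar = overwater_distance_matrix(cents, bar_grid, realms)
        assert D_bar[0, 1] > D_open[0, 1]
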