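import numpy as np
import pytest

from nervemap import (
    DensityMap,
    FiberMask,
    hotspot_volume,
    innervation_profile,
    mean_nnd,
    morans_i,
    shannon_entropy,
)


def _dm(grid, cell_area=None, tissue_frac=None, window_px=10):
    grid = np.asarray(grid, dtype=float)
    if cell_area is None:
        cell_area = np.full(grid.shape, window_px * window_px)
    return DensityMap(grid=grid, cell_area=np.asarray(cell_area), window_px=window_px,
                      window_mm2=0.0064, mpp_eff=8.0, tissue_frac=tissue_frac)


def morans_brute_force(x, valid, adjacency):
    """O(N^2) double-sum oracle for Moran's I on a lattice."""
    rows, cols = x.shape
    cells = [(i, j) for i in range(rows) for j in range(cols) if valid[i, j]]
    n = len(cells)
    xbar = np.mean([x[c] for c in cells])
    num = 0.0
    w = 0
    for i, j in cells:
        for k, l in cells:
            if (i, j) == (k, l):
                continue
            di, dj = abs(i - k), abs(j - l)
            if adjacency == "rook":
                adj = di + dj == 1
            else:
                adj = max(di, dj) == 1
            if adj:
                num += (x[i, j] - xbar) * (x[k, l] - xbar)
                w += 1
    denom = sum((x[c] - xbar) ** 2 for c in cells)
    return (n / w) * num / denom


class TestShannonEntropy:
    def test_single_bin_is_zero(self):
        dm = _dm(np.full((3, 3), 0.05))
        assert shannon_entropy(dm, edges=np.array([0.01, 0.1])) == 0.0

    @pytest.mark.parametrize("k", [2, 4, 8])
    def test_equal_occupancy_gives_ln_k(self, k):
        """Cells equally split across k occupied bins give exactly ln k."""
        edges = np.linspace(0.1, 0.9, k)
        values = np.repeat(edges + 0.01, 6)
        dm = _dm(values.reshape(-1, k))
        assert shannon_entropy(dm, edges=edges) == pytest.approx(np.log(k), abs=1e-12)

    def test_empty_map_raises(self):
        dm = _dm(np.zeros((2, 2)), tissue_frac=np.zeros((2, 2)))
        with pytest.raises(ValueError):
            shannon_entropy(dm)

    def test_only_tissue_cells_counted(self):
        grid = np.array([[0.5, 0.0], [0.5, 0.0]])
        tf = np.array([[1.0, 0.0], [1.0, 0.0]])
        dm = _dm(grid, tissue_frac=tf)
        # covered cells all share one bin -> zero entropy
        assert shannon_entropy(dm, edges=np.array([0.1])) == 0.0

    def test_permutation_invariant(self, rng):
        vals = rng.random(24)
        e1 = shannon_entropy(_dm(vals.reshape(4, 6)))
        e2 = shannon_entropy(_dm(rng.permutation(vals).reshape(6, 4)))
        assert e1 == pytest.approx(e2, abs=1e-12)


class TestMoransI:
    def test_sequential_grid_rook_is_half(self):
        """The 3x3 grid 1..9 with rook adjacency evaluates to exactly 0.5."""
        x = np.arange(1.0, 10.0).reshape(3, 3)
        assert morans_i(x, adjacency="rook") == pytest.approx(0.5, abs=1e-12)

    def test_checkerboard_is_minus_one(self):
        x = (np.indices((4, 4)).sum(axis=0) % 2) * 2.0 - 1.0
        assert morans_i(x, adjacency="rook") == pytest.approx(-1.0, abs=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            x = rng.random((8, 8))
            valid = rng.random((8, 8)) < 0.9
            if valid.sum() < 4:
                continue
            for adj in ("rook", "queen"):
                got = morans_i(x, valid, adj)
                ref = morans_brute_force(x, valid, adj)
                assert got == pytest.approx(ref, abs=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="variance"):
            morans_i(np.ones((3, 3)))

    def test_too_few_cells_raises(self):
        with pytest.raises(ValueError):
            morans_i(np.array([[1.0, 2.0]]), np.array([[True, False]]))

    def test_rotation_invariant(self, rng):
        x = rng.random((6, 6))
        assert morans_i(x, adjacency="queen") == pytest.approx(
            morans_i(np.rot90(x), adjacency="queen"), abs=1e-12
        )


class TestMeanNnd:
    def test_two_points(self):
        assert mean_nnd(np.array([[0.0, 0.0], [0.0, 5.0]])) == pytest.approx(5.0)

    def test_filled_2x2_block(self):
        mask = np.zeros((4, 4), bool)
        mask[1:3, 1:3] = True
        assert mean_nnd(FiberMask(mask, mpp_eff=8.0)) == pytest.approx(1.0)

    def test_single_point_raises(self):
        with pytest.raises(ValueError):
            mean_nnd(np.array([[1.0, 1.0]]))

    def test_matches_all_pairs_brute_force(self, rng):
        for _ in range(20):
            n = rng.integers(2, 200)
            pts = rng.uniform(0, 100, (int(n), 2))
            d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
            np.fill_diagonal(d, np.inf)
            ref = d.min(axis=1).mean()
            assert mean_nnd(pts) == pytest.approx(ref, abs=1e-12)

    def test_rotation_invariant(self, rng):
        mask = rng.random((10, 10)) < 0.3
        if mask.sum() < 2:
            mask[0, 0] = mask[5, 5] = True
        a = mean_nnd(FiberMask(mask, mpp_eff=8.0))
        b = mean_nnd(FiberMask(np.rot90(mask), mpp_eff=8.0))
        assert a == pytest.approx(b, abs=1e-12)


class TestHotspotVolume:
    def test_counts_window_areas_above_threshold(self):
        dm = _dm([[0.6, 0.4], [0.7, 0.1]])
        assert hotspot_volume(dm, 0.5) == 200  # two windows x 100 px

    def test_threshold_is_strict(self):
        dm = _dm([[1.0, 1.0]])
        assert hotspot_volume(dm, 1.0) == 0

    def test_threshold_zero_counts_all_positive(self):
        dm = _dm([[0.2, 0.3], [0.1, 0.4]])
        assert hotspot_volume(dm, 0.0) == 400

    def test_monotone_non_increasing_in_threshold(self, rng):
        dm = _dm(rng.random((6, 6)))
        vols = [hotspot_volume(dm, t) for t in np.linspace(0, 1, 11)]
        assert all(a >= b for a, b in zip(vols, vols[1:]))


class TestInnervationProfile:
    def _slices(self, values_list):
        return [(i + 1, _dm(v)) for i, v in enumerate(values_list)]

    def test_single_slice_single_region(self):
        table = innervation_profile(
            self._slices([np.array([[0.1, 0.5], [0.9, 0.3]])]),
            region_spec={"apex": (1, 1)},
        )
        assert len(table.slices) == 1
        row = table.regions.iloc[0]
        assert row["entropy_mean"] == pytest.approx(table.slices["entropy"][0])
        assert np.isnan(row["entropy_ci_lo"])  # CI undefined for n=1

    def test_identical_slices_zero_width_ci(self):
        v = np.array([[0.1, 0.5], [0.9, 0.3]])
        table = innervation_profile(self._slices([v, v.copy()]), region_spec={"all": (1, 2)})
        row = table.regions.iloc[0]
        assert row["morans_i_ci_lo"] == pytest.approx(row["morans_i_mean"])
        assert row["morans_i_ci_hi"] == pytest.approx(row["morans_i_mean"])

    def test_region_with_absent_slice_raises(self):
        with pytest.raises(ValueError, match="absent"):
            innervation_profile(
                self._slices([np.array([[0.1, 0.5], [0.9, 0.3]])]),
                region_spec={"base": (1, 3)},
            )

    def test_rows_sorted_by_slice_index(self, rng):
        entries = [(3, _dm(rng.random((3, 3)))), (1, _dm(rng.random((3, 3)))),
                   (2, _dm(rng.random((3, 3))))]
        table = innervation_profile(entries)
        assert list(table.slices["slice_index"]) == [1, 2, 3]

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            innervation_profile([])
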