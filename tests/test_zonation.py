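"""Grid geometry: masks, contours, distance fields, bands, UPGMC."""

import numpy as np
import pytest
import scipy.sparse as sp

from conftest import random_blob_mask
from oracles import multisource_dijkstra_oracle, upgmc_oracle
from tmezone import zonation
from tmezone.model import CellTable, ConfigError, PanelGenes
from tmezone.synthetic import default_marker_config
from tmezone.zonation import (
    Band,
    BandPartition,
    SurfaceContour,
    build_grid,
    distance_field,
    extract_contour,
    smooth_mask,
    tumour_mask,
    upgmc_cluster,
)

SQRT2 = np.sqrt(2.0)


def _point_table(points, counts=None, genes=("g",)):
    points = np.asarray(points, float)
    n = len(points)
    if counts is None:
        counts = np.ones((n, len(genes)), int)
    return CellTable(
        cell_ids=[f"c{i}" for i in range(n)],
        x=points[:, 0], y=points[:, 1], area=np.full(n, 50.0),
        counts=sp.csr_matrix(np.asarray(counts)), genes=PanelGenes(tuple(genes)),
    )


def _contour_from_cells(cells):
    return SurfaceContour(walk=[tuple(c) for c in cells])


class TestBuildGrid:
    def test_grid_dimensions(self):
        pts = [(0, 0), (99, 99)]
        grid = build_grid(_point_table(pts), s=10)
        assert (grid.nx, grid.ny) == (10, 10)

    def test_single_cell_lands_in_origin_bin(self):
        t = _point_table([(5, 5), (95, 95)], counts=[[3], [0]])
        grid = build_grid(t, s=10)
        assert grid.gene_image("g")[0, 0] == 3

    def test_count_conservation(self, small_tissue):
        grid = build_grid(small_tissue.table, s=10)
        assert grid.counts.sum() == small_tissue.table.counts.sum()

    def test_empty_table_rejected(self):
        genes = PanelGenes(("g",))
        t = CellTable([], np.empty(0), np.empty(0), np.empty(0),
                      sp.csr_matrix((0, 1)), genes)
        with pytest.raises(ValueError):
            build_grid(t)


class TestTumourMask:
    GENES = ("CDH1", "SFTPB", "SFTPC", "SFTPD")

    def _grid(self, counts):
        t = _point_table([(5, 5)], counts=[counts], genes=self.GENES)
        return build_grid(t, s=10)

    def test_all_positive_no_negative(self):
        mask = tumour_mask(self._grid([3, 2, 2, 0]), default_marker_config())
        assert mask[0, 0]

    def test_negative_marker_vetoes(self):
        mask = tumour_mask(self._grid([9, 9, 9, 2]), default_marker_config())
        assert not mask[0, 0]

    def test_all_zero_is_false(self):
        mask = tumour_mask(self._grid([0, 0, 0, 0]), default_marker_config())
        assert not mask[0, 0]


class TestSmoothMask:
    def test_isolated_cell_removed(self):
        mask = np.zeros((7, 7), bool)
        mask[3, 3] = True
        assert not smooth_mask(mask).any()

    def test_constant_masks_preserved(self):
        assert smooth_mask(np.ones((5, 5), bool)).all()
        assert not smooth_mask(np.zeros((5, 5), bool)).any()

    def test_block_instance_hand_convolution(self):
        """5×5 field with a 3×3 true block: median keeps only the centre
        3×3 (corners of the block have 4/9 true neighbourhood), and the
        blur then leaves exactly the centre cell at >=0.5."""
        mask = np.zeros((5, 5), bool)
        mask[1:4, 1:4] = True
        # hand-computed median pass: cell (2,2) has 9/9; edge-centres of the
        # block 6/9; corners 4/9 → median output is the plus-shaped set
        med_expected = np.zeros((5, 5), bool)
        med_expected[2, 1:4] = True
        med_expected[1:4, 2] = True
        import scipy.ndimage

        med = scipy.ndimage.median_filter(mask.astype(np.uint8), 3,
                                          mode="nearest").astype(bool)
        np.testing.assert_array_equal(med, med_expected)
        # hand blur of the plus: only (2,2) has 5/9 >= 0.5
        out = smooth_mask(mask)
        expected = np.zeros((5, 5), bool)
        expected[2, 2] = True
        np.testing.assert_array_equal(out, expected)


class TestExtractContour:
    def test_single_cell(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        cont = extract_contour(mask)
        assert cont.walk == [(2, 2)]

    def test_solid_block_perimeter(self):
        mask = np.zeros((5, 5), bool)
        mask[1:4, 1:4] = True
        cont = extract_contour(mask)
        cells = {tuple(c) for c in cont.cells}
        expected = {(y, x) for y in range(1, 4) for x in range(1, 4)} - {(2, 2)}
        assert cells == expected

    def test_first_contour_in_raster_order(self):
        mask = np.zeros((10, 10), bool)
        mask[6:9, 1:4] = True       # later in raster order
        mask[1:3, 5:8] = True       # first true cell appears here
        cont = extract_contour(mask, which="first")
        assert all(y < 3 for y, x in cont.cells)
        largest = extract_contour(mask, which="largest")
        assert all(y >= 6 for y, x in largest.cells)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            extract_contour(np.zeros((3, 3), bool))

    @pytest.mark.parametrize("seed", range(5))
    def test_contour_invariants_on_random_blobs(self, seed):
        """Contour cells are mask-true, border the outside, and form a
        closed 8-connected walk."""
        rng = np.random.default_rng(seed)
        mask = random_blob_mask(rng, 20, 20)
        cont = extract_contour(mask, which="largest")
        padded = np.pad(mask, 1, constant_values=False)
        for y, x in cont.cells:
            assert mask[y, x]
            neigh = padded[y:y + 3, x:x + 3]
            assert not neigh.all()
        walk = cont.walk
        for a, b in zip(walk, walk[1:] + walk[:1]):
            if a == b:
                continue
            assert max(abs(a[0] - b[0]), abs(a[1] - b[1])) == 1


class TestDistanceField:
    def test_elementary_distances(self):
        """Contour cell 0; orthogonal +10; diagonal 10·√2; interior −20."""
        mask = np.zeros((7, 7), bool)
        mask[2:5, 2:5] = True
        cont = extract_contour(mask)
        df = distance_field(mask, cont, spacing=10.0)
        assert df.signed[2, 2] == 0.0
        assert df.signed[2, 1] == pytest.approx(10.0)
        assert df.signed[1, 1] == pytest.approx(10.0 * SQRT2)
        # centre of the 3×3 block is inside, one step from the ring
        assert df.signed[3, 3] == pytest.approx(-10.0)

    def test_corridor_two_steps_inside(self):
        """A 5-wide solid bar: the middle row is two orthogonal steps from
        the contour rows → −20 µm."""
        mask = np.zeros((7, 9), bool)
        mask[1:6, 2:7] = True
        cont = extract_contour(mask)
        df = distance_field(mask, cont, spacing=10.0)
        assert df.signed[3, 4] == pytest.approx(-20.0)

    def test_oracle_equivalence_small(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            mask = random_blob_mask(rng, 15, 15)
            cont = extract_contour(mask, which="largest")
            df = distance_field(mask, cont, spacing=10.0)
            oracle = multisource_dijkstra_oracle(mask, cont.cells, 10.0)
            np.testing.assert_allclose(np.abs(df.signed), oracle, atol=1e-9)

    def test_euclidean_lower_bound(self):
        """Path length dominates the straight-line chord to the nearest
        contour cell centre."""
        rng = np.random.default_rng(7)
        mask = random_blob_mask(rng, 20, 20)
        cont = extract_contour(mask, which="largest")
        df = distance_field(mask, cont, spacing=10.0)
        yy, xx = np.mgrid[0:20, 0:20]
        chord = np.full((20, 20), np.inf)
        for y, x in cont.cells:
            chord = np.minimum(chord, np.hypot(yy - y, xx - x) * 10.0)
        assert np.all(np.abs(df.signed) >= chord - 1e-9)

    def test_source_monotonicity(self):
        """Adding contour sources never increases any distance magnitude."""
        rng = np.random.default_rng(13)
        mask = random_blob_mask(rng, 18, 18)
        cont = extract_contour(mask, which="largest")
        half = _contour_from_cells(cont.cells[: max(1, len(cont.cells) // 2)])
        d_half = distance_field(mask, half, spacing=10.0)
        d_full = distance_field(mask, cont, spacing=10.0)
        assert np.all(np.abs(d_full.signed) <= np.abs(d_half.signed) + 1e-9)

    def test_four_connectivity_option(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        cont = extract_contour(mask)
        df = distance_field(mask, cont, spacing=10.0, connectivity=4)
        assert df.signed[1, 1] == pytest.approx(20.0)  # no diagonal step


class TestBands:
    def test_named_band_assignment(self):
        """15 µm → peri; 50 µm → mid; 20 µm → mid (half-open edges)."""
        bands = BandPartition.outside_default()
        out = bands.assign(np.array([15.0, 50.0, 20.0, 119.9, 120.0, -5.0]))
        assert out.tolist() == ["peri", "mid", "mid", "distal", "beyond", "beyond"]

    def test_uniform_bands_cover_negative_range(self):
        bands = BandPartition.uniform(-60.0, 150.0, 30.0)
        assert bands.assign(np.array([-30.0]))[0] == "[-30,0)"
        assert bands.assign(np.array([-60.0]))[0] == "[-60,-30)"
        assert len(bands.bands) == 7

    def test_overlapping_bands_rejected(self):
        with pytest.raises(ConfigError, match="overlap"):
            BandPartition((Band("a", 0, 30), Band("b", 20, 50)))

    def test_non_finite_distance_unassigned(self):
        bands = BandPartition.outside_default()
        assert bands.assign(np.array([np.inf]))[0] == "unassigned"

    def test_band_areas_partition_finite_area(self, small_tissue):
        grid = build_grid(small_tissue.table, s=10)
        mask = smooth_mask(tumour_mask(grid, default_marker_config()))
        cont = extract_contour(mask, which="largest")
        df = distance_field(mask, cont, spacing=10.0, origin=grid.origin)
        bands = BandPartition.uniform(-200.0, 400.0, 30.0)
        _, profile = zonation.assign_bands(small_tissue.table, grid, df, bands)
        total_area = sum(profile.band_areas.values())
        finite = np.isfinite(df.signed)
        in_range = (df.signed >= -200) & (df.signed < 400) & finite
        assert total_area == pytest.approx(in_range.sum() * 100.0)


class TestUPGMC:
    def test_identical_profiles_merge_at_zero(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]])
        dend = upgmc_cluster(X)
        assert dend.linkage_matrix[0, 2] == pytest.approx(0.0)

    def test_hand_traced_three_points(self):
        """{0},{1},{10}: merge {0,1} at 1, then with {10} at 9.5."""
        X = np.array([[0.0], [1.0], [10.0]])
        dend = upgmc_cluster(X)
        heights = dend.linkage_matrix[:, 2]
        np.testing.assert_allclose(heights, [1.0, 9.5], atol=1e-12)

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(8, 4))
        dend = upgmc_cluster(X)
        oracle = upgmc_oracle(X)
        np.testing.assert_allclose(
            dend.linkage_matrix[:, 2], [m[2] for m in oracle], atol=1e-9
        )

    def test_duplicates_merge_before_distinct_pairs(self):
        X = np.array([[0.0], [0.0], [3.0], [3.0], [9.0]])
        dend = upgmc_cluster(X)
        assert np.all(dend.linkage_matrix[:2, 2] == 0.0)

    def test_requires_two_profiles(self):
        with pytest.raises(ValueError):
            upgmc_cluster(np.array([[1.0, 2.0]]))

    def test_newick_export_parses(self):
        import dendropy

        X = np.array([[0.0], [1.0], [10.0]])
        dend = upgmc_cluster(X, labels=["a", "b", "c"])
        tree = dendropy.Tree.get(data=dend.to_newick(), schema="newick")
        assert {leaf.taxon.label for leaf in tree.leaf_node_iter()} == {"a", "b", "c"}
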