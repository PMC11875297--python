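"""Bin->nucleus aggregation: mask loading, containment assignment against a
brute-force oracle, filtering, mitochondrial gene removal, conservation."""

import numpy as np
import pytest
from scipy import sparse
from shapely.geometry import Point, box

from shelfspace.cellbin import (
    BinMatrix,
    OverlapError,
    assign_bins_to_nuclei,
    filter_cells,
    load_label_mask,
    nuclei_from_polygons,
    remove_mito_genes,
    segment_nuclei_threshold,
)
from shelfspace.config import default_config
from shelfspace.simulate import simulate_hd_tissue


def _grid_bins(counts, bin_side=2.0, genes=None):
    counts = np.asarray(counts)
    n_genes, n_bins = counts.shape
    side = int(round(np.sqrt(n_bins)))
    assert side * side == n_bins
    xs = (np.arange(side) + 0.5) * bin_side
    gx, gy = np.meshgrid(xs, xs)
    return BinMatrix(
        counts=sparse.csr_matrix(counts),
        gene_names=genes or [f"g{i}" for i in range(n_genes)],
        bin_centers=np.column_stack([gx.ravel(), gy.ravel()]),
        bin_side=bin_side,
    )


class TestLoadLabelMask:
    def test_empty_raster(self):
        nuc = load_label_mask(np.zeros((8, 8), dtype=int), pixel_size=1.0)
        assert len(nuc) == 0

    def test_square_label_area(self):
        raster = np.zeros((20, 20), dtype=int)
        raster[3:13, 5:15] = 7
        nuc = load_label_mask(raster, pixel_size=1.0)
        assert len(nuc) == 1
        row = nuc.table.iloc[0]
        assert row["label"] == 7
        assert row["area_um2"] == pytest.approx(100.0)
        # centroid = mean of pixel centers
        assert row["centroid_x"] == pytest.approx(np.mean(np.arange(5, 15) + 0.5))
        assert row["centroid_y"] == pytest.approx(np.mean(np.arange(3, 13) + 0.5))

    def test_interleaved_labels_centroids_match_pixel_oracle(self):
        raster = np.zeros((4, 6), dtype=int)
        raster[::2, ::2] = 1
        raster[1::2, 1::2] = 2
        p = 0.5
        nuc = load_label_mask(raster, pixel_size=p)
        for label in (1, 2):
            iy, ix = np.nonzero(raster == label)
            row = nuc.table.set_index("label").loc[label]
            assert row["centroid_x"] == pytest.approx(np.mean((ix + 0.5) * p))
            assert row["centroid_y"] == pytest.approx(np.mean((iy + 0.5) * p))
            assert row["area_um2"] == pytest.approx(len(ix) * p**2)

    def test_rejects_float_raster(self):
        with pytest.raises(ValueError):
            load_label_mask(np.zeros((4, 4)), pixel_size=1.0)


class TestThresholdSegmenter:
    def test_uniform_background(self):
        nuc = segment_nuclei_threshold(np.full((10, 10), 5.0), threshold=10,
                                       min_pixels=1)
        assert len(nuc) == 0

    def test_two_blobs(self):
        img = np.zeros((20, 20))
        img[2:6, 2:6] = 100
        img[12:17, 12:16] = 100
        nuc = segment_nuclei_threshold(img, threshold=50, min_pixels=4)
        assert len(nuc) == 2

    def test_small_component_discarded(self):
        img = np.zeros((10, 10))
        img[0, :5] = 100  # 5-pixel component
        nuc = segment_nuclei_threshold(img, threshold=50, min_pixels=6)
        assert len(nuc) == 0
        nuc = segment_nuclei_threshold(img, threshold=50, min_pixels=5)
        assert len(nuc) == 1


class TestAssignment:
    def test_empty_nucleus_set(self):
        bins = _grid_bins(np.ones((3, 16)))
        nuc = load_label_mask(np.zeros((8, 8), dtype=int), pixel_size=1.0)
        cells = assign_bins_to_nuclei(bins, nuc)
        assert cells.n_cells == 0

    def test_single_nucleus_covering_grid_sums_everything(self, rng):
        counts = rng.integers(0, 5, (4, 16))
        bins = _grid_bins(counts, bin_side=2.0)
        raster = np.ones((16, 16), dtype=int)  # 0.5 um pixels cover 8x8 um
        nuc = load_label_mask(raster, pixel_size=0.5)
        cells = assign_bins_to_nuclei(bins, nuc)
        assert cells.n_cells == 1
        np.testing.assert_array_equal(
            cells.counts.toarray().ravel(), counts.sum(axis=1)
        )

    def _brute_force(self, bins, regions):
        """Exhaustive bin-center point-in-region scan (lower-left edge rule)."""
        totals = {label: np.zeros(bins.n_genes, dtype=int) for label in regions}
        dense = bins.counts.toarray()
        for j, (cx, cy) in enumerate(bins.bin_centers):
            for label, (x0, y0, x1, y1) in regions.items():
                if x0 < cx <= x1 and y0 < cy <= y1:
                    totals[label] += dense[:, j]
                    break
        return totals

    def test_two_rect_nuclei_match_brute_force_raster(self, rng):
        counts = rng.integers(0, 4, (3, 16))
        bins = _grid_bins(counts, bin_side=2.0)  # centers at odd um on [0,8]^2
        p = 0.5
        raster = np.zeros((16, 16), dtype=int)
        raster[0:8, 0:6] = 1  # y in (0,4], x in (0,3]
        raster[10:16, 4:16] = 2  # y in (5,8], x in (2,8]
        nuc = load_label_mask(raster, pixel_size=p)
        cells = assign_bins_to_nuclei(bins, nuc)
        oracle = self._brute_force(
            bins, {1: (0.0, 0.0, 3.0, 4.0), 2: (2.0, 5.0, 8.0, 8.0)}
        )
        for label, expected in oracle.items():
            got = cells.counts[:, cells.cell_ids.index(label)].toarray().ravel()
            np.testing.assert_array_equal(got, expected)

    def test_edge_centers_go_to_lower_left_pixel(self):
        # one bin whose center (1.0, 1.0) sits exactly on a 0.5 um pixel
        # corner: it must join the pixel to its lower left, pixel (1,1)
        bins = BinMatrix(
            counts=sparse.csr_matrix(np.array([[3]])),
            gene_names=["g"],
            bin_centers=np.array([[1.0, 1.0]]),
            bin_side=2.0,
        )
        raster = np.zeros((4, 4), dtype=int)
        raster[1, 1] = 9  # pixel (0.5,1.0] x (0.5,1.0]
        nuc = load_label_mask(raster, pixel_size=0.5)
        cells = assign_bins_to_nuclei(bins, nuc)
        assert cells.counts.toarray().sum() == 3

    def test_polygon_nuclei_match_raster_style_oracle(self, rng):
        counts = rng.integers(0, 4, (3, 16))
        bins = _grid_bins(counts, bin_side=2.0)
        polys = {1: box(0, 0, 4, 4), 2: box(4, 4, 8, 8)}
        nuc = nuclei_from_polygons(polys)
        cells = assign_bins_to_nuclei(bins, nuc)
        dense = counts
        for label, poly in polys.items():
            expected = np.zeros(3, dtype=int)
            for j, (cx, cy) in enumerate(bins.bin_centers):
                if poly.contains(Point(cx, cy)):
                    expected += dense[:, j]
            got = cells.counts[:, cells.cell_ids.index(label)].toarray().ravel()
            np.testing.assert_array_equal(got, expected)

    def test_overlapping_polygons_rejected(self):
        with pytest.raises(OverlapError):
            nuclei_from_polygons({1: box(0, 0, 4, 4), 2: box(2, 2, 6, 6)})

    def test_conservation_on_simulated_tissue(self):
        cfg = default_config(n_genes=15)
        hd = simulate_hd_tissue(cfg, seed=6)
        nuc = load_label_mask(hd.mask, cfg.hd.pixel_size)
        cells = assign_bins_to_nuclei(hd.bins, nuc)
        # assigned + unassigned = everything
        p = cfg.hd.pixel_size
        ix = np.ceil(hd.bins.bin_centers[:, 0] / p).astype(int) - 1
        iy = np.ceil(hd.bins.bin_centers[:, 1] / p).astype(int) - 1
        labels = hd.mask[iy.clip(0, hd.mask.shape[0] - 1),
                         ix.clip(0, hd.mask.shape[1] - 1)]
        unassigned = hd.bins.counts[:, labels == 0].sum()
        assert cells.total_counts() + unassigned == hd.bins.total_counts()

    def test_exact_ground_truth_with_degenerate_spread(self):
        cfg = default_config(n_genes=15)
        cfg.hd.spread = 0.0
        cfg.hd.background = 0.0
        hd = simulate_hd_tissue(cfg, seed=7)
        nuc = load_label_mask(hd.mask, cfg.hd.pixel_size)
        cells = assign_bins_to_nuclei(hd.bins, nuc)
        truth = hd.truth_cells.set_index("label")["total_count"]
        got = dict(zip(cells.cell_ids, cells.total_umi))
        for label, expected in truth.items():
            assert got[label] == expected


class TestFilters:
    def _cells(self, rng, n=6):
        cfg = default_config(n_genes=10)
        hd = simulate_hd_tissue(cfg, seed=8)
        nuc = load_label_mask(hd.mask, cfg.hd.pixel_size)
        return assign_bins_to_nuclei(hd.bins, nuc)

    def test_identity_thresholds(self, rng):
        cells = self._cells(rng)
        out = filter_cells(cells, min_area=0, max_area=np.inf, min_umi=0)
        assert out.n_cells == cells.n_cells

    def test_boundary_umi(self, rng):
        cells = self._cells(rng)
        threshold = int(cells.total_umi.max())
        out = filter_cells(cells, min_area=0, max_area=np.inf,
                           min_umi=threshold + 1)
        assert threshold not in out.total_umi

    def test_survivors_match_predicate_scan(self, rng):
        cells = self._cells(rng)
        lo, hi, umi = 40.0, 90.0, 15
        out = filter_cells(cells, min_area=lo, max_area=hi, min_umi=umi)
        expected = [
            cid
            for cid, a, u in zip(cells.cell_ids, cells.area_um2, cells.total_umi)
            if lo <= a <= hi and u >= umi
        ]
        assert out.cell_ids == expected

    def test_bad_thresholds(self, rng):
        cells = self._cells(rng)
        with pytest.raises(ValueError):
            filter_cells(cells, min_area=100, max_area=10)

    def test_idempotent(self, rng):
        cells = self._cells(rng)
        once = filter_cells(cells, min_area=40, max_area=90, min_umi=15)
        twice = filter_cells(once, min_area=40, max_area=90, min_umi=15)
        assert once.cell_ids == twice.cell_ids
        assert (once.counts != twice.counts).nnz == 0


class TestMitoRemoval:
    def _matrix(self, genes):
        n = len(genes)
        return BinMatrix(
            counts=sparse.csr_matrix(np.arange(n * 2).reshape(n, 2)),
            gene_names=genes,
            bin_centers=np.array([[1.0, 1.0], [3.0, 1.0]]),
            bin_side=2.0,
        )

    def test_removes_prefixed_gene(self):
        out = remove_mito_genes(self._matrix(["mt-Co1", "Col1a1"]), "mt-")
        assert out.gene_names == ["Col1a1"]

    def test_no_match_is_identity(self):
        m = self._matrix(["Col1a1", "Eln"])
        out = remove_mito_genes(m, "mt-")
        assert out.gene_names == m.gene_names
        assert (out.counts != m.counts).nnz == 0

    def test_case_insensitive_but_hyphen_required(self):
        out = remove_mito_genes(self._matrix(["MT-Nd1", "Mtor"]), "mt-")
        assert out.gene_names == ["Mtor"]

    def test_idempotent(self):
        m = self._matrix(["mt-Co1", "Col1a1", "MT-Nd1"])
        once = remove_mito_genes(m, "mt-")
        twice = remove_mito_genes(once, "mt-")
        assert once.gene_names == twice.gene_names

    def test_empty_prefix_rejected(self):
        with pytest.raises(ValueError):
            remove_mito_genes(self._matrix(["a"]), "")
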