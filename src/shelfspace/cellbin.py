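"""Nucleus-driven single-cell binning of high-definition spatial counts.

The high-definition assay reports counts on a fixed grid of small square
bins (2x2 um by default).  Given a nucleus segmentation of the matched
image, each bin is assigned to the nucleus whose region contains the bin
center, and assigned bins are summed per nucleus to yield a single-cell
count matrix.  Improperly segmented nuclei are then removed by area and
total-UMI thresholds, and mitochondrial genes are dropped.

Conventions: rasters are indexed ``[iy, ix]`` with ``iy`` increasing with y
(origin at the lower left); pixel ``(iy, ix)`` covers the box
``(ix*p, (ix+1)*p] x (iy*p, (iy+1)*p]`` for pixel size ``p`` — a point
exactly on a pixel edge belongs to the pixel to its lower left.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage, sparse
from shapely.geometry import Polygon
from shapely import contains_xy
from skimage import measure


class OverlapError(ValueError):
    """Nucleus regions overlap; labels must partition space."""


def _lower_left_index(coord: np.ndarray, step: float) -> np.ndarray:
    """Grid index under the lower-left edge rule (edge points go down/left)."""
    return np.asarray(np.ceil(np.asarray(coord, dtype=float) / step) - 1, dtype=int)


@dataclass
class BinMatrix:
    """Genes x spatial-bins counts with bin geometry."""

    counts: sparse.csr_matrix  # genes x bins, non-negative integers
    gene_names: list[str]
    bin_centers: np.ndarray  # (n_bins, 2) um
    bin_side: float  # um

    def __post_init__(self) -> None:
        self.counts = sparse.csr_matrix(self.counts)
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        if self.counts.shape != (len(self.gene_names), self.bin_centers.shape[0]):
            raise ValueError("counts shape does not match gene/bin annotations")
        if self.bin_side <= 0:
            raise ValueError("bin_side must be positive")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    @property
    def n_bins(self) -> int:
        return self.bin_centers.shape[0]

    def total_counts(self) -> int:
        return int(self.counts.sum())


@dataclass
class CellMatrix:
    """Genes x cells counts after bin->nucleus aggregation."""

    counts: sparse.csr_matrix  # genes x cells
    gene_names: list[str]
    cell_ids: list[int]  # nucleus labels
    area_um2: np.ndarray
    centroid: np.ndarray  # (n_cells, 2) um

    def __post_init__(self) -> None:
        self.counts = sparse.csr_matrix(self.counts)
        self.area_um2 = np.asarray(self.area_um2, dtype=float)
        self.centroid = np.asarray(self.centroid, dtype=float).reshape(-1, 2)
        n = len(self.cell_ids)
        if self.counts.shape != (len(self.gene_names), n):
            raise ValueError("counts shape does not match gene/cell annotations")
        if self.area_um2.shape != (n,) or self.centroid.shape != (n, 2):
            raise ValueError("per-cell annotations do not match cell count")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def total_umi(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def total_counts(self) -> int:
        return int(self.counts.sum())


@dataclass
class NucleusSet:
    """Segmented nuclei, raster-backed (label image) or polygon-backed."""

    table: pd.DataFrame  # label, area_um2, centroid_x, centroid_y
    labels: np.ndarray | None = None  # [iy, ix] integer raster
    pixel_size: float | None = None  # um per raster pixel
    polygons: dict[int, Polygon] | None = None

    def __post_init__(self) -> None:
        ids = self.table["label"].to_numpy()
        if len(ids) != len(set(ids)) or (ids <= 0).any():
            raise ValueError("nucleus labels must be unique positive integers")
        if (self.table["area_um2"].to_numpy() <= 0).any():
            raise ValueError("nucleus areas must be positive")

    def __len__(self) -> int:
        return len(self.table)


def load_label_mask(raster: np.ndarray, pixel_size: float) -> NucleusSet:
    """Build a :class:`NucleusSet` from an integer label image.

    One nucleus per distinct positive label; area is the pixel count scaled
    by ``pixel_size**2`` and the centroid is the mean of pixel centers.
    """
    raster = np.asarray(raster)
    if raster.ndim != 2:
        raise ValueError("label raster must be single-channel (2-D)")
    if not np.issubdtype(raster.dtype, np.integer):
        raise ValueError("label raster must hold integers")
    if raster.size and raster.min() < 0:
        raise ValueError("label raster must be non-negative")
    ids = np.unique(raster)
    ids = ids[ids > 0]
    if ids.size == 0:
        table = pd.DataFrame(
            columns=["label", "area_um2", "centroid_x", "centroid_y"]
        ).astype({"label": int})
        return NucleusSet(table=table, labels=raster, pixel_size=pixel_size)
    npix = ndimage.sum_labels(np.ones_like(raster, dtype=float), raster, ids)
    com = ndimage.center_of_mass(np.ones_like(raster, dtype=float), raster, ids)
    com = np.asarray(com)  # (iy, ix) means of pixel indices
    table = pd.DataFrame(
        {
            "label": ids.astype(int),
            "area_um2": npix * pixel_size**2,
            "centroid_x": (com[:, 1] + 0.5) * pixel_size,
            "centroid_y": (com[:, 0] + 0.5) * pixel_size,
        }
    )
    return NucleusSet(table=table, labels=raster, pixel_size=pixel_size)


def nuclei_from_polygons(polygons: dict[int, Polygon]) -> NucleusSet:
    """Build a :class:`NucleusSet` from per-label polygons (must not overlap)."""
    items = sorted(polygons.items())
    for i, (la, pa) in enumerate(items):
        for lb, pb in items[i + 1 :]:
            if pa.intersection(pb).area > 1e-9:
                raise OverlapError(f"nucleus regions {la} and {lb} overlap")
    table = pd.DataFrame(
        {
            "label": [l for l, _ in items],
            "area_um2": [p.area for _, p in items],
            "centroid_x": [p.centroid.x for _, p in items],
            "centroid_y": [p.centroid.y for _, p in items],
        }
    )
    return NucleusSet(table=table, polygons=dict(items))


def segment_nuclei_threshold(
    image: np.ndarray, threshold: float, min_pixels: int, pixel_size: float = 1.0
) -> NucleusSet:
    """Fixture-grade segmenter: 4-connected components of ``image >= threshold``.

    Components smaller than ``min_pixels`` are discarded.  Intended for
    synthetic images only; real nuclei come from an external segmentation
    model and enter through :func:`load_label_mask`.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("image must be single-channel (2-D)")
    fg = image >= threshold
    labels = measure.label(fg, connectivity=1)
    if min_pixels > 1 and labels.max() > 0:
        sizes = np.bincount(labels.ravel())
        small = np.flatnonzero(sizes < min_pixels)
        labels[np.isin(labels, small)] = 0
        labels = measure.label(labels > 0, connectivity=1)
    return load_label_mask(labels.astype(np.int32), pixel_size=pixel_size)


def assign_bins_to_nuclei(bins: BinMatrix, nuclei: NucleusSet) -> CellMatrix:
    """Aggregate bin counts onto nuclei by bin-center containment.

    A bin belongs to nucleus L iff its center falls inside L's region; the
    assignment is a partition (bins outside every nucleus are dropped).
    """
    if nuclei.labels is not None:
        p = nuclei.pixel_size
        ix = _lower_left_index(bins.bin_centers[:, 0], p)
        iy = _lower_left_index(bins.bin_centers[:, 1], p)
        ny, nx = nuclei.labels.shape
        inside = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
        bin_label = np.zeros(bins.n_bins, dtype=int)
        bin_label[inside] = nuclei.labels[iy[inside], ix[inside]]
    elif nuclei.polygons is not None:
        bin_label = np.zeros(bins.n_bins, dtype=int)
        x, y = bins.bin_centers[:, 0], bins.bin_centers[:, 1]
        for label, poly in sorted(nuclei.polygons.items()):
            hit = contains_xy(poly, x, y) & (bin_label == 0)
            bin_label[hit] = label
    else:
        raise ValueError("NucleusSet carries neither raster nor polygons")

    cell_ids = nuclei.table["label"].to_list()
    if not cell_ids:
        return CellMatrix(
            counts=sparse.csr_matrix((bins.n_genes, 0), dtype=bins.counts.dtype),
            gene_names=list(bins.gene_names),
            cell_ids=[],
            area_um2=np.empty(0),
            centroid=np.empty((0, 2)),
        )
    col_of = {label: j for j, label in enumerate(cell_ids)}
    assigned = np.flatnonzero(bin_label > 0)
    rows = assigned
    cols = np.array([col_of[l] for l in bin_label[assigned]], dtype=int)
    indicator = sparse.coo_matrix(
        (np.ones(len(assigned)), (rows, cols)),
        shape=(bins.n_bins, len(cell_ids)),
    ).tocsr()
    cell_counts = (bins.counts @ indicator).astype(bins.counts.dtype)
    return CellMatrix(
        counts=cell_counts,
        gene_names=list(bins.gene_names),
        cell_ids=cell_ids,
        area_um2=nuclei.table["area_um2"].to_numpy(),
        centroid=nuclei.table[["centroid_x", "centroid_y"]].to_numpy(),
    )


def filter_cells(
    cells: CellMatrix,
    min_area: float = 15.0,
    max_area: float = 400.0,
    min_umi: int = 10,
) -> CellMatrix:
    """Drop improperly segmented nuclei by area and total-UMI thresholds.

    Defaults are nucleus-scale plausibilities, not published cutoffs; they
    are expected to be tuned per data set.
    """
    if min_area < 0 or min_umi < 0:
        raise ValueError("thresholds must be non-negative")
    if min_area > max_area:
        raise ValueError("min_area must not exceed max_area")
    keep = (
        (cells.area_um2 >= min_area)
        & (cells.area_um2 <= max_area)
        & (cells.total_umi >= min_umi)
    )
    idx = np.flatnonzero(keep)
    return CellMatrix(
        counts=cells.counts[:, idx],
        gene_names=list(cells.gene_names),
        cell_ids=[cells.cell_ids[i] for i in idx],
        area_um2=cells.area_um2[idx],
        centroid=cells.centroid[idx],
    )


def remove_mito_genes(matrix: BinMatrix | CellMatrix, prefix: str = "mt-"):
    """Drop genes whose name starts with ``prefix`` (case-insensitive)."""
    if not prefix:
        raise ValueError("prefix must be non-empty")
    pfx = prefix.lower()
    keep = [i for i, g in enumerate(matrix.gene_names) if not g.lower().startswith(pfx)]
    names = [matrix.gene_names[i] for i in keep]
    return replace(matrix, counts=matrix.counts[keep, :], gene_names=names)
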