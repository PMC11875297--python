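"""Oronasal domain geometry from marker co-expression.

*Shh* is expressed in the epithelium of the oral side of each palatal
shelf, and its target *Ptch1* in the adjacent mesenchyme, so the region
where their transcript densities overlap traces the oral aspect of the
shelf.  The pipeline formalizes the manual density-map procedure as:

1. per-gene kernel-smoothed density maps on a shared lattice;
2. a co-expression mask — the geometric mean of the two max-normalized
   maps, thresholded at a high quantile of its nonzero values;
3. a straight oronasal axis — the principal direction of the masked lattice
   cells inside one shelf, through their centroid;
4. a split of the shelf polygon by that axis into oral palatal (OP) and
   nasal palatal (NP) domains;
5. seeded placement of area-standardized square ROIs (80 um side, 6400 um^2)
   inside each domain, three per side of the axis per shelf.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely import contains_xy
from shapely.geometry import LineString, Polygon, box
from shapely.ops import split as shapely_split, unary_union

#: standard ROI area and its validation tolerance, um^2
ROI_AREA = 6400.0
ROI_AREA_TOL = 100.0
#: default ROI side (area exactly 6400 um^2)
ROI_SIDE = 80.0

ROISET_COLUMNS = [
    "roi_id", "shelf", "domain", "center_x", "center_y", "side_um", "area_um2"
]


@dataclass
class DensityMap:
    """Transcript density (per um^2) on a square lattice.

    ``grid`` is indexed ``[iy, ix]`` with y increasing upward; cell
    ``(iy, ix)`` covers ``[origin + i*cell_size, origin + (i+1)*cell_size)``.
    """

    grid: np.ndarray
    cell_size: float
    origin: tuple[float, float]
    bandwidth: float

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.grid.shape
        xs = self.origin[0] + (np.arange(nx) + 0.5) * self.cell_size
        ys = self.origin[1] + (np.arange(ny) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)


@dataclass
class BoolGrid:
    """Boolean mask on the same lattice as the density maps it came from."""

    grid: np.ndarray
    cell_size: float
    origin: tuple[float, float]

    def true_centers(self) -> np.ndarray:
        iy, ix = np.nonzero(self.grid)
        x = self.origin[0] + (ix + 0.5) * self.cell_size
        y = self.origin[1] + (iy + 0.5) * self.cell_size
        return np.column_stack([x, y])


@dataclass
class AxisLine:
    """Straight oronasal axis: point + unit direction; ``oral_side_sign``
    says which side of the line (sign of the normal offset) is oral."""

    point: tuple[float, float]
    direction: tuple[float, float]
    oral_side_sign: int

    @property
    def normal(self) -> tuple[float, float]:
        dx, dy = self.direction
        return (-dy, dx)

    def side_of(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        nx, ny = self.normal
        return np.sign(nx * (np.asarray(x) - self.point[0])
                       + ny * (np.asarray(y) - self.point[1]))


@dataclass
class DomainPartition:
    """One shelf split into its oral (OP) and nasal (NP) halves."""

    shelf_id: str
    oral: Polygon
    nasal: Polygon


def _lattice(
    transcripts: pd.DataFrame, cell_size: float
) -> tuple[tuple[float, float], int, int]:
    """Shared lattice over the full transcript table, snapped to cell_size."""
    x = transcripts["x_location"].to_numpy(dtype=float)
    y = transcripts["y_location"].to_numpy(dtype=float)
    if len(x) == 0:
        return (0.0, 0.0), 1, 1
    ox = np.floor(x.min() / cell_size) * cell_size
    oy = np.floor(y.min() / cell_size) * cell_size
    nx = int(np.floor((x.max() - ox) / cell_size)) + 1
    ny = int(np.floor((y.max() - oy) / cell_size)) + 1
    return (ox, oy), nx, ny


def density_map(
    transcripts: pd.DataFrame,
    gene: str,
    cell_size: float = 10.0,
    bandwidth: float = 15.0,
) -> DensityMap:
    """Per-gene transcript density on a lattice shared across genes.

    Counts are binned on the lattice, divided by cell area, then Gaussian
    smoothed with the stated bandwidth (standard deviation, in um);
    bandwidth 0 gives the raw histogram density.  The lattice extent comes
    from the whole table, so maps of different genes share it.
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    if bandwidth < 0:
        raise ValueError("bandwidth must be non-negative")
    origin, nx, ny = _lattice(transcripts, cell_size)
    sub = transcripts[transcripts["feature_name"] == gene]
    if len(transcripts) and not len(sub):
        warnings.warn(f"gene {gene!r} absent from transcript table; zero map")
    grid = np.zeros((ny, nx))
    if len(sub):
        ix = ((sub["x_location"].to_numpy() - origin[0]) / cell_size).astype(int)
        iy = ((sub["y_location"].to_numpy() - origin[1]) / cell_size).astype(int)
        ix = np.clip(ix, 0, nx - 1)
        iy = np.clip(iy, 0, ny - 1)
        np.add.at(grid, (iy, ix), 1.0)
    grid /= cell_size**2
    if bandwidth > 0:
        grid = ndimage.gaussian_filter(grid, sigma=bandwidth / cell_size)
    return DensityMap(grid=grid, cell_size=cell_size, origin=origin,
                      bandwidth=bandwidth)


def coexpression_mask(
    a: DensityMap, b: DensityMap, quantile: float = 0.9
) -> BoolGrid:
    """Cells where both markers are jointly dense.

    Each map is rescaled to [0, 1] by its maximum; the co-expression score
    is the geometric mean of the two, and the mask keeps scores above the
    ``quantile``-th quantile of the nonzero scores.
    """
    if a.grid.shape != b.grid.shape or a.origin != b.origin \
            or a.cell_size != b.cell_size:
        raise ValueError("density maps must share their lattice")
    if not 0 < quantile < 1:
        raise ValueError("quantile must lie in (0, 1)")
    amax, bmax = a.grid.max(), b.grid.max()
    if amax == 0 or bmax == 0:
        raise ValueError("marker absent: a density map is all zero")
    co = np.sqrt((a.grid / amax) * (b.grid / bmax))
    nonzero = co[co > 0]
    if nonzero.size == 0:
        raise ValueError("marker supports are disjoint: co-expression empty")
    thr = np.quantile(nonzero, quantile)
    return BoolGrid(grid=co > thr, cell_size=a.cell_size, origin=a.origin)


def fit_oronasal_axis(mask: BoolGrid, shelf: Polygon) -> AxisLine:
    """Principal axis of the masked cells inside one shelf.

    The line passes through the centroid of the masked cell centers along
    their principal (largest-variance) direction.  The oral side is the
    half-plane into which the masked centroid is displaced from the shelf
    centroid — the co-expression band sits on the oral aspect.
    """
    pts = mask.true_centers()
    inside = contains_xy(shelf, pts[:, 0], pts[:, 1])
    pts = pts[inside]
    if len(pts) < 3:
        raise ValueError(
            f"need >= 3 masked cells inside the shelf, found {len(pts)}"
        )
    centroid = pts.mean(axis=0)
    cov = np.cov((pts - centroid).T)
    evals, evecs = np.linalg.eigh(cov)
    direction = evecs[:, int(np.argmax(evals))]
    if direction[0] < 0 or (direction[0] == 0 and direction[1] < 0):
        direction = -direction
    direction = direction / np.linalg.norm(direction)
    normal = np.array([-direction[1], direction[0]])
    offset = centroid - np.array([shelf.centroid.x, shelf.centroid.y])
    sign = int(np.sign(normal @ offset))
    if sign == 0:
        sign = 1
    return AxisLine(
        point=(float(centroid[0]), float(centroid[1])),
        direction=(float(direction[0]), float(direction[1])),
        oral_side_sign=sign,
    )


def partition_domains(
    shelf: Polygon, axis: AxisLine, shelf_id: str = "P"
) -> DomainPartition:
    """Split the shelf polygon by the axis line into OP and NP domains."""
    minx, miny, maxx, maxy = shelf.bounds
    diam = float(np.hypot(maxx - minx, maxy - miny))
    p = np.array(axis.point)
    d = np.array(axis.direction)
    cutter = LineString([tuple(p - 10 * diam * d), tuple(p + 10 * diam * d)])
    if not cutter.intersects(shelf):
        raise ValueError("axis does not intersect the shelf")
    pieces = shapely_split(shelf, cutter)
    oral_parts, nasal_parts = [], []
    for piece in pieces.geoms:
        c = piece.representative_point()
        s = axis.side_of(c.x, c.y)
        (oral_parts if s == axis.oral_side_sign else nasal_parts).append(piece)
    oral = unary_union(oral_parts) if oral_parts else Polygon()
    nasal = unary_union(nasal_parts) if nasal_parts else Polygon()
    tol = 1e-9 * shelf.area
    if oral.area <= tol or nasal.area <= tol:
        raise ValueError("axis grazes the shelf: a domain is degenerate")
    return DomainPartition(shelf_id=shelf_id, oral=oral, nasal=nasal)


def place_rois(
    partition: DomainPartition,
    n_per_side: int = 3,
    side: float = ROI_SIDE,
    seed: int = 0,
    max_attempts: int = 20000,
) -> pd.DataFrame:
    """Place axis-aligned square ROIs inside each domain of one shelf.

    ``n_per_side`` squares of the given side are drawn by seeded uniform
    rejection sampling per domain, fully inside the domain polygon and
    pairwise non-overlapping (touching edges allowed).  Returns a table in
    ``ROISET_COLUMNS`` order.
    """
    if n_per_side < 0:
        raise ValueError("n_per_side must be >= 0")
    if side <= 0:
        raise ValueError("side must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for domain_name, poly in (("OP", partition.oral), ("NP", partition.nasal)):
        placed: list[Polygon] = []
        minx, miny, maxx, maxy = poly.bounds
        attempts = 0
        while len(placed) < n_per_side:
            if attempts >= max_attempts:
                raise RuntimeError(
                    f"could not place {n_per_side} ROIs of side {side} um in "
                    f"domain {domain_name} of shelf {partition.shelf_id}"
                )
            attempts += 1
            cx = rng.uniform(minx + side / 2, maxx - side / 2)
            cy = rng.uniform(miny + side / 2, maxy - side / 2)
            square = box(cx - side / 2, cy - side / 2, cx + side / 2, cy + side / 2)
            if not poly.contains(square):
                continue
            if any(square.intersection(q).area > 1e-9 for q in placed):
                continue
            placed.append(square)
            rows.append(
                {
                    "roi_id": f"{partition.shelf_id}_{domain_name}_{len(placed)}",
                    "shelf": partition.shelf_id,
                    "domain": domain_name,
                    "center_x": cx,
                    "center_y": cy,
                    "side_um": side,
                    "area_um2": side**2,
                }
            )
    return pd.DataFrame(rows, columns=ROISET_COLUMNS)


def validate_roi_table(
    rois: pd.DataFrame,
    target_area: float = ROI_AREA,
    area_tol: float = ROI_AREA_TOL,
) -> None:
    """Check the standardized-area and consistency invariants of an ROI set."""
    missing = [c for c in ROISET_COLUMNS if c not in rois.columns]
    if missing:
        raise ValueError(f"ROI table missing columns: {missing}")
    if not np.allclose(rois["area_um2"], rois["side_um"] ** 2):
        raise ValueError("ROI area must equal side^2")
    bad = rois[np.abs(rois["area_um2"] - target_area) > area_tol]
    if len(bad):
        raise ValueError(
            f"{len(bad)} ROIs deviate more than {area_tol} um^2 from the "
            f"standard {target_area} um^2 area"
        )


def shelf_partitions(
    transcripts: pd.DataFrame,
    shelf_polygons: dict[str, Polygon],
    oral_marker: str = "Shh",
    responder_marker: str = "Ptch1",
    cell_size: float = 10.0,
    bandwidth: float = 15.0,
    quantile: float = 0.9,
) -> dict[str, DomainPartition]:
    """Marker maps -> co-expression mask -> per-shelf axis and NP/OP split."""
    a = density_map(transcripts, oral_marker, cell_size, bandwidth)
    b = density_map(transcripts, responder_marker, cell_size, bandwidth)
    mask = coexpression_mask(a, b, quantile)
    out = {}
    for shelf_id, shelf in sorted(shelf_polygons.items()):
        axis = fit_oronasal_axis(mask, shelf)
        out[shelf_id] = partition_domains(shelf, axis, shelf_id=shelf_id)
    return out


def place_section_rois(
    partitions: dict[str, DomainPartition],
    n_per_side: int = 3,
    side: float = ROI_SIDE,
    seed: int = 0,
) -> pd.DataFrame:
    """ROIs for a whole section: 3/side x 2 domains x 2 shelves = 12."""
    children = np.random.SeedSequence(seed).spawn(len(partitions))
    tables = []
    for (shelf_id, part), child in zip(sorted(partitions.items()), children):
        sub_seed = int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        tables.append(place_rois(part, n_per_side=n_per_side, side=side,
                                 seed=sub_seed))
    return pd.concat(tables, ignore_index=True)
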