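"""Synthetic palate sections with known ground truth.

Three generators:

* :func:`simulate_section` — an in-situ style transcript point cloud over a
  two-shelf coronal section.  Each gene is an independent homogeneous
  Poisson process within each compartment, at rate
  ``baseline intensity x condition multiplier``.
* :func:`simulate_hd_tissue` — a high-definition binned tissue: elliptical
  nuclei emit per-gene Poisson counts that are deposited on a 2 um bin grid
  with a Gaussian spatial spread, over a uniform background; a matching
  nucleus label raster is produced.
* :func:`simulate_cell_cohort` — a plain two-group single-cell count matrix
  (per-gene Poisson rates, optional fold change), for exercising the
  downstream single-cell statistics at scale.

All randomness flows from explicit integer seeds; identical (config, seed)
reproduce identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, sparse
from shapely import contains_xy
from shapely.geometry import Polygon, box
from skimage.draw import ellipse as draw_ellipse

from shelfspace.cellbin import BinMatrix, CellMatrix
from shelfspace.config import COMPARTMENTS, COND_SEP, SimConfig, condition_label

TRANSCRIPT_COLUMNS = ["feature_name", "x_location", "y_location", "qv"]


class ConfigurationError(ValueError):
    """Simulation request inconsistent with the configuration."""


class GenerationError(RuntimeError):
    """Stochastic generation failed within its retry budget."""


@dataclass
class SectionSim:
    """One simulated coronal section plus its ground truth."""

    transcripts: pd.DataFrame  # feature_name, x_location, y_location, qv
    geometry: dict[str, dict[str, Polygon]]  # shelf -> compartment polygons
    truth: pd.DataFrame  # per-gene applied intensities and log2 rate ratio
    genotype: str
    stage: str


@dataclass
class HDSim:
    """One simulated high-definition tissue plus its ground truth."""

    bins: BinMatrix
    mask: np.ndarray  # uint16 label raster, [iy, ix], y upward
    pixel_size: float
    truth_cells: pd.DataFrame  # label, cell_type, centroid, area, total_count
    truth_counts: np.ndarray  # genes x nuclei, transcripts actually generated
    n_background: int = 0  # background transcripts deposited


def compartment_polygons(config: SimConfig) -> dict[str, dict[str, Polygon]]:
    """Split each shelf into its three compartments by horizontal cuts."""
    out: dict[str, dict[str, Polygon]] = {}
    for shelf_id, shelf in config.shelf_polygons.items():
        minx, miny, maxx, maxy = shelf.bounds
        pad = 10.0
        y_band = miny + config.epithelium_band_width
        y_oral = miny + config.oral_fraction * (maxy - miny)
        if not y_band < y_oral < maxy:
            raise ConfigurationError(
                "epithelium band must fit below the oral/nasal boundary"
            )
        band = shelf.intersection(box(minx - pad, miny - pad, maxx + pad, y_band))
        oral = shelf.intersection(box(minx - pad, y_band, maxx + pad, y_oral))
        nasal = shelf.intersection(box(minx - pad, y_oral, maxx + pad, maxy + pad))
        out[shelf_id] = {
            "shelf": shelf,
            "oral_epithelium": band,
            "oral_mesenchyme": oral,
            "nasal_mesenchyme": nasal,
        }
    return out


def _sample_in_polygon(
    poly: Polygon, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform points inside a polygon by rejection from its bounding box."""
    if n == 0:
        return np.empty((0, 2))
    minx, miny, maxx, maxy = poly.bounds
    accept_frac = max(poly.area / ((maxx - minx) * (maxy - miny)), 1e-3)
    out = np.empty((n, 2))
    filled = 0
    while filled < n:
        m = int((n - filled) / accept_frac * 1.2) + 16
        x = rng.uniform(minx, maxx, m)
        y = rng.uniform(miny, maxy, m)
        ok = contains_xy(poly, x, y)
        k = min(int(ok.sum()), n - filled)
        out[filled : filled + k, 0] = x[ok][:k]
        out[filled : filled + k, 1] = y[ok][:k]
        filled += k
    return out


def simulate_section(
    config: SimConfig, genotype: str, stage: str, seed: int
) -> SectionSim:
    """Draw one section for one (genotype, stage) condition.

    Transcripts are independent per-gene homogeneous Poisson processes in
    each compartment of each shelf, at rate
    ``gene_profiles[gene, compartment] * condition_multipliers[gene, cond]``.
    """
    config.validate()
    label = condition_label(genotype, stage)
    if label not in config.condition_multipliers.columns:
        raise ConfigurationError(f"unknown condition {genotype!r}/{stage!r}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    geometry = compartment_polygons(config)

    mult = config.condition_multipliers[label].to_numpy()
    genes = np.asarray(config.gene_names)
    parts: list[pd.DataFrame] = []
    for shelf_id in sorted(geometry):
        for comp in COMPARTMENTS:
            poly = geometry[shelf_id][comp]
            if poly.is_empty or poly.area <= 0:
                continue
            rates = config.gene_profiles[comp].to_numpy() * mult
            counts = rng.poisson(rates * poly.area)
            total = int(counts.sum())
            if total == 0:
                continue
            pts = _sample_in_polygon(poly, total, rng)
            parts.append(
                pd.DataFrame(
                    {
                        "feature_name": np.repeat(genes, counts),
                        "x_location": pts[:, 0],
                        "y_location": pts[:, 1],
                    }
                )
            )
    if parts:
        table = pd.concat(parts, ignore_index=True)
    else:
        table = pd.DataFrame(
            {"feature_name": genes[:0], "x_location": [], "y_location": []}
        )
    qv = np.full(len(table), config.qv_pass)
    if config.low_quality_fraction > 0 and len(table):
        low = rng.random(len(table)) < config.low_quality_fraction
        qv[low] = config.qv_fail
    table["qv"] = qv

    truth = config.gene_profiles.mul(mult, axis=0)
    truth = truth.assign(
        multiplier=mult, log2_rate_ratio=np.log2(mult), condition=label
    )
    return SectionSim(
        transcripts=table, geometry=geometry, truth=truth,
        genotype=genotype, stage=stage,
    )


def simulate_cohort(
    config: SimConfig, seed: int
) -> dict[tuple[str, str], SectionSim]:
    """One section per configured (genotype, stage), with independent
    sub-seeds derived deterministically from ``seed``."""
    conditions = config.conditions
    if not conditions:
        raise ConfigurationError("no conditions configured")
    children = np.random.SeedSequence(seed).spawn(len(conditions))
    out: dict[tuple[str, str], SectionSim] = {}
    for (genotype, stage), child in zip(conditions, children):
        sub_seed = int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        out[(genotype, stage)] = simulate_section(config, genotype, stage, sub_seed)
    return out


def _hd_type_profiles(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-cell-type expected transcripts per gene (log-normal across genes)."""
    hd = config.hd
    sigma = 0.8
    mu = np.log(hd.mean_counts_per_gene) - sigma**2 / 2
    data = {
        t: rng.lognormal(mean=mu, sigma=sigma, size=config.n_genes)
        for t in hd.cell_types
    }
    return pd.DataFrame(data, index=pd.Index(config.gene_names, name="gene"))


def simulate_hd_tissue(config: SimConfig, seed: int) -> HDSim:
    """Simulate a binned high-definition tissue with a nucleus label mask."""
    config.validate()
    if not any(
        g.lower().startswith(config.mito_prefix.lower()) for g in config.gene_names
    ):
        raise ConfigurationError(
            f"panel must include a {config.mito_prefix}* gene for the HD track"
        )
    hd = config.hd
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    width, height = hd.extent
    rmin, rmax = hd.nucleus_radius

    # -- place non-overlapping elliptical nuclei -------------------------
    centers: list[tuple[float, float]] = []
    majors: list[float] = []
    shapes: list[tuple[float, float, float]] = []  # a, b, theta
    types: list[str] = []
    margin = rmax + hd.pixel_size
    for i in range(hd.n_nuclei):
        placed = False
        for _ in range(hd.placement_attempts):
            cx = rng.uniform(margin, width - margin)
            cy = rng.uniform(margin, height - margin)
            a, b = np.sort(rng.uniform(rmin, rmax, 2))
            ok = all(
                (cx - px) ** 2 + (cy - py) ** 2
                >= (b + pm + hd.pixel_size) ** 2
                for (px, py), pm in zip(centers, majors)
            )
            if ok:
                centers.append((cx, cy))
                majors.append(b)
                shapes.append((a, b, rng.uniform(0, np.pi)))
                types.append(hd.cell_types[rng.integers(len(hd.cell_types))])
                placed = True
                break
        if not placed:
            raise GenerationError(
                f"could not place nucleus {i + 1}/{hd.n_nuclei} without overlap"
            )

    # -- label raster ----------------------------------------------------
    p = hd.pixel_size
    ny_pix, nx_pix = int(round(height / p)), int(round(width / p))
    mask = np.zeros((ny_pix, nx_pix), dtype=np.uint16)
    for lab, ((cx, cy), (a, b, theta)) in enumerate(zip(centers, shapes), start=1):
        rr, cc = draw_ellipse(
            cy / p - 0.5, cx / p - 0.5, b / p, a / p,
            shape=mask.shape, rotation=theta,
        )
        mask[rr, cc] = lab

    # -- transcripts -----------------------------------------------------
    profiles = _hd_type_profiles(config, rng)
    nx = int(np.ceil(width / hd.bin_side))
    ny = int(np.ceil(height / hd.bin_side))
    grid = np.zeros((config.n_genes, ny * nx), dtype=np.int64)
    truth_counts = np.zeros((config.n_genes, len(centers)), dtype=np.int64)

    def deposit(gene_idx: np.ndarray, x: np.ndarray, y: np.ndarray) -> None:
        ix = np.clip((x / hd.bin_side).astype(int), 0, nx - 1)
        iy = np.clip((y / hd.bin_side).astype(int), 0, ny - 1)
        np.add.at(grid, (gene_idx, iy * nx + ix), 1)

    for j, ((cx, cy), cell_type) in enumerate(zip(centers, types)):
        counts = rng.poisson(profiles[cell_type].to_numpy())
        truth_counts[:, j] = counts
        total = int(counts.sum())
        if total == 0:
            continue
        gene_idx = np.repeat(np.arange(config.n_genes), counts)
        if hd.spread > 0:
            pts = rng.normal(loc=(cx, cy), scale=hd.spread, size=(total, 2))
        else:
            pts = np.tile((cx, cy), (total, 1))
        deposit(gene_idx, pts[:, 0], pts[:, 1])

    n_background = 0
    if hd.background > 0:
        bg_counts = rng.poisson(hd.background * width * height, config.n_genes)
        n_background = int(bg_counts.sum())
        if n_background:
            gene_idx = np.repeat(np.arange(config.n_genes), bg_counts)
            deposit(gene_idx, rng.uniform(0, width, n_background),
                    rng.uniform(0, height, n_background))

    xs = (np.arange(nx) + 0.5) * hd.bin_side
    ys = (np.arange(ny) + 0.5) * hd.bin_side
    gx, gy = np.meshgrid(xs, ys)
    bins = BinMatrix(
        counts=sparse.csr_matrix(grid),
        gene_names=list(config.gene_names),
        bin_centers=np.column_stack([gx.ravel(), gy.ravel()]),
        bin_side=hd.bin_side,
    )
    areas = ndimage.sum_labels(
        np.ones_like(mask, dtype=float), mask, np.arange(1, len(centers) + 1)
    ) * p**2 if len(centers) else np.empty(0)
    truth_cells = pd.DataFrame(
        {
            "label": np.arange(1, len(centers) + 1),
            "cell_type": types,
            "centroid_x": [c[0] for c in centers],
            "centroid_y": [c[1] for c in centers],
            "area_um2": areas,
            "total_count": truth_counts.sum(axis=0),
        }
    )
    return HDSim(
        bins=bins, mask=mask, pixel_size=p,
        truth_cells=truth_cells, truth_counts=truth_counts,
        n_background=n_background,
    )



def simulate_cell_cohort(
    n_genes: int = 200,
    n_cells: tuple[int, int] = (100, 100),
    base_rate: float = 0.35,
    n_de: int = 20,
    fold: float = 4.0,
    seed: int = 0,
) -> tuple[CellMatrix, np.ndarray, pd.DataFrame]:
    """Two-group single-cell counts with a known set of fold-changed genes.

    Counts are per-gene Poisson with log-normal rates around ``base_rate``
    (sparse detection, exercising both hurdle components); the first
    ``n_de`` genes carry ``fold``-times the rate in group B.  Returns the
    combined matrix, a per-cell group label array ("A"/"B"), and a truth
    table.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    sigma = 0.5
    lam = rng.lognormal(np.log(base_rate) - sigma**2 / 2, sigma, n_genes)
    lam_b = lam.copy()
    lam_b[:n_de] *= fold
    na, nb = n_cells
    counts = np.concatenate(
        [
            rng.poisson(lam[:, None], (n_genes, na)),
            rng.poisson(lam_b[:, None], (n_genes, nb)),
        ],
        axis=1,
    )
    genes = [f"Gene{i + 1:04d}" for i in range(n_genes)]
    cells = CellMatrix(
        counts=sparse.csr_matrix(counts),
        gene_names=genes,
        cell_ids=list(range(1, na + nb + 1)),
        area_um2=np.full(na + nb, 50.0),
        centroid=np.zeros((na + nb, 2)),
    )
    labels = np.array(["A"] * na + ["B"] * nb)
    truth = pd.DataFrame(
        {
            "gene": genes,
            "rate_a": lam,
            "rate_b": lam_b,
            "is_de": [i < n_de for i in range(n_genes)],
            "log2_ratio": np.log2(lam_b / lam),
        }
    ).set_index("gene")
    return cells, labels, truth
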