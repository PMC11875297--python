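"""Simulation and run configuration.

All coordinates are micrometres, origin at the lower left, y increasing
upward (toward the nasal side).  Shelf polygons are simple, closed and
counter-clockwise.  A section holds two mirror-image shelves, ``P_L`` and
``P_R``, separated by a midline gap; the oral edge is the lower boundary.

Compartments of one shelf, from the oral edge upward:

``oral_epithelium``
    band of width :attr:`SimConfig.epithelium_band_width` along the oral
    boundary; the oral marker (*Shh*) is confined here.
``oral_mesenchyme``
    mesenchyme between the band and ``oral_fraction`` of the shelf height;
    the responder marker (*Ptch1*) is elevated only here.
``nasal_mesenchyme``
    the remainder of the shelf.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

COMPARTMENTS = ("oral_epithelium", "oral_mesenchyme", "nasal_mesenchyme")

#: condition label separator: "WT:E12.5" = (genotype "WT", stage "E12.5")
COND_SEP = ":"

# a handful of genes from the palate literature seed the synthetic panel;
# the rest are anonymous filler
_NAMED_GENES = [
    "Shh", "Ptch1", "mt-Co1", "mt-Nd1",
    "Col1a1", "Eln", "Bgn", "Prrx1", "Alx1", "Dlx1", "Wnt5a", "Wnt16",
    "Msx1", "Gsc", "Dkk1", "Rspo1", "Lgr5", "Wif1", "Tnn", "Jag1",
    "Lum", "Ogn", "Fmod", "Dcn", "Postn", "Pax9",
]


def condition_label(genotype: str, stage: str) -> str:
    return f"{genotype}{COND_SEP}{stage}"


@dataclass
class HdConfig:
    """Parameters of the high-definition (binned) tissue simulation."""

    extent: tuple[float, float] = (200.0, 200.0)  # um
    bin_side: float = 2.0  # um
    pixel_size: float = 0.5  # um per mask pixel
    n_nuclei: int = 60
    nucleus_radius: tuple[float, float] = (3.0, 5.0)  # semi-axis range, um
    spread: float = 2.0  # Gaussian transcript spread around centroid, um
    background: float = 2e-4  # uniform background, transcripts/um^2/gene
    cell_types: tuple[str, ...] = ("epithelial", "mesenchymal")
    mean_counts_per_gene: float = 0.3  # expected transcripts/nucleus/gene
    placement_attempts: int = 200  # retries per nucleus before giving up


@dataclass
class SimConfig:
    """Full description of a synthetic palate section experiment."""

    n_genes: int
    gene_names: list[str]
    shelf_polygons: dict[str, Polygon]
    epithelium_band_width: float  # um
    oral_fraction: float  # fraction of shelf height that is oral
    gene_profiles: pd.DataFrame  # genes x COMPARTMENTS, transcripts/um^2
    condition_multipliers: pd.DataFrame  # genes x condition labels, rate ratios
    seed: int = 0
    oral_marker: str = "Shh"
    responder_marker: str = "Ptch1"
    mito_prefix: str = "mt-"
    low_quality_fraction: float = 0.0  # fraction of transcripts flagged low-qv
    qv_pass: float = 40.0
    qv_fail: float = 10.0
    hd: HdConfig = field(default_factory=HdConfig)

    # -- derived helpers -------------------------------------------------
    @property
    def conditions(self) -> list[tuple[str, str]]:
        out = []
        for label in self.condition_multipliers.columns:
            genotype, stage = label.split(COND_SEP, 1)
            out.append((genotype, stage))
        return out

    @property
    def genotypes(self) -> list[str]:
        seen: list[str] = []
        for g, _ in self.conditions:
            if g not in seen:
                seen.append(g)
        return seen

    @property
    def stages(self) -> list[str]:
        seen: list[str] = []
        for _, s in self.conditions:
            if s not in seen:
                seen.append(s)
        return seen

    def validate(self) -> None:
        if self.n_genes < 3:
            raise ValueError("n_genes must be >= 3 (two markers plus a test gene)")
        if len(self.gene_names) != self.n_genes:
            raise ValueError("gene_names length does not match n_genes")
        if len(set(self.gene_names)) != self.n_genes:
            raise ValueError("gene names must be unique")
        for marker in (self.oral_marker, self.responder_marker):
            if marker not in self.gene_names:
                raise ValueError(f"marker gene {marker!r} missing from panel")
        if not 0 < self.oral_fraction < 1:
            raise ValueError("oral_fraction must lie in (0, 1)")
        if self.epithelium_band_width <= 0:
            raise ValueError("epithelium_band_width must be positive")
        if not 0 <= self.low_quality_fraction <= 1:
            raise ValueError("low_quality_fraction must lie in [0, 1]")
        for shelf_id, poly in self.shelf_polygons.items():
            if not poly.is_valid or not poly.is_simple:
                raise ValueError(f"shelf polygon {shelf_id!r} is not simple")
            if poly.area <= 0:
                raise ValueError(f"shelf polygon {shelf_id!r} has zero area")
        prof = self.gene_profiles
        if list(prof.index) != list(self.gene_names):
            raise ValueError("gene_profiles index must equal gene_names")
        if list(prof.columns) != list(COMPARTMENTS):
            raise ValueError(f"gene_profiles columns must be {COMPARTMENTS}")
        if (prof.to_numpy() < 0).any():
            raise ValueError("intensities must be >= 0")
        mult = self.condition_multipliers
        if list(mult.index) != list(self.gene_names):
            raise ValueError("condition_multipliers index must equal gene_names")
        if (mult.to_numpy() <= 0).any():
            raise ValueError("multipliers must be > 0")

    def with_overrides(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


def default_shelves(
    width: float = 400.0, height: float = 600.0, gap: float = 200.0
) -> dict[str, Polygon]:
    """Two mirror-image convex shelves with chamfered nasal corners."""
    x0 = gap / 2.0
    right = Polygon(
        [
            (x0, 0.0),
            (x0 + width, 0.0),
            (x0 + width, 0.75 * height),
            (x0 + 0.85 * width, height),
            (x0 + 0.15 * width, height),
            (x0, 0.75 * height),
        ]
    )
    left = Polygon([(-x, y) for x, y in reversed(right.exterior.coords[:-1])])
    return {"P_L": left, "P_R": right}


def default_config(
    n_genes: int = 350,
    seed: int = 0,
    genotypes: tuple[str, ...] = ("WT", "KO"),
    stages: tuple[str, ...] = ("E12.5", "E13.5"),
    de_fold: float = 8.0,
    **overrides,
) -> SimConfig:
    """Construct the standard synthetic experiment.

    The panel mimics a 350-plex targeted in situ panel.  Baseline per-gene
    intensities are log-normal around 3e-3 transcripts/um^2 (tens of
    transcripts per 6400 um^2 ROI).  A fixed fraction of filler genes carries
    condition effects of ``de_fold`` (default 8x, i.e. |log2 ratio| = 3):
    8% up and 3% down between stages, 3% up and 6% down in the knockout.
    ``seed`` fixes the panel construction; simulation seeds are separate.
    """
    if n_genes < 3:
        raise ValueError("n_genes must be >= 3")
    rng = np.random.default_rng(seed)

    names = list(_NAMED_GENES[:n_genes])
    while len(names) < n_genes:
        names.append(f"Gene{len(names) + 1:04d}")

    base = rng.lognormal(mean=np.log(3e-3), sigma=0.6, size=n_genes)
    prof = pd.DataFrame(
        {c: base.copy() for c in COMPARTMENTS}, index=pd.Index(names, name="gene")
    )
    # marker structure: Shh confined to the oral epithelial band, Ptch1
    # elevated only in the adjacent (oral) mesenchyme
    prof.loc["Shh"] = [0.08, 0.0, 0.0]
    if "Ptch1" in prof.index:
        prof.loc["Ptch1"] = [0.002, 0.05, 0.002]

    reserved = {"Shh", "Ptch1"} | {n for n in names if n.lower().startswith("mt-")}
    candidates = [n for n in names if n not in reserved]
    rng.shuffle(candidates)

    n_pool = len(candidates)

    def take(frac: float) -> list[str]:
        k = int(round(frac * n_pool))
        picked = candidates[:k]
        del candidates[:k]
        return picked

    stage_up = take(0.08)
    stage_down = take(0.03)
    ko_up = take(0.03)
    ko_down = take(0.06)

    mult = pd.DataFrame(
        1.0,
        index=prof.index,
        columns=[condition_label(g, s) for g in genotypes for s in stages],
    )
    later_stages = list(stages[1:])
    ko_genotypes = list(genotypes[1:])
    for g in genotypes:
        for s in later_stages:
            mult.loc[stage_up, condition_label(g, s)] *= de_fold
            mult.loc[stage_down, condition_label(g, s)] /= de_fold
    for g in ko_genotypes:
        for s in stages:
            mult.loc[ko_up, condition_label(g, s)] *= de_fold
            mult.loc[ko_down, condition_label(g, s)] /= de_fold

    kwargs = dict(
        shelf_polygons=default_shelves(),
        epithelium_band_width=100.0,
        oral_fraction=0.35,
    )
    kwargs.update(overrides)
    cfg = SimConfig(
        n_genes=n_genes,
        gene_names=names,
        gene_profiles=prof,
        condition_multipliers=mult,
        seed=seed,
        **kwargs,
    )
    cfg.validate()
    return cfg


def null_config(n_genes: int = 100, seed: int = 0, **overrides) -> SimConfig:
    """Default panel with every condition multiplier forced to 1 (no true DE)."""
    cfg = default_config(n_genes=n_genes, seed=seed, **overrides)
    cfg.condition_multipliers.loc[:, :] = 1.0
    return cfg
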