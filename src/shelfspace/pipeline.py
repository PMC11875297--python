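"""End-to-end reproducible runs: simulate -> domains -> ROIs -> ROI-DGE.

A run is described by a :class:`RunConfig` (YAML-loadable; unknown keys
rejected).  Outputs are staged in a temporary directory and moved into
place only on success, so a failed run leaves no partial outputs.  Every
run writes a machine-readable ``manifest.json`` with the resolved
configuration, the seeds, the package version and a SHA-256 per output
file; identical config + seed reproduce identical hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
import tempfile
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from shelfspace import __version__
from shelfspace import io as sio
from shelfspace.config import default_config
from shelfspace.geometry import (
    ROI_SIDE,
    place_section_rois,
    shelf_partitions,
)
from shelfspace.roi_dge import (
    DENSITY_PSEUDOCOUNT,
    LFC_THRESHOLD,
    P_THRESHOLD,
    build_roi_density_table,
    roi_dge_compare,
    volcano_table,
)
from shelfspace.simulate import simulate_cohort

log = logging.getLogger("shelfspace")


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run."""

    seed: int = 0
    # synthetic experiment
    n_genes: int = 350
    panel_seed: int = 0
    epithelium_band_width: float = 100.0
    oral_fraction: float = 0.35
    low_quality_fraction: float = 0.0
    de_fold: float = 8.0
    # optional measured inputs: condition label -> transcript CSV; when set,
    # these replace the corresponding simulated sections
    inputs: dict = field(default_factory=dict)
    # domain geometry
    oral_marker: str = "Shh"
    responder_marker: str = "Ptch1"
    density_cell_size: float = 10.0
    density_bandwidth: float = 15.0
    coexpression_quantile: float = 0.9
    # ROIs
    roi_side: float = ROI_SIDE
    rois_per_side: int = 3
    # differential expression
    contrasts: list = field(
        default_factory=lambda: [
            {"a": "WT:E13.5", "b": "WT:E12.5", "scope": "whole"},
            {"a": "WT:E13.5", "b": "WT:E12.5", "scope": "NP"},
            {"a": "WT:E13.5", "b": "WT:E12.5", "scope": "OP"},
            {"a": "KO:E13.5", "b": "WT:E13.5", "scope": "whole"},
        ]
    )
    p_threshold: float = P_THRESHOLD
    lfc_threshold: float = LFC_THRESHOLD
    pseudocount: float = DENSITY_PSEUDOCOUNT
    alpha_f: float = 0.05
    classify_on: str = "raw"
    version: str = __version__

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.pop("version", None)
        return cls(**raw)

    def resolved(self) -> dict:
        return asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute simulate -> domains -> ROI placement -> ROI-DGE.

    Returns the output directory, which holds per-condition transcript
    CSVs and ROI CSVs, the pooled density table, one volcano TSV per
    contrast x scope, and ``manifest.json``.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()):
        raise FileExistsError(f"output directory {out_dir} is not empty")
    for cond, path in config.inputs.items():
        if not Path(path).exists():
            raise FileNotFoundError(f"input for {cond!r} not found: {path}")

    sim_cfg = default_config(
        n_genes=config.n_genes,
        seed=config.panel_seed,
        de_fold=config.de_fold,
        epithelium_band_width=config.epithelium_band_width,
        oral_fraction=config.oral_fraction,
        low_quality_fraction=config.low_quality_fraction,
    )
    log.info("resolved config: %s", json.dumps(config.resolved(), sort_keys=True))

    staging = Path(tempfile.mkdtemp(prefix=out_dir.name + ".", dir=out_dir.parent))
    try:
        outputs: list[Path] = []

        log.info("simulating cohort (seed=%d)", config.seed)
        cohort = simulate_cohort(sim_cfg, seed=config.seed)
        transcripts = {}
        for (genotype, stage), section in sorted(cohort.items()):
            label = f"{genotype}:{stage}"
            transcripts[label] = section.transcripts
        for cond, path in config.inputs.items():
            transcripts[cond] = sio.read_transcripts(path)
        for label, table in transcripts.items():
            path = staging / f"transcripts_{label.replace(':', '_')}.csv"
            sio.write_transcripts(table, path)
            outputs.append(path)

        log.info("deriving oronasal domains and placing ROIs")
        roi_seed_children = np.random.SeedSequence(config.seed).spawn(
            len(transcripts) + 1
        )
        rois_by_cond = {}
        for (label, table), child in zip(
            sorted(transcripts.items()), roi_seed_children
        ):
            partitions = shelf_partitions(
                table,
                sim_cfg.shelf_polygons,
                oral_marker=config.oral_marker,
                responder_marker=config.responder_marker,
                cell_size=config.density_cell_size,
                bandwidth=config.density_bandwidth,
                quantile=config.coexpression_quantile,
            )
            sub_seed = int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
            rois = place_section_rois(
                partitions,
                n_per_side=config.rois_per_side,
                side=config.roi_side,
                seed=sub_seed,
            )
            rois_by_cond[label] = rois
            path = staging / f"rois_{label.replace(':', '_')}.csv"
            sio.write_rois(rois, path)
            outputs.append(path)

        log.info("quantifying ROI transcript densities")
        table = build_roi_density_table(
            transcripts, rois_by_cond, sim_cfg.gene_names
        )
        dens_path = staging / "roi_densities.tsv"
        table.densities.join(table.meta).to_csv(dens_path, sep="\t")
        outputs.append(dens_path)

        for contrast in config.contrasts:
            a, b, scope = contrast["a"], contrast["b"], contrast["scope"]
            log.info("ROI-DGE %s vs %s (%s)", a, b, scope)
            records = roi_dge_compare(
                table,
                (a, b),
                scope=scope,
                p_thr=config.p_threshold,
                lfc_thr=config.lfc_threshold,
                pseudocount=config.pseudocount,
                alpha_f=config.alpha_f,
                classify_on=config.classify_on,
            )
            volcano = volcano_table(records)
            name = (
                f"dge_{a.replace(':', '_')}_vs_{b.replace(':', '_')}_{scope}.tsv"
            )
            path = staging / name
            sio.write_table(volcano, path)
            outputs.append(path)

        manifest = {
            "version": __version__,
            "seed": config.seed,
            "config": config.resolved(),
            "inputs": {k: str(v) for k, v in config.inputs.items()},
            "n_rois_per_section": {
                label: int(len(r)) for label, r in sorted(rois_by_cond.items())
            },
            "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
        }
        with open(staging / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

        if out_dir.exists():
            out_dir.rmdir()
        staging.replace(out_dir)
    except BaseException:
        shutil.rmtree(staging, ignore_errors=True)
        raise
    return out_dir
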