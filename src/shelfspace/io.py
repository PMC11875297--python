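"""Readers and writers for the pipeline's file formats.

CSV (transcripts, ROIs), MatrixMarket + TSV sidecars (count matrices,
10x-style triplet), GMT (gene sets), PGM (label masks), TSV (result
tables).  All text is UTF-8 with ``.`` decimals; every writer round-trips
with its reader.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import io as scipy_io
from scipy import sparse

from shelfspace.cellbin import BinMatrix, CellMatrix
from shelfspace.geometry import ROISET_COLUMNS, validate_roi_table
from shelfspace.simulate import TRANSCRIPT_COLUMNS


class FormatError(ValueError):
    """A file does not conform to its expected format."""


# -- transcript tables ---------------------------------------------------

def read_transcripts(path: str | Path) -> pd.DataFrame:
    """Read a transcript point-cloud CSV.

    Requires ``feature_name``, ``x_location``, ``y_location`` columns
    (``qv`` optional, filled with 40 when absent).  Rows whose coordinates
    are missing or non-numeric raise with their line numbers (line 1 is
    the header).
    """
    path = Path(path)
    table = pd.read_csv(path, dtype=str)
    for col in ("feature_name", "x_location", "y_location"):
        if col not in table.columns:
            raise FormatError(f"{path.name}: missing mandatory column {col!r}")
    out = pd.DataFrame({"feature_name": table["feature_name"].astype(str)})
    for col in ("x_location", "y_location"):
        vals = pd.to_numeric(table[col], errors="coerce")
        bad = vals.index[vals.isna()] + 2  # header is line 1
        if len(bad):
            raise FormatError(
                f"{path.name}: non-numeric {col} on line(s) "
                f"{', '.join(map(str, bad[:10]))}"
            )
        out[col] = vals.astype(float)
    if "qv" in table.columns:
        out["qv"] = pd.to_numeric(table["qv"], errors="coerce").fillna(40.0)
    else:
        out["qv"] = 40.0
    return out[TRANSCRIPT_COLUMNS]


def write_transcripts(table: pd.DataFrame, path: str | Path) -> None:
    table[TRANSCRIPT_COLUMNS].to_csv(path, index=False)


# -- count matrices ------------------------------------------------------

def _find(directory: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = directory / name
        if p.exists():
            return p
    raise FormatError(f"{directory}: missing {stem}[.gz]")


def _read_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _read_mtx(path: Path) -> sparse.csr_matrix:
    if path.suffix == ".gz":
        with gzip.open(path, "rb") as fh:
            mat = scipy_io.mmread(fh)
    else:
        mat = scipy_io.mmread(path)
    return sparse.csr_matrix(mat)


def read_counts(directory: str | Path) -> BinMatrix | CellMatrix:
    """Read a MatrixMarket triplet directory.

    ``matrix.mtx[.gz]`` + ``features.tsv[.gz]`` plus either ``bins.tsv``
    (-> :class:`BinMatrix`) or ``cells.tsv`` (-> :class:`CellMatrix`).
    """
    directory = Path(directory)
    counts = _read_mtx(_find(directory, "matrix.mtx"))
    features = _read_tsv(_find(directory, "features.tsv"))
    if "gene" not in features.columns:
        raise FormatError("features.tsv must have a 'gene' column")
    genes = features["gene"].astype(str).to_list()
    if counts.shape[0] != len(genes):
        raise FormatError(
            f"matrix has {counts.shape[0]} rows but features.tsv lists "
            f"{len(genes)} genes"
        )
    has_bins = (directory / "bins.tsv").exists() or (
        directory / "bins.tsv.gz"
    ).exists()
    if has_bins:
        bins = _read_tsv(_find(directory, "bins.tsv"))
        if counts.shape[1] != len(bins):
            raise FormatError(
                f"matrix has {counts.shape[1]} columns but bins.tsv lists "
                f"{len(bins)} bins"
            )
        side = bins["side_um"].unique()
        if len(side) != 1:
            raise FormatError("bins.tsv mixes bin side lengths")
        return BinMatrix(
            counts=counts,
            gene_names=genes,
            bin_centers=bins[["center_x", "center_y"]].to_numpy(),
            bin_side=float(side[0]),
        )
    cells = _read_tsv(_find(directory, "cells.tsv"))
    if counts.shape[1] != len(cells):
        raise FormatError(
            f"matrix has {counts.shape[1]} columns but cells.tsv lists "
            f"{len(cells)} cells"
        )
    return CellMatrix(
        counts=counts,
        gene_names=genes,
        cell_ids=cells["cell_id"].astype(int).to_list(),
        area_um2=cells["area_um2"].to_numpy(),
        centroid=cells[["centroid_x", "centroid_y"]].to_numpy(),
    )


def write_counts(
    matrix: BinMatrix | CellMatrix, directory: str | Path, compress: bool = False
) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    suffix = ".gz" if compress else ""

    def _write_tsv(frame: pd.DataFrame, stem: str) -> None:
        frame.to_csv(directory / (stem + suffix), sep="\t", index=False)

    mtx_path = directory / ("matrix.mtx" + suffix)
    if compress:
        with gzip.open(mtx_path, "wb") as fh:
            scipy_io.mmwrite(fh, matrix.counts.tocoo(), field="integer")
    else:
        scipy_io.mmwrite(mtx_path, matrix.counts.tocoo(), field="integer")
    _write_tsv(pd.DataFrame({"gene": matrix.gene_names}), "features.tsv")
    if isinstance(matrix, BinMatrix):
        _write_tsv(
            pd.DataFrame(
                {
                    "bin_id": np.arange(matrix.n_bins),
                    "center_x": matrix.bin_centers[:, 0],
                    "center_y": matrix.bin_centers[:, 1],
                    "side_um": matrix.bin_side,
                }
            ),
            "bins.tsv",
        )
    else:
        _write_tsv(
            pd.DataFrame(
                {
                    "cell_id": matrix.cell_ids,
                    "area_um2": matrix.area_um2,
                    "centroid_x": matrix.centroid[:, 0],
                    "centroid_y": matrix.centroid[:, 1],
                    "total_umi": matrix.total_umi,
                }
            ),
            "cells.tsv",
        )


# -- gene sets -----------------------------------------------------------

@dataclass
class GeneSetCollection:
    """GMT collection: term -> unique gene list (+ description)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str]

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a tab-separated GMT file (term, description, genes...)."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path.name}: line {lineno} has {len(fields)} fields; "
                    "GMT needs term, description and at least one gene"
                )
            term, desc, *genes = fields
            seen: list[str] = []
            for g in genes:
                if g and g not in seen:
                    seen.append(g)
            sets[term] = seen
            descriptions[term] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term, genes in collection.sets.items():
            desc = collection.descriptions.get(term, "")
            fh.write("\t".join([term, desc, *genes]) + "\n")


# -- label masks ---------------------------------------------------------

def read_mask(path: str | Path) -> np.ndarray:
    """Read a single-channel integer raster (PGM/PNG/TIFF)."""
    arr = np.asarray(iio.imread(path))
    if arr.ndim != 2:
        raise FormatError(f"{Path(path).name}: mask must be single-channel")
    return arr.astype(np.int32)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    mask = np.asarray(mask)
    if mask.min() < 0 or mask.max() > np.iinfo(np.uint16).max:
        raise ValueError("mask labels must fit in uint16")
    iio.imwrite(Path(path), mask.astype(np.uint16))


# -- ROI tables ----------------------------------------------------------

def read_rois(path: str | Path, validate: bool = True) -> pd.DataFrame:
    rois = pd.read_csv(path)
    missing = [c for c in ROISET_COLUMNS if c not in rois.columns]
    if missing:
        raise FormatError(f"{Path(path).name}: missing columns {missing}")
    if validate:
        validate_roi_table(rois)
    return rois[ROISET_COLUMNS]


def write_rois(rois: pd.DataFrame, path: str | Path) -> None:
    rois[ROISET_COLUMNS].to_csv(path, index=False)


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """Result tables go out as TSV with a fixed column order."""
    table.to_csv(path, sep="\t", index=False)
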