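"""Aggregate the HD bins onto segmented nuclei.

Reads the binned counts and nucleus mask from 01, assigns each 2 um bin to
the nucleus containing its center, filters nuclei by area and total UMI,
removes mitochondrial genes, and writes the single-cell matrix under
results/02_cells/.
"""

from pathlib import Path

from shelfspace import io as sio
from shelfspace.cellbin import (
    assign_bins_to_nuclei,
    filter_cells,
    load_label_mask,
    remove_mito_genes,
)

ROOT = Path(__file__).resolve().parents[1] / "results"
PIXEL_SIZE = 0.5  # um, the mask resolution used by 01


def main() -> None:
    out = ROOT / "02_cells"
    out.mkdir(parents=True, exist_ok=True)
    bins = sio.read_counts(ROOT / "01_simulate" / "hd_bins")
    mask = sio.read_mask(ROOT / "01_simulate" / "nuclei_mask.pgm")
    nuclei = load_label_mask(mask, pixel_size=PIXEL_SIZE)
    print(f"{len(nuclei)} nuclei; bin matrix "
          f"{bins.n_genes} genes x {bins.n_bins} bins, "
          f"{bins.total_counts()} counts")

    cells = assign_bins_to_nuclei(bins, nuclei)
    assigned = cells.total_counts()
    print(f"assigned {assigned} counts "
          f"({assigned / bins.total_counts():.1%} of all bins' counts) "
          f"to {cells.n_cells} cells")

    cells = filter_cells(cells, min_area=15.0, max_area=400.0, min_umi=10)
    print(f"{cells.n_cells} cells pass the area/UMI filter")

    n_before = len(cells.gene_names)
    cells = remove_mito_genes(cells, prefix="mt-")
    print(f"removed {n_before - len(cells.gene_names)} mitochondrial genes")

    sio.write_counts(cells, out)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
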