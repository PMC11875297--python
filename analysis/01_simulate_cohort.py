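"""Simulate the synthetic palate cohort.

Generates one coronal section per condition (WT/KO x E12.5/E13.5) with the
default 350-plex panel, plus one high-definition binned tissue with its
nucleus label mask.  Writes transcript CSVs, the HD count triplet and the
mask under results/01_simulate/.
"""

from pathlib import Path

from shelfspace import io as sio
from shelfspace.config import default_config
from shelfspace.simulate import simulate_cohort, simulate_hd_tissue

SEED = 20260924
OUT = Path(__file__).resolve().parents[1] / "results" / "01_simulate"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = default_config()
    cohort = simulate_cohort(cfg, seed=SEED)
    for (genotype, stage), section in sorted(cohort.items()):
        path = OUT / f"transcripts_{genotype}_{stage}.csv"
        sio.write_transcripts(section.transcripts, path)
        n_shh = (section.transcripts["feature_name"] == "Shh").sum()
        print(f"{genotype} {stage}: {len(section.transcripts)} transcripts "
              f"({n_shh} Shh) -> {path.name}")

    tissue = simulate_hd_tissue(cfg, seed=SEED + 1)
    sio.write_counts(tissue.bins, OUT / "hd_bins")
    sio.write_mask(tissue.mask, OUT / "nuclei_mask.pgm")
    tissue.truth_cells.to_csv(OUT / "hd_truth_cells.tsv", sep="\t", index=False)
    print(f"HD tissue: {tissue.bins.total_counts()} counts in "
          f"{tissue.bins.n_bins} bins, {len(tissue.truth_cells)} nuclei "
          f"({tissue.n_background} background transcripts)")


if __name__ == "__main__":
    main()
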