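"""ROI transcript-density differential expression.

Quantifies per-gene densities in every section's own ROIs and runs the
variance-gated comparison for the developmental contrast (WT E13.5 vs
E12.5) and the genotype contrast (KO vs WT at E13.5), each at whole-shelf,
NP and OP scope.  Writes one volcano TSV per contrast x scope under
results/05_roi_dge/ and prints the up/down counts.
"""

from pathlib import Path

from shelfspace import io as sio
from shelfspace.config import default_config
from shelfspace.roi_dge import build_roi_density_table, roi_dge_compare, volcano_table

ROOT = Path(__file__).resolve().parents[1] / "results"

CONTRASTS = [
    ("WT_E13.5", "WT_E12.5"),
    ("KO_E13.5", "WT_E13.5"),
]


def main() -> None:
    out = ROOT / "05_roi_dge"
    out.mkdir(parents=True, exist_ok=True)
    cfg = default_config()
    transcripts, rois = {}, {}
    for csv in sorted((ROOT / "01_simulate").glob("transcripts_*.csv")):
        condition = csv.stem.replace("transcripts_", "")
        transcripts[condition] = sio.read_transcripts(csv)
        rois[condition] = sio.read_rois(
            ROOT / "04_domains" / f"rois_{condition}.csv"
        )
    table = build_roi_density_table(transcripts, rois, cfg.gene_names)

    for a, b in CONTRASTS:
        for scope in ("whole", "NP", "OP"):
            records = roi_dge_compare(table, (a, b), scope=scope)
            volcano = volcano_table(records)
            path = out / f"dge_{a}_vs_{b}_{scope}.tsv"
            sio.write_table(volcano, path)
            n_up = int((records["class"] == "up").sum())
            n_down = int((records["class"] == "down").sum())
            print(f"{a} vs {b} [{scope}]: {n_up} up, {n_down} down "
                  f"of {len(records)} genes")


if __name__ == "__main__":
    main()
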