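"""Oronasal domains and ROI placement per section.

For each simulated condition: Shh and Ptch1 density maps, co-expression
mask, per-shelf oronasal axis, NP/OP split, and 12 area-standardized ROIs
(3 per side of the axis per shelf).  Writes ROI CSVs and a domain summary
under results/04_domains/.
"""

from pathlib import Path

import pandas as pd

from shelfspace import io as sio
from shelfspace.config import default_config
from shelfspace.geometry import place_section_rois, shelf_partitions

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 20260924


def main() -> None:
    out = ROOT / "04_domains"
    out.mkdir(parents=True, exist_ok=True)
    cfg = default_config()
    summary = []
    for i, csv in enumerate(sorted((ROOT / "01_simulate").glob("transcripts_*.csv"))):
        condition = csv.stem.replace("transcripts_", "")
        table = sio.read_transcripts(csv)
        parts = shelf_partitions(table, cfg.shelf_polygons)
        rois = place_section_rois(parts, seed=SEED + i)
        sio.write_rois(rois, out / f"rois_{condition}.csv")
        for shelf_id, part in sorted(parts.items()):
            summary.append(
                {
                    "condition": condition,
                    "shelf": shelf_id,
                    "op_area_um2": round(part.oral.area, 1),
                    "np_area_um2": round(part.nasal.area, 1),
                    "n_rois": int((rois["shelf"] == shelf_id).sum()),
                }
            )
        print(f"{condition}: {len(rois)} ROIs "
              f"(areas {sorted(rois['area_um2'].unique())})")
    pd.DataFrame(summary).to_csv(out / "domain_summary.tsv", sep="\t",
                                 index=False)
    print(f"wrote {out / 'domain_summary.tsv'}")


if __name__ == "__main__":
    main()
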