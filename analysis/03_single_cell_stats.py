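"""Single-cell statistics on the nucleus-binned matrix.

Uses the ground-truth cell types from 01 as group labels (clustering is
out of scope; labels are pipeline inputs), ranks epithelial markers by
AUC, runs the hurdle DE test epithelial vs mesenchymal, and performs ORA
against a small synthetic gene-set collection built from the panel.
Writes TSVs under results/03_sc_stats/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from shelfspace import io as sio
from shelfspace.io import GeneSetCollection
from shelfspace.sc_stats import auc_markers, deg_calls, hurdle_deg, lognormalize, ora

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 20260924


def main() -> None:
    out = ROOT / "03_sc_stats"
    out.mkdir(parents=True, exist_ok=True)
    cells = sio.read_counts(ROOT / "02_cells")
    truth = pd.read_csv(ROOT / "01_simulate" / "hd_truth_cells.tsv", sep="\t")
    labels = (
        truth.set_index("label")["cell_type"].reindex(cells.cell_ids).to_numpy()
    )
    norm = lognormalize(cells, scale_factor=1e4)

    markers = auc_markers(norm, labels, "epithelial")
    sio.write_table(markers, out / "markers_epithelial.tsv")
    top = markers.head(3)
    print("top epithelial markers by AUC:")
    for _, row in top.iterrows():
        print(f"  {row['gene']}: auc={row['auc']:.3f} power={row['power']:.3f}")

    deg = hurdle_deg(norm, labels, "epithelial", "mesenchymal")
    sio.write_table(deg, out / "deg_epithelial_vs_mesenchymal.tsv")
    calls = deg_calls(deg)
    print(f"{calls.sum()} of {len(deg)} genes pass |log2FC|>1 at FDR<0.01")

    # synthetic gene sets: one enriched in the DE hits, the rest random draws
    # from the panel (synthetic stand-in for a curated GO/KEGG GMT)
    rng = np.random.default_rng(SEED)
    universe = list(deg["gene"])
    hits = list(deg.loc[calls, "gene"])
    sets, descriptions = {}, {}
    if len(hits) >= 2:
        k = min(10, len(hits))
        seeded = list(rng.choice(hits, size=k, replace=False))
        filler = list(rng.choice(universe, size=10, replace=False))
        sets["SYNTH_DE_ENRICHED"] = sorted(set(seeded + filler))
        descriptions["SYNTH_DE_ENRICHED"] = "synthetic set seeded with DE genes"
    for i in range(5):
        draw = list(rng.choice(universe, size=15, replace=False))
        sets[f"SYNTH_RANDOM_{i + 1}"] = draw
        descriptions[f"SYNTH_RANDOM_{i + 1}"] = "synthetic random set"
    collection = GeneSetCollection(sets=sets, descriptions=descriptions)
    sio.write_gmt(collection, out / "synthetic_sets.gmt")

    if hits:
        enriched = ora(hits, universe, collection)
        sio.write_table(enriched, out / "ora.tsv")
        print(f"ORA: {len(enriched)} term(s) reported "
              f"(P<0.05 and >1 hit) of {len(collection)} tested")
    else:
        print("ORA skipped: no DE hits")


if __name__ == "__main__":
    main()
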