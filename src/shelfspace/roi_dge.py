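"""ROI transcript-density differential expression.

Per-gene transcript densities (transcripts/um^2) inside area-standardized
ROIs are the replicates.  The comparison between two conditions follows a
spreadsheet-style recipe:

* log2 fold change on the **raw** densities of the group means;
* p-value from the **log2(x + 1)**-transformed densities via a
  variance-gated two-sample t-test — a two-sided F-test on the variance
  ratio at alpha 0.05 decides between Student's (equal-variance) and
  Welch's (unequal-variance) t-test;
* Benjamini-Hochberg adjustment across genes, per contrast and scope;
* volcano classification: up if p < 0.05 and lfc > 1, down if p < 0.05 and
  lfc < -1, otherwise ns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from shelfspace.geometry import ROI_AREA
from shelfspace.sc_stats import bh_adjust

#: default pseudocount: one transcript per standard ROI, in density units
DENSITY_PSEUDOCOUNT = 1.0 / ROI_AREA
#: volcano thresholds
P_THRESHOLD = 0.05
LFC_THRESHOLD = 1.0
#: cap for -log10(p) at p = 0
NEGLOG10_CAP = 300.0

DGE_COLUMNS = ["gene", "lfc", "p_raw", "p_adj", "f_p", "test_used", "class"]
SCOPES = ("whole", "NP", "OP")


@dataclass
class RoiDensityTable:
    """Rows = ROIs, columns = genes, values = transcripts/um^2."""

    densities: pd.DataFrame  # index roi_id, columns genes
    meta: pd.DataFrame  # index roi_id: shelf, domain, condition

    def __post_init__(self) -> None:
        if not self.densities.index.equals(self.meta.index):
            raise ValueError("densities and meta must share the ROI index")
        if (self.densities.to_numpy() < 0).any():
            raise ValueError("densities must be non-negative")

    def scope_rows(self, scope: str) -> pd.Index:
        if scope == "whole":
            return self.densities.index
        if scope in ("NP", "OP"):
            return self.meta.index[self.meta["domain"] == scope]
        raise ValueError(f"scope must be one of {SCOPES}, got {scope!r}")


def roi_transcript_density(
    transcripts: pd.DataFrame, roi: pd.Series, gene_names: list[str]
) -> pd.Series:
    """Per-gene transcript density inside one square ROI.

    The square is half-open: left/bottom edges inclusive, right/top
    exclusive.
    """
    half = roi["side_um"] / 2.0
    x0, y0 = roi["center_x"] - half, roi["center_y"] - half
    x1, y1 = roi["center_x"] + half, roi["center_y"] + half
    x = transcripts["x_location"].to_numpy()
    y = transcripts["y_location"].to_numpy()
    inside = (x >= x0) & (x < x1) & (y >= y0) & (y < y1)
    counts = (
        transcripts.loc[inside, "feature_name"]
        .value_counts()
        .reindex(gene_names, fill_value=0)
    )
    return counts / roi["area_um2"]


def build_roi_density_table(
    transcripts_by_condition: dict[str, pd.DataFrame],
    rois: pd.DataFrame | dict[str, pd.DataFrame],
    gene_names: list[str],
) -> RoiDensityTable:
    """Quantify every ROI in every condition's transcript table.

    ``rois`` may be one table applied to every condition, or a per-condition
    mapping (each section quantified in its own ROI layout).  ROI ids are
    prefixed with the condition label.
    """
    dens_rows, meta_rows, index = [], [], []
    for condition, table in transcripts_by_condition.items():
        cond_rois = rois[condition] if isinstance(rois, dict) else rois
        for _, roi in cond_rois.iterrows():
            index.append(f"{condition}::{roi['roi_id']}")
            dens_rows.append(roi_transcript_density(table, roi, gene_names))
            meta_rows.append(
                {
                    "shelf": roi["shelf"],
                    "domain": roi["domain"],
                    "condition": condition,
                }
            )
    idx = pd.Index(index, name="roi")
    densities = pd.DataFrame(dens_rows, index=idx)
    meta = pd.DataFrame(meta_rows, index=idx)
    return RoiDensityTable(densities=densities, meta=meta)


def lfc_raw(group_a, group_b, pseudocount: float = DENSITY_PSEUDOCOUNT) -> float:
    """log2 ratio of raw-density group means, pseudocount-guarded."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("groups must be non-empty")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return float(np.log2((a.mean() + pseudocount) / (b.mean() + pseudocount)))


def variance_gated_pvalue(
    group_a, group_b, alpha_f: float = 0.05
) -> tuple[float, str, float]:
    """Two-sample test on log2(x + 1)-transformed densities.

    A two-sided F-test (larger sample variance in the numerator) at
    significance ``alpha_f`` gates the choice: unequal variances trigger
    Welch's t-test, otherwise Student's.  Returns (p, test_used, f_p).
    """
    a = np.log2(np.asarray(group_a, dtype=float) + 1.0)
    b = np.log2(np.asarray(group_b, dtype=float) + 1.0)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        f_p = 1.0
        p = 1.0 if a.mean() == b.mean() else 0.0
        return p, "student", f_p
    if va >= vb:
        f, dfn, dfd = (va / vb if vb > 0 else np.inf), len(a) - 1, len(b) - 1
    else:
        f, dfn, dfd = (vb / va if va > 0 else np.inf), len(b) - 1, len(a) - 1
    f_p = float(min(2.0 * stats.f.sf(f, dfn, dfd), 1.0)) if np.isfinite(f) else 0.0
    if f_p < alpha_f:
        res = stats.ttest_ind(a, b, equal_var=False)
        return float(res.pvalue), "welch", f_p
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.pvalue), "student", f_p


def classify(lfc: float, p: float, p_thr: float, lfc_thr: float) -> str:
    if p < p_thr and lfc > lfc_thr:
        return "up"
    if p < p_thr and lfc < -lfc_thr:
        return "down"
    return "ns"


def roi_dge_compare(
    table: RoiDensityTable,
    contrast: tuple[str, str],
    scope: str = "whole",
    p_thr: float = P_THRESHOLD,
    lfc_thr: float = LFC_THRESHOLD,
    pseudocount: float = DENSITY_PSEUDOCOUNT,
    alpha_f: float = 0.05,
    classify_on: str = "raw",
) -> pd.DataFrame:
    """Per-gene ROI-density comparison of condition A vs condition B.

    ``scope`` restricts the replicates: ``whole`` pools all ROIs (12 per
    section at defaults), ``NP``/``OP`` keep one domain.  Classification
    thresholds the raw p by default (``classify_on='adjusted'`` switches to
    the BH-adjusted p).
    """
    cond_a, cond_b = contrast
    if classify_on not in ("raw", "adjusted"):
        raise ValueError("classify_on must be 'raw' or 'adjusted'")
    rows_in_scope = table.scope_rows(scope)
    meta = table.meta.loc[rows_in_scope]
    dens = table.densities.loc[rows_in_scope]
    ra = dens[meta["condition"] == cond_a]
    rb = dens[meta["condition"] == cond_b]
    for cond, r in ((cond_a, ra), (cond_b, rb)):
        if len(r) < 2:
            raise ValueError(
                f"condition {cond!r} has {len(r)} ROIs in scope {scope!r}; "
                "need at least 2"
            )
    records = []
    for gene in dens.columns:
        a, b = ra[gene].to_numpy(), rb[gene].to_numpy()
        lfc = lfc_raw(a, b, pseudocount)
        p, test_used, f_p = variance_gated_pvalue(a, b, alpha_f)
        records.append(
            {"gene": gene, "lfc": lfc, "p_raw": p, "f_p": f_p,
             "test_used": test_used}
        )
    out = pd.DataFrame(records)
    out["p_adj"] = bh_adjust(out["p_raw"].to_list())
    p_for_class = out["p_raw"] if classify_on == "raw" else out["p_adj"]
    out["class"] = [
        classify(l, p, p_thr, lfc_thr) for l, p in zip(out["lfc"], p_for_class)
    ]
    return out[DGE_COLUMNS]


def volcano_table(records: pd.DataFrame) -> pd.DataFrame:
    """Add -log10(p_raw) (capped at 300 for p = 0) and sort for export."""
    if len(records) == 0:
        raise ValueError("no records to tabulate")
    out = records.copy()
    with np.errstate(divide="ignore"):
        neglog = -np.log10(out["p_raw"].to_numpy())
    out["neglog10p"] = np.minimum(neglog, NEGLOG10_CAP)
    order = {"up": 0, "down": 1, "ns": 2}
    out = out.sort_values(
        ["class", "p_raw"], key=lambda s: s.map(order) if s.name == "class" else s
    ).reset_index(drop=True)
    return out
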