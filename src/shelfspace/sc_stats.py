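"""Single-cell statistics on the nucleus-binned count matrix.

Normalization is a plain library-size log-transform
(``log2(1 + scale * count / total)``); the variance-stabilizing regression
normalization used by some toolchains is deliberately not reproduced here
(see docs/methods.md).  Marker ranking uses the Mann-Whitney AUC ("roc"
ranking); differential expression uses a two-part hurdle test: a logistic
(detection) component and a Gaussian (positive-value) component, whose
likelihood-ratio statistics are summed and referred to a chi-square with
one degree of freedom per estimable component.  Gene-set enrichment is a
hypergeometric over-representation test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from shelfspace.cellbin import CellMatrix

#: headline differential-expression call: |log2 FC| > 1 at FDR < 0.01
DEG_LFC_THRESHOLD = 1.0
DEG_FDR_THRESHOLD = 0.01
#: over-representation report: P < 0.05 and more than one hit in the set
ORA_P_THRESHOLD = 0.05
ORA_MIN_HITS = 2

MARKER_COLUMNS = ["gene", "auc", "power", "mean_in", "mean_out"]
DEG_COLUMNS = ["gene", "lfc", "p", "fdr", "components_used",
               "lr_discrete", "lr_continuous", "df"]
ORA_COLUMNS = ["term", "hits_in_set", "set_size", "universe_size",
               "hits_total", "p", "fdr", "reported"]


@dataclass
class NormMatrix:
    """log2(1 + scaled counts), genes x cells."""

    values: np.ndarray
    gene_names: list[str]
    cell_ids: list[int]
    scale_factor: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_names), len(self.cell_ids)):
            raise ValueError("values shape does not match annotations")


def lognormalize(cells: CellMatrix, scale_factor: float = 1e4) -> NormMatrix:
    """Library-size normalization followed by a log2(1 + x) transform."""
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    totals = cells.total_umi.astype(float)
    if (totals <= 0).any():
        raise ValueError(
            "cells with zero total UMI present; run filter_cells first"
        )
    dense = cells.counts.toarray().astype(float)
    values = np.log2(1.0 + scale_factor * dense / totals[None, :])
    return NormMatrix(
        values=values,
        gene_names=list(cells.gene_names),
        cell_ids=list(cells.cell_ids),
        scale_factor=scale_factor,
    )


def _mann_whitney_auc(x_in: np.ndarray, x_out: np.ndarray) -> float:
    """AUC of in-group vs out-group values, ties counted one half."""
    n1, n2 = len(x_in), len(x_out)
    ranks = stats.rankdata(np.concatenate([x_in, x_out]))
    r1 = ranks[:n1].sum()
    return (r1 - n1 * (n1 + 1) / 2.0) / (n1 * n2)


def auc_markers(
    norm: NormMatrix, labels: np.ndarray, group: str
) -> pd.DataFrame:
    """Rank genes by their power to tell ``group`` cells from the rest.

    Per gene, the Mann-Whitney AUC of in-group vs out-group expression;
    predictive power is ``2 * |auc - 0.5|``.  Sorted by power descending,
    ties broken by gene name.
    """
    labels = np.asarray(labels)
    if len(labels) != len(norm.cell_ids):
        raise ValueError("labels length does not match cell count")
    in_mask = labels == group
    if not in_mask.any():
        raise ValueError(f"group {group!r} not present in labels")
    if in_mask.all():
        raise ValueError("out-group empty: labeling has a single group")
    x_in = norm.values[:, in_mask]
    x_out = norm.values[:, ~in_mask]
    auc = np.array(
        [_mann_whitney_auc(x_in[g], x_out[g]) for g in range(len(norm.gene_names))]
    )
    table = pd.DataFrame(
        {
            "gene": norm.gene_names,
            "auc": auc,
            "power": 2.0 * np.abs(auc - 0.5),
            "mean_in": x_in.mean(axis=1),
            "mean_out": x_out.mean(axis=1),
        }
    )
    table = table.sort_values(
        ["power", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return table[MARKER_COLUMNS]


def _binom_ll(k: int, n: int) -> float:
    """Log-likelihood of a binomial proportion at its MLE (0 log 0 = 0)."""
    ll = 0.0
    if 0 < k:
        ll += k * np.log(k / n)
    if k < n:
        ll += (n - k) * np.log((n - k) / n)
    return ll


def _hurdle_one_gene(
    va: np.ndarray, vb: np.ndarray
) -> tuple[float, float, int, str]:
    """(lr_discrete, lr_continuous, df, components_used) for one gene."""
    na, nb = len(va), len(vb)
    ka, kb = int((va > 0).sum()), int((vb > 0).sum())
    k, n = ka + kb, na + nb

    lr_d = 0.0
    disc_ok = 0 < k < n
    if disc_ok:
        lr_d = 2.0 * (_binom_ll(ka, na) + _binom_ll(kb, nb) - _binom_ll(k, n))

    pa, pb = va[va > 0], vb[vb > 0]
    cont_ok = len(pa) >= 1 and len(pb) >= 1 and len(pa) + len(pb) >= 3
    lr_c = 0.0
    if cont_ok:
        pooled = np.concatenate([pa, pb])
        rss0 = float(((pooled - pooled.mean()) ** 2).sum())
        rss1 = float(((pa - pa.mean()) ** 2).sum()
                     + ((pb - pb.mean()) ** 2).sum())
        if rss0 <= 0:
            lr_c = 0.0
        else:
            lr_c = len(pooled) * np.log(rss0 / max(rss1, 1e-300))

    df = int(disc_ok) + int(cont_ok)
    which = {(True, True): "both", (True, False): "discrete",
             (False, True): "continuous", (False, False): "none"}[
        (disc_ok, cont_ok)]
    return lr_d, lr_c, df, which


def hurdle_deg(
    norm: NormMatrix,
    labels: np.ndarray,
    group_a: str,
    group_b: str,
) -> pd.DataFrame:
    """Two-part hurdle differential expression between two cell groups.

    Per gene, the detection (logistic) and positive-value (Gaussian)
    likelihood-ratio statistics are summed; p comes from the chi-square
    upper tail with one df per estimable component.  ``lfc`` is the
    difference of group means of the normalized values including zeros
    (log2 units).  ``fdr`` is Benjamini-Hochberg across genes.
    """
    labels = np.asarray(labels)
    ma, mb = labels == group_a, labels == group_b
    if not ma.any() or not mb.any():
        raise ValueError("both groups must be non-empty")
    rows = []
    for g, gene in enumerate(norm.gene_names):
        va, vb = norm.values[g, ma], norm.values[g, mb]
        lr_d, lr_c, df, which = _hurdle_one_gene(va, vb)
        if df == 0:
            p = 1.0
        else:
            p = float(stats.chi2.sf(lr_d + lr_c, df))
        rows.append(
            {
                "gene": gene,
                "lfc": float(va.mean() - vb.mean()),
                "p": p,
                "components_used": which,
                "lr_discrete": lr_d,
                "lr_continuous": lr_c,
                "df": df,
            }
        )
    table = pd.DataFrame(rows)
    table["fdr"] = bh_adjust(table["p"].to_list())
    return table[DEG_COLUMNS]


def deg_calls(
    table: pd.DataFrame,
    lfc_thr: float = DEG_LFC_THRESHOLD,
    fdr_thr: float = DEG_FDR_THRESHOLD,
) -> pd.Series:
    """Boolean DE call: FDR below threshold and |log2 FC| above threshold."""
    return (table["fdr"] < fdr_thr) & (table["lfc"].abs() > lfc_thr)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ora(
    hits: list[str],
    universe: list[str],
    sets,
    p_thr: float = ORA_P_THRESHOLD,
    min_hits: int = ORA_MIN_HITS,
    only_reported: bool = True,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``hits`` against gene sets.

    ``sets`` maps term -> gene list (a GMT collection).  Set sizes are
    taken within the universe.  BH adjustment runs across all tested terms;
    a term is reported iff ``p < p_thr`` and it contains at least
    ``min_hits`` hit genes.
    """
    uni = set(universe)
    hit_set = set(hits)
    stray = hit_set - uni
    if stray:
        raise ValueError(f"hit genes absent from universe: {sorted(stray)[:5]}")
    if hasattr(sets, "sets"):
        sets = sets.sets
    if not sets:
        raise ValueError("gene-set collection is empty")
    m = len(uni)
    n_hits = len(hit_set)
    rows = []
    for term, genes in sets.items():
        in_uni = set(genes) & uni
        k = len(in_uni & hit_set)
        if len(in_uni) == 0:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(k - 1, m, len(in_uni), n_hits))
        rows.append(
            {
                "term": term,
                "hits_in_set": k,
                "set_size": len(in_uni),
                "universe_size": m,
                "hits_total": n_hits,
                "p": p,
            }
        )
    table = pd.DataFrame(rows)
    table["fdr"] = bh_adjust(table["p"].to_list())
    table["reported"] = (table["p"] < p_thr) & (table["hits_in_set"] >= min_hits)
    table = table[ORA_COLUMNS].sort_values(["p", "term"]).reset_index(drop=True)
    if only_reported:
        return table[table["reported"]].reset_index(drop=True)
    return table
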