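"""Normalization, AUC marker ranking, hurdle DE, BH and ORA against
independent oracles (pair counting, definitional BH, combinatorial
enumeration)."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import sparse

from shelfspace.cellbin import CellMatrix
from shelfspace.sc_stats import (
    NormMatrix,
    auc_markers,
    bh_adjust,
    deg_calls,
    hurdle_deg,
    lognormalize,
    ora,
)


def _cells(counts):
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    return CellMatrix(
        counts=sparse.csr_matrix(counts),
        gene_names=[f"g{i}" for i in range(n_genes)],
        cell_ids=list(range(1, n_cells + 1)),
        area_um2=np.full(n_cells, 50.0),
        centroid=np.zeros((n_cells, 2)),
    )


def _norm(values, genes=None):
    values = np.asarray(values, dtype=float)
    return NormMatrix(
        values=values,
        gene_names=genes or [f"g{i}" for i in range(values.shape[0])],
        cell_ids=list(range(values.shape[1])),
        scale_factor=1.0,
    )


class TestLognormalize:
    def test_zero_counts_stay_zero(self):
        cells = _cells([[0, 0], [3, 5]])
        norm = lognormalize(cells, scale_factor=10.0)
        assert (norm.values[0] == 0).all()

    def test_full_library_with_unit_scale(self):
        cells = _cells([[4, 0], [0, 7]])
        norm = lognormalize(cells, scale_factor=1.0)
        # count == cell total, scale 1 -> log2(2) = 1
        assert norm.values[0, 0] == pytest.approx(1.0)
        assert norm.values[1, 1] == pytest.approx(1.0)

    def test_matches_elementwise_recomputation(self, rng):
        counts = rng.integers(0, 20, (6, 9))
        counts[0, :] += 1  # avoid zero-total cells
        cells = _cells(counts)
        norm = lognormalize(cells, scale_factor=1e4)
        totals = counts.sum(axis=0)
        for g in range(6):
            for c in range(9):
                expected = math.log2(1 + 1e4 * counts[g, c] / totals[c])
                assert norm.values[g, c] == pytest.approx(expected)

    def test_zero_total_cell_rejected(self):
        with pytest.raises(ValueError, match="filter"):
            lognormalize(_cells([[0, 1], [0, 2]]))


class TestAucMarkers:
    def test_constant_gene_is_uninformative(self):
        norm = _norm([[2.0] * 7])
        table = auc_markers(norm, np.array(["a"] * 3 + ["b"] * 4), "a")
        assert table["auc"].iloc[0] == pytest.approx(0.5)
        assert table["power"].iloc[0] == pytest.approx(0.0)

    def test_complete_separation(self):
        norm = _norm([[5.0, 6.0, 7.0, 1.0, 2.0]])
        table = auc_markers(norm, np.array(["a"] * 3 + ["b"] * 2), "a")
        assert table["auc"].iloc[0] == pytest.approx(1.0)

    def test_matches_exhaustive_pair_count(self, rng):
        # 5 vs 4 cells with ties: AUC = (#concordant + ties/2) / (n1*n2)
        values = np.array([[1.0, 3.0, 3.0, 0.0, 2.0, 3.0, 1.0, 0.5, 2.0]])
        labels = np.array(["in"] * 5 + ["out"] * 4)
        table = auc_markers(_norm(values), labels, "in")
        x_in, x_out = values[0, :5], values[0, 5:]
        score = 0.0
        for a, b in itertools.product(x_in, x_out):
            score += 1.0 if a > b else (0.5 if a == b else 0.0)
        assert table["auc"].iloc[0] == pytest.approx(score / 20)

    def test_complement_symmetry(self, rng):
        values = rng.normal(size=(8, 12))
        labels = np.array(["a"] * 5 + ["b"] * 7)
        ta = auc_markers(_norm(values), labels, "a").set_index("gene")
        tb = auc_markers(_norm(values), labels, "b").set_index("gene")
        for g in ta.index:
            assert ta.loc[g, "auc"] + tb.loc[g, "auc"] == pytest.approx(1.0)

    def test_sorted_by_power_with_name_ties(self, rng):
        values = rng.normal(size=(6, 10))
        labels = np.array(["a"] * 5 + ["b"] * 5)
        table = auc_markers(_norm(values), labels, "a")
        powers = table["power"].to_numpy()
        assert (np.diff(powers) <= 1e-12).all()

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            auc_markers(_norm([[1.0, 2.0]]), np.array(["a", "a"]), "a")


class TestHurdleDeg:
    def test_identical_groups_give_p_one(self):
        # exchangeable construction: both groups hold the same values
        vals = np.array([[0.0, 1.5, 0.0, 2.0, 0.0, 1.5, 0.0, 2.0]])
        labels = np.array(["A"] * 4 + ["B"] * 4)
        table = hurdle_deg(_norm(vals), labels, "A", "B")
        assert table["p"].iloc[0] == pytest.approx(1.0)
        assert table["lfc"].iloc[0] == pytest.approx(0.0)

    def test_all_zero_gene(self):
        vals = np.zeros((1, 10))
        labels = np.array(["A"] * 5 + ["B"] * 5)
        table = hurdle_deg(_norm(vals), labels, "A", "B")
        row = table.iloc[0]
        assert row["p"] == 1.0
        assert row["lfc"] == 0.0
        assert row["components_used"] == "none"
        assert row["df"] == 0

    def test_null_type_one_error_calibrated(self):
        from shelfspace.simulate import simulate_cell_cohort

        cells, labels, _ = simulate_cell_cohort(
            n_genes=200, n_cells=(50, 50), n_de=0, seed=42
        )
        table = hurdle_deg(lognormalize(cells), labels, "A", "B")
        frac = (table["p"] < 0.05).mean()
        se = math.sqrt(0.05 * 0.95 / 200)
        assert abs(frac - 0.05) <= 3 * se

    def test_detection_only_shift_uses_discrete_component(self):
        rng = np.random.default_rng(0)
        a = (rng.random(80) < 0.8).astype(float) * 2.0
        b = (rng.random(80) < 0.2).astype(float) * 2.0
        vals = np.concatenate([a, b])[None, :]
        labels = np.array(["A"] * 80 + ["B"] * 80)
        table = hurdle_deg(_norm(vals), labels, "A", "B")
        assert table["p"].iloc[0] < 1e-6
        # positive values are constant: continuous part carries no signal
        assert table["lr_continuous"].iloc[0] == pytest.approx(0.0)

    def test_deg_call_criterion(self):
        table = pd.DataFrame(
            {
                "gene": ["a", "b", "c", "d"],
                "lfc": [2.0, 0.5, -3.0, 2.0],
                "fdr": [0.001, 0.001, 0.005, 0.5],
            }
        )
        calls = deg_calls(table)
        assert calls.tolist() == [True, False, True, False]


class TestBhAdjust:
    def _brute_force(self, pvals):
        m = len(pvals)
        order = np.argsort(pvals, kind="mergesort")
        adj = np.empty(m)
        for rank_pos, i in enumerate(order):
            tail = [
                m * pvals[j] / (list(order).index(j) + 1) for j in order[rank_pos:]
            ]
            adj[i] = min(1.0, min(tail))
        return adj

    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_matches_definitional_minimum(self):
        p = [0.01, 0.02, 0.03, 0.04]
        np.testing.assert_allclose(bh_adjust(p), self._brute_force(p))

    def test_all_equal_stay_equal(self):
        np.testing.assert_allclose(bh_adjust([0.2] * 5), [0.2] * 5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=12,
        )
    )
    def test_definitional_and_monotone(self, pvals):
        adj = bh_adjust(pvals)
        np.testing.assert_allclose(adj, self._brute_force(pvals), atol=1e-12)
        order = np.argsort(pvals, kind="mergesort")
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestOra:
    def _sets(self, mapping):
        return mapping

    def test_disjoint_term_not_reported(self):
        table = ora(
            hits=["a", "b"],
            universe=["a", "b", "c", "d", "e"],
            sets={"T": ["c", "d"]},
            only_reported=False,
        )
        assert table["p"].iloc[0] == pytest.approx(1.0)
        assert not table["reported"].iloc[0]

    def test_matches_exhaustive_enumeration(self):
        # universe 10, set 4, hits 5, overlap 4
        universe = [f"g{i}" for i in range(10)]
        gene_set = universe[:4]
        hits = universe[:4] + [universe[7]]
        table = ora(hits, universe, {"T": gene_set}, only_reported=False)
        count = sum(
            1
            for draw in itertools.combinations(universe, 5)
            if len(set(draw) & set(gene_set)) >= 4
        )
        expected = count / math.comb(10, 5)
        assert table["p"].iloc[0] == pytest.approx(expected)

    def test_single_hit_term_excluded_despite_tiny_p(self):
        universe = [f"g{i}" for i in range(200)]
        table = ora(
            hits=["g0"],
            universe=universe,
            sets={"T": ["g0"]},
            only_reported=False,
        )
        assert table["p"].iloc[0] < 0.05
        assert not table["reported"].iloc[0]
        assert len(ora(["g0"], universe, {"T": ["g0"]})) == 0

    def test_hit_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            ora(["x"], ["a", "b"], {"T": ["a"]})

    def test_enumeration_agreement_on_random_small_universes(self, rng):
        for _ in range(10):
            m = int(rng.integers(4, 13))
            universe = [f"g{i}" for i in range(m)]
            k_set = int(rng.integers(1, m))
            k_hits = int(rng.integers(1, m))
            gene_set = list(rng.choice(universe, size=k_set, replace=False))
            hits = list(rng.choice(universe, size=k_hits, replace=False))
            table = ora(hits, universe, {"T": gene_set}, only_reported=False)
            overlap_needed = len(set(hits) & set(gene_set))
            count = sum(
                1
                for draw in itertools.combinations(universe, k_hits)
                if len(set(draw) & set(gene_set)) >= overlap_needed
            )
            expected = count / math.comb(m, k_hits)
            assert table["p"].iloc[0] == pytest.approx(expected)
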