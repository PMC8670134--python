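"""Survival grouping, log-rank, adjusted Cox PH, and BH FDR."""

import math

import numpy as np
import pandas as pd
import pytest

from mexnet import ClinicalTable, MutationMatrix
from mexnet.survival import (
    analyze_bases,
    bh_fdr,
    coxph_adjusted,
    group_by_genes,
    life_table,
    logrank_test,
)


def _clinical(times, events, ages=None, sexes=None, samples=None):
    n = len(times)
    return ClinicalTable(
        pd.DataFrame(
            {
                "sample": samples or [f"S{i}" for i in range(n)],
                "time": times,
                "event": events,
                "age": ages or [60] * n,
                "sex": sexes or ["female"] * n,
            }
        )
    )


def _matrix(rows: dict, n_samples: int):
    samples = [f"S{i}" for i in range(n_samples)]
    genes = sorted(rows)
    values = np.zeros((len(genes), n_samples), dtype=int)
    for i, g in enumerate(genes):
        values[i, list(rows[g])] = 1
    return MutationMatrix(genes, samples, values)


class TestGroupByGenes:
    def test_single_gene_counts(self):
        m = _matrix({"A": {0, 1, 2}}, 10)
        clin = _clinical([10.0] * 10, [1] * 10)
        groups = group_by_genes(m, {"A"}, clin)
        assert (groups["group"] == "mutated").sum() == 3
        assert (groups["group"] == "non_mutated").sum() == 7

    def test_gene_set_union(self):
        m = _matrix({"A": {0, 1, 2}, "B": {3, 4, 5, 6}}, 12)
        clin = _clinical([10.0] * 12, [1] * 12)
        groups = group_by_genes(m, {"A", "B"}, clin)
        assert (groups["group"] == "mutated").sum() == 7

    def test_union_at_least_single_gene(self):
        rng = np.random.default_rng(2)
        m = _matrix(
            {g: set(rng.choice(50, size=8, replace=False)) for g in "ABC"}, 50
        )
        clin = _clinical([10.0] * 50, [1] * 50)
        n_union = (group_by_genes(m, set("ABC"), clin)["group"] == "mutated").sum()
        for g in "ABC":
            n_single = (group_by_genes(m, {g}, clin)["group"] == "mutated").sum()
            assert n_union >= n_single

    def test_unknown_samples_dropped_with_warning(self, caplog):
        m = _matrix({"A": {0}}, 3)
        clin = _clinical([5.0, 5.0], [1, 1], samples=["S0", "NOPE"])
        groups = group_by_genes(m, {"A"}, clin)
        assert groups["sample"].tolist() == ["S0"]
        assert any("dropped" in r.message for r in caplog.records)

    def test_disjoint_samples_error(self):
        m = _matrix({"A": {0}}, 2)
        clin = _clinical([5.0], [1], samples=["ZZZ"])
        with pytest.raises(ValueError):
            group_by_genes(m, {"A"}, clin)


class TestLogrank:
    def test_identical_groups_chisq_zero(self):
        m = _matrix({"A": {0, 1, 2}}, 6)
        clin = _clinical([3.0, 5.0, 8.0, 3.0, 5.0, 8.0], [1, 1, 0, 1, 1, 0])
        chisq, p = logrank_test(group_by_genes(m, {"A"}, clin), clin)
        assert chisq == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_textbook_toy_matches_hand_computation(self):
        # mutated: times 1,2,3; non-mutated: 4,5,6; all events.
        # O-E over the 6 event times: E_mut = 3/6+2/5+1/4 = 1.15,
        # V = 0.25+0.24+0.1875 = 0.6775, chisq = (3-1.15)^2/0.6775
        m = _matrix({"A": {0, 1, 2}}, 6)
        clin = _clinical([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], [1] * 6)
        chisq, p = logrank_test(group_by_genes(m, {"A"}, clin), clin)
        expected = (3 - 1.15) ** 2 / 0.6775
        assert chisq == pytest.approx(expected, rel=1e-9)
        from scipy.stats import chi2

        assert p == pytest.approx(chi2.sf(expected, 1), rel=1e-9)

    def test_group_swap_symmetry(self):
        m = _matrix({"A": {0, 1, 2}}, 8)
        m_inv = _matrix({"A": {3, 4, 5, 6, 7}}, 8)
        clin = _clinical([1, 2, 3, 4, 5, 6, 7, 8.0], [1, 1, 0, 1, 0, 1, 1, 1])
        c1, p1 = logrank_test(group_by_genes(m, {"A"}, clin), clin)
        c2, p2 = logrank_test(group_by_genes(m_inv, {"A"}, clin), clin)
        assert c1 == pytest.approx(c2, rel=1e-12)
        assert p1 == pytest.approx(p2, rel=1e-12)


class TestCoxph:
    def test_planted_hazard_ratio_recovered(self):
        rng = np.random.default_rng(2)
        n = 500
        mutated = rng.random(n) < 0.4
        rate = 0.002 * np.where(mutated, 2.0, 1.0)
        t_event = rng.exponential(1.0 / rate)
        t_cens = rng.exponential(1500.0, size=n)
        m = _matrix({"A": set(np.nonzero(mutated)[0])}, n)
        clin = _clinical(
            np.minimum(t_event, t_cens).tolist(),
            (t_event <= t_cens).astype(int).tolist(),
            ages=rng.normal(60, 10, n).tolist(),
            sexes=list(rng.choice(["male", "female"], size=n)),
        )
        hr, p = coxph_adjusted(group_by_genes(m, {"A"}, clin), clin)
        assert 1.6 <= hr <= 2.5
        assert p < 0.01

    def test_no_covariate_variation_reduces_to_unadjusted(self):
        rng = np.random.default_rng(6)
        n = 120
        mutated = rng.random(n) < 0.5
        rate = 0.01 * np.where(mutated, 2.5, 1.0)
        t = rng.exponential(1.0 / rate)
        m = _matrix({"A": set(np.nonzero(mutated)[0])}, n)
        clin = _clinical(t.tolist(), [1] * n)  # constant age and sex
        groups = group_by_genes(m, {"A"}, clin)
        hr_adj, _ = coxph_adjusted(groups, clin)

        from lifelines import CoxPHFitter

        df = pd.DataFrame({"time": t, "event": 1, "mutated": mutated.astype(int)})
        cph = CoxPHFitter().fit(df, "time", "event")
        assert hr_adj == pytest.approx(math.exp(cph.params_["mutated"]), rel=1e-6)


class TestBhFdr:
    def test_hand_step_up(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])

    def test_all_equal_unchanged(self):
        assert bh_fdr([0.03, 0.03, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_output_dominates_input_and_order_preserved(self):
        rng = np.random.default_rng(9)
        p = rng.random(25)
        adj = np.array(bh_fdr(list(p)))
        assert (adj >= p - 1e-15).all()
        # monotone when inputs sorted ascending
        p_sorted = np.sort(p)
        adj_sorted = np.array(bh_fdr(list(p_sorted)))
        assert (np.diff(adj_sorted) >= -1e-15).all()

    def test_empty(self):
        assert bh_fdr([]) == []


class TestAnalyzeBases:
    def test_batch_fdr_and_group_sizes(self):
        rng = np.random.default_rng(4)
        n = 80
        rows = {g: set(rng.choice(n, size=10, replace=False)) for g in "ABC"}
        m = _matrix(rows, n)
        clin = _clinical(
            rng.exponential(100, n).tolist(),
            (rng.random(n) < 0.7).astype(int).tolist(),
            ages=rng.normal(60, 8, n).tolist(),
            sexes=list(rng.choice(["male", "female"], size=n)),
        )
        bases = {"A": {"A"}, "B": {"B"}, "SUB": set("ABC")}
        results = analyze_bases(m, clin, bases)
        assert [r.basis for r in results] == ["A", "B", "SUB"]
        sub = results[-1]
        assert sub.n_mutated >= max(results[0].n_mutated, results[1].n_mutated)
        for r in results:
            assert r.fdr >= r.coxph_p - 1e-15


class TestLifeTable:
    def test_counts_match_brute_force(self):
        m = _matrix({"A": {0, 1, 2, 3}}, 10)
        clin = _clinical(
            [2, 4, 4, 9, 1, 3, 5, 5, 7, 11.0],
            [1, 1, 0, 1, 1, 1, 0, 1, 1, 0],
        )
        lt = life_table(group_by_genes(m, {"A"}, clin), clin)
        assert lt["time"].is_monotonic_increasing
        first = lt.iloc[0]  # earliest event time t=1, non-mutated sample S4
        assert first["time"] == 1
        assert first["at_risk_mutated"] == 4
        assert first["at_risk_non"] == 6
        assert first["events_non"] == 1
        assert (lt["events_mutated"] + lt["events_non"] >= 1).all()
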