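"""Hub ranking, survival evaluation, chi-squared comparison, DEG proximity."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bilayernet.datatypes import BetaMatrix, ClinicalTable, SiteGeneMap
from bilayernet.hubs import (
    chi_squared_2x2,
    compare_networks,
    deg_two_step_reachability,
    hub_correlation_matrix,
    km_logrank,
    top_k,
)


class TestTopK:
    def test_star_center_by_degree(self):
        from bilayernet.metrics import degree_centrality

        dc = degree_centrality(nx.star_graph(3))
        assert top_k(dc, 1) == [0]

    def test_ties_broken_by_ascending_id(self):
        assert top_k({"cgB": 1.0, "cgA": 1.0, "cgC": 0.5}, 2) == ["cgA", "cgB"]

    def test_oversized_k_truncates(self):
        assert top_k({"a": 1.0}, 5) == ["a"]


def _clinical(times, events, ids=None):
    ids = ids or [f"p{i}" for i in range(len(times))]
    return ClinicalTable(rows=pd.DataFrame(
        {"sample_id": ids, "time": list(map(float, times)), "event": list(events)}
    ))


class TestKmLogrank:
    def test_identical_groups_give_null_statistic(self):
        # 3 high + 3 low patients with identical time/event patterns
        ids = [f"p{i}" for i in range(6)]
        beta_row = pd.Series([0.9, 0.9, 0.9, 0.1, 0.1, 0.1], index=ids)
        clin = _clinical([5, 8, 10, 5, 8, 10], [1, 0, 1, 1, 0, 1], ids)
        fit = km_logrank(beta_row, clin)
        assert fit.statistic == pytest.approx(0.0, abs=1e-12)
        assert fit.p_value == pytest.approx(1.0)

    def test_hand_computed_mantel_cox_table(self):
        # high group: times (2 censored, 4, 6); low group: (1, 3, 5 censored)
        # Mantel-Cox by hand: O-E = -2/3, V = 13/18, chi2 = 8/13
        ids = [f"p{i}" for i in range(6)]
        beta_row = pd.Series([0.9, 0.9, 0.9, 0.1, 0.1, 0.1], index=ids)
        clin = _clinical([2, 4, 6, 1, 3, 5], [0, 1, 1, 1, 1, 0], ids)
        fit = km_logrank(beta_row, clin)
        assert fit.statistic == pytest.approx(8 / 13, rel=1e-9)
        assert fit.p_value == pytest.approx(stats.chi2.sf(8 / 13, 1), rel=1e-9)

    def test_km_curves_are_nonincreasing_probabilities(self):
        rng = np.random.default_rng(0)
        ids = [f"p{i}" for i in range(40)]
        beta_row = pd.Series(rng.uniform(size=40), index=ids)
        clin = _clinical(rng.exponential(10, size=40),
                         rng.integers(0, 2, size=40), ids)
        fit = km_logrank(beta_row, clin)
        for curve in (fit.high_curve, fit.low_curve):
            s = curve["survival"].to_numpy()
            assert ((s >= 0) & (s <= 1)).all()
            assert (np.diff(s) <= 1e-12).all()

    def test_eventless_data_gives_p_one(self):
        ids = [f"p{i}" for i in range(6)]
        beta_row = pd.Series([0.9, 0.8, 0.7, 0.3, 0.2, 0.1], index=ids)
        clin = _clinical([2, 4, 6, 1, 3, 5], [0, 0, 0, 0, 0, 0], ids)
        fit = km_logrank(beta_row, clin)
        assert fit.p_value == 1.0

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(4)
        ids = [f"p{i}" for i in range(30)]
        b = pd.Series(rng.uniform(size=30), index=ids)
        clin = _clinical(rng.exponential(10, size=30), rng.integers(0, 2, 30), ids)
        fit = km_logrank(b, clin)
        flipped = km_logrank(1 - b, clin)  # mirrors the split
        assert fit.statistic == pytest.approx(flipped.statistic, rel=1e-9)


class TestChiSquared:
    def test_known_table(self):
        statistic, p = chi_squared_2x2([[10, 20], [20, 10]])
        assert statistic == pytest.approx(20 / 3, rel=1e-9)
        assert p == pytest.approx(stats.chi2.sf(20 / 3, 1), rel=1e-9)

    def test_identical_rows_give_zero(self):
        statistic, p = chi_squared_2x2([[15, 5], [15, 5]])
        assert statistic == 0.0
        assert p == pytest.approx(1.0)

    def test_zero_margin_is_an_error(self):
        with pytest.raises(ValueError, match="margin"):
            chi_squared_2x2([[0, 0], [5, 5]])

    def test_matches_closed_form_and_termwise_sum(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            a, b, c, d = rng.integers(1, 100, size=4)
            statistic, _ = chi_squared_2x2([[a, b], [c, d]])
            n = a + b + c + d
            closed = (a * d - b * c) ** 2 * n / ((a + b) * (c + d) * (a + c) * (b + d))
            assert statistic == pytest.approx(closed, rel=1e-10)
            # literal observed-vs-expected summation
            obs = np.array([[a, b], [c, d]], dtype=float)
            exp = np.outer(obs.sum(1), obs.sum(0)) / n
            assert statistic == pytest.approx(((obs - exp) ** 2 / exp).sum(), rel=1e-12)


class TestCompareNetworks:
    def test_identical_hub_lists_give_zero(self, dataset):
        hubs = dataset.manifest["hub_sites"][:20]
        _, statistic, p = compare_networks(hubs, hubs, dataset.beta, dataset.clinical)
        assert statistic == 0.0

    def test_unequal_k_is_an_error(self, dataset):
        with pytest.raises(ValueError, match="equal k"):
            compare_networks(["cg00000000"], ["cg00000000", "cg00000001"],
                             dataset.beta, dataset.clinical)

    def test_counts_90_vs_60_closed_form(self):
        statistic, _ = chi_squared_2x2([[90, 10], [60, 40]])
        n = 200
        closed = (90 * 40 - 10 * 60) ** 2 * n / (100 * 100 * 150 * 50)
        assert statistic == pytest.approx(closed, rel=1e-10)


class TestHubCorrelation:
    def test_perfectly_correlated_module(self):
        base = np.linspace(0.2, 0.8, 20)
        values = pd.DataFrame(
            np.vstack([base, base, base]),
            index=["cg01", "cg02", "cg03"],
            columns=[f"s{i}" for i in range(20)],
        )
        beta = BetaMatrix(values=values, group_labels=pd.Series(
            ["tumor"] * 20, index=values.columns))
        corr, summary = hub_correlation_matrix(["cg01", "cg02", "cg03"], beta)
        assert summary["mean_abs_r"] == pytest.approx(1.0)

    def test_single_hub_summary_is_missing(self, dataset):
        _, summary = hub_correlation_matrix([dataset.beta.site_ids[0]], dataset.beta)
        assert summary["mean_abs_r"] is None

    def test_absent_hub_is_an_error(self, dataset):
        with pytest.raises(ValueError, match="absent"):
            hub_correlation_matrix(["cgnotasite"], dataset.beta)

    def test_same_gene_groups_correlate_more(self, dataset):
        truth = dataset.manifest
        hubs = truth["hub_sites"][:50] + truth["diff_sites"][-50:]
        _, summary = hub_correlation_matrix(hubs, dataset.beta, dataset.site_gene_map)
        assert summary["same_gene_mean_abs_r"] > summary["mean_abs_r"]


class TestDegReachability:
    def _setup(self):
        sgmap = SiteGeneMap(pairs={
            ("cg01", "DEG1"), ("cg02", "A"), ("cg03", "A2"), ("cg04", "X")
        })
        rna = nx.Graph([("A", "B"), ("B", "DEG1"),
                        ("A2", "B2"), ("B2", "C2"), ("C2", "DEG1"),
                        ("X", "Y")])
        return sgmap, rna

    def test_hub_gene_itself_deg(self):
        sgmap, rna = self._setup()
        flags, count = deg_two_step_reachability(["cg01"], sgmap, rna, ["DEG1"])
        assert flags["cg01"] and count == 1

    def test_two_step_bridge(self):
        sgmap, rna = self._setup()
        flags, _ = deg_two_step_reachability(["cg02"], sgmap, rna, ["DEG1"])
        assert flags["cg02"]

    def test_distance_three_not_reachable(self):
        sgmap, rna = self._setup()
        flags, _ = deg_two_step_reachability(["cg03"], sgmap, rna, ["DEG1"])
        assert not flags["cg03"]

    def test_unmapped_hub_flagged_false(self):
        sgmap, rna = self._setup()
        flags, _ = deg_two_step_reachability(["cg99"], sgmap, rna, ["DEG1"])
        assert not flags["cg99"]

    def test_matches_breadth_limited_search_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            genes = [f"G{i}" for i in range(30)]
            rna = nx.gnp_random_graph(30, 0.08, seed=int(rng.integers(2**31)))
            rna = nx.relabel_nodes(rna, dict(enumerate(genes)))
            sites = [f"cg{i:02d}" for i in range(20)]
            pairs = {(s, str(rng.choice(genes))) for s in sites}
            sgmap = SiteGeneMap(pairs=pairs)
            degs = [str(g) for g in rng.choice(genes, size=3, replace=False)]
            flags, _ = deg_two_step_reachability(sites, sgmap, rna, degs)
            for s in sites:
                expected = False
                for g in sgmap.genes_of(s):
                    if g in degs:
                        expected = True
                    elif g in rna:
                        lengths = nx.single_source_shortest_path_length(rna, g, cutoff=2)
                        if any(d in lengths for d in degs):
                            expected = True
                assert flags[s] == expected, s
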