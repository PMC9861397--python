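"""Correlation layer, RNA layer and the three-condition edge filter."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from bilayernet.datatypes import BetaMatrix, RnaInteractionTable, SiteGeneMap
from bilayernet.network import (
    admissible,
    build_methylation_layer,
    build_rna_layer,
    filter_methylation_edges,
    pearson_r,
)


def _beta(values, n_tumor=None):
    values = np.asarray(values, dtype=float)
    n_samples = values.shape[1]
    n_tumor = n_samples if n_tumor is None else n_tumor
    cols = [f"s{i}" for i in range(n_samples)]
    labels = pd.Series(
        ["tumor"] * n_tumor + ["normal"] * (n_samples - n_tumor), index=cols
    )
    index = [f"cg{i:02d}" for i in range(values.shape[0])]
    return BetaMatrix(values=pd.DataFrame(values, index=index, columns=cols),
                      group_labels=labels)


def _rna_graph(edges):
    table = RnaInteractionTable(rows=pd.DataFrame(
        [{"rna_a": a, "rna_b": b, "type_a": "mRNA", "type_b": "mRNA",
          "confidence": 0.9} for a, b in edges],
        columns=["rna_a", "rna_b", "type_a", "type_b", "confidence"],
    ))
    return build_rna_layer(table)


class TestPearson:
    def test_self_correlation_is_one(self):
        assert pearson_r([0.1, 0.5, 0.9], [0.1, 0.5, 0.9]) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        assert pearson_r([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        assert pearson_r([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_length_mismatch_is_an_error(self):
        with pytest.raises(ValueError, match="mismatch"):
            pearson_r([1, 2, 3], [1, 2])

    def test_constant_vector_gives_nan(self):
        assert np.isnan(pearson_r([1, 1, 1], [1, 2, 3]))


class TestMethylationLayer:
    def test_copied_sites_link_and_noise_does_not(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0.2, 0.8, 30)
        layer = build_methylation_layer(_beta(np.vstack([a, a, rng.uniform(0.2, 0.8, 30)])))
        assert set(layer.edges) == {("cg00", "cg01")}
        assert layer.number_of_nodes() == 3

    def test_cutoff_one_gives_no_edges(self):
        rng = np.random.default_rng(1)
        layer = build_methylation_layer(_beta(rng.uniform(size=(5, 20))), cutoff=1.0)
        assert layer.number_of_edges() == 0

    def test_correlation_uses_tumor_samples_only(self):
        # identical over tumor samples, divergent over normals: edge must exist
        tumor_part = np.tile(np.linspace(0.2, 0.8, 10), (2, 1))
        normal_part = np.array([[0.1] * 10, [0.9] * 10])
        beta = _beta(np.hstack([tumor_part, normal_part]), n_tumor=10)
        layer = build_methylation_layer(beta)
        assert layer.has_edge("cg00", "cg01")

    def test_too_few_tumor_samples_is_an_error(self):
        with pytest.raises(ValueError, match="3 tumor"):
            build_methylation_layer(_beta(np.random.default_rng(0).uniform(size=(3, 4)),
                                          n_tumor=2))

    def test_dense_module_density_exceeds_cutoff_rate(self, dataset):
        mod = next(m for m in dataset.manifest["modules"] if m["rho"] >= 0.95)
        layer = build_methylation_layer(dataset.beta, mod["sites"])
        n = len(mod["sites"])
        density = layer.number_of_edges() / (n * (n - 1) / 2)
        assert density > 0.8

    def test_blockwise_equals_direct(self, dataset):
        sites = dataset.manifest["modules"][0]["sites"] + dataset.manifest["modules"][1]["sites"]
        direct = build_methylation_layer(dataset.beta, sites, block_size=10_000)
        blocked = build_methylation_layer(dataset.beta, sites, block_size=3)
        assert set(direct.edges) == set(blocked.edges)


class TestRnaLayer:
    def test_two_rows_give_path_graph(self):
        graph = _rna_graph([("A", "B"), ("B", "C")])
        assert sorted(graph.nodes) == ["A", "B", "C"]
        assert graph.number_of_edges() == 2

    def test_empty_table_gives_empty_graph(self):
        graph = build_rna_layer(RnaInteractionTable(rows=pd.DataFrame(
            columns=["rna_a", "rna_b", "type_a", "type_b", "confidence"])))
        assert graph.number_of_nodes() == 0

    def test_counts_match_generator_manifest(self, dataset):
        graph = build_rna_layer(dataset.interactions)
        assert graph.number_of_edges() == len(dataset.interactions)


class TestAdmissibility:
    sgmap = SiteGeneMap(pairs={
        ("cg01", "G1"), ("cg02", "G1"),     # same gene
        ("cg03", "A"), ("cg04", "C"),       # via shared neighbor B
        ("cg05", "A"), ("cg06", "D"),       # distance 3 in A-B-C-D
        ("cg07", "B"),
    })
    rna = None

    def setup_method(self):
        self.rna = _rna_graph([("A", "B"), ("B", "C"), ("C", "D")])

    def test_same_gene(self):
        assert admissible("cg01", "cg02", self.sgmap, self.rna) == (True, "same_gene")

    def test_direct_edge(self):
        assert admissible("cg05", "cg07", self.sgmap, self.rna) == (True, "direct_edge")

    def test_shared_neighbor(self):
        assert admissible("cg03", "cg04", self.sgmap, self.rna) == (True, "shared_neighbor")

    def test_distance_three_is_inadmissible(self):
        assert admissible("cg05", "cg06", self.sgmap, self.rna) == (False, "none")

    def test_unmapped_site_is_inadmissible(self):
        assert admissible("cg99", "cg01", self.sgmap, self.rna) == (False, "none")

    def test_symmetry(self):
        sites = ["cg01", "cg02", "cg03", "cg04", "cg05", "cg06", "cg07"]
        for a in sites:
            for b in sites:
                if a < b:
                    assert (admissible(a, b, self.sgmap, self.rna)
                            == admissible(b, a, self.sgmap, self.rna))


def brute_force_admissible(a, b, sgmap, rna):
    """Independent check: same gene, or some gene pair at distance <= 2."""
    ga, gb = sgmap.genes_of(a), sgmap.genes_of(b)
    if not ga or not gb:
        return False
    if ga & gb:
        return True
    for x in ga:
        for y in gb:
            if x in rna and y in rna:
                try:
                    if nx.shortest_path_length(rna, x, y) <= 2:
                        return True
                except nx.NetworkXNoPath:
                    continue
    return False


def random_instance(rng, n_sites=24, n_genes=10):
    sites = [f"cg{i:02d}" for i in range(n_sites)]
    genes = [f"G{i}" for i in range(n_genes)]
    pairs = set()
    for s in sites:
        for g in rng.choice(genes, size=rng.integers(1, 3), replace=False):
            pairs.add((s, str(g)))
    sgmap = SiteGeneMap(pairs=pairs)
    rna_edges = []
    for i in range(n_genes):
        for j in range(i + 1, n_genes):
            if rng.uniform() < 0.15:
                rna_edges.append((genes[i], genes[j]))
    rna = _rna_graph(rna_edges) if rna_edges else _rna_graph([])
    layer = nx.Graph()
    layer.add_nodes_from(sites)
    for i in range(n_sites):
        for j in range(i + 1, n_sites):
            if rng.uniform() < 0.3:
                layer.add_edge(sites[i], sites[j], r=float(rng.uniform(0.8, 1.0)))
    return layer, sgmap, rna


class TestFilter:
    def test_same_gene_layer_is_unchanged(self):
        sgmap = SiteGeneMap(pairs={("cg01", "G"), ("cg02", "G"), ("cg03", "G")})
        layer = nx.Graph([("cg01", "cg02"), ("cg02", "cg03")])
        out = filter_methylation_edges(layer, sgmap, _rna_graph([]))
        assert set(out.methylation.edges) == set(layer.edges)
        assert all(c == "same_gene" for c in out.provenance.values())

    def test_empty_rna_layer_removes_inter_gene_edges(self):
        sgmap = SiteGeneMap(pairs={("cg01", "G1"), ("cg02", "G2")})
        layer = nx.Graph([("cg01", "cg02")])
        out = filter_methylation_edges(layer, sgmap, _rna_graph([]))
        assert out.methylation.number_of_edges() == 0
        assert out.removed_edges == 1
        assert out.methylation.number_of_nodes() == 2  # nodes stay in place

    def test_idempotent_and_subset(self):
        rng = np.random.default_rng(7)
        layer, sgmap, rna = random_instance(rng)
        once = filter_methylation_edges(layer, sgmap, rna)
        twice = filter_methylation_edges(once.methylation, sgmap, rna)
        assert set(once.methylation.edges) == set(twice.methylation.edges)
        assert set(once.methylation.edges) <= set(layer.edges)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            layer, sgmap, rna = random_instance(rng)
            out = filter_methylation_edges(layer, sgmap, rna)
            for a, b in layer.edges:
                expected = brute_force_admissible(a, b, sgmap, rna)
                assert out.methylation.has_edge(a, b) == expected

    def test_planted_inadmissible_modules_are_fully_filtered(self, pipeline_results):
        bilayer = pipeline_results["bilayer"].methylation
        bad = set(pipeline_results["truth"]["inadmissible_sites"])
        assert all(bilayer.degree(s) == 0 for s in bad if s in bilayer)
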