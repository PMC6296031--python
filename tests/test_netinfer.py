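"""Ensemble inference: base methods, rank aggregation, BIC selection,
consensus modules and marker annotation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata
from sklearn.metrics import adjusted_rand_score

from gliaseq import netinfer, simulate
from gliaseq.netinfer import GeneNetwork


def noise_data(n_genes, n_samples, seed):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.standard_normal((n_genes, n_samples)), index=[f"g{i:03d}" for i in range(n_genes)]
    )


class TestBaseMethods:
    def test_corr_adjacency_beta_one_on_rank_one_pair(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(100)
        data = pd.DataFrame([x, 2 * x + 1], index=["a", "b"])
        w = netinfer.infer_base("corr_adjacency", data, beta=1.0)
        assert w.loc["a", "b"] == pytest.approx(1.0)

    def test_weights_symmetric_nonnegative_zero_diagonal(self):
        data = noise_data(12, 80, 1)
        for method in netinfer.BASE_METHODS:
            w = netinfer.infer_base(method, data)
            assert np.allclose(w.values, w.values.T)
            assert (w.values >= 0).all()
            assert np.allclose(np.diag(w.values), 0.0)

    def test_unknown_method_raises(self):
        with pytest.raises(ValueError, match="unknown method"):
            netinfer.infer_base("wgcna_deluxe", noise_data(5, 30, 0))

    def test_dpi_removes_indirect_edge_of_markov_chain(self):
        removed = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal(300)
            y = x + 0.5 * rng.standard_normal(300)
            z = y + 0.5 * rng.standard_normal(300)
            w = netinfer.infer_base("mi_aracne", pd.DataFrame([x, y, z], index=["X", "Y", "Z"]))
            removed += (
                w.loc["X", "Z"] == 0 and w.loc["X", "Y"] > 0 and w.loc["Y", "Z"] > 0
            )
        assert removed > 10

    def test_null_correlation_weights_are_small(self):
        data = noise_data(50, 500, 2)
        w = netinfer.infer_base("corr_adjacency", data, beta=1.0)
        iu = np.triu_indices(50, k=1)
        assert np.quantile(w.values[iu], 0.95) < 0.15

    def test_c3net_keeps_only_row_maxima(self):
        data = noise_data(8, 100, 3)
        w = netinfer.infer_base("c3net_like", data).values
        mi = netinfer.mutual_information_matrix(data.values)
        for i in range(8):
            for j in range(8):
                if w[i, j] > 0:
                    assert mi[i, j] in (mi[i].max(), mi[j].max())


class TestAggregateRanks:
    def test_identical_orderings_are_preserved(self):
        data = noise_data(8, 60, 4)
        w = netinfer.infer_base("corr_adjacency", data, beta=1.0)
        agg = netinfer.aggregate_ranks({"m1": w, "m2": w.copy()})
        iu = np.triu_indices(8, k=1)
        expected = rankdata(-w.values[iu], method="average")
        assert np.allclose(agg["mean_rank"].values, np.sort(expected))

    def test_reversed_orderings_tie_at_midpoint(self):
        genes = ["a", "b", "c", "d"]
        rng = np.random.default_rng(5)
        vals = rng.uniform(0.1, 1.0, (4, 4))
        w1 = pd.DataFrame((vals + vals.T) / 2, index=genes, columns=genes)
        np.fill_diagonal(w1.values, 0)
        w2 = pd.DataFrame(w1.values.max() + w1.values.min() - w1.values, index=genes, columns=genes)
        np.fill_diagonal(w2.values, 0)
        agg = netinfer.aggregate_ranks({"m1": w1, "m2": w2})
        n_edges = 6
        assert np.allclose(agg["mean_rank"].values, (n_edges + 1) / 2)

    def test_matches_brute_force_and_method_order_invariance(self):
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(10)]
        tables = {}
        for name in ("alpha", "beta", "gamma"):
            v = rng.uniform(size=(10, 10))
            v = (v + v.T) / 2
            np.fill_diagonal(v, 0)
            tables[name] = pd.DataFrame(v, index=genes, columns=genes)
        agg = netinfer.aggregate_ranks(tables)
        reversed_order = dict(reversed(list(tables.items())))
        agg_rev = netinfer.aggregate_ranks(reversed_order)
        pd.testing.assert_frame_equal(agg, agg_rev)

        iu = np.triu_indices(10, k=1)
        brute = np.zeros(len(iu[0]))
        for t in tables.values():
            brute += rankdata(-t.values[iu], method="average")
        brute /= len(tables)
        lookup = dict(zip(zip(np.array(genes)[iu[0]], np.array(genes)[iu[1]]), brute))
        for pair, row in agg.iterrows():
            assert row["mean_rank"] == pytest.approx(lookup[pair])

    def test_mismatched_universe_raises(self):
        a = noise_data(5, 50, 0)
        b = noise_data(6, 50, 0)
        wa = netinfer.infer_base("corr_adjacency", a)
        wb = netinfer.infer_base("corr_adjacency", b)
        with pytest.raises(ValueError, match="universe"):
            netinfer.aggregate_ranks({"a": wa, "b": wb})


class TestSelectEdgesBIC:
    def test_pure_noise_mean_degree_below_one(self):
        sizes = []
        for seed in range(20):
            data = noise_data(50, 200, 100 + seed)
            tables = {
                m: netinfer.infer_base(m, data)
                for m in ("corr_adjacency", "ridge_neighborhood")
            }
            ranks = netinfer.aggregate_ranks(tables)
            net = netinfer.select_edges_bic(ranks, data, max_neighbors=10)
            sizes.append(net.neighborhood_sizes.mean())
        assert np.mean(sizes) <= 1.0

    def test_planted_module_is_selected_with_few_cross_edges(self):
        spec = simulate.DesignSpec(n_genes=30, seed=7)
        truth = simulate.make_planted_truth(spec, n_modules=3, genes_per_module=10, seed=7)
        data = simulate.generate_coexpression_samples(250, truth, noise_sd=0.5, seed=7)
        tables = {
            m: netinfer.infer_base(m, data) for m in ("corr_adjacency", "lasso_neighborhood")
        }
        net = netinfer.select_edges_bic(netinfer.aggregate_ranks(tables), data, max_neighbors=8)
        modules = truth.module_assignment
        cross = sum(modules[a] != modules[b] for a, b in zip(net.edges["gene_a"], net.edges["gene_b"]))
        assert cross / len(net.edges) < 0.05
        within_neighbors = {g: 0 for g in data.index}
        for a, b in zip(net.edges["gene_a"], net.edges["gene_b"]):
            if modules[a] == modules[b]:
                within_neighbors[a] += 1
                within_neighbors[b] += 1
        assert all(v >= 1 for v in within_neighbors.values())

    def test_worsening_candidate_is_not_selected(self):
        rng = np.random.default_rng(8)
        data = pd.DataFrame(rng.standard_normal((2, 100)), index=["a", "b"])
        tables = {
            "m1": netinfer.infer_base("corr_adjacency", data),
            "m2": netinfer.infer_base("ridge_neighborhood", data),
        }
        net = netinfer.select_edges_bic(netinfer.aggregate_ranks(tables), data, max_neighbors=1)
        assert len(net.edges) == 0
        assert (net.degree == 0).all()

    def test_selection_is_deterministic_and_degrees_conserve(self):
        spec = simulate.DesignSpec(n_genes=20, seed=9)
        truth = simulate.make_planted_truth(spec, n_modules=2, genes_per_module=10, seed=9)
        data = simulate.generate_coexpression_samples(150, truth, noise_sd=0.7, seed=9)
        tables = {m: netinfer.infer_base(m, data) for m in ("corr_adjacency", "mrnet_like")}
        ranks = netinfer.aggregate_ranks(tables)
        net1 = netinfer.select_edges_bic(ranks, data, max_neighbors=6)
        net2 = netinfer.select_edges_bic(ranks, data, max_neighbors=6)
        pd.testing.assert_frame_equal(net1.edges, net2.edges)
        assert net1.degree.sum() == 2 * len(net1.edges)

    def test_too_few_samples_raises(self):
        data = noise_data(5, 8, 0)
        tables = {m: netinfer.infer_base(m, data) for m in ("corr_adjacency", "mrnet_like")}
        with pytest.raises(ValueError):
            netinfer.select_edges_bic(netinfer.aggregate_ranks(tables), data, max_neighbors=10)


class TestConsensusModules:
    def _clique_network(self, sizes):
        genes, edges = [], []
        start = 0
        for block, size in enumerate(sizes):
            members = [f"b{block}_{i}" for i in range(size)]
            genes.extend(members)
            for i in range(size):
                for j in range(i + 1, size):
                    edges.append((members[i], members[j]))
            start += size
        table = pd.DataFrame(edges, columns=["gene_a", "gene_b"])
        table["mean_rank"] = np.arange(len(table), dtype=float)
        return GeneNetwork(genes, table)

    def test_two_disjoint_cliques_are_two_modules(self):
        net = self._clique_network([15, 15])
        modules, consensus = netinfer.consensus_modules(net, seed=0)
        truth = [g.split("_")[0] for g in modules.index]
        assert adjusted_rand_score(truth, modules.values) == 1.0
        assert modules.nunique() == 2

    def test_consensus_matrix_symmetric_with_unit_diagonal(self):
        net = self._clique_network([10, 8])
        _, consensus = netinfer.consensus_modules(net, seed=1)
        assert np.allclose(consensus, consensus.T)
        assert np.allclose(np.diag(consensus), 1.0)

    def test_planted_stochastic_block_model_recovered(self):
        hits = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n_per, k = 40, 4
            genes = [f"g{i:03d}" for i in range(n_per * k)]
            labels = np.repeat(np.arange(k), n_per)
            edges = []
            for i in range(len(genes)):
                for j in range(i + 1, len(genes)):
                    p = 0.3 if labels[i] == labels[j] else 0.02
                    if rng.random() < p:
                        edges.append((genes[i], genes[j]))
            table = pd.DataFrame(edges, columns=["gene_a", "gene_b"])
            table["mean_rank"] = np.arange(len(table), dtype=float)
            net = GeneNetwork(genes, table)
            modules, _ = netinfer.consensus_modules(net, seed=seed)
            hits.append(adjusted_rand_score(labels, modules.reindex(genes).values))
        assert np.mean(hits) >= 0.8

    def test_empty_graph_gives_singleton_modules(self):
        net = GeneNetwork(["a", "b", "c"], pd.DataFrame(columns=["gene_a", "gene_b", "mean_rank"]))
        modules, _ = netinfer.consensus_modules(net, seed=0)
        assert modules.nunique() == 3

    def test_modules_numbered_by_decreasing_size(self):
        net = self._clique_network([12, 5, 8])
        modules, _ = netinfer.consensus_modules(net, seed=2)
        sizes = modules.value_counts().sort_index()
        assert list(sizes.values) == sorted(sizes.values, reverse=True)


class TestAnnotateCelltypes:
    def test_pure_module_gets_its_marker_label(self):
        modules = pd.Series(
            [1] * 20 + [2] * 20, index=[f"g{i}" for i in range(40)], dtype=int
        )
        markers = {
            "microglia": {f"g{i}" for i in range(20)},
            "neuron": {f"g{i}" for i in range(20, 40)},
        }
        labels = netinfer.annotate_celltypes(modules, markers)
        assert labels == {1: "microglia", 2: "neuron"}

    def test_module_without_markers_is_unassigned(self):
        modules = pd.Series([1] * 10 + [2] * 10, index=[f"g{i}" for i in range(20)])
        markers = {"microglia": {f"g{i}" for i in range(10)}}
        labels = netinfer.annotate_celltypes(modules, markers)
        assert labels[2] == "unassigned"

    def test_shared_marker_genes_are_dropped_before_testing(self):
        modules = pd.Series([1] * 10, index=[f"g{i}" for i in range(10)])
        markers = {"a": {"g0", "g1", "g2"}, "b": {"g0", "g1", "g2"}}
        labels = netinfer.annotate_celltypes(modules, markers)
        assert labels[1] == "unassigned"

    def test_planted_seventy_percent_purity_recovered(self):
        correct = total = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            celltypes = ["microglia", "endothelial", "astrocyte"]
            genes = [f"g{i:03d}" for i in range(240)]
            markers = {
                ct: set(genes[i * 80 : (i + 1) * 80]) for i, ct in enumerate(celltypes)
            }
            assignment = {}
            for mod, ct in enumerate(celltypes, start=1):
                own = rng.choice(sorted(markers[ct]), 28, replace=False)
                others = sorted(set(genes) - markers[ct])
                noise = rng.choice(others, 12, replace=False)
                for g in list(own) + list(noise):
                    assignment[g] = mod
            modules = pd.Series(assignment)
            labels = netinfer.annotate_celltypes(modules, markers, universe=set(genes))
            for mod, ct in enumerate(celltypes, start=1):
                total += 1
                correct += labels[mod] == ct
        assert correct / total >= 0.9
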