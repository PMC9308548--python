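"""Ego-network scoring: weights, CLR, topology oracles, ranking."""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from _oracles import brute_force_topology

from methego import PipelineConfig
from methego.egonet import (
    EmptySubnetworkError,
    build_target_subnetwork,
    clr_adjacency,
    correlation_gate_threshold,
    gate_by_correlation,
    gene_level_signal,
    rank_ego_genes,
    run_egonet,
    topology_metrics,
    weight_edges,
)
from methego.io import BetaMatrix, ProbeAnnotation


def _edges(pairs, confidence=900):
    return pd.DataFrame([(a, b, confidence) for a, b in pairs],
                        columns=["gene_a", "gene_b", "confidence"])


def _annot_for(probe_gene: dict[str, str]) -> ProbeAnnotation:
    table = pd.DataFrame({
        "chrom": "1", "pos": 1, "snp_distance": 100, "maf": 0.3,
        "cross_hyb": 0, "design_type": "I",
        "gene": pd.Series(probe_gene),
    })
    table.index.name = "probe_id"
    return ProbeAnnotation(table)


class TestGeneLevelSignal:
    def test_mean_aggregation(self):
        beta = BetaMatrix(pd.DataFrame({"S1": [0.2, 0.4]}, index=["cg1", "cg2"]))
        annot = _annot_for({"cg1": "G1", "cg2": "G1"})
        calls = pd.DataFrame({"p_value": [0.5, 0.5]}, index=["cg1", "cg2"])
        gm, _ = gene_level_signal(beta, annot, calls)
        assert gm.loc["G1", "S1"] == pytest.approx(0.3)

    def test_min_p_rule_and_neglog10(self):
        beta = BetaMatrix(pd.DataFrame({"S1": [0.2, 0.4]}, index=["cg1", "cg2"]))
        annot = _annot_for({"cg1": "G1", "cg2": "G1"})
        calls = pd.DataFrame({"p_value": [0.01, 0.001]}, index=["cg1", "cg2"])
        _, sig = gene_level_signal(beta, annot, calls)
        assert sig.loc["G1", "gene_p"] == pytest.approx(0.001)
        assert sig.loc["G1", "p_i"] == pytest.approx(3.0)

    def test_score_floor_at_one(self):
        beta = BetaMatrix(pd.DataFrame({"S1": [0.2]}, index=["cg1"]))
        annot = _annot_for({"cg1": "G1"})
        calls = pd.DataFrame({"p_value": [0.5]}, index=["cg1"])
        _, sig = gene_level_signal(beta, annot, calls)
        assert sig.loc["G1", "p_i"] == 1.0


class TestBuildTargetSubnetwork:
    def test_both_endpoint_rule(self):
        subnet = build_target_subnetwork(_edges([("A", "B"), ("B", "C")]), {"A", "B"})
        assert len(subnet.edges) == 1
        assert subnet.nodes == ["A", "B"]

    def test_isolated_seed_absent(self):
        subnet = build_target_subnetwork(_edges([("A", "B")]), {"A", "B"},
                                         seed_genes={"Z"})
        assert "Z" not in subnet.nodes

    def test_empty_subnetwork_raises(self):
        with pytest.raises(EmptySubnetworkError):
            build_target_subnetwork(_edges([("A", "B")]), {"C", "D"})

    def test_module_edges_survive(self, small_dataset):
        _, _, edges, _, truth = small_dataset
        subnet = build_target_subnetwork(edges, truth.diff_genes, truth.seed_genes)
        module = set(truth.module_genes)
        internal = [(a, b) for a, b in
                    edges[["gene_a", "gene_b"]].itertuples(index=False)
                    if a in module and b in module]
        for a, b in internal:
            assert subnet.graph.has_edge(a, b)


class TestGateByCorrelation:
    def _subnet_with_matrix(self, rows: dict[str, list[float]]):
        genes = list(rows)
        pairs = list(itertools.combinations(genes, 2))
        subnet = build_target_subnetwork(_edges(pairs), set(genes))
        gm = pd.DataFrame(rows).T
        gm.columns = [f"S{i}" for i in range(gm.shape[1])]
        return subnet, gm

    def test_perfect_correlation_retained(self):
        subnet, gm = self._subnet_with_matrix({
            "A": [0.1, 0.2, 0.3, 0.4, 0.5],
            "B": [0.2, 0.4, 0.6, 0.8, 1.0],
        })
        gated = gate_by_correlation(subnet, gm)
        assert not gated.edges.iloc[0]["gated"]
        assert gated.edges.iloc[0]["r"] == pytest.approx(1.0)
        assert gated.edges.iloc[0]["p_r"] == 0.0

    def test_zero_correlation_gated(self):
        subnet, gm = self._subnet_with_matrix({
            "A": [0.1, 0.2, 0.1, 0.2, 0.1, 0.2],
            "B": [0.3, 0.3, 0.4, 0.4, 0.3, 0.3],
        })
        gated = gate_by_correlation(subnet, gm)
        row = gated.edges.iloc[0]
        assert abs(row["r"]) < gated.delta
        assert row["gated"]

    def test_zero_variance_gene_gated(self):
        subnet, gm = self._subnet_with_matrix({
            "A": [0.5, 0.5, 0.5, 0.5, 0.5],
            "B": [0.2, 0.4, 0.6, 0.8, 1.0],
        })
        gated = gate_by_correlation(subnet, gm)
        assert gated.edges.iloc[0]["gated"]
        assert np.isnan(gated.edges.iloc[0]["r"])

    def test_delta_matches_brute_force_inversion(self):
        # brute-force search over |r| for the value whose two-sided Pearson
        # p equals 0.05 at m = 38
        from scipy.stats import t as t_dist
        m = 38
        lo, hi = 0.0, 1.0 - 1e-12
        for _ in range(60):
            mid = (lo + hi) / 2
            t_mid = mid * math.sqrt((m - 2) / (1 - mid**2))
            p = 2 * t_dist.sf(t_mid, m - 2)
            if p > 0.05:
                lo = mid
            else:
                hi = mid
        expected = (lo + hi) / 2
        assert correlation_gate_threshold(m, 0.05) == pytest.approx(expected, abs=1e-6)


class TestWeightEdges:
    def _weighted(self, p_i: dict[str, float], pairs, gated=None):
        subnet = build_target_subnetwork(_edges(pairs), set(p_i))
        edges = subnet.edges.assign(
            r=1.0, p_r=0.0,
            gated=[bool(gated and (a, b) in gated) for a, b in
                   subnet.edges[["gene_a", "gene_b"]].itertuples(index=False)])
        subnet.edges = edges
        sig = pd.DataFrame({"p_i": pd.Series(p_i)})
        return weight_edges(subnet, sig)

    def test_both_endpoints_at_maximum_give_one(self):
        out = self._weighted({"A": 5.0, "B": 5.0, "C": 2.0},
                             [("A", "B"), ("B", "C")])
        ab = out.edges.set_index(["gene_a", "gene_b"])["omega"]
        assert ab[("A", "B")] == pytest.approx(1.0)

    def test_gated_edge_zero(self):
        out = self._weighted({"A": 5.0, "B": 5.0}, [("A", "B")],
                             gated={("A", "B")})
        assert out.edges.iloc[0]["omega"] == 0.0

    def test_direct_substitution(self):
        # ln p = 2 and 4 with max ln p = 4 -> omega = 6/8
        p = {"A": math.exp(2), "B": math.exp(4)}
        out = self._weighted(p, [("A", "B")])
        assert out.edges.iloc[0]["omega"] == pytest.approx(0.75)

    def test_omega_in_unit_interval(self, small_dataset):
        rng = np.random.default_rng(0)
        _, _, edges, _, truth = small_dataset
        subnet = build_target_subnetwork(edges, truth.diff_genes, truth.seed_genes)
        p_i = pd.Series(1.0 + rng.uniform(0, 9, len(subnet.nodes)),
                        index=subnet.nodes)
        subnet.edges = subnet.edges.assign(r=1.0, p_r=0.0, gated=False)
        out = weight_edges(subnet, pd.DataFrame({"p_i": p_i}))
        assert out.edges["omega"].between(0, 1).all()

    def test_all_scores_at_floor_warns_and_zeroes(self, caplog):
        with caplog.at_level("WARNING", logger="methego"):
            out = self._weighted({"A": 1.0, "B": 1.0}, [("A", "B")])
        assert out.edges.iloc[0]["omega"] == 0.0
        assert "floor" in caplog.text


class TestTopologyMetrics:
    def _metrics(self, g: nx.Graph) -> pd.DataFrame:
        edges = _edges(list(g.edges))
        subnet = build_target_subnetwork(edges, set(g.nodes))
        return topology_metrics(subnet)

    def test_triangle(self):
        m = self._metrics(nx.complete_graph(["A", "B", "C"]))
        for v in ("A", "B", "C"):
            assert m.loc[v, "degree"] == 2
            assert m.loc[v, "closeness"] == pytest.approx(1.0)
            assert m.loc[v, "betweenness"] == 0.0
            assert m.loc[v, "transitivity"] == 1.0

    def test_path_betweenness(self):
        m = self._metrics(nx.path_graph(["A", "B", "C"]))
        assert m.loc["B", "betweenness"] == pytest.approx(1.0)
        assert m.loc["A", "betweenness"] == 0.0

    def test_matches_exhaustive_oracle_on_random_graphs(self):
        rng = np.random.default_rng(7)
        for rep in range(200):
            n = int(rng.integers(3, 9))
            p = float(rng.uniform(0.25, 0.9))
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
            g = nx.relabel_nodes(g, {i: f"N{i}" for i in range(n)})
            if g.number_of_edges() == 0:
                continue
            m = self._metrics(g)
            # isolated nodes drop out of the subnetwork
            expected = brute_force_topology(g.subgraph(m.index))
            for metric in ("degree", "closeness", "betweenness", "transitivity"):
                for v in m.index:
                    assert m.loc[v, metric] == pytest.approx(
                        expected[metric][v], abs=1e-9), (rep, metric, v)


class TestCLRAdjacency:
    def test_constant_matrix_gives_zero(self):
        # all off-diagonal entries equal -> every row sigma is 0
        W = np.full((4, 4), 0.7)
        np.fill_diagonal(W, 0.0)
        assert np.allclose(clr_adjacency(W), 0.0)

    def test_hand_computed_three_by_three(self):
        W = np.array([[0.0, 1.0, 2.0],
                      [1.0, 0.0, 4.0],
                      [2.0, 4.0, 0.0]])
        A = clr_adjacency(W)
        # row stats: row0 mu=1.5 sd=.5; row1 mu=2.5 sd=1.5; row2 mu=3 sd=1
        expected = np.array([[0.0, 0.0, 1.0],
                             [0.0, 0.0, math.sqrt(2.0)],
                             [1.0, math.sqrt(2.0), 0.0]])
        np.testing.assert_allclose(A, expected, atol=1e-12)

    def test_symmetric_nonnegative_zero_diagonal(self):
        rng = np.random.default_rng(1)
        M = rng.uniform(size=(10, 10))
        W = (M + M.T) / 2
        np.fill_diagonal(W, 0.0)
        A = clr_adjacency(W)
        np.testing.assert_array_equal(A, A.T)
        assert (A >= 0).all()
        assert np.allclose(np.diag(A), 0.0)

    def test_invariant_to_constant_shift(self):
        rng = np.random.default_rng(2)
        M = rng.uniform(size=(8, 8))
        W = (M + M.T) / 2
        np.fill_diagonal(W, 0.0)
        A1 = clr_adjacency(W)
        shifted = W + 0.37
        np.fill_diagonal(shifted, 0.0)
        # shift applied to off-diagonal entries only (diagonal stays zero);
        # per-row z-scores are location-free so A is unchanged
        A2 = clr_adjacency(shifted)
        off = ~np.eye(8, dtype=bool)
        np.testing.assert_allclose(A1[off], A2[off], atol=1e-10)

    def test_too_small_matrix_rejected(self):
        with pytest.raises(ValueError, match="3 nodes"):
            clr_adjacency(np.zeros((2, 2)))


class TestRankEgoGenes:
    def _adjacency(self, n: int, seed: int = 0) -> pd.DataFrame:
        rng = np.random.default_rng(seed)
        M = rng.uniform(size=(n, n))
        W = (M + M.T) / 2
        np.fill_diagonal(W, 0.0)
        genes = [f"G{i:02d}" for i in range(n)]
        return pd.DataFrame(clr_adjacency(W), index=genes, columns=genes)

    def test_ten_nodes_three_ego_genes(self, default_config):
        table = rank_ego_genes(self._adjacency(10), default_config)
        assert int(table["is_ego"].sum()) == 3  # ceil(0.3 * 10)

    def test_dominant_node_ranks_first(self, default_config):
        genes = [f"G{i}" for i in range(6)]
        W = pd.DataFrame(0.01, index=genes, columns=genes)
        for g in genes[1:]:
            W.loc["G0", g] = W.loc[g, "G0"] = 1.0
        np.fill_diagonal(W.values, 0.0)
        A = clr_adjacency(W)
        table = rank_ego_genes(A, default_config)
        assert table.index[0] == "G0"
        assert table.iloc[0]["rank"] == 1

    def test_z_scores_standardized(self, default_config):
        table = rank_ego_genes(self._adjacency(40), default_config)
        assert table["g_i"].mean() == pytest.approx(0.0, abs=1e-12)
        assert table["g_i"].std(ddof=0) == pytest.approx(1.0, abs=1e-12)

    def test_constant_rows_warn_and_rank_by_gene(self, caplog, default_config):
        genes = ["B", "A", "C"]
        A = pd.DataFrame(0.0, index=genes, columns=genes)
        with caplog.at_level("WARNING", logger="methego"):
            table = rank_ego_genes(A, default_config)
        assert (table["g_i"] == 0).all()
        assert list(table.index) == ["A", "B", "C"]

    def test_permutation_equivariance(self, default_config):
        A = self._adjacency(12, seed=3)
        table = rank_ego_genes(A, default_config)
        mapping = {g: f"X{g}" for g in A.index}
        A2 = A.rename(index=mapping, columns=mapping)
        table2 = rank_ego_genes(A2, default_config)
        ego1 = {mapping[g] for g in table.index[table["is_ego"]]}
        ego2 = set(table2.index[table2["is_ego"]])
        assert ego1 == ego2


class TestRunEgonet:
    def test_end_to_end_on_fixture(self, small_dataset, default_config):
        beta, annot, edges, _, truth = small_dataset
        from methego.diffmeth import test_differential as run_ttests
        calls = run_ttests(beta)
        cfg = default_config.replace(seed_genes=tuple(truth.seed_genes))
        subnet, node_table, gene_matrix = run_egonet(
            beta, annot, calls, edges, truth.diff_genes, cfg)
        assert node_table["is_ego"].sum() >= 1
        assert subnet.edges["omega"].between(0, 1).all()
        # module genes should dominate the ego set
        ego = set(node_table.index[node_table["is_ego"]])
        module_in_v = set(truth.module_genes) & set(node_table.index)
        recall = len(ego & module_in_v) / len(module_in_v)
        assert recall >= 0.8
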