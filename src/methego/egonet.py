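"""Ego-network scoring of candidate genes.

Pipeline: restrict the interaction network to differential genes plus the
designated susceptibility seed genes; gate each edge by the Pearson
correlation of gene-level methylation (|r| below the δ matching a target
correlation p-value is zeroed); weight surviving edges by

    ω_ij = (log p_i + log p_j) / (2 · max_{v∈V} log p_v),

where p_i = max(−log10(gene-level differential p-value), 1) so that
log p_i >= 0 and ω lands in [0, 1]; convert the weight matrix to a CLR
adjacency (per-row z-scores, clamped at 0, combined per edge as the
Euclidean norm of the two endpoint z-scores); and rank genes by the
standardized row strength of that adjacency.  The top fraction (default
30%) are flagged as ego genes.

The node score p_i is a documented modelling choice — the weighting
formula's inputs are not fully pinned down by its source; an alternative
(raw mean β) is available via ``node_score="beta_mean"``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import chi2, t as t_dist

from .config import PipelineConfig
from .io import BetaMatrix, ProbeAnnotation

__all__ = [
    "EmptySubnetworkError",
    "TargetSubnetwork",
    "gene_level_signal",
    "build_target_subnetwork",
    "gate_by_correlation",
    "weight_edges",
    "topology_metrics",
    "clr_adjacency",
    "rank_ego_genes",
    "correlation_gate_threshold",
    "run_egonet",
]

logger = logging.getLogger("methego")


class EmptySubnetworkError(RuntimeError):
    """No interaction edge has both endpoints in the target gene set."""


@dataclass
class TargetSubnetwork:
    """Gene graph restricted to differential ∪ susceptibility genes.

    ``edges`` has one row per retained undirected edge (gene_a < gene_b)
    with columns confidence, r, p_r, gated and omega (filled in by the
    gating/weighting steps); ``delta`` is the |r| gate threshold.
    """

    graph: nx.Graph
    edges: pd.DataFrame
    delta: float | None = None

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def weight_matrix(self) -> pd.DataFrame:
        """Symmetric ω matrix over the node set (zero diagonal)."""
        nodes = self.nodes
        W = pd.DataFrame(0.0, index=nodes, columns=nodes)
        if "omega" not in self.edges.columns:
            raise ValueError("weight_edges has not been applied yet")
        for a, b, w in self.edges[["gene_a", "gene_b", "omega"]].itertuples(index=False):
            W.loc[a, b] = w
            W.loc[b, a] = w
        return W


def gene_level_signal(beta: BetaMatrix, annot: ProbeAnnotation,
                      calls: pd.DataFrame,
                      combine: str = "min") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate probe-level data to genes.

    Gene methylation is the unweighted mean β over the gene's probes per
    sample.  The gene-level differential p is the minimum probe p-value
    (or Fisher's combination with ``combine="fisher"``); the node score is
    p_i = max(−log10(gene_p), 1).

    Returns (gene × sample matrix, node table with gene_p and p_i).
    """
    gene_map = annot.table["gene"].reindex(beta.probes)
    if gene_map.isna().any():
        missing = beta.probes[gene_map.isna()][:5].tolist()
        raise ValueError(f"probes without gene annotation: {missing}")
    gene_matrix = beta.data.groupby(gene_map).mean()
    gene_matrix.index.name = "gene"

    p = calls["p_value"].reindex(beta.probes)
    grouped = p.groupby(gene_map)
    if combine == "min":
        gene_p = grouped.min()
    elif combine == "fisher":
        def _fisher(ps: pd.Series) -> float:
            ps = np.clip(ps.to_numpy(), 1e-300, 1.0)
            stat = -2.0 * np.log(ps).sum()
            return float(chi2.sf(stat, 2 * len(ps)))
        gene_p = grouped.apply(_fisher)
    else:
        raise ValueError(f"unknown combine rule {combine!r}")
    node_sig = pd.DataFrame({"gene_p": gene_p})
    node_sig["p_i"] = np.maximum(-np.log10(np.clip(gene_p, 1e-300, 1.0)), 1.0)
    node_sig.index.name = "gene"
    return gene_matrix, node_sig


def build_target_subnetwork(edges: pd.DataFrame, diff_genes: set[str] | list[str],
                            seed_genes: set[str] | list[str] = ()) -> TargetSubnetwork:
    """Keep edges whose BOTH endpoints are differential or seed genes.

    Nodes left without any edge drop out of the subnetwork entirely.
    """
    target = set(diff_genes) | set(seed_genes)
    keep = edges["gene_a"].isin(target) & edges["gene_b"].isin(target)
    sub = edges[keep].copy()
    if sub.empty:
        raise EmptySubnetworkError(
            "no interaction edge has both endpoints in the target gene set"
        )
    graph = nx.Graph()
    for a, b, c in sub[["gene_a", "gene_b", "confidence"]].itertuples(index=False):
        graph.add_edge(a, b, confidence=c)
    sub = sub.sort_values(["gene_a", "gene_b"]).reset_index(drop=True)
    logger.info("build_target_subnetwork: %d nodes, %d edges",
                graph.number_of_nodes(), len(sub))
    return TargetSubnetwork(graph, sub)


def correlation_gate_threshold(n_samples: int, p: float) -> float:
    """|r| whose two-sided Pearson p-value equals ``p`` at ``n_samples``.

    Inverts t = r·sqrt((m−2)/(1−r²)): δ = t*/sqrt(m−2+t*²) with
    t* = t_{1−p/2, m−2}.
    """
    m = int(n_samples)
    if m < 4:
        raise ValueError("need at least 4 samples for a Pearson p-value")
    t_star = t_dist.ppf(1.0 - p / 2.0, m - 2)
    return float(t_star / math.sqrt(m - 2 + t_star**2))


def gate_by_correlation(subnet: TargetSubnetwork, gene_matrix: pd.DataFrame,
                        config: PipelineConfig | None = None) -> TargetSubnetwork:
    """Annotate edges with Pearson r / p and mark correlation-gated edges.

    The gate threshold δ is the |r| whose two-sided p equals
    ``delta_corr_p`` for the available sample count; edges with |r| < δ
    (or with a zero-variance endpoint) are gated — their ω will be 0.
    """
    config = config or PipelineConfig()
    m = gene_matrix.shape[1]
    delta = correlation_gate_threshold(m, config.delta_corr_p)

    X = gene_matrix
    r_vals, p_vals, gated = [], [], []
    for a, b in subnet.edges[["gene_a", "gene_b"]].itertuples(index=False):
        xa = X.loc[a].to_numpy()
        xb = X.loc[b].to_numpy()
        sa, sb = xa.std(), xb.std()
        if sa == 0 or sb == 0:
            r_vals.append(np.nan)
            p_vals.append(np.nan)
            gated.append(True)
            continue
        r = float(np.corrcoef(xa, xb)[0, 1])
        r = max(min(r, 1.0), -1.0)
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t_r = r * math.sqrt((m - 2) / (1.0 - r * r))
            p = float(2.0 * t_dist.sf(abs(t_r), m - 2))
        r_vals.append(r)
        p_vals.append(p)
        gated.append(abs(r) < delta)
    edges = subnet.edges.assign(r=r_vals, p_r=p_vals, gated=gated)
    n_gated = int(sum(gated))
    logger.info("gate_by_correlation: delta=%.4f (m=%d), %d / %d edges gated",
                delta, m, n_gated, len(edges))
    return TargetSubnetwork(subnet.graph, edges, delta=delta)


def weight_edges(subnet: TargetSubnetwork,
                 node_sig: pd.DataFrame) -> TargetSubnetwork:
    """Attach ω to every edge.

    ω_ij = (ln p_i + ln p_j) / (2 · max_{v∈V} ln p_v) for retained edges,
    0 for gated edges.  Natural logarithm — the base cancels in the ratio.
    Nodes missing a score get p_i = 1 (score floor) with a warning; if
    every node sits at the floor (max ln p = 0) all ω are set to 0.
    """
    if "gated" not in subnet.edges.columns:
        raise ValueError("gate_by_correlation must run before weight_edges")
    nodes = subnet.nodes
    p_i = node_sig["p_i"].reindex(nodes)
    n_missing = int(p_i.isna().sum())
    if n_missing:
        logger.warning("weight_edges: %d node(s) without a score; floored at 1", n_missing)
        p_i = p_i.fillna(1.0)
    log_p = np.log(p_i)
    max_log = float(log_p.max())
    edges = subnet.edges.copy()
    if max_log <= 0:
        logger.warning("weight_edges: all node scores at the floor; ω set to 0")
        edges["omega"] = 0.0
    else:
        om = (log_p[edges["gene_a"]].to_numpy() + log_p[edges["gene_b"]].to_numpy()) \
            / (2.0 * max_log)
        edges["omega"] = np.where(edges["gated"].to_numpy(), 0.0, om)
    return TargetSubnetwork(subnet.graph, edges, delta=subnet.delta)


def topology_metrics(subnet: TargetSubnetwork) -> pd.DataFrame:
    """Per-node degree, closeness, betweenness and transitivity.

    Computed on the ungated, unweighted graph.  Closeness is
    (reachable − 1) / Σ shortest-path lengths within the node's component;
    betweenness is the unnormalized shortest-path pair-fraction sum;
    transitivity is the local clustering coefficient (0 for degree < 2).
    """
    g = subnet.graph
    nodes = subnet.nodes
    closeness = nx.closeness_centrality(g, wf_improved=False)
    betweenness = nx.betweenness_centrality(g, normalized=False)
    clustering = nx.clustering(g)
    return pd.DataFrame(
        {
            "degree": [g.degree(v) for v in nodes],
            "closeness": [closeness[v] for v in nodes],
            "betweenness": [betweenness[v] for v in nodes],
            "transitivity": [clustering[v] for v in nodes],
        },
        index=pd.Index(nodes, name="gene"),
    )


def clr_adjacency(W: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Context-likelihood-of-relatedness transform of a weight matrix.

    Per node i, the mean μ_i and (population) standard deviation σ_i of
    the off-diagonal row entries define z_i(ij) = max(0, (W_ij − μ_i)/σ_i)
    (0 when σ_i = 0); the adjacency combines both endpoints as
    A_ij = sqrt(z_i(ij)² + z_j(ij)²).  A is symmetric, non-negative and
    zero on the diagonal.
    """
    labels = None
    if isinstance(W, pd.DataFrame):
        labels = W.index
        M = W.to_numpy(dtype=float)
    else:
        M = np.asarray(W, dtype=float)
    n = M.shape[0]
    if M.shape[0] != M.shape[1]:
        raise ValueError("weight matrix must be square")
    if n < 3:
        raise ValueError("CLR needs at least 3 nodes for row statistics")
    if not np.allclose(M, M.T):
        raise ValueError("weight matrix must be symmetric")

    off = ~np.eye(n, dtype=bool)
    mu = (M * off).sum(axis=1) / (n - 1)
    var = ((M - mu[:, None]) ** 2 * off).sum(axis=1) / (n - 1)
    sigma = np.sqrt(var)
    # rows with (numerically) constant off-diagonal entries carry no signal
    degenerate_row = sigma <= 1e-12 * max(1.0, float(np.abs(M).max()))
    with np.errstate(divide="ignore", invalid="ignore"):
        Z = (M - mu[:, None]) / sigma[:, None]
    Z[degenerate_row, :] = 0.0
    Z = np.maximum(Z, 0.0)
    A = np.sqrt(Z**2 + Z.T**2)
    np.fill_diagonal(A, 0.0)
    if labels is not None:
        return pd.DataFrame(A, index=labels, columns=labels)
    return A


def rank_ego_genes(A: pd.DataFrame, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Rank genes by standardized CLR row strength; flag the top fraction.

    r_i = Σ_j A_ij; g_i = (r_i − mean r) / sd(r) (population sd).  Genes
    are sorted by descending g_i with lexicographic tie-breaking; the top
    ceil(ego_top_fraction · |V|) are ego genes, with boundary ties all
    included.
    """
    config = config or PipelineConfig()
    r = A.sum(axis=1)
    genes = r.index
    sd = float(r.std(ddof=0))
    if sd == 0:
        logger.warning("rank_ego_genes: constant row strengths; all z-scores 0")
        g = pd.Series(0.0, index=genes)
    else:
        g = (r - r.mean()) / sd
    table = pd.DataFrame({"r_i": r, "g_i": g})
    table = table.loc[sorted(genes, key=lambda v: (-g[v], v))]
    table["rank"] = np.arange(1, len(table) + 1)
    n_ego = math.ceil(config.ego_top_fraction * len(table))
    is_ego = table["rank"] <= n_ego
    if n_ego < len(table):
        boundary = table["g_i"].iloc[n_ego - 1]
        tied = (table["g_i"] == boundary) & ~is_ego
        if tied.any():
            logger.info("rank_ego_genes: including %d boundary tie(s)", int(tied.sum()))
            is_ego |= tied
    table["is_ego"] = is_ego
    table.index.name = "gene"
    return table


def run_egonet(beta: BetaMatrix, annot: ProbeAnnotation, calls: pd.DataFrame,
               edges: pd.DataFrame, diff_genes: list[str],
               config: PipelineConfig | None = None
               ) -> tuple[TargetSubnetwork, pd.DataFrame, pd.DataFrame]:
    """End-to-end ego-network scoring.

    Returns (subnetwork with r/p/ω per edge, node table, gene × sample
    matrix).  The node table carries p_i, the four topology metrics, CLR
    row strength r_i, z-score g_i, rank and the is_ego flag.
    """
    config = config or PipelineConfig()
    gene_matrix, node_sig = gene_level_signal(beta, annot, calls,
                                              combine=config.gene_p_combine)
    if config.node_score == "beta_mean":
        node_sig = node_sig.copy()
        node_sig["p_i"] = np.maximum(gene_matrix.mean(axis=1) * 10.0, 1.0)
    subnet = build_target_subnetwork(edges, diff_genes, config.seed_genes)
    missing = [v for v in subnet.nodes if v not in gene_matrix.index]
    if missing:
        logger.warning("run_egonet: %d subnetwork gene(s) without methylation data",
                       len(missing))
    subnet = gate_by_correlation(subnet, gene_matrix.reindex(subnet.nodes).fillna(0.0),
                                 config)
    subnet = weight_edges(subnet, node_sig)
    topo = topology_metrics(subnet)
    A = clr_adjacency(subnet.weight_matrix())
    scores = rank_ego_genes(A, config)
    node_table = topo.join(node_sig, how="left").join(scores, how="left")
    node_table = node_table.loc[scores.index]  # rank order
    return subnet, node_table, gene_matrix
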