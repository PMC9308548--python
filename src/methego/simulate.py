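"""Synthetic β-value data with ground truth for every downstream stage.

The generator emulates a methylation-array study design: β-values drawn
from beta mixtures with unmethylated/hemimethylated/methylated states, two
probe design classes (class II compressed toward 0.5), a planted fraction
of hyper-/hypomethylated CpGs with a stated effect size, contiguous
many-CpGs-per-gene blocks, a scale-free interaction network with a planted
dense disease module around designated susceptibility genes, and gene sets
some of which are enriched for the planted differential genes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .io import (
    BetaMatrix,
    ProbeAnnotation,
    write_beta_matrix,
    write_gene_sets,
    write_network_edges,
    write_probe_annotation,
    write_sample_groups,
)

__all__ = [
    "SimulationDesign",
    "GroundTruth",
    "simulate_beta_matrix",
    "simulate_network",
    "simulate_gene_sets",
    "simulate_dataset",
    "write_dataset",
]

logger = logging.getLogger("methego")

STATE_MEANS = (0.10, 0.50, 0.85)  # unmethylated / hemimethylated / methylated
MEAN_CLIP = (0.02, 0.98)
QC_CRITERIA = ("snp_proximity", "low_maf", "cross_hyb", "sex_chromosome")
CASE_LABEL = "tumor"
CONTROL_LABEL = "normal"


@dataclass(frozen=True)
class SimulationDesign:
    """Parameters of one synthetic dataset.

    Defaults mirror the study shape at desk scale: 29 case / 9 control
    samples, 20000 probes over 2000 genes (10 CpGs per gene).
    """

    n_probes: int = 20000
    n_genes: int = 2000
    n_case: int = 29
    n_control: int = 9
    frac_diff: float = 0.05
    frac_hyper: float = 0.8
    delta_beta: float = 0.3
    dispersion: float = 30.0
    frac_typeII: float = 0.5
    typeII_attenuation: float = 0.8
    frac_qc_fail: float = 0.10
    n_seed_genes: int = 4
    module_size: int = 15
    attach_m: int = 3
    n_gene_sets: int = 50
    enriched_sets: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_probes < 1 or self.n_genes < 1 or self.n_probes < self.n_genes:
            raise ValueError("need n_probes >= n_genes >= 1")
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("need at least 2 samples per group")
        for name in ("frac_hyper", "frac_typeII"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("frac_diff", "frac_qc_fail"):
            if not (0.0 <= getattr(self, name) < 1.0):
                raise ValueError(f"{name} must lie in [0, 1)")
        if not (0.0 < self.delta_beta < 1.0):
            raise ValueError("delta_beta must lie in (0, 1)")
        if not (0.0 < self.typeII_attenuation <= 1.0):
            raise ValueError("typeII_attenuation must lie in (0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.frac_diff + self.frac_qc_fail >= 1.0:
            raise ValueError("frac_diff + frac_qc_fail must be < 1")
        if self.module_size + self.n_seed_genes > self.n_genes:
            raise ValueError("module_size + n_seed_genes must not exceed n_genes")
        if self.attach_m < 1:
            raise ValueError("attach_m must be >= 1")
        if self.enriched_sets > self.n_gene_sets:
            raise ValueError("enriched_sets must not exceed n_gene_sets")


@dataclass
class GroundTruth:
    """Planted truth labels for parameter-recovery testing.

    ``diff_probes`` maps probe ID → direction (+1 hyper, −1 hypo in the
    case group); ``probe_gene`` maps every probe to its gene.
    """

    diff_probes: dict[str, int] = field(default_factory=dict)
    probe_gene: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))
    qc_fail_probes: dict[str, str] = field(default_factory=dict)
    module_genes: list[str] = field(default_factory=list)
    seed_genes: list[str] = field(default_factory=list)
    enriched_set_names: list[str] = field(default_factory=list)

    @property
    def diff_genes(self) -> list[str]:
        genes = self.probe_gene.loc[list(self.diff_probes)].unique()
        return sorted(genes)


def _child_rng(design: SimulationDesign, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([design.seed, stream]))


def _gene_blocks(design: SimulationDesign) -> tuple[np.ndarray, list[str], list[str]]:
    """Assign probes to genes in contiguous, near-equal blocks."""
    probes = [f"cg{i:07d}" for i in range(design.n_probes)]
    genes = [f"G{i:05d}" for i in range(design.n_genes)]
    gene_idx = (np.arange(design.n_probes) * design.n_genes) // design.n_probes
    return gene_idx, probes, genes


def simulate_beta_matrix(
    design: SimulationDesign,
) -> tuple[BetaMatrix, ProbeAnnotation, GroundTruth]:
    """Sample a β matrix plus annotation and ground truth.

    Non-differential probes share a state mean across both groups; values
    come from a beta distribution parameterized by (mean m, precision s):
    a = m·s, b = (1−m)·s.  Differential probes shift the case-group mean so
    that the *observed* case − control difference equals ``delta_beta``
    even for class-II probes, whose values are subsequently compressed
    toward 0.5 by ``typeII_attenuation`` (x ← 0.5 + att·(x − 0.5)).

    Differential probes are planted gene-blockwise (whole genes at a time)
    so the set of truth-differential genes is well defined.  QC-failing
    probes (10% by default, split evenly over the four removal criteria)
    never overlap truth-differential probes.
    """
    design.validate()
    rng = _child_rng(design, 0)
    gene_idx, probes, genes = _gene_blocks(design)
    n = design.n_probes
    s = design.dispersion

    # --- plant differential probes gene-blockwise ---
    n_diff = int(round(design.frac_diff * n))
    gene_order = rng.permutation(design.n_genes)
    diff_mask = np.zeros(n, dtype=bool)
    taken = 0
    for g in gene_order:
        if taken >= n_diff:
            break
        block = np.flatnonzero(gene_idx == g)
        take = min(len(block), n_diff - taken)
        diff_mask[block[:take]] = True
        taken += take
    diff_idx = np.flatnonzero(diff_mask)
    assert diff_idx.size == n_diff

    direction = np.zeros(n, dtype=int)
    if n_diff:
        n_hyper = int(round(design.frac_hyper * n_diff))
        hyper_pick = rng.permutation(n_diff)
        direction[diff_idx[hyper_pick[:n_hyper]]] = 1
        direction[diff_idx[hyper_pick[n_hyper:]]] = -1

    # --- probe design class ---
    n_typeII = int(round(design.frac_typeII * n))
    typeII_mask = np.zeros(n, dtype=bool)
    typeII_mask[rng.permutation(n)[:n_typeII]] = True

    # --- QC-failing probes, disjoint from truth-differential probes ---
    n_qc = int(round(design.frac_qc_fail * n))
    candidates = np.flatnonzero(~diff_mask)
    if n_qc > candidates.size:
        raise ValueError("not enough non-differential probes to plant QC failures")
    qc_idx = rng.choice(candidates, size=n_qc, replace=False)
    qc_criterion = np.full(n, "", dtype=object)
    for j, idx in enumerate(qc_idx):
        qc_criterion[idx] = QC_CRITERIA[j % len(QC_CRITERIA)]

    # --- state means; differential probes draw from states where the
    #     (possibly attenuation-inflated) shift fits inside MEAN_CLIP ---
    att = design.typeII_attenuation
    means = np.asarray(STATE_MEANS)
    base_mean = means[rng.integers(0, len(means), size=n)]
    case_mean = base_mean.copy()
    for idx in diff_idx:
        d_u = design.delta_beta / att if typeII_mask[idx] else design.delta_beta
        sign = direction[idx]
        ok = means[(means + sign * d_u >= MEAN_CLIP[0]) & (means + sign * d_u <= MEAN_CLIP[1])]
        if ok.size == 0:
            raise ValueError(
                f"delta_beta={design.delta_beta} too large to plant at any base state"
            )
        m = ok[rng.integers(0, ok.size)]
        base_mean[idx] = m
        case_mean[idx] = m + sign * d_u

    def _sample(mean_vec: np.ndarray, n_samples: int) -> np.ndarray:
        a = mean_vec * s
        b = (1.0 - mean_vec) * s
        return rng.beta(a[:, None], b[:, None], size=(n, n_samples))

    control = _sample(base_mean, design.n_control)
    case = _sample(case_mean, design.n_case)
    values = np.concatenate([case, control], axis=1)
    values[typeII_mask] = 0.5 + att * (values[typeII_mask] - 0.5)
    np.clip(values, 0.0, 1.0, out=values)

    case_ids = [f"T{i:03d}" for i in range(design.n_case)]
    ctrl_ids = [f"N{i:03d}" for i in range(design.n_control)]
    samples = case_ids + ctrl_ids
    data = pd.DataFrame(values, index=probes, columns=samples)
    groups = pd.Series(
        [CASE_LABEL] * design.n_case + [CONTROL_LABEL] * design.n_control,
        index=samples, name="group",
    )

    # --- annotation: clean probes pass every QC rule by construction ---
    snp_distance = rng.integers(3, 200, size=n)
    maf = rng.uniform(0.05, 0.5, size=n)
    cross_hyb = np.zeros(n, dtype=int)
    chrom = np.array([f"chr{1 + (g % 22)}" for g in gene_idx], dtype=object)
    for idx in np.flatnonzero(qc_criterion != ""):
        crit = qc_criterion[idx]
        if crit == "snp_proximity":
            snp_distance[idx] = rng.integers(0, 3)
        elif crit == "low_maf":
            maf[idx] = rng.uniform(0.0, 0.0499)
        elif crit == "cross_hyb":
            cross_hyb[idx] = 1
        else:  # sex_chromosome
            chrom[idx] = "chrX" if rng.random() < 0.5 else "chrY"
    annot = pd.DataFrame(
        {
            "chrom": [c[3:] for c in chrom],
            "pos": np.arange(n) * 100 + 1,
            "snp_distance": snp_distance,
            "maf": np.round(maf, 6),
            "cross_hyb": cross_hyb,
            "design_type": np.where(typeII_mask, "II", "I"),
            "gene": [genes[g] for g in gene_idx],
        },
        index=pd.Index(probes, name="probe_id"),
    )

    truth = GroundTruth(
        diff_probes={probes[i]: int(direction[i]) for i in diff_idx},
        probe_gene=annot["gene"].copy(),
        qc_fail_probes={probes[i]: qc_criterion[i] for i in np.flatnonzero(qc_criterion != "")},
    )
    logger.info(
        "simulate_beta_matrix: %d probes (%d differential, %d QC-failing), %d samples",
        n, n_diff, n_qc, len(samples),
    )
    return BetaMatrix(data, groups), ProbeAnnotation(annot), truth


def simulate_network(
    design: SimulationDesign,
    gene_universe: list[str],
    truth: GroundTruth,
) -> pd.DataFrame:
    """Scale-free backbone plus a planted dense module.

    Builds a Barabási–Albert graph over the gene universe, designates
    ``n_seed_genes`` susceptibility stand-ins, plants a module of
    ``module_size`` truth-differential genes together with the seed genes,
    and wires the module to at least 60% internal edge density.  Updates
    ``truth`` in place with the module and seed-gene identities; returns
    the edge table (gene_a, gene_b, confidence ∈ [400, 1000]).
    """
    rng = _child_rng(design, 1)
    n = len(gene_universe)
    if design.module_size + design.n_seed_genes > n:
        raise ValueError("module does not fit in the gene universe")
    graph = nx.barabasi_albert_graph(n, design.attach_m, seed=int(rng.integers(2**31)))
    mapping = dict(enumerate(gene_universe))
    graph = nx.relabel_nodes(graph, mapping)

    diff_genes = [g for g in truth.diff_genes if g in set(gene_universe)]
    if len(diff_genes) < design.module_size:
        raise ValueError(
            f"only {len(diff_genes)} truth-differential genes available for a "
            f"module of size {design.module_size}"
        )
    module: list[str] = []
    if design.module_size:
        module = sorted(map(str, rng.choice(diff_genes, size=design.module_size,
                                            replace=False)))
    others = sorted(set(gene_universe) - set(module))
    seeds: list[str] = []
    if design.n_seed_genes:
        seeds = sorted(map(str, rng.choice(others, size=design.n_seed_genes,
                                           replace=False)))
    truth.module_genes = list(module)
    truth.seed_genes = list(seeds)

    cluster = list(module) + list(seeds)
    pairs = [(cluster[i], cluster[j]) for i in range(len(cluster))
             for j in range(i + 1, len(cluster))]
    target_edges = math.ceil(0.6 * len(pairs))
    present = [p for p in pairs if graph.has_edge(*p)]
    absent = [p for p in pairs if not graph.has_edge(*p)]
    need = max(0, target_edges - len(present))
    if need:
        extra = rng.choice(len(absent), size=need, replace=False)
        graph.add_edges_from(absent[k] for k in extra)

    rows = []
    for a, b in graph.edges():
        lo, hi = (a, b) if a <= b else (b, a)
        rows.append((lo, hi, int(rng.integers(400, 1001))))
    edges = pd.DataFrame(rows, columns=["gene_a", "gene_b", "confidence"])
    return edges.sort_values(["gene_a", "gene_b"]).reset_index(drop=True)


def simulate_gene_sets(
    design: SimulationDesign,
    gene_universe: list[str],
    truth: GroundTruth,
) -> dict[str, list[str]]:
    """Gene-set collection with a few sets enriched for differential genes.

    Enriched sets draw at least 70% of members from truth-differential
    genes; null sets draw uniformly.  Set sizes lie in [15, 200] (capped
    by the universe).  Updates ``truth.enriched_set_names``.
    """
    rng = _child_rng(design, 2)
    universe = list(gene_universe)
    if len(universe) < 15:
        raise ValueError("gene universe smaller than the minimum set size (15)")
    max_size = min(200, len(universe))
    diff_genes = [g for g in truth.diff_genes if g in set(universe)]
    non_diff = sorted(set(universe) - set(diff_genes))

    sets: dict[str, list[str]] = {}
    enriched_names: list[str] = []
    for i in range(design.n_gene_sets):
        name = f"SET{i + 1:04d}"
        size = int(rng.integers(15, max_size + 1))
        if i < design.enriched_sets:
            if len(diff_genes) < 11:
                raise ValueError("too few truth-differential genes for enriched sets")
            size = min(size, int(len(diff_genes) / 0.7), max_size)
            size = max(size, 15)
            n_from_diff = math.ceil(0.7 * size)
            n_from_diff = min(n_from_diff, len(diff_genes))
            picked = list(rng.choice(diff_genes, size=n_from_diff, replace=False))
            rest_pool = non_diff if non_diff else diff_genes
            remaining = size - n_from_diff
            if remaining:
                picked += list(rng.choice(rest_pool, size=remaining, replace=False))
            enriched_names.append(name)
        else:
            picked = list(rng.choice(universe, size=size, replace=False))
        sets[name] = sorted(picked)
    truth.enriched_set_names = enriched_names
    return sets


def simulate_dataset(
    design: SimulationDesign,
) -> tuple[BetaMatrix, ProbeAnnotation, pd.DataFrame, dict[str, list[str]], GroundTruth]:
    """Generate the full input bundle for one end-to-end pipeline run."""
    beta, annot, truth = simulate_beta_matrix(design)
    genes = sorted(annot.table["gene"].unique())
    edges = simulate_network(design, genes, truth)
    sets = simulate_gene_sets(design, genes, truth)
    return beta, annot, edges, sets, truth


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    """Serialize ground truth as a long-format key/id/value TSV."""
    rows = [("diff_probe", p, str(d)) for p, d in truth.diff_probes.items()]
    rows += [("qc_fail_probe", p, c) for p, c in truth.qc_fail_probes.items()]
    rows += [("module_gene", g, "") for g in truth.module_genes]
    rows += [("seed_gene", g, "") for g in truth.seed_genes]
    rows += [("enriched_set", s, "") for s in truth.enriched_set_names]
    pd.DataFrame(rows, columns=["kind", "id", "value"]).to_csv(path, sep="\t", index=False)


def write_dataset(design: SimulationDesign, out_dir: str | Path) -> dict[str, Path]:
    """Write beta.tsv, annot.tsv, groups.tsv, edges.tsv, sets.gmt, truth.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    beta, annot, edges, sets, truth = simulate_dataset(design)
    paths = {
        "beta": out / "beta.tsv",
        "annot": out / "annot.tsv",
        "groups": out / "groups.tsv",
        "edges": out / "edges.tsv",
        "gmt": out / "sets.gmt",
        "truth": out / "truth.tsv",
    }
    write_beta_matrix(beta, paths["beta"])
    write_probe_annotation(annot, paths["annot"])
    write_sample_groups(beta.groups, paths["groups"])
    write_network_edges(edges, paths["edges"])
    write_gene_sets(sets, paths["gmt"])
    write_truth(truth, paths["truth"])
    return paths
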