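"""End-to-end pipeline driver.

Stage order: filter → normalize → differential → cluster → enrich →
egonet → classify.  Every intermediate table is written to the output
directory as TSV; the manifest records per-stage record counts, status and
wall timestamps.  Given identical inputs, config and seed, all result
tables are byte-identical (timestamps live only in the manifest).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as clf
from . import diffmeth, egonet, enrichment, preprocess
from .config import PipelineConfig
from .io import (
    BetaMatrix,
    read_beta_matrix,
    read_gene_sets,
    read_network_edges,
    read_probe_annotation,
    read_sample_groups,
    write_beta_matrix,
)

__all__ = ["RunManifest", "StageRecord", "PipelineError", "run_pipeline"]

logger = logging.getLogger("methego")

STAGES = ("filter", "normalize", "differential", "cluster", "enrich", "egonet",
          "classify")

FLOAT_FORMAT = "%.10g"


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class StageRecord:
    name: str
    status: str = "pending"  # pending | completed | skipped
    n_in: int = 0
    n_out: int = 0
    outputs: list[str] = field(default_factory=list)
    started: float | None = None
    finished: float | None = None
    note: str = ""


@dataclass
class RunManifest:
    seed: int
    stages: list[StageRecord] = field(default_factory=list)
    status: str = "running"
    inputs: dict[str, str] = field(default_factory=dict)

    def stage(self, name: str) -> StageRecord:
        return next(s for s in self.stages if s.name == name)

    @property
    def completed_stages(self) -> list[str]:
        return [s.name for s in self.stages if s.status == "completed"]

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "status": self.status,
                "inputs": self.inputs,
                "stages": [vars(s) for s in self.stages],
            },
            indent=2,
        )

    def write(self, path: Path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def _write_tsv(df: pd.DataFrame, path: Path, index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, na_rep=".",
              index=index_label is not None, index_label=index_label)


def run_pipeline(config: PipelineConfig, beta_path: str | Path,
                 annot_path: str | Path, groups_path: str | Path,
                 edges_path: str | Path, gmt_path: str | Path,
                 out_dir: str | Path) -> RunManifest:
    """Execute every stage on the given input files.

    Degenerate intermediate results (no differential CpGs, or an empty
    target subnetwork) terminate the run gracefully: the manifest carries
    an explicit status and downstream stages are marked skipped.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=config.rng_seed)
    manifest.inputs = {
        "beta": str(beta_path), "annot": str(annot_path), "groups": str(groups_path),
        "edges": str(edges_path), "gmt": str(gmt_path),
    }
    manifest.stages = [StageRecord(name) for name in STAGES]

    def _run(name: str, fn):
        rec = manifest.stage(name)
        rec.started = time.time()
        try:
            fn(rec)
        except _GracefulStop:
            raise
        except Exception as exc:
            manifest.status = f"failed at {name}"
            manifest.write(out / "manifest.json")
            raise PipelineError(name, exc) from exc
        rec.finished = time.time()
        rec.status = "completed"
        logger.info("stage %s: %d -> %d records", name, rec.n_in, rec.n_out)

    class _GracefulStop(Exception):
        pass

    beta = read_beta_matrix(beta_path)
    groups = read_sample_groups(groups_path)
    beta = beta.with_groups(groups)
    annot = read_probe_annotation(annot_path)
    edges = read_network_edges(edges_path)
    gene_sets = read_gene_sets(gmt_path)

    state: dict = {}

    def filter_stage(rec: StageRecord) -> None:
        rec.n_in = beta.shape[0]
        report = preprocess.filter_probes(annot, maf_rule=config.maf_rule)
        present = set(beta.probes)
        kept = [p for p in report.kept_probes if p in present]
        filtered = BetaMatrix(beta.data.loc[kept], beta.groups)
        write_beta_matrix(filtered, out / "filtered_beta.tsv")
        rep = pd.DataFrame(
            [(c, report.removed_by[c]) for c in preprocess.CRITERIA_ORDER]
            + [("kept", len(report.kept_probes)), ("input", report.input_count)],
            columns=["criterion", "count"],
        )
        _write_tsv(rep, out / "filter_report.tsv")
        state["beta"] = filtered
        state["filter_report"] = report
        rec.n_out = filtered.shape[0]
        rec.outputs = ["filtered_beta.tsv", "filter_report.tsv"]

    def normalize_stage(rec: StageRecord) -> None:
        b = state["beta"]
        rec.n_in = b.shape[0]
        normalized, _info = preprocess.normalize_typeII(b, annot)
        write_beta_matrix(normalized, out / "normalized_beta.tsv")
        state["beta"] = normalized
        rec.n_out = normalized.shape[0]
        rec.outputs = ["normalized_beta.tsv"]

    def differential_stage(rec: StageRecord) -> None:
        b = state["beta"]
        rec.n_in = b.shape[0]
        calls = diffmeth.test_differential(b, method=config.ttest)
        diffmeth.stage1_select(calls, config)
        kept, attrition = diffmeth.stage2_refine(calls, config)
        _write_tsv(calls, out / "diffcalls.tsv", index_label="probe_id")
        diff_probes = pd.DataFrame({"probe_id": sorted(kept)})
        _write_tsv(diff_probes, out / "differential_probes.tsv")
        gene_map = annot.table["gene"]
        diff_genes = sorted(gene_map.loc[sorted(kept)].unique()) if len(kept) else []
        _write_tsv(pd.DataFrame({"gene": diff_genes}), out / "differential_genes.tsv")
        state["calls"] = calls
        state["diff_probes"] = sorted(kept)
        state["diff_genes"] = diff_genes
        rec.n_out = len(kept)
        rec.outputs = ["diffcalls.tsv", "differential_probes.tsv",
                       "differential_genes.tsv"]
        if len(kept) == 0:
            rec.finished = time.time()
            rec.status = "completed"
            rec.note = "no differential CpGs"
            raise _GracefulStop("no differential CpGs")

    def cluster_stage(rec: StageRecord) -> None:
        b = state["beta"]
        sub = BetaMatrix(b.data.loc[state["diff_probes"]], b.groups)
        rec.n_in = sub.shape[0]
        if sub.shape[0] < 2:
            rec.note = "fewer than 2 differential CpGs; clustering skipped"
            rec.n_out = 0
            return
        result = diffmeth.cluster_samples(sub)
        lab = result.labels.rename("cluster").to_frame()
        lab["ari"] = result.ari
        _write_tsv(lab, out / "cluster_labels.tsv", index_label="sample")
        state["cluster"] = result
        rec.n_out = len(result.labels)
        rec.outputs = ["cluster_labels.tsv"]

    def enrich_stage(rec: StageRecord) -> None:
        gene_map = annot.table["gene"]
        universe = sorted(gene_map.loc[list(state["beta"].probes)].unique())
        rec.n_in = len(gene_sets)
        table = enrichment.fisher_enrich(state["diff_genes"], universe, gene_sets,
                                         config)
        _write_tsv(table, out / "enrichment.tsv")
        state["enrichment"] = table
        rec.n_out = len(table)
        rec.outputs = ["enrichment.tsv"]

    def egonet_stage(rec: StageRecord) -> None:
        rec.n_in = len(edges)
        try:
            subnet, node_table, gene_matrix = egonet.run_egonet(
                state["beta"], annot, state["calls"], edges,
                state["diff_genes"], config,
            )
        except egonet.EmptySubnetworkError:
            rec.finished = time.time()
            rec.status = "completed"
            rec.note = "empty target subnetwork"
            raise _GracefulStop("empty target subnetwork")
        _write_tsv(subnet.edges, out / "subnetwork_edges.tsv")
        _write_tsv(node_table, out / "ego_nodes.tsv", index_label="gene")
        state["subnet"] = subnet
        state["node_table"] = node_table
        state["gene_matrix"] = gene_matrix
        state["ego_genes"] = sorted(node_table.index[node_table["is_ego"]])
        rec.n_out = len(node_table)
        rec.outputs = ["subnetwork_edges.tsv", "ego_nodes.tsv"]

    def classify_stage(rec: StageRecord) -> None:
        gene_matrix = state["gene_matrix"]
        ego_genes = state["ego_genes"]
        rec.n_in = len(ego_genes)
        features = gene_matrix.loc[ego_genes]  # genes x samples
        b = state["beta"]
        plan = clf.split_samples(list(b.samples), b.groups,
                                 train_fraction=config.split_train_fraction,
                                 seed=config.stage_seed(STAGES.index("classify")))
        labels = sorted(b.groups.unique())
        positive = "tumor" if "tumor" in labels else labels[0]
        X_train = features[plan.train].to_numpy().T
        X_test = features[plan.test].to_numpy().T
        y_train = b.groups.loc[plan.train].to_numpy()
        y_test = b.groups.loc[plan.test].to_numpy()
        fitted = clf.train_linear_svm(
            X_train, y_train, positive_label=positive, cv_folds=config.cv_folds,
            seed=config.stage_seed(STAGES.index("classify")),
            standardize=config.standardize,
        )
        report, scores = clf.evaluate(fitted, X_test, y_test)
        _write_tsv(report.to_series().rename("value").to_frame(),
                   out / "classification_report.tsv", index_label="metric")
        score_df = pd.DataFrame({"sample": plan.test, "group": y_test,
                                 "score": scores})
        _write_tsv(score_df, out / "test_scores.tsv")
        state["classification"] = report
        rec.n_out = len(plan.test)
        rec.outputs = ["classification_report.tsv", "test_scores.tsv"]

    stage_fns = {
        "filter": filter_stage,
        "normalize": normalize_stage,
        "differential": differential_stage,
        "cluster": cluster_stage,
        "enrich": enrich_stage,
        "egonet": egonet_stage,
        "classify": classify_stage,
    }
    try:
        for name in STAGES:
            _run(name, stage_fns[name])
    except _GracefulStop as stop:
        for srec in manifest.stages:
            if srec.status == "pending":
                srec.status = "skipped"
                srec.note = str(stop)
        manifest.status = str(stop)
        manifest.write(out / "manifest.json")
        manifest.state = state  # type: ignore[attr-defined]
        return manifest

    manifest.status = "completed"
    manifest.write(out / "manifest.json")
    manifest.state = state  # type: ignore[attr-defined]
    return manifest
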