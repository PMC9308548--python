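"""Two-stage differential-methylation calling and sample clustering.

Stage 1 keeps CpGs with t-test p < stage1_p and mean-difference
A > stage1_delta.  Stage 2 refines to CpGs with methylation score > 50,
p < 0.001, |t| > 3, A >= 0.17 and BH-adjusted q < 0.05.  The surviving
CpGs feed unsupervised hierarchical clustering of samples (Euclidean
distance, average linkage / UPGMA).

Interpretation notes:
"methylation score" is read as 100 x max(group mean β) — substantially
methylated in at least one group; "absolute value > 3" is read as the
|t-statistic|; the A threshold "≥ 17" is read as 17 percentage points,
i.e. 0.17 in β-fraction units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import t as t_dist
from sklearn.metrics import adjusted_rand_score

from .config import PipelineConfig
from .io import BetaMatrix

__all__ = ["test_differential", "bh_adjust", "stage1_select", "stage2_refine",
           "cluster_samples", "ClusterResult"]

logger = logging.getLogger("methego")

STAGE2_CRITERIA = ("methylation_score", "p_value", "t_stat", "A", "q_value")


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment.

    q_(i) = min over j >= i of p_(j) * n / j, clipped at 1; empty input
    yields an empty result.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def _welch(case: np.ndarray, ctrl: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n1, n2 = case.shape[1], ctrl.shape[1]
    m1 = case.mean(axis=1)
    m2 = ctrl.mean(axis=1)
    v1 = case.var(axis=1, ddof=1)
    v2 = ctrl.var(axis=1, ddof=1)
    se2 = v1 / n1 + v2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / (v1**2 / (n1**2 * (n1 - 1)) + v2**2 / (n2**2 * (n2 - 1)))
    return t, df, se2


def _pooled(case: np.ndarray, ctrl: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n1, n2 = case.shape[1], ctrl.shape[1]
    m1 = case.mean(axis=1)
    m2 = ctrl.mean(axis=1)
    v1 = case.var(axis=1, ddof=1)
    v2 = ctrl.var(axis=1, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    se2 = sp2 * (1 / n1 + 1 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
    df = np.full_like(t, float(n1 + n2 - 2))
    return t, df, se2


def test_differential(beta: BetaMatrix, groups: pd.Series | None = None,
                      case_label: str | None = None,
                      method: str = "welch") -> pd.DataFrame:
    """Per-probe two-sample t-test between case and control samples.

    Returns a DataFrame indexed by probe with columns mean_case,
    mean_control, A (|mean difference|), t_stat, p_value, q_value,
    methylation_score (100 x max group mean), direction (hyper/hypo,
    case vs control) and a degenerate flag for zero-variance probes.
    """
    if groups is None:
        groups = beta.groups
    if groups is None:
        raise ValueError("no group labels supplied")
    groups = groups.loc[beta.samples]
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {labels}")
    if case_label is None:
        # convention: "tumor" beats alphabetical order if present
        case_label = "tumor" if "tumor" in labels else labels[0]
    control_label = next(l for l in labels if l != case_label)
    case_cols = groups.index[groups == case_label]
    ctrl_cols = groups.index[groups == control_label]
    if len(case_cols) < 2 or len(ctrl_cols) < 2:
        raise ValueError("need at least 2 samples per group")

    case = beta.data[case_cols].to_numpy()
    ctrl = beta.data[ctrl_cols].to_numpy()
    stat_fn = _welch if method == "welch" else _pooled
    t, df, se2 = stat_fn(case, ctrl)

    m1 = case.mean(axis=1)
    m2 = ctrl.mean(axis=1)
    diff = m1 - m2
    degenerate = se2 == 0
    # zero variance in both groups: equal means -> p = 1; unequal -> p = 0
    with np.errstate(invalid="ignore"):
        t = np.where(degenerate & (diff == 0), 0.0, t)
        t = np.where(degenerate & (diff != 0), np.sign(diff) * np.inf, t)
    with np.errstate(invalid="ignore"):
        p = 2.0 * t_dist.sf(np.abs(t), np.where(degenerate, 1.0, df))
    p = np.where(degenerate & (diff == 0), 1.0, p)
    p = np.where(degenerate & (diff != 0), 0.0, p)

    calls = pd.DataFrame(
        {
            "mean_case": m1,
            "mean_control": m2,
            "A": np.abs(diff),
            "t_stat": t,
            "p_value": p,
            "q_value": bh_adjust(p),
            "methylation_score": 100.0 * np.maximum(m1, m2),
            "direction": np.where(diff > 0, "hyper", "hypo"),
            "degenerate": degenerate,
        },
        index=beta.probes,
    )
    n_deg = int(degenerate.sum())
    if n_deg:
        logger.info("test_differential: %d degenerate zero-variance probes", n_deg)
    return calls


def stage1_select(calls: pd.DataFrame, config: PipelineConfig) -> pd.Index:
    """Stage-1 selection: p < stage1_p AND A > stage1_delta.

    Adds/overwrites a ``stage1_pass`` column on ``calls`` and returns the
    index of kept probes.
    """
    keep = (calls["p_value"] < config.stage1_p) & (calls["A"] > config.stage1_delta)
    calls["stage1_pass"] = keep
    kept = calls.index[keep]
    logger.info("stage1_select: %d / %d probes pass (p<%g, A>%g)",
                len(kept), len(calls), config.stage1_p, config.stage1_delta)
    return kept


def stage2_refine(calls: pd.DataFrame,
                  config: PipelineConfig) -> tuple[pd.Index, dict[str, int]]:
    """Stage-2 refinement of the stage-1 set.

    Keeps stage-1 probes with methylation_score > stage2_score AND
    p < stage2_p AND |t| > stage2_tstat AND A >= stage2_delta AND
    q < stage2_q.  Returns the kept index and per-criterion attrition
    counts (number of stage-1 probes failing each criterion).
    """
    if "stage1_pass" not in calls.columns:
        stage1_select(calls, config)
    s1 = calls["stage1_pass"]
    crit = {
        "methylation_score": calls["methylation_score"] > config.stage2_score,
        "p_value": calls["p_value"] < config.stage2_p,
        "t_stat": calls["t_stat"].abs() > config.stage2_tstat,
        "A": calls["A"] >= config.stage2_delta,
        "q_value": calls["q_value"] < config.stage2_q,
    }
    keep = s1.copy()
    attrition: dict[str, int] = {}
    for name in STAGE2_CRITERIA:
        attrition[name] = int((s1 & ~crit[name]).sum())
        keep &= crit[name]
    calls["stage2_pass"] = keep
    kept = calls.index[keep]
    logger.info("stage2_refine: %d / %d stage-1 probes remain (attrition %s)",
                len(kept), int(s1.sum()), attrition)
    return kept, attrition


@dataclass
class ClusterResult:
    """UPGMA clustering of samples on the differential CpGs."""

    linkage_matrix: np.ndarray  # scipy hierarchical-linkage encoding
    sample_order: list[str]
    labels: pd.Series  # sample -> cluster id in {1, 2}
    ari: float  # adjusted Rand index vs the known groups

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]


def cluster_samples(beta: BetaMatrix, groups: pd.Series | None = None) -> ClusterResult:
    """Agglomerative clustering of samples: Euclidean distance, average linkage.

    Samples are sorted by ID first so distance ties resolve
    deterministically.  The dendrogram is cut into two clusters and scored
    against the known groups with the adjusted Rand index.
    """
    if groups is None:
        groups = beta.groups
    if beta.shape[0] < 2:
        raise ValueError("need at least 2 CpGs to cluster")
    if beta.shape[1] < 3:
        raise ValueError("need at least 3 samples to cluster")
    order = sorted(beta.samples)
    X = beta.data[order].to_numpy().T  # samples x probes
    Z = linkage(X, method="average", metric="euclidean")
    labels = pd.Series(fcluster(Z, t=2, criterion="maxclust"), index=order, name="cluster")
    ari = float("nan")
    if groups is not None:
        ari = float(adjusted_rand_score(groups.loc[order].to_numpy(), labels.to_numpy()))
    return ClusterResult(Z, order, labels, ari)
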