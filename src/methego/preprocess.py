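"""Probe QC filtering and β-mixture quantile normalization.

The filter cascade removes probes that sit within 2 bp of a SNP, fail the
MAF rule, cross-hybridize, or map to a sex chromosome.  Normalization fits
a three-component beta mixture (unmethylated / hemimethylated /
methylated) to each probe design class per sample and quantile-maps the
class-II component distributions onto their class-I counterparts, undoing
the class-II compression toward 0.5.

Note on the MAF rule: the default removes probes with MAF < 0.05,
which inverts the conventional direction (removing probes with a *common*
variant under the probe).  ``maf_rule="conventional"`` flips it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import betaln, logsumexp, polygamma, psi
from scipy.stats import beta as beta_dist

from .io import BetaMatrix, ProbeAnnotation, SEX_CHROMS

__all__ = ["FilterReport", "MixtureFit", "filter_probes", "fit_beta_mixture",
           "normalize_typeII"]

logger = logging.getLogger("methego")

EPS = 1e-6
CRITERIA_ORDER = ("snp_proximity", "low_maf", "cross_hyb", "sex_chromosome")


@dataclass
class FilterReport:
    """Accounting of the QC filter cascade.

    ``removed_by`` attributes each removed probe to the *first* matching
    criterion in the order snp_proximity → low_maf → cross_hyb →
    sex_chromosome; removal itself is the union of all four rules.
    """

    input_count: int
    removed_by: dict[str, int]
    kept_probes: list[str]
    removed_probes: dict[str, str]  # probe -> first matching criterion
    n_missing_defaulted: int = 0

    @property
    def removed_count(self) -> int:
        return sum(self.removed_by.values())

    def validate(self) -> None:
        assert len(self.kept_probes) + self.removed_count == self.input_count


def filter_probes(annot: ProbeAnnotation, maf_rule: str = "as_printed") -> FilterReport:
    """Apply the four-rule QC cascade to a probe annotation table.

    A probe is removed iff snp_distance <= 2 OR it fails the MAF rule OR
    cross_hyb is set OR it lies on a sex chromosome.  Missing
    snp_distance/MAF values default to "keep" (logged), so unannotated
    probes are never silently dropped.
    """
    if maf_rule not in ("as_printed", "conventional"):
        raise ValueError(f"unknown maf_rule {maf_rule!r}")
    t = annot.table
    snp_missing = t["snp_distance"].isna()
    maf_missing = t["maf"].isna()
    n_missing = int((snp_missing | maf_missing).sum())
    if n_missing:
        logger.info("filter_probes: %d probes with missing QC fields kept by default",
                    n_missing)

    fail_snp = (t["snp_distance"] <= 2) & ~snp_missing
    if maf_rule == "as_printed":
        fail_maf = (t["maf"] < 0.05) & ~maf_missing
    else:
        fail_maf = (t["maf"] >= 0.05) & ~maf_missing
    fail_cross = t["cross_hyb"].fillna(0).astype(int) == 1
    fail_sex = t["chrom"].isin(SEX_CHROMS)

    removed_by = {c: 0 for c in CRITERIA_ORDER}
    removed: dict[str, str] = {}
    masks = dict(zip(CRITERIA_ORDER, (fail_snp, fail_maf, fail_cross, fail_sex)))
    assigned = pd.Series(False, index=t.index)
    for crit in CRITERIA_ORDER:
        hit = masks[crit] & ~assigned
        removed_by[crit] = int(hit.sum())
        for p in t.index[hit]:
            removed[p] = crit
        assigned |= masks[crit]
    kept = [p for p in t.index if p not in removed]

    report = FilterReport(
        input_count=len(t),
        removed_by=removed_by,
        kept_probes=kept,
        removed_probes=removed,
        n_missing_defaulted=n_missing,
    )
    report.validate()
    logger.info("filter_probes: kept %d / %d probes (removed %s)",
                len(kept), len(t), removed_by)
    return report


# --------------------------------------------------------------------------
# beta-mixture EM


@dataclass
class MixtureFit:
    """A fitted beta mixture with components ordered by ascending mean."""

    a: np.ndarray
    b: np.ndarray
    weights: np.ndarray
    loglik_trace: list[float]
    n_iter: int
    degenerate: bool = False

    @property
    def k(self) -> int:
        return len(self.weights)

    @property
    def means(self) -> np.ndarray:
        return self.a / (self.a + self.b)

    def responsibilities(self, x: np.ndarray) -> np.ndarray:
        """Posterior component probabilities, shape (k, n)."""
        x = _clip_unit(x)
        log_r = _component_logpdf(x, self.a, self.b) + np.log(self.weights)[:, None]
        return np.exp(log_r - logsumexp(log_r, axis=0))


def _clip_unit(x: np.ndarray) -> np.ndarray:
    return np.clip(np.asarray(x, dtype=float), EPS, 1.0 - EPS)


def _component_logpdf(x: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = a[:, None]
    b = b[:, None]
    return (a - 1) * np.log(x)[None, :] + (b - 1) * np.log1p(-x)[None, :] - betaln(a, b)


def _moment_estimate(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    wsum = w.sum()
    m = float((w * x).sum() / wsum)
    v = float((w * (x - m) ** 2).sum() / wsum)
    m = min(max(m, 1e-3), 1 - 1e-3)
    v = max(v, 1e-8)
    s = max(m * (1 - m) / v - 1.0, 1e-2)
    return m * s, (1 - m) * s


def _weighted_beta_mle(x: np.ndarray, w: np.ndarray,
                       a0: float, b0: float) -> tuple[float, float]:
    """Weighted beta MLE by Newton iteration on the digamma equations.

    Solves psi(a) − psi(a+b) = ⟨log x⟩_w and psi(b) − psi(a+b) = ⟨log 1−x⟩_w.
    Falls back to the weighted moment estimate if Newton fails.
    """
    wsum = w.sum()
    if wsum <= 0:
        return a0, b0
    t1 = float((w * np.log(x)).sum() / wsum)
    t2 = float((w * np.log1p(-x)).sum() / wsum)
    a, b = max(a0, 1e-3), max(b0, 1e-3)
    for _ in range(60):
        f1 = psi(a) - psi(a + b) - t1
        f2 = psi(b) - psi(a + b) - t2
        if abs(f1) < 1e-12 and abs(f2) < 1e-12:
            break
        tri_ab = polygamma(1, a + b)
        j11 = polygamma(1, a) - tri_ab
        j22 = polygamma(1, b) - tri_ab
        det = j11 * j22 - tri_ab * tri_ab
        if not np.isfinite(det) or abs(det) < 1e-300:
            return _moment_estimate(x, w)
        da = -(f1 * j22 + f2 * tri_ab) / det
        db = -(f2 * j11 + f1 * tri_ab) / det
        step = 1.0
        while (a + step * da <= 1e-4 or b + step * db <= 1e-4) and step > 1e-8:
            step *= 0.5
        a += step * da
        b += step * db
        if not (np.isfinite(a) and np.isfinite(b)):
            return _moment_estimate(x, w)
        a = min(a, 1e6)
        b = min(b, 1e6)
    return a, b


def fit_beta_mixture(values: np.ndarray, k: int = 3, tol: float = 1e-6,
                     max_iter: int = 500) -> MixtureFit:
    """Fit a k-component beta mixture by EM.

    Initialization is deterministic: component means at the 10th/50th/90th
    percentiles (for k = 3; evenly spaced quantiles otherwise) with equal
    weights and initial precision 10, so repeated fits and input
    permutations give identical results.  Components whose weight falls
    below 1e-4 are merged away and the fit restarts with k − 1 (flagged
    degenerate).
    """
    x = _clip_unit(np.asarray(values, dtype=float).ravel())
    n = x.size
    if n < 50:
        raise ValueError(f"need at least 50 values to fit a mixture, got {n}")
    if np.ptp(x) < 1e-10:
        m = min(max(float(x[0]), 1e-3), 1 - 1e-3)
        s = 1e4
        return MixtureFit(np.array([m * s]), np.array([(1 - m) * s]),
                          np.array([1.0]), [], 0, degenerate=True)

    if k == 3:
        q = (0.10, 0.50, 0.90)
    else:
        q = tuple((i + 1) / (k + 1) for i in range(k))
    m0 = np.clip(np.quantile(x, q), 0.02, 0.98)
    s0 = 10.0
    a = m0 * s0
    b = (1.0 - m0) * s0
    w = np.full(k, 1.0 / k)

    trace: list[float] = []
    ll_prev = -np.inf
    degenerate = False
    for it in range(1, max_iter + 1):
        log_r = _component_logpdf(x, a, b) + np.log(w)[:, None]
        log_norm = logsumexp(log_r, axis=0)
        ll = float(log_norm.sum())
        trace.append(ll)
        resp = np.exp(log_r - log_norm)
        w = resp.mean(axis=1)
        if k > 1 and (w < 1e-4).any():
            sub = fit_beta_mixture(values, k=k - 1, tol=tol, max_iter=max_iter)
            sub.degenerate = True
            return sub
        for j in range(k):
            a[j], b[j] = _weighted_beta_mle(x, resp[j], a[j], b[j])
        if ll - ll_prev < tol and it > 1:
            break
        ll_prev = ll

    order = np.argsort(a / (a + b))
    return MixtureFit(a[order], b[order], w[order], trace, it, degenerate=degenerate)


# --------------------------------------------------------------------------
# quantile normalization of class-II probes


def _map_components(fit_from: MixtureFit, fit_to: MixtureFit) -> list[tuple[int, int]]:
    # components are mean-ordered; pair by rank, clamping if the fits
    # collapsed to different component counts
    return [(j, min(j, fit_to.k - 1)) for j in range(fit_from.k)]


def normalize_typeII(beta: BetaMatrix, annot: ProbeAnnotation,
                     min_class: int = 50) -> tuple[BetaMatrix, dict[str, dict]]:
    """Quantile-map class-II β-values onto the class-I mixture, per sample.

    For each sample the class-I and class-II probe values are fitted with
    separate three-component beta mixtures; every class-II value is
    assigned to its maximum-responsibility component k and transformed via
    u = F_IIk(β), β′ = F⁻¹_Ik(u).  Class-I values are never altered.
    Samples where either class has fewer than ``min_class`` probes are
    passed through unchanged with a warning.
    """
    t = annot.table.reindex(beta.probes)
    typeI = beta.probes[(t["design_type"] == "I").to_numpy()]
    typeII = beta.probes[(t["design_type"] == "II").to_numpy()]
    out = beta.data.copy()
    info: dict[str, dict] = {}
    for sample in beta.samples:
        col = beta.data[sample]
        x1 = col.loc[typeI].dropna().to_numpy()
        x2 = col.loc[typeII].dropna().to_numpy()
        if len(x1) < min_class or len(x2) < min_class:
            logger.warning("normalize_typeII: sample %s skipped "
                           "(class sizes %d / %d)", sample, len(x1), len(x2))
            info[sample] = {"skipped": True}
            continue
        fit1 = fit_beta_mixture(x1)
        fit2 = fit_beta_mixture(x2)
        x2_idx = col.loc[typeII].dropna().index
        x2c = _clip_unit(col.loc[x2_idx].to_numpy())
        comp = fit2.responsibilities(x2c).argmax(axis=0)
        mapped = np.empty_like(x2c)
        pairing = _map_components(fit2, fit1)
        for j, j_to in pairing:
            mask = comp == j
            if not mask.any():
                continue
            u = beta_dist.cdf(x2c[mask], fit2.a[j], fit2.b[j])
            mapped[mask] = beta_dist.ppf(u, fit1.a[j_to], fit1.b[j_to])
        mapped = np.clip(mapped, 0.0, 1.0)
        out.loc[x2_idx, sample] = mapped
        info[sample] = {
            "skipped": False,
            "fit_typeI": fit1,
            "fit_typeII": fit2,
        }
    return BetaMatrix(out, beta.groups), info
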