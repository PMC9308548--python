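"""Fisher's-exact (hypergeometric) over-representation analysis.

One-sided over-representation tail: with a universe of N genes of which K
are differential, a set of n genes and an observed overlap x, the p-value
is P(X >= x) for X ~ Hypergeometric(N, K, n).  p-values are BH-adjusted
across all tested sets and rows are sorted by ascending FDR.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom

from .config import PipelineConfig
from .diffmeth import bh_adjust

__all__ = ["fisher_enrich", "apply_significance"]

logger = logging.getLogger("methego")


def fisher_enrich(diff_genes: Iterable[str], universe: Iterable[str],
                  gene_sets: Mapping[str, list[str]],
                  config: PipelineConfig | None = None) -> pd.DataFrame:
    """Test every gene set for over-representation of differential genes.

    Sets are intersected with the universe before testing; sets with no
    members in the universe are skipped with a warning.  Returns one row
    per tested set: name, set_size, diff_count, overlap, p_value, fdr,
    significant — sorted by ascending FDR (ties by p, then name).
    """
    config = config or PipelineConfig()
    universe = set(universe)
    diff = set(diff_genes)
    stray = diff - universe
    if stray:
        raise ValueError(f"differential genes outside the universe: {sorted(stray)[:5]}")
    N = len(universe)
    K = len(diff)

    rows = []
    for name, members in gene_sets.items():
        in_univ = universe.intersection(members)
        n = len(in_univ)
        if n == 0:
            logger.warning("fisher_enrich: set %r has no members in the universe; skipped",
                           name)
            continue
        overlap = len(diff.intersection(in_univ))
        p = float(hypergeom.sf(overlap - 1, N, K, n))
        p = min(p, 1.0)
        rows.append((name, n, K, overlap, p))
    table = pd.DataFrame(rows, columns=["set", "set_size", "diff_count", "overlap",
                                        "p_value"])
    if len(table):
        table["fdr"] = bh_adjust(table["p_value"].to_numpy())
    else:
        table["fdr"] = pd.Series(dtype=float)
    table["significant"] = (table["fdr"] < config.enrich_fdr) & \
        (table["overlap"] > config.enrich_min_count)
    table = table.sort_values(["fdr", "p_value", "set"], kind="stable")
    return table.reset_index(drop=True)


def apply_significance(rows: pd.DataFrame,
                       config: PipelineConfig | None = None) -> pd.DataFrame:
    """Subset to rows with fdr < enrich_fdr AND overlap > enrich_min_count."""
    config = config or PipelineConfig()
    keep = (rows["fdr"] < config.enrich_fdr) & (rows["overlap"] > config.enrich_min_count)
    return rows[keep].reset_index(drop=True)
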