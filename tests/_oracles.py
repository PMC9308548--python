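"""Independent oracles shared by the unit and acceptance suites.

Everything here is deliberately coded from first principles (brute force,
exact rational arithmetic, exhaustive enumeration) and must stay decoupled
from the package implementations it checks.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction
from math import comb

import networkx as nx
import numpy as np


def welch_oracle(x, y) -> tuple[float, float]:
    """Textbook Welch t-test on two small samples."""
    from scipy.stats import t as t_dist
    n1, n2 = len(x), len(y)
    v1 = sum((xi - sum(x) / n1) ** 2 for xi in x) / (n1 - 1)
    v2 = sum((yi - sum(y) / n2) ** 2 for yi in y) / (n2 - 1)
    se2 = v1 / n1 + v2 / n2
    t = (sum(x) / n1 - sum(y) / n2) / math.sqrt(se2)
    df = se2**2 / (v1**2 / (n1**2 * (n1 - 1)) + v2**2 / (n2**2 * (n2 - 1)))
    return t, 2 * t_dist.sf(abs(t), df)


def bh_step_up_oracle(p: np.ndarray) -> np.ndarray:
    """Literal step-up procedure with explicit loops."""
    p = list(map(float, p))
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    q = [0.0] * n
    running_min = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * n / rank)
        q[i] = min(running_min, 1.0)
    return np.array(q)


def hypergeom_tail_exact(N: int, K: int, n: int, x: int) -> float:
    """P(X >= x) for X ~ Hypergeometric(N, K, n), exact rational arithmetic."""
    total = comb(N, n)
    acc = Fraction(0)
    for k in range(x, min(K, n) + 1):
        acc += Fraction(comb(K, k) * comb(N - K, n - k), total)
    return float(acc)


def trapezoid_auc(scores: np.ndarray, y_positive: np.ndarray) -> float:
    """AUC by trapezoidal integration of the empirical ROC curve."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y_positive, dtype=bool)
    thresholds = np.unique(scores)[::-1]
    tpr = [0.0]
    fpr = [0.0]
    for thr in thresholds:
        pred = scores >= thr
        tpr.append((pred & y).sum() / y.sum())
        fpr.append((pred & ~y).sum() / (~y).sum())
    return float(np.trapezoid(tpr, fpr))


def brute_force_topology(g: nx.Graph) -> dict[str, dict]:
    """Exhaustive-path node metrics (degree, closeness, betweenness, local
    clustering) for graphs with at most ~8 nodes."""
    nodes = list(g.nodes)

    def all_paths(s, t):
        paths = []

        def dfs(v, seen):
            if v == t:
                paths.append(list(seen))
                return
            for w in g.neighbors(v):
                if w not in seen:
                    dfs(w, seen + [w])

        dfs(s, [s])
        return paths

    degree = {v: g.degree(v) for v in nodes}
    closeness, betweenness, transitivity = {}, {}, {}
    shortest = {}
    for s, t in itertools.permutations(nodes, 2):
        paths = all_paths(s, t)
        if paths:
            d = min(len(p) - 1 for p in paths)
            shortest[(s, t)] = [p for p in paths if len(p) - 1 == d]
    for v in nodes:
        reach = [t for t in nodes if (v, t) in shortest]
        total = sum(len(shortest[(v, t)][0]) - 1 for t in reach)
        closeness[v] = len(reach) / total if total else 0.0
        bet = 0.0
        for s, t in itertools.combinations(nodes, 2):
            if s == v or t == v or (s, t) not in shortest:
                continue
            sp = shortest[(s, t)]
            bet += sum(v in p for p in sp) / len(sp)
        betweenness[v] = bet
        nbrs = list(g.neighbors(v))
        if len(nbrs) < 2:
            transitivity[v] = 0.0
        else:
            links = sum(g.has_edge(a, b)
                        for a, b in itertools.combinations(nbrs, 2))
            transitivity[v] = links / math.comb(len(nbrs), 2)
    return {"degree": degree, "closeness": closeness,
            "betweenness": betweenness, "transitivity": transitivity}
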