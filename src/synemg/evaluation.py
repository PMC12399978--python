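"""Agreement metrics and the statistical comparisons used in reporting.

Moment-tracking agreement is summarized by range-normalized errors,

    %RMSE = sqrt(mean((exp - mod)^2)) / (max(exp) - min(exp))
    %MAE  =      mean(|exp - mod|)    / (max(exp) - min(exp)),

plus the Pearson correlation r.  Activation-prediction agreement uses raw
RMSE / r / MAE (activations are already dimensionless in [0, 1]).

Group comparisons: paired t-tests for calibration-vs-validation metrics;
Kruskal-Wallis followed by Dunn's post-hoc z-tests on mean ranks (tie
corrected) for method/synergy-number comparisons.  Dunn p-values are
unadjusted by default, with Bonferroni/Holm available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["rmse", "mae", "pct_rmse", "pct_mae", "pearson_r",
           "paired_t", "kruskal_dunn", "StatTestResult"]


def _pair(exp, mod):
    exp = np.asarray(exp, dtype=float).ravel()
    mod = np.asarray(mod, dtype=float).ravel()
    if exp.shape != mod.shape or exp.size < 2:
        raise ValueError("series must share a length of at least 2")
    return exp, mod


def rmse(exp, mod) -> float:
    exp, mod = _pair(exp, mod)
    return float(np.sqrt(np.mean((exp - mod) ** 2)))


def mae(exp, mod) -> float:
    exp, mod = _pair(exp, mod)
    return float(np.mean(np.abs(exp - mod)))


def _range(exp) -> float:
    r = float(np.max(exp) - np.min(exp))
    if r <= 0:
        raise ValueError("constant reference series: range normalization undefined")
    return r


def pct_rmse(exp, mod) -> float:
    """RMSE normalized by the range of the reference series."""
    exp, mod = _pair(exp, mod)
    return rmse(exp, mod) / _range(exp)


def pct_mae(exp, mod) -> float:
    """MAE normalized by the range of the reference series."""
    exp, mod = _pair(exp, mod)
    return mae(exp, mod) / _range(exp)


def pearson_r(x, y) -> float:
    """Product-moment correlation; errors on constant input."""
    x, y = _pair(x, y)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant series: correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


@dataclass
class StatTestResult:
    test: str
    statistic: float
    pvalue: float
    pairwise: dict = field(default_factory=dict)   # (i, j) -> p-value
    pairwise_z: dict = field(default_factory=dict)
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.pvalue < self.alpha

    def significant_pairs(self) -> list:
        return [pair for pair, p in self.pairwise.items() if p < self.alpha]


def paired_t(a, b, alpha: float = 0.05) -> StatTestResult:
    """Two-sided paired t-test; errors on degenerate (zero-variance) differences."""
    a, b = _pair(a, b)
    d = a - b
    if np.allclose(a, b):
        return StatTestResult("paired t", 0.0, 1.0, alpha=alpha)
    if np.std(d, ddof=1) == 0:
        raise ValueError("zero-variance differences: paired t-test degenerate")
    res = stats.ttest_rel(a, b)
    return StatTestResult("paired t", float(res.statistic), float(res.pvalue),
                          alpha=alpha)


def _dunn(groups, alpha: float, adjust: str | None):
    """Dunn's post-hoc pairwise z-tests on mean ranks, tie-corrected."""
    pooled = np.concatenate(groups)
    N = pooled.size
    ranks = stats.rankdata(pooled)
    sizes = [g.size for g in groups]
    edges = np.cumsum([0] + sizes)
    mean_ranks = [ranks[edges[k]:edges[k + 1]].mean() for k in range(len(groups))]

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_term

    zs, ps = {}, {}
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se
            zs[(i, j)] = float(z)
            ps[(i, j)] = float(2 * stats.norm.sf(abs(z)))

    if adjust is not None:
        keys = list(ps)
        raw = np.array([ps[k] for k in keys])
        k = len(raw)
        if adjust == "bonferroni":
            adj = np.minimum(raw * k, 1.0)
        elif adjust == "holm":
            order = np.argsort(raw)
            adj = np.empty(k)
            running = 0.0
            for rank, idx in enumerate(order):
                running = max(running, raw[idx] * (k - rank))
                adj[idx] = min(running, 1.0)
        else:
            raise ValueError(f"unknown adjustment {adjust!r}")
        ps = {key: float(p) for key, p in zip(keys, adj)}
    return zs, ps


def kruskal_dunn(groups, alpha: float = 0.05,
                 adjust: str | None = None) -> StatTestResult:
    """Kruskal-Wallis H test with Dunn's post-hoc pairwise comparisons.

    ``groups`` is a sequence of 1-D samples (each with >= 2 observations).
    The H statistic is tie-corrected (scipy); pairwise Dunn z-tests use the
    tie-corrected rank variance.  Errors if all observations are identical.
    """
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need at least two groups with two observations each")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        raise ValueError("all observations identical: ranks undefined")
    H, p = stats.kruskal(*groups)
    zs, ps = _dunn(groups, alpha, adjust)
    return StatTestResult("kruskal-wallis + dunn", float(H), float(p),
                          pairwise=ps, pairwise_z=zs, alpha=alpha)
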