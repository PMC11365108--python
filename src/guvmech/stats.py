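"""Population statistics for per-vesicle measurements.

Group summaries use inverse-error weights w_i = 1/sigma_i (a reliability
convention stated with the source data; the conventional 1/sigma_i^2 is
available via ``weight_power=2``).  Group comparisons use the Kruskal-Wallis
rank test with tie correction (chi-square approximation) followed by Dunn's
pairwise z-tests on the pooled mid-ranks with Holm step-down adjustment.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, rankdata

from .exceptions import AnalysisError

__all__ = [
    "weighted_mean_sd",
    "kruskal_wallis",
    "posthoc_pairwise",
    "holm_adjust",
    "build_report",
    "StatsReport",
]


def weighted_mean_sd(values, errors, weight_power: int = 1):
    """Inverse-error weighted mean and weighted (frequency-form) SD.

    w_i = 1/sigma_i ** weight_power; mean = sum(w x)/sum(w);
    SD = sqrt(sum(w (x - mean)^2) / sum(w)).
    """
    x = np.asarray(values, dtype=np.float64)
    s = np.asarray(errors, dtype=np.float64)
    if x.size == 0:
        raise AnalysisError("no values")
    if np.any(s <= 0):
        raise AnalysisError("all errors must be positive for inverse-error weighting")
    w = 1.0 / s**weight_power
    mean = float(np.sum(w * x) / np.sum(w))
    sd = float(math.sqrt(np.sum(w * (x - mean) ** 2) / np.sum(w)))
    return mean, sd


def _tie_term(pooled: np.ndarray) -> float:
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(np.float64) ** 3 - counts))


def kruskal_wallis(groups):
    """Kruskal-Wallis H with tie correction and chi-square p-value.

    H = [12/(N(N+1)) * sum R_j^2/n_j - 3(N+1)] / (1 - sum(t^3 - t)/(N^3 - N))
    with mid-ranks for ties.  When all pooled values are identical the tie
    correction degenerates and H is defined as 0 with p = 1.
    """
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(groups) < 2 or any(g.size < 1 for g in groups):
        raise AnalysisError("need >= 2 non-empty groups")
    sizes = np.array([g.size for g in groups])
    n_total = int(sizes.sum())
    if n_total < 3:
        raise AnalysisError("need at least 3 observations in total")
    pooled = np.concatenate(groups)
    ranks = rankdata(pooled)  # mid-ranks
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    rank_sums = np.array(
        [ranks[bounds[i] : bounds[i + 1]].sum() for i in range(len(groups))]
    )
    h_raw = 12.0 / (n_total * (n_total + 1)) * np.sum(
        rank_sums**2 / sizes
    ) - 3.0 * (n_total + 1)
    correction = 1.0 - _tie_term(pooled) / (n_total**3 - n_total)
    if correction <= 0:  # all values identical
        return 0.0, 1.0
    h = float(h_raw / correction)
    h = max(h, 0.0)
    p = float(chi2.sf(h, len(groups) - 1))
    return h, p


def holm_adjust(pvalues):
    """Holm step-down adjustment (monotone, clipped at 1)."""
    p = np.asarray(pvalues, dtype=np.float64)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(running, 1.0)
    return adj


def posthoc_pairwise(groups, labels=None, alpha: float = 0.05) -> pd.DataFrame:
    """Dunn's pairwise z-tests on pooled mid-ranks, Holm-adjusted.

    Returns a DataFrame with one row per pair: z, raw and adjusted two-sided
    p-values, and a significance flag at ``alpha``.
    """
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(groups) < 2:
        raise AnalysisError("need >= 2 groups for post-hoc tests")
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    sizes = np.array([g.size for g in groups], dtype=np.float64)
    n_total = int(sizes.sum())
    pooled = np.concatenate(groups)
    ranks = rankdata(pooled)
    bounds = np.concatenate([[0], np.cumsum(sizes.astype(int))])
    mean_ranks = np.array(
        [ranks[bounds[i] : bounds[i + 1]].mean() for i in range(len(groups))]
    )
    tie = _tie_term(pooled)
    base_var = n_total * (n_total + 1) / 12.0 - tie / (12.0 * (n_total - 1))
    rows = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        se = math.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p_raw = 2.0 * float(norm.sf(abs(z)))
        rows.append(
            {"group_a": labels[i], "group_b": labels[j], "z": z, "p_raw": min(p_raw, 1.0)}
        )
    df = pd.DataFrame(rows)
    df["p_adj"] = holm_adjust(df["p_raw"].to_numpy())
    df["significant"] = df["p_adj"] < alpha
    return df


@dataclass(frozen=True)
class StatsReport:
    per_group: pd.DataFrame          # label, n, weighted_mean, weighted_sd
    h_statistic: float | None
    p_value: float | None
    pairwise: pd.DataFrame | None
    alpha: float = 0.05

    def to_text(self) -> str:
        lines = ["Group summary (inverse-error weighted)", "-" * 54]
        for r in self.per_group.itertuples(index=False):
            lines.append(
                f"{r.label:<18s} n={r.n:<4d} {r.weighted_mean:8.1f} +/- {r.weighted_sd:.1f}"
            )
        if self.h_statistic is not None:
            sig = "significant" if self.p_value < self.alpha else "n.s."
            lines.append("")
            lines.append(
                f"Kruskal-Wallis: H = {self.h_statistic:.4g}, p = {self.p_value:.4g} ({sig})"
            )
        if self.pairwise is not None and len(self.pairwise):
            lines.append("")
            lines.append("Post-hoc (Dunn, Holm-adjusted):")
            for r in self.pairwise.itertuples(index=False):
                mark = "*" if r.significant else "n.s."
                lines.append(
                    f"  {r.group_a} vs {r.group_b}: p_adj = {r.p_adj:.4g} {mark}"
                )
        return "\n".join(lines)


def build_report(
    measurements: pd.DataFrame,
    group_col: str = "group",
    value_col: str = "value",
    error_col: str = "error",
    alpha: float = 0.05,
    weight_power: int = 1,
) -> StatsReport:
    """Per-group weighted summaries plus the group-comparison statistics.

    ``measurements`` holds one row per vesicle.  Groups appear in input
    order; the comparison block is omitted when only one group is present.
    """
    if measurements.empty:
        raise AnalysisError("no measurements")
    labels = list(dict.fromkeys(measurements[group_col]))
    rows = []
    groups = []
    for label in labels:
        sub = measurements[measurements[group_col] == label]
        values = sub[value_col].to_numpy(dtype=float)
        errors = sub[error_col].to_numpy(dtype=float)
        if np.all(errors > 0):
            mean, sd = weighted_mean_sd(values, errors, weight_power=weight_power)
        else:
            mean = float(values.mean())
            sd = float(values.std(ddof=0))
        rows.append(
            {"label": label, "n": int(values.size), "weighted_mean": mean, "weighted_sd": sd}
        )
        groups.append(values)
    per_group = pd.DataFrame(rows)
    if len(groups) >= 2:
        h, p = kruskal_wallis(groups)
        pairwise = posthoc_pairwise(groups, labels=labels, alpha=alpha)
    else:
        h = p = None
        pairwise = None
    return StatsReport(
        per_group=per_group, h_statistic=h, p_value=p, pairwise=pairwise, alpha=alpha
    )
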