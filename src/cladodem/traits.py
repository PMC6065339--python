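"""Per-trait life-history summaries and (weighted) one-way ANOVA.

Covers the scalar trait metrics — relative shrinkage rates of attached
and detached cladodes, flowering frequency R/T of terminal cladodes, the
maturation-effort quantities derived from R/T, and the clonality
potential of detached cladodes — plus a weighted-least-squares one-way
ANOVA with directional pairwise contrasts.  Entries averaged over more
cladodes (per-plant growth parameters) receive proportionally larger
weights; with equal weights the ANOVA reduces exactly to the classical
unweighted one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "attached_shrinkage_rate",
    "detached_shrinkage_rate",
    "flowering_frequency",
    "maturation_threshold",
    "budding_events_to_reproduction",
    "clonality_potential",
    "fold_advantage",
    "AnovaResult",
    "weighted_anova",
]


def attached_shrinkage_rate(max_log_size, min_log_size, interval_days):
    """Relative size loss per day of a cladode on a rooted plant:
    ``(max - min) / (interval * max)``.  Inputs may be arrays."""
    max_log_size = np.asarray(max_log_size, dtype=float)
    min_log_size = np.asarray(min_log_size, dtype=float)
    interval_days = np.asarray(interval_days, dtype=float)
    if np.any(interval_days <= 0):
        raise ValueError("interval_days must be positive")
    if np.any(max_log_size < min_log_size):
        raise ValueError("max size must be >= min size")
    return (max_log_size - min_log_size) / (interval_days * max_log_size)


def detached_shrinkage_rate(weight0_g, weight1_g, interval_days):
    """Relative weight loss per day of a detached cladode:
    ``(w0 - w1) / (interval * w0)``.  Weight gain yields a negative rate
    (allowed, flagged by the caller if needed)."""
    weight0_g = np.asarray(weight0_g, dtype=float)
    weight1_g = np.asarray(weight1_g, dtype=float)
    interval_days = np.asarray(interval_days, dtype=float)
    if np.any(weight0_g <= 0) or np.any(weight1_g <= 0):
        raise ValueError("weights must be positive")
    if np.any(interval_days <= 0):
        raise ValueError("interval_days must be positive")
    return (weight0_g - weight1_g) / (interval_days * weight0_g)


def flowering_frequency(terminal_flowering, terminal_total):
    """R/T: flowering terminal cladodes over all terminal cladodes."""
    terminal_flowering = np.asarray(terminal_flowering, dtype=float)
    terminal_total = np.asarray(terminal_total, dtype=float)
    if np.any(terminal_total < 1):
        raise ValueError("terminal_total must be >= 1")
    if np.any(terminal_flowering > terminal_total):
        raise ValueError("flowering count cannot exceed total")
    return terminal_flowering / terminal_total


def maturation_threshold(mean_rt: float) -> tuple[float, int]:
    """Minimum number of adult-size terminal cladodes a plant needs, on
    average, to produce one reproductive cladode: the reciprocal of the
    gender's mean R/T.  Returns (raw, rounded)."""
    if not 0.0 < mean_rt <= 1.0:
        raise ValueError("mean R/T must lie in (0, 1]")
    raw = 1.0 / mean_rt
    return raw, int(round(raw))


def budding_events_to_reproduction(
    mean_rt: float, p_bud_to_adult: float
) -> tuple[float, int]:
    """Expected vegetative budding events before first reproduction:
    the maturation threshold divided by the bud-to-adult survival
    probability.  Returns (raw, rounded)."""
    if not 0.0 < mean_rt <= 1.0:
        raise ValueError("mean R/T must lie in (0, 1]")
    if not 0.0 < p_bud_to_adult <= 1.0:
        raise ValueError("p_bud_to_adult must lie in (0, 1]")
    raw = (1.0 / mean_rt) / p_bud_to_adult
    return raw, int(round(raw))


def clonality_potential(p_shoot: float, p_bud_to_adult: float) -> float:
    """Probability a detached cladode yields an established plant:
    shooting (rooting and budding) probability times the probability that
    the new bud reaches adult size."""
    for name, p in (("p_shoot", p_shoot), ("p_bud_to_adult", p_bud_to_adult)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    return p_shoot * p_bud_to_adult


def fold_advantage(potential_a: float, potential_b: float) -> float:
    """How many times likelier gender a is than gender b to clone itself
    from a detached cladode.  Antisymmetric: f(a, b) = 1 / f(b, a)."""
    if potential_b <= 0:
        raise ValueError("potential_b must be positive")
    return potential_a / potential_b


# ----------------------------------------------------------------------
# weighted one-way ANOVA with directional contrasts
# ----------------------------------------------------------------------


@dataclass
class AnovaResult:
    """Weighted one-way ANOVA with per-group summaries.

    ``group_stats`` has one row per group: mean (weighted), se (from the
    pooled weighted residual variance), n (entry count), weight_sum.
    """

    F: float
    df1: int
    df2: int
    p: float
    s2_pooled: float
    group_stats: pd.DataFrame

    def contrast(self, group_a: str, group_b: str, direction: str = "greater") -> dict:
        """Pairwise linear contrast with pooled weighted variance.

        ``direction`` gives the one-tailed alternative for group a
        relative to group b (``greater`` or ``less``).  Returns a dict
        with t, df, p_two_sided, p_one_tailed.
        """
        gs = self.group_stats.set_index("group")
        ma, wa = gs.loc[group_a, "mean"], gs.loc[group_a, "weight_sum"]
        mb, wb = gs.loc[group_b, "mean"], gs.loc[group_b, "weight_sum"]
        se = np.sqrt(self.s2_pooled * (1.0 / wa + 1.0 / wb))
        if se == 0:
            t = 0.0 if ma == mb else np.inf * np.sign(ma - mb)
        else:
            t = (ma - mb) / se
        p_two = 2.0 * stats.t.sf(abs(t), self.df2)
        if direction == "greater":
            p_one = stats.t.sf(t, self.df2)
        elif direction == "less":
            p_one = stats.t.cdf(t, self.df2)
        else:
            raise ValueError("direction must be 'greater' or 'less'")
        return {
            "t": float(t),
            "df": self.df2,
            "p_two_sided": float(p_two),
            "p_one_tailed": float(p_one),
            "estimate": float(ma - mb),
        }


def weighted_anova(values, groups, weights=None) -> AnovaResult:
    """Weighted-least-squares one-way ANOVA.

    Weights are normalized to mean 1 so the total weight equals the entry
    count and the degrees of freedom match the classical ANOVA; equal
    weights therefore reproduce the unweighted F exactly.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    n = values.size
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if np.all(w == 0):
            raise ValueError("all weights are zero")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        w = w * (n / w.sum())
    labels = pd.unique(groups)
    k = labels.size
    if k < 2:
        raise ValueError("need at least two groups")
    if n - k < 1:
        raise ValueError("need at least two residual degrees of freedom")

    grand = float(np.sum(w * values) / np.sum(w))
    rows = []
    ssb = 0.0
    ssw = 0.0
    for g in labels:
        m = groups == g
        wg = w[m]
        xg = values[m]
        W = float(wg.sum())
        mean_g = float(np.sum(wg * xg) / W)
        ssb += W * (mean_g - grand) ** 2
        ssw += float(np.sum(wg * (xg - mean_g) ** 2))
        rows.append({"group": g, "mean": mean_g, "n": int(m.sum()), "weight_sum": W})
    df1, df2 = k - 1, n - k
    s2 = ssw / df2
    F = (ssb / df1) / s2 if s2 > 0 else (0.0 if ssb == 0 else np.inf)
    p = float(stats.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    gs = pd.DataFrame(rows)
    gs["se"] = np.sqrt(s2 / gs["weight_sum"])
    return AnovaResult(
        F=float(F), df1=df1, df2=df2, p=p, s2_pooled=s2, group_stats=gs
    )
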