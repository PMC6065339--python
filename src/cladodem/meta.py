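"""Within-study multi-trait effect-size synthesis.

Each life-history trait contributes one signed standardized mean
difference (Hedges' d) per gender pair, oriented so a positive d supports
the working hypothesis that the gender spending less on reproduction
(the "saver": male over female, and either unisexual over hermaphrodite)
performs better.  Continuous traits use the pooled-SD d with the
small-sample correction ``J = 1 - 3/(4*df - 1)``; dichotomous traits
(survival, rooting, budding) are converted from the log odds ratio with
the Hasselblad–Hedges factor ``sqrt(3)/pi``, the log-OR standard error
being recovered from the two-sided p of the corresponding exact or Wald
test (``SE = |ln OR| / z``).

Effects are pooled two ways: the inverse-variance weighted mean d++ and
the unweighted mean u.  Percentile 95% confidence intervals come from
resampling the traits (the synthesis is at trait level, not subject
level).  One-tailed p-values are combined with Fisher's statistic
``T = -2 * sum(ln p)`` referred to a Monte-Carlo competitive null of
independent uniforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EffectSize",
    "MetaResult",
    "hedges_correction",
    "d_continuous",
    "d_dichotomous",
    "pool",
    "bootstrap_ci",
    "combine_pvalues_correlated",
    "gender_comparison",
    "PAIRS",
]

# (saver, spender): the first-listed gender is hypothesized to perform better
PAIRS = [
    ("male", "hermaphrodite"),
    ("female", "hermaphrodite"),
    ("male", "female"),
]

_SQRT3_OVER_PI = np.sqrt(3.0) / np.pi


@dataclass(frozen=True)
class EffectSize:
    trait: str
    saver: str
    spender: str
    d: float
    v: float
    p_one_tailed: float
    source: str  # continuous | dichotomous

    def __post_init__(self):
        if not self.v > 0:
            raise ValueError("sampling variance must be positive")
        if not 0.0 < self.p_one_tailed <= 1.0:
            raise ValueError("one-tailed p must lie in (0, 1]")


@dataclass
class MetaResult:
    saver: str
    spender: str
    k: int
    d_plus_plus: float
    u: float
    ci95_d_plus_plus: tuple | None = None
    ci95_u: tuple | None = None
    combined_p: float | None = None
    degenerate_ci: bool = False


def hedges_correction(df: int) -> float:
    """Small-sample bias correction J = 1 - 3/(4*df - 1)."""
    if df < 2:
        raise ValueError("df must be >= 2")
    return 1.0 - 3.0 / (4.0 * df - 1.0)


def d_continuous(
    mean1: float,
    se1: float,
    n1: int,
    mean2: float,
    se2: float,
    n2: int,
    direction: str = "higher",
    trait: str = "",
    saver: str = "",
    spender: str = "",
    p_one_tailed: float = 1.0,
) -> EffectSize:
    """Hedges' d from group summaries (group 1 = saver, group 2 = spender).

    Group SDs are recovered from the reported standard errors
    (``s = SE * sqrt(n)``), pooled with n-1 weights, and the raw mean
    difference is standardized and bias-corrected.  ``direction="lower"``
    flips the sign (the hypothesis predicts a *lower* trait value in the
    saver, e.g. shrinkage or lag duration).  The sampling variance is the
    standard large-sample expression
    ``v = (n1 + n2)/(n1*n2) + d^2 / (2*(n1 + n2))``.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    if se1 < 0 or se2 < 0 or (se1 == 0 and se2 == 0 and mean1 != mean2):
        raise ValueError("invalid standard errors for unequal means")
    s1 = se1 * np.sqrt(n1)
    s2 = se2 * np.sqrt(n2)
    df = n1 + n2 - 2
    S = np.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df)
    diff = mean1 - mean2
    if S == 0:
        if diff != 0:
            raise ValueError("zero pooled SD with unequal means: infinite effect")
        d = 0.0
    else:
        d = hedges_correction(df) * diff / S
    if direction == "lower":
        d = -d
    elif direction != "higher":
        raise ValueError("direction must be 'higher' or 'lower'")
    v = (n1 + n2) / (n1 * n2) + d**2 / (2.0 * (n1 + n2))
    return EffectSize(trait, saver, spender, float(d), float(v), p_one_tailed,
                      "continuous")


def d_dichotomous(
    odds_ratio: float,
    p_two_sided: float,
    direction: str = "higher",
    trait: str = "",
    saver: str = "",
    spender: str = "",
    p_one_tailed: float = 1.0,
) -> EffectSize:
    """Hedges-scale d from an odds ratio and its two-sided test p.

    ``z = |Phi^-1(p/2)|`` recovers the log-OR standard error as
    ``SE = |ln OR| / z``; the conversion to the d scale multiplies by
    ``sqrt(3)/pi`` so ``v = 3 * SE^2 / pi^2``.  Zero-cell tables must be
    continuity-corrected (+0.5 per cell) before computing the OR.
    """
    if odds_ratio <= 0:
        raise ValueError("odds ratio must be positive")
    if not 0.0 < p_two_sided < 1.0:
        raise ValueError("p_two_sided must lie strictly inside (0, 1)")
    lor = np.log(odds_ratio)
    if lor == 0.0:
        raise ValueError("odds ratio of exactly 1 carries no standard error")
    z = abs(stats.norm.ppf(p_two_sided / 2.0))
    se_lor = abs(lor) / z
    d = lor * _SQRT3_OVER_PI
    if direction == "lower":
        d = -d
    elif direction != "higher":
        raise ValueError("direction must be 'higher' or 'lower'")
    v = 3.0 * se_lor**2 / np.pi**2
    return EffectSize(trait, saver, spender, float(d), float(v), p_one_tailed,
                      "dichotomous")


def pool(effects: list[EffectSize]) -> MetaResult:
    """Inverse-variance weighted mean d++ and unweighted mean u."""
    if not effects:
        raise ValueError("cannot pool an empty effect list")
    pairs = {(e.saver, e.spender) for e in effects}
    if len(pairs) > 1:
        raise ValueError("all effects must share one gender pair")
    d = np.array([e.d for e in effects])
    w = 1.0 / np.array([e.v for e in effects])
    saver, spender = next(iter(pairs))
    return MetaResult(
        saver=saver,
        spender=spender,
        k=len(effects),
        d_plus_plus=float(np.sum(w * d) / np.sum(w)),
        u=float(np.mean(d)),
    )


def bootstrap_ci(
    effects: list[EffectSize], n_boot: int = 2000, seed: int = 0
) -> dict:
    """Percentile 95% intervals for d++ and u by resampling traits.

    With a single trait the interval is degenerate and flagged.
    """
    k = len(effects)
    if k == 0:
        raise ValueError("no effects to bootstrap")
    d = np.array([e.d for e in effects])
    w = 1.0 / np.array([e.v for e in effects])
    if k == 1:
        return {
            "ci95_d_plus_plus": (float(d[0]), float(d[0])),
            "ci95_u": (float(d[0]), float(d[0])),
            "degenerate": True,
        }
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    idx = rng.integers(0, k, size=(n_boot, k))
    db, wb = d[idx], w[idx]
    dpp = np.sum(wb * db, axis=1) / np.sum(wb, axis=1)
    u = np.mean(db, axis=1)
    return {
        "ci95_d_plus_plus": tuple(np.percentile(dpp, [2.5, 97.5])),
        "ci95_u": tuple(np.percentile(u, [2.5, 97.5])),
        "degenerate": False,
    }


def combine_pvalues_correlated(
    p_values, n_mc: int = 10000, seed: int = 0
) -> float:
    """Fisher-type combination against a Monte-Carlo competitive null.

    ``T = -2 * sum(ln p_i)`` is compared with the same statistic on
    ``n_mc`` draws of k independent uniforms; the combined p is the
    fraction of draws with ``T_draw >= T_observed``.  Zeros are clipped
    to the smallest positive float with a warning.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        warnings.warn("zero p-value clipped to the machine minimum")
        p = np.clip(p, np.finfo(float).tiny, 1.0)
    T = -2.0 * np.sum(np.log(p))
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    draws = rng.random((n_mc, p.size))
    Td = -2.0 * np.sum(np.log(draws), axis=1)
    return float(np.mean(Td >= T))


# ----------------------------------------------------------------------
# full gender comparison
# ----------------------------------------------------------------------


def gender_comparison(
    trait_summaries: pd.DataFrame,
    trait_tests: pd.DataFrame,
    n_boot: int = 2000,
    n_mc: int = 10000,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Build, pool, bootstrap and combine the per-trait effect sizes.

    ``trait_summaries`` rows: trait, gender, mean, se, n, direction
    (``higher``/``lower``: the saver is hypothesized to have a
    higher/lower trait value).  ``trait_tests`` rows: trait, gender_a
    (saver), gender_b (spender), kind (``continuous``/``dichotomous``),
    p_one_tailed, p_two_sided, odds_ratio (dichotomous only; already
    continuity-corrected where needed).

    Returns (effect_sizes table, {(saver, spender): MetaResult}).  Traits
    whose inputs are missing or degenerate are skipped with a warning.
    """
    effects_rows = []
    results = {}
    summaries = trait_summaries.set_index(["trait", "gender"]) if len(
        trait_summaries
    ) else trait_summaries
    for i, (saver, spender) in enumerate(PAIRS):
        effects = []
        for _, t in trait_tests[
            (trait_tests.gender_a == saver) & (trait_tests.gender_b == spender)
        ].iterrows():
            try:
                if t["kind"] == "continuous":
                    row_a = summaries.loc[(t["trait"], saver)]
                    row_b = summaries.loc[(t["trait"], spender)]
                    eff = d_continuous(
                        row_a["mean"], row_a["se"], int(row_a["n"]),
                        row_b["mean"], row_b["se"], int(row_b["n"]),
                        direction=row_a["direction"],
                        trait=t["trait"], saver=saver, spender=spender,
                        p_one_tailed=min(max(t["p_one_tailed"], 1e-300), 1.0),
                    )
                else:
                    direction = "higher"
                    if len(trait_summaries):
                        sel = trait_summaries[trait_summaries.trait == t["trait"]]
                        if len(sel):
                            direction = sel.direction.iloc[0]
                    eff = d_dichotomous(
                        t["odds_ratio"], min(max(t["p_two_sided"], 1e-300), 1 - 1e-12),
                        direction=direction,
                        trait=t["trait"], saver=saver, spender=spender,
                        p_one_tailed=min(max(t["p_one_tailed"], 1e-300), 1.0),
                    )
            except (KeyError, ValueError) as exc:
                warnings.warn(
                    f"trait {t['trait']!r} skipped for {saver} vs {spender}: {exc}"
                )
                continue
            effects.append(eff)
            effects_rows.append(
                {"trait": eff.trait, "saver": saver, "spender": spender,
                 "d": eff.d, "v": eff.v, "p_one_tailed": eff.p_one_tailed,
                 "source": eff.source}
            )
        if not effects:
            warnings.warn(f"no usable traits for {saver} vs {spender}")
            continue
        res = pool(effects)
        ci = bootstrap_ci(effects, n_boot=n_boot, seed=seed * 7919 + i)
        res.ci95_d_plus_plus = ci["ci95_d_plus_plus"]
        res.ci95_u = ci["ci95_u"]
        res.degenerate_ci = ci["degenerate"]
        res.combined_p = combine_pvalues_correlated(
            [e.p_one_tailed for e in effects], n_mc=n_mc, seed=seed * 104729 + i
        )
        results[(saver, spender)] = res
    return pd.DataFrame(effects_rows), results
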