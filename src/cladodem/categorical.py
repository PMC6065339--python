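"""Maximum-likelihood categorical models for cladode survival and loss cause.

Survival (alive/dead) is modelled as a binary logit on plant gender (a
three-level factor, hermaphrodite as reference — the hypotheses compare
unisexuals against hermaphrodites) plus the log-size at which the cladode
was last recorded alive, optionally with a gender x size interaction.
Per-effect tests are likelihood-ratio chi-squares; pairwise gender
contrasts are Wald chi-squares on coefficient differences.  A residual
Pearson goodness-of-fit chi-square is computed over plant-level
populations (cladodes are nested within plants), with degrees of freedom
``n_plants - n_parameters``.

Loss-cause composition (herbivory vs intact death vs sectioning, among
lost cladodes) is compared between genders one cause at a time with a
binary logit of (cause vs other causes) on gender and pairwise Wald
chi-squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .config import GENDERS, LOSS_CAUSES

REFERENCE_GENDER = "hermaphrodite"

# |coefficient| beyond which a logit fit is treated as separated/degenerate
_SEPARATION_BOUND = 15.0


@dataclass
class CategoricalFit:
    """A fitted survival logit with its test battery."""

    params: pd.Series
    cov: pd.DataFrame
    loglik: float
    effect_tests: pd.DataFrame  # effect, chisq, df, p
    residual_chisq: float
    residual_df: int
    residual_p: float
    n_populations: int
    flagged: bool = False
    message: str = ""


def _gender_dummies(genders: pd.Series, present: list[str]) -> pd.DataFrame:
    ref = REFERENCE_GENDER if REFERENCE_GENDER in present else present[0]
    cols = {}
    for g in present:
        if g != ref:
            cols[f"gender[{g}]"] = (genders == g).astype(float)
    return pd.DataFrame(cols, index=genders.index), ref


def _fit_glm(y, X):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X, family=sm.families.Binomial())
        res = model.fit(maxiter=200)
    return res


def fit_survival_logit(
    records: pd.DataFrame, include_interaction: bool = False
) -> CategoricalFit:
    """Fit the survival logit and its effect tests.

    ``records`` follows the survival.csv schema.  Raises ``ValueError``
    for single-gender input or non-finite sizes.  Complete separation and
    degenerate responses (all alive / all dead) yield a flagged fit.
    """
    records = records.reset_index(drop=True)
    present = [g for g in GENDERS if (records.gender == g).any()]
    if len(present) < 2:
        raise ValueError("survival model needs at least two genders")
    size = records.last_log_size.astype(float)
    if not np.all(np.isfinite(size)):
        raise ValueError("last_log_size must be finite")
    y = records.alive.astype(float)

    dummies, ref = _gender_dummies(records.gender, present)
    X = pd.DataFrame({"const": 1.0}, index=records.index)
    X = pd.concat([X, dummies], axis=1)
    flagged = False
    message = ""
    # a constant size column is collinear with the intercept; drop it so
    # the gender model stays a proper saturated fit
    size_varies = np.ptp(size.to_numpy()) > 0
    if size_varies:
        X["size"] = size
        if include_interaction:
            for c in dummies.columns:
                X[f"{c}:size"] = dummies[c] * size
    else:
        message = "size covariate constant: dropped from the model"
    if y.nunique() < 2:
        # degenerate outcome: no information about any effect
        flagged = True
        message = "degenerate response: all cladodes share one outcome"

    res = _fit_glm(y, X)
    if np.max(np.abs(res.params.values)) > _SEPARATION_BOUND:
        flagged = True
        message = message or "possible complete separation (unbounded coefficient)"

    # likelihood-ratio chi-square per effect (drop its columns, refit)
    effects = {"gender": list(dummies.columns)}
    if size_varies:
        effects["size"] = ["size"]
        if include_interaction:
            effects["gender:size"] = [f"{c}:size" for c in dummies.columns]
    rows = []
    for name, cols in effects.items():
        reduced = _fit_glm(y, X.drop(columns=cols))
        chisq = max(0.0, 2.0 * (res.llf - reduced.llf))
        df = len(cols)
        p = float(stats.chi2.sf(chisq, df)) if not flagged else np.nan
        rows.append({"effect": name, "chisq": chisq, "df": df, "p": p})
    effect_tests = pd.DataFrame(rows)

    # residual Pearson GOF over plant-level populations
    fitted = np.asarray(res.fittedvalues)
    grp = records.groupby("plant_id", sort=True).indices
    obs = np.array([y.values[idx].sum() for idx in grp.values()])
    exp = np.array([fitted[idx].sum() for idx in grp.values()])
    var = np.array([(fitted[idx] * (1 - fitted[idx])).sum() for idx in grp.values()])
    ok = var > 1e-12
    residual_chisq = float(np.sum((obs[ok] - exp[ok]) ** 2 / var[ok]))
    n_pop = len(grp)
    residual_df = max(n_pop - X.shape[1], 1)
    residual_p = float(stats.chi2.sf(residual_chisq, residual_df))

    return CategoricalFit(
        params=res.params,
        cov=pd.DataFrame(
            res.cov_params(), index=res.params.index, columns=res.params.index
        ),
        loglik=float(res.llf),
        effect_tests=effect_tests,
        residual_chisq=residual_chisq,
        residual_df=residual_df,
        residual_p=residual_p,
        n_populations=n_pop,
        flagged=flagged,
        message=message,
    )


def _gender_coef(fit: CategoricalFit, gender: str) -> tuple[np.ndarray, float]:
    """Contrast vector picking up the gender's logit offset (0 for the
    reference level)."""
    c = np.zeros(len(fit.params))
    name = f"gender[{gender}]"
    if name in fit.params.index:
        c[list(fit.params.index).index(name)] = 1.0
    return c, float(c @ fit.params.values)


def pairwise_gender_contrast(
    fit: CategoricalFit, gender_a: str, gender_b: str
) -> dict:
    """Wald chi-square (df=1) on the coefficient difference between two
    genders.  Returns {'chisq', 'df', 'p', 'estimate', 'flagged'}."""
    ca, va = _gender_coef(fit, gender_a)
    cb, vb = _gender_coef(fit, gender_b)
    c = ca - cb
    est = va - vb
    if not np.any(c):
        return {"chisq": 0.0, "df": 1, "p": 1.0, "estimate": 0.0,
                "flagged": fit.flagged}
    var = float(c @ fit.cov.values @ c)
    chisq = est**2 / var if var > 0 else np.inf
    return {
        "chisq": float(chisq),
        "df": 1,
        "p": float(stats.chi2.sf(chisq, 1)),
        "estimate": est,
        "flagged": fit.flagged,
    }


def survival_table(records: pd.DataFrame, gender_a: str, gender_b: str):
    """Collapsed 2x2 (alive/dead) counts for two genders, as a dict."""
    out = {}
    for key, g in (("a", gender_a), ("b", gender_b)):
        sub = records[records.gender == g]
        out[f"successes_{key}"] = int(sub.alive.sum())
        out[f"failures_{key}"] = int((1 - sub.alive).sum())
    return out


def odds_ratio(successes_a, failures_a, successes_b, failures_b, haldane="auto"):
    """Odds ratio of a 2x2 table.  ``haldane="auto"`` adds 0.5 to every
    cell only when a zero cell would make the ratio degenerate — a
    reporting convention, never used for model fitting."""
    cells = np.array([successes_a, failures_a, successes_b, failures_b], float)
    if haldane is True or (haldane == "auto" and np.any(cells == 0)):
        cells = cells + 0.5
    a, b, c, d = cells
    return (a * d) / (b * c)


def loss_cause_tests(records: pd.DataFrame) -> pd.DataFrame:
    """Per-cause pairwise gender tests on loss-cause composition.

    For each cause, a binary logit of (this cause vs the other causes)
    on gender is fitted among lost cladodes, and Wald chi-squares compare
    each gender pair.  Genders with zero lost cladodes are excluded (one
    log row per exclusion, flagged with ``excluded=True``).
    """
    dead = records[records.alive == 0].copy()
    rows = []
    present = []
    for g in GENDERS:
        if (dead.gender == g).any():
            present.append(g)
        elif (records.gender == g).any():
            rows.append(
                {"cause": None, "gender_a": g, "gender_b": None, "chisq": np.nan,
                 "df": np.nan, "p": np.nan, "excluded": True,
                 "note": "no lost cladodes"}
            )
    pairs = [(a, b) for i, a in enumerate(present) for b in present[i + 1:]]
    for cause in LOSS_CAUSES:
        y = (dead.loss_cause == cause).astype(float)
        if y.nunique() < 2:
            for a, b in pairs:
                rows.append(
                    {"cause": cause, "gender_a": a, "gender_b": b, "chisq": np.nan,
                     "df": 1, "p": np.nan, "excluded": False,
                     "note": "degenerate: cause frequency 0 or 1"}
                )
            continue
        dummies, ref = _gender_dummies(dead.gender, present)
        X = pd.concat(
            [pd.DataFrame({"const": 1.0}, index=dead.index), dummies], axis=1
        )
        res = _fit_glm(y, X)
        sep = np.max(np.abs(res.params.values)) > _SEPARATION_BOUND
        cov = res.cov_params()
        names = list(res.params.index)
        for a, b in pairs:
            c = np.zeros(len(names))
            for g, sign in ((a, 1.0), (b, -1.0)):
                nm = f"gender[{g}]"
                if nm in names:
                    c[names.index(nm)] += sign
            est = float(c @ res.params.values)
            var = float(c @ np.asarray(cov) @ c)
            chisq = est**2 / var if var > 0 else np.inf
            rows.append(
                {"cause": cause, "gender_a": a, "gender_b": b,
                 "chisq": float(chisq), "df": 1,
                 "p": float(stats.chi2.sf(chisq, 1)),
                 "excluded": False,
                 "note": "separation" if sep else ""}
            )
    return pd.DataFrame(rows)
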