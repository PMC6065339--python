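"""Sigmoidal growth-curve fitting for individual cladode trajectories.

Each trajectory (log10 of length x width against days) is fitted with the
modified Gompertz and modified logistic models, both parameterized directly
in the three quantities of biological interest:

* ``A``   — asymptotic log-size (final cladode size),
* ``lam`` — lag-phase duration in days (t-intercept of the inflection
  tangent),
* ``mu``  — maximum growth rate in log-size per day (slope at the
  inflection point).

Gompertz:  ``y(t) = A * exp(-exp(mu*e/A * (lam - t) + 1))``
Logistic:  ``y(t) = A / (1 + exp(4*mu/A * (lam - t) + 2))``

The best parametric model is chosen by AIC (``n*ln(RSS/n) + 2k`` with
``k = 4``: three parameters plus the error variance).  A model-free
GCV-smoothed cubic spline provides a fallback and an alternative estimate;
between the AIC-best parametric fit and the spline, the final choice
minimizes the summed relative width of 90% case-resampling bootstrap
intervals across the three parameters (ties favor the parametric model).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from scipy.optimize import least_squares

__all__ = [
    "CladodeTrajectory",
    "GrowthParams",
    "gompertz_value",
    "logistic_value",
    "fit_parametric",
    "fit_spline",
    "bootstrap_params",
    "select_best",
    "exponential_phase_duration",
    "per_plant_params",
    "fit_growth_table",
]

_E = np.e
_PARAM_NAMES = ("A", "lam", "mu")


@dataclass(frozen=True)
class CladodeTrajectory:
    """Ordered size observations for one cladode on one plant."""

    plant_id: str
    gender: str
    cladode_id: str
    day: np.ndarray
    log_size: np.ndarray

    def __post_init__(self):
        day = np.asarray(self.day, dtype=float)
        y = np.asarray(self.log_size, dtype=float)
        object.__setattr__(self, "day", day)
        object.__setattr__(self, "log_size", y)
        if day.size < 5:
            raise ValueError("trajectory needs at least 5 observations")
        if day.size != y.size:
            raise ValueError("day and log_size lengths differ")
        if not np.all(np.diff(day) > 0):
            raise ValueError("observation days must be strictly increasing")
        if not np.all(np.isfinite(y)):
            raise ValueError("log_size must be finite")


@dataclass
class GrowthParams:
    """Fitted (A, lam, mu) with fit metadata.

    ``converged`` is False for a fit-failure result; ``degenerate`` marks
    spline fits with non-positive maximum slope (e.g. constant data).
    ``ci90`` maps parameter name to a (lo, hi) 90% bootstrap percentile
    interval; ``ci_unreliable`` is set when more than half the bootstrap
    resamples failed to fit.
    """

    model: str
    A: float = np.nan
    lam: float = np.nan
    mu: float = np.nan
    rss: float = np.nan
    aic: float = np.nan
    converged: bool = False
    degenerate: bool = False
    message: str = ""
    ci90: dict | None = None
    ci_unreliable: bool = False
    n_obs: int = 0

    def as_tuple(self):
        return (self.A, self.lam, self.mu)


# ----------------------------------------------------------------------
# model functions
# ----------------------------------------------------------------------

def gompertz_value(t, A, lam, mu):
    """Modified-Gompertz log-size at time ``t`` (days)."""
    u = np.clip(mu * _E / A * (lam - t) + 1.0, -700.0, 30.0)
    return A * np.exp(-np.exp(u))


def logistic_value(t, A, lam, mu):
    """Modified-logistic log-size at time ``t`` (days)."""
    v = np.clip(4.0 * mu / A * (lam - t) + 2.0, -700.0, 700.0)
    return A / (1.0 + np.exp(v))


def _gompertz_jac(t, A, lam, mu):
    u = np.clip(mu * _E / A * (lam - t) + 1.0, -700.0, 30.0)
    eu = np.exp(u)
    core = np.exp(-eu)
    dA = core * (1.0 + eu * mu * _E * (lam - t) / A)
    dlam = -mu * _E * eu * core
    dmu = -_E * (lam - t) * eu * core
    return np.column_stack([dA, dlam, dmu])


def _logistic_jac(t, A, lam, mu):
    v = np.clip(4.0 * mu / A * (lam - t) + 2.0, -700.0, 700.0)
    ev = np.exp(v)
    den = (1.0 + ev) ** 2
    dA = 1.0 / (1.0 + ev) + ev / den * 4.0 * mu * (lam - t) / A
    dlam = -4.0 * mu * ev / den
    dmu = -4.0 * (lam - t) * ev / den
    return np.column_stack([dA, dlam, dmu])


_MODELS = {
    "gompertz": (gompertz_value, _gompertz_jac),
    "logistic": (logistic_value, _logistic_jac),
}

_N_PARAMS = 4  # A, lam, mu + error variance, for AIC


def _aic(rss: float, n: int) -> float:
    return n * np.log(max(rss, 1e-300) / n) + 2 * _N_PARAMS


def _heuristic_start(t, y):
    """Heuristic start: A from the max, mu from the steepest successive
    slope, lam from that tangent's t-intercept."""
    A0 = max(float(np.max(y)), 1e-6)
    dt = np.diff(t)
    ok = dt > 0  # bootstrap resamples can duplicate days
    if not ok.any():
        return A0, float(t[0]), 1e-6
    slopes = np.where(ok, np.diff(y) / np.where(ok, dt, 1.0), -np.inf)
    i = int(np.argmax(slopes))
    mu0 = max(float(slopes[i]), 1e-6)
    tm = 0.5 * (t[i] + t[i + 1])
    ym = 0.5 * (y[i] + y[i + 1])
    lam0 = tm - ym / mu0
    return A0, lam0, mu0


def _starts(t, y):
    A0, lam0, mu0 = _heuristic_start(t, y)
    span = t[-1] - t[0]
    yield (A0, lam0, mu0)
    # four jittered restarts around the heuristic
    yield (A0 * 1.2, lam0 + 0.1 * span, mu0 * 0.5)
    yield (A0 * 0.9, lam0 - 0.1 * span, mu0 * 2.0)
    yield (A0 * 1.05, lam0 + 0.25 * span, mu0 * 1.0)
    yield (A0 * 1.5, lam0, mu0 * 0.75)


def _fit_parametric_arrays(t, y, model: str) -> GrowthParams:
    fun, jac = _MODELS[model]

    def resid(p):
        return fun(t, *p) - y

    def jac_(p):
        return jac(t, *p)

    def solve(x0):
        # unconstrained LM first (fast); bounded TRF fallback keeps A, mu > 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                sol = least_squares(resid, x0, jac=jac_, method="lm", max_nfev=200)
                if np.all(np.isfinite(sol.x)) and sol.x[0] > 0 and sol.x[2] > 0:
                    return sol
            except Exception:
                pass
            try:
                return least_squares(
                    resid,
                    x0,
                    jac=jac_,
                    bounds=([1e-9, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
                    method="trf",
                    max_nfev=200,
                )
            except Exception:
                return None

    best = None
    for x0 in _starts(t, y):
        sol = solve(x0)
        if sol is None or not np.all(np.isfinite(sol.x)):
            continue
        if sol.x[0] <= 0 or sol.x[2] <= 0:
            continue
        rss = float(2.0 * sol.cost)
        if best is None or rss < best[0]:
            best = (rss, sol.x)
        if rss < 1e-14:  # machine-exact fit; jitters cannot improve
            break
    if best is None:
        return GrowthParams(model=model, converged=False, message="all starts failed",
                            n_obs=t.size)
    rss, x = best
    return GrowthParams(
        model=model,
        A=float(x[0]),
        lam=float(x[1]),
        mu=float(x[2]),
        rss=rss,
        aic=_aic(rss, t.size),
        converged=True,
        n_obs=t.size,
    )


def fit_parametric(traj: CladodeTrajectory, model: str = "gompertz") -> GrowthParams:
    """Nonlinear least-squares fit of one parametric model.

    Non-convergence across all starts yields a fit-failure result
    (``converged=False``), not an exception.
    """
    if model not in _MODELS:
        raise ValueError(f"unknown model {model!r}")
    return _fit_parametric_arrays(traj.day, traj.log_size, model)


# ----------------------------------------------------------------------
# model-free spline
# ----------------------------------------------------------------------

def _fit_spline_arrays(t, y, w=None) -> GrowthParams:
    n = t.size
    if n < 5:
        raise ValueError("spline fit needs at least 5 points")
    try:
        spl = make_smoothing_spline(t, y, w=w)
    except Exception as exc:  # pragma: no cover - singular inputs
        return GrowthParams(model="spline", converged=False, message=str(exc), n_obs=n)
    grid = np.linspace(t[0], t[-1], 401)
    vals = spl(grid)
    A = float(np.max(vals))
    d1 = spl.derivative()(grid)
    i = int(np.argmax(d1))
    mu = float(d1[i])
    rss = float(np.sum((spl(t) - y) ** 2))
    if mu <= 1e-12:
        return GrowthParams(
            model="spline", A=A, lam=np.nan, mu=0.0, rss=rss, converged=True,
            degenerate=True, message="non-positive maximum slope", n_obs=n,
        )
    lam = float(grid[i] - vals[i] / mu)
    return GrowthParams(
        model="spline", A=A, lam=lam, mu=mu, rss=rss, converged=True, n_obs=n
    )


def fit_spline(traj: CladodeTrajectory) -> GrowthParams:
    """GCV-smoothed cubic spline; A is the maximum fitted value, mu the
    maximum first derivative, lam the t-intercept of the max-slope tangent."""
    return _fit_spline_arrays(traj.day, traj.log_size)


# ----------------------------------------------------------------------
# bootstrap and selection
# ----------------------------------------------------------------------

def _resample_fit(t, y, fitter_kind: str, model: str, rng) -> GrowthParams | None:
    idx = np.sort(rng.integers(0, t.size, size=t.size))
    tb, yb = t[idx], y[idx]
    if fitter_kind == "parametric":
        if np.unique(tb).size < 4:  # not enough support for 3 parameters
            return None
        fit = _fit_parametric_arrays(tb, yb, model)
        return fit if fit.converged else None
    # spline path: aggregate duplicate days into weighted means
    uniq, inv, counts = np.unique(tb, return_inverse=True, return_counts=True)
    if uniq.size < 5:
        return None
    ym = np.zeros(uniq.size)
    np.add.at(ym, inv, yb)
    ym /= counts
    fit = _fit_spline_arrays(uniq, ym, w=counts.astype(float))
    return fit if fit.converged and not fit.degenerate else None


def bootstrap_params(
    traj: CladodeTrajectory,
    fitter: str = "gompertz",
    n_boot: int = 100,
    seed: int = 0,
) -> dict:
    """Case-resampling bootstrap of one fitter.

    ``fitter`` is ``"gompertz"``, ``"logistic"`` or ``"spline"``.  Returns
    ``{"ci90": {param: (lo, hi)}, "n_failed": int, "reliable": bool}``;
    ``reliable`` is False when more than half the resamples failed.
    """
    t, y = traj.day, traj.log_size
    kind = "spline" if fitter == "spline" else "parametric"
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    draws = {p: [] for p in _PARAM_NAMES}
    n_failed = 0
    for _ in range(n_boot):
        fit = _resample_fit(t, y, kind, fitter, rng)
        if fit is None:
            n_failed += 1
            continue
        for p in _PARAM_NAMES:
            draws[p].append(getattr(fit, p))
    reliable = n_failed <= n_boot // 2
    ci90 = {}
    for p in _PARAM_NAMES:
        arr = np.asarray(draws[p])
        if arr.size == 0:
            ci90[p] = (np.nan, np.nan)
        else:
            ci90[p] = tuple(np.percentile(arr, [5.0, 95.0]))
    return {"ci90": ci90, "n_failed": n_failed, "reliable": reliable}


def _ci_score(fit: GrowthParams) -> float:
    """Summed relative 90% CI width over (A, lam, mu); scale-free."""
    if fit.ci90 is None:
        return np.inf
    total = 0.0
    for p in _PARAM_NAMES:
        lo, hi = fit.ci90[p]
        est = getattr(fit, p)
        if not (np.isfinite(lo) and np.isfinite(hi)):
            return np.inf
        total += (hi - lo) / max(abs(est), 1e-12)
    return total


def select_best(
    traj: CladodeTrajectory,
    n_boot: int = 100,
    seed: int = 0,
    selection: str = "ci",
) -> GrowthParams | None:
    """Fit Gompertz, logistic and spline; return the selected fit.

    The AIC-best converged parametric model competes with the spline.  With
    ``selection="ci"`` (and ``n_boot > 0``) the winner has the smaller
    summed relative 90% bootstrap CI width, ties going to the parametric
    model; with ``selection="aic"`` the parametric fit wins whenever it
    converged, the spline serving as fallback.  Returns ``None`` when every
    fit failed (caller logs and excludes the cladode).
    """
    fits = [fit_parametric(traj, m) for m in ("gompertz", "logistic")]
    par = min(
        (f for f in fits if f.converged), key=lambda f: f.aic, default=None
    )
    if (selection == "aic" or n_boot <= 0) and par is not None:
        return par
    spl = fit_spline(traj)
    if spl.degenerate or not spl.converged:
        spl = None
    if par is None and spl is None:
        return None
    if selection == "aic" or n_boot <= 0:
        return par if par is not None else spl
    if selection != "ci":
        raise ValueError(f"unknown selection rule {selection!r}")
    if par is None:
        return spl
    if spl is None:
        return _attach_ci(traj, par, n_boot, seed)
    par = _attach_ci(traj, par, n_boot, seed)
    spl = _attach_ci(traj, spl, n_boot, seed + 1)
    return par if _ci_score(par) <= _ci_score(spl) else spl


def _attach_ci(traj, fit: GrowthParams, n_boot: int, seed: int) -> GrowthParams:
    boot = bootstrap_params(traj, fitter=fit.model, n_boot=n_boot, seed=seed)
    return replace(fit, ci90=boot["ci90"], ci_unreliable=not boot["reliable"])


def exponential_phase_duration(params: GrowthParams | tuple) -> float:
    """Days the inflection tangent needs to climb from 0 to A: ``A / mu``."""
    A, _, mu = params.as_tuple() if isinstance(params, GrowthParams) else params
    if not mu > 0:
        raise ValueError("mu must be positive")
    return A / mu


# ----------------------------------------------------------------------
# table-level interface
# ----------------------------------------------------------------------

def trajectories_from_table(growth_df: pd.DataFrame):
    """Yield :class:`CladodeTrajectory` objects from the long growth table."""
    for (plant, clad), sub in growth_df.groupby(["plant_id", "cladode_id"], sort=True):
        sub = sub.sort_values("day")
        yield CladodeTrajectory(
            plant_id=str(plant),
            gender=str(sub.gender.iloc[0]),
            cladode_id=str(clad),
            day=sub.day.to_numpy(float),
            log_size=sub.log_size.to_numpy(float),
        )


def fit_growth_table(
    growth_df: pd.DataFrame,
    n_boot: int = 100,
    seed: int = 0,
    selection: str = "ci",
) -> tuple[pd.DataFrame, list[str]]:
    """Fit every cladode in the long growth table.

    Returns (fits table, list of excluded cladode descriptions).  Cladodes
    whose every fit failed are excluded with a logged reason.
    """
    rows, excluded = [], []
    for k, traj in enumerate(trajectories_from_table(growth_df)):
        fit = select_best(traj, n_boot=n_boot, seed=seed + k, selection=selection)
        if fit is None:
            excluded.append(f"{traj.plant_id}/{traj.cladode_id}: all fits failed")
            continue
        row = {
            "plant_id": traj.plant_id,
            "gender": traj.gender,
            "cladode_id": traj.cladode_id,
            "model": fit.model,
            "A": fit.A,
            "lam": fit.lam,
            "mu": fit.mu,
            "rss": fit.rss,
            "aic": fit.aic,
        }
        for p in _PARAM_NAMES:
            lo, hi = fit.ci90[p] if fit.ci90 else (np.nan, np.nan)
            row[f"ci90_{p}_lo"] = lo
            row[f"ci90_{p}_hi"] = hi
        rows.append(row)
    return pd.DataFrame(rows), excluded


def per_plant_params(fits_df: pd.DataFrame) -> pd.DataFrame:
    """Per-plant arithmetic means of (A, lam, mu) with the cladode count
    carried as the downstream ANOVA weight."""
    grouped = fits_df.groupby(["plant_id", "gender"], sort=True)
    out = grouped[["A", "lam", "mu"]].mean()
    out["n_cladodes"] = grouped.size()
    return out.reset_index()
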