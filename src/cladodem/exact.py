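"""Exact tests for 2x2 gender x outcome tables.

Boschloo's unconditional exact test treats only the two group sizes
(here, the number of detached cladodes per gender) as fixed and
maximizes, over the nuisance success probability pi, the probability of
observing a table whose Fisher p-value is at least as extreme as the
observed one, with both group outcomes Binomial(n, pi).  It is uniformly
at least as powerful as Fisher's conditional test, which serves as its
ordering statistic (two-sided orderings use the two-sided Fisher p).

The nuisance maximization runs on a uniform grid over
``pi in [1e-6, 1 - 1e-6]`` followed by a bounded local refinement around
the grid argmax; binomial probabilities are accumulated in log space so
tail tables at n ~ 30 do not underflow.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, xlog1py, xlogy

__all__ = [
    "TwoByTwoTable",
    "fisher_exact",
    "fisher_p_grid",
    "boschloo_test",
    "boschloo_all_tables",
    "pairwise_clonality_tests",
]

_ALTERNATIVES = ("greater", "less", "two_sided")
_TIE_REL = 1e-12  # relative tolerance grouping tied Fisher p-values
_PI_EDGE = 1e-6


@dataclass(frozen=True)
class TwoByTwoTable:
    """Counts for two independent binomial samples."""

    successes_a: int
    failures_a: int
    successes_b: int
    failures_b: int
    label_a: str = "a"
    label_b: str = "b"

    def __post_init__(self):
        for name in ("successes_a", "failures_a", "successes_b", "failures_b"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer")
        if self.n_a < 1 or self.n_b < 1:
            raise ValueError("both row totals must be >= 1")

    @property
    def n_a(self) -> int:
        return self.successes_a + self.failures_a

    @property
    def n_b(self) -> int:
        return self.successes_b + self.failures_b

    def swapped(self) -> "TwoByTwoTable":
        return TwoByTwoTable(
            self.successes_b, self.failures_b, self.successes_a, self.failures_a,
            self.label_b, self.label_a,
        )


def _check_alternative(alternative: str) -> None:
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {_ALTERNATIVES}")


def fisher_p_grid(n_a: int, n_b: int, alternative: str = "two_sided") -> np.ndarray:
    """Fisher p-values for every table with the given row totals.

    Entry ``[x_a, x_b]`` is the p-value of the table with ``x_a``
    successes of ``n_a`` in group a and ``x_b`` of ``n_b`` in group b,
    conditioning on the realized column margin.  ``greater`` means group a
    has the higher success probability.
    """
    _check_alternative(alternative)
    return _fisher_p_grid_cached(n_a, n_b, alternative).copy()


@lru_cache(maxsize=256)
def _fisher_p_grid_cached(n_a: int, n_b: int, alternative: str) -> np.ndarray:
    N = n_a + n_b
    xa = np.arange(n_a + 1)
    out = np.ones((n_a + 1, n_b + 1))
    if alternative == "greater":
        for xb in range(n_b + 1):
            out[:, xb] = stats.hypergeom.sf(xa - 1, N, xa + xb, n_a)
    elif alternative == "less":
        for xb in range(n_b + 1):
            out[:, xb] = stats.hypergeom.cdf(xa, N, xa + xb, n_a)
    else:
        # iterate over the column margin m; one pmf vector serves every
        # table on that anti-diagonal
        for m in range(N + 1):
            lo = max(0, m - n_b)
            hi = min(n_a, m)
            support = np.arange(lo, hi + 1)
            pmf = stats.hypergeom.pmf(support, N, m, n_a)
            below = pmf[None, :] <= pmf[:, None] * (1 + 1e-7)
            ps = (below * pmf[None, :]).sum(axis=1)
            for x, p in zip(support, ps):
                xb = m - x
                if 0 <= xb <= n_b:
                    out[x, xb] = p
    out = np.clip(out, 0.0, 1.0)
    out[out > 1.0 - 1e-12] = 1.0  # full-support sums are exactly 1
    out.setflags(write=False)
    return out


def fisher_exact(table: TwoByTwoTable, alternative: str = "two_sided") -> float:
    """Fisher's conditional exact test (hypergeometric tail or
    minimum-likelihood two-sided sum)."""
    grid = fisher_p_grid(table.n_a, table.n_b, alternative)
    return float(grid[table.successes_a, table.successes_b])


def _log_binom(n: int, grid: np.ndarray) -> np.ndarray:
    """Binomial log-pmf matrix, shape (n+1, len(grid)), accumulated with
    log-gamma terms so tail probabilities at n ~ 30 do not underflow."""
    x = np.arange(n + 1)[:, None]
    g = grid[None, :]
    logc = gammaln(n + 1) - gammaln(x + 1) - gammaln(n - x + 1)
    return logc + xlogy(x, g) + xlog1py(n - x, -g)


def _joint_prob_matrix(n_a, n_b, grid):
    """P[x_a, x_b | pi] for every table and grid point; shape (T, G)."""
    La = _log_binom(n_a, grid)  # (n_a+1, G)
    Lb = _log_binom(n_b, grid)  # (n_b+1, G)
    return np.exp(La[:, None, :] + Lb[None, :, :]).reshape(
        (n_a + 1) * (n_b + 1), grid.size
    )


def _rejection_masses(n_a, n_b, alternative, grid):
    """For every candidate table t, the function
    ``f_t(pi) = P[Fisher p(X) <= Fisher p(t)]`` evaluated on the grid.

    Returns (fisher_flat, mass) where mass has shape (T, G).
    """
    F = _fisher_p_grid_cached(n_a, n_b, alternative).ravel()
    P = _joint_prob_matrix(n_a, n_b, grid)
    order = np.argsort(F, kind="stable")
    sorted_f = F[order]
    C = np.cumsum(P[order], axis=0)
    # map each table to the last sorted position within its tie group
    pos = np.searchsorted(sorted_f, F * (1 + _TIE_REL), side="right") - 1
    mass = C[pos]
    return F, np.clip(mass, 0.0, 1.0)


@lru_cache(maxsize=64)
def _boschloo_grid_cached(n_a, n_b, alternative, grid_points):
    """Per-table grid maximum and its grid argmax, shapes (T,) and (T,)."""
    grid = np.linspace(_PI_EDGE, 1 - _PI_EDGE, grid_points)
    _, mass = _rejection_masses(n_a, n_b, alternative, grid)
    pmax = mass.max(axis=1)
    argmax = mass.argmax(axis=1)
    pmax.setflags(write=False)
    argmax.setflags(write=False)
    return pmax, argmax


def boschloo_all_tables(
    n_a: int, n_b: int, alternative: str = "two_sided", grid_points: int = 1000
) -> np.ndarray:
    """Grid-maximized Boschloo p for every table with the given row totals.

    Shape (n_a+1, n_b+1).  No per-table local refinement is applied (the
    grid bounds the error; see :func:`boschloo_test` for the refined
    single-table version).  Useful for simulation studies where the whole
    outcome space is needed at once.
    """
    _check_alternative(alternative)
    pmax, _ = _boschloo_grid_cached(n_a, n_b, alternative, grid_points)
    out = pmax.copy().reshape(n_a + 1, n_b + 1)
    out[out > 1.0 - 1e-12] = 1.0
    return out


def _single_table_objective(table: TwoByTwoTable, alternative: str):
    """Return f(pi) = P[Fisher p(X) <= Fisher p(observed)] as a callable."""
    n_a, n_b = table.n_a, table.n_b
    F = fisher_p_grid(n_a, n_b, alternative)
    p_obs = F[table.successes_a, table.successes_b]
    mask = (F <= p_obs * (1 + _TIE_REL)).ravel()
    xa = np.arange(n_a + 1)
    xb = np.arange(n_b + 1)

    def f(pi):
        pi = np.atleast_1d(np.asarray(pi, dtype=float))
        La = _log_binom(n_a, pi)
        Lb = _log_binom(n_b, pi)
        P = np.exp(La[:, None, :] + Lb[None, :, :]).reshape(-1, pi.size)
        return P[mask].sum(axis=0)

    return f


def boschloo_test(
    table: TwoByTwoTable,
    alternative: str = "two_sided",
    grid_points: int = 1000,
    refine: bool = True,
) -> float:
    """Boschloo's unconditional exact p-value for one 2x2 table.

    ``greater`` tests whether group a's success probability exceeds group
    b's.  The supremum over the nuisance probability is taken on a uniform
    grid and, when ``refine`` is set, sharpened with a bounded scalar
    maximization bracketing the grid argmax.
    """
    _check_alternative(alternative)
    grid = np.linspace(_PI_EDGE, 1 - _PI_EDGE, grid_points)
    pmax, argmax = _boschloo_grid_cached(
        table.n_a, table.n_b, alternative, grid_points
    )
    flat = table.successes_a * (table.n_b + 1) + table.successes_b
    best = float(pmax[flat])
    k = int(argmax[flat])
    if refine:
        f = _single_table_objective(table, alternative)
        lo = grid[max(k - 1, 0)]
        hi = grid[min(k + 1, grid.size - 1)]
        if hi > lo:
            res = minimize_scalar(
                lambda p: -f(p)[0],
                bounds=(lo, hi),
                method="bounded",
                options={"xatol": 1e-12},
            )
            best = max(best, float(-res.fun))
    best = min(best, 1.0)
    return 1.0 if best > 1.0 - 1e-12 else float(best)


# ----------------------------------------------------------------------
# gender-pair battery for the clonality table
# ----------------------------------------------------------------------

# canonical pair order: hypothesized resource-saver listed first
_PAIR_ORDER = [
    ("male", "hermaphrodite"),
    ("female", "hermaphrodite"),
    ("male", "female"),
]


def pairwise_clonality_tests(clonality: pd.DataFrame) -> pd.DataFrame:
    """Boschloo (and Fisher) tests for rooting and budding, per gender pair.

    Emits, for each outcome in (rooted, budded) and each gender pair with
    at least one cladode, the 2x2 counts, the two-sided Fisher p, the
    two-sided Boschloo p, and the one-sided (first-listed gender greater)
    Boschloo p used by the directional meta-analysis.
    """
    for col in ("gender", "rooted", "budded"):
        if col not in clonality.columns:
            raise ValueError(f"clonality table missing column {col!r}")
    counts = clonality.groupby("gender")[["rooted", "budded"]].agg(["sum", "count"])
    genders = list(counts.index)
    if len(genders) < 2:
        raise ValueError("need at least two genders with cladodes")
    rows = []
    for a, b in _PAIR_ORDER:
        if a not in genders or b not in genders:
            continue
        for outcome in ("rooted", "budded"):
            sa = int(counts.loc[a, (outcome, "sum")])
            na = int(counts.loc[a, (outcome, "count")])
            sb = int(counts.loc[b, (outcome, "sum")])
            nb = int(counts.loc[b, (outcome, "count")])
            t = TwoByTwoTable(sa, na - sa, sb, nb - sb, a, b)
            rows.append(
                {
                    "outcome": outcome,
                    "gender_a": a,
                    "gender_b": b,
                    "a": t.successes_a,
                    "b": t.failures_a,
                    "c": t.successes_b,
                    "d": t.failures_b,
                    "fisher_p": fisher_exact(t, "two_sided"),
                    "boschloo_p_two": boschloo_test(t, "two_sided"),
                    "boschloo_p_one": boschloo_test(t, "greater"),
                }
            )
    return pd.DataFrame(rows)
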