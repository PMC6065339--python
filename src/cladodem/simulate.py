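"""Synthetic cladode-demography datasets.

One call to :func:`simulate_population` draws a complete monitoring
campaign with the statistical structure the downstream analysis assumes:

* per-cladode Gompertz growth trajectories (log10 of cladode length x
  width) observed on a fixed day grid with additive Gaussian measurement
  noise on the log scale (multiplicative on the raw scale);
* Bernoulli survival from bud to adult with a gender intercept and a
  size slope on the logit scale, size being the log-size at the last
  observation while alive;
* a three-category loss-cause draw (herbivory / intact death /
  sectioning) conditional on death;
* truncated-Gaussian (at 0) relative shrinkage rates for attached and
  detached cladodes;
* binomial flowering counts of terminal cladodes per reproductive plant;
* nested Bernoulli rooting/budding of detached cladodes (budding implies
  rooting — an unrooted cladode desiccates before it can shoot).

Randomness flows from a single master seed expanded into per-table
substreams with fixed spawn keys, so each table is reproducible on its
own and the whole bundle is byte-identical under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .config import GENDERS, LOSS_CAUSES, SimulationConfig
from .growth import gompertz_value

# fixed substream spawn keys, one per generated table
_STREAMS = {
    "core": 0,
    "shrink_attached": 1,
    "shrink_detached": 2,
    "flowering": 3,
    "clonality": 4,
}


@dataclass
class DatasetBundle:
    """The six analysis tables of one campaign (see :mod:`cladodem.io`)."""

    survival: pd.DataFrame
    growth: pd.DataFrame
    shrink_attached: pd.DataFrame
    shrink_detached: pd.DataFrame
    flowering: pd.DataFrame
    clonality: pd.DataFrame

    def tables(self):
        for f in fields(self):
            yield f.name, getattr(self, f.name)

    def equals(self, other: "DatasetBundle") -> bool:
        return all(df.equals(getattr(other, name)) for name, df in self.tables())

    @classmethod
    def empty(cls) -> "DatasetBundle":
        return cls(
            **{name: pd.DataFrame(columns=cols) for name, cols in io.SCHEMAS.items()}
        )


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(_STREAMS[stream],))
    return np.random.default_rng(ss)


def _truncated_normal(rng, mean, sd, size) -> np.ndarray:
    """Gaussian truncated at 0 by redrawing (exact truncation, seedable)."""
    x = rng.normal(mean, sd, size=size)
    for _ in range(1000):
        bad = x < 0
        if not bad.any():
            break
        x[bad] = rng.normal(np.broadcast_to(mean, x.shape)[bad], sd)
    return np.maximum(x, 0.0)


def simulate_population(config: SimulationConfig) -> DatasetBundle:
    """Draw one complete dataset bundle from the generative model."""
    config.validate()
    days = np.asarray(config.obs_days, dtype=float)
    n_days = days.size

    rng = _rng(config, "core")

    # --- plants and cladodes ------------------------------------------
    plant_gender, plant_ids = [], []
    for g in GENDERS:
        for i in range(config.n_plants[g]):
            plant_ids.append(f"{g[0]}{i + 1:03d}")
            plant_gender.append(g)
    plant_gender = np.asarray(plant_gender)
    n_plants = len(plant_ids)

    n_clad = 1 + rng.poisson(config.cladodes_per_plant_mean - 1.0, size=n_plants)
    plant_idx = np.repeat(np.arange(n_plants), n_clad)
    clad_rank = np.concatenate([np.arange(1, k + 1) for k in n_clad])
    n_total = plant_idx.size
    genders = plant_gender[plant_idx]
    cladode_ids = np.array([f"c{r}" for r in clad_rank])

    # --- per-cladode growth parameters and trajectories ---------------
    A_g = np.array([config.growth[g].A for g in genders])
    lam_g = np.array([config.growth[g].lam for g in genders])
    mu_g = np.array([config.growth[g].mu for g in genders])
    cv = config.growth_cv
    if cv > 0:
        sig = np.sqrt(np.log1p(cv**2))
        jit = np.exp(rng.normal(-0.5 * sig**2, sig, size=(3, n_total)))
    else:
        jit = np.ones((3, n_total))
    A, lam, mu = A_g * jit[0], lam_g * jit[1], mu_g * jit[2]

    traj = gompertz_value(days[None, :], A[:, None], lam[:, None], mu[:, None])
    traj = traj + rng.normal(0.0, config.noise_sd, size=traj.shape)

    # --- survival ------------------------------------------------------
    plant_eff = (
        rng.normal(0.0, config.plant_intercept_sd, size=n_plants)
        if config.plant_intercept_sd > 0
        else np.zeros(n_plants)
    )
    last_idx = rng.integers(0, n_days, size=n_total)
    last_log_size = traj[np.arange(n_total), last_idx]
    intercept = np.array([config.survival_intercept[g] for g in genders])
    logit = (
        intercept
        + plant_eff[plant_idx]
        + config.survival_slope * (last_log_size - config.survival_size_ref)
    )
    alive = (rng.random(n_total) < 1.0 / (1.0 + np.exp(-logit))).astype(int)

    loss_cause = np.full(n_total, np.nan, dtype=object)
    for g in GENDERS:
        dead = (genders == g) & (alive == 0)
        if dead.any():
            loss_cause[dead] = rng.choice(
                LOSS_CAUSES, size=int(dead.sum()), p=config.loss_causes[g]
            )

    survival = pd.DataFrame(
        {
            "plant_id": np.asarray(plant_ids)[plant_idx],
            "gender": genders,
            "cladode_id": cladode_ids,
            "last_log_size": last_log_size,
            "alive": alive,
            "loss_cause": loss_cause,
        }
    )

    # --- growth long table: cladodes that completed their trajectory --
    grown = alive == 1
    growth = pd.DataFrame(
        {
            "plant_id": np.repeat(survival.plant_id.to_numpy()[grown], n_days),
            "gender": np.repeat(genders[grown], n_days),
            "cladode_id": np.repeat(cladode_ids[grown], n_days),
            "day": np.tile(days, int(grown.sum())),
            "log_size": traj[grown].ravel(),
        }
    )

    # --- attached shrinkage -------------------------------------------
    rng_sa = _rng(config, "shrink_attached")
    rows = []
    grown_idx = np.flatnonzero(grown)
    for g in GENDERS:
        pool = grown_idx[genders[grown_idx] == g]
        take = min(config.n_shrink_attached[g], pool.size)
        chosen = rng_sa.choice(pool, size=take, replace=False)
        lo, hi = config.shrink_attached_interval
        interval = rng_sa.integers(lo, hi + 1, size=take)
        rate = _truncated_normal(
            rng_sa, config.shrink_attached_mean[g], config.shrink_attached_sd, take
        )
        max_ls = traj[chosen, -1]
        frac = np.clip(rate * interval, 0.0, 0.95)
        rows.append(
            pd.DataFrame(
                {
                    "plant_id": survival.plant_id.to_numpy()[chosen],
                    "gender": g,
                    "cladode_id": cladode_ids[chosen],
                    "max_log_size": max_ls,
                    "min_log_size": max_ls * (1.0 - frac),
                    "interval_days": interval,
                }
            )
        )
    shrink_attached = pd.concat(rows, ignore_index=True)

    # --- detached shrinkage -------------------------------------------
    rng_sd = _rng(config, "shrink_detached")
    rows = []
    for g in GENDERS:
        n = config.n_shrink_detached[g]
        w0 = _truncated_normal(
            rng_sd, config.detached_weight_mean_g, config.detached_weight_sd_g, n
        )
        lo, hi = config.shrink_detached_interval
        interval = rng_sd.integers(lo, hi + 1, size=n)
        rate = _truncated_normal(
            rng_sd, config.shrink_detached_mean[g], config.shrink_detached_sd, n
        )
        frac = np.clip(rate * interval, 0.0, 0.95)
        rows.append(
            pd.DataFrame(
                {
                    "cladode_id": [f"det_{g[0]}{i + 1:03d}" for i in range(n)],
                    "gender": g,
                    "weight0_g": w0,
                    "weight1_g": w0 * (1.0 - frac),
                    "interval_days": interval,
                }
            )
        )
    shrink_detached = pd.concat(rows, ignore_index=True)

    # --- flowering -----------------------------------------------------
    rng_fl = _rng(config, "flowering")
    rows = []
    for g in GENDERS:
        n = config.n_flowering_plants[g]
        total = 1 + rng_fl.poisson(config.terminal_mean_extra, size=n)
        flowering = rng_fl.binomial(total, config.flowering_p[g])
        rows.append(
            pd.DataFrame(
                {
                    "plant_id": [f"rep_{g[0]}{i + 1:03d}" for i in range(n)],
                    "gender": g,
                    "terminal_total": total,
                    "terminal_flowering": flowering,
                }
            )
        )
    flowering = pd.concat(rows, ignore_index=True)

    # --- clonality -----------------------------------------------------
    rng_cl = _rng(config, "clonality")
    rows = []
    for g in GENDERS:
        n = config.n_clonality[g]
        p_root = config.clonality_p_rooted[g]
        p_bud = config.clonality_p_budded[g]
        rooted = (rng_cl.random(n) < p_root).astype(int)
        p_bud_given_root = p_bud / p_root if p_root > 0 else 0.0
        budded = rooted * (rng_cl.random(n) < p_bud_given_root).astype(int)
        rows.append(
            pd.DataFrame(
                {
                    "cladode_id": [f"det_{g[0]}{i + 1:03d}" for i in range(n)],
                    "gender": g,
                    "rooted": rooted,
                    "budded": budded,
                }
            )
        )
    clonality = pd.concat(rows, ignore_index=True)

    return DatasetBundle(
        survival=survival,
        growth=growth,
        shrink_attached=shrink_attached,
        shrink_detached=shrink_detached,
        flowering=flowering,
        clonality=clonality,
    )


def write_dataset(bundle: DatasetBundle, directory: str | Path) -> list[Path]:
    """Write the six CSVs; returns the paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    return [io.write_table(df, name, directory) for name, df in bundle.tables()]


def read_dataset(directory: str | Path) -> DatasetBundle:
    """Read a bundle previously written by :func:`write_dataset`."""
    return DatasetBundle(**{name: io.read_table(name, directory) for name in io.SCHEMAS})
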