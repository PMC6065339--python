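"""Configuration for the synthetic cladode-demography generator.

The defaults emulate the study conditions of a trioecious *Opuntia robusta*
population monitored at the cladode (ramet) level: per-gender plant counts,
sigmoidal (Gompertz) cladode growth on the log10(length x width) scale,
size-dependent Bernoulli survival, a three-category loss-cause distribution,
truncated-Gaussian shrinkage rates, binomial flowering frequency of terminal
cladodes, and nested Bernoulli rooting/budding of detached cladodes.
"""

from __future__ import annotations


from dataclasses import dataclass, field, replace

GENDERS = ("female", "hermaphrodite", "male")
LOSS_CAUSES = ("herbivory", "intact", "sectioned")


class ConfigError(ValueError):
    """Raised when a simulation configuration field is out of range."""


@dataclass(frozen=True)
class GompertzParams:
    """Sigmoid growth parameters: asymptote A (log-size units), lag
    duration lam (days), maximum slope mu (log-size per day)."""

    A: float
    lam: float
    mu: float


@dataclass(frozen=True)
class SimulationConfig:
    """Full generative model for one synthetic monitoring campaign.

    All per-gender fields are dicts keyed by ``female | hermaphrodite |
    male``.  Probabilities are in [0, 1]; each ``loss_causes`` vector
    (herbivory, intact death, rancher sectioning — conditional on loss)
    sums to 1.  ``plant_intercept_sd`` adds an optional plant-level random
    intercept on the survival logit; its default of 0.0 is a guess — field
    data almost surely carry positive within-plant correlation of cladode
    fates, but no estimate of its magnitude is available, so correlation is
    off unless explicitly requested.
    """

    # population layout
    n_plants: dict = field(
        default_factory=lambda: {"female": 29, "hermaphrodite": 96, "male": 31}
    )
    cladodes_per_plant_mean: float = 1.91

    # growth: fixed 10-day observation grid spanning lag through plateau
    obs_days: tuple = tuple(float(d) for d in range(0, 70, 7))
    growth: dict = field(
        default_factory=lambda: {
            "female": GompertzParams(A=2.9, lam=15.0, mu=2.9 / 27.0),
            "hermaphrodite": GompertzParams(A=2.9, lam=15.0, mu=2.9 / 27.0),
            "male": GompertzParams(A=3.1, lam=15.0, mu=3.1 / 27.0),
        }
    )
    growth_cv: float = 0.10  # per-cladode lognormal CV on (A, lam, mu)
    noise_sd: float = 0.02  # measurement noise, log10 units

    # survival: logit = intercept_gender + plant_effect + slope*(size - ref).
    # Intercepts calibrated so the marginal bud-to-adult survival
    # frequencies land near 0.65 / 0.38 / 0.42 (female / hermaphrodite /
    # male) given the size distribution induced by the observation grid.
    survival_intercept: dict = field(
        default_factory=lambda: {
            "female": 0.845,
            "hermaphrodite": -0.647,
            "male": -0.525,
        }
    )
    survival_slope: float = 1.0
    survival_size_ref: float = 1.5
    plant_intercept_sd: float = 0.0

    # loss causes, conditional on death: (herbivory, intact, sectioned)
    loss_causes: dict = field(
        default_factory=lambda: {
            "female": (0.55, 0.30, 0.15),
            "hermaphrodite": (0.50, 0.35, 0.15),
            "male": (0.27, 0.55, 0.18),
        }
    )

    # shrinkage of cladodes still attached to rooted plants
    # (relative log-size loss per day, Gaussian truncated at 0)
    shrink_attached_mean: dict = field(
        default_factory=lambda: {
            "female": 0.0015,
            "hermaphrodite": 0.0022,
            "male": 0.0008,
        }
    )
    shrink_attached_sd: float = 0.0006
    n_shrink_attached: dict = field(
        default_factory=lambda: {"female": 26, "hermaphrodite": 27, "male": 26}
    )
    shrink_attached_interval: tuple = (90, 120)

    # shrinkage of manually detached cladodes (relative weight loss per day)
    shrink_detached_mean: dict = field(
        default_factory=lambda: {
            "female": 0.0020,
            "hermaphrodite": 0.0030,
            "male": 0.0015,
        }
    )
    shrink_detached_sd: float = 0.0006
    n_shrink_detached: dict = field(
        default_factory=lambda: {"female": 33, "hermaphrodite": 33, "male": 33}
    )
    shrink_detached_interval: tuple = (71, 79)
    detached_weight_mean_g: float = 1500.0
    detached_weight_sd_g: float = 300.0

    # flowering frequency of terminal cladodes (per reproductive plant)
    flowering_p: dict = field(
        default_factory=lambda: {"female": 0.36, "hermaphrodite": 0.33, "male": 0.50}
    )
    n_flowering_plants: dict = field(
        default_factory=lambda: {"female": 47, "hermaphrodite": 177, "male": 72}
    )
    terminal_mean_extra: float = 2.0  # terminal_total = 1 + Poisson(this)

    # clonality of detached cladodes: budding is nested within rooting
    # (a cladode that never roots desiccates and cannot bud)
    clonality_p_rooted: dict = field(
        default_factory=lambda: {"female": 0.70, "hermaphrodite": 0.417, "male": 0.80}
    )
    clonality_p_budded: dict = field(
        default_factory=lambda: {"female": 0.32, "hermaphrodite": 0.075, "male": 0.57}
    )
    n_clonality: dict = field(
        default_factory=lambda: {"female": 26, "hermaphrodite": 24, "male": 30}
    )

    seed: int = 0

    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Raise :class:`ConfigError` naming the first offending field."""
        for g in GENDERS:
            for name in (
                "n_plants",
                "growth",
                "survival_intercept",
                "loss_causes",
                "shrink_attached_mean",
                "shrink_detached_mean",
                "flowering_p",
                "clonality_p_rooted",
                "clonality_p_budded",
                "n_clonality",
                "n_flowering_plants",
                "n_shrink_attached",
                "n_shrink_detached",
            ):
                if g not in getattr(self, name):
                    raise ConfigError(f"{name} missing gender {g!r}")
        for name in ("n_plants", "n_flowering_plants", "n_clonality"):
            for g, n in getattr(self, name).items():
                if int(n) != n or n <= 0:
                    raise ConfigError(f"{name}[{g!r}] must be a positive integer")
        if self.cladodes_per_plant_mean < 1:
            raise ConfigError("cladodes_per_plant_mean must be >= 1")
        if len(self.obs_days) < 5 or any(
            b <= a for a, b in zip(self.obs_days, self.obs_days[1:])
        ):
            raise ConfigError("obs_days must be >= 5 strictly increasing days")
        for g, gp in self.growth.items():
            if gp.A <= 0 or gp.mu <= 0 or gp.lam < 0:
                raise ConfigError(f"growth[{g!r}] requires A > 0, mu > 0, lam >= 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.growth_cv < 0:
            raise ConfigError("growth_cv must be >= 0")
        if self.plant_intercept_sd < 0:
            raise ConfigError("plant_intercept_sd must be >= 0")
        for g, vec in self.loss_causes.items():
            if len(vec) != 3 or any(p < 0 or p > 1 for p in vec):
                raise ConfigError(f"loss_causes[{g!r}] must be three probabilities")
            if abs(sum(vec) - 1.0) > 1e-9:
                raise ConfigError(f"loss_causes[{g!r}] must sum to 1")
        for name in ("flowering_p", "clonality_p_rooted", "clonality_p_budded"):
            for g, p in getattr(self, name).items():
                if not 0.0 <= p <= 1.0:
                    raise ConfigError(f"{name}[{g!r}] must lie in [0, 1]")
        for g in GENDERS:
            if self.clonality_p_budded[g] > self.clonality_p_rooted[g]:
                raise ConfigError(
                    f"clonality_p_budded[{g!r}] cannot exceed clonality_p_rooted"
                )
        for name in ("shrink_attached_sd", "shrink_detached_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("shrink_attached_interval", "shrink_detached_interval"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ConfigError(f"{name} must be a positive (lo, hi) pair")
        if self.detached_weight_mean_g <= 0 or self.detached_weight_sd_g < 0:
            raise ConfigError("detached weight distribution must be positive")


def default_config(seed: int = 0) -> SimulationConfig:
    """Study-condition defaults (validated)."""
    cfg = SimulationConfig(seed=seed)
    cfg.validate()
    return cfg


def null_config(seed: int = 0) -> SimulationConfig:
    """Defaults with every gender difference removed (all per-gender
    parameters set to the hermaphrodite value): the no-effect null."""
    base = default_config(seed)
    h = "hermaphrodite"
    cfg = replace(
        base,
        growth={g: base.growth[h] for g in GENDERS},
        survival_intercept={g: base.survival_intercept[h] for g in GENDERS},
        loss_causes={g: base.loss_causes[h] for g in GENDERS},
        shrink_attached_mean={g: base.shrink_attached_mean[h] for g in GENDERS},
        shrink_detached_mean={g: base.shrink_detached_mean[h] for g in GENDERS},
        flowering_p={g: base.flowering_p[h] for g in GENDERS},
        clonality_p_rooted={g: base.clonality_p_rooted[h] for g in GENDERS},
        clonality_p_budded={g: base.clonality_p_budded[h] for g in GENDERS},
    )
    cfg.validate()
    return cfg
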