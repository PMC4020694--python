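"""Run orchestration: configuration, initialization, the generation loop,
and replicate management with extinction re-runs.

A replicate runs the life cycle for ``n_generations`` (default 10,000):
environment step, birth-cohort development (each juvenile perceives the cue
of its natal deme), then dispersal and selection in the configured order,
then soft-selection reproduction.  A parameter combination is replicated
until ``n_replicates`` (default 20) runs avoid metapopulation extinction,
trying at most ``max_attempts`` (default 60) seeds; outcomes are averaged
over successful replicates only.

Seeding: attempt ``a`` uses root seed ``base_seed + a``; independent
generator streams are spawned from it for initialization, the environment,
developmental noise, and demography, so runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from .demography import (
    DispersalPattern,
    LifeHistoryOrder,
    LifeHistorySpec,
    disperse_island,
    disperse_stepping_stone,
    reproduce,
    select,
)
from .environment import (
    EnvironmentState,
    GradientSpec,
    TemporalPattern,
    TemporalSpec,
    developmental_cue,
    init_environment,
    step_environment,
)
from .genetics import N_ALLELES, LocusConfig, pleiotropic_sd
from .population import Population

__all__ = [
    "SimConfig",
    "ReplicateResult",
    "initialize",
    "develop_population",
    "run_generation",
    "run_replicate",
    "run_replicates",
]

#: discrete allelic values of the founding generation (equiprobable)
INITIAL_ALLELE_VALUES = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of one simulation run."""

    grad: GradientSpec = field(default_factory=GradientSpec)
    temporal: TemporalSpec = field(default_factory=TemporalSpec)
    life: LifeHistorySpec = field(default_factory=LifeHistorySpec)
    loci: LocusConfig = field(default_factory=LocusConfig)
    n_generations: int = 10_000
    n_replicates: int = 20
    max_attempts: int = 60
    base_seed: int = 0
    mutation_rate: float = 0.10
    mutation_sd: float = 0.1
    report_window: int = 100
    record_series: bool = True

    def __post_init__(self) -> None:
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if not 1 <= self.n_replicates <= self.max_attempts:
            raise ValueError("need 1 <= n_replicates <= max_attempts")
        if self.grad.n_demes == 1 and self.life.dispersal_rate != 0.0:
            raise ValueError(
                "a single-deme run cannot disperse; set dispersal_rate=0"
            )
        if self.report_window < 1:
            raise ValueError("report_window must be >= 1")
        if self.report_window > self.n_generations:
            # short runs: average over whatever is available
            object.__setattr__(
                self, "report_window", self.n_generations
            )

    # -- convenience constructors -------------------------------------

    @staticmethod
    def tau_from_percent(grad: GradientSpec, percent: float) -> float:
        """Temporal sd expressed as a percentage of the gradient span
        (the difference in optima between the terminal demes)."""
        return (percent / 100.0) * grad.span

    @staticmethod
    def tau_from_sigma_ratio(sigma: float, ratio: float) -> float:
        """Temporal sd expressed relative to the selection width sigma
        (the convention for single-deme runs)."""
        return ratio * sigma

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimConfig":
        """Build a config from a flat key-value mapping (config files).

        Temporal sd may be given as ``tau`` (optimum units),
        ``tau_percent`` (of the gradient span), or ``tau_over_sigma``.
        """
        d = dict(d)
        grad = GradientSpec(
            n_demes=int(d.pop("n_demes", 50)),
            optimum_step=float(d.pop("optimum_step", 0.4)),
            cue_slope=float(d.pop("cue_slope", 0.04)),
        )
        life = LifeHistorySpec(
            order=LifeHistoryOrder(d.pop("order", "move_first")),
            dispersal_pattern=DispersalPattern(
                d.pop("dispersal_pattern", "stepping_stone")
            ),
            dispersal_rate=float(d.pop("dispersal_rate", 0.0)),
            sigma=float(d.pop("sigma", 2.0)),
            carrying_capacity=int(
                d.pop("carrying_capacity", 1000 if grad.n_demes == 1 else 100)
            ),
        )
        if "tau" in d:
            tau = float(d.pop("tau"))
        elif "tau_percent" in d:
            tau = cls.tau_from_percent(grad, float(d.pop("tau_percent")))
        elif "tau_over_sigma" in d:
            tau = cls.tau_from_sigma_ratio(
                life.sigma, float(d.pop("tau_over_sigma"))
            )
        else:
            tau = 0.0
        temporal = TemporalSpec(
            pattern=TemporalPattern(d.pop("pattern", "none")),
            tau=tau,
            rho=float(d.pop("rho", 0.0)),
            synchronized=bool(d.pop("synchronized", False)),
        )
        mode = d.pop("mode", "independent")
        if mode not in ("independent", "pleiotropic"):
            raise ValueError(f"unknown genetics mode: {mode!r}")
        instability_loci = bool(d.pop("instability_loci", True))
        loci = LocusConfig(
            has_plastic=bool(d.pop("plastic_loci", True)),
            has_instability=(mode == "independent") and instability_loci,
            pleiotropic=(mode == "pleiotropic"),
            pleiotropy_strength=float(d.pop("pleiotropy_strength", 0.0)),
        )
        kwargs = {
            k: d.pop(k)
            for k in (
                "n_generations",
                "n_replicates",
                "max_attempts",
                "base_seed",
                "mutation_rate",
                "mutation_sd",
                "report_window",
                "record_series",
            )
            if k in d
        }
        if d:
            raise ValueError(f"unknown config keys: {sorted(d)}")
        return cls(grad=grad, temporal=temporal, life=life, loci=loci, **kwargs)

    def to_dict(self) -> dict[str, Any]:
        """Flat mapping, the inverse of :meth:`from_dict`."""
        return {
            "n_demes": self.grad.n_demes,
            "optimum_step": self.grad.optimum_step,
            "cue_slope": self.grad.cue_slope,
            "order": self.life.order.value,
            "dispersal_pattern": self.life.dispersal_pattern.value,
            "dispersal_rate": self.life.dispersal_rate,
            "sigma": self.life.sigma,
            "carrying_capacity": self.life.carrying_capacity,
            "pattern": self.temporal.pattern.value,
            "tau": self.temporal.tau,
            "rho": self.temporal.rho,
            "synchronized": self.temporal.synchronized,
            "mode": "pleiotropic" if self.loci.pleiotropic else "independent",
            "plastic_loci": self.loci.has_plastic,
            "instability_loci": self.loci.has_instability,
            "pleiotropy_strength": self.loci.pleiotropy_strength,
            "n_generations": self.n_generations,
            "n_replicates": self.n_replicates,
            "max_attempts": self.max_attempts,
            "base_seed": self.base_seed,
            "mutation_rate": self.mutation_rate,
            "mutation_sd": self.mutation_sd,
            "report_window": self.report_window,
            "record_series": self.record_series,
        }


@dataclass
class ReplicateResult:
    """Outcome of one replicate attempt.

    Extinct replicates carry no summary statistics (all None) and are
    excluded from cross-replicate averages.  ``mean_plasticity`` and
    ``mean_instability`` are time-averages over the final ``report_window``
    generations; ``final_*`` are last-generation snapshots.
    ``relative_plasticity`` is the window-mean reaction-norm slope divided
    by the optimal slope.
    """

    seed: int
    attempt: int
    extinct: bool
    n_generations_run: int
    mean_plasticity: float | None = None
    final_plasticity: float | None = None
    relative_plasticity: float | None = None
    mean_instability: float | None = None
    final_instability: float | None = None
    series: dict[str, np.ndarray] | None = None


def _rng_streams(seed: int) -> dict[str, np.random.Generator]:
    init, env, dev, demo = np.random.SeedSequence(seed).spawn(4)
    return {
        "init": np.random.default_rng(init),
        "env": np.random.default_rng(env),
        "dev": np.random.default_rng(dev),
        "demo": np.random.default_rng(demo),
    }


def initialize(
    config: SimConfig, rng: np.random.Generator
) -> tuple[Population, EnvironmentState]:
    """Founding generation and initial environment.

    Every deme is filled to carrying capacity with newborns whose
    nonplastic and plastic alleles are drawn uniformly from
    {-2, -1, 0, 1, 2}; instability alleles all start at zero.  The
    environment state starts at a stationary AR(1) draw.
    """
    k = config.life.carrying_capacity
    d = config.grad.n_demes
    n = k * d

    def discrete_init() -> np.ndarray:
        return rng.choice(INITIAL_ALLELE_VALUES, size=(n, N_ALLELES))

    loci = config.loci
    deme = np.repeat(np.arange(d, dtype=np.int64), k)
    pop = Population(
        nonplastic=discrete_init(),
        plastic=discrete_init() if loci.has_plastic else None,
        instability=np.zeros((n, N_ALLELES)) if loci.has_instability else None,
        phenotype=np.full(n, np.nan),
        deme=deme,
        natal_deme=deme.copy(),
    )
    env = init_environment(config.temporal, config.grad, rng)
    return pop, env


def develop_population(
    pop: Population,
    env: EnvironmentState,
    config: SimConfig,
    rng: np.random.Generator,
) -> None:
    """Fix every juvenile's phenotype using its natal deme's cue.

    One Gaussian noise draw per individual, sd = summed instability alleles
    (independent mode) or the pleiotropic sd; exactly zero noise when the
    sd is zero.  Modifies ``pop.phenotype`` in place.
    """
    cue = developmental_cue(env, config.grad, pop.natal_deme)
    t = pop.nonplastic.sum(axis=1)
    if pop.plastic is not None:
        sum_p = pop.plastic.sum(axis=1)
        t = t + cue * sum_p
    if config.loci.pleiotropic:
        sd = pleiotropic_sd(pop.plastic, config.loci.pleiotropy_strength)
    elif pop.instability is not None:
        sd = pop.instability.sum(axis=1)
    else:
        sd = None
    if sd is not None:
        t = t + rng.standard_normal(pop.size) * sd
    pop.phenotype = t


def run_generation(
    pop: Population,
    env: EnvironmentState,
    config: SimConfig,
    rngs: dict[str, np.random.Generator],
) -> tuple[Population, EnvironmentState]:
    """One full life cycle; returns next generation's juveniles.

    Stage order: environment step, development, then dispersal/selection in
    the configured life-history order, then reproduction.  An empty
    returned population signals metapopulation extinction.
    """
    life, grad = config.life, config.grad
    env = step_environment(env, config.temporal, grad, rngs["env"])
    develop_population(pop, env, config, rngs["dev"])

    def move(p: Population) -> Population:
        if grad.n_demes == 1 or life.dispersal_rate == 0.0:
            return p
        if life.dispersal_pattern is DispersalPattern.STEPPING_STONE:
            return disperse_stepping_stone(
                p, life.dispersal_rate, grad.n_demes, rngs["demo"]
            )
        return disperse_island(
            p, life.dispersal_rate, grad.n_demes, rngs["demo"]
        )

    if life.order is LifeHistoryOrder.MOVE_FIRST:
        pop = move(pop)
        pop = select(pop, env.theta_sel, life.sigma, rngs["demo"])
    else:
        pop = select(pop, env.theta_sel, life.sigma, rngs["demo"])
        pop = move(pop)

    pop = reproduce(
        pop,
        life.carrying_capacity,
        grad.n_demes,
        rngs["demo"],
        mutation_rate=config.mutation_rate,
        mutation_sd=config.mutation_sd,
    )
    return pop, env


def _instability_stat(pop: Population, config: SimConfig) -> float:
    """Population mean of the developmental-noise sd: mean summed
    instability alleles, or mean pleiotropic sd in the pleiotropic
    variant (where no instability loci exist)."""
    if config.loci.pleiotropic:
        return float(
            np.mean(
                pleiotropic_sd(pop.plastic, config.loci.pleiotropy_strength)
            )
        )
    if pop.instability is None:
        return np.nan
    return float(pop.instability.sum(axis=1).mean())


def run_replicate(config: SimConfig, seed: int, attempt: int = 0) -> ReplicateResult:
    """Run one replicate to completion or extinction.

    Per-generation statistics are taken on the juvenile cohort after
    reproduction, when every occupied deme holds exactly its carrying
    capacity — so the plain mean over individuals equals the
    equal-weight-per-deme mean.
    """
    rngs = _rng_streams(seed)
    pop, env = initialize(config, rngs["init"])
    n_gen = config.n_generations
    plast = np.full(n_gen, np.nan)
    inst = np.full(n_gen, np.nan)
    popsize = np.zeros(n_gen, dtype=np.int64)

    for t in range(n_gen):
        pop, env = run_generation(pop, env, config, rngs)
        if pop.size == 0:
            return ReplicateResult(
                seed=seed, attempt=attempt, extinct=True, n_generations_run=t + 1
            )
        if pop.plastic is not None:
            plast[t] = pop.plastic.sum(axis=1).mean()
        inst[t] = _instability_stat(pop, config)
        popsize[t] = pop.size

    w = config.report_window
    mean_p = float(np.mean(plast[-w:])) if pop.plastic is not None else None
    has_inst = pop.instability is not None or config.loci.pleiotropic
    series = None
    if config.record_series:
        series = {
            "generation": np.arange(1, n_gen + 1),
            "mean_plasticity": plast,
            "mean_instability": inst,
            "population_size": popsize,
        }
    return ReplicateResult(
        seed=seed,
        attempt=attempt,
        extinct=False,
        n_generations_run=n_gen,
        mean_plasticity=mean_p,
        final_plasticity=float(plast[-1]) if pop.plastic is not None else None,
        relative_plasticity=None
        if mean_p is None
        else mean_p / config.grad.optimal_slope,
        mean_instability=float(np.mean(inst[-w:])) if has_inst else None,
        final_instability=float(inst[-1]) if has_inst else None,
        series=series,
    )


def run_replicates(
    config: SimConfig, progress: Any = None
) -> list[ReplicateResult]:
    """Replicate a parameter combination, re-running extinctions.

    Attempt ``a`` (0-based) is seeded with ``base_seed + a``.  Attempts
    continue until ``n_replicates`` succeed or ``max_attempts`` have been
    made; the returned list contains every attempt, extinct ones included.
    An all-extinct outcome is a valid result, not an exception.
    ``progress``, if given, is called with each finished ReplicateResult.
    """
    results: list[ReplicateResult] = []
    successes = 0
    for attempt in range(config.max_attempts):
        if successes >= config.n_replicates:
            break
        res = run_replicate(config, config.base_seed + attempt, attempt)
        results.append(res)
        if not res.extinct:
            successes += 1
        if progress is not None:
            progress(res)
    return results
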