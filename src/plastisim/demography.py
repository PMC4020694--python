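"""Within-generation demography: viability selection, dispersal,
soft-selection reproduction.

Survival is Gaussian stabilizing selection around the local realized
optimum, ``W = exp(-(T - theta)^2 / (2 sigma^2))``, applied as an
independent Bernoulli trial per individual.  Dispersal is either
stepping-stone (Gaussian displacement rounded to whole demes, variance
calibrated so the probability of moving at all equals the configured rate,
terminal demes absorbing) or island (fixed move probability, destination
uniform over the other demes); dispersal itself is cost-free.  Reproduction
is soft selection: every occupied deme recruits exactly its carrying
capacity of offspring, each from a parent pair drawn uniformly with
replacement (selfing allowed) from the deme's adults.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.stats import norm

from .genetics import segregate, mutate
from .population import Population

__all__ = [
    "LifeHistoryOrder",
    "DispersalPattern",
    "LifeHistorySpec",
    "select",
    "stepping_stone_sd",
    "disperse_stepping_stone",
    "disperse_island",
    "reproduce",
]


class LifeHistoryOrder(str, Enum):
    MOVE_FIRST = "move_first"
    SELECT_FIRST = "select_first"


class DispersalPattern(str, Enum):
    STEPPING_STONE = "stepping_stone"
    ISLAND = "island"


@dataclass(frozen=True)
class LifeHistorySpec:
    """Life-cycle ordering, dispersal kernel and rate, selection strength,
    and per-deme carrying capacity.

    ``move_first``: birth, development, dispersal, selection, reproduction.
    ``select_first``: birth, development, selection, dispersal, reproduction.
    Both orders use the identical per-capita dispersal kernel; fewer
    individuals disperse under select-first only because selection has
    already thinned the demes.
    """

    order: LifeHistoryOrder = LifeHistoryOrder.MOVE_FIRST
    dispersal_pattern: DispersalPattern = DispersalPattern.STEPPING_STONE
    dispersal_rate: float = 0.32
    sigma: float = 2.0
    carrying_capacity: int = 100

    def __post_init__(self) -> None:
        if not 0.0 <= self.dispersal_rate < 1.0:
            raise ValueError("dispersal_rate must lie in [0, 1)")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.carrying_capacity < 1:
            raise ValueError("carrying_capacity must be >= 1")


def select(
    pop: Population,
    theta_sel: np.ndarray,
    sigma: float,
    rng: np.random.Generator,
) -> Population:
    """Gaussian viability selection against the local realized optimum.

    Each individual survives independently with probability
    ``exp(-(T - theta)^2 / (2 sigma^2))`` where ``theta`` is the
    selection-stage optimum of its *current* deme.  Survivors keep their
    phenotype and deme.
    """
    diff = pop.phenotype - theta_sel[pop.deme]
    w = np.exp(-(diff**2) / (2.0 * sigma**2))
    alive = rng.random(pop.size) < w
    return pop.subset(alive)


def stepping_stone_sd(rate: float) -> float:
    """Gaussian displacement sd ``s`` such that ``P(round(N(0, s)) != 0)``
    equals ``rate`` — i.e. ``2 * Phi(-0.5 / s) = rate``.

    Calibrating on the movement probability makes the configured dispersal
    rate comparable between the stepping-stone and island kernels.
    """
    if not 0.0 < rate < 1.0:
        raise ValueError("dispersal rate must lie in (0, 1)")
    return -0.5 / norm.ppf(rate / 2.0)


def disperse_stepping_stone(
    pop: Population, rate: float, n_demes: int, rng: np.random.Generator
) -> Population:
    """Distance-decaying dispersal along the gradient.

    Each individual draws a displacement ``round(N(0, s))`` with ``s`` from
    :func:`stepping_stone_sd`; higher rates mean both more movers and longer
    moves.  Individuals that would leave the gradient stop in the terminal
    deme.  No dispersal mortality.
    """
    if n_demes < 2:
        raise ValueError("dispersal requires >= 2 demes")
    if rate == 0.0:
        return pop
    s = stepping_stone_sd(rate)
    step = np.rint(rng.normal(0.0, s, size=pop.size)).astype(np.int64)
    pop.deme = np.clip(pop.deme + step, 0, n_demes - 1)
    return pop


def disperse_island(
    pop: Population, rate: float, n_demes: int, rng: np.random.Generator
) -> Population:
    """Gradient-free dispersal: move with probability ``rate``; movers land
    uniformly on any of the ``n_demes - 1`` other demes."""
    if n_demes < 2:
        raise ValueError("dispersal requires >= 2 demes")
    if rate == 0.0:
        return pop
    moves = rng.random(pop.size) < rate
    n_movers = int(moves.sum())
    if n_movers:
        dest = rng.integers(0, n_demes - 1, size=n_movers)
        dest += dest >= pop.deme[moves]  # skip the origin deme
        pop.deme[moves] = dest
    return pop


def reproduce(
    pop: Population,
    carrying_capacity: int,
    n_demes: int,
    rng: np.random.Generator,
    *,
    mutation_rate: float,
    mutation_sd: float,
) -> Population:
    """Soft-selection recruitment of the next generation of juveniles.

    Every deme holding at least one adult produces exactly
    ``carrying_capacity`` offspring, independent of how many adults
    survived.  Each offspring's mother and father are independent uniform
    draws with replacement from the deme's adults (selfing possible);
    inheritance is Mendelian with free recombination, then every allele
    mutates with ``mutation_rate`` adding ``N(0, mutation_sd)`` (instability
    alleles clamped at zero).  Empty demes recruit nothing this generation;
    they can be recolonized later.  Returns juveniles with undeveloped
    (NaN) phenotypes.
    """
    k = carrying_capacity
    classes = {
        "nonplastic": pop.nonplastic,
        "plastic": pop.plastic,
        "instability": pop.instability,
    }
    chunks: dict[str, list[np.ndarray]] = {
        name: [] for name, arr in classes.items() if arr is not None
    }
    demes: list[np.ndarray] = []

    for d in range(n_demes):
        adults = np.flatnonzero(pop.deme == d)
        if adults.size == 0:
            continue
        mothers = adults[rng.integers(0, adults.size, size=k)]
        fathers = adults[rng.integers(0, adults.size, size=k)]
        for name in chunks:
            arr = classes[name]
            gm = segregate(arr, mothers, rng)
            gf = segregate(arr, fathers, rng)
            child = np.empty((k, arr.shape[1]))
            child[:, 0::2] = gm
            child[:, 1::2] = gf
            chunks[name].append(child)
        demes.append(np.full(k, d, dtype=np.int64))

    if not demes:  # metapopulation extinct
        empty = np.empty((0, pop.nonplastic.shape[1]))
        return Population(
            nonplastic=empty,
            plastic=None if pop.plastic is None else empty.copy(),
            instability=None if pop.instability is None else empty.copy(),
            phenotype=np.empty(0),
            deme=np.empty(0, dtype=np.int64),
            natal_deme=np.empty(0, dtype=np.int64),
        )

    def stacked(name: str, nonneg: bool = False) -> np.ndarray:
        return mutate(
            np.vstack(chunks[name]),
            mutation_rate,
            mutation_sd,
            rng,
            nonnegative=nonneg,
        )

    deme_vec = np.concatenate(demes)
    return Population(
        nonplastic=stacked("nonplastic"),
        plastic=stacked("plastic") if pop.plastic is not None else None,
        instability=stacked("instability", nonneg=True)
        if pop.instability is not None
        else None,
        phenotype=np.full(deme_vec.size, np.nan),
        deme=deme_vec,
        natal_deme=deme_vec.copy(),
    )
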