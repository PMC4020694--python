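"""Spatial gradient and temporally varying optima.

Demes sit on a linear gradient: the mean optimum of deme ``i`` (1-based) is
``optimum_step * (i - (D + 1)/2)`` and the mean developmental cue is
``cue_slope * (i - (D + 1)/2)``; with the defaults (step 0.4, cue slope
0.04 per deme, 50 demes) optima span -9.8..+9.8 and the slope of the
optimal reaction norm is ``optimum_step / cue_slope = 10``.

On top of the gradient, among-generation change perturbs the realized
optimum at the development stage, the selection stage, or both, following
four patterns:

* **P1** — change at selection only (the cue never varies);
* **P2** — change at development only (selection optima stay fixed);
* **P3** — independent change at both stages (an unreliable cue);
* **P4** — change at development carries over to selection (a fully
  reliable cue).

Deviations follow a stationary AR(1) process with sd ``tau`` and lag-1
autocorrelation ``rho``::

    dev_t = rho * dev_{t-1} + tau * sqrt(1 - rho**2) * z_t

Deviates may be independent per deme or synchronized (one shared deviate
per generation shifting all demes alike).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "TemporalPattern",
    "GradientSpec",
    "TemporalSpec",
    "EnvironmentState",
    "init_environment",
    "step_environment",
    "developmental_cue",
]


class TemporalPattern(str, Enum):
    """Timing of among-generation environmental change."""

    NONE = "none"
    P1_SELECTION_ONLY = "p1_selection_only"
    P2_DEVELOPMENT_ONLY = "p2_development_only"
    P3_BOTH_INDEPENDENT = "p3_both_independent"
    P4_DEVELOPMENT_CARRIES_OVER = "p4_development_carries_over"

    @property
    def varies_dev(self) -> bool:
        return self in (
            TemporalPattern.P2_DEVELOPMENT_ONLY,
            TemporalPattern.P3_BOTH_INDEPENDENT,
            TemporalPattern.P4_DEVELOPMENT_CARRIES_OVER,
        )

    @property
    def varies_sel(self) -> bool:
        return self in (
            TemporalPattern.P1_SELECTION_ONLY,
            TemporalPattern.P3_BOTH_INDEPENDENT,
            TemporalPattern.P4_DEVELOPMENT_CARRIES_OVER,
        )


@dataclass(frozen=True)
class GradientSpec:
    """Linear spatial gradient of optima and cues."""

    n_demes: int = 50
    optimum_step: float = 0.4
    cue_slope: float = 0.04

    def __post_init__(self) -> None:
        if self.n_demes < 1:
            raise ValueError("n_demes must be >= 1")
        if self.optimum_step <= 0 or self.cue_slope <= 0:
            raise ValueError("gradient slopes must be positive")

    @property
    def optimal_slope(self) -> float:
        """Reaction-norm slope that exactly tracks the gradient (10)."""
        return self.optimum_step / self.cue_slope

    @property
    def span(self) -> float:
        """Difference in mean optima between the two terminal demes."""
        return self.optimum_step * (self.n_demes - 1)

    def mean_optima(self) -> np.ndarray:
        """Per-deme mean optimum; centred so the middle of the array is 0."""
        i = np.arange(self.n_demes, dtype=float)
        return self.optimum_step * (i - (self.n_demes - 1) / 2.0)

    def mean_cues(self) -> np.ndarray:
        """Per-deme mean developmental cue (E_i)."""
        i = np.arange(self.n_demes, dtype=float)
        return self.cue_slope * (i - (self.n_demes - 1) / 2.0)


@dataclass(frozen=True)
class TemporalSpec:
    """Among-generation environmental variation.

    ``tau`` is the *stationary* sd of the deviation process on the optimum
    scale; ``rho`` the lag-1 autocorrelation; ``synchronized`` shares a
    single deviate across demes each generation.
    """

    pattern: TemporalPattern = TemporalPattern.NONE
    tau: float = 0.0
    rho: float = 0.0
    synchronized: bool = False

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("|rho| must be < 1")


@dataclass
class EnvironmentState:
    """Realized optima and AR(1) carry state for the current generation.

    ``carry_dev`` / ``carry_sel`` hold the previous deviation from the mean
    optimum at each stage; ``theta_dev`` / ``theta_sel`` the realized
    per-deme optima after the latest :func:`step_environment`.
    """

    theta_dev: np.ndarray
    theta_sel: np.ndarray
    carry_dev: np.ndarray
    carry_sel: np.ndarray


def _innovation(
    spec: TemporalSpec, n_demes: int, rng: np.random.Generator
) -> np.ndarray:
    """One generation's unit-variance shock; shared across demes when
    synchronized, otherwise independent per deme."""
    if spec.synchronized:
        return np.full(n_demes, rng.standard_normal())
    return rng.standard_normal(n_demes)


def init_environment(
    spec: TemporalSpec, grad: GradientSpec, rng: np.random.Generator
) -> EnvironmentState:
    """Initial state with AR(1) carries drawn from the stationary
    distribution ``Normal(0, tau^2)`` (zero for stages that do not vary)."""
    mean = grad.mean_optima()
    d = grad.n_demes

    def stationary(varies: bool) -> np.ndarray:
        if not varies or spec.tau == 0:
            return np.zeros(d)
        return spec.tau * _innovation(spec, d, rng)

    carry_dev = stationary(spec.pattern.varies_dev)
    if spec.pattern is TemporalPattern.P4_DEVELOPMENT_CARRIES_OVER:
        carry_sel = carry_dev.copy()
    else:
        carry_sel = stationary(spec.pattern.varies_sel)
    return EnvironmentState(
        theta_dev=mean + carry_dev,
        theta_sel=mean + carry_sel,
        carry_dev=carry_dev,
        carry_sel=carry_sel,
    )


def step_environment(
    state: EnvironmentState,
    spec: TemporalSpec,
    grad: GradientSpec,
    rng: np.random.Generator,
) -> EnvironmentState:
    """Advance the realized optima by one generation (call before
    development).

    Each varying stage updates its deviation by the stationary AR(1)
    recursion; under P4 a single deviate drives development and carries
    over unchanged to selection.  Non-varying stages stay at the mean
    optima.  The input state is not modified.
    """
    mean = grad.mean_optima()
    d = grad.n_demes
    tau, rho = spec.tau, spec.rho
    scale = tau * np.sqrt(1.0 - rho**2)

    def advance(carry: np.ndarray) -> np.ndarray:
        return rho * carry + scale * _innovation(spec, d, rng)

    if spec.pattern is TemporalPattern.P4_DEVELOPMENT_CARRIES_OVER and tau > 0:
        carry_dev = advance(state.carry_dev)
        carry_sel = carry_dev.copy()
    else:
        carry_dev = (
            advance(state.carry_dev)
            if spec.pattern.varies_dev and tau > 0
            else np.zeros(d)
        )
        carry_sel = (
            advance(state.carry_sel)
            if spec.pattern.varies_sel and tau > 0
            else np.zeros(d)
        )
    return EnvironmentState(
        theta_dev=mean + carry_dev,
        theta_sel=mean + carry_sel,
        carry_dev=carry_dev,
        carry_sel=carry_sel,
    )


def developmental_cue(
    state: EnvironmentState, grad: GradientSpec, deme: int | np.ndarray
) -> float | np.ndarray:
    """Cue perceived at development in ``deme`` (0-based index).

    The realized developmental optimum rescaled into cue units by the fixed
    ratio ``cue_slope / optimum_step``, so a slope-10 reaction norm exactly
    tracks any perturbation that carries over to selection (pattern P4).
    Equals the fixed mean cue E_i when ``tau = 0`` or under pattern P1.
    """
    ratio = grad.cue_slope / grad.optimum_step
    theta = state.theta_dev[deme]
    if np.ndim(deme) == 0:
        return float(theta) * ratio
    return theta * ratio
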