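"""Deterministic representations of a cohort model.

Two classical views of the same linear dynamics:

* **cohort simulation** — the discrete-time recursion ``N(t + tau) = N(t) P_tau``
  that projects a real-valued occupancy vector forward one Markov cycle at a
  time;
* **continuous-time cohort model** — the ODE ``dN/dt = N Q`` obtained as the
  cycle-length-to-zero limit of the recursion, solved exactly here by the
  matrix exponential ``N(t) = N(0) exp(Q t)`` (the equation is linear with
  constant coefficients, so no numerical stepping is needed).

Both conserve total cohort mass because rows of ``P_tau`` sum to one (rows of
``Q`` sum to zero).  The single-individual Markov chain ``p(t + tau) = p(t)
P_tau`` is the same recursion on a probability vector.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Union

import numpy as np

from .core import (
    DistributionVector,
    GeneratorMatrix,
    ModelValidationError,
    OccupancyVector,
    TimeGrid,
    TransitionProbabilityMatrix,
    propagator,
    transition_matrix,
    _check_states_match,
)

__all__ = [
    "DeterministicTrajectory",
    "chain_step",
    "cohort_step",
    "cohort_simulate",
    "ode_mean_trajectory",
]


@dataclass(frozen=True)
class DeterministicTrajectory:
    """Occupancy (or distribution) vectors evaluated on a time grid."""

    grid: TimeGrid
    values: tuple  # per-time OccupancyVector or DistributionVector

    def __post_init__(self):
        if len(self.values) != self.grid.n_points:
            raise ModelValidationError("one value per grid time is required")

    def as_array(self) -> np.ndarray:
        """(n_times, s) array of the per-state values."""
        rows = [
            v.values if isinstance(v, OccupancyVector) else v.probs
            for v in self.values
        ]
        return np.asarray(rows)

    @property
    def states(self):
        return self.values[0].states


def chain_step(
    p: DistributionVector, P: TransitionProbabilityMatrix
) -> DistributionVector:
    """One cycle of the single-individual chain: p -> p P."""
    _check_states_match(p.states, P.states)
    return DistributionVector(states=p.states, probs=p.probs @ P.probs)


def cohort_step(
    N: OccupancyVector, P: TransitionProbabilityMatrix
) -> OccupancyVector:
    """One cycle of cohort simulation: N -> N P; total mass is conserved."""
    _check_states_match(N.states, P.states)
    return OccupancyVector(
        states=N.states, values=N.values @ P.probs, time=N.time + P.step
    )


def cohort_simulate(
    N0: OccupancyVector, Q: GeneratorMatrix, grid: TimeGrid
) -> DeterministicTrajectory:
    """Discrete-time cohort simulation on a uniform grid with cycle tau.

    values[n] = N0 (P_tau)^n with P_tau = exp(Q tau), computed by repeated
    vector-matrix products.
    """
    _check_states_match(N0.states, Q.states)
    if not grid.is_uniform():
        raise ModelValidationError(
            "cohort simulation is cycle-based and needs a uniform grid"
        )
    if not N0.total > 0:
        raise ModelValidationError("initial cohort size must be positive")
    P = transition_matrix(Q, grid.cycle)
    values: List[OccupancyVector] = [
        OccupancyVector(states=N0.states, values=N0.values, time=grid.times[0])
    ]
    current = N0.values
    for t in grid.times[1:]:
        current = current @ P.probs
        values.append(OccupancyVector(states=N0.states, values=current, time=t))
    return DeterministicTrajectory(grid=grid, values=tuple(values))


def ode_mean_trajectory(
    N0: OccupancyVector, Q: GeneratorMatrix, grid: TimeGrid
) -> DeterministicTrajectory:
    """Continuous-time cohort model dN/dt = N Q, solved exactly.

    values at time t equal N0 exp(Q (t - t0)); works on any strictly
    increasing grid, uniform or not, with no step-size artifacts.
    """
    _check_states_match(N0.states, Q.states)
    values = []
    for t in grid.times:
        B = propagator(Q, t - grid.t0)
        values.append(
            OccupancyVector(states=N0.states, values=N0.values @ B.probs, time=t)
        )
    return DeterministicTrajectory(grid=grid, values=tuple(values))
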