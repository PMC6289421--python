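"""Core domain objects for continuous-time state-transition cohort models.

A model is specified by a finite set of health states and an infinitesimal
generator matrix ``Q`` of transition intensities (units: 1/time, years by
default).  Off-diagonal entries of ``Q`` are the per-individual transition
rates ``c_kl`` between distinct states; diagonal entries are forced to the
negative row sums so that every row of ``Q`` sums to zero.  The transition
probability matrix over a duration ``t`` is the matrix exponential
``B(t) = exp(Q t)``, which is row-stochastic and satisfies the semigroup
property ``B(a) B(b) = B(a + b)``.

The inverse direction — recovering ``Q`` from a discrete-time transition
probability matrix — is the embedding problem; it is solved here with the
principal matrix logarithm and succeeds only when the result is a valid
generator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence, Tuple

import numpy as np
from scipy.linalg import expm, logm

logger = logging.getLogger("cohortme")

DEFAULT_TIME_UNIT = "years"

#: Off-diagonal entries of a candidate generator logarithm more negative than
#: this are a hard embeddability failure; entries in [-EMBED_TOL, 0) are
#: treated as logm round-off and clipped to zero.
EMBED_TOL = 1e-8

ROW_SUM_TOL = 1e-10


class ModelValidationError(ValueError):
    """A model object violates its invariants (bad rates, labels, grids...)."""


class NotEmbeddableError(ModelValidationError):
    """A transition probability matrix has no valid continuous-time generator."""


class NumericalError(RuntimeError):
    """A numerical routine (integrator, logarithm) failed to converge."""


# ---------------------------------------------------------------------------
# State space and vectors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StateSpace:
    """Ordered, mutually exclusive and exhaustive health states."""

    labels: Tuple[str, ...]

    def __init__(self, labels: Sequence[str]):
        labels = tuple(str(x) for x in labels)
        if len(labels) < 2:
            raise ModelValidationError("a state space needs at least 2 states")
        if len(set(labels)) != len(labels):
            raise ModelValidationError(f"state labels must be unique: {labels}")
        if any(not lab for lab in labels):
            raise ModelValidationError("state labels must be non-empty")
        object.__setattr__(self, "labels", labels)

    @property
    def s(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise ModelValidationError(
                f"unknown state label {label!r}; declared states are {self.labels}"
            ) from None


def _check_states_match(a: StateSpace, b: StateSpace) -> None:
    if a.labels != b.labels:
        raise ModelValidationError(
            f"state spaces do not match: {a.labels} vs {b.labels}"
        )


@dataclass(frozen=True)
class GeneratorMatrix:
    """Infinitesimal generator Q: off-diagonals >= 0, rows sum to zero."""

    states: StateSpace
    rates: np.ndarray
    time_unit: str = DEFAULT_TIME_UNIT

    def __post_init__(self):
        rates = np.asarray(self.rates, dtype=float)
        s = self.states.s
        if rates.shape != (s, s):
            raise ModelValidationError(
                f"rate matrix shape {rates.shape} does not match {s} states"
            )
        off = rates.copy()
        np.fill_diagonal(off, 0.0)
        if np.any(off < 0):
            k, l = np.argwhere(off < 0)[0]
            raise ModelValidationError(
                f"negative off-diagonal rate {rates[k, l]} for transition "
                f"{self.states.labels[k]} -> {self.states.labels[l]}"
            )
        if np.max(np.abs(rates.sum(axis=1))) > 1e-12 * max(1.0, np.max(np.abs(rates))):
            raise ModelValidationError("generator rows must sum to zero")
        object.__setattr__(self, "rates", rates)

    @property
    def s(self) -> int:
        return self.states.s

    def rate(self, source: str, target: str) -> float:
        return float(self.rates[self.states.index(source), self.states.index(target)])

    def absorbing_states(self) -> Tuple[str, ...]:
        """States with no outgoing rate."""
        off = self.rates.copy()
        np.fill_diagonal(off, 0.0)
        return tuple(
            lab for lab, row in zip(self.states.labels, off) if np.all(row == 0.0)
        )


@dataclass(frozen=True)
class TransitionProbabilityMatrix:
    """Row-stochastic matrix of transition probabilities over a step tau."""

    states: StateSpace
    probs: np.ndarray
    step: float

    def __post_init__(self):
        probs = np.asarray(self.probs, dtype=float)
        s = self.states.s
        if probs.shape != (s, s):
            raise ModelValidationError(
                f"probability matrix shape {probs.shape} does not match {s} states"
            )
        if not self.step > 0:
            raise ModelValidationError(f"time step must be positive, got {self.step}")
        if np.any(probs < -1e-12) or np.any(probs > 1 + 1e-12):
            raise ModelValidationError("transition probabilities must lie in [0, 1]")
        # entries within 1e-12 of the boundary are round-off: clip
        probs = np.clip(probs, 0.0, 1.0)
        if np.max(np.abs(probs.sum(axis=1) - 1.0)) > ROW_SUM_TOL:
            raise ModelValidationError("transition probability rows must sum to 1")
        object.__setattr__(self, "probs", probs)

    @property
    def s(self) -> int:
        return self.states.s


@dataclass(frozen=True)
class StateConfiguration:
    """Integer vector of population counts per state (a lattice point)."""

    states: StateSpace
    counts: np.ndarray
    time: float = 0.0

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.shape != (self.states.s,):
            raise ModelValidationError(
                f"counts shape {counts.shape} does not match {self.states.s} states"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            if np.any(np.abs(counts - rounded) > 0):
                raise ModelValidationError("counts must be integers")
            counts = rounded.astype(np.int64)
        else:
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise ModelValidationError("counts must be nonnegative")
        if self.time < 0:
            raise ModelValidationError("time stamp must be nonnegative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class OccupancyVector:
    """Real-valued occupancy per state: the cohort-simulation relaxation."""

    states: StateSpace
    values: np.ndarray
    time: float = 0.0

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.shape != (self.states.s,):
            raise ModelValidationError(
                f"values shape {values.shape} does not match {self.states.s} states"
            )
        if np.any(values < -1e-9 * max(1.0, values.sum())):
            raise ModelValidationError("occupancy values must be nonnegative")
        object.__setattr__(self, "values", np.maximum(values, 0.0))

    @property
    def total(self) -> float:
        return float(self.values.sum())


@dataclass(frozen=True)
class DistributionVector:
    """Probability distribution of a single individual over states."""

    states: StateSpace
    probs: np.ndarray

    def __post_init__(self):
        probs = np.asarray(self.probs, dtype=float)
        if probs.shape != (self.states.s,):
            raise ModelValidationError(
                f"probs shape {probs.shape} does not match {self.states.s} states"
            )
        if np.any(probs < -1e-12) or np.any(probs > 1 + 1e-12):
            raise ModelValidationError("probabilities must lie in [0, 1]")
        probs = np.clip(probs, 0.0, 1.0)
        if abs(probs.sum() - 1.0) > 1e-10:
            raise ModelValidationError("probabilities must sum to 1")
        object.__setattr__(self, "probs", probs)


@dataclass(frozen=True)
class TimeGrid:
    """Strictly increasing evaluation times; uniform grids carry a cycle tau."""

    t0: float
    times: np.ndarray
    cycle: float | None = None

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        if times.ndim != 1 or times.size < 1:
            raise ModelValidationError("a time grid needs at least one time")
        if np.any(np.diff(times) <= 0):
            raise ModelValidationError("grid times must be strictly increasing")
        if times[0] < self.t0:
            raise ModelValidationError("grid times must not precede t0")
        if self.cycle is not None:
            if not self.cycle > 0:
                raise ModelValidationError("cycle length must be positive")
            expected = self.t0 + np.arange(times.size) * self.cycle
            if not np.array_equal(times, expected):
                raise ModelValidationError(
                    "uniform grid times must equal t0 + n*cycle exactly"
                )
        object.__setattr__(self, "times", times)

    @classmethod
    def uniform(cls, t0: float, cycle: float, n_cycles: int) -> "TimeGrid":
        """Grid t0, t0+tau, ..., t0 + n_cycles*tau (n_cycles+1 points)."""
        if n_cycles < 0:
            raise ModelValidationError("number of cycles must be nonnegative")
        times = t0 + np.arange(n_cycles + 1) * float(cycle)
        return cls(t0=t0, times=times, cycle=float(cycle))

    @classmethod
    def from_times(cls, times: Sequence[float]) -> "TimeGrid":
        times = np.asarray(times, dtype=float)
        return cls(t0=float(times[0]), times=times, cycle=None)

    @property
    def n_points(self) -> int:
        return int(self.times.size)

    def is_uniform(self) -> bool:
        return self.cycle is not None


# ---------------------------------------------------------------------------
# Construction and conversions
# ---------------------------------------------------------------------------

def build_generator(
    states: StateSpace,
    rate_table: Mapping[Tuple[str, str], float],
    time_unit: str = DEFAULT_TIME_UNIT,
) -> GeneratorMatrix:
    """Assemble Q from a (source, target) -> rate table.

    Unspecified pairs get rate zero.  Self-rates are rejected: a self
    transition leaves the configuration unchanged and would be
    unidentifiable, so diagonals are always derived as negative row sums.
    """
    s = states.s
    rates = np.zeros((s, s))
    for (src, tgt), rate in rate_table.items():
        if src == tgt:
            raise ModelValidationError(
                f"self-transition rate for state {src!r} is not allowed; "
                "diagonal entries are derived from the off-diagonal rates"
            )
        i, j = states.index(src), states.index(tgt)
        if rate < 0:
            raise ModelValidationError(
                f"negative rate {rate} for transition {src!r} -> {tgt!r}"
            )
        rates[i, j] = float(rate)
    np.fill_diagonal(rates, 0.0)
    np.fill_diagonal(rates, -rates.sum(axis=1))
    return GeneratorMatrix(states=states, rates=rates, time_unit=time_unit)


def propagator(Q: GeneratorMatrix, t: float) -> TransitionProbabilityMatrix:
    """B(t) = exp(Q t): the transition probability matrix over duration t.

    Uses scipy's scaling-and-squaring matrix exponential.  ``t`` may be zero
    (the identity); a degenerate "step" of the smallest positive float is
    recorded in that case so the returned object stays valid.
    """
    if t < 0:
        raise ModelValidationError(f"propagation time must be nonnegative, got {t}")
    if t == 0:
        probs = np.eye(Q.s)
    else:
        probs = expm(Q.rates * t)
        probs = np.clip(probs, 0.0, 1.0)
    step = t if t > 0 else np.finfo(float).tiny
    return TransitionProbabilityMatrix(states=Q.states, probs=probs, step=step)


def transition_matrix(Q: GeneratorMatrix, tau: float) -> TransitionProbabilityMatrix:
    """P_tau = exp(Q tau): the one-cycle transition probability matrix."""
    if not tau > 0:
        raise ModelValidationError(f"cycle length must be positive, got {tau}")
    return propagator(Q, tau)


def generator_from_transition_matrix(
    P: TransitionProbabilityMatrix,
) -> GeneratorMatrix:
    """Recover Q from P by the principal matrix logarithm: Q = logm(P)/tau.

    Raises :class:`NotEmbeddableError` when P has an eigenvalue off the
    positive real axis analytically incompatible with a real principal
    logarithm, or when the candidate logarithm has an off-diagonal entry
    below ``-EMBED_TOL``.  Off-diagonal entries in ``[-EMBED_TOL, 0)`` are
    clipped to zero as round-off and the diagonal is re-forced.
    """
    eig = np.linalg.eigvals(P.probs)
    bad = eig[(np.abs(eig.imag) < 1e-12) & (eig.real <= 0)]
    if bad.size:
        raise NotEmbeddableError(
            f"transition matrix has non-positive real eigenvalue(s) {bad}; "
            "no real principal logarithm exists"
        )
    L = logm(P.probs)
    if np.max(np.abs(L.imag)) > 1e-8:
        raise NotEmbeddableError(
            "principal matrix logarithm is not real "
            f"(max imaginary part {np.max(np.abs(L.imag)):.3g})"
        )
    Qcand = L.real / P.step
    off = Qcand.copy()
    np.fill_diagonal(off, 0.0)
    if np.any(off < -EMBED_TOL):
        idx = np.argwhere(off < -EMBED_TOL)
        offenders = [
            (P.states.labels[k], P.states.labels[l], float(Qcand[k, l]))
            for k, l in idx
        ]
        raise NotEmbeddableError(
            f"matrix logarithm has negative off-diagonal entries {offenders}; "
            "the transition matrix is not embeddable"
        )
    off = np.maximum(off, 0.0)
    np.fill_diagonal(off, -off.sum(axis=1) + np.diag(off))
    rates = off
    np.fill_diagonal(rates, 0.0)
    np.fill_diagonal(rates, -rates.sum(axis=1))
    return GeneratorMatrix(states=P.states, rates=rates)
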