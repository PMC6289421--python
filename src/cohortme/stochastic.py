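"""Monte Carlo engines for the cohort process.

Two exact samplers of the same stochastic process:

* **microsimulation** — discrete-time: each Markov cycle, the occupants of
  every state are redistributed by one multinomial draw with that state's row
  of ``P_tau = exp(Q tau)``.  Because individuals are exchangeable and
  independent, this is distributionally identical to simulating ``n0``
  individual Markov chains, at a fraction of the cost.
* **Gillespie SSA (direct method)** — continuous-time: with total propensity
  ``Lambda(n) = sum_{k != l} c_kl n_k``, waiting times are exponential with
  rate ``Lambda`` and each event is chosen with probability proportional to
  its propensity ``c_kl n_k``.  The resulting event path is an exact sample
  of the master equation's process.

Seeding contract: a single user seed reproduces a whole ensemble; replicate
``r`` uses the stream ``numpy.random.default_rng(numpy.random.SeedSequence(
seed, spawn_key=(r,)))``, so any replicate can be regenerated in isolation
and distinct replicates get independent streams.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy import stats

from .core import (
    GeneratorMatrix,
    ModelValidationError,
    StateConfiguration,
    TimeGrid,
    TransitionProbabilityMatrix,
    _check_states_match,
)
from .master_eq import MomentTrajectory, events_from_generator

__all__ = [
    "ReplicateEnsemble",
    "EnsembleSummary",
    "EventRecord",
    "SSAPath",
    "replicate_rng",
    "microsim_replicate",
    "microsim_ensemble",
    "ssa_replicate",
    "ssa_ensemble",
    "ensemble_summary",
    "compare_to_analytic",
    "ComparisonReport",
]


def replicate_rng(seed: int, replicate: int) -> np.random.Generator:
    """Independent stream for one replicate; part of the public contract."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(replicate,)))


@dataclass(frozen=True)
class ReplicateEnsemble:
    """Integer count trajectories from repeated Monte Carlo runs."""

    grid: TimeGrid
    counts: np.ndarray        # (R, n_times, s) integer counts
    seed: int                 # master seed; replicate r uses replicate_rng(seed, r)
    engine: str               # "microsim" or "ssa"

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 3 or counts.shape[1] != self.grid.n_points:
            raise ModelValidationError("ensemble counts must be (R, n_times, s)")
        totals = counts.sum(axis=2)
        if not np.all(totals == totals[:, :1]):
            raise ModelValidationError("replicates must conserve the cohort total")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def n_replicates(self) -> int:
        return int(self.counts.shape[0])

    @property
    def n0(self) -> int:
        return int(self.counts[0, 0].sum())


@dataclass(frozen=True)
class EnsembleSummary:
    """Empirical mean and unbiased (R-1 denominator) variance per state/time."""

    grid: TimeGrid
    mean: np.ndarray
    variance: np.ndarray
    n_replicates: int

    def __post_init__(self):
        if self.n_replicates < 2:
            raise ModelValidationError(
                "at least 2 replicates are required for an unbiased variance"
            )
        if np.any(np.asarray(self.variance) < 0):
            raise ModelValidationError("empirical variances must be nonnegative")


@dataclass(frozen=True)
class EventRecord:
    """One SSA event: at `time`, one individual moved source -> target."""

    time: float
    source: int
    target: int


@dataclass(frozen=True)
class SSAPath:
    """A full SSA realization: the event log plus a trajectory sampler."""

    initial: StateConfiguration
    events: Tuple[EventRecord, ...]
    t_max: float

    def at(self, t: float) -> np.ndarray:
        """Configuration at query time t (right-continuous step convention).

        An event with time stamp exactly t has already taken effect at t.
        """
        if t < self.initial.time:
            raise ModelValidationError("query time precedes the initial time")
        counts = self.initial.counts.copy()
        # bisect_right: events at exactly t are included
        times = [e.time for e in self.events]
        upto = bisect.bisect_right(times, t)
        for e in self.events[:upto]:
            counts[e.source] -= 1
            counts[e.target] += 1
        return counts

    def sample(self, times: Sequence[float]) -> np.ndarray:
        """Configurations at each query time, as an (n_times, s) array."""
        out = np.empty((len(times), self.initial.counts.size), dtype=np.int64)
        ev_times = [e.time for e in self.events]
        counts = self.initial.counts.copy()
        pos = 0
        for j, t in enumerate(sorted_check(times)):
            upto = bisect.bisect_right(ev_times, t)
            for e in self.events[pos:upto]:
                counts[e.source] -= 1
                counts[e.target] += 1
            pos = upto
            out[j] = counts
        return out


def sorted_check(times: Sequence[float]) -> Sequence[float]:
    if np.any(np.diff(np.asarray(times, dtype=float)) < 0):
        raise ModelValidationError("query times must be nondecreasing")
    return times


# ---------------------------------------------------------------------------
# Microsimulation
# ---------------------------------------------------------------------------

def microsim_replicate(
    n0cfg: StateConfiguration,
    P: TransitionProbabilityMatrix,
    steps: int,
    seed: int,
    replicate: int = 0,
) -> np.ndarray:
    """One microsimulation trajectory: (steps+1, s) integer counts.

    Per cycle, each state's occupants are redistributed by a single
    multinomial draw with that state's row of P — equivalent in law to
    independent individual chains.  Identical (seed, replicate) pairs give
    bit-identical trajectories.
    """
    _check_states_match(n0cfg.states, P.states)
    if steps < 1:
        raise ModelValidationError("at least one cycle is required")
    rng = replicate_rng(seed, replicate)
    s = P.s
    out = np.empty((steps + 1, s), dtype=np.int64)
    out[0] = n0cfg.counts
    current = n0cfg.counts.copy()
    for step in range(1, steps + 1):
        nxt = np.zeros(s, dtype=np.int64)
        for k in range(s):
            if current[k] == 0:
                continue
            nxt += rng.multinomial(current[k], P.probs[k])
        current = nxt
        out[step] = current
    return out


def microsim_ensemble(
    n0cfg: StateConfiguration,
    P: TransitionProbabilityMatrix,
    grid: TimeGrid,
    n_replicates: int,
    seed: int,
) -> ReplicateEnsemble:
    """R independent microsimulation replicates on a uniform cycle grid."""
    if not grid.is_uniform():
        raise ModelValidationError("microsimulation needs a uniform cycle grid")
    if abs(grid.cycle - P.step) > 1e-12 * max(grid.cycle, P.step):
        raise ModelValidationError(
            f"grid cycle {grid.cycle} does not match the matrix step {P.step}"
        )
    steps = grid.n_points - 1
    counts = np.empty((n_replicates, grid.n_points, P.s), dtype=np.int64)
    for r in range(n_replicates):
        counts[r] = microsim_replicate(n0cfg, P, steps, seed, replicate=r)
    return ReplicateEnsemble(grid=grid, counts=counts, seed=seed, engine="microsim")


# ---------------------------------------------------------------------------
# Gillespie SSA (direct method)
# ---------------------------------------------------------------------------

def ssa_replicate(
    n0cfg: StateConfiguration,
    Q: GeneratorMatrix,
    t_max: float,
    seed: int,
    replicate: int = 0,
) -> SSAPath:
    """One exact continuous-time realization by the Gillespie direct method.

    Terminates at t_max or when the total propensity hits zero (all mass in
    absorbing states).
    """
    _check_states_match(n0cfg.states, Q.states)
    if not t_max > 0:
        raise ModelValidationError("t_max must be positive")
    rng = replicate_rng(seed, replicate)
    channels = events_from_generator(Q)
    rates = np.array([c.rate for c in channels], dtype=float)
    sources = np.array([c.source for c in channels], dtype=np.int64)
    targets = np.array([c.target for c in channels], dtype=np.int64)
    counts = n0cfg.counts.copy()
    t = float(n0cfg.time)
    events: List[EventRecord] = []
    while True:
        prop = rates * counts[sources]
        lam = prop.sum()
        if lam <= 0:
            break
        t += rng.exponential(1.0 / lam)
        if t > t_max:
            break
        j = np.searchsorted(np.cumsum(prop), rng.random() * lam, side="right")
        j = min(j, prop.size - 1)
        counts[sources[j]] -= 1
        counts[targets[j]] += 1
        events.append(EventRecord(time=t, source=int(sources[j]), target=int(targets[j])))
    return SSAPath(initial=n0cfg, events=tuple(events), t_max=float(t_max))


def ssa_ensemble(
    n0cfg: StateConfiguration,
    Q: GeneratorMatrix,
    grid: TimeGrid,
    n_replicates: int,
    seed: int,
) -> ReplicateEnsemble:
    """R independent SSA realizations sampled at the grid times."""
    t_max = float(grid.times[-1])
    counts = np.empty((n_replicates, grid.n_points, Q.s), dtype=np.int64)
    for r in range(n_replicates):
        path = ssa_replicate(n0cfg, Q, max(t_max, 1e-12), seed, replicate=r)
        counts[r] = path.sample(grid.times)
    return ReplicateEnsemble(grid=grid, counts=counts, seed=seed, engine="ssa")


# ---------------------------------------------------------------------------
# Summaries and comparison with the analytic moments
# ---------------------------------------------------------------------------

def ensemble_summary(ensemble: ReplicateEnsemble) -> EnsembleSummary:
    """Empirical per-state/time mean and unbiased variance across replicates."""
    if ensemble.n_replicates < 2:
        raise ModelValidationError(
            "at least 2 replicates are required for an unbiased variance"
        )
    mean = ensemble.counts.mean(axis=0)
    var = ensemble.counts.var(axis=0, ddof=1)
    return EnsembleSummary(
        grid=ensemble.grid, mean=mean, variance=var,
        n_replicates=ensemble.n_replicates,
    )


@dataclass(frozen=True)
class ComparisonReport:
    """Cell-by-cell agreement between an ensemble and the analytic moments."""

    grid: TimeGrid
    mean_z: np.ndarray           # z-scores of the empirical means
    mean_pass: np.ndarray        # |z| <= z_limit per cell (bool)
    variance_pass: np.ndarray    # inside the two-sided chi-square interval
    mean_pass_fraction: float
    variance_pass_fraction: float
    z_limit: float
    interval_level: float

    @property
    def pass_fraction(self) -> float:
        both = self.mean_pass & self.variance_pass
        return float(both.mean())


def compare_to_analytic(
    summary: EnsembleSummary,
    analytic: MomentTrajectory,
    z_limit: float = 3.0,
    interval_level: float = 0.99,
) -> ComparisonReport:
    """Check empirical moments against the analytic mean/variance formulas.

    Means: per-cell z = (empirical - analytic) / sqrt(V_i(t)/R); pass when
    |z| <= z_limit.  Variances: pass when the empirical (unbiased) variance
    falls inside the two-sided chi-square interval
    [V * chi2_{alpha/2, R-1}/(R-1), V * chi2_{1-alpha/2, R-1}/(R-1)] with
    alpha = 1 - interval_level.  Cells with analytic variance zero require
    exact agreement.
    """
    if summary.grid.n_points != analytic.grid.n_points or np.any(
        summary.grid.times != analytic.grid.times
    ):
        raise ModelValidationError("summary and analytic grids do not align")
    R = summary.n_replicates
    V = analytic.variance
    M = analytic.mean
    degenerate = V <= 1e-12
    se = np.sqrt(np.where(degenerate, 1.0, V) / R)
    z = np.where(
        degenerate,
        np.where(np.abs(summary.mean - M) <= 1e-9, 0.0, np.inf),
        (summary.mean - M) / se,
    )
    mean_pass = np.abs(z) <= z_limit
    alpha = 1.0 - interval_level
    lo_q = stats.chi2.ppf(alpha / 2, R - 1) / (R - 1)
    hi_q = stats.chi2.ppf(1 - alpha / 2, R - 1) / (R - 1)
    variance_pass = np.where(
        degenerate,
        summary.variance <= 1e-12,
        (summary.variance >= V * lo_q) & (summary.variance <= V * hi_q),
    )
    return ComparisonReport(
        grid=summary.grid,
        mean_z=z,
        mean_pass=mean_pass,
        variance_pass=variance_pass,
        mean_pass_fraction=float(mean_pass.mean()),
        variance_pass_fraction=float(variance_pass.mean()),
        z_limit=z_limit,
        interval_level=interval_level,
    )
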