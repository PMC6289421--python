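"""Master equation of the cohort process on the integer count lattice.

A cohort of ``n0`` exchangeable individuals moving independently among ``s``
states with rates ``c_kl`` defines a continuous-time Markov chain on the
lattice of count vectors ``n`` with fixed total ``n0``.  A transition event
``R_kl`` moves one individual from state k to state l, changing the
configuration by ``s_kl = e_l - e_k``, and fires with propensity
``nu_kl(n) = c_kl * n_k`` (each of the ``n_k`` occupants of the source state
can make the move).  The probability ``P(n, t)`` of observing configuration
``n`` evolves by the forward Kolmogorov (master) equation

    dP(n,t)/dt = sum_{k != l} [ nu_kl(n - s_kl) P(n - s_kl, t)
                                - nu_kl(n) P(n, t) ],

a balance of probability flux into and out of ``n``.

Because individuals are independent, the master equation has a closed-form
solution.  With all individuals starting in state 1, ``N(t)`` is multinomial
with category probabilities given by the first row of the propagator
``B(t) = exp(Q t)``:

    P(n, t) = n0! * prod_m B_1m(t)^{n_m} / n_m!

with probability generating function ``G(x, t) = (sum_m x_m B_1m(t))^{n0}``,
mean ``E[N_i(t)] = n0 B_1i(t)`` and variance
``V_i(t) = n0 B_1i(t) (1 - B_1i(t))``.  For an arbitrary initial distribution
over configurations, the solution is the mixture over initial configurations
of the convolution of one multinomial per source state, and the moments
follow from the law of total expectation/variance.

This module provides both the closed forms and a brute-force numerical
integration of the master equation over the enumerated lattice, which serves
as an independent verification oracle at small cohort sizes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import sparse
from scipy.integrate import solve_ivp
from scipy.special import gammaln

from .core import (
    GeneratorMatrix,
    ModelValidationError,
    NumericalError,
    StateConfiguration,
    TimeGrid,
    propagator,
)

__all__ = [
    "TransitionEvent",
    "MasterEquationSystem",
    "LatticeDistribution",
    "MomentTrajectory",
    "LatticeSizeError",
    "enumerate_lattice",
    "lattice_size",
    "propensity",
    "master_rhs",
    "solve_master_bruteforce",
    "exact_probability",
    "exact_distribution",
    "exact_probability_arbitrary",
    "exact_distribution_arbitrary",
    "pgf_evaluate",
    "analytic_moments",
    "analytic_moments_arbitrary",
    "empirical_moments_from_distribution",
]

#: Largest lattice the exact/brute-force machinery will enumerate by default.
DEFAULT_LATTICE_CAP = 2_000_000


class LatticeSizeError(ModelValidationError):
    """The configuration lattice exceeds the enumeration cap."""


# ---------------------------------------------------------------------------
# Lattice enumeration
# ---------------------------------------------------------------------------

def lattice_size(s: int, n0: int) -> int:
    """Number of configurations of n0 individuals over s states: C(n0+s-1, s-1)."""
    return math.comb(n0 + s - 1, s - 1)


def _compositions_colex(s: int, n0: int):
    """Yield all s-part compositions of n0 in colexicographic order.

    Colex order sorts by the last coordinate, then the second-to-last, and so
    on; the first configuration is (n0, 0, ..., 0) and the last is
    (0, ..., 0, n0).
    """
    if s == 1:
        yield (n0,)
        return
    for last in range(n0 + 1):
        for head in _compositions_colex(s - 1, n0 - last):
            yield head + (last,)


def enumerate_lattice(
    s: int, n0: int, cap: int = DEFAULT_LATTICE_CAP
) -> np.ndarray:
    """All count configurations with total n0, as an (L, s) int array.

    Order is colexicographic and deterministic; raises
    :class:`LatticeSizeError` when C(n0+s-1, s-1) exceeds ``cap``.
    """
    if s < 2:
        raise ModelValidationError("lattice enumeration needs s >= 2")
    if n0 < 1:
        raise ModelValidationError("cohort size must be at least 1")
    size = lattice_size(s, n0)
    if size > cap:
        raise LatticeSizeError(
            f"lattice has {size} configurations (cap {cap}); "
            "use the analytic-moment or Monte Carlo path instead"
        )
    out = np.fromiter(
        itertools.chain.from_iterable(_compositions_colex(s, n0)),
        dtype=np.int64,
        count=size * s,
    ).reshape(size, s)
    return out


# ---------------------------------------------------------------------------
# Events and systems
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransitionEvent:
    """One transition channel R_kl: move an individual from state k to l."""

    source: int
    target: int
    rate: float

    def __post_init__(self):
        if self.source == self.target:
            raise ModelValidationError("transition events need source != target")
        if self.rate < 0:
            raise ModelValidationError("event rate must be nonnegative")

    def change(self, s: int) -> np.ndarray:
        """The configuration change vector s_kl = e_l - e_k."""
        v = np.zeros(s, dtype=np.int64)
        v[self.source] -= 1
        v[self.target] += 1
        return v


def events_from_generator(Q: GeneratorMatrix) -> Tuple[TransitionEvent, ...]:
    """All transition channels with strictly positive rate."""
    ev = []
    for k in range(Q.s):
        for l in range(Q.s):
            if k != l and Q.rates[k, l] > 0:
                ev.append(TransitionEvent(source=k, target=l, rate=Q.rates[k, l]))
    return tuple(ev)


class MasterEquationSystem:
    """A generator plus a cohort size, with lazily built lattice machinery."""

    def __init__(
        self,
        generator: GeneratorMatrix,
        n0: int,
        lattice_cap: int = DEFAULT_LATTICE_CAP,
    ):
        if n0 < 1:
            raise ModelValidationError("cohort size must be at least 1")
        self.generator = generator
        self.n0 = int(n0)
        self.lattice_cap = lattice_cap
        self.events = events_from_generator(generator)
        self._lattice: np.ndarray | None = None
        self._index: Dict[Tuple[int, ...], int] | None = None
        self._flux_matrix: sparse.csr_matrix | None = None

    @property
    def s(self) -> int:
        return self.generator.s

    @property
    def lattice(self) -> np.ndarray:
        if self._lattice is None:
            self._lattice = enumerate_lattice(self.s, self.n0, self.lattice_cap)
        return self._lattice

    def config_index(self, counts: Sequence[int]) -> int:
        if self._index is None:
            self._index = {tuple(row): i for i, row in enumerate(self.lattice.tolist())}
        key = tuple(int(c) for c in counts)
        try:
            return self._index[key]
        except KeyError:
            raise ModelValidationError(
                f"configuration {key} is not on the lattice with total {self.n0}"
            ) from None

    def flux_matrix(self) -> sparse.csr_matrix:
        """Sparse lattice generator M with dP/dt = M @ P.

        Column j carries the outflux of configuration j on the diagonal and
        its influx contributions to the neighbouring configurations.
        """
        if self._flux_matrix is None:
            lattice = self.lattice
            L = lattice.shape[0]
            rows: List[int] = []
            cols: List[int] = []
            vals: List[float] = []
            for ev in self.events:
                a = ev.rate * lattice[:, ev.source].astype(float)  # nu_kl(n)
                nz = np.nonzero(a)[0]
                shifted = lattice[nz] + ev.change(self.s)
                tgt = np.fromiter(
                    (self.config_index(row) for row in shifted),
                    dtype=np.int64,
                    count=nz.size,
                )
                rows.extend(nz.tolist())
                cols.extend(nz.tolist())
                vals.extend((-a[nz]).tolist())
                rows.extend(tgt.tolist())
                cols.extend(nz.tolist())
                vals.extend(a[nz].tolist())
            self._flux_matrix = sparse.csr_matrix(
                (vals, (rows, cols)), shape=(L, L)
            )
        return self._flux_matrix


@dataclass(frozen=True)
class LatticeDistribution:
    """Probability mass over every configuration of the system's lattice."""

    system: MasterEquationSystem
    mass: np.ndarray
    time: float = 0.0

    def __post_init__(self):
        mass = np.asarray(self.mass, dtype=float)
        L = self.system.lattice.shape[0]
        if mass.shape != (L,):
            raise ModelValidationError(
                f"mass vector length {mass.shape} does not match lattice size {L}"
            )
        if np.any(mass < -1e-12):
            raise ModelValidationError("probability masses must be nonnegative")
        mass = np.maximum(mass, 0.0)
        if abs(mass.sum() - 1.0) > 1e-9:
            raise ModelValidationError(
                f"lattice distribution must be normalized (sum {mass.sum()!r})"
            )
        object.__setattr__(self, "mass", mass)

    @classmethod
    def degenerate(
        cls, system: MasterEquationSystem, counts: Sequence[int], time: float = 0.0
    ) -> "LatticeDistribution":
        mass = np.zeros(system.lattice.shape[0])
        mass[system.config_index(counts)] = 1.0
        return cls(system=system, mass=mass, time=time)

    @classmethod
    def from_points(
        cls,
        system: MasterEquationSystem,
        points: Sequence[Tuple[Sequence[int], float]],
        time: float = 0.0,
    ) -> "LatticeDistribution":
        """Distribution from (configuration, probability) pairs."""
        mass = np.zeros(system.lattice.shape[0])
        for counts, p in points:
            mass[system.config_index(counts)] += p
        return cls(system=system, mass=mass, time=time)

    def probability(self, counts: Sequence[int]) -> float:
        return float(self.mass[self.system.config_index(counts)])


@dataclass(frozen=True)
class MomentTrajectory:
    """Per-state mean and variance of the counts on a time grid."""

    grid: TimeGrid
    mean: np.ndarray      # (n_times, s)
    variance: np.ndarray  # (n_times, s)
    source: str = "analytic-degenerate"

    def __post_init__(self):
        mean = np.asarray(self.mean, dtype=float)
        var = np.asarray(self.variance, dtype=float)
        if mean.shape != var.shape or mean.shape[0] != self.grid.n_points:
            raise ModelValidationError("moment arrays must align with the grid")
        if np.any(var < -1e-12):
            raise ModelValidationError("variances must be nonnegative")
        object.__setattr__(self, "variance", np.maximum(var, 0.0))
        object.__setattr__(self, "mean", mean)


# ---------------------------------------------------------------------------
# Propensities and the master equation right-hand side
# ---------------------------------------------------------------------------

def propensity(n: StateConfiguration, event: TransitionEvent) -> float:
    """nu_kl(n) = c_kl * n_k: the instantaneous firing rate of R_kl at n."""
    return float(event.rate * n.counts[event.source])


def master_rhs(dist: LatticeDistribution) -> np.ndarray:
    """Time derivative of P(n, t) for every lattice configuration.

    Balances influx from configurations ``n - s_kl`` (when on the lattice)
    against outflux from ``n``; the result sums to zero, conserving total
    probability.
    """
    return dist.system.flux_matrix() @ dist.mass


def solve_master_bruteforce(
    dist0: LatticeDistribution,
    grid: TimeGrid,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> List[LatticeDistribution]:
    """Numerically integrate the master equation over the enumerated lattice.

    This is the independent verification oracle for the closed forms: a
    stiff-capable ODE solve (LSODA) of the linear system dP/dt = M P at tight
    tolerances.  Rates spanning orders of magnitude make the lattice system
    stiff, hence the method choice.
    """
    M = dist0.system.flux_matrix()
    t0 = dist0.time
    times = grid.times
    if times[0] < t0:
        raise ModelValidationError("grid starts before the initial distribution time")
    # constant Jacobian: pass it densely for small lattices so the stiff
    # solver does not rebuild it by finite differences
    jac = M.toarray() if M.shape[0] <= 2000 else None
    sol = solve_ivp(
        lambda t, p: M @ p,
        t_span=(t0, float(times[-1])) if times[-1] > t0 else (t0, t0 + 1e-12),
        y0=dist0.mass,
        t_eval=times,
        method="LSODA",
        rtol=rtol,
        atol=atol,
        jac=(lambda t, p: jac) if jac is not None else None,
    )
    if not sol.success:
        raise NumericalError(f"master equation integration failed: {sol.message}")
    out = []
    for j, t in enumerate(times):
        mass = np.maximum(sol.y[:, j], 0.0)
        mass = mass / mass.sum()
        out.append(LatticeDistribution(system=dist0.system, mass=mass, time=float(t)))
    return out


# ---------------------------------------------------------------------------
# Closed-form solution: degenerate start (all individuals in state 1)
# ---------------------------------------------------------------------------

def _multinomial_logpmf(counts: np.ndarray, probs: np.ndarray) -> np.ndarray:
    """Row-wise multinomial log-mass; computed in log space via log-gamma."""
    counts = np.atleast_2d(counts)
    n = counts.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(counts > 0, counts * np.log(probs), 0.0)
    # counts > 0 where probs == 0 has mass zero
    impossible = (counts > 0) & (probs == 0.0)
    out = gammaln(n + 1) - gammaln(counts + 1).sum(axis=1) + logp.sum(axis=1)
    out[impossible.any(axis=1)] = -np.inf
    return out


def exact_probability(
    system: MasterEquationSystem, n: StateConfiguration, t: float
) -> float:
    """Closed-form P(n, t) for all individuals starting in state 1.

    Multinomial with category probabilities B_11(t), ..., B_1s(t); evaluated
    in log space so cohort sizes like 10000 do not overflow.
    """
    if n.total != system.n0:
        raise ModelValidationError(
            f"configuration total {n.total} does not equal cohort size {system.n0}"
        )
    B = propagator(system.generator, t).probs
    logpmf = _multinomial_logpmf(n.counts[None, :], B[0])
    return float(np.exp(logpmf[0]))


def exact_distribution(
    system: MasterEquationSystem, t: float
) -> LatticeDistribution:
    """Closed-form P(., t) over the whole lattice (degenerate start)."""
    B = propagator(system.generator, t).probs
    logpmf = _multinomial_logpmf(system.lattice, B[0])
    mass = np.exp(logpmf)
    return LatticeDistribution(system=system, mass=mass / mass.sum(), time=t)


# ---------------------------------------------------------------------------
# Closed-form solution: arbitrary initial distribution
# ---------------------------------------------------------------------------

def _multinomial_grid(m: int, probs: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Dense s-dim array holding the multinomial(m, probs) pmf on a count grid."""
    s = probs.size
    grid = np.zeros(shape)
    counts = enumerate_lattice(s, m) if m >= 1 else np.zeros((1, s), dtype=np.int64)
    logpmf = _multinomial_logpmf(counts, probs)
    grid[tuple(counts.T)] = np.exp(logpmf)
    return grid


def _convolve_counts(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Convolution of two count-grid pmfs, truncated to the common grid.

    Both supports sum to totals whose combined total fits the grid, so no
    mass is lost by the truncation.
    """
    out = np.zeros_like(a)
    for idx in np.argwhere(b > 0):
        w = b[tuple(idx)]
        src = tuple(slice(0, a.shape[d] - idx[d]) for d in range(a.ndim))
        dst = tuple(slice(idx[d], a.shape[d]) for d in range(a.ndim))
        out[dst] += w * a[src]
    return out


def exact_distribution_arbitrary(
    system: MasterEquationSystem, dist0: LatticeDistribution, t: float
) -> LatticeDistribution:
    """Closed-form P(., t) for an arbitrary initial distribution.

    For a fixed initial configuration n0, the counts at time t are the sum of
    s independent multinomials — the n0_k individuals starting in state k
    scatter with category probabilities B_k1(t), ..., B_ks(t) — computed by
    iterated convolution over source states; the final answer mixes these
    over dist0.
    """
    B = propagator(system.generator, t).probs
    s = system.s
    shape = (system.n0 + 1,) * s
    total = np.zeros(shape)
    for i in np.nonzero(dist0.mass)[0]:
        w = dist0.mass[i]
        init = system.lattice[i]
        grid = None
        for k in range(s):
            if init[k] == 0:
                continue
            gk = _multinomial_grid(int(init[k]), B[k], shape)
            grid = gk if grid is None else _convolve_counts(grid, gk)
        if grid is None:  # n0 >= 1 always gives at least one factor
            raise ModelValidationError("initial configuration has zero total")
        total += w * grid
    mass = total[tuple(system.lattice.T)]
    return LatticeDistribution(system=system, mass=mass / mass.sum(), time=t)


def exact_probability_arbitrary(
    system: MasterEquationSystem,
    dist0: LatticeDistribution,
    n: StateConfiguration,
    t: float,
) -> float:
    """P(n, t) for an arbitrary initial distribution (mixture of convolutions)."""
    if n.total != system.n0:
        raise ModelValidationError(
            f"configuration total {n.total} does not equal cohort size {system.n0}"
        )
    if t == 0:
        return dist0.probability(n.counts)
    return exact_distribution_arbitrary(system, dist0, t).probability(n.counts)


# ---------------------------------------------------------------------------
# PGF and analytic moments
# ---------------------------------------------------------------------------

def pgf_evaluate(system: MasterEquationSystem, x: Sequence[float], t: float) -> float:
    """G(x, t) = (sum_m x_m B_1m(t))^{n0} for the degenerate start in state 1.

    The PGF of the multinomial solution; G(1, t) = 1 and partial derivatives
    at x = 1 yield the factorial moments.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (system.s,):
        raise ModelValidationError(
            f"PGF argument needs {system.s} components, got {x.shape}"
        )
    B = propagator(system.generator, t).probs
    return float((x @ B[0]) ** system.n0)


def analytic_moments(
    system: MasterEquationSystem, grid: TimeGrid
) -> MomentTrajectory:
    """Mean n0*B_1i(t) and variance n0*B_1i(t)*(1 - B_1i(t)), degenerate start."""
    t0 = grid.t0
    mean = np.empty((grid.n_points, system.s))
    var = np.empty_like(mean)
    for j, t in enumerate(grid.times):
        b = propagator(system.generator, t - t0).probs[0]
        mean[j] = system.n0 * b
        var[j] = system.n0 * b * (1.0 - b)
    return MomentTrajectory(grid=grid, mean=mean, variance=var,
                            source="analytic-degenerate")


def analytic_moments_arbitrary(
    system: MasterEquationSystem, dist0: LatticeDistribution, grid: TimeGrid
) -> MomentTrajectory:
    """Moments for an arbitrary initial distribution over configurations.

    Conditional on an initial configuration n0, the count in state i at time
    t has mean sum_k n0_k B_ki(t) and variance sum_k n0_k B_ki(t)(1 - B_ki(t))
    (independent multinomial scatter).  Averaging over dist0:

        mean_i(t) = E[ conditional mean ]
        var_i(t)  = E[ conditional second moment ] - mean_i(t)^2

    which reduces exactly to the degenerate-start formulas when dist0 puts
    all mass on (n0, 0, ..., 0).
    """
    support = np.nonzero(dist0.mass)[0]
    weights = dist0.mass[support]
    configs = dist0.system.lattice[support].astype(float)
    t0 = grid.t0
    mean = np.empty((grid.n_points, system.s))
    var = np.empty_like(mean)
    for j, t in enumerate(grid.times):
        B = propagator(system.generator, t - t0).probs
        cond_mean = configs @ B              # (support, s)
        cond_var = configs @ (B * (1.0 - B))
        m = weights @ cond_mean
        second = weights @ (cond_var + cond_mean**2)
        mean[j] = m
        var[j] = second - m**2
    return MomentTrajectory(grid=grid, mean=mean, variance=var,
                            source="analytic-arbitrary")


def empirical_moments_from_distribution(
    dists: Sequence[LatticeDistribution], grid: TimeGrid
) -> MomentTrajectory:
    """Mean/variance by direct summation over lattice distributions."""
    if len(dists) != grid.n_points:
        raise ModelValidationError("one distribution per grid time is required")
    system = dists[0].system
    lattice = system.lattice.astype(float)
    mean = np.empty((grid.n_points, system.s))
    var = np.empty_like(mean)
    for j, d in enumerate(dists):
        m = d.mass @ lattice
        second = d.mass @ lattice**2
        mean[j] = m
        var[j] = second - m**2
    return MomentTrajectory(grid=grid, mean=mean, variance=var, source="empirical")
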