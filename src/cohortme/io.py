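"""Model configuration, the built-in 4-state example, and CSV serialization.

Config schema (YAML or JSON, one documented structure)::

    states: [S1, S2, S3, S4]
    rates:
      - {source: S1, target: S2, rate: 0.05}
      ...
    initial:
      counts: [10000, 0, 0, 0]
      # or, for a distribution over configurations:
      # distribution:
      #   - {counts: [3, 2, 0], prob: 0.5}
      #   - {counts: [5, 0, 0], prob: 0.5}
    grid:
      t0: 0.0
      cycle: 1.0
      n_cycles: 50
      # or: times: [0.0, 0.5, 1.0, ...]
    engine:
      replicates: 1000
      seed: 1
      t_max: 50.0

Result CSVs are long-format with fixed headers; numbers are written with 17
significant digits so a read-back reproduces them exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .core import (
    GeneratorMatrix,
    ModelValidationError,
    StateConfiguration,
    StateSpace,
    TimeGrid,
    build_generator,
)
from .deterministic import DeterministicTrajectory
from .master_eq import LatticeDistribution, MasterEquationSystem, MomentTrajectory
from .stochastic import EnsembleSummary, ReplicateEnsemble, SSAPath

__all__ = [
    "ModelConfig",
    "load_config",
    "save_config",
    "example_model",
    "random_model",
    "write_trajectory",
    "read_trajectory",
    "write_moments",
    "write_distribution",
    "write_ensemble",
    "write_events",
]

_FLOAT_FMT = "%.17g"


@dataclass(frozen=True)
class ModelConfig:
    """Everything needed to run any of the simulators on one model."""

    states: Tuple[str, ...]
    rates: Tuple[Tuple[str, str, float], ...]   # (source, target, rate)
    initial_counts: Optional[Tuple[int, ...]] = None
    initial_distribution: Optional[Tuple[Tuple[Tuple[int, ...], float], ...]] = None
    t0: float = 0.0
    cycle: Optional[float] = 1.0
    n_cycles: Optional[int] = None
    times: Optional[Tuple[float, ...]] = None
    replicates: int = 1000
    seed: int = 1
    t_max: Optional[float] = None

    def __post_init__(self):
        if self.initial_counts is None and self.initial_distribution is None:
            raise ModelValidationError("an initial condition is required")
        # everything else is validated on conversion to model objects
        self.state_space()
        self.generator()
        self.grid()
        self.initial_configuration()

    # -- conversions to model objects ------------------------------------

    def state_space(self) -> StateSpace:
        return StateSpace(self.states)

    def generator(self) -> GeneratorMatrix:
        table = {}
        for src, tgt, rate in self.rates:
            if (src, tgt) in table:
                raise ModelValidationError(
                    f"duplicate rate entry for {src!r} -> {tgt!r}"
                )
            table[(src, tgt)] = rate
        return build_generator(self.state_space(), table)

    def grid(self) -> TimeGrid:
        if self.times is not None:
            if self.cycle is not None or self.n_cycles is not None:
                raise ModelValidationError(
                    "give either explicit times or (cycle, n_cycles), not both"
                )
            return TimeGrid.from_times(self.times)
        if self.cycle is None or self.n_cycles is None:
            raise ModelValidationError(
                "a uniform grid needs both cycle and n_cycles"
            )
        return TimeGrid.uniform(self.t0, self.cycle, self.n_cycles)

    @property
    def n0(self) -> int:
        if self.initial_counts is not None:
            return int(sum(self.initial_counts))
        totals = {sum(c) for c, _ in self.initial_distribution}
        if len(totals) != 1:
            raise ModelValidationError(
                "all configurations in the initial distribution must share one total"
            )
        return int(totals.pop())

    def initial_configuration(self) -> StateConfiguration:
        """The initial counts (for a distribution: its first configuration)."""
        space = self.state_space()
        if self.initial_counts is not None:
            counts = np.asarray(self.initial_counts)
        else:
            probs = [p for _, p in self.initial_distribution]
            if abs(sum(probs) - 1.0) > 1e-10:
                raise ModelValidationError(
                    "initial distribution probabilities must sum to 1"
                )
            self.n0  # validates the shared total
            counts = np.asarray(self.initial_distribution[0][0])
        return StateConfiguration(states=space, counts=counts, time=self.t0)

    def initial_lattice_distribution(
        self, system: MasterEquationSystem
    ) -> LatticeDistribution:
        if self.initial_counts is not None:
            return LatticeDistribution.degenerate(
                system, self.initial_counts, time=self.t0
            )
        return LatticeDistribution.from_points(
            system, self.initial_distribution, time=self.t0
        )

    def system(self, **kwargs) -> MasterEquationSystem:
        return MasterEquationSystem(self.generator(), self.n0, **kwargs)


# ---------------------------------------------------------------------------
# Config file round trip
# ---------------------------------------------------------------------------

_TOP_KEYS = {"states", "rates", "initial", "grid", "engine"}
_GRID_KEYS = {"t0", "cycle", "n_cycles", "times"}
_ENGINE_KEYS = {"replicates", "seed", "t_max"}
_INITIAL_KEYS = {"counts", "distribution"}


def _check_keys(mapping: dict, allowed: set, where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ModelValidationError(
            f"unknown key(s) {sorted(unknown)} in {where}; allowed: {sorted(allowed)}"
        )


def config_from_dict(raw: dict) -> ModelConfig:
    if not isinstance(raw, dict):
        raise ModelValidationError("config root must be a mapping")
    _check_keys(raw, _TOP_KEYS, "config")
    if "states" not in raw or "rates" not in raw:
        raise ModelValidationError("config needs 'states' and 'rates'")
    rates = []
    for i, entry in enumerate(raw["rates"]):
        _check_keys(entry, {"source", "target", "rate"}, f"rates[{i}]")
        try:
            rates.append(
                (str(entry["source"]), str(entry["target"]), float(entry["rate"]))
            )
        except KeyError as e:
            raise ModelValidationError(f"rates[{i}] is missing key {e}") from None
    initial = raw.get("initial", {})
    _check_keys(initial, _INITIAL_KEYS, "initial")
    counts = initial.get("counts")
    distribution = initial.get("distribution")
    if distribution is not None:
        distribution = tuple(
            (tuple(int(c) for c in d["counts"]), float(d["prob"]))
            for d in distribution
        )
    grid = raw.get("grid", {})
    _check_keys(grid, _GRID_KEYS, "grid")
    engine = raw.get("engine", {})
    _check_keys(engine, _ENGINE_KEYS, "engine")
    times = grid.get("times")
    return ModelConfig(
        states=tuple(str(x) for x in raw["states"]),
        rates=tuple(rates),
        initial_counts=tuple(int(c) for c in counts) if counts is not None else None,
        initial_distribution=distribution,
        t0=float(grid.get("t0", 0.0)),
        cycle=float(grid["cycle"]) if grid.get("cycle") is not None else (None if times is not None else 1.0),
        n_cycles=int(grid["n_cycles"]) if grid.get("n_cycles") is not None else None,
        times=tuple(float(t) for t in times) if times is not None else None,
        replicates=int(engine.get("replicates", 1000)),
        seed=int(engine.get("seed", 1)),
        t_max=float(engine["t_max"]) if engine.get("t_max") is not None else None,
    )


def config_to_dict(config: ModelConfig) -> dict:
    raw: dict = {
        "states": list(config.states),
        "rates": [
            {"source": s, "target": t, "rate": r} for s, t, r in config.rates
        ],
    }
    if config.initial_counts is not None:
        raw["initial"] = {"counts": list(config.initial_counts)}
    else:
        raw["initial"] = {
            "distribution": [
                {"counts": list(c), "prob": p}
                for c, p in config.initial_distribution
            ]
        }
    grid: dict = {"t0": config.t0}
    if config.times is not None:
        grid["times"] = list(config.times)
    else:
        grid["cycle"] = config.cycle
        grid["n_cycles"] = config.n_cycles
    raw["grid"] = grid
    engine: dict = {"replicates": config.replicates, "seed": config.seed}
    if config.t_max is not None:
        engine["t_max"] = config.t_max
    raw["engine"] = engine
    return raw


def load_config(path: Union[str, Path]) -> ModelConfig:
    """Read and validate a YAML or JSON model configuration."""
    path = Path(path)
    if not path.exists():
        raise ModelValidationError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    return config_from_dict(raw)


def save_config(config: ModelConfig, path: Union[str, Path]) -> None:
    path = Path(path)
    raw = config_to_dict(config)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(raw, indent=2))
    else:
        path.write_text(yaml.safe_dump(raw, sort_keys=False))


# ---------------------------------------------------------------------------
# Built-in example and fixture generator
# ---------------------------------------------------------------------------

def example_model() -> ModelConfig:
    """The built-in 4-state verification model.

    Progressive disease with an absorbing death state S4: rates (per year)
    c12=0.05, c13=0.01, c14=0.001, c23=0.1, c24=0.05, c34=2; all 10000
    individuals start in S1; 1-year cycles over a 50-year horizon (long
    enough to show near-complete absorption); 1000 Monte Carlo replicates.
    """
    return ModelConfig(
        states=("S1", "S2", "S3", "S4"),
        rates=(
            ("S1", "S2", 0.05),
            ("S1", "S3", 0.01),
            ("S1", "S4", 0.001),
            ("S2", "S3", 0.1),
            ("S2", "S4", 0.05),
            ("S3", "S4", 2.0),
        ),
        initial_counts=(10000, 0, 0, 0),
        t0=0.0,
        cycle=1.0,
        n_cycles=50,
        replicates=1000,
        seed=1,
        t_max=50.0,
    )


def random_model(
    s: int,
    seed: int,
    rate_scale: float = 0.5,
    density: float = 0.7,
    force_absorbing: bool = False,
    n0: int = 100,
) -> ModelConfig:
    """Seed-reproducible random model for property tests.

    Off-diagonal rates are exponential with mean ``rate_scale``, each present
    independently with probability ``density``; the construction always
    yields a valid generator.
    """
    if s < 2:
        raise ModelValidationError("random models need s >= 2")
    rng = np.random.default_rng(seed)
    labels = tuple(f"S{i + 1}" for i in range(s))
    rates: List[Tuple[str, str, float]] = []
    for k in range(s):
        for l in range(s):
            if k == l:
                continue
            if force_absorbing and k == s - 1:
                continue
            if rng.random() < density:
                rates.append((labels[k], labels[l], float(rng.exponential(rate_scale))))
    counts = [0] * s
    counts[0] = n0
    return ModelConfig(
        states=labels,
        rates=tuple(rates),
        initial_counts=tuple(counts),
        t0=0.0,
        cycle=1.0,
        n_cycles=10,
        replicates=100,
        seed=seed,
        t_max=10.0,
    )


# ---------------------------------------------------------------------------
# CSV writers / readers (long format, fixed headers, 17 significant digits)
# ---------------------------------------------------------------------------

def _traj_frame(result) -> pd.DataFrame:
    if isinstance(result, DeterministicTrajectory):
        arr = result.as_array()
        labels = result.states.labels
        rows = [
            {"time": t, "state": lab, "statistic": "value", "value": arr[i, j],
             "replicate": ""}
            for i, t in enumerate(result.grid.times)
            for j, lab in enumerate(labels)
        ]
        return pd.DataFrame(rows)
    if isinstance(result, MomentTrajectory):
        # states unknown at this layer; caller should use write_moments
        raise ModelValidationError("use write_moments for MomentTrajectory")
    raise ModelValidationError(f"cannot serialize {type(result).__name__}")


def write_trajectory(result: DeterministicTrajectory, path: Union[str, Path]) -> None:
    """Long-format CSV: time, state, statistic, value, replicate (empty)."""
    _traj_frame(result).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trajectory(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    expected = ["time", "state", "statistic", "value", "replicate"]
    if list(df.columns) != expected:
        raise ModelValidationError(
            f"unexpected trajectory columns {list(df.columns)}; expected {expected}"
        )
    return df


def write_moments(
    moments: MomentTrajectory, states: StateSpace, path: Union[str, Path]
) -> None:
    """Long-format CSV: time, state, mean, variance."""
    rows = [
        {"time": t, "state": lab,
         "mean": moments.mean[i, j], "variance": moments.variance[i, j]}
        for i, t in enumerate(moments.grid.times)
        for j, lab in enumerate(states.labels)
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_distribution(dist: LatticeDistribution, path: Union[str, Path]) -> None:
    """One row per configuration: count per state..., probability."""
    labels = dist.system.generator.states.labels
    df = pd.DataFrame(dist.system.lattice, columns=list(labels))
    df["probability"] = dist.mass
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_ensemble(ensemble: ReplicateEnsemble, states: StateSpace,
                   path: Union[str, Path]) -> None:
    """Long-format CSV with a replicate column."""
    R, T, s = ensemble.counts.shape
    rows = []
    for r in range(R):
        for i, t in enumerate(ensemble.grid.times):
            for j, lab in enumerate(states.labels):
                rows.append({"time": t, "state": lab, "statistic": "value",
                             "value": ensemble.counts[r, i, j], "replicate": r})
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_summary(summary: EnsembleSummary, states: StateSpace,
                  path: Union[str, Path]) -> None:
    rows = []
    for i, t in enumerate(summary.grid.times):
        for j, lab in enumerate(states.labels):
            rows.append({"time": t, "state": lab,
                         "mean": summary.mean[i, j],
                         "variance": summary.variance[i, j]})
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_events(path_obj: SSAPath, states: StateSpace,
                 path: Union[str, Path]) -> None:
    """SSA event log: time, source, target (state labels)."""
    rows = [
        {"time": e.time, "source": states.labels[e.source],
         "target": states.labels[e.target]}
        for e in path_obj.events
    ]
    pd.DataFrame(rows, columns=["time", "source", "target"]).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )
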