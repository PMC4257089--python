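"""Stochastic semi-synchronous simulation of logical networks.

Semantics
---------
External nodes are environment-driven: at every iteration each external node
is independently resampled ON with probability ``level/100``, where the level
is that simulation's activity level for the stimulus.  Internal nodes update
synchronously, each applying its Boolean rule to the *previous* state.
Perturbations override the result: knocked-out nodes are clamped to 0;
forced nodes are resampled ON with probability ``forced_level/100`` each
iteration, ignoring their rule entirely.

Activity of a node is the percentage of ON states over the trailing window
of the trajectory (defaults: 800 iterations, window 300).

Random-number contract: each simulation consumes a single NumPy Generator.
The draw order is fixed — one uniform per node for the initial state, then a
``(total_iterations, n_external)`` block for the environment, then a
``(total_iterations, n_forced)`` block for forced nodes — so identical seeds
give bit-identical trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .network import EXTERNAL, INTERNAL, LogicalNetwork

__all__ = [
    "SimulationConfig",
    "PerturbationSpec",
    "Trajectory",
    "ActivityProfile",
    "CompiledNetwork",
    "compile_network",
    "step",
    "simulate",
    "simulate_batch",
]

RANDOM_UNIFORM = "random_uniform"
ALL_OFF = "all_off"
FIXED = "fixed"


@dataclass(frozen=True)
class SimulationConfig:
    """Protocol parameters for one simulation.

    Defaults follow the experimental protocol: 800 iterations with node
    activity computed over the last 300.
    """

    total_iterations: int = 800
    window: int = 300
    seed: int = 0
    initial_state_policy: str = RANDOM_UNIFORM
    fixed_initial: Optional[Mapping[str, int]] = None
    resample_external: bool = True

    def __post_init__(self):
        if self.total_iterations <= 0:
            raise ValueError("total_iterations must be positive")
        if not (0 < self.window <= self.total_iterations):
            raise ValueError("window must be in (0, total_iterations]")
        if self.initial_state_policy not in (RANDOM_UNIFORM, ALL_OFF, FIXED):
            raise ValueError(f"unknown initial_state_policy "
                             f"{self.initial_state_policy!r}")
        if self.initial_state_policy == FIXED and self.fixed_initial is None:
            raise ValueError("fixed policy requires fixed_initial")


@dataclass(frozen=True)
class PerturbationSpec:
    """Genotype perturbation: knockout clamps and forced activations."""

    clamp_off: frozenset = frozenset()
    forced: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "clamp_off", frozenset(self.clamp_off))
        object.__setattr__(self, "forced", dict(self.forced))
        overlap = self.clamp_off & set(self.forced)
        if overlap:
            raise ValueError(f"nodes both clamped and forced: {sorted(overlap)}")
        for node, level in self.forced.items():
            if not (0 <= level <= 100):
                raise ValueError(f"forced level for {node!r} outside [0, 100]")

    @property
    def is_null(self) -> bool:
        return not self.clamp_off and not self.forced


NO_PERTURBATION = PerturbationSpec()


@dataclass
class Trajectory:
    """Binary state matrix, (total_iterations + 1) x nodes, initial state first."""

    nodes: List[str]
    states: np.ndarray  # uint8, shape (T + 1, N)

    def activity_over_window(self, window: int) -> "ActivityProfile":
        """Recompute activity (% ON over the trailing ``window`` states)."""
        tail = self.states[-window:, :]
        pct = 100.0 * tail.mean(axis=0)
        return ActivityProfile(dict(zip(self.nodes, pct)))

    def to_tsv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.states, columns=self.nodes)
        df.index.name = "iteration"
        df.to_csv(path, sep="\t")


@dataclass
class ActivityProfile:
    """Per-node activity (% ON over the trailing window) for one simulation."""

    activity: Dict[str, float]

    def __getitem__(self, node: str) -> float:
        return self.activity[node]

    def to_series(self):
        import pandas as pd

        return pd.Series(self.activity, name="activity_percent")

    def to_csv(self, path) -> None:
        s = self.to_series()
        s.index.name = "node"
        s.to_frame().to_csv(path, float_format="%.6f")


# ---------------------------------------------------------------------------
# Compilation: truth tables + index arrays for fast synchronous updates
# ---------------------------------------------------------------------------

class CompiledNetwork:
    """Network lowered to truth tables over node indices."""

    def __init__(self, network: LogicalNetwork, max_regulators: int = 20):
        report = network.validate()
        if report.dangling or report.ruleless_internal:
            raise ValueError(f"cannot compile invalid network:\n{report}")
        self.network = network
        self.names: List[str] = network.names
        self.index: Dict[str, int] = {n: i for i, n in enumerate(self.names)}
        self.n = len(self.names)
        self.ext_names: List[str] = network.external_names
        self.ext_idx = np.array([self.index[n] for n in self.ext_names], dtype=np.intp)
        self.int_idx = np.array([self.index[n] for n in network.internal_names],
                                dtype=np.intp)
        self.internal: List[Tuple[int, np.ndarray, np.ndarray, np.ndarray]] = []
        for name in network.internal_names:
            rule = network[name].rule
            k = len(rule.regulators)
            if k > max_regulators:
                raise ValueError(f"node {name!r} has {k} regulators; "
                                 f"compile limit is {max_regulators}")
            regs = np.array([self.index[r] for r in rule.regulators], dtype=np.intp)
            powers = (1 << np.arange(k)).astype(np.int64)
            table = rule.truth_table()
            self.internal.append((self.index[name], regs, powers, table))


def compile_network(network: LogicalNetwork, max_regulators: int = 20) -> CompiledNetwork:
    return CompiledNetwork(network, max_regulators=max_regulators)


# ---------------------------------------------------------------------------
# Single-step reference semantics
# ---------------------------------------------------------------------------

def _check_perturbation(network: LogicalNetwork, pert: PerturbationSpec) -> None:
    missing = [n for n in (*pert.clamp_off, *pert.forced) if n not in network]
    if missing:
        raise KeyError(f"perturbed nodes absent from network: {sorted(missing)}")


def step(network: LogicalNetwork,
         current_state: Mapping[str, int],
         env: Mapping[str, float],
         perturbation: PerturbationSpec = NO_PERTURBATION,
         rng: Optional[np.random.Generator] = None) -> Dict[str, int]:
    """One synchronous update; the definitional (uncompiled) semantics.

    External nodes resample ON with probability ``env[node]/100``; internal
    nodes evaluate their rule on ``current_state``; clamp/force overrides
    applied last.
    """
    rng = rng if rng is not None else np.random.default_rng()
    _check_perturbation(network, perturbation)
    nxt: Dict[str, int] = {}
    ext = network.external_names
    draws = rng.random(len(ext))
    for name, u in zip(ext, draws):
        nxt[name] = int(u < env[name] / 100.0)
    for name in network.internal_names:
        nxt[name] = network[name].rule.evaluate(current_state)
    for name in perturbation.clamp_off:
        nxt[name] = 0
    forced_names = list(perturbation.forced)
    fdraws = rng.random(len(forced_names))
    for name, u in zip(forced_names, fdraws):
        nxt[name] = int(u < perturbation.forced[name] / 100.0)
    return nxt


# ---------------------------------------------------------------------------
# Batched simulation
# ---------------------------------------------------------------------------

def _initial_states(cnet: CompiledNetwork, u0: np.ndarray, levels: np.ndarray,
                    config: SimulationConfig) -> np.ndarray:
    """Initial state matrix (S x N) from per-sim uniforms ``u0`` (S x N)."""
    S = u0.shape[0]
    X = np.zeros((S, cnet.n), dtype=np.uint8)
    if cnet.ext_idx.size:
        X[:, cnet.ext_idx] = (u0[:, cnet.ext_idx] < levels / 100.0).astype(np.uint8)
    if config.initial_state_policy == RANDOM_UNIFORM:
        X[:, cnet.int_idx] = (u0[:, cnet.int_idx] < 0.5).astype(np.uint8)
    elif config.initial_state_policy == ALL_OFF:
        pass
    else:  # FIXED
        for name, value in config.fixed_initial.items():
            X[:, cnet.index[name]] = 1 if value else 0
    return X


def simulate_batch(cnet: CompiledNetwork,
                   levels: np.ndarray,
                   perturbations: Sequence[PerturbationSpec],
                   config: SimulationConfig,
                   rngs: Sequence[np.random.Generator],
                   record: bool = False) -> Tuple[np.ndarray, Optional[Trajectory]]:
    """Run ``S`` independent simulations with shared iteration structure.

    Parameters
    ----------
    levels:
        (S x n_external) activity levels in [0, 100], one row per simulation.
    perturbations:
        One spec per simulation.  Clamp/force node *sets* must be identical
        across the batch (forced levels may differ per simulation).
    rngs:
        One generator per simulation (the per-simulation random stream).
    record:
        If True (requires S == 1), also return the full trajectory.

    Returns
    -------
    (activities, trajectory):
        activities is (S x N) percent-ON over the trailing window.
    """
    S = levels.shape[0]
    if len(perturbations) != S or len(rngs) != S:
        raise ValueError("levels, perturbations, and rngs must agree in length")
    if record and S != 1:
        raise ValueError("trajectory recording requires a single simulation")
    T, W = config.total_iterations, config.window

    p0 = perturbations[0]
    clamp_names = sorted(p0.clamp_off)
    forced_names = list(p0.forced)
    for p in perturbations:
        if sorted(p.clamp_off) != clamp_names or list(p.forced) != forced_names:
            raise ValueError("perturbation node sets must match across the batch")
    for p in perturbations:
        _check_perturbation(cnet.network, p)
    clamp_idx = np.array([cnet.index[n] for n in clamp_names], dtype=np.intp)
    forced_idx = np.array([cnet.index[n] for n in forced_names], dtype=np.intp)
    forced_levels = np.array([[p.forced[n] for n in forced_names]
                              for p in perturbations], dtype=float)
    nf = forced_idx.size
    ne = cnet.ext_idx.size

    # Pre-draw every stream in the documented order.
    u0 = np.empty((S, cnet.n))
    ebits = np.empty((S, T, ne), dtype=np.uint8) if ne else np.zeros((S, T, 0), np.uint8)
    fbits = np.empty((S, T, nf), dtype=np.uint8) if nf else np.zeros((S, T, 0), np.uint8)
    for i, rng in enumerate(rngs):
        u0[i] = rng.random(cnet.n)
        if ne:
            ebits[i] = rng.random((T, ne)) < levels[i] / 100.0
        if nf:
            fbits[i] = rng.random((T, nf)) < forced_levels[i] / 100.0

    X = _initial_states(cnet, u0, levels, config)
    # Overrides apply to the initial state as well: a knocked-out node is
    # never ON, a forced node starts from its forced Bernoulli draw.
    if clamp_idx.size:
        X[:, clamp_idx] = 0
    if nf:
        X[:, forced_idx] = (u0[:, forced_idx] < forced_levels / 100.0).astype(np.uint8)

    traj = np.empty((T + 1, cnet.n), dtype=np.uint8) if record else None
    if record:
        traj[0] = X[0]

    acc = np.zeros((S, cnet.n), dtype=np.int64)
    start = T - W  # accumulate states produced at iterations start+1 .. T
    Xnext = np.empty_like(X)
    for t in range(1, T + 1):
        for pos, regs, powers, table in cnet.internal:
            idx = X[:, regs].astype(np.int64) @ powers
            Xnext[:, pos] = table[idx]
        if ne:
            if config.resample_external:
                Xnext[:, cnet.ext_idx] = ebits[:, t - 1, :]
            else:
                Xnext[:, cnet.ext_idx] = X[:, cnet.ext_idx]
        if clamp_idx.size:
            Xnext[:, clamp_idx] = 0
        if nf:
            Xnext[:, forced_idx] = fbits[:, t - 1, :]
        X, Xnext = Xnext, X
        if record:
            traj[t] = X[0]
        if t > start:
            acc += X

    activities = 100.0 * acc / W
    trajectory = Trajectory(list(cnet.names), traj) if record else None
    return activities, trajectory


def simulate(network,
             env: Mapping[str, float],
             perturbation: PerturbationSpec = NO_PERTURBATION,
             config: SimulationConfig = SimulationConfig(),
             record: bool = False,
             rng: Optional[np.random.Generator] = None
             ) -> Tuple[ActivityProfile, Optional[Trajectory]]:
    """One full simulation; returns (ActivityProfile, Trajectory or None).

    ``network`` may be a :class:`LogicalNetwork` or a pre-compiled network.
    ``rng`` overrides the config seed (used when a caller threads one stream
    through environment sampling and simulation).
    """
    cnet = network if isinstance(network, CompiledNetwork) else compile_network(network)
    missing = [n for n in cnet.ext_names if n not in env]
    if missing:
        raise ValueError(f"environment missing levels for {missing}")
    for n in cnet.ext_names:
        if not (0 <= env[n] <= 100):
            raise ValueError(f"activity level for {n!r} outside [0, 100]")
    levels = np.array([[env[n] for n in cnet.ext_names]], dtype=float)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    acts, traj = simulate_batch(cnet, levels, [perturbation], config, [rng],
                                record=record)
    profile = ActivityProfile(dict(zip(cnet.names, acts[0])))
    return profile, traj
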