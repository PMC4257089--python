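"""Genotype experiments, most-affected ranking, and dose-response curves.

An *experiment* is 1,000 independent simulations of a network under one
tissue condition and one CAV1 genotype.  Each simulation draws its own
stimulus levels from the condition's categories, applies the genotype
perturbation, runs 800 iterations, and reports per-node activity over the
last 300.  Genotypes:

* ``WT``               — no perturbation;
* ``KO``               — target clamped OFF (null allele);
* ``Het50``            — target forced ON 50% of iterations (one functional
  allele, driven through the activator bypassing upstream regulation);
* ``RandomActivation`` — target forced at a level drawn uniformly in
  [0, 100] per simulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .engine import (NO_PERTURBATION, CompiledNetwork, PerturbationSpec,
                     SimulationConfig, compile_network, simulate_batch)
from .environments import (EnvironmentSpec, build_environment,
                           fixed_environment, sample_environment)
from .network import LogicalNetwork

__all__ = [
    "GENOTYPES",
    "GenotypeCondition",
    "ExperimentResult",
    "run_experiment",
    "rank_most_affected",
    "DoseResponseCurve",
    "dose_response",
    "monotonicity_score",
]

logger = logging.getLogger(__name__)

GENOTYPES = ("WT", "KO", "Het50", "RandomActivation")


@dataclass(frozen=True)
class GenotypeCondition:
    """Genotype regime mapped onto a perturbation of the target node."""

    label: str
    target_node: str = "CAV1"

    def __post_init__(self):
        if self.label not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.label!r}; "
                             f"valid: {', '.join(GENOTYPES)}")

    def perturbation(self, rng: Optional[np.random.Generator] = None) -> PerturbationSpec:
        """Perturbation for one simulation; RandomActivation draws its level."""
        if self.label == "WT":
            return NO_PERTURBATION
        if self.label == "KO":
            return PerturbationSpec(clamp_off=frozenset({self.target_node}))
        if self.label == "Het50":
            return PerturbationSpec(forced={self.target_node: 50.0})
        if rng is None:
            raise ValueError("RandomActivation requires an rng to draw its level")
        return PerturbationSpec(forced={self.target_node: float(rng.uniform(0, 100))})


@dataclass
class ExperimentResult:
    """All per-simulation activity profiles of one experiment."""

    condition: str
    genotype: str
    activities: pd.DataFrame  # simulations x nodes, percent
    seed: int

    @property
    def n_simulations(self) -> int:
        return len(self.activities)

    def summary(self) -> pd.DataFrame:
        """Per-node mean and sample standard deviation of activity."""
        out = pd.DataFrame({
            "mean": self.activities.mean(axis=0),
            "sd": self.activities.std(axis=0, ddof=1),
        })
        out.index.name = "node"
        return out

    def to_csv(self, path) -> None:
        self.summary().to_csv(path, float_format="%.6f")


def _levels_for_network(cnet: CompiledNetwork,
                        sampled: Mapping[str, float],
                        warn_missing: set) -> np.ndarray:
    row = np.zeros(len(cnet.ext_names))
    for j, name in enumerate(cnet.ext_names):
        if name in sampled:
            row[j] = sampled[name]
        else:
            warn_missing.add(name)
    return row


def run_experiment(network,
                   env_spec: EnvironmentSpec,
                   genotype: GenotypeCondition,
                   config: SimulationConfig = SimulationConfig(),
                   n_simulations: int = 1000,
                   level_mode: str = "randomized") -> ExperimentResult:
    """Run ``n_simulations`` independent simulations of one genotype.

    Each simulation ``i`` uses the random stream seeded ``config.seed + i``
    for its environment draw, genotype draw, and trajectory, so the whole
    experiment is a pure function of its arguments.
    """
    if n_simulations < 2:
        raise ValueError("an experiment needs at least 2 simulations")
    cnet = network if isinstance(network, CompiledNetwork) else compile_network(network)

    unknown = [s for s in env_spec.categories if s not in cnet.index]
    if unknown:
        logger.info("stimuli not in network (ignored): %s", unknown)
    warn_missing: set = set()

    levels = np.empty((n_simulations, len(cnet.ext_names)))
    perturbations: List[PerturbationSpec] = []
    rngs: List[np.random.Generator] = []
    for i in range(n_simulations):
        rng = np.random.default_rng(config.seed + i)
        sampled = sample_environment(env_spec, rng, mode=level_mode)
        levels[i] = _levels_for_network(cnet, sampled, warn_missing)
        perturbations.append(genotype.perturbation(rng))
        rngs.append(rng)
    if warn_missing:
        logger.info("network inputs not covered by %s (defaulted to 0): %s",
                    env_spec.condition_name, sorted(warn_missing))

    acts, _ = simulate_batch(cnet, levels, perturbations, config, rngs)
    df = pd.DataFrame(acts, columns=cnet.names)
    df.index.name = "simulation"
    return ExperimentResult(env_spec.condition_name, genotype.label, df,
                            seed=config.seed)


def rank_most_affected(result: ExperimentResult,
                       baseline_result: ExperimentResult,
                       k: int = 15) -> pd.DataFrame:
    """Top-k nodes by |mean activity shift| vs the baseline experiment.

    Delta is signed (condition - baseline); ties in |delta| break
    lexicographically by node name.
    """
    cond = result.summary()["mean"]
    base = baseline_result.summary()["mean"]
    if set(cond.index) != set(base.index):
        raise ValueError("experiments ran on different node sets")
    base = base.reindex(cond.index)
    delta = cond - base
    table = pd.DataFrame({
        "node": cond.index,
        "mean_activity_condition": cond.values,
        "mean_activity_baseline": base.values,
        "delta": delta.values,
    })
    table = table.sort_values(by=["delta", "node"],
                              key=lambda s: -s.abs() if s.name == "delta" else s,
                              kind="mergesort")
    table = table.head(k).reset_index(drop=True)
    return table


@dataclass
class DoseResponseCurve:
    """Mean output activity as a function of one swept input level."""

    input_node: str
    output_node: str
    grid: np.ndarray
    responses: np.ndarray
    sds: np.ndarray
    reps: int

    def __post_init__(self):
        g = np.asarray(self.grid, dtype=float)
        if (np.diff(g) <= 0).any():
            raise ValueError("grid must be strictly increasing")
        if g.min() < 0 or g.max() > 100:
            raise ValueError("grid levels must lie in [0, 100]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "level": self.grid,
            "mean_response": self.responses,
            "sd": self.sds,
            "reps": self.reps,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6f")


def dose_response(network,
                  input_node: str,
                  output_node: str,
                  grid: Optional[Sequence[float]] = None,
                  reps: int = 30,
                  config: SimulationConfig = SimulationConfig(),
                  background: Optional[Mapping[str, float]] = None,
                  perturbation: PerturbationSpec = NO_PERTURBATION
                  ) -> DoseResponseCurve:
    """Sweep one external input and record mean output activity per level.

    All non-swept inputs are held at ``background`` (default: the wild-type
    tissue condition in fixed mode; inputs without a background level are 0).
    """
    cnet = network if isinstance(network, CompiledNetwork) else compile_network(network)
    if input_node not in cnet.ext_names:
        raise ValueError(f"input node {input_node!r} is not an external node")
    if output_node not in cnet.index:
        raise ValueError(f"output node {output_node!r} not in network")
    if grid is None:
        grid = np.arange(0.0, 101.0, 10.0)
    grid = np.asarray(grid, dtype=float)

    if background is None:
        background = fixed_environment("Tissue_WT")
    base_row = np.array([background.get(n, 0.0) for n in cnet.ext_names])
    sweep_j = cnet.ext_names.index(input_node)

    means = np.empty(len(grid))
    sds = np.empty(len(grid))
    out_pos = cnet.index[output_node]
    for gi, level in enumerate(grid):
        levels = np.tile(base_row, (reps, 1))
        levels[:, sweep_j] = level
        rngs = [np.random.default_rng(config.seed + gi * reps + r)
                for r in range(reps)]
        acts, _ = simulate_batch(cnet, levels, [perturbation] * reps, config, rngs)
        means[gi] = acts[:, out_pos].mean()
        sds[gi] = acts[:, out_pos].std(ddof=1)
    return DoseResponseCurve(input_node, output_node, grid, means, sds, reps)


def monotonicity_score(curve) -> float:
    """Spearman rank correlation of (level, response); average-rank ties.

    Accepts a :class:`DoseResponseCurve` or a (grid, responses) pair.
    """
    if isinstance(curve, DoseResponseCurve):
        grid, responses = curve.grid, curve.responses
    else:
        grid, responses = curve
    grid = np.asarray(grid, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if len(grid) < 3:
        raise ValueError("monotonicity needs at least 3 grid points")
    rho = stats.spearmanr(grid, responses).statistic
    return float(rho)
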