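"""Exact Markov-chain oracle for small networks.

The stochastic update semantics of :mod:`cav1net.engine` define a Markov
chain on the ``2**n`` binary states of an ``n``-node network: internal nodes
move deterministically (given the previous state), while external and forced
nodes are independent Bernoulli draws.  For ``n <= 12`` the transition matrix
can be built exactly and the state distribution propagated, giving the exact
expectation of the simulated activity profile.  This is the independent
check of the simulation engine, computed without any sampling.
"""

from __future__ import annotations

from typing import Dict, Mapping, Optional

import numpy as np

from .engine import (ALL_OFF, FIXED, NO_PERTURBATION, RANDOM_UNIFORM,
                     CompiledNetwork, PerturbationSpec, compile_network)
from .network import LogicalNetwork

__all__ = ["stationary_oracle"]

MAX_NODES = 12


def stationary_oracle(network,
                      env: Mapping[str, float],
                      perturbation: PerturbationSpec = NO_PERTURBATION,
                      horizon: int = 800,
                      window: int = 300,
                      initial_state_policy: str = RANDOM_UNIFORM,
                      fixed_initial: Optional[Mapping[str, int]] = None
                      ) -> Dict[str, float]:
    """Exact expected activity (% ON over the trailing window) per node.

    Parameters mirror :func:`cav1net.engine.simulate`: the distribution is
    iterated ``horizon`` steps from the initial-state distribution and the
    per-node ON-probability averaged over the final ``window`` steps.
    """
    cnet = network if isinstance(network, CompiledNetwork) else compile_network(network)
    n = cnet.n
    if n > MAX_NODES:
        raise ValueError(f"state space too large: {n} nodes (limit {MAX_NODES})")
    if not (0 < window <= horizon):
        raise ValueError("window must be in (0, horizon]")
    for node in (*perturbation.clamp_off, *perturbation.forced):
        if node not in cnet.index:
            raise KeyError(f"perturbed node {node!r} absent from network")

    M = 1 << n
    states = np.arange(M, dtype=np.int64)
    bits = ((states[:, None] >> np.arange(n)) & 1).astype(np.float64)  # M x n

    clamp = {cnet.index[c] for c in perturbation.clamp_off}
    forced = {cnet.index[f]: lvl / 100.0 for f, lvl in perturbation.forced.items()}

    # Deterministic part of the next state (internal, unperturbed nodes).
    det_next = np.zeros(M, dtype=np.int64)
    stochastic = []  # (bit position, ON-probability)
    for pos, regs, powers, table in cnet.internal:
        if pos in clamp or pos in forced:
            continue
        idx = (bits[:, regs].astype(np.int64) @ powers)
        det_next |= table[idx].astype(np.int64) << pos
    for name, pos in zip(cnet.ext_names, cnet.ext_idx):
        if pos in clamp:
            continue
        if pos in forced:
            continue
        stochastic.append((int(pos), env[name] / 100.0))
    for pos, p in forced.items():
        stochastic.append((int(pos), p))
    # Clamped nodes contribute bit 0 (absent from det_next and stochastic).

    # Transition matrix: enumerate joint outcomes of the stochastic bits.
    m = len(stochastic)
    P = np.zeros((M, M))
    rows = np.arange(M)
    for combo in range(1 << m):
        prob = 1.0
        cb = 0
        for j, (pos, p) in enumerate(stochastic):
            if (combo >> j) & 1:
                prob *= p
                cb |= 1 << pos
            else:
                prob *= 1.0 - p
        if prob == 0.0:
            continue
        np.add.at(P, (rows, det_next | cb), prob)

    # Initial distribution: product of per-node ON-probabilities.
    p_init = np.zeros(n)
    for name, pos in zip(cnet.ext_names, cnet.ext_idx):
        p_init[pos] = env[name] / 100.0
    if initial_state_policy == RANDOM_UNIFORM:
        p_init[cnet.int_idx] = 0.5
    elif initial_state_policy == ALL_OFF:
        p_init[cnet.int_idx] = 0.0
    elif initial_state_policy == FIXED:
        if fixed_initial is None:
            raise ValueError("fixed policy requires fixed_initial")
        for name, value in fixed_initial.items():
            p_init[cnet.index[name]] = 1.0 if value else 0.0
    else:
        raise ValueError(f"unknown initial_state_policy {initial_state_policy!r}")
    for pos in clamp:
        p_init[pos] = 0.0
    for pos, p in forced.items():
        p_init[pos] = p

    pi = np.ones(M)
    for j in range(n):
        pi *= np.where(bits[:, j] == 1, p_init[j], 1.0 - p_init[j])

    acc = np.zeros(n)
    start = horizon - window
    for t in range(1, horizon + 1):
        pi = pi @ P
        if t > start:
            acc += pi @ bits
    expected = 100.0 * acc / window
    return dict(zip(cnet.names, expected))
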