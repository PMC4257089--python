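"""Random Boolean network generator (test fixtures and property checks).

Generates networks with random wiring and random per-node truth tables at a
chosen ON-bias.  Wiring may be cyclic (regulators drawn from all nodes) or
acyclic (regulators drawn from inputs and earlier internal nodes, giving an
input-driven feed-forward network whose window averages are ergodic).
"""

from __future__ import annotations

from typing import List

import numpy as np

from .network import EXTERNAL, INTERNAL, LogicalNetwork, NodeSpec
from .rules import And, Const, Expr, LogicRule, Not, Or, Var

__all__ = ["generate_random_network"]


def _sop_from_table(regs: List[str], table: np.ndarray) -> Expr:
    """Sum-of-products expression realizing a truth table (reg 0 = LSB)."""
    k = len(regs)
    if table.all():
        return Const(1)
    if not table.any():
        return Const(0)
    terms: List[Expr] = []
    for i in range(2 ** k):
        if not table[i]:
            continue
        lits: List[Expr] = []
        for j, r in enumerate(regs):
            lits.append(Var(r) if (i >> j) & 1 else Not(Var(r)))
        term = lits[0]
        for lit in lits[1:]:
            term = And(term, lit)
        terms.append(term)
    expr = terms[0]
    for t in terms[1:]:
        expr = Or(expr, t)
    return expr


def generate_random_network(n_nodes: int,
                            n_inputs: int,
                            max_regulators: int = 3,
                            bias: float = 0.5,
                            seed: int = 0,
                            acyclic: bool = False) -> LogicalNetwork:
    """Random Boolean network with ``n_inputs`` external and the rest internal.

    Each internal node receives 1..max_regulators distinct regulators and a
    random truth table whose entries are ON with probability ``bias``.
    Deterministic for a given seed.
    """
    if not (1 <= n_inputs < n_nodes):
        raise ValueError("need 1 <= n_inputs < n_nodes")
    if max_regulators < 1:
        raise ValueError("max_regulators must be >= 1")
    if not (0.0 <= bias <= 1.0):
        raise ValueError("bias must be in [0, 1]")
    rng = np.random.default_rng(seed)

    input_names = [f"I{j}" for j in range(n_inputs)]
    internal_names = [f"N{j}" for j in range(n_nodes - n_inputs)]
    all_names = input_names + internal_names

    nodes = [NodeSpec(n, EXTERNAL) for n in input_names]
    for j, name in enumerate(internal_names):
        pool = input_names + internal_names[:j] if acyclic else all_names
        k = int(rng.integers(1, min(max_regulators, len(pool)) + 1))
        regs = [pool[i] for i in rng.choice(len(pool), size=k, replace=False)]
        table = (rng.random(2 ** k) < bias).astype(np.uint8)
        expr = _sop_from_table(regs, table)
        nodes.append(NodeSpec(name, INTERNAL, LogicRule(expr)))
    return LogicalNetwork(nodes, name=f"random_{n_nodes}n_{seed}")
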