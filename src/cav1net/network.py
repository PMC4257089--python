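"""Logical-network data model, validation, and the plain-text rule format.

A :class:`LogicalNetwork` is an ordered mapping of named nodes.  External
nodes have no rule — their state is driven by the environment (a Bernoulli
activity level).  Internal nodes carry exactly one Boolean update rule over
other node names.

Plain-text format (UTF-8, ``#`` comments)::

    input APC
    input ECM
    TCR = APC
    Integrin = ECM & CAV1
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .rules import LogicRule, parse_rule

__all__ = [
    "NodeSpec",
    "LogicalNetwork",
    "ValidationReport",
    "validate_network",
    "validate_nodes",
    "parse_rules_text",
    "format_rules",
    "load_rules",
    "save_rules",
]

EXTERNAL = "external"
INTERNAL = "internal"


@dataclass(frozen=True)
class NodeSpec:
    """One node: name, kind (external/internal), rule, free-text annotation."""

    name: str
    kind: str
    rule: Optional[LogicRule] = None
    annotation: str = ""

    def __post_init__(self):
        if not self.name or not self.name.strip():
            raise ValueError("node name must be non-empty")
        if self.kind not in (EXTERNAL, INTERNAL):
            raise ValueError(f"unknown node kind {self.kind!r}")
        if self.kind == EXTERNAL and self.rule is not None:
            raise ValueError(f"external node {self.name!r} must not have a rule")
        if self.kind == INTERNAL and self.rule is None:
            raise ValueError(f"internal node {self.name!r} requires a rule")


@dataclass
class ValidationReport:
    """Structural problems found in a network (empty report = valid)."""

    dangling: List[Tuple[str, str]] = field(default_factory=list)   # (node, missing regulator)
    duplicates: List[str] = field(default_factory=list)
    ruleless_internal: List[str] = field(default_factory=list)
    unreferenced_externals: List[str] = field(default_factory=list)

    @property
    def entries(self) -> List[str]:
        out = [f"dangling reference: {n} -> {r}" for n, r in self.dangling]
        out += [f"duplicate node name: {n}" for n in self.duplicates]
        out += [f"internal node without rule: {n}" for n in self.ruleless_internal]
        out += [f"unreferenced external node: {n}" for n in self.unreferenced_externals]
        return out

    def is_empty(self) -> bool:
        return not self.entries

    def __str__(self):
        return "\n".join(self.entries) if self.entries else "OK"


class LogicalNetwork:
    """Ordered collection of nodes with unique names.

    Parameters
    ----------
    nodes:
        Node specs; order is preserved and defines simulation state layout.
    name, version:
        Free-text metadata.
    """

    def __init__(self, nodes: Iterable[NodeSpec], name: str = "", version: str = ""):
        self.nodes: Dict[str, NodeSpec] = {}
        for spec in nodes:
            if spec.name in self.nodes:
                raise ValueError(f"duplicate node name {spec.name!r}")
            self.nodes[spec.name] = spec
        if not any(n.kind == INTERNAL for n in self.nodes.values()):
            raise ValueError("network needs at least one internal node")
        self.name = name
        self.version = version

    # -- views ------------------------------------------------------------
    @property
    def names(self) -> List[str]:
        return list(self.nodes)

    @property
    def external_names(self) -> List[str]:
        return [n for n, s in self.nodes.items() if s.kind == EXTERNAL]

    @property
    def internal_names(self) -> List[str]:
        return [n for n, s in self.nodes.items() if s.kind == INTERNAL]

    def __len__(self):
        return len(self.nodes)

    def __contains__(self, name):
        return name in self.nodes

    def __getitem__(self, name) -> NodeSpec:
        return self.nodes[name]

    # -- semantics --------------------------------------------------------
    def validate(self) -> ValidationReport:
        return validate_nodes(self.nodes.values())

    def equivalent_to(self, other: "LogicalNetwork") -> bool:
        """Node-by-node equivalence: same names, kinds, and rule truth tables."""
        if set(self.nodes) != set(other.nodes):
            return False
        for name, spec in self.nodes.items():
            o = other.nodes[name]
            if spec.kind != o.kind:
                return False
            if spec.kind == INTERNAL:
                if spec.rule.regulators != o.rule.regulators:
                    # same regulators may appear in different order; compare on
                    # the union ordering via truth tables over sorted regulators
                    if set(spec.rule.regulators) != set(o.rule.regulators):
                        return False
                    if not _same_function(spec.rule, o.rule):
                        return False
                elif (spec.rule.truth_table() != o.rule.truth_table()).any():
                    return False
        return True


def _same_function(a: LogicRule, b: LogicRule) -> bool:
    regs = sorted(set(a.regulators))
    for i in range(2 ** len(regs)):
        state = {r: (i >> j) & 1 for j, r in enumerate(regs)}
        if a.evaluate(state) != b.evaluate(state):
            return False
    return True


def validate_nodes(nodes: Iterable[NodeSpec]) -> ValidationReport:
    """Report structural problems in a sequence of node specs.

    Accepts a raw sequence (not a network) so duplicate names can be reported
    instead of raising.
    """
    report = ValidationReport()
    seen: Dict[str, NodeSpec] = {}
    ordered: List[NodeSpec] = []
    for spec in nodes:
        if spec.name in seen:
            report.duplicates.append(spec.name)
        else:
            seen[spec.name] = spec
        ordered.append(spec)

    referenced = set()
    for spec in ordered:
        if spec.kind == INTERNAL:
            if spec.rule is None:  # unreachable via NodeSpec, reachable via mocks
                report.ruleless_internal.append(spec.name)
                continue
            for reg in spec.rule.regulators:
                referenced.add(reg)
                if reg not in seen:
                    report.dangling.append((spec.name, reg))
    for spec in ordered:
        if spec.kind == EXTERNAL and spec.name not in referenced:
            report.unreferenced_externals.append(spec.name)
    return report


def validate_network(network: LogicalNetwork) -> ValidationReport:
    """Validate an assembled network (see :func:`validate_nodes`)."""
    return network.validate()


# ---------------------------------------------------------------------------
# Plain-text rule format
# ---------------------------------------------------------------------------

def parse_rules_text(text: str, name: str = "", version: str = "") -> LogicalNetwork:
    nodes: List[NodeSpec] = []
    names = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("input ") or line == "input":
            node_name = line[len("input"):].strip()
            if not node_name:
                raise ValueError(f"line {lineno}: input declaration without a name")
            spec = NodeSpec(node_name, EXTERNAL)
        elif "=" in line:
            node_name, expr_text = line.split("=", 1)
            node_name = node_name.strip()
            try:
                rule = parse_rule(expr_text)
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from exc
            spec = NodeSpec(node_name, INTERNAL, rule)
        else:
            raise ValueError(f"line {lineno}: expected 'input NAME' or 'NAME = expression'")
        if spec.name in names:
            raise ValueError(f"line {lineno}: duplicate node name {spec.name!r}")
        names.add(spec.name)
        nodes.append(spec)
    return LogicalNetwork(nodes, name=name, version=version)


def format_rules(network: LogicalNetwork) -> str:
    """Canonical plain-text serialization (inputs first, network order)."""
    lines = []
    if network.name:
        lines.append(f"# {network.name}" + (f" v{network.version}" if network.version else ""))
    for n in network.external_names:
        lines.append(f"input {n}")
    for n in network.internal_names:
        lines.append(f"{n} = {network[n].rule}")
    return "\n".join(lines) + "\n"


def load_rules(path) -> LogicalNetwork:
    p = Path(path)
    return parse_rules_text(p.read_text(encoding="utf-8"), name=p.stem)


def save_rules(network: LogicalNetwork, path) -> None:
    Path(path).write_text(format_rules(network), encoding="utf-8")
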