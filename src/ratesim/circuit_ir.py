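"""Graph intermediate representation of a network model.

A circuit is a graph of operator-bearing nodes joined by weighted, optionally
delayed edges.  Templates (:mod:`ratesim.templates`) instantiate into this
representation; the compute engine (:mod:`ratesim.engine`) consumes the flat
form.  Sub-circuits nest arbitrarily and are promoted to label-prefixed
top-level nodes by :meth:`CircuitIR.flatten`.

Within a node, operators are ordered into evaluation *stages* from their
input/output variable names: equations inside one operator evaluate
simultaneously, operators whose inputs name another operator's output
evaluate in a later stage.  Cyclic operator dependencies are rejected —
use a self-edge on the node to close such loops.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import networkx as nx
import numpy as np

from .expressions import EquationAST, free_variables, parse_equation, render_equation

__all__ = [
    "CircuitError",
    "VarState",
    "OperatorIR",
    "NodeIR",
    "EdgeIR",
    "CircuitIR",
    "sort_operators",
]

ROLES = ("input", "output", "variable", "constant")


class CircuitError(ValueError):
    """Structural error in a circuit definition."""


@dataclass
class VarState:
    """One operator variable: its connectivity role and current value."""

    role: str
    value: float = 0.0
    description: str = ""

    def copy(self) -> "VarState":
        return VarState(self.role, self.value, self.description)


@dataclass
class OperatorIR:
    """An instantiated operator: parsed equations plus variable values."""

    name: str
    equations: List[EquationAST]
    variables: Dict[str, VarState]

    def copy(self) -> "OperatorIR":
        return OperatorIR(self.name, list(self.equations),
                          {k: v.copy() for k, v in self.variables.items()})

    @property
    def output(self) -> str:
        for var, state in self.variables.items():
            if state.role == "output":
                return var
        raise CircuitError(f"operator {self.name!r} declares no output variable")

    @property
    def inputs(self) -> Tuple[str, ...]:
        return tuple(v for v, s in self.variables.items() if s.role == "input")

    @property
    def state_variables(self) -> Tuple[str, ...]:
        """Variables advanced by a differential equation, in equation order."""
        return tuple(eq.lhs_variable for eq in self.equations if eq.is_differential)

    def rendered_equations(self) -> Tuple[str, ...]:
        return tuple(render_equation(eq) for eq in self.equations)

    def structure_signature(self) -> Tuple:
        """Equation strings and variable roles — equal signatures mean the
        operators differ at most in constant values."""
        return (self.rendered_equations(),
                tuple(sorted((v, s.role) for v, s in self.variables.items())))


def sort_operators(operators: Mapping[str, OperatorIR]) -> List[List[str]]:
    """Topological stages over the in-node operator dependency graph.

    Operator B depends on operator A when one of B's input variables carries
    the same name as A's output.  Operators without mutual dependencies share
    a stage (and may be evaluated in parallel); within a stage labels are
    sorted for determinism.
    """
    producers: Dict[str, List[str]] = {}
    for label, op in operators.items():
        producers.setdefault(op.output, []).append(label)
    deps: Dict[str, set] = {label: set() for label in operators}
    for label, op in operators.items():
        for inp in op.inputs:
            for producer in producers.get(inp, []):
                if producer != label:
                    deps[label].add(producer)
    stages: List[List[str]] = []
    remaining = dict(deps)
    done: set = set()
    while remaining:
        ready = sorted(label for label, d in remaining.items() if d <= done)
        if not ready:
            cycle = " -> ".join(sorted(remaining))
            raise CircuitError(
                f"cyclic operator dependencies are not allowed (cycle among: "
                f"{cycle}); use a self-edge on the node instead")
        stages.append(ready)
        done.update(ready)
        for label in ready:
            del remaining[label]
    return stages


@dataclass
class NodeIR:
    """A network node: labelled operators plus their evaluation stages."""

    operators: Dict[str, OperatorIR]

    def copy(self) -> "NodeIR":
        return NodeIR({k: v.copy() for k, v in self.operators.items()})

    @property
    def stages(self) -> List[List[str]]:
        return sort_operators(self.operators)

    def structure_signature(self) -> Tuple:
        return tuple(sorted((label, op.structure_signature())
                            for label, op in self.operators.items()))

    def get_variable(self, op_label: str, var: str) -> VarState:
        if op_label not in self.operators:
            raise CircuitError(f"unknown operator {op_label!r}")
        op = self.operators[op_label]
        if var not in op.variables:
            raise CircuitError(f"operator {op_label!r} has no variable {var!r}")
        return op.variables[var]


@dataclass
class EdgeIR:
    """A directed connection between two operator variables.

    ``weight`` scales the transported value (applied after any edge
    operators); ``delay`` (seconds) postpones arrival, ``None`` meaning
    next-step delivery.
    """

    source: str                     # "<node path>/<operator>/<variable>"
    target: str
    weight: float = 1.0
    delay: Optional[float] = None
    operators: List[OperatorIR] = field(default_factory=list)

    def copy(self) -> "EdgeIR":
        return EdgeIR(self.source, self.target, self.weight, self.delay,
                      [op.copy() for op in self.operators])

    def validate(self) -> None:
        if not np.isfinite(self.weight):
            raise CircuitError(f"edge {self.source} -> {self.target}: weight "
                               f"must be finite, got {self.weight}")
        if self.delay is not None and self.delay < 0:
            raise CircuitError(f"edge {self.source} -> {self.target}: delay "
                               f"must be >= 0, got {self.delay}")


class CircuitIR:
    """Hierarchical graph of operator-bearing nodes and weighted edges."""

    def __init__(self,
                 nodes: Optional[Dict[str, NodeIR]] = None,
                 edges: Optional[List[EdgeIR]] = None,
                 subcircuits: Optional[Dict[str, "CircuitIR"]] = None,
                 label: str = "circuit"):
        self.label = label
        self.nodes: Dict[str, NodeIR] = dict(nodes or {})
        self.edges: List[EdgeIR] = list(edges or [])
        self.subcircuits: Dict[str, CircuitIR] = dict(subcircuits or {})
        for path in self.nodes:
            if any(not seg for seg in path.split("/")):
                raise CircuitError(f"invalid node path {path!r}")

    # ------------------------------------------------------------------
    # structure queries
    # ------------------------------------------------------------------
    @property
    def is_flat(self) -> bool:
        return not self.subcircuits

    def node_paths(self) -> List[str]:
        return sorted(self.nodes)

    def resolve_variable(self, path: str) -> Tuple[str, str, str]:
        """Split ``node.../op/var`` and check that it exists (flat circuits)."""
        parts = path.split("/")
        if len(parts) < 3:
            raise CircuitError(f"variable path {path!r} must be "
                               "<node>/<operator>/<variable>")
        node_path, op_label, var = "/".join(parts[:-2]), parts[-2], parts[-1]
        if node_path not in self.nodes:
            raise CircuitError(f"unknown node {node_path!r} in path {path!r}")
        self.nodes[node_path].get_variable(op_label, var)
        return node_path, op_label, var

    def validate(self) -> None:
        circuit = self.flatten()
        for edge in circuit.edges:
            edge.validate()
            circuit.resolve_variable(edge.source)
            _, op, var = circuit.resolve_variable(edge.target)
            node = circuit.nodes["/".join(edge.target.split("/")[:-2])]
            role = node.get_variable(op, var).role
            if role != "input":
                raise CircuitError(
                    f"edge target {edge.target!r} has role {role!r}; edges "
                    "may only feed variables with role 'input'")
        for path, node in circuit.nodes.items():
            node.stages  # raises on cyclic operator dependencies

    # ------------------------------------------------------------------
    # flattening
    # ------------------------------------------------------------------
    def flatten(self) -> "CircuitIR":
        """Promote sub-circuit contents to label-prefixed top-level nodes.

        Idempotent; a flat circuit flattens to an equal copy.
        """
        nodes: Dict[str, NodeIR] = {}
        edges: List[EdgeIR] = []
        for path, node in self.nodes.items():
            nodes[path] = node.copy()
        for edge in self.edges:
            edges.append(edge.copy())
        for label, sub in self.subcircuits.items():
            flat = sub.flatten()
            for path, node in flat.nodes.items():
                new_path = f"{label}/{path}"
                if new_path in nodes:
                    raise CircuitError(f"node path collision after "
                                       f"prefixing: {new_path!r}")
                nodes[new_path] = node
            for edge in flat.edges:
                edge = edge.copy()
                edge.source = f"{label}/{edge.source}"
                edge.target = f"{label}/{edge.target}"
                edges.append(edge)
        return CircuitIR(nodes, edges, label=self.label)

    # ------------------------------------------------------------------
    # bulk edges
    # ------------------------------------------------------------------
    def add_edges_from_matrix(self, source_var: str, target_var: str,
                              nodes: Sequence[str],
                              weight: np.ndarray,
                              delay: Optional[np.ndarray] = None) -> "CircuitIR":
        """Create one edge per nonzero matrix entry.

        ``weight[i, j]`` becomes the weight of the edge from ``nodes[i]`` to
        ``nodes[j]`` (row = source, column = target); zero entries create no
        edge.  ``source_var``/``target_var`` are ``<operator>/<variable>``
        suffixes appended to each node path.  Returns ``self``.
        """
        weight = np.asarray(weight, dtype=float)
        n = len(nodes)
        if weight.shape != (n, n):
            raise CircuitError(
                f"weight matrix shape {weight.shape} does not match the "
                f"{n} listed nodes")
        if delay is not None:
            delay = np.asarray(delay, dtype=float)
            if delay.shape != (n, n):
                raise CircuitError(
                    f"delay matrix shape {delay.shape} does not match the "
                    f"{n} listed nodes")
        flat = self if self.is_flat else None
        for node in nodes:
            if node not in self.nodes:
                raise CircuitError(f"unknown node {node!r}")
        for i, src in enumerate(nodes):
            for j, tgt in enumerate(nodes):
                w = weight[i, j]
                if w == 0.0:
                    continue
                d = None
                if delay is not None and delay[i, j] > 0:
                    d = float(delay[i, j])
                edge = EdgeIR(f"{src}/{source_var}", f"{tgt}/{target_var}",
                              weight=float(w), delay=d)
                if flat is not None:
                    flat.resolve_variable(edge.source)
                    flat.resolve_variable(edge.target)
                self.edges.append(edge)
        return self

    # ------------------------------------------------------------------
    # export
    # ------------------------------------------------------------------
    def to_networkx(self) -> nx.MultiDiGraph:
        """Flat attribute graph (scalar attributes only, export-safe)."""
        flat = self.flatten()
        graph = nx.MultiDiGraph(label=self.label)
        for path, node in flat.nodes.items():
            graph.add_node(path,
                           operators=",".join(sorted(node.operators)),
                           n_operators=len(node.operators))
        for edge in flat.edges:
            src_node = "/".join(edge.source.split("/")[:-2])
            tgt_node = "/".join(edge.target.split("/")[:-2])
            graph.add_edge(src_node, tgt_node,
                           source_var="/".join(edge.source.split("/")[-2:]),
                           target_var="/".join(edge.target.split("/")[-2:]),
                           weight=float(edge.weight),
                           delay=float(edge.delay) if edge.delay is not None else -1.0)
        return graph

    def write_graphml(self, path: str) -> None:
        nx.write_graphml(self.to_networkx(), path)

    def write_dot(self, path: str) -> None:
        """Minimal DOT export for external visualization tools."""
        graph = self.to_networkx()
        lines = [f'digraph "{self.label}" {{']
        for node in sorted(graph.nodes):
            ops = graph.nodes[node]["operators"]
            lines.append(f'  "{node}" [label="{node}\\n{ops}"];')
        for u, v, data in graph.edges(data=True):
            attrs = f'label="w={data["weight"]:g}"'
            lines.append(f'  "{u}" -> "{v}" [{attrs}];')
        lines.append("}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    # ------------------------------------------------------------------
    def copy(self) -> "CircuitIR":
        return CircuitIR({p: n.copy() for p, n in self.nodes.items()},
                         [e.copy() for e in self.edges],
                         {l: s.copy() for l, s in self.subcircuits.items()},
                         label=self.label)

    def __repr__(self) -> str:
        flat = self.flatten()
        return (f"CircuitIR({self.label!r}, {len(flat.nodes)} nodes, "
                f"{len(flat.edges)} edges)")
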