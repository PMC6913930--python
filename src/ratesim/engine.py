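"""Vectorized fixed-step simulation engine.

:func:`compile` turns a flat :class:`~ratesim.circuit_ir.CircuitIR` into a
:class:`CompiledNetwork`: structurally identical nodes (same equations and
variable roles; constants may differ) are grouped into vectorized nodes whose
variables are NumPy vectors with one entry per member instance.  The network
is integrated with a synchronous update scheme:

1. edge transfer — every edge delivers its source value *from the previous
   step* (or from ``round(delay/dt)`` steps back through a ring buffer),
   scaled by the edge weight, summed into the target input; extrinsic
   per-step input arrays are added on top;
2. node evaluation — operator stages run in dependency order; algebraic
   equations assign, differential equations produce derivatives;
3. state advance — explicit Euler, midpoint, or a fixed-step third-order
   Bogacki–Shampine step (``rk23``);
4. sampling — declared outputs are recorded on the sampling grid (the first
   sample falls one sampling interval after the start; t=0 is not stored).

Because all cross-node reads use previous-step values, the evaluation order
across nodes cannot affect results, and vectorized and non-vectorized
compilations of the same circuit produce matching trajectories.

For each run a specialized step function is generated as Python source from
the parsed equations; long runs are JIT-compiled with numba when available,
short runs execute the same source interpreted.  Generated functions are
cached by source text, so parameter sweeps over one structure compile once.

A caution on stochastic drive: extrinsic inputs are added verbatim each
step, with no sqrt(dt) rescaling — when a model is driven with freshly drawn
noise per step, its response depends on the integration step size.
"""

from __future__ import annotations

import builtins
import hashlib
import math
import re
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .circuit_ir import CircuitError, CircuitIR, EdgeIR, NodeIR, OperatorIR
from .expressions import EquationAST, to_python_source

__all__ = [
    "SOLVERS",
    "SimulationConfig",
    "CompiledNetwork",
    "SimulationResult",
    "EngineError",
    "compile",
    "solver_step",
]

SOLVERS = ("euler", "midpoint", "rk23")

#: n_steps * (instances + edges) above which the generated loop is JIT-compiled
JIT_WORK_THRESHOLD = 4e5


class EngineError(RuntimeError):
    """Compilation or runtime failure in the compute engine."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Integration settings.

    dt and sampling_step_size are in seconds; step counts follow
    ``round(T / dt)`` and ``round(sampling_step_size / dt)``.
    """

    dt: float = 1e-4
    solver: str = "euler"
    simulation_time: Optional[float] = None
    sampling_step_size: Optional[float] = None
    vectorization: bool = True

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.solver not in SOLVERS:
            raise ValueError(f"solver must be one of {SOLVERS}, got "
                             f"{self.solver!r}")
        if self.sampling_step_size is not None \
                and self.sampling_step_size < self.dt:
            raise ValueError("sampling_step_size must be >= dt")
        if self.simulation_time is not None \
                and self.sampling_step_size is not None \
                and self.sampling_step_size > self.simulation_time:
            raise ValueError("sampling_step_size must be <= simulation_time")


# ---------------------------------------------------------------------------
# generic one-step solver (used standalone and mirrored by generated code)
# ---------------------------------------------------------------------------

def solver_step(solver: str, state: np.ndarray,
                rhs: Callable[[np.ndarray], np.ndarray],
                dt: float) -> np.ndarray:
    """Advance ``state`` by one step of the chosen explicit scheme.

    euler:    y + dt*f(y)
    midpoint: y + dt*f(y + dt/2*f(y))
    rk23:     fixed-step third-order Bogacki-Shampine advance,
              y + dt*(2*k1 + 3*k2 + 4*k3)/9 with k1=f(y),
              k2=f(y + dt/2*k1), k3=f(y + 3*dt/4*k2).
    """
    y = np.asarray(state, dtype=float)
    if solver == "euler":
        return y + dt * np.asarray(rhs(y))
    if solver == "midpoint":
        k1 = np.asarray(rhs(y))
        return y + dt * np.asarray(rhs(y + 0.5 * dt * k1))
    if solver == "rk23":
        k1 = np.asarray(rhs(y))
        k2 = np.asarray(rhs(y + 0.5 * dt * k1))
        k3 = np.asarray(rhs(y + 0.75 * dt * k2))
        return y + dt * (2.0 * k1 + 3.0 * k2 + 4.0 * k3) / 9.0
    raise ValueError(f"unknown solver {solver!r}")


# ---------------------------------------------------------------------------
# internal structures
# ---------------------------------------------------------------------------

def _sanitize(text: str) -> str:
    return re.sub(r"\W", "_", text)


@dataclass
class _Group:
    """A vectorized node group: structurally identical member nodes."""

    index: int
    members: List[str]                       # node paths, sorted
    template: NodeIR                         # representative structure
    stages: List[List[str]] = field(default_factory=list)
    # (op, var) -> 'state' | 'alg' | 'const' | 'input'
    var_kind: Dict[Tuple[str, str], str] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.members)

    def member_index(self, path: str) -> int:
        return self.members.index(path)


@dataclass
class _Bundle:
    """Edges sharing source/target variable slots and delay length."""

    src: Tuple[int, str, str]                # (group, op, var)
    tgt: Tuple[int, str, str]
    delay_steps: int                         # 0 = deliver next step
    sidx: List[int] = field(default_factory=list)
    tidx: List[int] = field(default_factory=list)
    weights: List[float] = field(default_factory=list)


def _classify_variables(group: _Group) -> None:
    for op_label, op in group.template.operators.items():
        algebraic = {eq.lhs_variable for eq in op.equations
                     if not eq.is_differential}
        states = set(op.state_variables)
        for var, vstate in op.variables.items():
            if var in states:
                kind = "state"
            elif var in algebraic:
                kind = "alg"
            elif vstate.role == "input":
                kind = "input"
            else:
                kind = "const"
            group.var_kind[(op_label, var)] = kind


def _splice_edge_operators(circuit: CircuitIR) -> CircuitIR:
    """Replace operator-bearing edges by mini-nodes carrying the chain.

    The chain becomes a node inserted between source and target, adding one
    step of transfer latency; the edge weight is applied on the outgoing
    hop, the delay on the incoming hop.
    """
    out = CircuitIR({p: n.copy() for p, n in circuit.nodes.items()}, [],
                    label=circuit.label)
    counter = 0
    for edge in circuit.edges:
        if not edge.operators:
            out.edges.append(edge.copy())
            continue
        node_path = f"__edge_{counter}"
        counter += 1
        ops = {f"op{i}": op.copy() for i, op in enumerate(edge.operators)}
        node = NodeIR(ops)
        stages = node.stages
        first_label = stages[0][0]
        last_label = stages[-1][-1]
        first_op = ops[first_label]
        inputs = first_op.inputs
        if len(inputs) != 1:
            raise EngineError(
                f"edge {edge.source} -> {edge.target}: the first edge "
                f"operator must declare exactly one input (throughput) "
                f"variable, found {len(inputs)}")
        out.nodes[node_path] = node
        out.edges.append(EdgeIR(edge.source,
                                f"{node_path}/{first_label}/{inputs[0]}",
                                weight=1.0, delay=edge.delay))
        out.edges.append(EdgeIR(
            f"{node_path}/{last_label}/{ops[last_label].output}",
            edge.target, weight=edge.weight, delay=None))
    return out


# ---------------------------------------------------------------------------
# code generation
# ---------------------------------------------------------------------------

_SOURCE_CACHE: Dict[str, Callable] = {}
_JIT_CACHE: Dict[str, Callable] = {}


def _get_numba():
    try:
        import numba
        return numba
    except ImportError:                                  # pragma: no cover
        return None


class _CodeGen:
    """Assembles the specialized step-loop source for one run."""

    def __init__(self) -> None:
        self.args: List[Tuple[str, object]] = []
        self.lines: List[str] = []

    def arg(self, name: str, value) -> str:
        self.args.append((name, value))
        return name

    def emit(self, line: str, indent: int = 1) -> None:
        self.lines.append("    " * indent + line)

    def source(self) -> str:
        header = "def _generated_run(n_steps, sample_every, dt, " + \
            ", ".join(name for name, _ in self.args) + "):"
        return "\n".join([header] + self.lines)


class CompiledNetwork:
    """A circuit compiled to vectorized state-update form."""

    def __init__(self, circuit: CircuitIR, dt: float = 1e-4,
                 solver: str = "euler", vectorization: bool = True):
        if solver not in SOLVERS:
            raise EngineError(f"solver must be one of {SOLVERS}, got "
                              f"{solver!r}")
        self.dt = float(dt)
        self.solver = solver
        self.vectorization = bool(vectorization)
        flat = circuit.flatten()
        flat.validate()
        flat = _splice_edge_operators(flat)
        self.circuit = flat
        self.step_count = 0                 # steps executed by the last run
        self._build_groups()
        self._build_bundles()

    # ------------------------------------------------------------------
    # structure
    # ------------------------------------------------------------------
    def _build_groups(self) -> None:
        sig_map: Dict[object, List[str]] = {}
        for path in sorted(self.circuit.nodes):
            node = self.circuit.nodes[path]
            key = node.structure_signature() if self.vectorization \
                else ("__solo__", path)
            sig_map.setdefault(key, []).append(path)
        ordered = sorted(sig_map.values(), key=lambda members: members[0])
        self.groups: List[_Group] = []
        self._node_group: Dict[str, Tuple[int, int]] = {}
        for gi, members in enumerate(ordered):
            template = self.circuit.nodes[members[0]]
            group = _Group(gi, members, template)
            group.stages = template.stages
            _classify_variables(group)
            self.groups.append(group)
            for mi, path in enumerate(members):
                self._node_group[path] = (gi, mi)

    def _resolve(self, path: str) -> Tuple[int, str, str, int]:
        node_path, op, var = self.circuit.resolve_variable(path)
        gi, mi = self._node_group[node_path]
        return gi, op, var, mi

    def _build_bundles(self) -> None:
        bundles: Dict[Tuple, _Bundle] = {}
        edges = sorted(self.circuit.edges,
                       key=lambda e: (e.target, e.source))
        for edge in edges:
            sgi, sop, svar, smi = self._resolve(edge.source)
            tgi, top, tvar, tmi = self._resolve(edge.target)
            if edge.delay is None or edge.delay == 0.0:
                delay_steps = 0
            else:
                delay_steps = int(round(edge.delay / self.dt))
                if delay_steps < 1:
                    warnings.warn(
                        f"edge {edge.source} -> {edge.target}: delay "
                        f"{edge.delay} s is shorter than dt={self.dt} s; "
                        "promoted to one integration step", stacklevel=2)
                    delay_steps = 1
            key = ((sgi, sop, svar), (tgi, top, tvar), delay_steps)
            bundle = bundles.setdefault(
                key, _Bundle(key[0], key[1], delay_steps))
            bundle.sidx.append(smi)
            bundle.tidx.append(tmi)
            bundle.weights.append(edge.weight)
        self.bundles: List[_Bundle] = [bundles[k] for k in sorted(bundles)]

    # convenience for tests and reporting -------------------------------
    def group_members(self) -> List[List[str]]:
        return [list(g.members) for g in self.groups]

    @property
    def n_instances(self) -> int:
        return sum(g.size for g in self.groups)

    @property
    def state_dimension(self) -> int:
        dim = 0
        for g in self.groups:
            for op in g.template.operators.values():
                dim += len(op.state_variables) * g.size
        return dim

    def state_value(self, path: str) -> float:
        """Current value of one variable (after a run: the terminal value)."""
        gi, op, var, mi = self._resolve(path)
        return float(self._arrays[(gi, op, var)][mi])

    # ------------------------------------------------------------------
    # path matching for inputs/outputs
    # ------------------------------------------------------------------
    def _match_variable(self, path: str) -> List[Tuple[str, int, str, str, int]]:
        """All (node_path, group, op, var, member) matching ``path``.

        A path matches a node exactly or as a trailing suffix, so that
        relative addresses like ``PC/PRO/V`` reach every instance in a
        hierarchical or stacked circuit.
        """
        parts = path.split("/")
        if len(parts) < 3:
            raise EngineError(f"variable path {path!r} must be "
                              "<node>/<operator>/<variable>")
        node_part, op, var = "/".join(parts[:-2]), parts[-2], parts[-1]
        matches = []
        for node_path in sorted(self.circuit.nodes):
            if node_path == node_part or node_path.endswith("/" + node_part):
                node = self.circuit.nodes[node_path]
                if op in node.operators and var in node.operators[op].variables:
                    gi, mi = self._node_group[node_path]
                    matches.append((node_path, gi, op, var, mi))
        if not matches:
            raise EngineError(f"variable path {path!r} matches nothing in "
                              "the compiled circuit")
        return matches

    # ------------------------------------------------------------------
    # run
    # ------------------------------------------------------------------
    def run(self,
            simulation_time: float,
            inputs: Optional[Mapping[str, np.ndarray]] = None,
            outputs: Optional[Mapping[str, str]] = None,
            sampling_step_size: Optional[float] = None,
            initial_values: Optional[Mapping[str, float]] = None,
            ) -> "SimulationResult":
        """Integrate for ``simulation_time`` seconds and sample outputs.

        ``inputs`` maps variable paths to per-step arrays (length = number
        of integration steps; relative paths broadcast to every matching
        instance).  ``outputs`` maps column names to variable paths.  Only
        declared outputs are retained.
        """
        dt = self.dt
        n_steps = int(round(simulation_time / dt))
        if n_steps <= 0:
            raise EngineError("simulation_time must cover at least one step")
        if sampling_step_size is None:
            sampling_step_size = dt
        sample_every = int(round(sampling_step_size / dt))
        if sample_every < 1:
            raise EngineError("sampling_step_size must be >= dt")
        n_rows = n_steps // sample_every
        self._n_rows = n_rows

        self._allocate_arrays(initial_values)
        input_binds = self._bind_inputs(inputs or {}, n_steps)
        output_taps = self._bind_outputs(outputs or {}, n_rows)

        gen, arrays = self._generate(input_binds, output_taps)
        source = gen.source()
        work = n_steps * (self.n_instances + len(self.circuit.edges) + 1)
        fn = self._compile_source(source, use_jit=work >= JIT_WORK_THRESHOLD)
        args = [value for _, value in gen.args]
        # overflow is detected via the periodic non-finite guard; the
        # intermediate IEEE warnings are noise
        with np.errstate(all="ignore"):
            steps_done, status = fn(n_steps, sample_every, dt, *args)
        self.step_count = int(steps_done)
        if status != 0:
            culprit = self._find_nonfinite()
            raise EngineError(
                f"non-finite state detected at step {steps_done}"
                + (f" in variable {culprit!r}" if culprit else "")
                + "; reduce dt or check the model parametrization")

        time_axis = (np.arange(n_rows) + 1) * sampling_step_size
        columns: Dict[Tuple[str, str], np.ndarray] = {}
        for name, taps in output_taps.items():
            buf = arrays[f"out_{_sanitize(name)}"]
            for col, (node_path, *_rest) in enumerate(taps):
                columns[(name, node_path)] = buf[:, col]
        df = pd.DataFrame(columns, index=pd.Index(time_axis, name="time"))
        df.columns = pd.MultiIndex.from_tuples(df.columns,
                                               names=["output", "node"])
        meta = {"dt": dt, "solver": self.solver,
                "simulation_time": simulation_time,
                "sampling_step_size": sampling_step_size,
                "vectorization": self.vectorization,
                "steps": self.step_count}
        return SimulationResult(df, meta)

    # ------------------------------------------------------------------
    def _allocate_arrays(self, initial_values) -> None:
        """Per-(group, op, var) float64 vectors for states and constants."""
        arrays: Dict[Tuple[int, str, str], np.ndarray] = {}
        for g in self.groups:
            for op_label in g.template.operators:
                rep = g.template.operators[op_label]
                for var in rep.variables:
                    kind = g.var_kind[(op_label, var)]
                    if kind == "alg":
                        continue
                    values = [self.circuit.nodes[m].operators[op_label]
                              .variables[var].value for m in g.members]
                    arrays[(g.index, op_label, var)] = np.asarray(
                        values, dtype=float)
        self._arrays = arrays
        for path, value in (initial_values or {}).items():
            for node_path, gi, op, var, mi in self._match_variable(path):
                kind = self.groups[gi].var_kind[(op, var)]
                if kind == "alg":
                    raise EngineError(f"cannot set initial value of computed "
                                      f"variable {path!r}")
                arrays[(gi, op, var)][mi] = float(value)

    def _bind_inputs(self, inputs, n_steps):
        binds = []
        for path, array in inputs.items():
            array = np.asarray(array, dtype=float)
            if array.ndim != 1 or array.shape[0] != n_steps:
                raise EngineError(
                    f"input {path!r}: expected a 1-D array with one value "
                    f"per integration step ({n_steps}), got shape "
                    f"{array.shape}")
            matches = self._match_variable(path)
            for node_path, gi, op, var, mi in matches:
                if self.groups[gi].var_kind[(op, var)] != "input":
                    raise EngineError(f"input path {path!r} does not address "
                                      "a variable with role 'input'")
            binds.append((path, matches, array))
        return binds

    def _bind_outputs(self, outputs, n_rows):
        taps: Dict[str, List] = {}
        for name, path in outputs.items():
            taps[name] = self._match_variable(path)
        return taps

    def _find_nonfinite(self) -> Optional[str]:
        for (gi, op, var), arr in self._arrays.items():
            if not np.isfinite(arr).all():
                bad = int(np.flatnonzero(~np.isfinite(arr))[0])
                return f"{self.groups[gi].members[bad]}/{op}/{var}"
        return None

    # ------------------------------------------------------------------
    # source generation
    # ------------------------------------------------------------------
    def _var_name(self, gi: int, op: str, var: str) -> str:
        kind = self.groups[gi].var_kind[(op, var)]
        prefix = {"state": "s", "const": "c", "input": "acc", "alg": "fa"}[kind]
        return f"{prefix}_g{gi}_{_sanitize(op)}_{_sanitize(var)}"

    def _generate(self, input_binds, output_taps):
        gen = _CodeGen()
        arrays: Dict[str, np.ndarray] = {}

        def add_array(name: str, value: np.ndarray) -> str:
            arrays[name] = value
            return gen.arg(name, value)

        # state and constant arrays
        state_names: List[str] = []
        for (gi, op, var), arr in sorted(self._arrays.items()):
            name = self._var_name(gi, op, var)
            kind = self.groups[gi].var_kind[(op, var)]
            if kind == "input":
                continue                     # inputs become acc arrays below
            add_array(name, arr)
            if kind == "state":
                state_names.append(name)

        # which inputs need accumulators (edges or extrinsic feeds)
        fed_inputs = {(b.tgt[0], b.tgt[1], b.tgt[2]) for b in self.bundles}
        for _path, matches, _array in input_binds:
            for node_path, gi, op, var, mi in matches:
                fed_inputs.add((gi, op, var))
        acc_names: Dict[Tuple[int, str, str], str] = {}
        for gi, op, var in sorted(fed_inputs):
            name = self._var_name(gi, op, var)
            add_array(name, np.zeros(self.groups[gi].size))
            acc_names[(gi, op, var)] = name
        # unfed inputs keep their declared default as a constant vector
        for g in self.groups:
            for (op, var), kind in g.var_kind.items():
                if kind == "input" and (g.index, op, var) not in fed_inputs:
                    name = f"c_g{g.index}_{_sanitize(op)}_{_sanitize(var)}"
                    add_array(name, self._arrays[(g.index, op, var)].copy())

        # extrinsic input arrays
        ext_lines: List[str] = []
        for bi, (path, matches, array) in enumerate(input_binds):
            ext = add_array(f"ext_{bi}", array)
            whole_groups = {}
            for node_path, gi, op, var, mi in matches:
                whole_groups.setdefault((gi, op, var), []).append(mi)
            for (gi, op, var), mis in whole_groups.items():
                acc = acc_names[(gi, op, var)]
                if sorted(mis) == list(range(self.groups[gi].size)):
                    ext_lines.append(f"{acc} += {ext}[step]")
                else:
                    for mi in mis:
                        ext_lines.append(f"{acc}[{mi}] += {ext}[step]")

        # bundle index/weight arrays and ring buffers
        bundle_meta = []
        for bi, bundle in enumerate(self.bundles):
            si = add_array(f"si_{bi}", np.asarray(bundle.sidx, dtype=np.int64))
            ti = add_array(f"ti_{bi}", np.asarray(bundle.tidx, dtype=np.int64))
            w = add_array(f"w_{bi}", np.asarray(bundle.weights, dtype=float))
            buf = None
            if bundle.delay_steps > 0:
                buf = add_array(f"buf_{bi}", np.zeros(
                    (bundle.delay_steps, len(bundle.sidx))))
            bundle_meta.append((bundle, si, ti, w, buf))

        # output tap index arrays and buffers
        tap_meta = []
        for name, taps in output_taps.items():
            safe = _sanitize(name)
            per_group: Dict[Tuple[int, str, str], List[Tuple[int, int]]] = {}
            for col, (node_path, gi, op, var, mi) in enumerate(taps):
                per_group.setdefault((gi, op, var), []).append((col, mi))
            buf_name = f"out_{safe}"
            tap_meta.append((buf_name, per_group))

        # ------------------------------------------------------------------
        # expression rendering helpers
        # ------------------------------------------------------------------
        def binding(gi: int, op: str, var: str, sprefix: str,
                    aprefix: str) -> str:
            """Code for reading variable ``var`` of operator ``op``."""
            g = self.groups[gi]
            kind = g.var_kind[(op, var)]
            if kind == "state":
                return f"{sprefix}_g{gi}_{_sanitize(op)}_{_sanitize(var)}"
            if kind == "alg":
                return f"{aprefix}_g{gi}_{_sanitize(op)}_{_sanitize(var)}"
            if kind == "const":
                return f"c_g{gi}_{_sanitize(op)}_{_sanitize(var)}"
            # input: accumulated feeds plus in-node producer outputs
            parts = []
            if (gi, op, var) in acc_names:
                parts.append(acc_names[(gi, op, var)])
            for other_label, other in g.template.operators.items():
                if other_label != op and other.output == var:
                    parts.append(binding(gi, other_label, var, sprefix,
                                         aprefix))
            if not parts:
                return f"c_g{gi}_{_sanitize(op)}_{_sanitize(var)}"
            return "(" + " + ".join(parts) + ")"

        def emit_eval(sprefix: str, dprefix: str, aprefix: str,
                      indent: int, derivatives: bool = True) -> None:
            """Stage-ordered equation evaluation for all groups."""
            for g in self.groups:
                for stage in g.stages:
                    for op_label in stage:
                        op = g.template.operators[op_label]
                        name_of = lambda ident, _g=g, _op=op_label: binding(
                            _g.index, _op, ident, sprefix, aprefix)
                        ordered = ([eq for eq in op.equations
                                    if not eq.is_differential]
                                   + [eq for eq in op.equations
                                      if eq.is_differential])
                        for eq in ordered:
                            rhs = to_python_source(eq.rhs, name_of)
                            tail = f"_g{g.index}_{_sanitize(op_label)}_" \
                                   f"{_sanitize(eq.lhs_variable)}"
                            if eq.is_differential:
                                if derivatives:
                                    gen.emit(f"{dprefix}{tail} = {rhs} + 0.0 * s{tail}",
                                             indent)
                            else:
                                gen.emit(f"{aprefix}{tail} = {rhs} + zeros_g{g.index}",
                                         indent)

        # per-group zero vectors force algebraic locals to vector shape
        for g in self.groups:
            add_array(f"zeros_g{g.index}", np.zeros(g.size))

        # ------------------------------------------------------------------
        # assemble the function body
        # ------------------------------------------------------------------
        # prologue: initial algebraic values (edge sources before step 0)
        emit_eval("s", "d0", "fa", 1, derivatives=False)
        gen.emit("for step in range(n_steps):", 1)
        for name in acc_names.values():
            gen.emit(f"{name}[:] = 0.0", 2)
        for bundle, si, ti, w, buf in bundle_meta:
            sgi, sop, svar = bundle.src
            src = self._var_name(sgi, sop, svar)
            if self.groups[sgi].var_kind[(sop, svar)] == "input":
                raise EngineError(
                    f"edge source {sop}/{svar} has role 'input'; edges must "
                    "read state, output or constant variables")
            tgt_acc = acc_names[bundle.tgt]
            if buf is not None:
                gen.emit(f"slot = step % {buf}.shape[0]", 2)
                gen.emit(f"for e in range({si}.shape[0]):", 2)
                gen.emit(f"{tgt_acc}[{ti}[e]] += {w}[e] * {buf}[slot, e]", 3)
            else:
                gen.emit(f"for e in range({si}.shape[0]):", 2)
                gen.emit(f"{tgt_acc}[{ti}[e]] += {w}[e] * {src}[{si}[e]]", 3)
        for line in ext_lines:
            gen.emit(line, 2)

        # solver advance
        if self.solver == "euler":
            emit_eval("s", "d1", "a1", 2)
            for name in state_names:
                gen.emit(f"{name} += dt * d1{name[1:]}", 2)
        elif self.solver == "midpoint":
            emit_eval("s", "d1", "a1", 2)
            for name in state_names:
                gen.emit(f"t{name[1:]} = {name} + (0.5 * dt) * d1{name[1:]}", 2)
            emit_eval("t", "d2", "a2", 2)
            for name in state_names:
                gen.emit(f"{name} += dt * d2{name[1:]}", 2)
        else:  # rk23
            emit_eval("s", "d1", "a1", 2)
            for name in state_names:
                gen.emit(f"t{name[1:]} = {name} + (0.5 * dt) * d1{name[1:]}", 2)
            emit_eval("t", "d2", "a2", 2)
            for name in state_names:
                gen.emit(f"t{name[1:]} = {name} + (0.75 * dt) * d2{name[1:]}", 2)
            emit_eval("t", "d3", "a3", 2)
            for name in state_names:
                gen.emit(f"{name} += dt * (2.0 * d1{name[1:]} + "
                         f"3.0 * d2{name[1:]} + 4.0 * d3{name[1:]}) / 9.0", 2)

        # refresh algebraic variables at the advanced state
        emit_eval("s", "dz", "fa", 2, derivatives=False)

        # write delayed-edge ring buffers (post-update source values)
        for bundle, si, ti, w, buf in bundle_meta:
            if buf is None:
                continue
            sgi, sop, svar = bundle.src
            src = self._var_name(sgi, sop, svar)
            gen.emit(f"slot = step % {buf}.shape[0]", 2)
            gen.emit(f"for e in range({si}.shape[0]):", 2)
            gen.emit(f"{buf}[slot, e] = {src}[{si}[e]]", 3)

        # sampling
        if tap_meta:
            gen.emit("if (step + 1) % sample_every == 0:", 2)
            gen.emit("row = (step + 1) // sample_every - 1", 3)
            for buf_name, per_group in tap_meta:
                total_cols = sum(len(v) for v in per_group.values())
                add_array(buf_name, np.zeros((self._n_rows, total_cols)))
                for (gi, op, var), cols in per_group.items():
                    # inputs tap their summed binding (e.g. the combined
                    # membrane potential), others their value array
                    src = binding(gi, op, var, "s", "fa")
                    for col, mi in cols:
                        gen.emit(f"{buf_name}[row, {col}] = ({src})[{mi}]", 3)

        # periodic non-finite guard
        checks = " and ".join(f"np.isfinite({name}).all()"
                              for name in state_names) or "True"
        gen.emit("if (step + 1) % 1000 == 0:", 2)
        gen.emit(f"if not ({checks}):", 3)
        gen.emit("return step + 1, 1", 4)

        gen.emit(f"if not ({checks}):", 1)
        gen.emit("return n_steps, 1", 2)
        gen.emit("return n_steps, 0", 1)
        return gen, arrays

    # number of rows is needed while generating output buffers
    _n_rows = 0

    def _compile_source(self, source: str, use_jit: bool) -> Callable:
        numba = _get_numba() if use_jit else None
        cache = _JIT_CACHE if numba is not None else _SOURCE_CACHE
        key = hashlib.sha256(source.encode()).hexdigest()
        if key in cache:
            return cache[key]
        namespace: Dict[str, object] = {"np": np}
        exec(builtins.compile(source, "<ratesim-generated>", "exec"),
             namespace)
        fn = namespace["_generated_run"]
        if numba is not None:
            fn = numba.njit(fn, cache=False, fastmath=False)
        cache[key] = fn
        return fn


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

class SimulationResult:
    """Sampled output series, indexed by time.

    ``df`` is a pandas DataFrame with a two-level column index
    (output name, node path) and the sampled time axis as index.
    """

    def __init__(self, df: pd.DataFrame, metadata: Mapping):
        self.df = df
        self.metadata = dict(metadata)

    @property
    def time(self) -> np.ndarray:
        return self.df.index.to_numpy()

    def series(self, name: str) -> np.ndarray:
        """1-D array for single-instance outputs, 2-D otherwise."""
        sub = self.df[name]
        values = sub.to_numpy()
        return values[:, 0] if values.shape[1] == 1 else values

    def to_csv(self, path: str) -> None:
        flat = self.df.copy()
        flat.columns = ["/".join(col).rstrip("/") for col in flat.columns]
        flat.to_csv(path)

    def __repr__(self) -> str:
        return (f"SimulationResult({self.df.shape[0]} rows x "
                f"{self.df.shape[1]} outputs)")


# ---------------------------------------------------------------------------
# public entry point
# ---------------------------------------------------------------------------

def compile(circuit, dt: float = 1e-4, solver: str = "euler",
            vectorization: bool = True) -> CompiledNetwork:
    """Compile a circuit (IR or template) for fixed-step integration.

    ``vectorization=True`` merges structurally identical nodes into one
    vectorized node with per-instance constant vectors;
    ``vectorization=False`` keeps every node separate (results agree either
    way).
    """
    if hasattr(circuit, "apply") and not isinstance(circuit, CircuitIR):
        circuit = circuit.apply()
    return CompiledNetwork(circuit, dt=dt, solver=solver,
                           vectorization=vectorization)
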