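"""Declarative model templates with inheritance.

Models are described by four template kinds that mirror the circuit
hierarchy: *operator* templates hold equations and variable declarations,
*node* templates list labelled operators, *edge* templates hold optional
coupling operators, and *circuit* templates wire nodes (and nested
sub-circuits) together with weighted, optionally delayed edges.

Templates live in YAML documents (one or more templates per file) or in
structurally identical in-memory mappings.  Every template names a ``base``:
either one of the four root kinds (``OperatorTemplate``, ``NodeTemplate``,
``EdgeTemplate``, ``CircuitTemplate``) or a parent template whose fields it
overrides — child variable defaults win key-by-key, equations are inherited
unless overridden or adapted through token-level ``replace``.

Example (abridged)::

    JansenRitSynapse:
      base: OperatorTemplate
      equations:
        - "d/dt * V = V_t"
        - "d/dt * V_t = h/tau * r_in - (1./tau)^2 * V - 2.*1./tau*V_t"
      variables:
        r_in: {default: input}
        V: {default: output}
        V_t: {default: variable}
        tau: {default: constant}
        h: {default: constant}

    ExcitatorySynapse:
      base: JansenRitSynapse
      variables:
        h: {default: 3.25e-3}
        tau: {default: 10e-3}
"""

from __future__ import annotations

import copy
import os
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import yaml

from .circuit_ir import (CircuitError, CircuitIR, EdgeIR, NodeIR, OperatorIR,
                         ROLES, VarState)
from .expressions import (ParseError, free_variables, parse_equation,
                          replace_identifiers, replace_in_equation_set,
                          CONSTANTS, FUNCTIONS)

__all__ = [
    "TemplateError",
    "OperatorTemplate",
    "NodeTemplate",
    "EdgeTemplate",
    "CircuitTemplate",
    "TemplateCollection",
    "load_template",
    "replace_in_equations",
]

_ROOTS = ("OperatorTemplate", "NodeTemplate", "EdgeTemplate", "CircuitTemplate")


class TemplateError(ValueError):
    """Malformed template document or unsatisfiable inheritance."""


# ---------------------------------------------------------------------------
# variable specifications
# ---------------------------------------------------------------------------

def _parse_variable_spec(spec) -> Tuple[Optional[str], Optional[float], str]:
    """Decode a variable declaration into (role, value, description).

    Accepted forms: a role name (``input``/``output``/``variable``/
    ``constant``), a number (value only — role inherited from the parent or
    defaulting to ``constant``), ``role(value)``, or a mapping with
    ``default`` plus optional ``description``.
    """
    description = ""
    if isinstance(spec, Mapping):
        description = str(spec.get("description", ""))
        if "default" not in spec:
            return None, None, description
        role, value, _ = _parse_variable_spec(spec["default"])
        return role, value, description
    if isinstance(spec, bool):
        raise TemplateError(f"invalid variable default {spec!r}")
    if isinstance(spec, (int, float)):
        return None, float(spec), description
    if isinstance(spec, str):
        text = spec.strip()
        if text in ROLES:
            return text, None, description
        if "(" in text and text.endswith(")"):
            role, _, rest = text.partition("(")
            role = role.strip()
            if role in ROLES:
                try:
                    return role, float(rest[:-1]), description
                except ValueError:
                    raise TemplateError(f"invalid variable default {spec!r}")
        try:
            return None, float(text), description
        except ValueError:
            raise TemplateError(f"invalid variable default {spec!r}")
    raise TemplateError(f"invalid variable default {spec!r}")


@dataclass
class _VarDecl:
    role: Optional[str] = None
    value: Optional[float] = None
    description: str = ""


# ---------------------------------------------------------------------------
# resolved template classes
# ---------------------------------------------------------------------------

@dataclass
class OperatorTemplate:
    name: str
    equations: Tuple[str, ...]
    variables: Dict[str, _VarDecl]
    description: str = ""

    def validate(self) -> None:
        outputs = [v for v, d in self.variables.items() if d.role == "output"]
        if len(outputs) != 1:
            raise TemplateError(
                f"operator {self.name!r} must declare exactly one output "
                f"variable, found {len(outputs)}")
        declared = set(self.variables)
        for eq_text in self.equations:
            eq = parse_equation(eq_text)
            used = free_variables(eq.rhs) | {eq.lhs_variable}
            for ident in used:
                if ident not in declared and ident not in CONSTANTS \
                        and ident not in FUNCTIONS:
                    raise TemplateError(
                        f"operator {self.name!r}: identifier {ident!r} in "
                        f"equation {eq_text!r} is not declared in variables")

    def instantiate(self) -> OperatorIR:
        equations = [parse_equation(text) for text in self.equations]
        variables = {
            var: VarState(decl.role or "constant",
                          decl.value if decl.value is not None else 0.0,
                          decl.description)
            for var, decl in self.variables.items()}
        return OperatorIR(self.name, equations, variables)

    def resolve(self) -> "OperatorTemplate":
        return self


@dataclass
class NodeTemplate:
    name: str
    operators: Dict[str, OperatorTemplate]   # label -> operator
    description: str = ""

    def instantiate(self) -> NodeIR:
        node = NodeIR({label: op.instantiate()
                       for label, op in self.operators.items()})
        node.stages  # raises on cyclic operator dependencies
        return node

    def resolve(self) -> "NodeTemplate":
        return self


@dataclass
class EdgeTemplate:
    name: str
    operators: Dict[str, OperatorTemplate] = field(default_factory=dict)
    description: str = ""

    def resolve(self) -> "EdgeTemplate":
        return self


@dataclass
class EdgeSpec:
    source: str
    target: str
    template: Optional[EdgeTemplate]
    attrs: Dict[str, float]

    @property
    def weight(self) -> float:
        return float(self.attrs.get("weight", 1.0))

    @property
    def delay(self) -> Optional[float]:
        delay = self.attrs.get("delay", None)
        return None if delay is None else float(delay)


@dataclass
class CircuitTemplate:
    name: str
    nodes: Dict[str, NodeTemplate]
    circuits: Dict[str, "CircuitTemplate"]
    edges: List[EdgeSpec]
    description: str = ""

    def resolve(self) -> "CircuitTemplate":
        return self

    # ------------------------------------------------------------------
    def apply(self, values: Optional[Mapping[str, float]] = None) -> CircuitIR:
        """Instantiate the template into a :class:`CircuitIR`.

        ``values`` maps variable paths (``<node>/<operator>/<variable>``,
        prefixed by sub-circuit labels where nested) to replacement values
        for declared constants/variables — including initial values of state
        variables.
        """
        circuit = self._build()
        if values:
            for path, value in values.items():
                _set_value(circuit, path, float(value))
        circuit.validate()
        return circuit

    def _build(self) -> CircuitIR:
        nodes = {label: tpl.instantiate() for label, tpl in self.nodes.items()}
        subcircuits = {label: tpl._build()
                       for label, tpl in self.circuits.items()}
        edges = []
        for spec in self.edges:
            operators = []
            if spec.template is not None:
                operators = [op.instantiate()
                             for op in spec.template.operators.values()]
            edge = EdgeIR(spec.source, spec.target, spec.weight, spec.delay,
                          operators)
            for key, value in spec.attrs.items():
                if key in ("weight", "delay"):
                    continue
                _set_edge_operator_value(edge, key, float(value))
            edges.append(edge)
        return CircuitIR(nodes, edges, subcircuits, label=self.name)

    # ------------------------------------------------------------------
    def with_edge_attrs(self, weight: Optional[float] = None,
                        delay: Optional[float] = None) -> "CircuitTemplate":
        """Copy of the template with this level's edge attributes replaced.

        Only the template's own edges are touched; edges inside sub-circuits
        are left alone.  Used by parameter sweeps over coupling strength and
        propagation delay.
        """
        new = copy.deepcopy(self)
        for spec in new.edges:
            if weight is not None:
                spec.attrs["weight"] = float(weight)
            if delay is not None:
                spec.attrs["delay"] = float(delay)
        return new


def _set_value(circuit: CircuitIR, path: str, value: float) -> None:
    parts = path.split("/")
    if parts and parts[0] in circuit.subcircuits:
        _set_value(circuit.subcircuits[parts[0]], "/".join(parts[1:]), value)
        return
    if len(parts) < 3:
        raise TemplateError(f"override path {path!r} must be "
                            "<node>/<operator>/<variable>")
    node_path, op, var = "/".join(parts[:-2]), parts[-2], parts[-1]
    if node_path not in circuit.nodes:
        raise TemplateError(f"override path {path!r}: unknown node "
                            f"{node_path!r}")
    try:
        circuit.nodes[node_path].get_variable(op, var).value = value
    except CircuitError as err:
        raise TemplateError(f"override path {path!r}: {err}") from err


def _set_edge_operator_value(edge: EdgeIR, key: str, value: float) -> None:
    parts = key.split("/")
    if len(parts) == 2:
        op_name, var = parts
        for op in edge.operators:
            if op.name == op_name and var in op.variables:
                op.variables[var].value = value
                return
    else:
        var = parts[0]
        for op in edge.operators:
            if var in op.variables:
                op.variables[var].value = value
                return
    raise TemplateError(f"edge attribute {key!r} matches no edge-operator "
                        "variable")


# ---------------------------------------------------------------------------
# template collections and inheritance resolution
# ---------------------------------------------------------------------------

class TemplateCollection:
    """A set of raw template definitions with lazy inheritance resolution.

    Construct from a mapping (template name -> definition mapping) or load
    from a YAML document via :meth:`from_yaml`.
    """

    def __init__(self, documents: Mapping[str, Mapping]):
        self.raw: Dict[str, Mapping] = dict(documents)
        self._cache: Dict[str, object] = {}

    @classmethod
    def from_yaml(cls, path: str) -> "TemplateCollection":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, Mapping):
            raise TemplateError(f"{path}: template document must be a mapping")
        return cls(data)

    # ------------------------------------------------------------------
    def _chain(self, name: str) -> List[Tuple[str, Mapping]]:
        """Inheritance chain root-first; raises on unknown or cyclic base."""
        chain: List[Tuple[str, Mapping]] = []
        seen: set = set()
        current = name
        while True:
            if current in seen:
                raise TemplateError(f"cyclic base chain involving {current!r}")
            seen.add(current)
            if current not in self.raw:
                raise TemplateError(f"unknown template {current!r}")
            spec = self.raw[current]
            if not isinstance(spec, Mapping):
                raise TemplateError(f"template {current!r} must be a mapping")
            chain.append((current, spec))
            base = spec.get("base")
            if base is None:
                raise TemplateError(f"template {current!r} declares no base")
            if base in _ROOTS:
                chain.append((base, {}))
                chain.reverse()
                return chain
            current = base

    def kind_of(self, name: str) -> str:
        return self._chain(name)[0][0]

    def resolve(self, name: str):
        """Fully merge the inheritance chain of ``name`` and validate.

        Returns an :class:`OperatorTemplate`, :class:`NodeTemplate`,
        :class:`EdgeTemplate` or :class:`CircuitTemplate`.  Results are
        cached; resolution is idempotent.
        """
        if name in self._cache:
            return self._cache[name]
        chain = self._chain(name)
        root = chain[0][0]
        builder = {
            "OperatorTemplate": self._resolve_operator,
            "NodeTemplate": self._resolve_node,
            "EdgeTemplate": self._resolve_edge,
            "CircuitTemplate": self._resolve_circuit,
        }[root]
        resolved = builder(name, chain[1:])
        self._cache[name] = resolved
        return resolved

    # -- operator ------------------------------------------------------
    def _resolve_operator(self, name: str, chain) -> OperatorTemplate:
        equations: Tuple[str, ...] = ()
        variables: Dict[str, _VarDecl] = {}
        description = ""
        for level_name, spec in chain:
            description = str(spec.get("description", description))
            eq_spec = spec.get("equations")
            if eq_spec is not None:
                if isinstance(eq_spec, Mapping) and "replace" in eq_spec:
                    mapping = {str(k): str(v)
                               for k, v in eq_spec["replace"].items()}
                    if not equations:
                        raise TemplateError(
                            f"template {level_name!r} uses equations.replace "
                            "but inherits no equations")
                    equations = replace_in_equation_set(equations, mapping)
                elif isinstance(eq_spec, (list, tuple)):
                    equations = tuple(str(eq) for eq in eq_spec)
                elif isinstance(eq_spec, str):
                    equations = (eq_spec,)
                else:
                    raise TemplateError(
                        f"template {level_name!r}: equations must be a list "
                        "or a replace mapping")
            for var, var_spec in (spec.get("variables") or {}).items():
                role, value, desc = _parse_variable_spec(var_spec)
                decl = variables.setdefault(var, _VarDecl())
                if role is not None:
                    if decl.role is not None and decl.role != role:
                        warnings.warn(
                            f"template {level_name!r} changes role of "
                            f"variable {var!r} from {decl.role!r} to {role!r}",
                            stacklevel=2)
                    decl.role = role
                if value is not None:
                    decl.value = value
                if desc:
                    decl.description = desc
        template = OperatorTemplate(name, equations, variables, description)
        template.validate()
        return template

    # -- node / edge operator lists ------------------------------------
    def _operator_map(self, spec_entry, owner: str) -> Dict[str, OperatorTemplate]:
        """Normalize an ``operators`` field to label -> resolved operator."""
        operators: Dict[str, OperatorTemplate] = {}

        def add(label: str, ref) -> None:
            if "/" in label:
                raise TemplateError(f"{owner}: operator label {label!r} may "
                                    "not contain '/'")
            if label in operators:
                raise TemplateError(f"{owner}: duplicate operator label "
                                    f"{label!r}")
            if isinstance(ref, str):
                tpl = self.resolve(ref)
            else:
                tpl = ref
            if not isinstance(tpl, OperatorTemplate):
                raise TemplateError(f"{owner}: {label!r} does not reference "
                                    "an operator template")
            operators[label] = tpl

        if isinstance(spec_entry, Mapping):
            for label, ref in spec_entry.items():
                add(str(label), ref)
        elif isinstance(spec_entry, (list, tuple)):
            for item in spec_entry:
                if isinstance(item, str):
                    add(item, item)
                elif isinstance(item, Mapping) and len(item) == 1:
                    ((label, ref),) = item.items()
                    add(str(label), ref)
                else:
                    raise TemplateError(f"{owner}: invalid operators entry "
                                        f"{item!r}")
        else:
            raise TemplateError(f"{owner}: operators must be a list or "
                                "mapping")
        return operators

    def _resolve_node(self, name: str, chain) -> NodeTemplate:
        operators: Dict[str, OperatorTemplate] = {}
        description = ""
        for level_name, spec in chain:
            description = str(spec.get("description", description))
            if "operators" in spec:
                operators = self._operator_map(spec["operators"], level_name)
        if not operators:
            raise TemplateError(f"node template {name!r} lists no operators")
        return NodeTemplate(name, operators, description)

    def _resolve_edge(self, name: str, chain) -> EdgeTemplate:
        operators: Dict[str, OperatorTemplate] = {}
        description = ""
        for level_name, spec in chain:
            description = str(spec.get("description", description))
            if "operators" in spec:
                operators = self._operator_map(spec["operators"], level_name)
        return EdgeTemplate(name, operators, description)

    # -- circuit -------------------------------------------------------
    def _resolve_circuit(self, name: str, chain) -> CircuitTemplate:
        nodes: Dict[str, NodeTemplate] = {}
        circuits: Dict[str, CircuitTemplate] = {}
        edges: List[EdgeSpec] = []
        description = ""
        for level_name, spec in chain:
            description = str(spec.get("description", description))
            for label, ref in (spec.get("nodes") or {}).items():
                tpl = self.resolve(ref) if isinstance(ref, str) else ref
                if not isinstance(tpl, NodeTemplate):
                    raise TemplateError(
                        f"{level_name}: node {label!r} does not reference a "
                        "node template")
                nodes[str(label)] = tpl
            for label, ref in (spec.get("circuits") or {}).items():
                tpl = self.resolve(ref) if isinstance(ref, str) else ref
                if not isinstance(tpl, CircuitTemplate):
                    raise TemplateError(
                        f"{level_name}: circuit {label!r} does not reference "
                        "a circuit template")
                circuits[str(label)] = tpl
            if "edges" in spec:
                edges = [self._parse_edge(item, level_name)
                         for item in spec["edges"] or []]
        return CircuitTemplate(name, nodes, circuits, edges, description)

    def _parse_edge(self, item, owner: str) -> EdgeSpec:
        if not isinstance(item, (list, tuple)) or not 2 <= len(item) <= 4:
            raise TemplateError(
                f"{owner}: each edge must be a list of 2-4 elements "
                "[source, target, template, attributes]")
        source, target = str(item[0]), str(item[1])
        template = None
        if len(item) >= 3 and item[2] not in (None, "null"):
            ref = item[2]
            tpl = self.resolve(ref) if isinstance(ref, str) else ref
            if not isinstance(tpl, EdgeTemplate):
                raise TemplateError(f"{owner}: edge template reference "
                                    f"{ref!r} is not an edge template")
            template = tpl
        attrs: Dict[str, float] = {}
        if len(item) == 4:
            if not isinstance(item[3], Mapping):
                raise TemplateError(f"{owner}: edge attributes must be a "
                                    "mapping")
            attrs = {str(k): v for k, v in item[3].items()}
        return EdgeSpec(source, target, template, attrs)


# ---------------------------------------------------------------------------
# public helpers
# ---------------------------------------------------------------------------

def load_template(source: str):
    """Load one template by ``path/to/file/TemplateName`` address.

    The last path component names the template; the rest names a YAML file
    (the ``.yaml``/``.yml`` extension may be omitted).
    """
    path, _, name = source.replace(os.sep, "/").rpartition("/")
    if not path:
        raise TemplateError(
            f"template address {source!r} must be <file path>/<TemplateName>")
    for candidate in (path, path + ".yaml", path + ".yml"):
        if os.path.isfile(candidate):
            return TemplateCollection.from_yaml(candidate).resolve(name)
    raise TemplateError(f"no template file found for {source!r}")


def replace_in_equations(template: OperatorTemplate,
                         mapping: Mapping[str, str],
                         new_variables: Optional[Mapping] = None,
                         name: Optional[str] = None) -> OperatorTemplate:
    """Whole-token identifier substitution over an operator's equations.

    Keys must match complete identifier tokens (``V`` never matches inside
    ``V_t``).  Free variables introduced by the substitution must be declared
    through ``new_variables`` in the same adaptation.
    """
    equations = replace_in_equation_set(template.equations, mapping)
    variables = {var: _VarDecl(decl.role, decl.value, decl.description)
                 for var, decl in template.variables.items()}
    for var, spec in (new_variables or {}).items():
        role, value, desc = _parse_variable_spec(spec)
        variables[var] = _VarDecl(role or "constant",
                                  value if value is not None else 0.0, desc)
    adapted = OperatorTemplate(name or template.name, equations, variables,
                               template.description)
    adapted.validate()
    return adapted
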