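"""Equation syntax for operator definitions.

Model equations are plain strings such as ``"a = 5 * (b + c) / d**2"`` or
``"d/dt * V = V_t"``.  This module turns them into small expression trees
(:class:`EquationAST`), evaluates those trees against variable bindings with
NumPy broadcasting semantics, and renders them back to strings.

Syntax summary
--------------
* arithmetic: ``+ - * / **`` (``^`` is a synonym for ``**``), unary minus,
  parentheses for grouping;
* first-order derivatives on the left-hand side: ``d/dt * x = ...`` or the
  shorthand ``x' = ...``; higher orders are rejected — rewrite them as
  coupled first-order equations;
* function calls: ``exp(x)``, ``sum(A, 0)``, ... (see :data:`FUNCTIONS`);
* comparisons (``> < >= <= == !=``) produce boolean masks; wrap them in
  ``float(...)`` to obtain 0.0/1.0 values;
* indexing follows NumPy: ``a[3]``, ``a[1:3]``, ``a[0:5, 3:7]``,
  ``a[[3], [4]]`` and boolean masks ``a[a > 5]``.

Precedence, loosest to tightest: comparisons, ``+ -``, ``* /``, unary minus,
``**`` (right-associative; unary minus binds tighter than ``*`` but looser
than ``**``, so ``-a**b`` is ``-(a**b)``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

__all__ = [
    "ParseError",
    "EvaluationError",
    "EquationAST",
    "Num",
    "Var",
    "UnaryOp",
    "BinOp",
    "Compare",
    "Call",
    "Index",
    "SliceSpec",
    "ListLit",
    "FUNCTIONS",
    "CONSTANTS",
    "parse_equation",
    "parse_expression",
    "evaluate",
    "free_variables",
    "render",
    "render_equation",
    "replace_identifiers",
    "tokenize",
    "to_python_source",
]


# ---------------------------------------------------------------------------
# errors
# ---------------------------------------------------------------------------

class ParseError(ValueError):
    """Raised for malformed equation text; carries the offending position."""

    def __init__(self, message: str, position: int = -1, token: str = ""):
        self.position = position
        self.token = token
        loc = f" at position {position}" if position >= 0 else ""
        tok = f" (near {token!r})" if token else ""
        super().__init__(f"{message}{loc}{tok}")


class EvaluationError(ValueError):
    """Raised when an expression tree cannot be evaluated."""


# ---------------------------------------------------------------------------
# tokens
# ---------------------------------------------------------------------------

_SYMBOLS = (
    "**", "^", ">=", "<=", "==", "!=", "+", "-", "*", "/", ">", "<",
    "(", ")", "[", "]", ",", ":", "=", "'",
)


@dataclass(frozen=True)
class Token:
    kind: str        # "num" | "ident" | "sym" | "end"
    text: str
    pos: int


def tokenize(text: str) -> List[Token]:
    tokens: List[Token] = []
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c.isspace():
            i += 1
            continue
        if c.isdigit() or (c == "." and i + 1 < n and text[i + 1].isdigit()):
            j = i
            while j < n and (text[j].isdigit() or text[j] == "."):
                j += 1
            if j < n and text[j] in "eE":
                k = j + 1
                if k < n and text[k] in "+-":
                    k += 1
                if k < n and text[k].isdigit():
                    j = k
                    while j < n and text[j].isdigit():
                        j += 1
            tokens.append(Token("num", text[i:j], i))
            i = j
            continue
        if c.isalpha() or c == "_":
            j = i
            while j < n and (text[j].isalnum() or text[j] == "_"):
                j += 1
            tokens.append(Token("ident", text[i:j], i))
            i = j
            continue
        for sym in _SYMBOLS:
            if text.startswith(sym, i):
                tokens.append(Token("sym", sym, i))
                i += len(sym)
                break
        else:
            raise ParseError("unexpected character", i, c)
    tokens.append(Token("end", "", n))
    return tokens


# ---------------------------------------------------------------------------
# AST node types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Num:
    value: float


@dataclass(frozen=True)
class Var:
    name: str


@dataclass(frozen=True)
class UnaryOp:
    op: str
    operand: "Node"


@dataclass(frozen=True)
class BinOp:
    op: str
    left: "Node"
    right: "Node"


@dataclass(frozen=True)
class Compare:
    op: str
    left: "Node"
    right: "Node"


@dataclass(frozen=True)
class Call:
    name: str
    args: Tuple["Node", ...]


@dataclass(frozen=True)
class SliceSpec:
    start: Optional["Node"]
    stop: Optional["Node"]
    step: Optional["Node"] = None


@dataclass(frozen=True)
class ListLit:
    items: Tuple["Node", ...]


@dataclass(frozen=True)
class Index:
    base: "Node"
    spec: Tuple[Union["Node", SliceSpec], ...]


Node = Union[Num, Var, UnaryOp, BinOp, Compare, Call, Index, ListLit]


@dataclass(frozen=True)
class EquationAST:
    """A parsed equation: assignment target plus right-hand-side tree."""

    lhs_variable: str
    lhs_is_derivative: bool
    rhs: Node

    @property
    def is_differential(self) -> bool:
        return self.lhs_is_derivative


# ---------------------------------------------------------------------------
# function registry
# ---------------------------------------------------------------------------

def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float))) if np.ndim(x) else 1.0 / (1.0 + math.exp(-x))


def _as_float(x):
    if np.ndim(x):
        return np.asarray(x).astype(float)
    return float(x)


def _maxmin(fn, reduce_fn):
    def call(*args):
        if len(args) == 1:
            return reduce_fn(args[0])
        if len(args) == 2:
            return fn(args[0], args[1])
        raise EvaluationError(f"{reduce_fn.__name__} takes 1 or 2 arguments")
    return call


def _sum(*args):
    if len(args) == 1:
        return np.sum(args[0])
    if len(args) == 2:
        return np.sum(args[0], axis=int(np.asarray(args[1]).item()))
    raise EvaluationError("sum takes 1 or 2 arguments")


#: name -> (callable, (min_arity, max_arity)); all elementwise unless noted.
FUNCTIONS: Dict[str, Tuple[Callable, Tuple[int, int]]] = {
    "exp": (np.exp, (1, 1)),
    "sin": (np.sin, (1, 1)),
    "cos": (np.cos, (1, 1)),
    "tan": (np.tan, (1, 1)),
    "tanh": (np.tanh, (1, 1)),
    "sinh": (np.sinh, (1, 1)),
    "cosh": (np.cosh, (1, 1)),
    "sqrt": (np.sqrt, (1, 1)),
    "log": (np.log, (1, 1)),
    "abs": (np.abs, (1, 1)),
    "sigmoid": (_sigmoid, (1, 1)),
    "float": (_as_float, (1, 1)),
    "sum": (_sum, (1, 2)),           # sum(A) or sum(A, axis)
    "max": (_maxmin(np.maximum, np.max), (1, 2)),
    "min": (_maxmin(np.minimum, np.min), (1, 2)),
}

#: predefined constants usable in any equation
CONSTANTS: Dict[str, float] = {"PI": math.pi, "E": math.e}


# ---------------------------------------------------------------------------
# parser
# ---------------------------------------------------------------------------

class _Parser:
    def __init__(self, tokens: List[Token]):
        self.tokens = tokens
        self.i = 0

    # -- token helpers --
    def peek(self) -> Token:
        return self.tokens[self.i]

    def next(self) -> Token:
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def accept(self, text: str) -> Optional[Token]:
        tok = self.peek()
        if tok.kind == "sym" and tok.text == text:
            return self.next()
        return None

    def expect(self, text: str) -> Token:
        tok = self.accept(text)
        if tok is None:
            cur = self.peek()
            raise ParseError(f"expected {text!r}", cur.pos, cur.text)
        return tok

    # -- grammar --
    def expression(self) -> Node:
        left = self.additive()
        tok = self.peek()
        if tok.kind == "sym" and tok.text in (">", "<", ">=", "<=", "==", "!="):
            self.next()
            right = self.additive()
            return Compare(tok.text, left, right)
        return left

    def additive(self) -> Node:
        node = self.multiplicative()
        while True:
            tok = self.peek()
            if tok.kind == "sym" and tok.text in ("+", "-"):
                self.next()
                node = BinOp(tok.text, node, self.multiplicative())
            else:
                return node

    def multiplicative(self) -> Node:
        node = self.unary()
        while True:
            tok = self.peek()
            if tok.kind == "sym" and tok.text in ("*", "/"):
                self.next()
                node = BinOp(tok.text, node, self.unary())
            else:
                return node

    def unary(self) -> Node:
        if self.accept("-"):
            return UnaryOp("-", self.unary())
        if self.accept("+"):
            return self.unary()
        return self.power()

    def power(self) -> Node:
        base = self.postfix()
        tok = self.peek()
        if tok.kind == "sym" and tok.text in ("**", "^"):
            self.next()
            # right-associative; exponent may carry a unary sign: a**-b
            return BinOp("**", base, self.unary())
        return base

    def postfix(self) -> Node:
        node = self.atom()
        while self.accept("["):
            spec = [self.index_item()]
            while self.accept(","):
                spec.append(self.index_item())
            self.expect("]")
            node = Index(node, tuple(spec))
        return node

    def index_item(self) -> Union[Node, SliceSpec]:
        # a slice has a ':' at top level; otherwise a plain expression
        def at_slice_colon() -> bool:
            tok = self.peek()
            return tok.kind == "sym" and tok.text == ":"

        start: Optional[Node] = None
        if not at_slice_colon():
            start = self.expression()
            if not at_slice_colon():
                return start
        self.expect(":")
        stop: Optional[Node] = None
        tok = self.peek()
        if not (tok.kind == "sym" and tok.text in (":", "]", ",")):
            stop = self.expression()
        step: Optional[Node] = None
        if self.accept(":"):
            tok = self.peek()
            if not (tok.kind == "sym" and tok.text in ("]", ",")):
                step = self.expression()
        return SliceSpec(start, stop, step)

    def atom(self) -> Node:
        tok = self.next()
        if tok.kind == "num":
            return Num(float(tok.text))
        if tok.kind == "ident":
            if self.accept("("):
                args: List[Node] = []
                if not (self.peek().kind == "sym" and self.peek().text == ")"):
                    args.append(self.expression())
                    while self.accept(","):
                        args.append(self.expression())
                self.expect(")")
                if tok.text not in FUNCTIONS:
                    raise ParseError("unknown function", tok.pos, tok.text)
                lo, hi = FUNCTIONS[tok.text][1]
                if not (lo <= len(args) <= hi):
                    raise ParseError(
                        f"function {tok.text} takes {lo}" + (f"-{hi}" if hi != lo else "") + " arguments",
                        tok.pos, tok.text)
                return Call(tok.text, tuple(args))
            return Var(tok.text)
        if tok.kind == "sym" and tok.text == "(":
            node = self.expression()
            self.expect(")")
            return node
        if tok.kind == "sym" and tok.text == "[":
            items: List[Node] = []
            if not (self.peek().kind == "sym" and self.peek().text == "]"):
                items.append(self.expression())
                while self.accept(","):
                    items.append(self.expression())
            self.expect("]")
            return ListLit(tuple(items))
        raise ParseError("unexpected token", tok.pos, tok.text or "<end>")

    def done(self) -> bool:
        return self.peek().kind == "end"


def parse_expression(text: str) -> Node:
    """Parse a bare right-hand-side expression (no ``=``)."""
    parser = _Parser(tokenize(text))
    node = parser.expression()
    if not parser.done():
        tok = parser.peek()
        raise ParseError("trailing input after expression", tok.pos, tok.text)
    return node


def _parse_lhs(tokens: List[Token], text: str) -> Tuple[str, bool]:
    """Interpret the token sequence left of ``=`` as an assignment target."""
    toks = [t for t in tokens if t.kind != "end"]
    # plain identifier
    if len(toks) == 1 and toks[0].kind == "ident":
        return toks[0].text, False
    # x'
    if len(toks) == 2 and toks[0].kind == "ident" and toks[1].text == "'":
        return toks[0].text, True
    # x'' and beyond
    if len(toks) >= 3 and toks[0].kind == "ident" and all(t.text == "'" for t in toks[1:]):
        raise ParseError(
            "higher-order derivatives are not supported; rewrite the equation "
            "as a set of coupled first-order differential equations",
            toks[1].pos, "'")
    # d/dt * x
    if (len(toks) == 5 and [t.text for t in toks[:4]] == ["d", "/", "dt", "*"]
            and toks[4].kind == "ident"):
        return toks[4].text, True
    # d2/dt2 * x or similar
    if (toks and toks[0].kind == "ident" and toks[0].text.startswith("d")
            and any(t.kind == "ident" and t.text.startswith("dt") for t in toks)):
        raise ParseError(
            "only first-order derivatives (d/dt * x) may appear on the "
            "left-hand side; rewrite higher orders as coupled first-order equations",
            toks[0].pos, toks[0].text)
    pos = toks[0].pos if toks else 0
    raise ParseError(
        "left-hand side must be a single variable or its first derivative",
        pos, text.split("=")[0].strip())


def parse_equation(text: str) -> EquationAST:
    """Parse ``"lhs = rhs"`` into an :class:`EquationAST`.

    The left-hand side must be a single identifier, ``x'`` or ``d/dt * x``;
    the two derivative spellings parse identically.
    """
    tokens = tokenize(text)
    eq_positions = [idx for idx, t in enumerate(tokens)
                    if t.kind == "sym" and t.text == "="]
    if len(eq_positions) == 0:
        raise ParseError("equation must contain '='", len(text))
    if len(eq_positions) > 1:
        bad = tokens[eq_positions[1]]
        raise ParseError("equation must contain exactly one '='", bad.pos, "=")
    split = eq_positions[0]
    lhs_var, is_deriv = _parse_lhs(tokens[:split], text)
    rhs_tokens = tokens[split + 1:]
    if rhs_tokens[0].kind == "end":
        raise ParseError("empty right-hand side", tokens[split].pos, "=")
    parser = _Parser(rhs_tokens)
    rhs = parser.expression()
    if not parser.done():
        tok = parser.peek()
        raise ParseError("trailing input after expression", tok.pos, tok.text)
    return EquationAST(lhs_var, is_deriv, rhs)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

_BINOPS: Dict[str, Callable] = {
    "+": lambda a, b: a + b,
    "-": lambda a, b: a - b,
    "*": lambda a, b: a * b,
    "/": lambda a, b: a / b,
    "**": lambda a, b: a ** b,
}

_CMPOPS: Dict[str, Callable] = {
    ">": lambda a, b: a > b,
    "<": lambda a, b: a < b,
    ">=": lambda a, b: a >= b,
    "<=": lambda a, b: a <= b,
    "==": lambda a, b: a == b,
    "!=": lambda a, b: a != b,
}


def _index_item_value(item: Union[Node, SliceSpec], bindings) :
    if isinstance(item, SliceSpec):
        def val(node):
            if node is None:
                return None
            v = evaluate(node, bindings)
            return int(np.asarray(v).item())
        return slice(val(item.start), val(item.stop), val(item.step))
    value = evaluate(item, bindings)
    if isinstance(value, np.ndarray) and value.dtype == bool:
        return value
    if isinstance(value, np.ndarray):
        return value.astype(int)
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    return int(np.asarray(value).item())


def evaluate(node: Union[Node, EquationAST], bindings: Mapping[str, object]):
    """Evaluate an expression tree (or an equation's rhs) against bindings.

    Array values broadcast elementwise per NumPy rules; comparisons yield
    boolean masks; ``float(...)`` converts masks to 0.0/1.0.  Unbound
    identifiers raise :class:`EvaluationError`.
    """
    if isinstance(node, EquationAST):
        return evaluate(node.rhs, bindings)
    if isinstance(node, Num):
        return node.value
    if isinstance(node, Var):
        if node.name in bindings:
            return bindings[node.name]
        if node.name in CONSTANTS:
            return CONSTANTS[node.name]
        raise EvaluationError(f"unbound identifier {node.name!r}")
    if isinstance(node, UnaryOp):
        return -evaluate(node.operand, bindings)
    if isinstance(node, BinOp):
        left = evaluate(node.left, bindings)
        right = evaluate(node.right, bindings)
        try:
            with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
                return _BINOPS[node.op](left, right)
        except ZeroDivisionError:
            # scalar python division by zero follows IEEE convention
            left = np.float64(left)
            with np.errstate(divide="ignore", invalid="ignore"):
                return _BINOPS[node.op](left, right)
    if isinstance(node, Compare):
        return _CMPOPS[node.op](evaluate(node.left, bindings),
                                evaluate(node.right, bindings))
    if isinstance(node, Call):
        fn = FUNCTIONS[node.name][0]
        return fn(*[evaluate(a, bindings) for a in node.args])
    if isinstance(node, ListLit):
        return np.asarray([evaluate(item, bindings) for item in node.items])
    if isinstance(node, Index):
        base = np.asarray(evaluate(node.base, bindings))
        spec = tuple(_index_item_value(item, bindings) for item in node.spec)
        if len(spec) == 1:
            spec_val = spec[0]
            if isinstance(spec_val, np.ndarray) and spec_val.dtype == bool \
                    and spec_val.shape != base.shape:
                raise EvaluationError(
                    f"boolean mask shape {spec_val.shape} does not match "
                    f"array shape {base.shape}")
            try:
                return base[spec_val]
            except IndexError as err:
                raise EvaluationError(str(err)) from err
        try:
            return base[spec]
        except IndexError as err:
            raise EvaluationError(str(err)) from err
    raise TypeError(f"cannot evaluate node {node!r}")


def free_variables(node: Union[Node, EquationAST]) -> set:
    """All identifiers referenced in an expression (excluding functions and
    predefined constants)."""
    if isinstance(node, EquationAST):
        return free_variables(node.rhs)
    out: set = set()

    def walk(n):
        if isinstance(n, Var):
            if n.name not in CONSTANTS:
                out.add(n.name)
        elif isinstance(n, UnaryOp):
            walk(n.operand)
        elif isinstance(n, (BinOp, Compare)):
            walk(n.left)
            walk(n.right)
        elif isinstance(n, Call):
            for a in n.args:
                walk(a)
        elif isinstance(n, ListLit):
            for item in n.items:
                walk(item)
        elif isinstance(n, Index):
            walk(n.base)
            for item in n.spec:
                if isinstance(item, SliceSpec):
                    for part in (item.start, item.stop, item.step):
                        if part is not None:
                            walk(part)
                else:
                    walk(item)

    walk(node)
    return out


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

_PREC = {"cmp": 1, "+": 2, "-": 2, "*": 3, "/": 3, "u-": 4, "**": 5, "atom": 6}


def _prec(node: Node) -> int:
    if isinstance(node, Compare):
        return _PREC["cmp"]
    if isinstance(node, BinOp):
        return _PREC[node.op]
    if isinstance(node, UnaryOp):
        return _PREC["u-"]
    return _PREC["atom"]


def render(node: Union[Node, EquationAST]) -> str:
    """Render an expression tree back to equation syntax.

    ``parse_expression(render(t))`` reproduces ``t`` for any tree this module
    can produce.
    """
    if isinstance(node, EquationAST):
        return render_equation(node)

    def wrap(child: Node, parent_prec: int, right_side: bool = False) -> str:
        text = render(child)
        child_prec = _prec(child)
        if child_prec < parent_prec or (child_prec == parent_prec and right_side):
            return f"({text})"
        return text

    if isinstance(node, Num):
        value = node.value
        if value == int(value) and abs(value) < 1e16:
            return repr(value)
        return repr(value)
    if isinstance(node, Var):
        return node.name
    if isinstance(node, UnaryOp):
        return "-" + wrap(node.operand, _PREC["u-"] + 1)
    if isinstance(node, BinOp):
        p = _PREC[node.op]
        if node.op == "**":
            # right-associative
            left = wrap(node.left, p + 1)
            right = wrap(node.right, p)
            return f"{left}**{right}"
        left = wrap(node.left, p)
        right = wrap(node.right, p, right_side=True)
        return f"{left} {node.op} {right}"
    if isinstance(node, Compare):
        return f"{wrap(node.left, _PREC['cmp'] + 1)} {node.op} {wrap(node.right, _PREC['cmp'] + 1)}"
    if isinstance(node, Call):
        return f"{node.name}({', '.join(render(a) for a in node.args)})"
    if isinstance(node, ListLit):
        return "[" + ", ".join(render(item) for item in node.items) + "]"
    if isinstance(node, Index):
        def item_text(item):
            if isinstance(item, SliceSpec):
                parts = [render(p) if p is not None else "" for p in (item.start, item.stop)]
                text = ":".join(parts)
                if item.step is not None:
                    text += ":" + render(item.step)
                return text
            return render(item)
        base = render(node.base)
        if _prec(node.base) < _PREC["atom"]:
            base = f"({base})"
        return base + "[" + ", ".join(item_text(i) for i in node.spec) + "]"
    raise TypeError(f"cannot render {node!r}")


def render_equation(eq: EquationAST) -> str:
    lhs = f"d/dt * {eq.lhs_variable}" if eq.lhs_is_derivative else eq.lhs_variable
    return f"{lhs} = {render(eq.rhs)}"


# ---------------------------------------------------------------------------
# token-level substitution (used by template `replace`)
# ---------------------------------------------------------------------------

def _replace_tokens(equation_text: str,
                    mapping: Mapping[str, str]) -> Tuple[str, set]:
    tokens = tokenize(equation_text)
    used: set = set()
    parts: List[str] = []
    prev_alnum = False
    for tok in tokens:
        if tok.kind == "end":
            break
        text = tok.text
        if tok.kind == "ident" and text in mapping:
            used.add(text)
            text = mapping[tok.text]
        alnum = bool(text) and (text[0].isalnum() or text[0] == "_")
        if parts and prev_alnum and alnum:
            parts.append(" ")
        parts.append(text)
        prev_alnum = bool(text) and (text[-1].isalnum() or text[-1] == "_" or text[-1] == ")")
    new_text = "".join(parts)
    parse_equation(new_text)  # validate; raises ParseError on damage
    return new_text, used


def replace_identifiers(equation_text: str, mapping: Mapping[str, str],
                        require_match: bool = True) -> str:
    """Whole-token identifier substitution in an equation string.

    Keys must match complete identifier tokens; ``V`` never matches inside
    ``V_t``.  With ``require_match`` (default), raises :class:`ParseError`
    if a key matches no token; always raises if the substituted equation no
    longer parses.
    """
    new_text, used = _replace_tokens(equation_text, mapping)
    if require_match:
        for key in mapping:
            if key not in used:
                raise ParseError(f"replacement key {key!r} matches no "
                                 f"identifier in {equation_text!r}")
    return new_text


def replace_in_equation_set(equations: Sequence[str],
                            mapping: Mapping[str, str]) -> Tuple[str, ...]:
    """Apply :func:`replace_identifiers` across a set of equations.

    Every key must match a token in at least one equation of the set.
    """
    results: List[str] = []
    used: set = set()
    for eq in equations:
        new_text, hits = _replace_tokens(eq, mapping)
        results.append(new_text)
        used |= hits
    for key in mapping:
        if key not in used:
            raise ParseError(f"replacement key {key!r} matches no identifier "
                             f"in the equation set")
    return tuple(results)


# ---------------------------------------------------------------------------
# python source generation (used by the compute engine)
# ---------------------------------------------------------------------------

_FUNC_SOURCE = {
    "exp": "np.exp", "sin": "np.sin", "cos": "np.cos", "tan": "np.tan",
    "tanh": "np.tanh", "sinh": "np.sinh", "cosh": "np.cosh",
    "sqrt": "np.sqrt", "log": "np.log", "abs": "np.abs",
}


def to_python_source(node: Node, name_of: Callable[[str], str]) -> str:
    """Render an expression tree to a NumPy-flavoured python source fragment.

    ``name_of`` maps every model identifier to the code name that holds its
    value.  Used by the engine to generate the compiled step function; the
    produced source restricts itself to constructs the JIT path supports
    (elementwise arithmetic and calls, no fancy indexing).
    """
    def go(n: Node) -> str:
        if isinstance(n, Num):
            return repr(n.value)
        if isinstance(n, Var):
            if n.name in CONSTANTS:
                return repr(CONSTANTS[n.name])
            return name_of(n.name)
        if isinstance(n, UnaryOp):
            return f"(-{go(n.operand)})"
        if isinstance(n, BinOp):
            return f"({go(n.left)} {n.op} {go(n.right)})"
        if isinstance(n, Compare):
            return f"({go(n.left)} {n.op} {go(n.right)})"
        if isinstance(n, Call):
            if n.name == "sigmoid":
                x = go(n.args[0])
                return f"(1.0 / (1.0 + np.exp(-({x}))))"
            if n.name == "float":
                return f"(({go(n.args[0])}) * 1.0)"
            if n.name == "sum":
                if len(n.args) == 1:
                    return f"np.sum({go(n.args[0])})"
                return f"np.sum({go(n.args[0])}, axis=int({go(n.args[1])}))"
            if n.name == "max":
                if len(n.args) == 1:
                    return f"np.max({go(n.args[0])})"
                return f"np.maximum({go(n.args[0])}, {go(n.args[1])})"
            if n.name == "min":
                if len(n.args) == 1:
                    return f"np.min({go(n.args[0])})"
                return f"np.minimum({go(n.args[0])}, {go(n.args[1])})"
            if n.name in _FUNC_SOURCE:
                return f"{_FUNC_SOURCE[n.name]}({go(n.args[0])})"
            raise ValueError(f"function {n.name!r} is not supported in "
                             "compiled equations")
        raise ValueError(f"construct {type(n).__name__} is not supported in "
                         "compiled equations (scalar per-instance variables only)")
    return go(node)
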