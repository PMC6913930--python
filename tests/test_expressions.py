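"""Equation parser and evaluator: grammar, precedence, indexing, rendering."""

import math
import random

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ratesim import expressions as ex


# ---------------------------------------------------------------------------
# parsing basics
# ---------------------------------------------------------------------------

def test_basic_equation_parses_and_evaluates():
    ast = ex.parse_equation("a = 5 * (b + c) / d**2")
    assert ast.lhs_variable == "a" and not ast.lhs_is_derivative
    assert ex.evaluate(ast, {"b": 2, "c": 3, "d": 2}) == pytest.approx(6.25)


def test_caret_is_power_synonym():
    assert ex.parse_equation("a = 5 * (b + c) / d^2") == \
        ex.parse_equation("a = 5 * (b + c) / d**2")


def test_prime_is_derivative_shorthand():
    assert ex.parse_equation("a' = a + d") == \
        ex.parse_equation("d/dt * a = a + d")
    assert ex.parse_equation("d/dt * a = a + d").lhs_is_derivative


@pytest.mark.parametrize("bad, fragment", [
    ("a + b = c", "left-hand side"),
    ("a'' = b", "first-order"),
    ("d2/dt2 * a = b", "first-order"),
    ("a = b = c", "exactly one"),
    ("a = b +", "unexpected token"),
    ("a = foo(b)", "unknown function"),
    ("3 = b", "left-hand side"),
])
def test_parse_errors(bad, fragment):
    with pytest.raises(ex.ParseError, match=fragment):
        ex.parse_equation(bad)


def test_parse_error_carries_position():
    with pytest.raises(ex.ParseError) as err:
        ex.parse_equation("a = b $ c")
    assert err.value.position == 6


def test_free_variables_cover_rhs():
    ast = ex.parse_equation("x = h/tau * r_in - (1./tau)^2 * V")
    assert ex.free_variables(ast) == {"h", "tau", "r_in", "V"}
    # predefined constants are not free
    assert ex.free_variables(ex.parse_expression("PI * r")) == {"r"}


# ---------------------------------------------------------------------------
# evaluation semantics
# ---------------------------------------------------------------------------

def test_sigmoid_matches_closed_form():
    xs = np.linspace(-20, 20, 101)
    got = ex.evaluate(ex.parse_expression("sigmoid(x)"), {"x": xs})
    np.testing.assert_array_equal(got, 1.0 / (1.0 + np.exp(-xs)))


def test_sigmoid_midpoint_is_half_rmax():
    expr = ex.parse_expression("r_max/(1+exp(s*(V_thr - V)))")
    val = ex.evaluate(expr, {"r_max": 5.0, "s": 560.0, "V_thr": 6e-3,
                             "V": 6e-3})
    assert val == pytest.approx(2.5)


def test_float_of_comparison_is_binary():
    expr = ex.parse_expression("float(V > V_thr)")
    assert ex.evaluate(expr, {"V": 2.0, "V_thr": 1.0}) == 1.0
    assert ex.evaluate(expr, {"V": 0.5, "V_thr": 1.0}) == 0.0
    arr = ex.evaluate(expr, {"V": np.array([0.0, 2.0]), "V_thr": 1.0})
    np.testing.assert_array_equal(arr, [0.0, 1.0])
    # bare comparisons stay boolean (usable as masks)
    mask = ex.evaluate(ex.parse_expression("V > V_thr"),
                       {"V": np.array([0.0, 2.0]), "V_thr": 1.0})
    assert mask.dtype == bool


def test_unbound_identifier_raises():
    with pytest.raises(ex.EvaluationError, match="unbound"):
        ex.evaluate(ex.parse_expression("a + b"), {"a": 1.0})


def test_division_by_zero_propagates_nonfinite():
    val = ex.evaluate(ex.parse_expression("a / b"), {"a": 1.0, "b": 0.0})
    assert np.isinf(val)


@pytest.mark.parametrize("text, bindings, expected", [
    ("a[a > 5]", {"a": np.array([1, 7, 3, 9.])}, [7.0, 9.0]),
    ("a[1:3]", {"a": np.array([1, 7, 3, 9.])}, [7.0, 3.0]),
    ("a[3]", {"a": np.array([1, 7, 3, 9.])}, 9.0),
    ("A[0:1, 1:2]", {"A": np.array([[1, 2], [3, 4.]])}, [[2.0]]),
    ("a[[3], [0]]", {"a": np.eye(4)}, [0.0]),
    ("sum(A, 0)", {"A": np.array([[1, 2], [3, 4.]])}, [4.0, 6.0]),
    ("sum(a)", {"a": np.array([1, 2, 3.])}, 6.0),
])
def test_indexing_and_reductions(text, bindings, expected):
    np.testing.assert_allclose(
        ex.evaluate(ex.parse_expression(text), bindings), expected)


def test_index_errors():
    a = np.array([1.0, 2.0])
    with pytest.raises(ex.EvaluationError):
        ex.evaluate(ex.parse_expression("a[5]"), {"a": a})
    with pytest.raises(ex.EvaluationError, match="mask"):
        ex.evaluate(ex.parse_expression("a[b > 0]"),
                    {"a": a, "b": np.ones(3)})


def test_evaluation_is_pure():
    expr = ex.parse_expression("exp(a) * sin(b) - a**3 / b")
    bindings = {"a": 0.731, "b": 1.618}
    first = ex.evaluate(expr, bindings)
    assert all(ex.evaluate(expr, bindings) == first for _ in range(5))


# ---------------------------------------------------------------------------
# precedence oracle: random expressions vs the host language's own parser
# ---------------------------------------------------------------------------

def _random_expression(rng, depth=0):
    """Random well-formed expression text; sub-trees shrink with depth."""
    choices = ["num", "var", "bin", "neg", "paren", "call"]
    if depth > 4:
        choices = ["num", "var"]
    kind = rng.choice(choices)
    if kind == "num":
        return f"{rng.uniform(0.1, 9.9):.3f}"
    if kind == "var":
        return rng.choice(["a", "b", "c"])
    if kind == "neg":
        return "-" + _random_expression(rng, depth + 1)
    if kind == "paren":
        return "(" + _random_expression(rng, depth + 1) + ")"
    if kind == "call":
        fn = rng.choice(["sin", "cos", "tanh", "exp", "abs"])
        return f"{fn}({_random_expression(rng, depth + 1)})"
    op = rng.choice(["+", "-", "*", "/", "**"])
    left = _random_expression(rng, depth + 1)
    if op == "**":
        # small integer exponents keep the value real and bounded
        return f"{left} ** {rng.choice([2, 3])}"
    right = _random_expression(rng, depth + 1)
    return f"{left} {op} {right}"


def test_parser_agrees_with_python_on_1000_random_expressions():
    """Precedence/associativity oracle: CPython's own parser evaluates the
    identical text; results must agree to floating-point accuracy."""
    rng = random.Random(20240901)
    namespace = {"sin": math.sin, "cos": math.cos, "tanh": math.tanh,
                 "exp": math.exp, "abs": abs,
                 "a": 1.37, "b": 0.62, "c": 2.41}
    checked = 0
    while checked < 1000:
        text = _random_expression(rng)
        try:
            expected = eval(text, {"__builtins__": {}}, dict(namespace))
        except OverflowError:
            continue
        if not np.isfinite(expected) or abs(expected) > 1e12:
            continue
        got = ex.evaluate(ex.parse_expression(text), namespace)
        assert got == pytest.approx(expected, rel=1e-12), text
        checked += 1


def test_render_parse_round_trip_on_random_expressions():
    rng = random.Random(77)
    for _ in range(300):
        text = _random_expression(rng)
        tree = ex.parse_expression(text)
        assert ex.parse_expression(ex.render(tree)) == tree, text


@given(st.sampled_from(["a = b + c", "x' = -x + u", "d/dt * V = V_t",
                        "r = r_max * sigmoid(s*(V - V_thr))",
                        "y = a^2 - b**2 / (c + 1.5)",
                        "z = float(a > b) * c"]))
def test_equation_round_trip(text):
    eq = ex.parse_equation(text)
    assert ex.parse_equation(ex.render_equation(eq)) == eq


def test_unary_minus_binds_looser_than_power():
    # -a**b parses as -(a**b)
    assert ex.evaluate(ex.parse_expression("-a**2"), {"a": 3.0}) == -9.0
    assert ex.evaluate(ex.parse_expression("(-a)**2"), {"a": 3.0}) == 9.0
    # power is right-associative
    assert ex.evaluate(ex.parse_expression("2**3**2"), {}) == 512.0


# ---------------------------------------------------------------------------
# token-level replacement
# ---------------------------------------------------------------------------

def test_replace_is_whole_token():
    eq = "d/dt * V_t = h/tau * r_in - (1./tau)^2 * V - 2.*1./tau*V_t"
    out = ex.replace_identifiers(eq, {"V": "VV"})
    # V_t untouched although it contains the key as a substring
    tokens = [t.text for t in ex.tokenize(out) if t.kind == "ident"]
    assert "VV" in tokens and "V_t" in tokens and "V" not in tokens


def test_replace_matches_the_documented_example():
    eq = "d/dt * V_t = h/tau * r_in - (1./tau)^2 * V - 2.*1./tau*V_t"
    out = ex.replace_identifiers(eq, {"r_in": "(r_in + u)"})
    assert ex.parse_equation(out) == ex.parse_equation(
        "d/dt*V_t = h/tau*(r_in+u) - (1./tau)^2*V - 2.*1./tau*V_t")


def test_replace_identity_and_missing_key():
    eq = "a = b + c"
    assert ex.parse_equation(ex.replace_identifiers(eq, {"b": "b"})) == \
        ex.parse_equation(eq)
    with pytest.raises(ex.ParseError, match="matches no"):
        ex.replace_identifiers(eq, {"zz": "y"})
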