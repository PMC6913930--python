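"""Compute engine: solvers, delays, vectorization, error handling."""

import math

import numpy as np
import pytest
from scipy import optimize

from ratesim import engine
from ratesim.engine import EngineError, SimulationConfig, compile, solver_step
from ratesim.model_library import (JRC_DRIVE_PATH, JRC_OUTPUT_PATH,
                                   MONTBRIO_INPUT_PATH, build_montbrio,
                                   random_drive)
from ratesim.templates import CircuitTemplate

from conftest import montbrio_rhs_oracle


# ---------------------------------------------------------------------------
# solver primitives
# ---------------------------------------------------------------------------

def test_one_step_values():
    f = lambda y: -y
    assert solver_step("euler", np.array([1.0]), f, 0.1)[0] == \
        pytest.approx(0.9)
    assert solver_step("midpoint", np.array([1.0]), f, 0.1)[0] == \
        pytest.approx(0.905)
    # fixed-step third-order Bogacki-Shampine advance, by hand:
    # k1=-1, k2=-0.95, k3=-0.928750 -> 1 + 0.1*(2k1+3k2+4k3)/9
    expected = 1.0 + 0.1 * (2 * -1.0 + 3 * -0.95 + 4 * -0.92875) / 9.0
    assert solver_step("rk23", np.array([1.0]), f, 0.1)[0] == \
        pytest.approx(expected, abs=1e-15)


@pytest.mark.parametrize("solver, order", [
    ("euler", 1.0), ("midpoint", 2.0), ("rk23", 3.0)])
def test_global_error_order(solver, order):
    """Log-log slope of the global error on dy/dt = -y at t=1."""
    f = lambda y: -y
    dts = 1.0 / np.round(np.logspace(2, 4, 5)).astype(int)
    errors = []
    for dt in dts:
        y = np.array([1.0])
        for _ in range(int(round(1.0 / dt))):
            y = solver_step(solver, y, f, dt)
        errors.append(abs(y[0] - math.exp(-1.0)))
    slope = np.polyfit(np.log(dts), np.log(errors), 1)[0]
    assert abs(slope - order) < 0.3


def test_unknown_solver_rejected(montbrio_template):
    with pytest.raises(ValueError):
        solver_step("rk45", np.array([1.0]), lambda y: -y, 0.1)
    with pytest.raises(EngineError):
        compile(montbrio_template, solver="rk45")
    with pytest.raises(ValueError):
        SimulationConfig(solver="rk45")


def test_simulation_config_invariants():
    with pytest.raises(ValueError):
        SimulationConfig(dt=-1e-4)
    with pytest.raises(ValueError):
        SimulationConfig(dt=1e-3, sampling_step_size=1e-4)
    with pytest.raises(ValueError):
        SimulationConfig(dt=1e-4, sampling_step_size=2.0, simulation_time=1.0)


# ---------------------------------------------------------------------------
# step and sample accounting
# ---------------------------------------------------------------------------

def test_step_counter_and_row_counts(montbrio_template):
    net = compile(montbrio_template, dt=1e-3)
    result = net.run(10.0, outputs={"r": "Pop1/MontbrioOperator/r"},
                     sampling_step_size=0.01)
    assert net.step_count == 10_000
    assert result.df.shape[0] == 1000            # floor(T / sampling)
    assert np.all(np.diff(result.time) > 0)
    assert result.time[0] == pytest.approx(0.01)  # t=0 not sampled


def test_input_length_mismatch_raises(montbrio_template):
    net = compile(montbrio_template, dt=1e-3)
    with pytest.raises(EngineError, match="per integration step"):
        net.run(1.0, inputs={MONTBRIO_INPUT_PATH: np.zeros(5)})


def test_unresolvable_output_path_raises(montbrio_template):
    net = compile(montbrio_template, dt=1e-3)
    with pytest.raises(EngineError, match="matches nothing"):
        net.run(0.1, outputs={"x": "Nope/MontbrioOperator/r"})


def test_nonfinite_state_aborts_with_step_and_path(montbrio_template):
    net = compile(montbrio_template, dt=1e-3)
    blow_up = np.full(5000, 1e12)
    with pytest.raises(EngineError, match="non-finite") as err:
        net.run(5.0, inputs={MONTBRIO_INPUT_PATH: blow_up})
    assert "step" in str(err.value)
    assert "Pop1/MontbrioOperator" in str(err.value)


# ---------------------------------------------------------------------------
# vectorization
# ---------------------------------------------------------------------------

def test_jrc_grouping(jrc_template):
    net = compile(jrc_template, vectorization=True)
    assert net.group_members() == [["EIN", "IIN"], ["PC"]]
    solo = compile(jrc_template, vectorization=False)
    assert solo.group_members() == [["EIN"], ["IIN"], ["PC"]]


def test_identical_populations_group_into_one_vector_node():
    from ratesim.model_library import load_model
    pop = load_model("MontbrioPopulation")
    circuit = CircuitTemplate("Many", nodes={f"P{i}": pop for i in range(5)},
                              circuits={}, edges=[])
    net = compile(circuit, dt=1e-3, vectorization=True)
    assert net.group_members() == [[f"P{i}" for i in range(5)]]
    assert net.state_dimension == 10              # (r, V) x 5 instances
    solo = compile(circuit, dt=1e-3, vectorization=False)
    assert len(solo.group_members()) == 5


@pytest.mark.parametrize("fixture_name", ["jrc", "double", "montbrio"])
def test_vectorized_equals_nonvectorized(fixture_name, jrc_template,
                                         double_jrc_template,
                                         montbrio_template):
    template = {"jrc": jrc_template, "double": double_jrc_template,
                "montbrio": montbrio_template}[fixture_name]
    T, dt = 0.5, 1e-4
    if fixture_name == "montbrio":
        dt = 1e-3
        inputs = {MONTBRIO_INPUT_PATH: np.full(int(T / dt), 3.0)}
        outputs = {"r": "Pop1/MontbrioOperator/r"}
    else:
        inputs = {JRC_DRIVE_PATH: random_drive(T, dt, seed=11)}
        outputs = {"V": JRC_OUTPUT_PATH}
    results = {}
    for vec in (True, False):
        net = compile(template, dt=dt, vectorization=vec)
        results[vec] = net.run(T, inputs=inputs, outputs=outputs,
                               sampling_step_size=dt).df.to_numpy()
    denom = np.maximum(np.abs(results[True]), 1e-30)
    assert np.max(np.abs(results[True] - results[False]) / denom) <= 1e-10


# ---------------------------------------------------------------------------
# delays
# ---------------------------------------------------------------------------

def test_delay_ring_buffer_length(chain_collection):
    net = compile(chain_collection.resolve("ChainDelayed"), dt=1e-4)
    delayed = [b for b in net.bundles if b.delay_steps > 0]
    assert len(delayed) == 1 and delayed[0].delay_steps == 100


def test_delayed_output_is_shifted_undelayed_output(chain_collection):
    """A delay of d seconds delivers the source value from round(d/dt)
    steps back instead of from the previous step, so the delayed trace
    lags the undelayed one by round(d/dt) - 1 samples."""
    dt, T = 1e-4, 0.05
    sig = np.sin(np.linspace(0.0, 20.0, int(T / dt)))
    out = {}
    for name in ("Chain", "ChainDelayed"):
        net = compile(chain_collection.resolve(name), dt=dt)
        res = net.run(T, inputs={"A/L/inp": sig}, outputs={"b": "B/L/out"},
                      sampling_step_size=dt)
        out[name] = res.series("b")
    shift = 100 - 1
    np.testing.assert_allclose(out["ChainDelayed"][shift:],
                               out["Chain"][:-shift])


def test_delay_shorter_than_dt_promoted_with_warning(chain_collection):
    tpl = chain_collection.resolve("ChainDelayed")
    circuit = tpl.apply()
    circuit.edges[0].delay = 1e-5                # < dt
    with pytest.warns(UserWarning, match="promoted"):
        net = compile(circuit, dt=1e-4)
    assert [b.delay_steps for b in net.bundles if b.delay_steps] == [1]


def test_zero_delay_means_next_step(chain_collection):
    tpl = chain_collection.resolve("ChainDelayed")
    circuit = tpl.apply()
    circuit.edges[0].delay = 0.0
    net = compile(circuit, dt=1e-4)
    assert all(b.delay_steps == 0 for b in net.bundles)


# ---------------------------------------------------------------------------
# dynamics sanity
# ---------------------------------------------------------------------------

def test_montbrio_terminal_state_is_equation_root(montbrio_template):
    """With constant input the trajectory settles onto a root of the
    mean-field equations, verified by an independent root finder."""
    net = compile(montbrio_template, dt=1e-3)
    I = 2.0
    steps = int(60.0 / 1e-3)
    net.run(60.0, inputs={MONTBRIO_INPUT_PATH: np.full(steps, I)},
            outputs={"r": "Pop1/MontbrioOperator/r"},
            initial_values={"Pop1/MontbrioOperator/r": 0.5,
                            "Pop1/MontbrioOperator/V": -1.0})
    terminal = np.array([net.state_value("Pop1/MontbrioOperator/r"),
                         net.state_value("Pop1/MontbrioOperator/V")])
    oracle = montbrio_rhs_oracle()
    root = optimize.fsolve(lambda y: oracle(y, I), terminal, xtol=1e-13)
    assert np.max(np.abs(oracle(root, I))) < 1e-6
    assert np.max(np.abs(terminal - root)) < 1e-6


def test_zero_input_jrc_settles_to_resting_state(jrc_template):
    """Without drive the column relaxes to a fixed point and stays there."""
    net = compile(jrc_template, dt=1e-4)
    net.run(10.0, outputs={"V": JRC_OUTPUT_PATH}, sampling_step_size=1e-3)
    state_paths = [f"{n}/{op}/{v}" for n in ("PC", "EIN", "IIN")
                   for op, v in (("RPO_e", "V"), ("RPO_e", "V_t"))]
    state_paths += ["PC/RPO_i/V", "PC/RPO_i/V_t"]
    settled = {p: net.state_value(p) for p in state_paths}
    net2 = compile(jrc_template, dt=1e-4)
    net2.run(1.0, outputs={"V": JRC_OUTPUT_PATH},
             initial_values=settled, sampling_step_size=1e-3)
    drift = max(abs(net2.state_value(p) - settled[p]) for p in state_paths)
    assert drift < 1e-9


def test_halving_dt_moves_alpha_peak_less_than_half_hertz(jrc_template):
    from ratesim import analysis
    peaks = {}
    T = 20.0
    for dt in (1e-4, 5e-5):
        drive = random_drive(T, dt, seed=7)
        net = compile(jrc_template, dt=dt)
        res = net.run(T, inputs={JRC_DRIVE_PATH: drive},
                      outputs={"V": JRC_OUTPUT_PATH},
                      sampling_step_size=1e-3)
        x = analysis.trim_transient(res.series("V"), res.time)
        freqs, power = analysis.power_spectrum(x, 1000.0)
        peaks[dt] = analysis.dominant_frequency(freqs, power)
    assert abs(peaks[1e-4] - peaks[5e-5]) < 0.5


# ---------------------------------------------------------------------------
# edge operators
# ---------------------------------------------------------------------------

def test_edge_operator_chain_scales_and_lags_one_step(chain_collection):
    from ratesim.templates import TemplateCollection
    doc = {
        "Lin": {"base": "OperatorTemplate", "equations": ["out = inp"],
                "variables": {"inp": {"default": "input"},
                              "out": {"default": "output"}}},
        "Gain": {"base": "OperatorTemplate",
                 "equations": ["out = 2. * inp"],
                 "variables": {"inp": {"default": "input"},
                               "out": {"default": "output"}}},
        "N": {"base": "NodeTemplate", "operators": {"L": "Lin"}},
        "E": {"base": "EdgeTemplate", "operators": {"G": "Gain"}},
        "WithOp": {"base": "CircuitTemplate",
                   "nodes": {"A": "N", "B": "N"},
                   "edges": [["A/L/out", "B/L/inp", "E", {"weight": 3.0}]]},
    }
    coll = TemplateCollection(doc)
    dt, T = 1e-3, 0.05
    sig = np.linspace(0.0, 1.0, int(T / dt))
    net = compile(coll.resolve("WithOp"), dt=dt)
    res = net.run(T, inputs={"A/L/inp": sig}, outputs={"b": "B/L/out"},
                  sampling_step_size=dt)
    plain = compile(chain_collection.resolve("Chain"), dt=dt)
    ref = plain.run(T, inputs={"A/L/inp": sig}, outputs={"b": "B/L/out"},
                    sampling_step_size=dt).series("b")
    got = res.series("b")
    # edge operators add one step of transfer latency; output scaled 2*3
    np.testing.assert_allclose(got[1:], 6.0 * ref[:-1], atol=1e-12)
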