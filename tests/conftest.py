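import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, max_examples=60,
                          deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def jrc_template():
    from ratesim.model_library import build_jansen_rit
    return build_jansen_rit()


@pytest.fixture(scope="session")
def double_jrc_template():
    from ratesim.model_library import load_model
    return load_model("DoubleJRCircuit")


@pytest.fixture(scope="session")
def montbrio_template():
    from ratesim.model_library import build_montbrio
    return build_montbrio()


@pytest.fixture()
def chain_collection():
    """Two pass-through nodes, with and without a delayed edge."""
    from ratesim.templates import TemplateCollection
    doc = {
        "Lin": {"base": "OperatorTemplate", "equations": ["out = inp"],
                "variables": {"inp": {"default": "input"},
                              "out": {"default": "output"}}},
        "N": {"base": "NodeTemplate", "operators": {"L": "Lin"}},
        "Chain": {"base": "CircuitTemplate",
                  "nodes": {"A": "N", "B": "N"},
                  "edges": [["A/L/out", "B/L/inp", None, {"weight": 1.0}]]},
        "ChainDelayed": {"base": "CircuitTemplate",
                         "nodes": {"A": "N", "B": "N"},
                         "edges": [["A/L/out", "B/L/inp", None,
                                    {"weight": 1.0, "delay": 0.01}]]},
    }
    return TemplateCollection(doc)


def montbrio_rhs_oracle(delta=1.0, eta=-5.0, J=15.0, tau=1.0):
    """Hand-written mean-field right-hand side, independent of the package's
    equation parser and engine."""
    def rhs(y, I=0.0):
        r, V = float(y[0]), float(y[1])
        dr = delta / (np.pi * tau ** 2) + 2.0 * r * V / tau
        dV = (V ** 2 + eta + I) / tau + J * r - tau * (np.pi * r) ** 2
        return np.array([dr, dV])
    return rhs
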