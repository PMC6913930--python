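"""Validated model templates and input generators.

Ships the Jansen-Rit cortical column and the Montbrió QIF mean-field model
as YAML templates (``ratesim/models/``), plus helpers to rescale their
parameters and to generate the extrinsic inputs used in validation:
uniform random firing-rate drive and constant/sinusoidal forcing windows.

Jansen-Rit weight convention: the four internal edges scale linearly with a
single connectivity constant C as

====================  =======  ==============
edge                  ratio    value at C=135
====================  =======  ==============
PC -> EIN (c_ee)      1.00 C   135
EIN -> PC (c_ep)      0.80 C   108
PC -> IIN (c_ie)      0.25 C   33.75
IIN -> PC (c_ip)      0.25 C   33.75
====================  =======  ==============

The ratios are fixed by the classic parametrization; ``build_jansen_rit``
reproduces the shipped template exactly at C=135.
"""

from __future__ import annotations

import copy
import os
from typing import Dict, Optional, Tuple

import numpy as np

from .templates import CircuitTemplate, TemplateCollection

__all__ = [
    "MODEL_DIR",
    "model_collection",
    "load_model",
    "build_jansen_rit",
    "build_montbrio",
    "JRC_WEIGHT_RATIOS",
    "JRC_DRIVE_PATH",
    "JRC_OUTPUT_PATH",
    "MONTBRIO_INPUT_PATH",
    "scale_efficacy",
    "random_drive",
    "forcing_window",
]

MODEL_DIR = os.path.join(os.path.dirname(__file__), "models")

#: (source node, target node) -> (target variable path suffix, ratio to C)
JRC_WEIGHT_RATIOS: Dict[Tuple[str, str], float] = {
    ("PC", "EIN"): 1.0,
    ("EIN", "PC"): 0.8,
    ("PC", "IIN"): 0.25,
    ("IIN", "PC"): 0.25,
}

#: default addresses used by the validation runs
JRC_DRIVE_PATH = "PC/RPO_e/u"
JRC_OUTPUT_PATH = "PC/PRO/V"
MONTBRIO_INPUT_PATH = "Pop1/MontbrioOperator/inp"

#: reference excitatory/inhibitory synaptic constants (efficacy in V, time
#: constant in s); inhibitory efficacy is negative — see the template notes.
JRC_EXC_H, JRC_EXC_TAU = 3.25e-3, 10e-3
JRC_INH_H, JRC_INH_TAU = -22e-3, 20e-3

_collections: Dict[str, TemplateCollection] = {}


def model_collection(family: str) -> TemplateCollection:
    """Template collection for a shipped model family.

    ``family`` is a YAML file stem in the models directory, currently
    ``jansen_rit`` or ``montbrio``.
    """
    if family not in _collections:
        path = os.path.join(MODEL_DIR, f"{family}.yaml")
        if not os.path.isfile(path):
            raise ValueError(f"unknown model family {family!r}")
        _collections[family] = TemplateCollection.from_yaml(path)
    return _collections[family]


_FAMILY_OF = {
    "JansenRitSynapse": "jansen_rit",
    "ExcitatorySynapse": "jansen_rit",
    "InhibitorySynapse": "jansen_rit",
    "JansenRitSynapse_with_input": "jansen_rit",
    "PotentialToRateOperator": "jansen_rit",
    "PyramidalCellPopulation": "jansen_rit",
    "ExcitatoryInterneurons": "jansen_rit",
    "InhibitoryInterneurons": "jansen_rit",
    "JansenRitCircuit": "jansen_rit",
    "DoubleJRCircuit": "jansen_rit",
    "MontbrioOperator": "montbrio",
    "MontbrioPopulation": "montbrio",
    "MontbrioNetwork": "montbrio",
}


def load_model(name: str):
    """Resolve a shipped template by name (e.g. ``JansenRitCircuit``)."""
    if name not in _FAMILY_OF:
        raise ValueError(f"unknown model template {name!r}")
    return model_collection(_FAMILY_OF[name]).resolve(name)


# ---------------------------------------------------------------------------
# parametrized builders
# ---------------------------------------------------------------------------

def build_jansen_rit(C: float = 135.0) -> CircuitTemplate:
    """Jansen-Rit circuit template with internal connectivity scaled by C.

    At C=135 the edge weights are the canonical (33.75, 135, 108, 33.75).
    """
    if C <= 0:
        raise ValueError("connectivity scaling C must be positive")
    template = copy.deepcopy(load_model("JansenRitCircuit"))
    for spec in template.edges:
        src = spec.source.split("/")[0]
        tgt = spec.target.split("/")[0]
        spec.attrs["weight"] = JRC_WEIGHT_RATIOS[(src, tgt)] * float(C)
    return template


def build_montbrio(delta: float = 1.0, eta: float = -5.0,
                   J: float = 15.0, tau: float = 1.0) -> CircuitTemplate:
    """Single-population Montbrió network template.

    Defaults are the bistable-regime constants (delta=1, eta=-5, J=15,
    tau=1); override per argument for other regimes.
    """
    template = copy.deepcopy(load_model("MontbrioNetwork"))
    op = template.nodes["Pop1"].operators["MontbrioOperator"]
    op.variables["delta"].value = float(delta)
    op.variables["eta"].value = float(eta)
    op.variables["J"].value = float(J)
    op.variables["tau"].value = float(tau)
    return template


def scale_efficacy(h_ref: float, tau_ref: float, tau_new: float) -> float:
    """Rescale a synaptic efficacy so the product h*tau stays constant.

    Used when sweeping synaptic timescales: h_new = h_ref * tau_ref /
    tau_new keeps the total charge transferred per synaptic event fixed.
    Efficacies may be negative (inhibition); time constants must be
    positive.
    """
    if tau_ref <= 0 or tau_new <= 0:
        raise ValueError("time constants must be positive")
    if h_ref == 0:
        raise ValueError("reference efficacy must be nonzero")
    return h_ref * tau_ref / tau_new


# ---------------------------------------------------------------------------
# input generators
# ---------------------------------------------------------------------------

def random_drive(simulation_time: float, dt: float,
                 lo: float = 120.0, hi: float = 320.0,
                 seed: int = 0) -> np.ndarray:
    """Uniform random firing-rate drive, one draw per integration step.

    Emulates unspecific afferent input between ``lo`` and ``hi`` (Hz); the
    default range 120-320 Hz is the standard drive of the Jansen-Rit
    pyramidal cells.  Fixed ``seed`` gives bit-identical arrays.
    """
    if lo >= hi:
        raise ValueError("require lo < hi")
    n_steps = int(round(simulation_time / dt))
    rng = np.random.default_rng(seed)
    return rng.uniform(lo, hi, n_steps)


def forcing_window(kind: str, I: float, omega: float,
                   t_on: float, t_off: float,
                   simulation_time: float, dt: float) -> np.ndarray:
    """Constant or sinusoidal forcing restricted to a time window.

    Zero outside ``[t_on, t_off)``; inside, ``I`` (constant) or
    ``I*sin(omega*t)`` (sinusoidal).  Times in the model's time unit.
    """
    if not 0 <= t_on < t_off <= simulation_time:
        raise ValueError("require 0 <= t_on < t_off <= simulation_time")
    if kind not in ("constant", "sinusoidal"):
        raise ValueError(f"kind must be 'constant' or 'sinusoidal', got "
                         f"{kind!r}")
    n_steps = int(round(simulation_time / dt))
    t = np.arange(n_steps) * dt
    window = (t >= t_on) & (t < t_off)
    if kind == "constant":
        return np.where(window, float(I), 0.0)
    return np.where(window, I * np.sin(omega * t), 0.0)
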