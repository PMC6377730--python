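"""Built-in oscillator case studies.

Four classic benchmark problems for parameter estimation in oscillatory
systems, each shipped with its published equations, default parameter bounds,
nominal (data-generating) parameter values, default initial conditions and a
default measurement protocol (number of points per experiment, time horizon):

``fhn``
    FitzHugh-Nagumo spiking-neuron model (2 states, 3 parameters, observable V).
``go``
    Goodwin oscillator: enzyme synthesis under feedback repression (3 states,
    8 parameters; fits observe x1 and x3, cross-validation additionally x2).
``rp``
    Repressilator synthetic gene network (6 states, 4 parameters; fits observe
    m3, cross-validation additionally p3).
``eo``
    Enzymatic (metabolic) oscillator with two coupled instability-generating
    mechanisms (3 states, 7 parameters, observables alpha and beta).
"""
from __future__ import annotations

import warnings

import numpy as np

from .models import DynamicModel

__all__ = ["build_case_study", "CASE_STUDIES"]


def _build_fhn():
    return DynamicModel(
        name="fhn",
        state_names=("V", "R"),
        param_names=("a", "b", "g"),
        rhs=(
            "g*(V - V**3/3 + R)",
            "-(V - a + b*R)/g",
        ),
        observations={"fitting": {"V": "V"}},
        default_x0=[-1.0, 1.0],
        bounds=([1e-5] * 3, [1e5] * 3),
        nominal=[0.2, 0.2, 3.0],
        default_horizon=(0.0, 20.0),
        n_points=6,
    )


def _build_go():
    ki_hill = "Ki**n / (Ki**n + x3**n)"
    return DynamicModel(
        name="go",
        state_names=("x1", "x2", "x3"),
        param_names=("k1", "k2", "k3", "k4", "k5", "k6", "Ki", "n"),
        rhs=(
            f"k1*{ki_hill} - k2*x1",
            "k3*x1 - k4*x2",
            "k5*x2 - k6*x3",
        ),
        observations={
            "fitting": {"x1": "x1", "x3": "x3"},
            "validation": {"x1": "x1", "x2": "x2", "x3": "x3"},
        },
        default_x0=[0.1, 0.2, 2.5],
        bounds=([1e-3] * 7 + [1.0], [1e3] * 7 + [12.0]),
        nominal=[1.0, 0.1, 1.0, 0.1, 1.0, 0.1, 1.0, 10.0],
        default_horizon=(0.0, 100.0),
        n_points=20,
    )


# The printed nominal vector for the repressilator is labelled with the Goodwin
# model's symbols, so its mapping onto {alpha0, alpha, beta, n} is ambiguous.
# Read in declaration order it gives n = 0.3, violating n in [1, 10]; the
# alternative reading swaps the last two entries (beta = 0.3, n = 8.5), which
# respects every bound.  Both are available; neither is asserted as truth.
_RP_NOMINAL = {
    "printed": [0.05, 298.0, 8.5, 0.3],
    "swapped": [0.05, 298.0, 0.3, 8.5],
}


def _build_rp(nominal_mapping="swapped"):
    if nominal_mapping not in _RP_NOMINAL:
        raise ValueError(f"unknown rp nominal mapping '{nominal_mapping}'")
    if nominal_mapping == "printed":
        warnings.warn(
            "repressilator 'printed' nominal mapping sets n=0.3, outside the "
            "declared bound n in [1, 10]; the 'swapped' mapping avoids this",
            stacklevel=2,
        )
    hill = "alpha0 + alpha/(1 + {p}**n)"
    return DynamicModel(
        name="rp",
        state_names=("p1", "p2", "p3", "m1", "m2", "m3"),
        param_names=("alpha0", "alpha", "beta", "n"),
        rhs=(
            "beta*(m1 - p1)",
            "beta*(m2 - p2)",
            "beta*(m3 - p3)",
            hill.format(p="p3") + " - m1",
            hill.format(p="p1") + " - m2",
            hill.format(p="p2") + " - m3",
        ),
        observations={
            "fitting": {"m3": "m3"},
            "validation": {"p3": "p3", "m3": "m3"},
        },
        default_x0=[10.0, 0.01, 1.0, 1.0, 0.01, 10.0],
        bounds=([1e-3, 1e-3, 1e-3, 1.0], [500.0, 500.0, 500.0, 10.0]),
        nominal=_RP_NOMINAL[nominal_mapping],
        default_horizon=(0.0, 50.0),
        n_points=20,
        metadata={"nominal_mapping": nominal_mapping},
    )


def _build_eo():
    # Scalings (1e6*L1, beta/100, the 50s) kept exactly as published.
    r2 = "a*sr2*(a + 1)*(b + 1)**2 / (1000000*L1 + (a + 1)**2*(b + 1)**2)"
    r3 = "s2r3*(c + 1)**2*(d*b/100 + 1)*b / (L2 + (c + 1)**2*(d*b/100 + 1)**2)"
    return DynamicModel(
        name="eo",
        state_names=("a", "b", "c"),  # alpha, beta, gamma
        param_names=("vKm1", "L1", "sr2", "L2", "d", "s2r3", "ks"),
        rhs=(
            f"vKm1 - {r2}",
            f"50*{r2} - {r3}",
            f"({r3})/50 - ks*c",
        ),
        observations={"fitting": {"alpha": "a", "beta": "b"}},
        default_x0=[29.1999, 188.8, 0.3367],
        bounds=([1e-3] * 7, [1e3] * 7),
        nominal=[0.4, 500.0, 10.0, 10.0, 0.07, 7.0, 2.5],
        default_horizon=(0.0, 100.0),
        n_points=14,
    )


CASE_STUDIES = {
    "fhn": _build_fhn,
    "go": _build_go,
    "rp": _build_rp,
    "eo": _build_eo,
}


def build_case_study(name, observation_variant="fitting", **kwargs):
    """Construct one of the built-in case studies.

    Parameters
    ----------
    name : {"fhn", "go", "rp", "eo"}
    observation_variant : {"fitting", "validation"}
        Requesting ``validation`` for a model without a dedicated validation
        map (fhn, eo) falls back to the fitting variant with a warning.
    kwargs
        Forwarded to the builder (``rp`` accepts ``nominal_mapping``).

    Returns
    -------
    DynamicModel
        With nominal parameters, default initial conditions, default bounds
        and measurement protocol attached.  ``metadata["variant"]`` records
        the resolved observation variant.
    """
    try:
        builder = CASE_STUDIES[name]
    except KeyError:
        raise KeyError(f"no such case study: '{name}'") from None
    model = builder(**kwargs)
    model.metadata["variant"] = model.resolve_variant(observation_variant)
    return model
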