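"""Plain-text declarative model format.

One declaration per line, ``#`` starts a comment, ``^`` may be used for powers::

    name myosc
    state V' = g*(V - V^3/3 + R)
    state R' = -(V - a + b*R)/g
    param a in [1e-5, 1e5]
    param b in [1e-5, 1e5]
    param g in [1e-5, 1e5]
    obs y = V
    valobs y = V          # optional separate validation observable
    init V = -1
    init R = 1
    time 0 20

States, parameters and observables may appear in any order; every symbol used
in an expression must be a declared state, parameter or ``t``.
"""
from __future__ import annotations

import re

import numpy as np

from .models import DynamicModel

__all__ = ["parse_model_text", "load_model_file"]

_STATE = re.compile(r"^state\s+(\w+)\s*'\s*=\s*(.+)$")
_PARAM = re.compile(r"^param\s+(\w+)\s+in\s*\[\s*([^\s,\]]+)\s*,\s*([^\s,\]]+)\s*\]$")
_OBS = re.compile(r"^(obs|valobs)\s+(\w+)\s*=\s*(.+)$")
_INIT = re.compile(r"^init\s+(\w+)\s*=\s*(.+)$")
_TIME = re.compile(r"^time\s+(\S+)\s+(\S+)$")
_NAME = re.compile(r"^name\s+(\S+)$")


def parse_model_text(text):
    """Parse the declarative model format into a :class:`DynamicModel`."""
    name = "custom"
    states, rhs, params, bounds_lo, bounds_hi = [], [], [], [], []
    fit_obs, val_obs, inits = {}, {}, {}
    horizon = (0.0, 10.0)
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        line = line.replace("^", "**")
        if m := _STATE.match(line):
            states.append(m.group(1))
            rhs.append(m.group(2))
        elif m := _PARAM.match(line):
            params.append(m.group(1))
            bounds_lo.append(float(m.group(2)))
            bounds_hi.append(float(m.group(3)))
        elif m := _OBS.match(line):
            target = fit_obs if m.group(1) == "obs" else val_obs
            target[m.group(2)] = m.group(3)
        elif m := _INIT.match(line):
            inits[m.group(1)] = float(m.group(2))
        elif m := _TIME.match(line):
            horizon = (float(m.group(1)), float(m.group(2)))
        elif m := _NAME.match(line):
            name = m.group(1)
        else:
            raise ValueError(f"line {lineno}: cannot parse declaration: {raw!r}")
    if not states:
        raise ValueError("model text declares no states")
    if not params:
        raise ValueError("model text declares no parameters")
    if not fit_obs:
        raise ValueError("model text declares no observables")
    unknown_init = set(inits) - set(states)
    if unknown_init:
        raise ValueError(f"init for undeclared states: {sorted(unknown_init)}")
    x0 = np.array([inits.get(s, 0.0) for s in states])
    observations = {"fitting": fit_obs}
    if val_obs:
        observations["validation"] = val_obs
    return DynamicModel(
        name=name,
        state_names=tuple(states),
        param_names=tuple(params),
        rhs=tuple(rhs),
        observations=observations,
        default_x0=x0,
        bounds=(bounds_lo, bounds_hi),
        default_horizon=horizon,
    )


def load_model_file(path):
    with open(path, encoding="utf-8") as fh:
        return parse_model_text(fh.read())
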