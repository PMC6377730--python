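"""Shared fixtures: tiny analytic models and small synthetic datasets."""
import numpy as np
import pandas as pd
import pytest

from oscifit import (
    DataGenConfig,
    DynamicModel,
    Experiment,
    ExperimentData,
    build_case_study,
    generate_fitting_datasets,
    simulate,
)


@pytest.fixture(scope="session")
def decay_model():
    """Scalar relaxation dx/dt = -theta * x with closed-form solution."""
    return DynamicModel(
        name="decay",
        state_names=("x",),
        param_names=("theta",),
        rhs=("-theta*x",),
        observations={"fitting": {"x": "x"}},
        default_x0=[1.0],
        bounds=([0.01], [10.0]),
        nominal=[1.0],
        default_horizon=(0.0, 5.0),
    )


@pytest.fixture(scope="session")
def harmonic_model():
    """Harmonic oscillator: s' = c, c' = -w^2 s; s(t) = sin(w t) at x0=(0, w)."""
    return DynamicModel(
        name="harmonic",
        state_names=("s", "c"),
        param_names=("w",),
        rhs=("c", "-w**2*s"),
        observations={"fitting": {"s": "s"}},
        default_x0=[0.0, 1.0],
        bounds=([0.1], [10.0]),
        nominal=[1.0],
        default_horizon=(0.0, 40.0),
    )


@pytest.fixture(scope="session")
def fhn_model():
    return build_case_study("fhn")


@pytest.fixture(scope="session")
def go_model():
    return build_case_study("go")


@pytest.fixture(scope="session")
def fhn_noiseless_data(fhn_model):
    """30-point noise-free FHN observations of V over [0, 20]."""
    cfg = DataGenConfig(noise_fraction=0.0, detection_threshold=None,
                        n_fitting_sets=1, n_points=30, horizon=(0.0, 20.0))
    return generate_fitting_datasets(fhn_model, config=cfg, seed=11)[0]


@pytest.fixture(scope="session")
def fhn_noisy_data(fhn_model):
    """One noisy FHN fitting replicate at the published protocol (6 points)."""
    return generate_fitting_datasets(fhn_model, seed=5)[0]


def make_dataset(times, values, sigmas, observable="V", x0=(-1.0, 1.0),
                 name="e1", variant="fitting"):
    df = pd.DataFrame({"observable": observable, "time": times,
                       "value": values, "sigma": sigmas})
    return ExperimentData([Experiment(name, np.asarray(x0), df)],
                          variant=variant)


@pytest.fixture
def simple_dataset():
    """Hand-sized single-observable dataset helper."""
    return make_dataset
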