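"""Synthetic measurement generator for the oscillator case studies.

Emulates the published pseudo-experimental protocol: trajectories simulated
at the nominal parameters on an equidistant grid, corrupted with Gaussian
noise whose standard deviation is 10.0% of the nominal signal value, and
left-censored at a detection threshold of 0.1 (values reported below the
limit of detection are recorded at it).  Ten fitting replicates share the
nominal initial conditions; ten cross-validation replicates randomise the
initial conditions (each nonzero component scaled by an independent
Uniform(0.5, 1.5) draw, zero components shifted by Uniform(0, 0.1)) and, for
the models that define one, use the richer validation observation map.

Stored measurement uncertainties are sigma = max(0.10*|y*|, 0.01); the floor
(10% of the detection threshold) keeps weights finite near censored points.
Replicate seeds are derived deterministically from the master seed, so a
given seed reproduces the datasets byte-identically.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import simulate
from .objective import Experiment, ExperimentData

__all__ = [
    "DataGenConfig",
    "add_noise",
    "generate_fitting_datasets",
    "generate_crossval_datasets",
]


@dataclass
class DataGenConfig:
    """Protocol parameters for synthetic dataset generation."""

    noise_fraction: float = 0.10
    detection_threshold: float = 0.1     # None disables left-censoring
    sigma_floor: float = 0.01
    n_fitting_sets: int = 10
    n_crossval_sets: int = 10
    n_points: int = None          # default: the model's published point count
    horizon: tuple = None         # default: the model's default horizon
    ic_scale_range: tuple = (0.5, 1.5)
    ic_zero_shift: float = 0.1
    max_redraws: int = 20
    rtol: float = 1e-8
    atol: float = 1e-10

    def __post_init__(self):
        if self.noise_fraction < 0:
            raise ValueError("noise_fraction must be non-negative")
        if self.detection_threshold is not None and self.detection_threshold < 0:
            raise ValueError("detection_threshold must be non-negative")


def _replicate_rng(master_seed, kind, replicate):
    # fixed-length entropy tuple -> deterministic, independent child streams
    return np.random.default_rng([int(master_seed) % (2**31), kind, replicate])


def add_noise(y_nominal, rng, config=None):
    """Apply the measurement model to noiseless signal values.

    Returns ``(y_measured, sigma)``: Gaussian noise with standard deviation
    ``noise_fraction * |y*|``, then left-censoring at the detection
    threshold; sigma is the nominal noise level floored at ``sigma_floor``.
    """
    config = config or DataGenConfig()
    y = np.asarray(y_nominal, dtype=float)
    sd = config.noise_fraction * np.abs(y)
    measured = y + rng.normal(0.0, 1.0, size=y.shape) * sd
    if config.detection_threshold is not None:
        measured = np.maximum(measured, config.detection_threshold)
    sigma = np.maximum(sd, config.sigma_floor)
    return measured, sigma


def _time_grid(model, config):
    t0, tend = config.horizon if config.horizon is not None else model.default_horizon
    n = config.n_points if config.n_points is not None else model.n_points
    return np.linspace(t0, tend, n)


def _make_experiment(model, theta, x0, times, variant, rng, config, name):
    traj = simulate(model, theta, x0=x0, times=times, rtol=config.rtol,
                    atol=config.atol, variant=variant)
    if not traj.ok:
        return None
    rows = []
    for j, oname in enumerate(traj.observable_names):
        y_star = traj.observables[:, j]
        measured, sigma = add_noise(y_star, rng, config)
        rows.append(pd.DataFrame({
            "observable": oname,
            "time": times,
            "value": measured,
            "sigma": sigma,
        }))
    return Experiment(name, x0, pd.concat(rows, ignore_index=True))


def generate_fitting_datasets(model, theta_nominal=None, x0_nominal=None,
                              config=None, seed=0):
    """Fitting replicates: shared nominal initial conditions, fitting variant.

    Returns a list of :class:`ExperimentData`, one per replicate (each holding
    a single experiment).  The nominal parameters must yield a feasible
    simulation, otherwise this raises.
    """
    config = config or DataGenConfig()
    theta = np.asarray(theta_nominal if theta_nominal is not None
                       else model.nominal, dtype=float)
    x0 = np.asarray(x0_nominal if x0_nominal is not None
                    else model.default_x0, dtype=float)
    times = _time_grid(model, config)
    datasets = []
    for rep in range(config.n_fitting_sets):
        rng = _replicate_rng(seed, 1, rep)
        exp = _make_experiment(model, theta, x0, times, "fitting", rng, config,
                               name=f"fit_{rep + 1}")
        if exp is None:
            raise RuntimeError(
                "infeasible simulation at the nominal parameters")
        datasets.append(ExperimentData([exp], variant="fitting"))
    return datasets


def generate_crossval_datasets(model, theta_nominal=None, x0_nominal=None,
                               config=None, seed=0):
    """Cross-validation replicates: randomised initial conditions.

    Uses the model's validation observation variant when it defines one
    (falling back to the fitting variant otherwise).  Initial conditions that
    break the integration are redrawn, up to ``max_redraws`` times.
    """
    config = config or DataGenConfig()
    theta = np.asarray(theta_nominal if theta_nominal is not None
                       else model.nominal, dtype=float)
    x0 = np.asarray(x0_nominal if x0_nominal is not None
                    else model.default_x0, dtype=float)
    variant = "validation" if "validation" in model.observations else "fitting"
    times = _time_grid(model, config)
    lo, hi = config.ic_scale_range
    datasets = []
    for rep in range(config.n_crossval_sets):
        rng = _replicate_rng(seed, 2, rep)
        exp = None
        for _ in range(config.max_redraws):
            factors = rng.uniform(lo, hi, size=x0.shape)
            shifts = rng.uniform(0.0, config.ic_zero_shift, size=x0.shape)
            x0_rep = np.where(x0 != 0, x0 * factors, shifts)
            exp = _make_experiment(model, theta, x0_rep, times, variant, rng,
                                   config, name=f"val_{rep + 1}")
            if exp is not None:
                break
        if exp is None:
            raise RuntimeError(
                f"could not find feasible initial conditions for replicate "
                f"{rep + 1} after {config.max_redraws} redraws")
        datasets.append(ExperimentData([exp], variant=variant))
    return datasets
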