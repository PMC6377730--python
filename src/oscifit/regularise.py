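"""Automatic tuning of the Tikhonov weight alpha and reference theta_ref.

Both regularisation parameters are derived from the phase-1 sampling archive
together with the per-parameter cost cut-offs and the reduced bounds, so that
the penalty and the tightened box cannot conflict:

* ``theta_ref`` is the consensus of the good-fit region: per parameter, the
  geometric mean (arithmetic for linear-scale parameters, which may be
  non-positive) of the accepted samples, clipped into the reduced bounds.
  Anchoring to the consensus rather than the single phase-1 optimum avoids
  re-importing the very overfit the penalty is meant to temper; the optimum
  can be selected instead via ``mode="phase1_optimum"``.
* ``alpha`` makes the penalty at the edge of the acceptable region
  commensurate with the acceptable cost degradation:
  ``alpha = median_j(cutoff_j - best_cost) / Gamma_max`` with ``Gamma_max``
  the largest penalty over the union of accepted samples.  If the accepted
  samples are (numerically) identical, no regularisation is needed and
  ``alpha = 0``.

Because the penalty weight matrix is W = diag(1/theta_ref), alpha is
invariant under per-parameter rescaling of units.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .bounding import _feasible, _to_scale
from .objective import regularisation_penalty

__all__ = ["RegularisationSetting", "tune_regularisation"]


@dataclass
class RegularisationSetting:
    alpha: float
    theta_ref: np.ndarray

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        self.theta_ref = np.asarray(self.theta_ref, dtype=float)
        if np.any(self.theta_ref == 0):
            raise ValueError("theta_ref components must be nonzero")

    def to_dict(self):
        return {"alpha": self.alpha, "theta_ref": self.theta_ref.tolist()}


def _interior_clip(value, lo, hi):
    """Clip into [lo, hi], nudging off an exact zero (W must stay defined)."""
    v = min(max(value, lo), hi)
    if v == 0.0:
        width = hi - lo
        v = min(max(1e-6 * width, lo), hi)
        if v == 0.0:
            v = np.nextafter(0.0, hi if hi > 0 else lo)
        warnings.warn("theta_ref component clipped away from zero", stacklevel=3)
    return v


def tune_regularisation(archive, cutoffs, reduced_bounds, theta_best,
                        scales=None, mode="consensus"):
    """Derive (alpha, theta_ref) from the phase-1 archive and cut-offs."""
    costs = archive.costs
    points = archive.points
    feas = _feasible(costs)
    if not np.any(feas):
        raise ValueError("archive contains no feasible evaluations")
    n_params = points.shape[1]
    if scales is None:
        scales = ("linear",) * n_params
    best_cost = float(np.min(costs[feas]))

    # -- reference vector -------------------------------------------------
    theta_ref = np.empty(n_params)
    if mode == "phase1_optimum":
        src = np.asarray(theta_best, dtype=float)
        for j in range(n_params):
            theta_ref[j] = _interior_clip(src[j], reduced_bounds.lower[j],
                                          reduced_bounds.upper[j])
    elif mode == "consensus":
        for j in range(n_params):
            mask = feas & (costs <= cutoffs.cutoffs[j])
            col = points[mask, j]
            if scales[j] == "log10":
                center = float(10.0 ** np.mean(np.log10(np.maximum(col, 1e-300))))
            else:
                center = float(np.mean(col))
            theta_ref[j] = _interior_clip(center, reduced_bounds.lower[j],
                                          reduced_bounds.upper[j])
    else:
        raise ValueError(f"unknown theta_ref mode '{mode}'")

    # -- weight -----------------------------------------------------------
    union = feas & (costs <= float(np.max(cutoffs.cutoffs)))
    rel = (points[union] - theta_ref) / theta_ref
    gammas = np.sum(rel * rel, axis=1)
    gamma_max = float(np.max(gammas)) if len(gammas) else 0.0
    gaps = cutoffs.cutoffs - best_cost
    if np.any(gaps < -1e-9 * max(abs(best_cost), 1.0)):
        raise RuntimeError("cost cut-off below the best archive cost")
    if gamma_max < 1e-12:
        alpha = 0.0
    else:
        alpha = float(np.median(np.maximum(gaps, 0.0)) / gamma_max)
    setting = RegularisationSetting(alpha=alpha, theta_ref=theta_ref)
    # self-consistency: penalty evaluates cleanly at the reference
    assert regularisation_penalty(theta_ref, setting.theta_ref) == 0.0
    return setting
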