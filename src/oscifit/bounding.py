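"""Sampling-based parameter bounding.

The phase-1 evaluation archive is turned into, per parameter, a *cost
cut-off* separating samples judged close to the optimum from the rest, and
then into a tightened search box for the second (regularised) estimation.

Cut-off rule (knee detection).  For parameter j, sweep candidate cut-offs c
over the sorted archive costs and track R_j(c), the spread (in search scale)
of theta_j over the accepted samples {i : cost_i <= c}.  R_j is flat while
only near-optimal samples are accepted and blows up towards the full box
width once far-from-optimum samples enter.  The cut-off is the candidate
maximising the perpendicular distance *below* the chord joining the curve's
endpoints in (log10 cost, spread) coordinates — the largest cost before the
spread takes off.  Ties break towards the smaller cost; archives that are
too small or span less than a decade of cost fall back to the 25th cost
percentile.

Reduction rule.  Per parameter, take the hull of theta_j over the accepted
set, widen it by 10% of its width on each side (search scale), optionally
snap outward to the nearest integer powers of ten, intersect with the
original bounds, and enlarge minimally so the phase-1 estimate stays strictly
interior.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .models import PENALTY_COST

__all__ = ["CutoffSet", "ReducedBounds", "cost_cutoffs", "reduce_bounds"]


@dataclass
class CutoffSet:
    """Per-parameter cost cut-offs with acceptance diagnostics."""

    cutoffs: np.ndarray          # zeta*_j, one per parameter
    n_accepted: np.ndarray       # |S_j| per parameter
    fallback: bool               # True when the percentile fallback fired
    min_cost: float

    def accepted_mask(self, costs, j):
        return np.asarray(costs) <= self.cutoffs[j]

    def to_dict(self):
        return {
            "cutoffs": self.cutoffs.tolist(),
            "n_accepted": self.n_accepted.tolist(),
            "fallback": self.fallback,
            "min_cost": self.min_cost,
        }


@dataclass
class ReducedBounds:
    lower: np.ndarray
    upper: np.ndarray

    def contains(self, theta, strict=False):
        theta = np.asarray(theta, dtype=float)
        if strict:
            return bool(np.all(theta > self.lower) and np.all(theta < self.upper))
        return bool(np.all(theta >= self.lower) and np.all(theta <= self.upper))

    def to_dict(self):
        return {"lower": self.lower.tolist(), "upper": self.upper.tolist()}


def _feasible(costs):
    return np.asarray(costs) < PENALTY_COST


def _to_scale(values, scale):
    values = np.asarray(values, dtype=float)
    if scale == "log10":
        return np.log10(np.maximum(values, 1e-300))
    return values


def _from_scale(values, scale):
    if scale == "log10":
        return 10.0 ** np.asarray(values, dtype=float)
    return np.asarray(values, dtype=float)


def cost_cutoffs(archive, scales=None, min_points=50, fallback_quantile=0.25):
    """Per-parameter cost cut-offs from a phase-1 sampling archive."""
    costs = archive.costs
    points = archive.points
    feas = _feasible(costs)
    if not np.any(feas):
        raise ValueError("archive contains no feasible evaluations")
    costs_f = costs[feas]
    points_f = points[feas]
    n_params = points.shape[1]
    if scales is None:
        scales = ("linear",) * n_params
    cmin = float(np.min(costs_f))
    cmax = float(np.max(costs_f))

    # degenerate archives: too few points or <1 decade of cost spread
    eps = max(1e-300, 1e-16 * max(cmax, 1.0))
    if len(costs_f) < min_points or (cmax + eps) / (cmin + eps) <= 10.0:
        if not (len(costs_f) >= min_points):
            warnings.warn(
                f"archive has only {len(costs_f)} feasible points; "
                "using percentile fallback for cost cut-offs", stacklevel=2)
        else:
            warnings.warn(
                "archive costs span less than one decade; "
                "using percentile fallback for cost cut-offs", stacklevel=2)
        cut = float(np.quantile(costs_f, fallback_quantile))
        cuts = np.full(n_params, cut)
        n_acc = np.array([int(np.sum(costs_f <= cut))] * n_params)
        return CutoffSet(cuts, n_acc, True, cmin)

    order = np.argsort(costs_f, kind="stable")
    sorted_costs = costs_f[order]
    sorted_pts = points_f[order]
    # candidate cut-offs: last occurrence of each unique cost
    uniq, last_idx = np.unique(sorted_costs, return_index=True)
    counts = np.diff(np.append(last_idx, len(sorted_costs)))
    cand_idx = last_idx + counts - 1
    x = np.log10(uniq + eps)

    # a cut-off must accept a non-trivial sample (the local-search iterates
    # pile hundreds of near-duplicates at the optimum, which would otherwise
    # let the knee collapse onto the single best point) and sit strictly
    # above the best cost
    n_f = len(costs_f)
    min_accept = min(max(10, -(-n_f * 2 // 100)), max(2, n_f // 2))
    cum_counts = cand_idx + 1
    eligible = (cum_counts >= min_accept) & (uniq > cmin)
    if not np.any(eligible):
        warnings.warn("no admissible cut-off candidates; "
                      "using percentile fallback for cost cut-offs",
                      stacklevel=2)
        cut = float(np.quantile(costs_f, fallback_quantile))
        cuts = np.full(n_params, cut)
        n_acc = np.array([int(np.sum(costs_f <= cut))] * n_params)
        return CutoffSet(cuts, n_acc, True, cmin)

    cuts = np.empty(n_params)
    n_acc = np.empty(n_params, dtype=int)
    for j in range(n_params):
        col = _to_scale(sorted_pts[:, j], scales[j])
        spread = (np.maximum.accumulate(col) - np.minimum.accumulate(col))[cand_idx]
        # distance below the chord from (x0, y0) to (x1, y1)
        x0, y0, x1, y1 = x[0], spread[0], x[-1], spread[-1]
        norm = math.hypot(x1 - x0, y1 - y0)
        chord_y = y0 + (x - x0) * ((y1 - y0) / (x1 - x0)) if x1 > x0 else spread
        below = (chord_y - spread) / (norm if norm > 0 else 1.0)
        below = np.where(eligible, below, -np.inf)
        k = int(np.argmax(below))  # argmax takes the first (smallest cost) tie
        cuts[j] = uniq[k]
        n_acc[j] = int(np.sum(costs_f <= uniq[k]))
    return CutoffSet(cuts, n_acc, False, cmin)


def _snap_down_pow10(v):
    return 10.0 ** math.floor(round(math.log10(v), 12))


def _snap_up_pow10(v):
    return 10.0 ** math.ceil(round(math.log10(v), 12))


def reduce_bounds(archive, cutoffs, bounds, theta_best, scales=None,
                  expand_fraction=0.1, snap_powers_of_ten=True):
    """Tighten the search box around the accepted samples.

    The reduced box is never wider than the original, and the phase-1
    estimate ``theta_best`` is kept strictly interior (up to the original
    bounds themselves).
    """
    lo = np.asarray(bounds[0], dtype=float)
    hi = np.asarray(bounds[1], dtype=float)
    costs = archive.costs
    points = archive.points
    feas = _feasible(costs)
    n_params = points.shape[1]
    if scales is None:
        scales = ("linear",) * n_params
    theta_best = np.asarray(theta_best, dtype=float)

    new_lo = lo.copy()
    new_hi = hi.copy()
    for j in range(n_params):
        mask = feas & (costs <= cutoffs.cutoffs[j])
        if not np.any(mask):
            warnings.warn(f"empty accepted set for parameter {j}; "
                          "keeping original bounds", stacklevel=2)
            continue
        col = _to_scale(points[mask, j], scales[j])
        s_lo, s_hi = float(np.min(col)), float(np.max(col))
        width = s_hi - s_lo
        pad = expand_fraction * width
        s_lo -= pad
        s_hi += pad
        v_lo = float(_from_scale(s_lo, scales[j]))
        v_hi = float(_from_scale(s_hi, scales[j]))
        if snap_powers_of_ten and scales[j] == "log10":
            v_lo = _snap_down_pow10(v_lo)
            v_hi = _snap_up_pow10(v_hi)
        # intersect with the original box
        v_lo = max(v_lo, lo[j])
        v_hi = min(v_hi, hi[j])
        if v_lo >= v_hi:  # degenerate after clipping: keep original
            v_lo, v_hi = lo[j], hi[j]
        # keep the phase-1 estimate strictly interior where possible
        tb = theta_best[j]
        if tb <= v_lo:
            v_lo = max(lo[j], tb - 1e-9 * max(abs(tb), 1.0)
                       if scales[j] == "linear" else tb / (1.0 + 1e-9))
        if tb >= v_hi:
            v_hi = min(hi[j], tb + 1e-9 * max(abs(tb), 1.0)
                       if scales[j] == "linear" else tb * (1.0 + 1e-9))
        new_lo[j], new_hi[j] = v_lo, v_hi
    return ReducedBounds(new_lo, new_hi)
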