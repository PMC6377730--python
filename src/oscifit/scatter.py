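"""Hybrid scatter-search global optimiser over box bounds.

A population-based metaheuristic in the enhanced-scatter-search family:
a Latin hypercube diversification set seeds a small reference set (best
members plus maximally diverse ones); members are recombined pairwise inside
biased hyper-rectangles, improving offspring replace their worse parent, and
an improving direction is followed further ("go-beyond").  Periodically a
bounded trust-region nonlinear least-squares refinement (NL2SOL-class, via
``scipy.optimize.least_squares``) is launched from promising unrefined
points, fed with analytic residual Jacobians when the objective can provide
them.  Every single objective evaluation — diversification, combination,
go-beyond and local-search iterates alike — is appended to a
:class:`SamplingArchive`, which downstream steps reuse for parameter bounding
and regularisation tuning.

Combination and local refinement operate in *search scale*: parameters
flagged log10 are transformed to their exponents, so that searches over
bounds spanning many decades remain well conditioned.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares, minimize

from .models import PENALTY_COST

__all__ = [
    "SamplingArchive",
    "EssConfig",
    "BoxScale",
    "FunctionObjective",
    "NLSObjective",
    "RegularisedObjective",
    "latin_hypercube",
    "local_refine",
    "ess_minimize",
]


# ---------------------------------------------------------------------------
# scale handling
class BoxScale:
    """Transform between natural parameter space and search space (z).

    log10-flagged coordinates are searched as exponents; linear ones as-is.
    """

    def __init__(self, bounds, scales=None):
        self.lo = np.asarray(bounds[0], dtype=float)
        self.hi = np.asarray(bounds[1], dtype=float)
        if not (np.all(np.isfinite(self.lo)) and np.all(np.isfinite(self.hi))):
            raise ValueError("bounds must be finite")
        if np.any(self.lo >= self.hi):
            raise ValueError("require lower < upper bounds")
        n = len(self.lo)
        if scales is None:
            scales = tuple(
                "log10" if (l > 0 and h / l > 100.0) else "linear"
                for l, h in zip(self.lo, self.hi)
            )
        self.scales = tuple(scales)
        self.is_log = np.array([s == "log10" for s in self.scales])
        if np.any(self.is_log & (self.lo <= 0)):
            raise ValueError("log10 scale requires positive lower bounds")
        self.zlo = np.where(self.is_log, np.log10(np.where(self.is_log, self.lo, 1.0)),
                            self.lo)
        self.zhi = np.where(self.is_log, np.log10(np.where(self.is_log, self.hi, 1.0)),
                            self.hi)
        self.n = n

    def to_theta(self, z):
        z = np.asarray(z, dtype=float)
        theta = np.where(self.is_log, 10.0 ** np.where(self.is_log, z, 0.0), z)
        # guard against round-trip drift past the box edges
        return np.clip(theta, self.lo, self.hi)

    def to_z(self, theta):
        theta = np.asarray(theta, dtype=float)
        return np.where(self.is_log,
                        np.log10(np.where(self.is_log, np.maximum(theta, 1e-300), 1.0)),
                        theta)

    def clip(self, z):
        return np.clip(z, self.zlo, self.zhi)

    def dtheta_dz(self, theta):
        """Diagonal of the chain-rule factor for Jacobians in z-space."""
        return np.where(self.is_log, np.asarray(theta) * math.log(10.0), 1.0)


# ---------------------------------------------------------------------------
# objectives
class FunctionObjective:
    """Wrap a plain callable f(theta) -> cost; optional residual form.

    ``residual_fn(theta) -> r`` and ``jac_fn(theta) -> dr/dtheta`` enable the
    least-squares local refinement; without them a quasi-Newton fallback with
    finite-difference gradients is used.
    """

    def __init__(self, fn=None, residual_fn=None, jac_fn=None):
        if fn is None and residual_fn is None:
            raise ValueError("need fn or residual_fn")
        self._fn = fn
        self._residual_fn = residual_fn
        self._jac_fn = jac_fn

    @property
    def has_residuals(self):
        return self._residual_fn is not None

    def cost(self, theta):
        if self._fn is not None:
            return float(self._fn(np.asarray(theta, dtype=float)))
        r = np.asarray(self._residual_fn(theta), dtype=float)
        return float(r @ r)

    def residuals(self, theta):
        return np.asarray(self._residual_fn(theta), dtype=float)

    def jacobian(self, theta):
        if self._jac_fn is None:
            return None
        return np.asarray(self._jac_fn(theta), dtype=float)


class NLSObjective:
    """Weighted least-squares data-misfit objective for a dynamic model.

    Residuals and their analytic Jacobian (from forward sensitivities) are
    available for gradient-based refinement.  Infeasible simulations are
    mapped to a flat penalty residual vector so local solvers retreat from
    non-integrable regions instead of crashing.
    """

    has_residuals = True

    def __init__(self, model, data, rtol=1e-8, atol=1e-10):
        from . import objective as obj  # late import avoids cycle at module load
        self._obj = obj
        self.model = model
        self.data = data
        self.rtol = rtol
        self.atol = atol
        self.n_res = data.n_residuals

    def cost(self, theta):
        return self._obj.nls_cost(self.model, theta, self.data,
                                  rtol=self.rtol, atol=self.atol).cost

    def residuals(self, theta):
        res = self._obj.nls_cost(self.model, theta, self.data,
                                 rtol=self.rtol, atol=self.atol)
        if not res.feasible:
            return np.full(self.n_res, math.sqrt(PENALTY_COST / self.n_res))
        return res.residuals

    def jacobian(self, theta):
        from .models import simulate_with_sensitivities
        model, data = self.model, self.data
        variant = model.resolve_variant(data.variant)
        rows = []
        for exp in data.experiments:
            times = np.unique(exp.observations["time"].to_numpy(dtype=float))
            idx = np.searchsorted(times,
                                  exp.observations["time"].to_numpy(dtype=float))
            traj, sens = simulate_with_sensitivities(
                model, theta, x0=exp.x0, times=times,
                rtol=self.rtol, atol=self.atol, variant=variant)
            if not traj.ok:
                return None
            names = list(model.observable_names(variant))
            cols = exp.observations["observable"].map(names.index).to_numpy()
            sig = exp.observations["sigma"].to_numpy(dtype=float)
            rows.append(sens.dy_dtheta[idx, cols, :] / sig[:, None])
        return np.vstack(rows)


class RegularisedObjective:
    """Tikhonov-extended objective Q_R = Q_NLS + alpha * Gamma.

    The penalty enters the residual vector as sqrt(alpha) * W (theta -
    theta_ref), so the extended problem stays an ordinary least-squares one
    and the same trust-region refinement applies.
    """

    has_residuals = True

    def __init__(self, base, alpha, theta_ref):
        if alpha < 0:
            raise ValueError("alpha must be non-negative")
        theta_ref = np.asarray(theta_ref, dtype=float)
        if np.any(theta_ref == 0):
            raise ValueError("theta_ref components must be nonzero")
        self.base = base
        self.alpha = float(alpha)
        self.theta_ref = theta_ref
        self._w = math.sqrt(self.alpha) / theta_ref

    def cost(self, theta):
        theta = np.asarray(theta, dtype=float)
        pen = (theta - self.theta_ref) * self._w
        return self.base.cost(theta) + float(pen @ pen)

    def residuals(self, theta):
        theta = np.asarray(theta, dtype=float)
        return np.concatenate(
            [self.base.residuals(theta), (theta - self.theta_ref) * self._w])

    def jacobian(self, theta):
        J = self.base.jacobian(theta)
        if J is None:
            return None
        return np.vstack([J, np.diag(self._w)])


# ---------------------------------------------------------------------------
# archive
class SamplingArchive:
    """Every parameter vector evaluated during a search, with its cost.

    The archive length equals the objective-evaluation counter exactly; the
    best index always points at the minimum recorded cost.
    """

    def __init__(self, n_params, param_names=None):
        self.n_params = n_params
        self.param_names = param_names
        self._points = []
        self._costs = []
        self.best_index = -1
        self._best_cost = math.inf

    def append(self, theta, cost):
        self._points.append(np.array(theta, dtype=float))
        self._costs.append(float(cost))
        if cost < self._best_cost:
            self._best_cost = float(cost)
            self.best_index = len(self._costs) - 1

    @property
    def n_evals(self):
        return len(self._costs)

    @property
    def points(self):
        return np.array(self._points) if self._points else np.empty((0, self.n_params))

    @property
    def costs(self):
        return np.array(self._costs)

    @property
    def best_cost(self):
        return self._best_cost

    @property
    def best_point(self):
        return np.array(self._points[self.best_index])

    def to_csv(self, path):
        import pandas as pd
        names = self.param_names or [f"theta_{j+1}" for j in range(self.n_params)]
        df = pd.DataFrame(self.points, columns=list(names))
        df.insert(0, "cost", self.costs)
        df.insert(0, "eval_index", np.arange(1, self.n_evals + 1))
        df.to_csv(path, index=False)


@dataclass
class EssConfig:
    """Tuning knobs for the scatter search.

    ``refset_size`` defaults to ``2*ceil(sqrt(N_theta)) + 2`` (minimum 8) and
    ``diverse_size`` to ``10*N_theta`` (minimum 100).  ``local_every`` is the
    number of outer iterations between local refinements; ``stall_limit``
    triggers a restart of the non-best reference members.
    """

    max_evals: int = 5000
    refset_size: int = None
    diverse_size: int = None
    local_search: bool = True
    local_every: int = 8
    local_budget: int = 150
    go_beyond: bool = True
    stall_limit: int = 12
    local_min_dist: float = 1e-3
    local_solver: str = "auto"  # auto | least_squares | lbfgsb

    def resolved(self, n_params, honour_budget=True):
        cfg = EssConfig(**self.__dict__)
        if cfg.refset_size is None:
            cfg.refset_size = max(8, 2 * math.ceil(math.sqrt(n_params)) + 2)
        if cfg.diverse_size is None:
            cfg.diverse_size = max(100, 10 * n_params)
        if cfg.refset_size < 4:
            raise ValueError("refset_size must be at least 4")
        if honour_budget and cfg.max_evals <= cfg.diverse_size:
            raise ValueError("max_evals must exceed diverse_set_size")
        return cfg


@dataclass
class EssResult:
    theta: np.ndarray
    cost: float
    archive: SamplingArchive
    n_local_searches: int = 0
    seed: int = None
    config: EssConfig = None


# ---------------------------------------------------------------------------
# operations
def latin_hypercube(bounds, n, seed, scales=None):
    """Stratified Latin hypercube sample in search scale.

    Each coordinate places exactly one point per stratum; points are returned
    in natural parameter scale.  Reproducible given the seed (an int or an
    already-constructed ``numpy.random.Generator``).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    scale = BoxScale(bounds, scales)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = _lhs_z(rng, scale, n)
    return np.array([scale.to_theta(zi) for zi in z])


def _lhs_z(rng, scale, n):
    u = (rng.permuted(np.tile(np.arange(n), (scale.n, 1)), axis=1).T
         + rng.uniform(size=(n, scale.n))) / n
    return scale.zlo + u * (scale.zhi - scale.zlo)


def local_refine(objective, theta0, bounds, scales=None, archive=None,
                 max_nfev=200, xtol=1e-12, ftol=1e-12):
    """Bounded gradient-based local refinement from ``theta0``.

    Uses a trust-region-reflective nonlinear least-squares solver with the
    objective's analytic residual Jacobian when available; otherwise falls
    back (with a warning) to a quasi-Newton bound-constrained minimiser with
    finite-difference gradients.  Never returns a point worse than the start;
    every cost evaluation is appended to ``archive`` when given.
    """
    scale = BoxScale(bounds, scales)
    z0 = scale.clip(scale.to_z(theta0))
    best = {"theta": np.asarray(theta0, dtype=float),
            "cost": objective.cost(theta0)}
    if archive is not None:
        archive.append(best["theta"], best["cost"])

    def track(theta, cost):
        if archive is not None:
            archive.append(theta, cost)
        if cost < best["cost"]:
            best["theta"] = np.array(theta)
            best["cost"] = cost

    use_ls = getattr(objective, "has_residuals", False)
    if use_ls and objective.jacobian(best["theta"]) is None:
        warnings.warn("Jacobian evaluation failed at start point; "
                      "falling back to gradient-free refinement", stacklevel=2)
        use_ls = False
    if use_ls:
        def fun(z):
            theta = scale.to_theta(z)
            r = objective.residuals(theta)
            track(theta, float(r @ r))
            return r

        def jac(z):
            theta = scale.to_theta(z)
            J = objective.jacobian(theta)
            if J is None:
                # repelled region: zero Jacobian halts the step harmlessly
                nr = len(objective.residuals(theta))
                return np.zeros((nr, scale.n))
            return J * scale.dtheta_dz(theta)[None, :]

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            least_squares(fun, z0, jac=jac, bounds=(scale.zlo, scale.zhi),
                          method="trf", max_nfev=max_nfev, xtol=xtol, ftol=ftol,
                          gtol=1e-12)
    else:
        def fun(z):
            theta = scale.to_theta(z)
            c = objective.cost(theta)
            track(theta, c)
            return c

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            minimize(fun, z0, method="L-BFGS-B",
                     bounds=list(zip(scale.zlo, scale.zhi)),
                     options={"maxfun": max_nfev})
    return best["theta"], best["cost"]


def _select_refset(zs, costs, m, rng):
    """Half best members, half greedy max-min-distance diverse members."""
    order = np.argsort(costs, kind="stable")
    n_best = m // 2
    chosen = list(order[:n_best])
    remaining = [i for i in order[n_best:]]
    while len(chosen) < m and remaining:
        sel = np.array([zs[i] for i in chosen])
        dists = [np.min(np.linalg.norm(sel - zs[i], axis=1)) for i in remaining]
        k = int(np.argmax(dists))
        chosen.append(remaining.pop(k))
    return chosen


def ess_minimize(objective, bounds, config=None, seed=0, scales=None,
                 x0=None):
    """Scatter-search global minimisation over box bounds.

    Returns an :class:`EssResult` with the best point ever evaluated, its
    cost, and the complete evaluation archive.  Bit-reproducible given
    ``seed``; raises if every evaluation hit the infeasibility penalty.
    """
    scale = BoxScale(bounds, scales)
    config = (config or EssConfig()).resolved(scale.n)
    rng = np.random.default_rng(seed)
    archive = SamplingArchive(scale.n)

    state = {"stop": False}

    def evaluate(z):
        if archive.n_evals >= config.max_evals:
            state["stop"] = True
            return math.inf
        theta = scale.to_theta(z)
        c = objective.cost(theta)
        archive.append(theta, c)
        return c

    # -- diversification --------------------------------------------------
    zs = list(_lhs_z(rng, scale, config.diverse_size))
    if x0 is not None:
        zs[0] = scale.clip(scale.to_z(x0))
    costs = [evaluate(z) for z in zs]

    m = min(config.refset_size, len(zs))
    idx = _select_refset(np.array(zs), np.array(costs), m, rng)
    ref_z = [zs[i] for i in idx]
    ref_c = [costs[i] for i in idx]

    refined = []
    n_local = 0
    last_best = min(ref_c)
    stall = 0
    iteration = 0

    def maybe_local():
        nonlocal n_local
        if not config.local_search or archive.n_evals >= config.max_evals:
            return
        order = np.argsort(ref_c, kind="stable")
        for i in order:
            z = ref_z[i]
            if ref_c[i] >= PENALTY_COST:
                continue
            if any(np.linalg.norm(z - zr) < config.local_min_dist *
                   max(np.linalg.norm(scale.zhi - scale.zlo), 1.0)
                   for zr in refined):
                continue
            budget = min(config.local_budget,
                         config.max_evals - archive.n_evals)
            if budget < 5:
                return
            theta_loc, cost_loc = local_refine(
                objective, scale.to_theta(z), (scale.lo, scale.hi),
                scales=scale.scales, archive=archive, max_nfev=budget)
            refined.append(z.copy())
            refined.append(scale.clip(scale.to_z(theta_loc)))
            n_local += 1
            if cost_loc < ref_c[i]:
                ref_z[i] = scale.clip(scale.to_z(theta_loc))
                ref_c[i] = cost_loc
            return

    maybe_local()

    while archive.n_evals < config.max_evals and not state["stop"]:
        iteration += 1
        pair_list = [(i, j) for i in range(m) for j in range(i + 1, m)]
        for i, j in pair_list:
            if archive.n_evals >= config.max_evals:
                break
            # bias the hyper-rectangle toward (and beyond) the better parent
            if ref_c[i] <= ref_c[j]:
                b, w, wi = ref_z[i], ref_z[j], j
            else:
                b, w, wi = ref_z[j], ref_z[i], i
            u = rng.uniform(-0.5, 1.0, size=scale.n)
            child = scale.clip(b + u * (b - w))
            c_child = evaluate(child)
            if state["stop"]:
                break
            if c_child < ref_c[wi]:
                ref_z[wi] = child
                ref_c[wi] = c_child
            # go-beyond: keep stepping while the direction improves on the
            # better parent
            if config.go_beyond and c_child < min(ref_c[i], ref_c[j]):
                parent_c, parent_z = (min(ref_c[i], ref_c[j]), b)
                step = child - parent_z
                cur_z, cur_c = child, c_child
                lam = 1.0
                while cur_c < parent_c and archive.n_evals < config.max_evals:
                    nxt = scale.clip(cur_z + lam * step)
                    if np.allclose(nxt, cur_z):
                        break
                    c_nxt = evaluate(nxt)
                    if c_nxt >= cur_c:
                        break
                    parent_c, parent_z = cur_c, cur_z
                    cur_z, cur_c = nxt, c_nxt
                    lam *= 2.0
                k = int(np.argmax(ref_c))
                if cur_c < ref_c[k]:
                    ref_z[k] = cur_z
                    ref_c[k] = cur_c

        if config.local_search and iteration % config.local_every == 0:
            maybe_local()

        best_now = min(ref_c)
        if best_now < last_best - 1e-12 * max(abs(last_best), 1.0):
            stall = 0
            last_best = best_now
        else:
            stall += 1
        if stall >= config.stall_limit and archive.n_evals < config.max_evals:
            # restart: keep the best member, redraw the rest
            keep = int(np.argmin(ref_c))
            fresh = _lhs_z(rng, scale, m - 1)
            slot = 0
            for k in range(m):
                if k == keep:
                    continue
                ref_z[k] = fresh[slot]
                ref_c[k] = evaluate(ref_z[k])
                slot += 1
                if state["stop"]:
                    break
            stall = 0

    # final polish: make the returned point stationary for its local solver,
    # so a follow-up search cannot trivially improve on it
    if config.local_search and archive.best_cost < PENALTY_COST:
        local_refine(objective, archive.best_point, (scale.lo, scale.hi),
                     scales=scale.scales, archive=archive,
                     max_nfev=config.local_budget)
        n_local += 1

    if archive.n_evals == 0 or archive.best_cost >= PENALTY_COST:
        raise RuntimeError("no feasible point found")
    return EssResult(theta=archive.best_point, cost=archive.best_cost,
                     archive=archive, n_local_searches=n_local, seed=seed,
                     config=config)
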