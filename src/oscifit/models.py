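"""Nonlinear ODE models with observation maps and forward sensitivities.

A :class:`DynamicModel` holds the symbolic right-hand side ``dx/dt = f(t, x, theta)``,
one or more named observation maps ``y = g(x, theta, t)`` (e.g. a ``fitting``
variant and a richer ``validation`` variant), parameter bounds and per-parameter
search scales.  Jacobians of ``f`` and ``g`` with respect to states and
parameters are derived symbolically once and cached, so that trajectories and
forward parametric sensitivities can be integrated efficiently with a
stiff-capable variable-step solver (LSODA).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import sympy as sp
from scipy.integrate import odeint
from scipy.signal import find_peaks

__all__ = [
    "DynamicModel",
    "Trajectory",
    "SensitivityTrajectory",
    "simulate",
    "simulate_with_sensitivities",
    "detect_sustained_oscillations",
    "PENALTY_COST",
    "InfeasibleSimulationWarning",
]

#: Cost sentinel consumed by objective functions when an integration fails.
#: Large enough to repel any search, finite so optimisers never see inf/NaN.
PENALTY_COST = 1.0e10

#: State magnitudes beyond this are treated as numerical blow-up.
_BLOWUP = 1.0e12

_TIME = sp.Symbol("t")


class InfeasibleSimulationWarning(RuntimeWarning):
    """Emitted when an initial-value problem cannot be solved over the grid."""


def _as_symbols(names):
    return [sp.Symbol(n) for n in names]


@dataclass
class DynamicModel:
    """Symbolic ODE model with observation variants and parameter bounds.

    Parameters
    ----------
    name : str
        Identifier for the model.
    state_names, param_names : sequence of str
        Names of the ``N_x`` state variables and ``N_theta`` parameters.
    rhs : sequence of sympy expressions (or strings)
        One expression per state, in terms of states, parameters and ``t``.
    observations : dict
        Maps variant name (``"fitting"``, ``"validation"``, ...) to an ordered
        mapping ``{observable_name: expression}``.
    default_x0 : array-like
        Default initial condition, length ``N_x``.
    bounds : pair of array-like
        ``(theta_min, theta_max)``, both length ``N_theta``.
    search_scale : sequence of {"linear", "log10"}, optional
        Per-parameter search scale.  Default: ``log10`` whenever a parameter's
        bounds are positive and span more than two decades, else linear.
    nominal : array-like, optional
        Nominal (data-generating) parameter vector, attached as metadata.
    default_horizon : (t0, t_end)
        Default simulation horizon.
    n_points : int
        Default number of measurement points per experiment.
    """

    name: str
    state_names: tuple
    param_names: tuple
    rhs: tuple
    observations: dict
    default_x0: np.ndarray
    bounds: tuple
    search_scale: tuple = None
    nominal: np.ndarray = None
    default_horizon: tuple = (0.0, 10.0)
    n_points: int = 20
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.state_names = tuple(self.state_names)
        self.param_names = tuple(self.param_names)
        allowed = set(self.state_names) | set(self.param_names) | {"t"}
        # explicit symbol table so names like beta/gamma parse as plain
        # symbols, not sympy special functions
        symtab = {n: sp.Symbol(n) for n in allowed}
        self.rhs = tuple(sp.sympify(e, locals=symtab, rational=False)
                         for e in self.rhs)
        if len(self.rhs) != len(self.state_names):
            raise ValueError(
                f"model '{self.name}': {len(self.rhs)} rhs expressions for "
                f"{len(self.state_names)} states"
            )
        obs = {}
        for variant, omap in self.observations.items():
            obs[variant] = {k: sp.sympify(v, locals=symtab, rational=False)
                            for k, v in omap.items()}
            if len(obs[variant]) < 1:
                raise ValueError(f"observation variant '{variant}' is empty")
        self.observations = obs
        for expr in list(self.rhs) + [e for m in obs.values() for e in m.values()]:
            unknown = {str(s) for s in expr.free_symbols} - allowed
            if unknown:
                raise ValueError(
                    f"model '{self.name}': unknown symbols {sorted(unknown)} in {expr}"
                )
        self.default_x0 = np.asarray(self.default_x0, dtype=float)
        lo = np.asarray(self.bounds[0], dtype=float)
        hi = np.asarray(self.bounds[1], dtype=float)
        if lo.shape != hi.shape or lo.size != self.n_params:
            raise ValueError("bounds must both have length N_theta")
        if np.any(lo >= hi):
            raise ValueError("require theta_min < theta_max componentwise")
        self.bounds = (lo, hi)
        if self.search_scale is None:
            self.search_scale = tuple(
                "log10" if (l > 0 and h / l > 100.0) else "linear"
                for l, h in zip(lo, hi)
            )
        else:
            self.search_scale = tuple(self.search_scale)
        for s, l in zip(self.search_scale, lo):
            if s == "log10" and l <= 0:
                raise ValueError("log10-scaled parameters require theta_min > 0")
        if self.nominal is not None:
            self.nominal = np.asarray(self.nominal, dtype=float)
        self._compiled = None

    # -- basic dimensions -------------------------------------------------
    @property
    def n_states(self):
        return len(self.state_names)

    @property
    def n_params(self):
        return len(self.param_names)

    def n_observables(self, variant="fitting"):
        return len(self.observations[self.resolve_variant(variant)])

    def observable_names(self, variant="fitting"):
        return tuple(self.observations[self.resolve_variant(variant)].keys())

    def resolve_variant(self, variant):
        """Map a requested observation variant to one the model defines.

        Requesting ``validation`` on a model without a dedicated validation
        map falls back to ``fitting`` with a warning (they are identical).
        """
        if variant in self.observations:
            return variant
        if variant == "validation" and "fitting" in self.observations:
            warnings.warn(
                f"model '{self.name}' has no separate validation observables; "
                "using the fitting variant",
                stacklevel=2,
            )
            return "fitting"
        raise KeyError(f"model '{self.name}' has no observation variant '{variant}'")

    # -- compiled numerics ------------------------------------------------
    @property
    def compiled(self):
        if self._compiled is None:
            self._compiled = _CompiledModel(self)
        return self._compiled


class _CompiledModel:
    """Lambdified rhs/observation functions and their symbolic Jacobians."""

    def __init__(self, model):
        xs = _as_symbols(model.state_names)
        ps = _as_symbols(model.param_names)
        args = (_TIME, *xs, *ps)
        f_mat = sp.Matrix(model.rhs)
        jac_x = f_mat.jacobian(xs)
        jac_p = f_mat.jacobian(ps)
        for mat in (jac_x, jac_p):
            if mat.has(sp.Derivative):
                bad = [e for e in mat if e.has(sp.Derivative)]
                raise ValueError(f"expression not differentiable symbolically: {bad[0]}")
        # scalar 'math' lambdification: lowest per-call overhead inside LSODA
        self.f = sp.lambdify(args, list(model.rhs), modules="math")
        self.jac_x = sp.lambdify(args, jac_x.tolist(), modules="math")
        self.jac_p = sp.lambdify(args, jac_p.tolist(), modules="math")
        self.obs = {}
        for variant, omap in model.observations.items():
            exprs = list(omap.values())
            g_mat = sp.Matrix(exprs)
            self.obs[variant] = (
                sp.lambdify(args, exprs, modules="numpy"),
                sp.lambdify(args, g_mat.jacobian(xs).tolist(), modules="math"),
                sp.lambdify(args, g_mat.jacobian(ps).tolist(), modules="math"),
            )


@dataclass
class Trajectory:
    """A solved trajectory on a time grid, with mapped observables.

    ``status`` is ``"ok"`` or ``"infeasible"``; ``fraction_solved`` records how
    far the integrator got before failing (1.0 on success).
    """

    times: np.ndarray
    states: np.ndarray
    observables: np.ndarray
    observable_names: tuple
    status: str = "ok"
    fraction_solved: float = 1.0

    @property
    def ok(self):
        return self.status == "ok"


@dataclass
class SensitivityTrajectory:
    """Forward parametric sensitivities along a trajectory.

    ``dx_dtheta`` has shape ``(N_t, N_x, N_theta)`` and ``dy_dtheta``
    ``(N_t, N_y, N_theta)``; at ``t0`` the state block is all zero because the
    initial condition does not depend on the parameters.
    """

    dx_dtheta: np.ndarray
    dy_dtheta: np.ndarray


def _check_bounds(model, theta):
    lo, hi = model.bounds
    theta = np.asarray(theta, dtype=float)
    tol = 1e-9 * (np.abs(lo) + np.abs(hi))
    if np.any(theta < lo - tol) or np.any(theta > hi + tol):
        warnings.warn(
            f"parameter vector outside bounds for model '{model.name}'", stacklevel=3
        )
    return theta


def _observe(model, variant, times, states, theta):
    g, _, _ = model.compiled.obs[variant]
    cols = states.T  # each row of cols is one state's series
    raw = g(times, *cols, *theta)
    out = np.empty((len(times), len(raw)))
    for j, col in enumerate(raw):
        out[:, j] = np.broadcast_to(np.asarray(col, dtype=float), times.shape)
    return out


def _integrate(rhs, dfun, x0, times, rtol, atol):
    """odeint wrapper returning (values, ok, fraction_solved)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            out, info = odeint(
                rhs,
                x0,
                times,
                Dfun=dfun,
                rtol=rtol,
                atol=atol,
                full_output=True,
                mxstep=100000,
            )
        except Exception:
            return None, False, 0.0
    ok = (
        info["message"] == "Integration successful."
        and np.all(np.isfinite(out))
        and np.max(np.abs(out)) < _BLOWUP
    )
    if ok:
        return out, True, 1.0
    span = times[-1] - times[0]
    tcur = float(info["tcur"][-1]) if len(info.get("tcur", [])) else times[0]
    frac = min(max((tcur - times[0]) / span, 0.0), 1.0) if span > 0 else 0.0
    return out, False, frac


def simulate(model, theta, x0=None, times=None, rtol=1e-8, atol=1e-10,
             variant="fitting"):
    """Solve the initial-value problem and map states to observables.

    Integration failures (blow-up, step-size underflow, domain errors in the
    rhs) never raise: the returned :class:`Trajectory` is flagged
    ``infeasible`` and downstream costs convert it into a penalty.
    """
    theta = _check_bounds(model, theta)
    variant = model.resolve_variant(variant)
    if x0 is None:
        x0 = model.default_x0
    x0 = np.asarray(x0, dtype=float)
    if times is None:
        t0, tend = model.default_horizon
        times = np.linspace(t0, tend, 201)
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or (len(times) > 1 and np.any(np.diff(times) <= 0)):
        raise ValueError("times must be a strictly increasing 1-D grid")
    names = model.observable_names(variant)
    if len(times) == 1:
        states = x0[None, :]
        return Trajectory(times, states, _observe(model, variant, times, states, theta),
                          names)

    f = model.compiled.f
    jx = model.compiled.jac_x
    th = tuple(float(v) for v in theta)
    nx = model.n_states

    def rhs(x, t):
        try:
            return f(t, *x, *th)
        except (ValueError, OverflowError, ZeroDivisionError):
            return [math.nan] * nx

    def dfun(x, t):
        try:
            return jx(t, *x, *th)
        except (ValueError, OverflowError, ZeroDivisionError):
            return [[math.nan] * nx for _ in range(nx)]

    out, ok, frac = _integrate(rhs, dfun, x0, times, rtol, atol)
    if not ok:
        states = out if out is not None else np.full((len(times), nx), np.nan)
        states = np.where(np.isfinite(states), states, np.nan)
        obs = np.full((len(times), len(names)), np.nan)
        return Trajectory(times, states, obs, names, status="infeasible",
                          fraction_solved=frac)
    return Trajectory(times, out, _observe(model, variant, times, out, theta), names)


def simulate_with_sensitivities(model, theta, x0=None, times=None, rtol=1e-8,
                                atol=1e-10, variant="fitting"):
    """Integrate states jointly with the forward sensitivity system.

    The sensitivities solve ``dS/dt = (df/dx) S + df/dtheta`` with
    ``S(t0) = 0``; observable sensitivities follow from the chain rule
    ``dy/dtheta = (dg/dx) S + dg/dtheta``.
    """
    theta = _check_bounds(model, theta)
    variant = model.resolve_variant(variant)
    if x0 is None:
        x0 = model.default_x0
    x0 = np.asarray(x0, dtype=float)
    if times is None:
        t0, tend = model.default_horizon
        times = np.linspace(t0, tend, 201)
    times = np.asarray(times, dtype=float)

    comp = model.compiled
    th = tuple(float(v) for v in theta)
    nx, np_ = model.n_states, model.n_params
    names = model.observable_names(variant)
    ny = len(names)

    if len(times) == 1:
        states = x0[None, :]
        traj = Trajectory(times, states, _observe(model, variant, times, states, theta),
                          names)
        dx = np.zeros((1, nx, np_))
        _, gx, gp = comp.obs[variant]
        dy = (np.asarray(gx(times[0], *x0, *th), float) @ dx[0]
              + np.asarray(gp(times[0], *x0, *th), float))[None, :, :]
        return traj, SensitivityTrajectory(dx, dy)

    f, jx, jp = comp.f, comp.jac_x, comp.jac_p

    def aug_rhs(z, t):
        x = z[:nx]
        try:
            fx = f(t, *x, *th)
            Jx = np.asarray(jx(t, *x, *th), dtype=float)
            Jp = np.asarray(jp(t, *x, *th), dtype=float)
        except (ValueError, OverflowError, ZeroDivisionError):
            return np.full(z.size, np.nan)
        S = z[nx:].reshape(nx, np_)
        return np.concatenate([np.asarray(fx, float), (Jx @ S + Jp).ravel()])

    z0 = np.concatenate([x0, np.zeros(nx * np_)])
    out, ok, frac = _integrate(aug_rhs, None, z0, times, rtol, atol)
    if not ok:
        states = np.full((len(times), nx), np.nan)
        obs = np.full((len(times), ny), np.nan)
        traj = Trajectory(times, states, obs, names, status="infeasible",
                          fraction_solved=frac)
        return traj, SensitivityTrajectory(
            np.full((len(times), nx, np_), np.nan),
            np.full((len(times), ny, np_), np.nan),
        )
    states = out[:, :nx]
    dx = out[:, nx:].reshape(len(times), nx, np_)
    traj = Trajectory(times, states, _observe(model, variant, times, states, theta),
                      names)
    _, gx, gp = comp.obs[variant]
    dy = np.empty((len(times), ny, np_))
    for i, t in enumerate(times):
        Gx = np.asarray(gx(t, *states[i], *th), dtype=float)
        Gp = np.asarray(gp(t, *states[i], *th), dtype=float)
        dy[i] = Gx @ dx[i] + Gp
    return traj, SensitivityTrajectory(dx, dy)


def detect_sustained_oscillations(model, theta, x0=None, horizon=None,
                                  state_index=0, n_grid=4001, rtol=1e-8,
                                  atol=1e-10):
    """Classify the long-run behaviour of one state as sustained / damped / steady.

    The model is simulated over ``horizon`` (default: ten times the model's
    default horizon, so that it covers many putative periods), the first half
    is discarded as transient, and peaks are located in the remaining window.
    The trajectory is *sustained* if at least three peaks remain and the last
    peak-to-trough amplitude is at least 95% of the first; *steady* if the
    window's amplitude is below ``1e-6`` of the overall signal scale; else
    *damped*.  Returns ``{"classification": ..., "period": ...}`` where the
    period is the mean peak-to-peak spacing (None unless sustained).
    """
    if horizon is None:
        t0, tend = model.default_horizon
        horizon = (t0, t0 + 10.0 * (tend - t0))
    times = np.linspace(horizon[0], horizon[1], n_grid)
    traj = simulate(model, theta, x0=x0, times=times, rtol=rtol, atol=atol)
    if not traj.ok:
        return {"classification": "infeasible", "period": None}
    signal = traj.states[:, state_index]
    scale = max(float(np.max(np.abs(signal))), 1e-300)
    half = len(signal) // 2
    w = signal[half:]
    tw = times[half:]
    amp_window = float(np.max(w) - np.min(w))
    if amp_window < 1e-6 * scale:
        return {"classification": "steady", "period": None}
    prominence = 1e-6 * amp_window
    peaks, _ = find_peaks(w, prominence=prominence)
    troughs, _ = find_peaks(-w, prominence=prominence)
    if len(peaks) < 3 or len(troughs) < 2:
        return {"classification": "damped", "period": None}
    m = min(len(peaks), len(troughs))
    amps = w[peaks[:m]] - w[troughs[:m]]
    amps = amps[amps > 0]
    if len(amps) < 2 or amps[-1] < 0.95 * amps[0]:
        return {"classification": "damped", "period": None}
    period = float(np.mean(np.diff(tw[peaks])))
    return {"classification": "sustained", "period": period}
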