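"""Cost functions, goodness-of-fit metrics and FIM-based uncertainty statistics.

The estimation cost is the weighted nonlinear least squares criterion

    Q_NLS(theta) = sum_kji ((y_kji(theta) - ytilde_kji) / sigma_kji)^2 = r'r,

equivalent (for known Gaussian noise) to maximum likelihood.  A Tikhonov
penalty Gamma(theta) = (theta - theta_ref)' W'W (theta - theta_ref) with
W = diag(1/theta_ref) can be added as Q_R = Q_NLS + alpha * Gamma.

Post-fit statistics build the Fisher information matrix from the observable
sensitivities at the estimate, FIM = J' inv(Sigma) J, and derive confidence
intervals, coefficients of variation and the parameter correlation matrix
from its (eigenvalue-thresholded) pseudo-inverse.
"""
from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .models import (
    PENALTY_COST,
    simulate,
    simulate_with_sensitivities,
)

__all__ = [
    "Experiment",
    "ExperimentData",
    "CostResult",
    "nls_cost",
    "log_likelihood",
    "regularisation_penalty",
    "regularised_cost",
    "nrmse",
    "nrmse_from_values",
    "fit_statistics",
    "FitStatistics",
]

_CSV_COLUMNS = ["experiment", "observable", "time", "value", "sigma"]


@dataclass
class Experiment:
    """One experiment: an initial condition plus measured time series.

    ``observations`` is a DataFrame with columns
    ``observable, time, value, sigma`` (one row per measured point).
    """

    name: str
    x0: np.ndarray
    observations: pd.DataFrame

    def __post_init__(self):
        self.x0 = np.asarray(self.x0, dtype=float)
        df = self.observations
        missing = set(_CSV_COLUMNS[1:]) - set(df.columns)
        if missing:
            raise ValueError(f"experiment '{self.name}' missing columns {missing}")
        if df[["time", "value", "sigma"]].isna().any().any():
            raise ValueError(f"experiment '{self.name}' contains NaN measurements")
        if (df["sigma"] <= 0).any():
            raise ValueError(f"experiment '{self.name}' has non-positive sigma")

    @property
    def n_points(self):
        return len(self.observations)


@dataclass
class ExperimentData:
    """A dataset: a list of experiments sharing an observation variant."""

    experiments: list
    variant: str = "fitting"

    def __post_init__(self):
        if self.n_residuals == 0:
            raise ValueError("dataset contains no measurements")

    @property
    def n_residuals(self):
        return sum(e.n_points for e in self.experiments)

    def validate_against(self, model):
        names = set(model.observable_names(self.variant))
        for e in self.experiments:
            bad = set(e.observations["observable"]) - names
            if bad:
                raise ValueError(
                    f"experiment '{e.name}' references observables {sorted(bad)} "
                    f"absent from variant '{self.variant}'"
                )
            if len(e.x0) != model.n_states:
                raise ValueError(f"experiment '{e.name}' x0 has wrong length")

    # -- CSV round trip ---------------------------------------------------
    def to_csv(self, path):
        frames = []
        for e in self.experiments:
            df = e.observations.copy()
            df.insert(0, "experiment", e.name)
            frames.append(df[_CSV_COLUMNS])
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, x0, variant="fitting"):
        """Load a dataset CSV (columns experiment,observable,time,value,sigma).

        ``x0`` is either a single initial-state vector (shared by all
        experiments) or a mapping ``{experiment_name: x0}``.
        """
        df = pd.read_csv(path)
        missing = set(_CSV_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"dataset CSV missing columns {missing}")
        experiments = []
        for name, sub in df.groupby("experiment", sort=False):
            exp_x0 = x0[name] if isinstance(x0, dict) else x0
            experiments.append(
                Experiment(str(name), exp_x0, sub.drop(columns="experiment")
                           .reset_index(drop=True))
            )
        return cls(experiments, variant=variant)


@dataclass
class CostResult:
    """Outcome of one cost evaluation.

    ``residuals`` is None when any experiment's simulation was infeasible, in
    which case ``cost`` is the penalty sentinel.
    """

    cost: float
    residuals: np.ndarray = None

    @property
    def feasible(self):
        return self.residuals is not None


def _experiment_grid(exp):
    """Union time grid for an experiment plus per-row indices into it."""
    times = np.unique(exp.observations["time"].to_numpy(dtype=float))
    idx = np.searchsorted(times, exp.observations["time"].to_numpy(dtype=float))
    return times, idx


def _simulate_experiment(model, theta, exp, variant, rtol, atol, with_sens=False):
    times, idx = _experiment_grid(exp)
    if with_sens:
        traj, sens = simulate_with_sensitivities(
            model, theta, x0=exp.x0, times=times, rtol=rtol, atol=atol,
            variant=variant)
        return traj, sens, times, idx
    traj = simulate(model, theta, x0=exp.x0, times=times, rtol=rtol, atol=atol,
                    variant=variant)
    return traj, None, times, idx


def _rows_to_matrix_entries(model, variant, exp):
    names = list(model.observable_names(variant))
    cols = exp.observations["observable"].map(names.index).to_numpy()
    return cols


def nls_cost(model, theta, data, rtol=1e-8, atol=1e-10):
    """Weighted least-squares cost and stacked weighted residual vector.

    One simulation per experiment (at that experiment's initial condition);
    infeasible simulations yield ``PENALTY_COST + fraction unsolved`` so a
    global search can continue past non-integrable regions.
    """
    data.validate_against(model)
    variant = model.resolve_variant(data.variant)
    residuals = []
    for exp in data.experiments:
        traj, _, _, idx = _simulate_experiment(model, theta, exp, variant, rtol, atol)
        if not traj.ok:
            return CostResult(PENALTY_COST + (1.0 - traj.fraction_solved))
        cols = _rows_to_matrix_entries(model, variant, exp)
        y = traj.observables[idx, cols]
        obs = exp.observations
        residuals.append((y - obs["value"].to_numpy()) / obs["sigma"].to_numpy())
    r = np.concatenate(residuals)
    if not np.all(np.isfinite(r)):
        return CostResult(PENALTY_COST + 1.0)
    return CostResult(float(r @ r), r)


def log_likelihood(model, theta, data, rtol=1e-8, atol=1e-10):
    """Gaussian log-likelihood; monotone decreasing in Q_NLS for fixed sigma."""
    res = nls_cost(model, theta, data, rtol=rtol, atol=atol)
    sig = np.concatenate(
        [e.observations["sigma"].to_numpy(dtype=float) for e in data.experiments]
    )
    return -0.5 * res.cost - float(np.sum(np.log(sig * math.sqrt(2.0 * math.pi))))


def regularisation_penalty(theta, theta_ref):
    """Tikhonov penalty Gamma = sum_i ((theta_i - theta_ref_i)/theta_ref_i)^2.

    The diagonal weighting W = diag(1/theta_ref) makes Gamma invariant under
    per-parameter unit rescaling, so no parameter dominates by scale alone.
    """
    theta = np.asarray(theta, dtype=float)
    theta_ref = np.asarray(theta_ref, dtype=float)
    if np.any(theta_ref == 0):
        raise ValueError("theta_ref components must be nonzero (W undefined)")
    z = (theta - theta_ref) / theta_ref
    return float(z @ z)


def regularised_cost(model, theta, data, alpha, theta_ref, rtol=1e-8, atol=1e-10):
    """Q_R = Q_NLS + alpha * Gamma; alpha = 0 recovers the plain NLS cost."""
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    res = nls_cost(model, theta, data, rtol=rtol, atol=atol)
    return res.cost + alpha * regularisation_penalty(theta, theta_ref)


def nrmse_from_values(series):
    """Range-normalised RMSE over a list of (y_sim, y_meas) series.

    Each residual is normalised by the measured range of its own
    observable-within-experiment series; the squared normalised residuals are
    pooled over all series and divided by the total point count before the
    single outer square root.  Series with zero measured range are excluded
    (with a warning), reducing the pooled count accordingly.
    """
    total = 0.0
    n = 0
    for y_sim, y_meas in series:
        y_sim = np.asarray(y_sim, dtype=float)
        y_meas = np.asarray(y_meas, dtype=float)
        rng = float(np.max(y_meas) - np.min(y_meas))
        if rng <= 0:
            warnings.warn("constant measured series excluded from NRMSE",
                          stacklevel=2)
            continue
        total += float(np.sum(((y_sim - y_meas) / rng) ** 2))
        n += len(y_meas)
    if n == 0:
        raise ValueError("no series with positive measured range")
    return math.sqrt(total / n)


def nrmse(model, theta, data, rtol=1e-8, atol=1e-10, penalty_clip=None):
    """Range-normalised root mean square error of the model against a dataset.

    Infeasible simulations are scored by clipping the simulated values at the
    penalty sentinel (``penalty_clip``, default the measured value plus the
    measured range) and flagged with a warning, never raised.
    """
    data.validate_against(model)
    variant = model.resolve_variant(data.variant)
    series = []
    for exp in data.experiments:
        traj, _, _, idx = _simulate_experiment(model, theta, exp, variant, rtol, atol)
        cols = _rows_to_matrix_entries(model, variant, exp)
        obs = exp.observations
        if traj.ok:
            y = traj.observables[idx, cols]
        else:
            warnings.warn(
                f"infeasible simulation for experiment '{exp.name}' at theta; "
                "scored at the penalty level", stacklevel=2)
            meas = obs["value"].to_numpy(dtype=float)
            shift = penalty_clip if penalty_clip is not None else np.ptp(meas)
            y = meas + (shift if shift > 0 else 1.0)
        for oname, sub_idx in obs.groupby("observable", sort=False).groups.items():
            loc = obs.index.get_indexer(sub_idx)
            series.append((y[loc], obs["value"].to_numpy()[loc]))
    return nrmse_from_values(series)


@dataclass
class FitStatistics:
    """FIM-based uncertainty and goodness-of-fit summary at an estimate."""

    theta: np.ndarray
    param_names: tuple
    nrmse: float
    r_squared: dict
    chi2_stat: float
    chi2_pvalue: float
    chi2_dof: int
    fim: np.ndarray
    covariance: np.ndarray
    ci95: np.ndarray
    cv_percent: np.ndarray
    correlation: np.ndarray
    bounds_status: tuple
    n_residuals: int = 0
    warnings_: list = field(default_factory=list)

    def to_dict(self):
        return {
            "theta": list(map(float, self.theta)),
            "param_names": list(self.param_names),
            "nrmse": self.nrmse,
            "r_squared": self.r_squared,
            "chi2_stat": self.chi2_stat,
            "chi2_pvalue": self.chi2_pvalue,
            "chi2_dof": self.chi2_dof,
            "fim": self.fim.tolist(),
            "covariance": self.covariance.tolist(),
            "ci95": self.ci95.tolist(),
            "cv_percent": self.cv_percent.tolist(),
            "correlation": self.correlation.tolist(),
            "bounds_status": list(self.bounds_status),
            "n_residuals": self.n_residuals,
            "warnings": list(self.warnings_),
        }

    def to_json(self, path):
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def pseudo_inverse(mat, rel_threshold=1e-12):
    """Symmetric pseudo-inverse with eigenvalues below rel_threshold*lambda_max
    treated as zero.  Returns (inverse, rank_deficient_flag)."""
    w, v = np.linalg.eigh((mat + mat.T) / 2.0)
    lam_max = float(np.max(np.abs(w))) if len(w) else 0.0
    cut = rel_threshold * lam_max
    keep = np.abs(w) > cut
    inv_w = np.where(keep, 1.0 / np.where(keep, w, 1.0), 0.0)
    return (v * inv_w) @ v.T, bool(np.any(~keep)) or lam_max == 0.0


def _bounds_status(model, theta):
    lo, hi = model.bounds
    out = []
    for j, (th, l, h, sc) in enumerate(
            zip(theta, lo, hi, model.search_scale)):
        if sc == "log10":
            width = math.log10(h) - math.log10(l)
            d_lo = (math.log10(max(th, 1e-300)) - math.log10(l)) / width
            d_hi = (math.log10(h) - math.log10(max(th, 1e-300))) / width
        else:
            width = h - l
            d_lo = (th - l) / width
            d_hi = (h - th) / width
        if d_lo <= 1e-3:
            out.append("Active at lower bound")
        elif d_hi <= 1e-3:
            out.append("Active at upper bound")
        else:
            out.append("Bounds not active")
    return tuple(out)


def fit_statistics(model, theta_hat, data, rtol=1e-8, atol=1e-10,
                   dof_mode="n_minus_p", use_t=False):
    """Post-fit statistics at an estimate: FIM, CIs, CVs, correlations, fit metrics.

    FIM = J' inv(Sigma) J with J the stacked observable-sensitivity matrix at
    the measurement points and Sigma = diag(sigma^2).  The covariance is the
    eigenvalue-thresholded pseudo-inverse of the FIM (a singular FIM warns
    about local non-identifiability rather than crashing); 95% intervals use
    the normal quantile 1.96 by default (Student-t via ``use_t``).  The chi^2
    statistic is Q_NLS at the estimate with ``n - N_theta`` degrees of freedom
    by default (``dof_mode="n"`` uses n).
    """
    data.validate_against(model)
    variant = model.resolve_variant(data.variant)
    theta_hat = np.asarray(theta_hat, dtype=float)
    notes = []
    rows_J, rows_r = [], []
    series = {}
    for exp in data.experiments:
        traj, sens, _, idx = _simulate_experiment(
            model, theta_hat, exp, variant, rtol, atol, with_sens=True)
        if not traj.ok:
            raise RuntimeError(
                f"infeasible simulation at the estimate for experiment '{exp.name}'")
        cols = _rows_to_matrix_entries(model, variant, exp)
        obs = exp.observations
        sig = obs["sigma"].to_numpy(dtype=float)
        y = traj.observables[idx, cols]
        rows_J.append(sens.dy_dtheta[idx, cols, :] / sig[:, None])
        rows_r.append((y - obs["value"].to_numpy()) / sig)
        for oname, sub_idx in obs.groupby("observable", sort=False).groups.items():
            loc = obs.index.get_indexer(sub_idx)
            series.setdefault(oname, []).append(
                (y[loc], obs["value"].to_numpy()[loc]))
    J = np.vstack(rows_J)
    r = np.concatenate(rows_r)
    n = len(r)
    fim = J.T @ J
    cov, deficient = pseudo_inverse(fim)
    if deficient:
        notes.append("parameters locally non-identifiable (singular FIM)")
        warnings.warn(notes[-1], stacklevel=2)
    var = np.clip(np.diag(cov), 0.0, None)
    sd = np.sqrt(var)
    dof = n - model.n_params if dof_mode == "n_minus_p" else n
    q = float(sps.t.ppf(0.975, max(dof, 1))) if use_t else 1.96
    ci95 = q * sd
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = 100.0 * sd / np.abs(theta_hat)
        denom = np.sqrt(np.outer(var, var))
        corr = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), 0.0)
    np.fill_diagonal(corr, 1.0)
    chi2_stat = float(r @ r)
    if dof > 0:
        chi2_p = float(sps.chi2.sf(chi2_stat, dof))
    else:
        chi2_p = float("nan")
        notes.append("chi2 test skipped: non-positive degrees of freedom")
    r2 = {}
    for oname, lst in series.items():
        y_all = np.concatenate([a for a, _ in lst])
        m_all = np.concatenate([b for _, b in lst])
        ss_tot = float(np.sum((m_all - m_all.mean()) ** 2))
        ss_res = float(np.sum((y_all - m_all) ** 2))
        r2[oname] = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    all_series = [pair for lst in series.values() for pair in lst]
    try:
        nrmse_val = nrmse_from_values(all_series)
    except ValueError:  # every series constant (e.g. single-point data)
        nrmse_val = float("nan")
        notes.append("NRMSE undefined: no series with positive measured range")
    return FitStatistics(
        theta=theta_hat,
        param_names=model.param_names,
        nrmse=nrmse_val,
        r_squared=r2,
        chi2_stat=chi2_stat,
        chi2_pvalue=chi2_p,
        chi2_dof=dof,
        fim=fim,
        covariance=cov,
        ci95=ci95,
        cv_percent=cv,
        correlation=corr,
        bounds_status=_bounds_status(model, theta_hat),
        n_residuals=n,
        warnings_=notes,
    )
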