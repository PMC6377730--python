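"""Two-phase regularised estimation pipeline.

:class:`TwoPhaseEstimator` is the model-like entry point: construct it from a
:class:`~oscifit.models.DynamicModel`, a fitting dataset and (optionally) a
cross-validation dataset, then call :meth:`fit`.  The workflow is

1. phase-1 global scatter search on the plain weighted least-squares cost,
   archiving every evaluation;
2. per-parameter cost cut-offs from the archive, then reduction of the
   parameter bounds;
3. automatic tuning of the Tikhonov weight ``alpha`` and reference
   ``theta_ref`` from the accepted samples;
4. phase-2 scatter search on the regularised cost inside the reduced bounds;
5. post-fit statistics (FIM-based intervals, NRMSE, R^2, chi^2), collinearity
   diagnostics and cross-validation of both estimates.

:meth:`fit` returns a :class:`TwoPhaseResults` carrying both the unregularised
estimate ``theta_I`` and the regularised estimate ``theta_R`` with their
statistics; ``summary()`` renders the usual text table.
"""
from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .bounding import ReducedBounds, cost_cutoffs, reduce_bounds
from .identifiability import collinearity_indices
from .models import simulate_with_sensitivities
from .objective import ExperimentData, fit_statistics, nls_cost, nrmse
from .regularise import tune_regularisation
from .scatter import (
    EssConfig,
    NLSObjective,
    RegularisedObjective,
    ess_minimize,
    local_refine,
)

__all__ = ["PipelineConfig", "TwoPhaseEstimator", "TwoPhaseResults",
           "crossval_nrmse"]


@dataclass
class PipelineConfig:
    """Configuration of the full two-phase workflow.

    Evaluation budgets default to ``5000 * N_theta`` (capped at 200000) for
    phase 1 and half of that for phase 2; desk-scale runs typically pass much
    smaller budgets.
    """

    phase1_max_evals: int = None
    phase2_max_evals: int = None
    refset_size: int = None
    diverse_size: int = None
    local_every: int = 8
    local_budget: int = 150
    go_beyond: bool = True
    stall_limit: int = 12
    rtol: float = 1e-8
    atol: float = 1e-10
    cutoff_method: str = "knee"            # knee | percentile
    snap_powers_of_ten: bool = True
    expand_fraction: float = 0.1
    theta_ref_mode: str = "consensus"      # consensus | phase1_optimum
    collinearity_threshold: float = 20.0
    collinearity_max_subset: int = 4
    dof_mode: str = "n_minus_p"
    use_t: bool = False
    structural_id_verdict: str = "not checked"

    def budgets(self, n_params):
        p1 = self.phase1_max_evals
        if p1 is None:
            p1 = min(5000 * n_params, 200000)
        p2 = self.phase2_max_evals
        if p2 is None:
            p2 = p1 // 2
        return p1, p2

    def ess_config(self, max_evals):
        return EssConfig(
            max_evals=max_evals,
            refset_size=self.refset_size,
            diverse_size=self.diverse_size,
            local_every=self.local_every,
            local_budget=self.local_budget,
            go_beyond=self.go_beyond,
            stall_limit=self.stall_limit,
        )


@dataclass
class TwoPhaseResults:
    """Both estimates with their statistics, diagnostics and provenance."""

    model_name: str
    param_names: tuple
    theta_I: np.ndarray
    theta_R: np.ndarray
    cost_I: float                 # Q_NLS at theta_I
    cost_R_nls: float             # Q_NLS at theta_R
    cost_R: float                 # Q_R at theta_R
    cutoffs: object
    reduced_bounds: ReducedBounds
    regularisation: object
    fit_stats_I: object
    fit_stats_R: object
    crossval_nrmse_I: float
    crossval_nrmse_R: float
    collinearity: object
    archive_phase1: object
    archive_phase2: object
    seed: int
    config: PipelineConfig
    timings: dict = field(default_factory=dict)

    def summary(self):
        lines = []
        w = 78
        lines.append("=" * w)
        lines.append(f"Two-phase regularised estimation: {self.model_name}")
        lines.append("=" * w)
        lines.append(
            f"phase-1 evals: {self.archive_phase1.n_evals}   "
            f"phase-2 evals: {self.archive_phase2.n_evals}   seed: {self.seed}")
        lines.append(
            f"Q_NLS(theta_I) = {self.cost_I:.6g}   "
            f"Q_NLS(theta_R) = {self.cost_R_nls:.6g}   "
            f"Q_R(theta_R) = {self.cost_R:.6g}")
        lines.append(
            f"alpha = {self.regularisation.alpha:.6g}")
        lines.append("-" * w)
        hdr = (f"{'parameter':<12}{'theta_I':>12}{'theta_R':>12}{'ci95':>12}"
               f"{'cv %':>10}  bounds status")
        lines.append(hdr)
        st = self.fit_stats_R
        for j, name in enumerate(self.param_names):
            lines.append(
                f"{name:<12}{self.theta_I[j]:>12.5g}{self.theta_R[j]:>12.5g}"
                f"{st.ci95[j]:>12.3g}{st.cv_percent[j]:>10.3g}  "
                f"{st.bounds_status[j]}")
        lines.append("-" * w)
        lines.append(f"{'reduced bounds':<16}" + "  ".join(
            f"[{lo:.3g}, {hi:.3g}]" for lo, hi in
            zip(self.reduced_bounds.lower, self.reduced_bounds.upper)))
        lines.append(
            f"fitting NRMSE:  theta_I {self.fit_stats_I.nrmse:.4f}   "
            f"theta_R {self.fit_stats_R.nrmse:.4f}")
        if self.crossval_nrmse_I is not None:
            lines.append(
                f"crossval NRMSE: theta_I {self.crossval_nrmse_I:.4f}   "
                f"theta_R {self.crossval_nrmse_R:.4f}")
        if self.collinearity is not None:
            if self.collinearity.identifiable:
                lines.append(
                    f"collinearity: no subset above threshold "
                    f"{self.collinearity.threshold:g} "
                    f"(max index {self.collinearity.max_index():.3g})")
            else:
                lines.append(
                    f"collinearity: {len(self.collinearity.flagged)} subsets "
                    f"above threshold {self.collinearity.threshold:g}")
        lines.append("=" * w)
        return "\n".join(lines)

    def to_dict(self):
        return {
            "schema_version": 1,
            "model": self.model_name,
            "param_names": list(self.param_names),
            "theta_I": self.theta_I.tolist(),
            "theta_R": self.theta_R.tolist(),
            "cost_I": self.cost_I,
            "cost_R_nls": self.cost_R_nls,
            "cost_R": self.cost_R,
            "cutoffs": self.cutoffs.to_dict(),
            "reduced_bounds": self.reduced_bounds.to_dict(),
            "regularisation": self.regularisation.to_dict(),
            "fit_stats_I": self.fit_stats_I.to_dict(),
            "fit_stats_R": self.fit_stats_R.to_dict(),
            "crossval_nrmse_I": self.crossval_nrmse_I,
            "crossval_nrmse_R": self.crossval_nrmse_R,
            "collinearity": (self.collinearity.to_dict()
                             if self.collinearity is not None else None),
            "archive_phase1_size": self.archive_phase1.n_evals,
            "archive_phase2_size": self.archive_phase2.n_evals,
            "seed": self.seed,
            "config": asdict(self.config),
            "timings": self.timings,
        }

    def save(self, out_dir):
        """Write result.json and both archives into ``out_dir``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "result.json", "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)
        self.archive_phase1.to_csv(out / "archive_phase1.csv")
        self.archive_phase2.to_csv(out / "archive_phase2.csv")
        with open(out / "summary.txt", "w", encoding="utf-8") as fh:
            fh.write(self.summary() + "\n")
        return out


def crossval_nrmse(model, theta, data, rtol=1e-8, atol=1e-10):
    """Pooled range-normalised RMSE of predictions on validation experiments.

    Each experiment is simulated from its own initial conditions at ``theta``
    using the dataset's observation variant; an infeasible simulation scores
    that experiment at the penalty level (flagged) instead of raising.
    """
    return nrmse(model, theta, data, rtol=rtol, atol=atol)


class TwoPhaseEstimator:
    """Estimator object binding a dynamic model to datasets.

    Parameters
    ----------
    model : DynamicModel
    data : ExperimentData or list of ExperimentData
        Fitting dataset(s); a list is merged into one dataset.
    crossval_data : ExperimentData or list, optional
        Validation experiments for overfitting assessment.
    config : PipelineConfig, optional
    """

    def __init__(self, model, data, crossval_data=None, config=None):
        self.model = model
        self.data = self._merge(data)
        self.crossval_data = (self._merge(crossval_data)
                              if crossval_data is not None else None)
        self.config = config or PipelineConfig()
        self.data.validate_against(model)
        if self.crossval_data is not None:
            self.crossval_data.validate_against(model)

    @staticmethod
    def _merge(data):
        if isinstance(data, ExperimentData):
            return data
        datasets = list(data)
        exps = [e for d in datasets for e in d.experiments]
        return ExperimentData(exps, variant=datasets[0].variant)

    @classmethod
    def from_csv(cls, model, data_csv, crossval_csv=None, x0=None,
                 crossval_x0=None, config=None):
        x0 = x0 if x0 is not None else model.default_x0
        data = ExperimentData.from_csv(data_csv, x0, variant="fitting")
        cv = None
        if crossval_csv is not None:
            variant = ("validation" if "validation" in model.observations
                       else "fitting")
            cv = ExperimentData.from_csv(
                crossval_csv, crossval_x0 if crossval_x0 is not None else x0,
                variant=variant)
        return cls(model, data, crossval_data=cv, config=config)

    # -----------------------------------------------------------------
    def fit(self, seed=0):
        """Run the full two-phase workflow; returns :class:`TwoPhaseResults`."""
        cfg = self.config
        model = self.model
        if cfg.structural_id_verdict == "not checked":
            warnings.warn(
                "structural identifiability not checked; run an external "
                "symbolic analysis and record the verdict in the config",
                stacklevel=2)
        timings = {}
        p1_budget, p2_budget = cfg.budgets(model.n_params)
        base_obj = NLSObjective(model, self.data, rtol=cfg.rtol, atol=cfg.atol)

        t0 = time.perf_counter()
        res1 = ess_minimize(base_obj, model.bounds,
                            cfg.ess_config(p1_budget), seed=seed,
                            scales=model.search_scale)
        theta_I = res1.theta
        cost_I = res1.cost
        timings["phase1"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        cutoffs = cost_cutoffs(
            res1.archive, scales=model.search_scale,
            fallback_quantile=0.25)
        if cfg.cutoff_method == "percentile":
            q = float(np.quantile(
                res1.archive.costs[res1.archive.costs < 1e9], 0.25))
            cutoffs.cutoffs[:] = q
            cutoffs.fallback = True
        reduced = reduce_bounds(
            res1.archive, cutoffs, model.bounds, theta_I,
            scales=model.search_scale,
            expand_fraction=cfg.expand_fraction,
            snap_powers_of_ten=cfg.snap_powers_of_ten)
        reg = tune_regularisation(
            res1.archive, cutoffs, reduced, theta_I,
            scales=model.search_scale, mode=cfg.theta_ref_mode)
        timings["bounding"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        reg_obj = RegularisedObjective(base_obj, reg.alpha, reg.theta_ref)
        res2 = ess_minimize(reg_obj, (reduced.lower, reduced.upper),
                            cfg.ess_config(p2_budget), seed=seed + 1,
                            scales=model.search_scale, x0=theta_I)
        theta_R = res2.theta
        cost_R = res2.cost
        qr_at_I = reg_obj.cost(theta_I)
        if qr_at_I < cost_R:
            warnings.warn(
                "phase-2 search did not improve on the phase-1 estimate "
                "under the regularised cost; keeping the better point",
                stacklevel=2)
            theta_R, cost_R = theta_I, qr_at_I
        cost_R_nls = nls_cost(model, theta_R, self.data,
                              rtol=cfg.rtol, atol=cfg.atol).cost
        if cost_R_nls < cost_I:
            # phase 2 stumbled on a better solution of the *unregularised*
            # problem; adopt it (refined under the plain cost) as theta_I so
            # the non-regularised estimate remains the best known data fit
            warnings.warn(
                "phase-2 search improved on the phase-1 data fit; updating "
                "the non-regularised estimate", stacklevel=2)
            theta_I, cost_I = local_refine(
                base_obj, theta_R, model.bounds, scales=model.search_scale,
                archive=res1.archive, max_nfev=cfg.local_budget)
        timings["phase2"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        stats_I = fit_statistics(model, theta_I, self.data, rtol=cfg.rtol,
                                 atol=cfg.atol, dof_mode=cfg.dof_mode,
                                 use_t=cfg.use_t)
        stats_R = fit_statistics(model, theta_R, self.data, rtol=cfg.rtol,
                                 atol=cfg.atol, dof_mode=cfg.dof_mode,
                                 use_t=cfg.use_t)
        cv_I = cv_R = None
        if self.crossval_data is not None:
            cv_I = crossval_nrmse(model, theta_I, self.crossval_data,
                                  rtol=cfg.rtol, atol=cfg.atol)
            cv_R = crossval_nrmse(model, theta_R, self.crossval_data,
                                  rtol=cfg.rtol, atol=cfg.atol)
        collin = self._collinearity(theta_R)
        timings["postfit"] = time.perf_counter() - t0

        share = (reg.alpha *
                 max(cost_R - cost_R_nls, 0.0) / cost_R if cost_R > 0 else 0.0)
        if cost_R > 0 and (cost_R - cost_R_nls) / cost_R > 0.5:
            warnings.warn("regularisation penalty dominates the phase-2 cost "
                          "(share > 50%)", stacklevel=2)
        return TwoPhaseResults(
            model_name=model.name,
            param_names=model.param_names,
            theta_I=theta_I,
            theta_R=theta_R,
            cost_I=cost_I,
            cost_R_nls=cost_R_nls,
            cost_R=cost_R,
            cutoffs=cutoffs,
            reduced_bounds=reduced,
            regularisation=reg,
            fit_stats_I=stats_I,
            fit_stats_R=stats_R,
            crossval_nrmse_I=cv_I,
            crossval_nrmse_R=cv_R,
            collinearity=collin,
            archive_phase1=res1.archive,
            archive_phase2=res2.archive,
            seed=seed,
            config=cfg,
            timings=timings,
        )

    def _collinearity(self, theta):
        cfg = self.config
        model = self.model
        variant = model.resolve_variant(self.data.variant)
        rows = []
        for exp in self.data.experiments:
            times = np.unique(exp.observations["time"].to_numpy(dtype=float))
            idx = np.searchsorted(
                times, exp.observations["time"].to_numpy(dtype=float))
            traj, sens = simulate_with_sensitivities(
                model, theta, x0=exp.x0, times=times, rtol=cfg.rtol,
                atol=cfg.atol, variant=variant)
            if not traj.ok:
                warnings.warn("infeasible simulation during collinearity "
                              "analysis; report skipped", stacklevel=2)
                return None
            names = list(model.observable_names(variant))
            cols = exp.observations["observable"].map(names.index).to_numpy()
            sig = exp.observations["sigma"].to_numpy(dtype=float)
            rows.append(sens.dy_dtheta[idx, cols, :] / sig[:, None])
        return collinearity_indices(
            np.vstack(rows), param_names=model.param_names,
            subset_max_size=cfg.collinearity_max_subset,
            threshold=cfg.collinearity_threshold)
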