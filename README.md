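# oscifit

Two-phase, automatically regularised parameter estimation for deterministic
nonlinear ODE models of biological oscillators.

Calibrating oscillator models (gene circuits, metabolic oscillators, spiking
neurons) to noisy time series is notoriously treacherous: the search boxes
are huge (often many decades per parameter), the weighted least-squares cost
landscape is heavily multimodal, small datasets invite overfitting, and
parameters are frequently only weakly identifiable. Plain local solvers —
even in multi-start fashion — converge to local optima or to overfit
solutions with excellent training cost and poor predictive power.

`oscifit` is aimed at modellers facing exactly that setting. It implements a
hands-off workflow:

1. **Global phase 1** — a hybrid enhanced-scatter-search metaheuristic
   minimises the weighted NLS cost `Q_NLS(θ) = Σ ((y−ỹ)/σ)² = rᵀr`, with
   gradient-based local refinement fed by analytic forward sensitivities,
   archiving *every* cost evaluation `(Θ, ζ)`.
2. **Parameter bounding** — per-parameter cost cut-offs (a deterministic
   knee detector on the cost-vs-spread curve) select the near-optimal
   samples; their hull, padded and snapped to powers of ten, becomes a
   reduced search box.
3. **Automatic Tikhonov tuning** — the penalty `Γ(θ) = (θ−θ_ref)ᵀWᵀW(θ−θ_ref)`
   with `W = diag(1/θ_ref)` is tuned from the same archive: `θ_ref` is the
   consensus of the accepted samples and the weight
   `α = median_j(ζ*_j − ζ_best)/Γ_max` makes the penalty at the edge of the
   acceptable region commensurate with the acceptable cost degradation.
4. **Regularised phase 2** — the search is re-run on `Q_R = Q_NLS + α·Γ`
   inside the reduced box.
5. **Post-fit analysis** — FIM-based confidence intervals, coefficients of
   variation and correlations, NRMSE/R²/χ² fit metrics, collinearity-index
   practical-identifiability diagnostics, and cross-validation of both the
   unregularised estimate θ̂_I and the regularised estimate θ̂_R on
   held-out experiments.

Four classic case studies ship with nominal parameters, published bounds and
measurement protocols: FitzHugh–Nagumo (`fhn`), the Goodwin oscillator
(`go`), the repressilator (`rp`) and an enzymatic oscillator (`eo`), plus a
synthetic-data generator reproducing the protocol (10% Gaussian noise,
detection threshold 0.1, 10 fitting and 10 cross-validation replicates).
Custom models can be declared in a small plain-text format (see
`oscifit.modeltext`).

See `docs/methods.md` for the algorithms, numerical choices and limitations.

## Worked example

Recover the FitzHugh–Nagumo parameters {a, b, g} = {0.2, 0.2, 3} from
noise-free observations of the membrane potential V (30 points on [0, 20]),
searching the full box `[1e-5, 1e5]` per parameter:

```python
from oscifit import (DataGenConfig, PipelineConfig, TwoPhaseEstimator,
                     build_case_study, generate_fitting_datasets)

model = build_case_study("fhn")
gen = DataGenConfig(noise_fraction=0.0, detection_threshold=None,
                    n_fitting_sets=1, n_points=30, horizon=(0.0, 20.0))
data = generate_fitting_datasets(model, config=gen, seed=1)[0]
cfg = PipelineConfig(phase1_max_evals=3000, phase2_max_evals=1500,
                     diverse_size=60, local_every=4, local_budget=120,
                     structural_id_verdict="externally verified")
res = TwoPhaseEstimator(model, data, config=cfg).fit(seed=1)
print(res.summary())
```

Output (about 15 s on one CPU):

```
==============================================================================
Two-phase regularised estimation: fhn
==============================================================================
phase-1 evals: 3003   phase-2 evals: 1511   seed: 1
Q_NLS(theta_I) = 1.47455e-23   Q_NLS(theta_R) = 0.0489524   Q_R(theta_R) = 0.425974
alpha = 3108.4
------------------------------------------------------------------------------
parameter        theta_I     theta_R        ci95      cv %  bounds status
a                    0.2     0.19979     0.00256     0.654  Bounds not active
b                    0.2     0.19943      0.0149      3.82  Bounds not active
g                      3      3.0004     0.00433    0.0736  Bounds not active
------------------------------------------------------------------------------
reduced bounds  [0.01, 1]  [0.01, 1]  [1, 10]
fitting NRMSE:  theta_I 0.0000   theta_R 0.0001
collinearity: no subset above threshold 20 (max index 3.57)
==============================================================================
```

Reading it: phase 1 found the zero-cost optimum (the data are noise-free, so
the generating parameters are recovered exactly — `theta_I` matches the
nominal values to machine precision). The sampling archive tightened each
ten-decade bound to two or one decades. The regularised estimate `theta_R`
deviates from the optimum by less than 0.3% — the tuned penalty trades a
tiny amount of fit (`Q_NLS` rises from ~0 to 0.05) for proximity to the
consensus of the good-fit region. The FIM-based 95% intervals are small, no
parameter sits at a bound, and no parameter subset exceeds the collinearity
threshold: the calibrated model is identifiable in practice.

The same workflow from the shell:

```sh
oscifit generate --model fhn --seed 1 --out datasets/
oscifit fit --model fhn --data datasets/fitting_1.csv \
    --crossval datasets/crossval_1.csv --manifest datasets/manifest.json \
    --seed 1 --out runs/fhn1/
oscifit report --run runs/fhn1/
```

## Acceptance script

`scripts/acceptance.py` recomputes the package's headline quantities from
scratch — the Goodwin integer-Hill-coefficient oscillation threshold at the
nominal rate constants, the FHN parameters a and g recovered by the full
two-phase pipeline from noise-free data, the Goodwin Hill coefficient
recovered by phase-1 global estimation, and the generator's empirical noise
level — and writes them to a JSON file:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

A run takes a few minutes on one CPU; all randomness derives from `--seed`.
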