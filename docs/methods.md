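# Methods

`oscifit` calibrates deterministic nonlinear ODE models of biological
oscillators to noisy time-series data using a two-phase, automatically
regularised estimation workflow, and diagnoses the practical identifiability
of the result. This note records the models, the algorithms, the numerical
choices and the limits of what the shipped tests establish.

## Model class and estimation problem

Models are systems `dx/dt = f(t, u(t), x, θ)`, `x(t0) = x0`, with an
observation map `y = g(x, θ, t)` selecting the measurable quantities.
Measurements `ỹ_kji` (experiment k, observable j, time i) carry known
standard deviations `σ_kji`. Estimation minimises the weighted least-squares
cost

    Q_NLS(θ) = Σ_kji ((y_kji(θ) − ỹ_kji) / σ_kji)² = rᵀr,

equivalent to maximum likelihood for known Gaussian noise, subject to box
bounds `θ_min ≤ θ ≤ θ_max`. These problems combine four pathologies: huge
search boxes (up to ten decades per parameter), heavy multimodality of the
cost landscape of oscillatory fits, overfitting (noise-fitting with excellent
training cost but poor prediction), and partial non-identifiability.

## Phase 1: global scatter search with exhaustive archiving

A hybrid enhanced-scatter-search metaheuristic minimises `Q_NLS`:

* Latin hypercube diversification (default `10·N_θ`, minimum 100 points),
  stratified in *search scale* — parameters whose bounds are positive and
  span more than two decades are searched as their log10 exponents, since a
  linear-scale search over `[1e-5, 1e5]` is degenerate;
* a reference set (default `2·⌈√N_θ⌉ + 2`, minimum 8) of the best plus
  maximally diverse members, recombined pairwise inside hyper-rectangles
  biased towards (and beyond) the better parent, with "go-beyond"
  continuation along improving directions and restart of the non-best
  members on stagnation;
* periodic local refinement with a bounded trust-region nonlinear
  least-squares solver (`scipy.optimize.least_squares`, trf — an
  NL2SOL-class method) fed with analytic residual Jacobians obtained from
  forward sensitivities; a final refinement from the incumbent guarantees the
  returned point is stationary for the local solver (this may exceed the
  nominal evaluation budget by up to one local-search budget).

Every cost evaluation — diversification, combination and local-search
iterates alike — is appended to a sampling archive `(Θ, ζ)`. The archive,
not just the optimum, is the product of phase 1: all downstream tuning reads
it. Integration failures (blow-up, step-size underflow, domain errors) never
raise inside the search; they are scored `1e10 + (fraction of the horizon
left unsolved)` so the search simply retreats from non-integrable regions.

## Parameter bounding (cost cut-offs and box reduction)

For each parameter j a *cost cut-off* `ζ*_j` separates samples deemed close
to the optimum. Sweeping candidate cut-offs c over the sorted archive costs,
the spread `R_j(c)` of `θ_j` (in search scale) over `{i : ζ_i ≤ c}` is flat
while only near-optimal samples are accepted and blows up towards the full
box width as poor samples enter. The cut-off is the candidate maximising the
perpendicular distance below the chord joining the endpoints of the curve
`(log10 c, R_j(c))` — a deterministic knee detector; ties break towards the
smaller cost. Two admissibility floors keep the rule non-degenerate: the
cut-off must exceed the best cost, and must accept at least
`max(10, 2% of the archive)` samples — without the floor, the hundreds of
near-duplicate local-search iterates piled at the optimum let the knee
collapse onto a single point. Archives with fewer than 50 feasible points or
spanning less than one decade of cost fall back to the 25th cost percentile
(with a warning).

The reduced box takes, per parameter, the hull of the accepted samples,
widens it by 10% of its width per side (search scale), snaps outward to
integer powers of ten (default on; off via config for continuous bounds),
intersects with the original bounds, and enlarges minimally so that the
phase-1 estimate stays strictly interior. The reduced box is therefore never
wider than the original.

## Automatic Tikhonov tuning

The phase-2 cost is `Q_R(θ) = Q_NLS(θ) + α·Γ(θ)` with

    Γ(θ) = (θ − θ_ref)ᵀ WᵀW (θ − θ_ref),  W = diag(1/θ_ref),

so the penalty is invariant under per-parameter unit rescaling. The tuning
rule derives both regularisation parameters from the phase-1 archive:

* `θ_ref` is the per-parameter geometric mean (arithmetic for linear-scale
  parameters, which may be non-positive) of the accepted samples, clipped
  into the reduced bounds. The consensus of the good-fit region is preferred
  to the phase-1 optimum as the anchor because the optimum is exactly the
  point suspected of overfitting; `theta_ref_mode="phase1_optimum"` selects
  the alternative.
* `α = median_j(ζ*_j − ζ_best) / Γ_max`, where `Γ_max` is the largest
  penalty over the union of accepted samples: the penalty at the edge of the
  acceptable region is made commensurate with the acceptable cost
  degradation. If the accepted samples are numerically identical
  (`Γ_max < 1e-12`), `α = 0`.

Phase 2 re-runs the scatter search on `Q_R` inside the reduced bounds,
seeding the initial population with the phase-1 estimate. If the search
fails to improve on `Q_R(θ_I)` the better of the two points is kept, with a
warning. Conversely, if phase 2 stumbles on a strictly better solution of
the *unregularised* problem (possible when α is tiny and phase 1 had not
fully converged), that point — re-refined under the plain cost — replaces
θ_I, so the non-regularised estimate always remains the best known data fit
and `Q_NLS(θ_I) ≤ Q_NLS(θ_R)` holds by construction. Two regimes of the
tuned α are worth knowing: on overfit-prone data with a tight good-fit
region, α is order 10–1000 and visibly tempers the estimate; when the
accepted region is broad (weakly identifying data, insensitive parameters),
`Γ_max` is large and α collapses towards zero — the procedure effectively
decides no regularisation is warranted. The penalty enters the local solver as extra residual rows
`√α · W(θ − θ_ref)`, so the refinement stays an ordinary least-squares
problem with an analytic Jacobian.

## Post-fit analysis

At both estimates: range-normalised RMSE (each residual divided by its
series' measured range, pooled over all series, one outer square root), R²
per observable, a χ² test of `Q_NLS` (default `n − N_θ` degrees of freedom;
`n` selectable — the convention is not settled), and FIM-based uncertainty.
The Fisher information matrix is `Jᵀ Σ⁻¹ J` from the observable
sensitivities at the measurement points; its eigenvalue-thresholded
pseudo-inverse (threshold `1e-12·λ_max`, so singular FIMs warn about local
non-identifiability instead of crashing) gives the covariance, 95%
confidence half-widths (normal quantile 1.96; Student-t optional),
coefficients of variation, and the parameter correlation matrix. A bounds
status flags estimates within 0.1% (search-scale distance) of either bound.
Cross-validation simulates each validation experiment from its own initial
conditions and pools the NRMSE; models with a richer validation observation
map (Goodwin adds x2, the repressilator adds p3) are scored on it.

Practical identifiability uses collinearity indices: with the weighted
sensitivity matrix column-normalised, `γ_K = 1/√λ_min` of the Gram matrix of
subset K. Subsets are enumerated exhaustively to size 4 (cheap at ≤ 8
parameters) then grown greedily; `γ > 20` (the conventional threshold — the
choice is configurable) flags a subset as not identifiable in practice.
Structural identifiability is deliberately *not* approximated numerically:
the workflow records an externally obtained verdict in the configuration and
warns when none is given.

## Sensitivities and integration

Right-hand sides, observation maps and all Jacobians (∂f/∂x, ∂f/∂θ, ∂g/∂x,
∂g/∂θ) are derived symbolically (sympy) once per model and compiled to plain
scalar callables (lowest per-call overhead inside the integrator). The IVP
solver is LSODA (`scipy.integrate.odeint`) with analytic Jacobian, default
tolerances rtol 1e-8 / atol 1e-10. Forward sensitivities integrate
`dS/dt = (∂f/∂x)S + ∂f/∂θ, S(t0) = 0` jointly with the states; observable
sensitivities follow by the chain rule. Finite-difference cross-checks agree
to better than 1e-3 relative on random in-bounds draws.

## Case studies and synthetic data

Four bundled benchmarks: FitzHugh–Nagumo (3 parameters, bounds `[1e-5,1e5]`,
nominal {a,b,g} = {0.2,0.2,3}, 6 points per experiment), the Goodwin
oscillator (8 parameters, k's and Ki in `[1e-3,1e3]`, Hill n in `[1,12]`,
nominal {1,0.1,1,0.1,1,0.1,1,10}, 20 points), the repressilator (4
parameters, 20 points) and the enzymatic oscillator (7 parameters in
`[1e-3,1e3]`, 14 points, scalings kept exactly as published rather than
re-derived). Time horizons are not part of the published protocols; the
defaults FHN [0,20], GO [0,100], RP [0,50], EO [0,100] cover at least two
oscillation periods at the nominal parameters, and the oscillation
classifier simulates ten times the default horizon. The repressilator's
printed nominal vector is labelled with another model's symbols; read in
declaration order it violates its own Hill-coefficient bound, so the package
defaults to the swapped reading (β = 0.3, n = 8.5) and offers the literal
one behind a warning. No recovery test is asserted for it.

The generator emulates the published measurement protocol: equidistant
grids, Gaussian noise with standard deviation 10.0% of the nominal signal,
left-censoring of reported values at the detection threshold 0.1, stored
`σ = max(0.10·|y*|, 0.01)` (the floor, 10% of the threshold, keeps weights
finite at censored points), 10 fitting replicates at nominal initial
conditions and 10 cross-validation replicates with every nonzero initial
condition scaled by Uniform(0.5, 1.5) (zeros shifted by Uniform(0, 0.1)) —
"a reasonable range" is not quantified in the protocol; ±50% multiplicative
is this package's choice. Censoring mechanics are likewise unspecified;
recording sub-threshold values at the threshold is the simplest consistent
reading. Note that for signals that go negative (FHN's V) censoring at 0.1
is destructive: the generator truth is then *not* a near-optimal fit to the
censored data. Noise-free recovery experiments therefore disable censoring
(`detection_threshold=None`); what a green recovery test establishes is that
the pipeline finds the zero-cost optimum that exists by construction, not
that the protocol with censoring is unbiased.

## Oscillation classifier

Sustained/damped/steady classification is a pragmatic proxy (the underlying
notion of "oscillatory dynamics" is never formalised in the protocol): the
trajectory's first half is discarded as transient; the remainder is
*steady* if its amplitude is below 1e-6 of the signal scale, *sustained* if
at least three peaks remain and the last peak-to-trough amplitude is ≥ 95%
of the first, else *damped*. The period estimate is the mean peak spacing.
On the Goodwin model at the nominal rate constants, an integer scan finds
damped behaviour through n = 8 and sustained oscillation from n = 9 (the
Hopf threshold sits between 8 and 8.5 — for equal degradation rates the
classical condition requires n to *exceed* 8), a contiguous split consistent
with the classical bound.

## Evaluation budgets (desk scale)

The published experiments do not state evaluation budgets; defaults are
`5000·N_θ` (capped at 2e5) for phase 1 and half that for phase 2. The
bundled tests and the acceptance script run far smaller, desk-scale budgets
(FHN 3000/1500, Goodwin 10000) — sufficient because the noise-free recovery
problems have zero-cost optima and the local refinement converges exactly
once the right basin is found. Noisy 6-point FHN replicates are run at
2000/800: at these budgets phase 1 occasionally stalls in a non-global
basin, which is precisely the regime the replicate-level property tests
average over.

## Known limitations

* The original per-parameter cut-off, bound-reduction and α-tuning
  procedures are published only as figure boxes; the rules here are explicit
  reconstructions honouring the stated constraints (per-parameter cut-offs,
  rejection of far-from-optimum costs, reduced bounds from accepted samples,
  tuning driven by cut-offs and reduced bounds). They are
  behaviour-compatible, not line-compatible; quantitative bound comparisons
  against the published tables are out of scope.
* The published modifications to the scatter-search solver are in
  supplementary material not available here; the implementation is the
  canonical algorithm plus the two behaviours the workflow requires
  (exhaustive archiving, analytic-sensitivity local search).
* No SBML/CellML import, events, delays, stochastic dynamics or adjoint
  sensitivities; no bootstrap confidence intervals or profile likelihoods.
* FIM-based intervals are first-order approximations and can be optimistic
  for strongly nonlinear fits.
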