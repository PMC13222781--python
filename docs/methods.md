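# Methods

## Scope and data model

The package operates on two-construct (plus optionally more constructs
for the regression panels), multi-wave panel data. Variables are
`(construct, wave)` pairs, serialized as `CONSTRUCT@WAVE`; wave indices
are 1-based. Two containers carry all analyses:
`LongitudinalCorrelationMatrix` (labeled, symmetric, unit-diagonal, PSD
to 1e-10) and `PanelDataset` (complete cases only; no missing-data
mechanism is modeled or accepted). Correlation-matrix and panel files
are plain delimited text with those labels.

**Divisor convention.** Standardization and empirical correlation use
the population divisor (n). This is what makes exact-mode generation
self-consistent: whitened-then-colored scores have column mean 0, SD 1
and empirical correlation equal to the target without n/(n−1) drift.
Pearson correlations are invariant to the divisor, so the regression
layer is unaffected. The SEM layer instead analyzes the sample
covariance with divisor n−1, pairing with its default (n−1) χ²
multiplier (Wishart convention); a multiplier of n is available via
`chi2_multiplier="n"`.

## Synthetic data generators

Three processes produce data; their defaults are the study conditions
(N = 561 subjects, 3 waves, standardized scores).

**Exact-mode correlation matching** (`simulate_from_corr(..., exact=True)`).
iid normal deviates are column-centered, whitened by the inverse
symmetric square root of their sample covariance, and colored by the
symmetric square root of the target. Symmetric (eigendecomposition)
square roots avoid any dependence on variable order; the label order is
fixed and documented. The empirical correlation matrix of the output
equals the target to ~1e-10, so every correlation-driven closed form
coincides with its regression counterpart on the same data. Requires
n > p. `exact=False` draws from the multivariate normal with the target
as population correlation.

**MoSLA process** (`simulate_mosla`). Traits (gN, gC) are bivariate
normal with covariance (φ_N, φ_C, φ_NC); the shared occasion state
starts at N(0, ψ) and evolves as a stationary AR(1) with disturbance
variance ψ(1−ρ²); residuals are iid N(0, θ); observed = trait + state +
residual. The default parameters (0.4, 0.4, 0.1, 0.3, 0.5, 0.3) satisfy
φ + ψ + θ = 1, so scores are standardized in population. Stationarity
of the state process is enforced by construction — it is what keeps the
model at six parameters. One integer seed is split into independent
sub-streams for traits, states and residuals, with states and residuals
drawn wave by wave, so extending the number of waves never perturbs
earlier draws.

**Common cause** (`simulate_common_cause`). A standard-normal latent CC
loads on X₁, Y₁, Y₂ and Y₁ feeds Y₂; there is no X₁→Y₂ path. Unique
variances are implied so each observed variance is 1; specifications
whose implied unique variance or correlation leaves [0,1]/[−1,1] are
rejected. Implied correlations follow the path-tracing rules
(r_{x1,y1} = λ_x λ_{y1}, r_{x1,y2} = λ_x(λ_{y2} + β λ_{y1}),
r_{y1,y2} = λ_{y1}λ_{y2} + β). The exposure is only measured at wave 1,
so this dataset deliberately has an incomplete construct × wave grid;
operations that need the full grid check `is_complete_grid`.

What the generators do *not* emulate: non-normal or ordinal indicators,
missingness, informant effects, mean structure, more than one shared
state factor. Passing tests therefore show the *logic* of the scrutiny
procedure under Gaussian, complete, stationary conditions — not that
real questionnaire data satisfy them.

## Difference-score effects

All regressions are OLS (statsmodels) on globally standardized columns;
the change score is the difference of standardized scores, matching the
standardized-effect framing in which the closed forms hold. Standard
errors are conventional homoskedastic OLS SEs with df = n − (fitted
coefficients, intercept included); significance flags are two-sided
z-tests at α = 0.05.

The unadjusted closed form is implemented as c₁ = r_{x1,y2} − r_{x1,y1},
the OLS slope of the standardized difference score on the standardized
exposure. (A published rendering of this formula collapses to an
identically zero expression by a typographical slip; the implemented
form is the one consistent with the unadjusted regression and with the
OLS oracle on exact-mode data.)

A panel (exposure → outcome) is the ordered sextet: adjust-initial for
timeframes 1→2 and 2→3, then adjust-subsequent, then unadjusted. The
exposure enters at the timeframe's first wave.

## Random-effects pooling

Inverse-variance weights w_i = 1/(se_i² + τ²); Wald 95% CIs (no
small-sample adjustment). τ² by REML (default; Fisher-scoring iteration,
converged at 1e-10, floored at 0) or DerSimonian–Laird (closed form,
floored at 0). Q and I² use fixed-effect weights. The six effects of a
panel come from overlapping data and are *not* independent; pooling
treats them as if they were, faithfully replicating the scrutiny
procedure rather than endorsing that independence assumption. A
multivariate meta-analysis respecting the dependence is explicitly out
of scope.

## The MoSLA engine

The implied covariance is assembled two independent ways — a closed
form (cov(N_t, N_u) = φ_N + ψρ^{|t−u|} + [t=u]θ, cross blocks with φ_NC)
and RAM path matrices Σ = F(I−A)⁻¹S(I−A)⁻ᵀFᵀ — and the two derivations
are required to agree to 1e-12 in the test suite.

**Identification.** The six-parameter construction (all loadings 1, one
shared residual variance, stationary shared state, free trait variances
and covariance) is the parsimonious structure that yields df = 15 at
three waves (21 moments − 6 parameters); freeing per-construct residual
variances would give df = 14 instead. With only two waves the model is
*not* identified: the one-parameter family ψ → ψ+d,
ρ → (ψρ+d)/(ψ+d), φ_N/φ_C/φ_NC → ·−d reproduces all two-wave moments
exactly (the test suite demonstrates the ridge). Three or more waves
break the ridge, but only through the lag-2 moments, so the trade-off
direction remains weakly determined: at n = 561 the ML estimates of the
trait parameters carry a finite-sample bias of roughly −0.02 (and ψ
about +0.02) under the default generating values, shrinking with n as
consistency requires. Fits should be read accordingly; the χ² test
statistic itself is well calibrated (mean ≈ df, ~5% rejection at the
nominal level).

**Estimation.** F_ML(θ) = ln|Σ(θ)| + tr(SΣ(θ)⁻¹) − ln|S| − p is
minimized over transformed parameters — log variances, atanh-transformed
trait correlation and ρ — which keeps every iterate admissible. The
gradient is analytic (tr[(Σ⁻¹ − Σ⁻¹SΣ⁻¹) ∂Σ/∂x]); L-BFGS-B runs from a
moment-based start plus five perturbed restarts (deterministic given the
seed), each followed by a damped-Newton polish, and the best solution
must reach a projected-gradient max-norm below 1e-8 or a convergence
error with diagnostics is raised. Standard errors come from the inverse
numerical Hessian of ((n−1)/2)·F at the optimum (pseudo-inverse at
boundary solutions such as ψ → 0), mapped to the natural scale by the
transformation Jacobian.

**Fit statistics.** χ² = (n−1)·F_min (default); p from the central χ²
upper tail. The baseline for CFI/TLI is the independence model (free
variances, zero covariances), whose ML discrepancy has the closed form
Σln S_ii − ln|S|. CFI = 1 − max(χ²−df, 0)/max(χ²_b−df_b, χ²−df, 0);
TLI = (χ²_b/df_b − χ²/df)/(χ²_b/df_b − 1), reported as NaN when the
baseline is degenerate rather than fabricated; TLI may exceed 1 when
χ² < df. RMSEA = √(max(χ²−df,0)/(df·(n−1))); its 90% CI inverts the
noncentral χ² cdf in the noncentrality parameter by bracketed Brent
root-finding (tolerance 1e-10, bracket [0, 10·df·max(χ²,1)]), with a
bound of 0 whenever no nonnegative solution exists. The standardized
solution scales each path by the ratio of implied SDs and reports
variance components as shares of the implied totals.

## Pipeline and reproducibility

`run_scrutiny(config)` takes exactly one data source — a panel file, a
correlation matrix plus n (analyzed via exact-mode simulation, which
reproduces every correlation-driven estimate of the unavailable raw
data), or a simulation recipe — and produces four default panels
(MPEE→CU, CU→MPEE, MNEE→CU, CU→MNEE) of effects 1–7 plus one MoSLA fit
(MNEE/CU pair by default; all pairs behind a flag). Reports serialize
losslessly to JSON and to a flat effects table; runs are byte-identical
for a fixed config and seed. The CLI (`scrutinize run|simulate`) is a
thin layer; flags override config scalars.

## Problem sizes

The test suite and the acceptance script use Monte-Carlo sizes chosen to
make their statistical assertions sharp at interactive runtimes: 1,000
random correlation triples for the closed-form/OLS equivalence sweep
(tolerance 1e-8), 500 replications at n = 561 for χ² calibration and
bias, 300 replications for the spuriousness mean-effect z statistic, 60
fits for average fit indices, and 50 population-recovery draws across
waves 2–4. The acceptance script runs a 300-triple sweep and 200-
replication summaries under one pass.

## Known limitations

- The MoSLA here is the fixed six-parameter structure; it is not a
  general SEM language, and robust/categorical estimators and FIML are
  out of scope.
- Two-wave fits are structurally unidentified (see above); the fitter
  will converge on the ridge and report one of the equivalent solutions.
- Pooling ignores within-panel dependence by design (replication
  fidelity).
- Closed-form/OLS equivalence is exact only for exact-mode data; on
  sampled data the two agree only in expectation.
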