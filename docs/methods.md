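# Methods

## Kinetic model

One V̇O2 trace is modeled as rest → exercise → recovery:

```
V̇O2(t) = V̇O2rest
        + (V̇O2ss − V̇O2rest) · (1 − exp(−(t − λ)/τ1))      for t > λ
        + (V̇O2rec − V̇O2ss) · R(τ2 · log((t − t0)/T½))      for t > t0
```

with λ the individual resting-phase length, t0 = λmax + 360 s the common
recovery onset of a cohort aligned on its longest rest, and R one of

| family | R(s) | fraction of the decrease at t0 + T½ | canonical sign of τ2 |
| --- | --- | --- | --- |
| log-logistic | 1/(1+eˢ) | 1/2 (exactly, any τ2) | negative |
| Weibull 1 | e^(−eˢ) | e⁻¹ ≈ 0.368 | negative |
| Weibull 2 | 1 − e^(−eˢ) | 1 − e⁻¹ ≈ 0.632 | positive |

Both time-varying components are gated to zero before their onsets, making
the model a total function of t (the recovery logarithm is otherwise
undefined before t0). The sigmoid's direction is set by sign(τ2); the
canonical signs above are used as starting values only, never as hard
constraints. Because Weibull 1 has achieved only e⁻¹ of the decrease at one
T½ (vs 1/2 for the log-logistic, 1−e⁻¹ for Weibull 2), fitting the three
families to the same data yields T½ estimates ordered
Weibull 1 ≤ log-logistic ≤ Weibull 2 — the asymmetric shapes trade scale for
skewness. The mean response time of the exercise rise (time to 63% of the
span) equals τ1.

Units: seconds and mL/min throughout. Parameters λ and λmax are
experimenter-controlled metadata, never estimated; after alignment
λ = λmax for every patient.

## Preprocessing

Breath-by-breath records are averaged over consecutive fixed windows
[k·w, (k+1)·w). The default w = 20 s follows the cardiopulmonary-exercise
recommendation; 5/10/15 s are exposed for the sensitivity analysis. The bin
timestamp is the window midpoint (unbiased under a within-bin linear trend);
empty bins are dropped, partial boundary bins kept — the fitting code
accepts irregular grids, so no interpolation is ever done. Alignment is the
pure translation t → t + (λmax − λᵢ).

## Per-patient fits

Six free parameters per curve, trust-region least squares with the analytic
Jacobian, bounds keeping τ1 and T½ positive (|τ2| ≤ 50). Tolerances: 1e-10
on the relative cost change (tighter than strictly needed so that noise-free
recoveries are exact to ~1e-7 relative). Starting values come from the phase
structure: plateau means for the three uptake levels, τ1 = 30 s, T½ from the
first crossing of the recovery midpoint on a 3-bin rolling mean (fallback
120 s), τ2 = ±2. A failed start is retried from up to three multiplicatively
jittered inits (seeded, deterministic); a fit that still fails is returned
with `converged=False` and excluded downstream with a note — never silently.

Uncertainty: cov = (JᵀJ)⁻¹ · σ̂² · n/(n−6) with σ̂² = RSS/n (the n/(n−6)
factor is the small-sample bias correction; per-patient n is ~50). The
Gaussian log-likelihood uses the ML variance, and AIC counts K = 7 (six
curve parameters plus σ), applied uniformly so that model comparisons are
unaffected by the convention.

## Mixed-effects model

y_ij = V̇O2(t_ij; β_i) + ε_ij with ε_ij ~ N(0, σ²) i.i.d. (identity
within-patient correlation), β_i = A_i β + B_i b_i: stage cell-means fixed
effects for all six parameters (3 stages × 6 = 18), random effects
b_i ~ N(0, G) on the four recovery parameters (V̇O2ss, T½, τ2, V̇O2rec).
G is diagonal by default — four correlated random effects on a ~61-patient
cohort are fragile — with a full log-Cholesky-parameterized G available.

Estimation alternates (Lindstrom–Bates):

1. **PNLS**: minimize Σᵢ‖yᵢ − fᵢ(β, bᵢ)‖² + bᵢᵀD⁻¹bᵢ jointly over β and all
   bᵢ, where G = σ²D; solved as a single trust-region least-squares problem
   with the exact block Jacobian.
2. **LME**: linearize f at (β̂, b̂ᵢ) and maximize the profiled marginal ML of
   the resulting linear mixed model over log-variance parameters (β and σ²
   profiled out in closed form; per-patient Woodbury identities keep all
   algebra at 4×4 scale). Random-effect modes are refreshed as BLUPs.

Outer loop: relative log-likelihood tolerance 1e-6, at most 200 iterations
(typically 3–6 suffice). The reported log-likelihood is the linearized ML
criterion at convergence; AIC counts K = 18 + (#G parameters) + 1. Wald
covariance for β is σ̂²(ΣXᵢᵀVᵢ⁻¹Xᵢ)⁻¹, and inference on stage estimates and
contrasts uses the normal reference. Fixed effects are initialized from
per-patient fit medians by stage, D from the spread of the per-patient
estimates, random-effect modes at zero.

Numerical notes. The outer criterion is monotone only up to
re-linearization error: each iteration moves the expansion point, so
decrements up to ~1e-4 relative can occur and the monotonicity check allows
them. During PNLS the optimizer may pass through invalid parameter
combinations; τ1 and T½ are floored (0.5 s and 1 s) inside the objective,
and the usual invariant checks are skipped there. Variance components that
collapse to the lower bound (log relative variance −16) are reported as
boundary notes. With an empty random set, the same machinery reduces
exactly to pooled per-stage nonlinear least squares. Non-convergence —
expected occasionally for single-stage subgroup fits on small samples — is
a first-class result carried with a reason, not an exception.

## Two-step pooling

Step 1 extracts φ̂ᵢ = T½ per patient with SE σᵢ. Step 2 offers:

- **Meta-analysis**: φ̂ᵢ = θ_stage(i) + Aᵢ + εᵢ, Aᵢ ~ N(0, τ²),
  εᵢ ~ N(0, σᵢ²) with the σᵢ taken as known (no residual scale estimated).
  τ² by REML (default; ML and DerSimonian–Laird available — DL doubles as a
  closed-form oracle in tests), stage estimates as inverse-variance means
  with SE 1/√Σwᵢ, z inference. With one patient per stage τ² is
  inestimable; it is fixed at 0 with an explicit note. AIC uses the fitting
  likelihood with K = q + 1.
- **Weighted regression**: εᵢ ~ N(0, σ²σᵢ²), σ̂² = weighted RSS/(m−q)
  estimated from the data; t inference with m−q df. Point estimates are
  invariant to rescaling all σᵢ by a constant (the meta estimates are not,
  since τ² competes with σᵢ² on an absolute scale).

Known limitation: T½ is a scale parameter, so σᵢ is roughly proportional to
the patient's own T½; under between-patient heterogeneity the 1/σᵢ² weights
then correlate with the random effect and the weighted estimator converges
to a *weighted* population mean that sits below the stage mean (≈10 s under
the default synthetic conditions), while its model-based SE ignores the
additive heterogeneity. The weighted stage estimates therefore shrink
towards the overall mean relative to the meta and mixed-effects estimates —
visible in every pipeline run — and weighted stage-level estimates can sit
2–3+ SE below the generating values even when the contrasts remain useful.
This spread compression is a tendency, not a theorem: with very noisy σᵢ
the weighted spread can exceed the meta spread in individual replicates.

## Model averaging

Akaike weights from any IC vector (invariant to shifts; lower IC ⇒ strictly
larger weight); θ̂_MA = Σw_pθ̂_p stays in the candidates' convex hull.
The unconditional SE uses Buckland's sum-of-square-roots form
Σ w_p √(var(θ̂_p) + (θ̂_p − θ̂_MA)²) — conservative, so averaged intervals
over-cover slightly. AIC is −2·loglik + 2K everywhere (AICc not used).
Subgroup selection tabulates per-stage AICs per family, flags the argmin,
and carries failed cells (e.g. non-converged subgroup mixed fits) with
their reason instead of dropping them.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, with defaults
fixed as the package's study conditions:

| quantity | default | why |
| --- | --- | --- |
| patients per stage | 21 / 30 / 10 | typical severity mix of a referred COPD cohort |
| truth family | log-logistic | symmetric reference shape |
| stage T½ | 128 / 133 / 168 s | recovery slows with severity; ~40 s moderate-to-very-severe gap |
| V̇O2rest, V̇O2ss, V̇O2rec | ≈300, 1310/1150/990, ≈400 mL/min | exercise span shrinks with severity |
| τ1 | 30/35/40 s | on-kinetics slow with severity |
| random SDs (V̇O2ss, T½, τ2, V̇O2rec) | 80, 25, 0.3, 40 | diagonal G; T½ spread matches a between-patient SD of ~25 s |
| breath noise | 100 mL/min per breath | ≈5% of the exercise span after 20-s binning |
| λᵢ | U(30, 90) s | experimenter-controlled resting phases |
| breath gaps | U(2, 4) s | realistic breath density for 20-s averaging |
| recovery recorded | 600 s | ≈3.5× the slowest stage's T½, so the recovery plateau (and hence V̇O2rec and T½) is identified per patient; a shorter window leaves the very severe stratum ~75% recovered and biases the two-step estimates |

Noise is additive Gaussian per breath; the rare draw below zero (rest sits
~3 SDs above zero) is redrawn, a truncation too small to register in a
skewness check at n = 10⁴. Parameter draws violating the curve invariants
are redrawn up to 100 times, then error. Everything is reproducible from a
single integer seed, and a truth ledger with every patient's parameters
accompanies each cohort.

What the generator does *not* emulate: autocorrelated or heteroscedastic
breath noise, measurement dropout and device artifacts, movement-phase
irregularities, or correlated random effects (available but off by
default). Passing recovery tests on these cohorts therefore demonstrates
the estimators' correctness under the stated model, not robustness to
real-world trace pathology.

## Test scaling

Unit and property tests run on reduced designs chosen once — 12–15-patient
cohorts, 6–20 replicates — keeping the default suite under ~2 minutes; the
end-to-end statistical checks in `tests/test_acceptance.py` use the full
61-patient design with 20 replicates for the contrast-power check. The
null-calibration check of the contrast machinery (type-I error ≈ 5%) runs
at the summary level (simulated φ̂ᵢ) where 500 replicates are cheap.
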