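# vo2kinetics

Modeling post-exercise oxygen-uptake (V̇O2) recovery after 6-minute walk
tests (6MWT) in COPD, with multimodel inference.

## The problem

A 6MWT produces a breath-by-breath V̇O2 trace with three phases: rest,
a 360-s walk during which uptake rises mono-exponentially to a steady state,
and a post-exercise recovery during which uptake decays back towards a
plateau. The speed of that recovery — summarized by the half-decrease time
T½V̇O2 — is an indicator of exercise capacity, and is expected to lengthen
with COPD severity (GOLD stages 2–4).

Two methodological questions arise when a cohort of such curves is analyzed:

1. **Which recovery model?** Several sigmoids are plausible: a symmetric
   log-logistic, and two asymmetric Weibull shapes with the inflection early
   (Weibull 1) or late (Weibull 2) in the recovery. With
   s = τ₂·log((t − t₀)/T½) and t₀ the common recovery onset,

   ```
   V̇O2(t) = V̇O2rest + (V̇O2ss − V̇O2rest)(1 − e^{−(t−λ)/τ₁}) + (V̇O2rec − V̇O2ss)·R(s)

   log-logistic: R = 1/(1 + eˢ)     Weibull 1: R = e^{−eˢ}     Weibull 2: R = 1 − e^{−eˢ}
   ```

   Rather than pick one, the package computes Akaike weights
   w_p = exp(−Δ_p/2)/Σ exp(−Δ_r/2) (Δ_p = AIC_p − min AIC) and the
   model-averaged estimate θ̂_MA = Σ w_p θ̂_p with Buckland's conservative
   unconditional standard error Σ w_p √(var(θ̂_p) + (θ̂_p − θ̂_MA)²).

2. **How to pool patients?** Three strategies are implemented and compared:
   - **nonlinear mixed effects** — one model for the whole cohort, with
     stage-specific fixed effects on all six curve parameters and random
     effects on the four recovery parameters (fitted by an alternating
     penalized-least-squares / linearized-ML scheme in the Lindstrom–Bates
     fashion);
   - **two-step meta-analysis** — fit each patient separately, then pool the
     per-patient T½ estimates φ̂ᵢ (with known SEs σᵢ) through a
     random-effects meta-regression with REML heterogeneity τ²;
   - **two-step weighted regression** — the same per-patient estimates pooled
     by WLS with weights 1/σᵢ² and a multiplicative residual variance.

   Stage contrasts (4−2, 3−2, 4−3) use Wald statistics — normal reference for
   the mixed-effects and meta strategies, t with m−q df for weighted
   regression.

Since the clinical dataset is not distributed with the package, a
synthetic-cohort generator (`vo2kinetics.synthetic`) reproduces its
statistical structure — 61 patients (21/30/10 per stage), jittered 2–4 s
breath intervals, Gaussian patient heterogeneity on the recovery parameters,
i.i.d. Gaussian breath noise — with a truth ledger so every stage of the
pipeline is testable by parameter recovery.

## Worked example

```python
from vo2kinetics import PipelineConfig, run_pipeline

cfg = PipelineConfig(seed=1, outdir="demo", run_sensitivity=False)
result = run_pipeline(cfg)
print(result.table3.round(3).to_string(index=False))
```

On the default synthetic cohort this prints (values from an actual run):

```
  method         family       aic  weight  estimate     se
   mixed   log_logistic 32556.881   1.000    29.893 10.811
   mixed      weibull_1 32665.279   0.000    27.800  9.532
   mixed      weibull_2 32677.776   0.000    31.262 11.675
   mixed model_averaged       NaN     NaN    29.893 10.811
    meta   log_logistic   567.464   0.007    27.614 11.238
    meta      weibull_1   557.656   0.993    24.477 10.124
    meta      weibull_2   575.555   0.000    29.601 12.041
    meta model_averaged       NaN     NaN    24.501 10.136
weighted   log_logistic   613.444   0.114    27.605 16.572
weighted      weibull_1   609.418   0.854    24.343 15.176
weighted      weibull_2   616.017   0.032    29.337 16.958
weighted model_averaged       NaN     NaN    24.873 15.443
```

Each block is one summarization strategy: per-family AIC, its Akaike weight,
the estimated 4−2 difference in T½V̇O2 (seconds) with its SE, and the
model-averaged row combining the three families. `result.table2` holds the
per-stage estimates and all three stage contrasts with p-values (for this
seed the mixed-effects 4−2 difference is 29.9 s, SE 10.8, p = 0.006 — the
very severe stage recovers more slowly). The cohort-level log-loss of the
mixed-effects fits strongly favors the generating family (log-logistic),
while the summary-level AICs of the two-step strategies rank the compressed
φ̂ᵢ distributions instead — exactly the model uncertainty that the averaged
row integrates out.

The same pipeline is exposed on the command line:

```bash
vo2kinetics simulate --seed 1 --outdir cohort
vo2kinetics report --input cohort/cohort.csv --outdir report
```

`report/` then contains `table2.csv`, `table3.csv`, `sensitivity.csv`
(T½ estimates across 5/10/15/20-s breath-averaging windows) and `log.json`
with seeds and versions.

## Layout

| module | contents |
| --- | --- |
| `models` | the three kinetic model families, analytic gradients, MRT |
| `preprocessing` | breath binning (5/10/15/20 s), cohort alignment on λmax, CSV I/O |
| `patient_fit` | per-patient nonlinear least squares with SEs and AIC |
| `mixed_effects` | cohort-level nonlinear mixed-effects estimation |
| `two_step` | random-effects meta-regression (REML/ML/DL) and weighted regression |
| `averaging` | Akaike weights, model averaging, subgroup model selection |
| `inference` | stage contrasts, z/t p-values, optional Holm adjustment |
| `synthetic` | cohort generator with truth ledger |
| `pipeline`, `cli` | orchestration, report tables, `vo2kinetics` console script |
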