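# survlock

**How mature must survival data be before extrapolation can be trusted?**

Economic evaluations of oncology treatments need lifetime survival, but the
trials and registries that inform them are right censored — often heavily so
at the time of market approval. `survlock` is a pipeline for studying how
the accuracy of parametric survival extrapolation depends on data maturity.
It simulates staggered-enrollment cohorts with a realistic (non-monotone)
overall-survival hazard, imposes artificial **database locks** of increasing
maximum follow-up, fits a roster of 16 survival models to each cut, and
scores every extrapolation against the long-follow-up Kaplan–Meier
estimate. It is aimed at health-economics and biostatistics researchers who
want to quantify, for cohorts like their own, how RMST error shrinks as
censoring falls and events accrue.

## The quantities and models at the core

**Restricted mean survival time.** For horizon τ,
RMST(τ) = E[min(T, τ)] = ∫₀^τ S(t) dt. The **RMST error** of a fitted model
is signed: RMST_model(τ) − RMST_KM(τ), with the Kaplan–Meier curve computed
from the longest available follow-up. The **conditional RMST** isolates the
extrapolated region: given survival to the lock's maximum follow-up t₀,
RMST(t₀, τ) = ∫_{t₀}^τ S(u) du / S(t₀).

**The model roster.** Seven standard parametric families fitted by censored
maximum likelihood — exponential, Weibull, Gompertz, gamma, log-logistic,
lognormal, and generalized gamma in the (μ, σ, Q) form — plus nine
Royston–Parmar flexible parametric models: a natural cubic spline
s(z) = γ₀ + γ₁z + Σⱼ γ_{j+1} vⱼ(z) in log time z = log t applied to the log
cumulative hazard (log H(t) = s), log cumulative odds, or probit transform of
S(t), with 1–3 internal knots at centiles of the uncensored log event times.
The right-censored log-likelihood ℓ = Σ_{δᵢ=1} log f(tᵢ) + Σ_{δᵢ=0} log S(tᵢ)
is maximized by quasi-Newton iteration with deterministic multi-starts.
Model selection uses lowest AIC = −2ℓ + 2k and lowest BIC = −2ℓ + k ln n,
with exact ties broken by the fewest free parameters.

**Database locks.** A lock at calendar time L excludes subjects enrolled at
or after L and administratively censors everyone still alive at L; a grid of
locks at maximum follow-up 3/6/8/10/13 years after the start of enrollment
produces data cuts of increasing maturity from one underlying cohort.

## Worked example

One 300-subject cohort with ~5 years of staggered enrollment and a
piecewise-exponential true hazard that rises from 0.10 to 0.35/year at 1.5
years and falls to 0.12/year at 5 years (median OS ≈ 3 years — no
single-turning-point family is correct for it):

```python
from survlock import (CohortSpec, ExperimentConfig, run_experiment,
                      mm_like_hazard_presets)

cfg = ExperimentConfig(
    cohorts=[CohortSpec(n_subjects=300, enroll_start=2002.72, enroll_end=2007.54,
                        survival_model=mm_like_hazard_presets()["piecewise"],
                        seed=42, label="mm-sim")],
    max_followups=(3.0, 6.0, 8.0, 10.0, 13.0),
    evaluation_horizon=14.0,
    seed=42,
)
records, summaries = run_experiment(cfg)
print(summaries["by_lock"][["rmst_error", "abs_rmst_error",
                            "abs_cond_rmst_error", "n_records"]].round(3))
```

```
      rmst_error  abs_rmst_error  abs_cond_rmst_error  n_records
lock
<10y      -0.085           0.132                0.220         16
<13y       0.045           0.046                0.033         16
<3y       -0.734           1.023                2.026         16
<6y       -0.425           0.425                1.625         16
<8y       -0.275           0.275                0.754         16
```

Reading the table: with only 3 years of maximum follow-up the roster's
median extrapolation misses the 14-year Kaplan–Meier RMST by about 1.0 year
(and by 2.0 years conditional on surviving to the lock); by 13 years of
follow-up the median absolute error has fallen below 0.05 years. The BIC
winner also migrates from rigid families to splines as data mature:

```
lock            model      bic  rmst_error
 <3y         gompertz  174.486      -1.413
 <6y          weibull  797.402      -0.729
 <8y   spline_odds_1k 1075.591      -0.353
<10y spline_hazard_2k 1201.431       0.086
<13y spline_hazard_2k 1322.171       0.041
```

The same experiment runs from the shell:

```bash
survlock simulate --n 300 --model piecewise --seed 42 --out cohort.csv
survlock lock cohort.csv --max-followups 3,6,8,10,13 --outdir locks/
survlock fit locks/lock_6y.csv --model all
survlock run config.yaml --outdir results/   # records + summaries + plots
```

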