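# Methods

## The simulated study

The pipeline asks one question: as a survival dataset matures — longer
follow-up, less censoring, more events — how quickly does parametric
extrapolation of restricted mean survival time (RMST) converge to the
nonparametric truth? Because individual-patient data of the motivating
kind (multiple-myeloma trial and registry cohorts) are not freely
redistributable, the package generates cohorts with the same statistical
structure and treats the generator as the study population.

A run proceeds in four stages:

1. **Generation.** Each subject draws a calendar enrollment time uniformly
   on a multi-year window, an overall-survival time from a fully known
   hazard, and optionally a loss-to-follow-up time (exponential). Every
   subject eventually dies in the generating process; there is no cure
   fraction, so censoring arises only from locks and loss to follow-up.
2. **Locking.** A database lock at calendar time L drops subjects enrolled
   at or after L and censors survivors at L. Locks are anchored at
   enrollment start + maximum follow-up, so the grid {3, 6, 8, 10, 13}
   years spans the maturity range from mostly-censored to mostly-observed.
3. **Fitting.** Sixteen models per locked dataset: seven standard
   parametric families and nine Royston–Parmar spline models (hazard,
   odds, probit scale × 1–3 internal knots), all by right-censored
   maximum likelihood.
4. **Scoring.** Signed RMST error against the Kaplan–Meier curve of a
   long-follow-up reference cut of the same cohort, over a horizon within
   that follow-up (default 14 years); a 35-year "lifetime" RMST for each
   extrapolation; and a conditional RMST error given survival to the
   lock's maximum follow-up, which isolates the purely extrapolated part
   of each curve. Lowest-AIC and lowest-BIC models are flagged per lock,
   with exact ties broken by fewest free parameters and then roster order.

## Data-generating presets

`mm_like_hazard_presets()` fixes the three study hazards:

- **gengamma** — generalized gamma (σ = 1.2, Q = 0.4, μ set so the median
  is exactly 3.5 years). Its hazard rises to a peak near one year and then
  declines, the shape typical of overall survival after an effective
  induction treatment; median OS of 3–4 years matches the target
  population.
- **piecewise** — piecewise-exponential with rates 0.10 → 0.35 → 0.12 per
  year and knots at 1.5 and 5 years (median ≈ 3.05 years). The hazard is
  left-continuous at its knots. Because the hazard rises *and* falls, no
  single-turning-point family in the roster is correctly specified — the
  deliberately unfavorable case for extrapolation.
- **exponential** — rate ln 2 / 3.5 (median 3.5 years), for closed-form
  verification.

Each preset exposes exact sampling, the true survival and hazard functions,
and the true RMST at any horizon (closed form where available, otherwise
adaptive quadrature to 1e-10), so simulation tests always have an oracle.

Default study conditions: cohorts of 300 subjects (the trial/registry range
of interest is roughly 100–650), enrollment uniform over a 4.8-year window
(decimal years 2002.72–2007.54), no loss to follow-up, reference cut at 25
years, evaluation horizon 14 years, lifetime horizon 35 years. The
acceptance script uses 20 replicate cohorts of this size — large enough for
the maturity gradient to be stable across seeds, small enough that a full
replicate set runs in minutes on one core.

What the generator does **not** emulate: covariate structure and treatment
contrasts, recruitment-rate ramps, cure fractions, calendar-time trends in
care, and day-rounded event times. Passing tests therefore demonstrate the
behavior of the estimators under a clean version of the sampling process,
not the idiosyncrasies of any registry.

## Parameterizations

Pinned so results are unambiguous across toolchains:
exponential S = e^{−λt}; Weibull S = exp(−(t/σ)^α); Gompertz h = b·e^{at}
with a real and b > 0 (a → 0 reduces to the exponential, computed with
`expm1` for stability); gamma in shape/rate form; log-logistic
S = 1/(1+(t/α)^β); lognormal S = 1 − Φ((ln t − μ)/σ); generalized gamma in
the (μ, σ, Q) form whose Q → 0 limit is the lognormal and whose Q = 1 slice
is Weibull(1/σ, e^μ). The generalized-gamma log-density folds the Stirling
residual a ln a − ln Γ(a) − a (a = Q⁻²) into one stably evaluated term so
the likelihood remains accurate down to |Q| ≈ 1e-8, below which the code
switches to the lognormal limit.

BIC uses the number of subjects, not events, as n; this matches the common
convention of survival fitting software and is recorded in output metadata.

## Numerical choices

- **Optimization.** Positive parameters are log-transformed and the
  likelihood maximized unconstrained by L-BFGS-B from five deterministic
  starts (a moment-based start plus four fixed-seed perturbations),
  followed by a Nelder–Mead polish. The polish both sharpens the optimum
  (needed for the 1e-4 spline↔Weibull equivalence checks) and certifies
  convergence when the line search of L-BFGS-B terminates abnormally at an
  already-converged point. Refits are bit-identical.
- **Spline fitting.** Initial coefficients come from least-squares
  regression of the link-transformed Kaplan–Meier estimate at event times
  on the spline basis; any coefficient vector producing a non-positive
  hazard at an observed event time scores −∞ (rejected, not clamped), which
  keeps the optimizer unconstrained. Knots collapse under heavy ties make a
  spec infeasible for that dataset; knots are never jittered, because
  jitter is irreproducible.
- **RMST quadrature.** Adaptive quadrature (absolute tolerance 1e-8).
  Spline survival is integrated in z = log t near the origin, where the
  spline is defined on log time and the direct integrand has a singular
  derivative.
- **Kaplan–Meier conventions.** At tied times deaths are processed before
  censorings. The KM RMST refuses horizons beyond the last observed time by
  default (the curve is undefined there); an explicit extend-flat override
  carries the last level forward and warns.
- **Lock ties.** A death exactly at the lock instant counts as censored
  (administrative censoring wins); with continuous times this is a
  measure-zero convention.
- **Smoothed hazard.** Epanechnikov kernel on Nelson–Aalen increments,
  cut-and-normalize boundary correction at t = 0, fixed bandwidth
  (auto = event-time range/8), 256-point grid. Used for visual diagnostics
  only.
- **Reproducibility.** Each subject draws from an independent substream
  keyed by (cohort seed, subject index), so cohorts are identical no matter
  how generation is batched or ordered; one experiment seed drives
  everything downstream.

## Open design points, as resolved here

- "1–3 knots" is read as *internal* knots (boundary knots always present at
  the extreme uncensored log event times), giving the 3 × 3 spline grid.
  Boundary knots use uncensored times only.
- Registry censoring before a lock can reflect loss to follow-up or pure
  administrative cut-off; the generator exposes `ltfu_rate` so either
  regime can be emulated. The default is 0 (administrative only).
- Locks are anchored at enrollment start + maximum follow-up, not at
  per-patient follow-up quantiles; calendar data-cut labels are metadata.
- Non-converged or infeasible fits stay in the results table as flagged
  records and are excluded from model selection — never silently dropped,
  since all-model spreads are themselves an output.
- Conditional RMST is reported only when the conditioning time t₀ lies
  strictly inside the evaluation horizon and the reference KM is positive
  at t₀; otherwise the fields are left missing.

## Limitations

The maturity gradient measured here is conditional on the generating
hazards above; hazards with late plateaus (cure-like behavior) would
stress extrapolation differently and are out of scope, as are mixture,
landmark and relative-survival models, covariate adjustment, interval
censoring, left truncation, and the use of external data to anchor
extrapolated tails. Visual-fit adjudication of curves is a human step;
the package emits the survival/hazard panels but does not score them.
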