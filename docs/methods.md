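# Methods

This note records the models, conventions and numerical choices behind
`maicsurv`, and what the synthetic study conditions do and do not establish
about behaviour on real data.

## Population adjustment

**Restriction.** Eligibility criteria are applied sequentially to the index
IPD; provenance records counts after each step and an empty result raises an
error naming the first criterion that excluded everyone.

**Weights.** Matching is on first moments of binary indicators only
(continuous age is expected to be dichotomised upstream at the comparator
median, mirroring how such trials report it). The weights take the
exponential-tilting / entropy-balancing form anchored at the target vector:
minimising `Q(α) = Σ exp(α'(x_i − x*))` (trust-region Newton with analytic
gradient and Hessian; gradient tolerance 1e-12) enforces the moment
constraints at the optimum, which the solver verifies to 1e-8 and otherwise
raises. A logistic propensity model is not an option here because only
aggregate moments of the comparator exist. Targets must lie strictly inside
the observed covariate support (tolerance 1e-9). Reported weights are
rescaled to sum to the restricted n; `M1b` and `M1c` stage indicators are
matched as two separate binary moments by default (callers can drop either).

## Pseudo-IPD reconstruction

The inversion follows the standard iterative scheme: within each interval
between risk-table times, a censoring count is iterated until the implied
number at risk at the next risk-table time matches the published one, with
events placed exactly at digitized step times and counts solved from the
product-limit ratios. Conventions that matter:

- A digitized step at grid time `t` aggregates events from just before `t`,
  so intervals are right-closed — the published at-risk count at `t` applies
  after the step at `t`. (The same convention makes monthly binning put a
  reconstructed event at time `t` into the bin it truly occurred in; with
  continuous subject-level times the choice is immaterial.)
- Censorings land at the interval midpoint when fewer than 5 are implied,
  else uniformly across the interval; subjects still at risk at the end of
  follow-up are censored there.
- Digitization noise that makes the survival sequence tick upward is
  repaired by isotonic (pool-adjacent-violators) projection before
  inversion; infeasible interval counts are clamped at zero and recorded in
  the result's provenance rather than raised.
- If the publication reports a total event count, a final pass converts
  events↔censorings at step times (preserving the subject count) to match it.
- Time is months everywhere in the package; convert upstream if needed.

## Overall-period comparison

The weighted Cox model has a single binary treatment covariate; lifelines
supplies the Efron-tie partial likelihood and the robust sandwich variance
(weights treated as known — the conservative practice when weights are
estimated). Because the partial likelihood is not exactly invariant to
rescaling one arm's weights against the unit-weight comparator arm, the fit
normalises index weights to mean 1 internally; rescaling by any positive
constant is therefore a no-op by construction. Proportionality is tested
with the Grambsch–Therneau scaled-Schoenfeld test against KM-transformed
time at threshold 0.05; violation hands the endpoint to the time-varying
model (configurable: `always`/`conditional`/`never`).

## Time-varying hazard-ratio model

Subject-level (weighted) data are binned monthly; bin death counts are
binomial given the count entering at risk, with
`q = 1 − exp(−h(t_mid)·Δ)` and the log-hazard a fractional polynomial of
time (powers from {−2, −1, −0.5, 0, 0.5, 1, 2}; `t^0 := ln t`; repeated
powers gain a `ln t` factor). The treatment effect acts on the scale alone
(proportional hazards), the scale plus either shape term, or all three.
Evaluating at bin midpoints keeps `t > 0` for logarithmic and negative
powers. MAIC weights enter as real-valued counts; the binomial log-density
is continued through the gamma function, which preserves the weighted
information without rounding bias (integer rounding remains available by
rounding the grid upstream).

Priors are Normal(0, 100) on every coefficient. Sampling uses an
affine-invariant ensemble (32 walkers, 2000 kept steps after 600 burn-in by
default, thinned to ≤4000 draws), with walkers initialised in a small ball
around the posterior mode found by L-BFGS with analytic gradients. Split-R̂
across walker half-chains above 1.05 on any coefficient flags the fit as
unconverged — flagged, never silent; `rank_models` uses only converged
candidates. DIC is `D̄ + p_D` with `p_D = D̄ − D(posterior mean)`; negative
`p_D` is flagged in diagnostics. Model selection keeps the candidate with
the fewest treatment-effect parameters among those within 3 DIC units of
the minimum ("comparable fit"); the default candidate set crosses three
second-order power pairs — (0,0), (0,1), (−1,1), the shapes usually selected
for immunotherapy-vs-targeted-therapy survival — with the scale-only and
single-shape structures, and the full first- plus second-order grid is
available by configuration when runtime permits.

Hazard-ratio curves are summarised per draw as
`HR(t) = exp(d0 + d1 f0(t) + d2 f1(t))` at integer months; interval
averages over months (t0, t1] are draw-wise arithmetic means of the monthly
values (an event-weighted mean is available, but the arithmetic mean is the
most literal reading of a "12-month average"). Months beyond the last
occupied bin are flagged extrapolated. The comparison is the direct two-arm
(unanchored) one, matching the Cox analysis.

## Safety

The weighted index margin is `p̂·ESS` effective events out of ESS, with
`p̂ = Σw·y/Σw`; the odds ratio is computed from the (possibly fractional)
2×2 table and its 95% credible interval from independent Jeffreys
`Beta(events+0.5, non-events+0.5)` posteriors on the two rates (200 000
draws). Jeffreys-Beta was chosen for fractional-count compatibility; a
published CrI built by other machinery (e.g., a Bayesian logistic model) is
comparable on the point OR but not bit-identical on the interval. Zero
cells raise with a pointer to continuity correction rather than silently
correcting.

## Synthetic study conditions

The generator emulates the evidence base such comparisons actually face: an
index arm of ~103 patients with a realistic binary-covariate mix, and
comparator publications (percent tables rounded to 0.1, KM curves sampled
monthly and rounded to 3 decimals to mimic plot digitization, optional
uniform jitter of ±0.002, at-risk tables at 3–6-month spacing, TRAE
counts). Covariates are independent by default — publications report only
marginals, which is all MAIC matches on — with an exchangeable
Gaussian-copula correlation hook. Event times are drawn by
inverse-transform on the numerically integrated cumulative hazard of a
fractional-polynomial log-hazard (4096-point grid, administrative censoring
at 60 months); PFS is the minimum of the death time and a progression time
drawn from the death hazard scaled by a multiplier > 1 (default 2), which
enforces PFS ≤ OS without modelling the endpoints' joint distribution.

What the generator does **not** emulate: dropout and non-administrative
censoring patterns, crossover and subsequent therapy, correlated effect
modifiers in real registries, non-proportional covariate effects, and
digitization artefacts beyond rounding/jitter. Passing tests therefore show
the machinery is correct under its stated model, not that any published
comparison is reproduced — headline estimates of the motivating analyses
would require the proprietary index IPD and the authors' digitized curves.

Problem sizes in the test and acceptance suites are chosen for Monte Carlo
precision at desk scale: n = 2000/arm where a point estimate is checked
against truth (Cox recovery, FP interval recovery, DIC selection across 50
replicates), n = 200 for reconstruction round trips, n = 103 where the
index-trial scale itself is the point (weighting/ESS), and 200 replicates
for the PH-test type-I error (expected rejection 0.05 ± 0.04 at that
replicate count).

## Known limitations

- The midpoint bin-hazard approximation biases fits when the true hazard
  varies strongly *within* a month (e.g., power-law effects singular at
  t → 0); scenarios and candidate models with bounded early variation are
  unaffected.
- DIC with ensemble MCMC inherits DIC's known weaknesses (focus-dependent,
  can under-penalise); the 3-unit comparability margin follows common
  practice, not a theorem.
- The weighted Cox sandwich variance ignores weight-estimation uncertainty;
  bootstrap-based intervals would be wider still.
- ESS is a summary of weight concentration, not a guarantee of effective
  information for any particular estimand.
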