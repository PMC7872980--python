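# maicsurv

Matching-adjusted indirect comparison (MAIC) of survival and safety outcomes
between a trial with individual patient data (IPD) and comparator trials that
exist only as publications — including pseudo-IPD reconstruction from
digitized Kaplan–Meier curves, exponential-tilting moment-matching weights,
weighted Cox estimation, and Bayesian fractional-polynomial (FP) time-varying
hazard-ratio models.

## Who this is for

Evidence-synthesis and HEOR analysts comparing, e.g., a first-line
immunotherapy doublet (IPD in hand) against targeted-therapy doublets whose
trials are available only as published baseline tables, survival figures with
numbers-at-risk, and adverse-event counts. No head-to-head randomized data
are needed: the index trial's patients are reweighted to the comparator
population, and the comparator's subject-level data are rebuilt from its
figures.

## The method

**Weighting.** With binary effect modifiers `x_i` in the index IPD and the
comparator's published proportions `x*`, patients receive weights

    w_i = exp(α'(x_i − x*)),   α = argmin Σ_i exp(α'(x_i − x*))

so that the weighted index means equal `x*` exactly (the stationarity
condition of the convex objective). Precision loss is summarised by Kish's
effective sample size `ESS = (Σw)² / Σw²`.

**Reconstruction.** A digitized curve plus numbers-at-risk is inverted into
per-subject (time, event) pairs: within each inter-risk-table interval, event
and censoring counts are solved so the product-limit steps and the next
at-risk count are both matched.

**Comparison.** The overall-period hazard ratio comes from a weighted Cox
model (Efron ties, robust sandwich variance) of the weighted index arm versus
the reconstructed comparator arm, with the Grambsch–Therneau test flagging
proportional-hazards violations. When PH fails, survival is binned monthly
and the log-hazard is modelled as a second-order fractional polynomial,

    ln h_k(t) = β0 + β1 t^(p0) + β2 t^(p1) + arm_k (d0 + d1 t^(p0) + d2 t^(p1))

with `t^0 := ln t` and repeated powers picking up a `ln t` factor. Candidate
powers/effect structures are ranked by DIC (simplest model within 3 units of
the best wins) and the selected posterior yields monthly hazard ratios and
interval averages (months 1–12, 13–60) with 95% credible intervals,
extrapolated to 60 months where follow-up is shorter. Grade 3/4
treatment-related adverse events are compared through an odds ratio on the
weighted 2×2 margin, with Jeffreys-Beta credible intervals that accept
fractional counts.

Because real comparisons of this kind hinge on proprietary IPD, the package
ships a synthetic-data module that generates complete two-trial scenarios —
index IPD plus comparator "publications" — with known ground-truth hazard
ratios, so every stage is testable end to end.

## Worked example

Reweight a 103-patient index arm to a comparator baseline
(`examples/03_maic_weighting.py`):

```
ESS after weighting: 90.50 of n=103
     age_gt55: unweighted 0.544 -> weighted 0.500 (target 0.500)
     ecog_ge1: unweighted 0.320 -> weighted 0.279 (target 0.279)
   ldh_gt_uln: unweighted 0.243 -> weighted 0.347 (target 0.347)
```

Every weighted mean hits its target to numerical precision; the ESS drop
from 103 to 90.5 is the information cost of moving the covariate mix.

Compare weighted safety margins (`examples/06_safety_odds_ratio.py`):

```
vs dabrafenib+trametinib:  weighted incidence 65% vs 48%; OR 2.01 (95% CrI 1.20-3.41)
vs vemurafenib+cobimetinib: weighted incidence 66% vs 76%; OR 0.63 (95% CrI 0.38-1.07)
```

The first CrI excludes 1 (significantly more severe adverse events with the
index therapy); the second spans 1 (comparable safety).

Fit the time-varying model on a scenario whose true interval HRs are 1.0
(months 1–12) then 0.4 (`examples/05_time_varying_hr.py`):

```
FP(0.0, 1.0) scale+shape2      DIC    704.5   <- selected
FP(0.0, 0.0) scale+shape1      DIC    751.9
FP(0.0, 0.0) scale             DIC    874.3
HR, months 1-12: 1.03 (95% CrI 0.96-1.11)
HR, months 13-60: 0.43 (95% CrI 0.39-0.48)
```

DIC recovers the generating model and the interval averages recover the
truth. A one-call pipeline (`examples/07_full_pipeline.py`, or `maicsurv run
--config ... --outdir ...` from a shell) chains every stage and writes
`report.json`/`report.md`.

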