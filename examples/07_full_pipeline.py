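"""One-call pipeline: scenario -> publication -> reconstruction ->
restriction -> weighting -> Cox -> PH check -> time-varying analysis ->
safety, with a reproducible report written to disk.
"""

import maicsurv as ms

config = {
    "name": "demo",
    "seed": 42,
    "censor_time": 60.0,
    "endpoints": ["os", "pfs"],
    "time_varying": "conditional",
    "fp_candidates": [
        {"powers": [0, 0], "structure": "scale"},
        {"powers": [0, 0], "structure": "scale+shape1"},
        {"powers": [0, 1], "structure": "scale+shape2"},
    ],
    "covariate_log_hazard_effects": {"ecog_ge1": 0.5, "ldh_gt_uln": 0.4},
    "index": {
        "n": 103,
        "covariates": {"age_gt55": 0.563, "male": 0.621, "ecog_ge1": 0.223,
                       "m1b": 0.136, "m1c": 0.583, "ldh_gt_uln": 0.320},
        "hazard": {"powers": [0, 0], "beta": [-3.9, 0.0, 0.0]},
        "trae_prob": 0.66,
    },
    "comparators": [{
        "name": "targeted-doublet",
        "n": 563,
        "covariates": {"age_gt55": 0.500, "male": 0.568, "ecog_ge1": 0.279,
                       "m1b": 0.185, "m1c": 0.645, "ldh_gt_uln": 0.347},
        "hazard": {"powers": [0, 0], "beta": [-3.6, 0.0, 0.0]},
        "trae_prob": 0.48,
        "match_on": ["age_gt55", "male", "ecog_ge1", "m1b", "m1c", "ldh_gt_uln"],
        "safety": True,
    }],
}

report = ms.run_pipeline(config, outdir="pipeline_out")
c = report.comparators[0]
print(f"comparator {c.name}: restricted n={c.n_restricted}, ESS {c.ess:.2f}")
for endpoint, er in c.endpoints.items():
    line = (f"  {endpoint.upper()}: HR {er.cox.hr:.2f} "
            f"({er.cox.ci95[0]:.2f}-{er.cox.ci95[1]:.2f}), "
            f"PH p={er.cox.ph_test_p:.3f}")
    if er.tvhr is not None:
        ivs = {f"{t0 + 1:.0f}-{t1:.0f}": round(v["hr"], 2)
               for (t0, t1), v in er.tvhr.interval_averages.items()}
        line += f"; time-varying ({er.fp_selected}): {ivs}"
    print(line)
if c.safety is not None:
    print(f"  safety OR {c.safety.or_point:.2f} "
          f"({c.safety.cri95[0]:.2f}-{c.safety.cri95[1]:.2f})")
print("report files: pipeline_out/report.json, pipeline_out/report.md")
# At this index-trial scale (n=103) the credible intervals are wide: the
# point estimates matter less than whether the intervals exclude 1.
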