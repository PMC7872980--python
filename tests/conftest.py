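import numpy as np
import pandas as pd
import pytest

import maicsurv as ms


def exponential_arms(n_per_arm, rate_ref, rate_trt, censor=60.0, seed=0):
    """Two constant-hazard arms: (index DataFrame, comparator PseudoIPD)."""
    rng = np.random.default_rng(seed)
    tt = rng.exponential(1.0 / rate_trt, n_per_arm)
    tr = rng.exponential(1.0 / rate_ref, n_per_arm)
    index = pd.DataFrame({
        "os_time": np.minimum(tt, censor),
        "os_event": (tt <= censor).astype(int),
        "weight": np.ones(n_per_arm),
    })
    comp = ms.PseudoIPD(pd.DataFrame({
        "time": np.minimum(tr, censor),
        "event": (tr <= censor).astype(int),
    }), arm_label="comparator")
    return index, comp


def flat_then_diverging_config(n_per_arm=2000, seed=11, lam=0.06,
                               hr_early=1.0, hr_late=0.4):
    """Scenario whose true interval HRs are hr_early (months 1-12) and
    hr_late (months 13-60), via a log-linear-in-t treatment effect."""
    d0, d2 = ms.powerlaw_hr_components(hr_early, hr_late, powers=(0.0, 1.0), term=1)
    return ms.ScenarioConfig(
        n_index=n_per_arm, n_comparator=n_per_arm,
        hazards={
            "index": ms.HazardSpec((0.0, 1.0), (np.log(lam) + d0, 0.0, d2)),
            "comparator": ms.HazardSpec((0.0, 1.0), (np.log(lam), 0.0, 0.0)),
        },
        seed=seed,
    )


def published_pseudo(config, endpoint="os", rng=None):
    """publish -> digitize -> reconstruct helper returning PseudoIPD."""
    agg = ms.publish_comparator(config, rng=rng)
    curve = ms.DigitizedCurve(agg.km_curves[endpoint]["time"],
                              agg.km_curves[endpoint]["survival"], endpoint)
    risk = ms.RiskTable(agg.risk_tables[endpoint]["time"],
                        agg.risk_tables[endpoint]["n_risk"],
                        total_events=agg.event_totals[endpoint])
    return ms.reconstruct(curve, risk, arm_label=agg.name), agg


@pytest.fixture(scope="session")
def table1_index_prevalences():
    """Index-trial covariate mix used across scenario tests (percent/100)."""
    return {"age_gt55": 0.563, "male": 0.621, "ecog_ge1": 0.223,
            "m1b": 0.136, "m1c": 0.583, "ldh_gt_uln": 0.320}


@pytest.fixture(scope="session")
def table1_comparator_targets():
    """Comparator baseline proportions of the dabrafenib+trametinib style arm."""
    return {"age_gt55": 0.500, "male": 0.568, "ecog_ge1": 0.279,
            "m1b": 0.185, "m1c": 0.645, "ldh_gt_uln": 0.347}
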