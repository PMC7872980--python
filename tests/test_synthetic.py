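import numpy as np
import pandas as pd
import pytest

import maicsurv as ms


class TestGenerateIndexIPD:
    def test_constant_hazard_matches_exponential_survival(self):
        # lambda = 0.05/month -> S(12) = exp(-0.6) ~ 0.549
        cfg = ms.ScenarioConfig(n_index=5000, n_comparator=100,
                                hazards={a: ms.HazardSpec((0, 0), (np.log(0.05), 0, 0))
                                         for a in ("index", "comparator")},
                                seed=7)
        ipd = ms.generate_index_ipd(cfg)
        km = ms.km_estimate(ipd.os_time, ipd.os_event)
        assert km.survival_at(12.0) == pytest.approx(np.exp(-0.6), abs=0.03)

    def test_degenerate_prevalence_gives_constant_covariate(self):
        cfg = ms.ScenarioConfig(n_index=50, n_comparator=10,
                                covariate_prevalences={"index": {"male": 1.0},
                                                       "comparator": {}},
                                seed=1)
        ipd = ms.generate_index_ipd(cfg)
        assert (ipd["male"] == 1).all()

    def test_fixed_seed_reproducible(self):
        cfg = ms.ScenarioConfig(n_index=200, n_comparator=50, seed=5)
        a = ms.generate_index_ipd(cfg)
        b = ms.generate_index_ipd(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_pfs_never_exceeds_os(self):
        cfg = ms.ScenarioConfig(n_index=1000, n_comparator=50, seed=2)
        ipd = ms.generate_index_ipd(cfg)
        assert (ipd.pfs_time <= ipd.os_time + 1e-12).all()

    def test_zero_hazard_rejected(self):
        cfg = ms.ScenarioConfig(
            n_index=10, n_comparator=10,
            hazards={a: ms.HazardSpec((0, 0), (-np.inf, 0, 0))
                     for a in ("index", "comparator")}, seed=0)
        with pytest.raises(ValueError):
            ms.generate_index_ipd(cfg)

    def test_covariate_effect_shifts_hazard(self):
        eff = 1.0
        cfg = ms.ScenarioConfig(
            n_index=4000, n_comparator=50,
            covariate_prevalences={"index": {"ecog_ge1": 0.5}, "comparator": {}},
            covariate_log_hazard_effects={"ecog_ge1": eff},
            hazards={a: ms.HazardSpec((0, 0), (np.log(0.02), 0, 0))
                     for a in ("index", "comparator")},
            seed=3)
        ipd = ms.generate_index_ipd(cfg)
        hi = ipd[ipd.ecog_ge1 == 1]
        lo = ipd[ipd.ecog_ge1 == 0]
        # exposed subgroup must die faster
        assert hi.os_time.mean() < lo.os_time.mean()


class TestPublishComparator:
    def test_risk_table_grid_arithmetic(self):
        cfg = ms.ScenarioConfig(n_index=10, n_comparator=200, seed=1,
                                risk_table_spacing=6.0, censor_time=60.0)
        agg = ms.publish_comparator(cfg)
        assert len(agg.risk_tables["os"]["time"]) == 11
        assert agg.risk_tables["os"]["time"][0] == 0.0
        assert agg.risk_tables["os"]["n_risk"][0] == 200

    def test_constant_hazard_published_survival(self):
        cfg = ms.ScenarioConfig(n_index=10, n_comparator=4000,
                                hazards={a: ms.HazardSpec((0, 0), (np.log(0.05), 0, 0))
                                         for a in ("index", "comparator")},
                                seed=9)
        agg = ms.publish_comparator(cfg)
        t = agg.km_curves["os"]["time"]
        s = agg.km_curves["os"]["survival"]
        assert s[t.index(12.0)] == pytest.approx(np.exp(-0.6), abs=0.03)

    def test_trae_count_binomial(self):
        cfg = ms.ScenarioConfig(n_index=10, n_comparator=211,
                                trae_probs={"index": 0.0, "comparator": 0.48}, seed=4)
        agg = ms.publish_comparator(cfg)
        assert agg.safety["total"] == 211
        # 3-sigma binomial band around 101
        assert abs(agg.safety["events"] - 0.48 * 211) < 3 * np.sqrt(211 * 0.48 * 0.52)

    def test_percentages_converge_to_prevalence(self):
        cfg = ms.ScenarioConfig(
            n_index=10, n_comparator=20000,
            covariate_prevalences={"index": {}, "comparator": {"ldh_gt_uln": 0.347}},
            seed=6)
        agg = ms.publish_comparator(cfg)
        assert agg.baseline["ldh_gt_uln"] == pytest.approx(34.7, abs=1.5)

    def test_round_trip_json(self, tmp_path):
        cfg = ms.ScenarioConfig(n_index=10, n_comparator=50, seed=0)
        agg = ms.publish_comparator(cfg)
        path = tmp_path / "agg.json"
        agg.to_json(path)
        back = ms.AggregateTrial.from_json(path)
        assert back == agg


def test_powerlaw_hr_components_hit_interval_targets():
    d0, d1 = ms.powerlaw_hr_components(1.0, 0.4)
    m = np.arange(1, 61.0)
    hr = np.exp(d0 + d1 * np.log(m))
    assert hr[:12].mean() == pytest.approx(1.0, abs=1e-9)
    assert hr[12:].mean() == pytest.approx(0.4, abs=1e-6)


def test_scenario_truth_null_is_one():
    cfg = ms.ScenarioConfig(n_index=10, n_comparator=10, seed=0)
    truth = ms.scenario_truth(cfg)
    assert truth.true_log_hr_components == (0.0, 0.0, 0.0)
    assert all(v == pytest.approx(1.0) for v in truth.true_interval_hr.values())
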