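import numpy as np
import pandas as pd
import pytest

import maicsurv as ms
from conftest import exponential_arms


class TestFPBasis:
    @pytest.mark.parametrize("t,powers,expected", [
        (1.0, (0, 0), (0.0, 0.0)),                 # ln 1 = 0
        (4.0, (-1, 1), (0.25, 4.0)),               # plain powers, canonical order
        (np.e**2, (0, 0), (2.0, 4.0)),             # repeated zero power
        (4.0, (2, 2), (16.0, 16.0 * np.log(4.0))),  # repeated nonzero power
        (9.0, (0.5,), (3.0,)),                     # first-order basis
    ])
    def test_values(self, t, powers, expected):
        np.testing.assert_allclose(ms.fp_basis(t, powers), expected, rtol=1e-12)

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            ms.fp_basis(0.0, (0, 0))

    def test_noncanonical_powers_rejected(self):
        with pytest.raises(ValueError):
            ms.FPModelSpec((1.0, -1.0), "scale")


class TestBinSurvival:
    def test_hand_binning(self):
        bins = ms.bin_survival([0.5, 1.5, 2.5], [1, 1, 0], width=1.0)
        assert bins.at_risk.tolist() == [3.0, 2.0, 1.0]
        assert bins.events.tolist() == [1.0, 1.0, 0.0]

    def test_no_events(self):
        bins = ms.bin_survival([0.5, 1.5], [0, 0], width=1.0)
        assert bins.events.sum() == 0

    def test_weight_doubling_doubles_counts(self):
        t, e = [0.5, 1.5, 2.5], [1, 0, 1]
        a = ms.bin_survival(t, e, 1.0, weights=[1, 1, 1])
        b = ms.bin_survival(t, e, 1.0, weights=[2, 2, 2])
        np.testing.assert_allclose(b.at_risk, 2 * a.at_risk)
        np.testing.assert_allclose(b.events, 2 * a.events)

    def test_invalid_width(self):
        with pytest.raises(ValueError):
            ms.bin_survival([1.0], [1], width=0.0)


def _null_grid(n=400, seed=0):
    # same subjects on both sides: the treatment effect is exactly null
    index, _ = exponential_arms(n, 0.05, 0.05, seed=seed)
    return ms.HazardGrid.from_subjects(index.os_time, index.os_event,
                                       index.os_time, index.os_event, width=1.0)


class TestFitFP:
    def test_null_case_d_centered_at_zero(self):
        grid = _null_grid(seed=3)
        post = ms.fit_fp(grid, ms.FPModelSpec((0, 0), "scale+shape1"),
                         ms.MCMCControls(seed=1))
        d0 = post.draws[:, 3]
        assert abs(np.median(d0)) < 0.3
        tv = ms.hr_curve(post)
        assert ((tv.monthly.lo <= 1.0) & (tv.monthly.hi >= 1.0)).all()

    def test_constant_hazard_recovery(self):
        index, comp = exponential_arms(2000, 0.05, 0.025, seed=9)
        grid = ms.HazardGrid.from_subjects(index.os_time, index.os_event,
                                           comp.time, comp.event, width=1.0)
        post = ms.fit_fp(grid, ms.FPModelSpec((0, 0), "scale+shape1"),
                         ms.MCMCControls(seed=2))
        d = post.draws
        assert abs(np.median(d[:, 4])) < 0.15  # shape effect near zero
        # implied HR at the average ln-t recovers the true rate ratio 0.5
        tv = ms.hr_curve(post)
        overall = np.exp(np.median(d[:, 3] + d[:, 4] * np.mean(np.log(np.arange(1, 61)))))
        assert 0.4 < overall < 0.6

    def test_weighted_count_rescale_leaves_posterior_stable(self):
        grid = _null_grid(seed=5)
        scaled = ms.HazardGrid(grid.bins.assign(at_risk=grid.bins.at_risk * 2,
                                                events=grid.bins.events * 2),
                               grid.width)
        a = ms.fit_fp(grid, ms.FPModelSpec((0, 0), "scale"), ms.MCMCControls(seed=3))
        b = ms.fit_fp(scaled, ms.FPModelSpec((0, 0), "scale"), ms.MCMCControls(seed=3))
        assert np.median(b.draws[:, 3]) == pytest.approx(np.median(a.draws[:, 3]),
                                                         abs=0.1)

    def test_no_events_rejected(self):
        bins = pd.DataFrame({"arm": [0, 1], "t_start": [0.0, 0.0],
                             "t_end": [1.0, 1.0], "at_risk": [10.0, 10.0],
                             "events": [0.0, 0.0]})
        with pytest.raises(ValueError):
            ms.fit_fp(ms.HazardGrid(bins, 1.0), ms.FPModelSpec((0, 0), "scale"))


def _fake_posterior(dic, structure="scale", draws=None):
    spec = ms.FPModelSpec((0, 0), structure)
    if draws is None:
        draws = np.zeros((10, 6))
    return ms.FPPosterior(spec=spec, draws=draws, dic=dic, dbar=dic, pd=0.0,
                          rhat={}, converged=True, data_end=48.0)


class TestRankModels:
    def test_comparable_fit_prefers_simpler(self):
        rich = _fake_posterior(100.0, "scale+both")
        simple = _fake_posterior(100.5, "scale+shape1")
        _, selected = ms.rank_models([rich, simple])
        assert selected is simple

    def test_clearly_better_complex_model_wins(self):
        rich = _fake_posterior(100.0, "scale+both")
        simple = _fake_posterior(110.0, "scale+shape1")
        _, selected = ms.rank_models([rich, simple])
        assert selected is rich

    def test_single_candidate(self):
        only = _fake_posterior(55.0)
        _, selected = ms.rank_models([only])
        assert selected is only

    def test_no_converged_candidate_raises(self):
        bad = _fake_posterior(10.0)
        bad.converged = False
        with pytest.raises(ValueError):
            ms.rank_models([bad])


class TestHRCurve:
    def test_scale_structure_is_proportional_hazards(self):
        draws = np.zeros((50, 6))
        draws[:, 3] = np.log(0.5) + 0.01 * np.arange(50)
        post = _fake_posterior(0.0, "scale", draws)
        tv = ms.hr_curve(post)
        # monthly HR constant across months in every draw => identical summaries
        assert tv.monthly.hr.nunique() == 1
        for v in tv.interval_averages.values():
            assert v["hr"] == pytest.approx(tv.monthly.hr.iloc[0])

    def test_degenerate_draws_give_constant_hr(self):
        draws = np.zeros((5, 6))
        draws[:, 3] = np.log(0.5)
        tv = ms.hr_curve(_fake_posterior(0.0, "scale", draws))
        np.testing.assert_allclose(tv.monthly.hr, 0.5)
        for v in tv.interval_averages.values():
            assert v["hr"] == pytest.approx(0.5)

    def test_single_draw_interval_mean_is_arithmetic(self):
        # hand-built draw with HR(t) = t over months 1..12 -> average 6.5
        draws = np.zeros((1, 6))
        draws[0, 4] = 1.0  # log HR = ln t with powers (0, 0) shape1
        post = ms.FPPosterior(spec=ms.FPModelSpec((0, 0), "scale+shape1"),
                              draws=draws, dic=0, dbar=0, pd=0, rhat={},
                              converged=True, data_end=60.0)
        tv = ms.hr_curve(post, months=np.arange(1.0, 13.0), intervals=((0, 12),))
        assert tv.interval_averages[(0, 12)]["hr"] == pytest.approx(6.5)

    def test_extrapolation_flagged_beyond_data(self):
        post = _fake_posterior(0.0)
        post.data_end = 48.0
        tv = ms.hr_curve(post, horizon=60.0)
        assert tv.monthly.loc[tv.monthly.month > 48, "extrapolated"].all()
        assert not tv.monthly.loc[tv.monthly.month <= 48, "extrapolated"].any()

    def test_empty_month_list_rejected(self):
        with pytest.raises(ValueError):
            ms.hr_curve(_fake_posterior(0.0), months=[])
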