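import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import maicsurv as ms


def make_ipd(n, prevalences, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({c: (rng.random(n) < p).astype(int)
                         for c, p in prevalences.items()})


class TestRestrict:
    def test_subsetting_counts(self):
        rng = np.random.default_rng(0)
        ipd = pd.DataFrame({"braf_mutant": np.r_[np.ones(103), np.zeros(211)].astype(int)})
        ipd = ipd.sample(frac=1, random_state=1).reset_index(drop=True)
        out, prov = ms.restrict_ipd(ipd, {"braf_mutant": 1})
        assert len(out) == 103
        assert prov["n_before"] == 314 and prov["n_after"] == 103

    def test_empty_criteria_is_identity(self):
        ipd = make_ipd(20, {"male": 0.5})
        out, _ = ms.restrict_ipd(ipd, [])
        pd.testing.assert_frame_equal(out, ipd)

    def test_contradictory_criteria_raise_with_culprit(self):
        ipd = make_ipd(20, {"male": 0.5}, seed=3)
        with pytest.raises(ValueError, match="male == 0"):
            ms.restrict_ipd(ipd, [("male == 1", lambda d: d.male == 1),
                                  ("male == 0", lambda d: d.male == 0)])


class TestSolveWeights:
    def test_identity_tilt_when_targets_equal_means(self):
        ipd = make_ipd(40, {"a": 0.5, "b": 0.3}, seed=2)
        targets = {c: float(ipd[c].mean()) for c in ("a", "b")}
        ws = ms.solve_weights(ipd, targets)
        np.testing.assert_allclose(ws.alpha, 0.0, atol=1e-6)
        np.testing.assert_allclose(ws.weights, 1.0, atol=1e-6)
        assert ws.ess == pytest.approx(40.0, abs=1e-6)

    def test_two_patient_hand_solution(self):
        # x in {0,1}, target 0.75 -> rescaled weights (0.5, 1.5)
        ws = ms.solve_weights(pd.DataFrame({"x": [0, 1]}), {"x": 0.75})
        np.testing.assert_allclose(np.sort(ws.weights), [0.5, 1.5], atol=1e-8)

    def test_weighted_moment_hits_published_target(self, table1_index_prevalences):
        ipd = make_ipd(103, table1_index_prevalences, seed=5)
        ws = ms.solve_weights(ipd, {"ecog_ge1": 0.279})
        wm = float(np.average(ipd["ecog_ge1"], weights=ws.weights))
        assert wm == pytest.approx(0.279, abs=1e-8)

    def test_all_published_moments_match(self, table1_index_prevalences,
                                         table1_comparator_targets):
        ipd = make_ipd(103, table1_index_prevalences, seed=6)
        ws = ms.solve_weights(ipd, table1_comparator_targets)
        for c, target in table1_comparator_targets.items():
            assert float(np.average(ipd[c], weights=ws.weights)) == pytest.approx(
                target, abs=1e-6)
        assert ws.ess < 103

    def test_infeasible_target_rejected(self):
        ipd = pd.DataFrame({"x": [1, 1, 1, 0]})
        with pytest.raises(ValueError, match="support"):
            ms.solve_weights(ipd, {"x": 1.0})

    def test_grid_search_oracle_objective(self):
        # brute-force lattice search cannot beat the optimizer's objective
        ipd = make_ipd(60, {"a": 0.4, "b": 0.6, "c": 0.3}, seed=9)
        targets = {"a": 0.5, "b": 0.5, "c": 0.35}
        ws = ms.solve_weights(ipd, targets, rescale_to_n=False)
        X = ipd[["a", "b", "c"]].to_numpy(float)
        Z = X - np.array([targets[c] for c in ("a", "b", "c")])

        def Q(alpha):
            return np.exp(Z @ np.asarray(alpha)).sum()

        lattice = np.linspace(-2, 2, 21)
        q_grid = min(Q(a) for a in itertools.product(lattice, repeat=3))
        assert Q(ws.alpha) <= q_grid + 1e-4

    def test_ess_monotone_away_from_observed_mean(self):
        ipd = make_ipd(200, {"x": 0.5}, seed=11)
        mean = float(ipd.x.mean())
        ess = [ms.solve_weights(ipd, {"x": t}).ess
               for t in np.linspace(mean, 0.85, 8)]
        assert all(a >= b - 1e-9 for a, b in zip(ess, ess[1:]))


class TestKishESS:
    def test_uniform_weights(self):
        assert ms.kish_ess(np.ones(10)) == pytest.approx(10.0)

    def test_hand_value(self):
        assert ms.kish_ess([2, 1, 1]) == pytest.approx(16 / 6)

    def test_single_nonzero_weight(self):
        assert ms.kish_ess([0, 0, 5]) == pytest.approx(1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            ms.kish_ess([0.0, 0.0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.01, 100), min_size=1, max_size=30),
           st.floats(0.1, 10))
    def test_scale_invariance_and_bounds(self, w, c):
        w = np.asarray(w)
        ess = ms.kish_ess(w)
        assert ms.kish_ess(c * w) == pytest.approx(ess, rel=1e-9)
        assert 1.0 - 1e-9 <= ess <= len(w) + 1e-9
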