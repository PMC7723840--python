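import itertools

import numpy as np
import pytest
from scipy import stats

from pvcouple.core import LfpTrace, SpikeTrain, StateInterval
from pvcouple.states import (
    assign_subtype,
    classify_states_from_lfp,
    cluster_subtypes_kmedoids,
    friedman_statistic,
    state_effect_test,
    state_firing_rates,
    subtype_ratios,
    subtype_unit,
)
from pvcouple.synthetic import SyntheticConfig, gen_lfp


class TestStateRates:
    def test_simple_rate(self):
        spikes = SpikeTrain(np.linspace(0.05, 9.95, 100), "u")
        rates = state_firing_rates(spikes, [StateInterval("AW", 0.0, 10.0)])
        assert rates.rates["AW"] == pytest.approx(10.0)
        assert np.isnan(rates.rates["SWS"])

    def test_empty_train_zero_rates(self):
        intervals = [StateInterval(s, 10.0 * i, 10.0 * (i + 1))
                     for i, s in enumerate(("AW", "QW", "REM", "SWS"))]
        rates = state_firing_rates(SpikeTrain(np.empty(0), "u"), intervals)
        assert all(rates.rates[s] == 0.0 for s in ("AW", "QW", "REM", "SWS"))

    def test_poisson_recovery_within_3se(self):
        rng = np.random.default_rng(0)
        truth = {"AW": 20.0, "QW": 5.0, "REM": 5.0, "SWS": 5.0}
        t_per = 600.0
        intervals, times = [], []
        t0 = 0.0
        for s, r in truth.items():
            intervals.append(StateInterval(s, t0, t0 + t_per))
            n = rng.poisson(r * t_per)
            times.append(rng.uniform(t0, t0 + t_per, n))
            t0 += t_per
        spikes = SpikeTrain(np.sort(np.concatenate(times)), "u")
        rates = state_firing_rates(spikes, intervals)
        for s, r in truth.items():
            se = np.sqrt(r / t_per)
            assert abs(rates.rates[s] - r) < 3 * se

    def test_splitting_interval_invariance(self):
        spikes = SpikeTrain(np.linspace(0.1, 19.9, 60), "u")
        whole = state_firing_rates(spikes, [StateInterval("AW", 0.0, 20.0)])
        split = state_firing_rates(
            spikes, [StateInterval("AW", 0.0, 7.0), StateInterval("AW", 7.0, 20.0)]
        )
        assert whole.rates["AW"] == pytest.approx(split.rates["AW"])

    def test_no_intervals_rejected(self):
        with pytest.raises(ValueError):
            state_firing_rates(SpikeTrain(np.empty(0), "u"), [])


class TestSubtyping:
    def _rates(self, aw, qw, rem, sws):
        from pvcouple.states import StateRates

        return StateRates("u", {"AW": aw, "QW": qw, "REM": rem, "SWS": sws},
                          {s: 600.0 for s in ("AW", "QW", "REM", "SWS")})

    def test_ratio_computation(self):
        r_aw, r_rem, floored = subtype_ratios(self._rates(20.0, 5.0, 5.0, 5.0))
        assert (r_aw, r_rem) == (4.0, 1.0)
        assert not floored

    def test_equal_rates_unit_ratios(self):
        r_aw, r_rem, _ = subtype_ratios(self._rates(5.0, 5.0, 5.0, 5.0))
        assert (r_aw, r_rem) == (1.0, 1.0)

    def test_zero_denominator_floored(self):
        r_aw, r_rem, floored = subtype_ratios(self._rates(1.0, 1.0, 1.0, 0.0))
        assert floored
        assert r_aw == pytest.approx(1.0 / 0.05)

    @pytest.mark.parametrize(
        "ratios,expected",
        [((4.0, 1.0), 1), ((3.0, 2.5), 2), ((1.1, 0.9), 3), ((1.0, 2.0), None)],
    )
    def test_assignment_rule(self, ratios, expected):
        assert assign_subtype(*ratios) == expected

    def test_scale_free(self):
        for scale in (0.1, 1.0, 7.3):
            rates = self._rates(15.0 * scale, 5.0 * scale, 5.0 * scale, 5.0 * scale)
            r_aw, r_rem, _ = subtype_ratios(rates)
            assert assign_subtype(r_aw, r_rem) == 1


class TestFriedman:
    def test_identical_rows_statistic_zero(self):
        mat = np.tile([3.0, 3.0, 3.0, 3.0], (6, 1))
        res = state_effect_test(mat)
        assert res.statistic == 0.0
        assert res.pvalue == 1.0

    def test_hand_ranked_toy_table(self):
        # 4 blocks x 3 conditions; rank sums (5, 8, 11) -> chi2 = 4.5
        mat = np.array([[1, 2, 3], [2, 1, 3], [1, 3, 2], [1, 2, 3]], dtype=float)
        assert friedman_statistic(mat) == pytest.approx(4.5)
        res = state_effect_test(mat, condition_labels=("a", "b", "c"))
        assert res.pvalue == pytest.approx(float(stats.chi2.sf(4.5, 2)))

    def test_matches_scipy_without_ties(self):
        rng = np.random.default_rng(3)
        mat = rng.normal(size=(12, 4))
        stat, p = stats.friedmanchisquare(*mat.T)
        res = state_effect_test(mat)
        assert res.statistic == pytest.approx(stat)
        assert res.pvalue == pytest.approx(p)

    def test_strictly_ordered_rates_significant(self):
        rng = np.random.default_rng(1)
        base = np.array([20.0, 10.0, 5.0, 1.0])
        mat = base + rng.uniform(0, 0.5, (8, 4))
        res = state_effect_test(mat)
        assert res.pvalue < 0.001
        # Dunn post hoc flags the extreme pair most strongly
        assert res.posthoc[("AW", "SWS")] == min(res.posthoc.values())

    def test_chi2_approximation_vs_permutation_n6(self):
        rng = np.random.default_rng(5)
        mat = rng.normal(size=(6, 4)) + np.array([1.0, 0.0, 0.0, -1.0])
        observed = friedman_statistic(mat)
        p_chi2 = float(stats.chi2.sf(observed, 3))
        # permutation null: independently permute each row
        reps = 20_000
        count = 0
        for _ in range(reps):
            perm = np.array([rng.permutation(row) for row in mat])
            if friedman_statistic(perm) >= observed - 1e-12:
                count += 1
        p_perm = count / reps
        assert abs(p_chi2 - p_perm) < 0.02


class TestLfpStateClassifier:
    def test_sws_only_session_all_sws(self):
        states = [StateInterval("SWS", 0.0, 120.0)]
        cfg = SyntheticConfig(seed=3, total_duration=120.0)
        lfp, _ = gen_lfp(states, cfg)
        pred = classify_states_from_lfp(lfp)
        assert {iv.label for iv in pred} == {"SWS"}

    def test_alternating_rem_sws_accuracy(self):
        states = [
            StateInterval("REM" if i % 2 == 0 else "SWS", 10.0 * i, 10.0 * (i + 1))
            for i in range(20)
        ]
        cfg = SyntheticConfig(seed=5, total_duration=200.0, hfo_rate={})
        lfp, _ = gen_lfp(states, cfg)
        pred = classify_states_from_lfp(lfp)
        correct = 0
        for e in range(100):
            t = 2.0 * e + 1.0
            true = "REM" if (int(t) // 10) % 2 == 0 else "SWS"
            lab = next(iv.label for iv in pred if iv.start <= t < iv.end)
            correct += lab == true
        assert correct / 100 >= 0.90

    def test_silent_input_defaults_to_qw(self):
        lfp = LfpTrace(np.zeros(20_000), 1000.0)
        pred = classify_states_from_lfp(lfp, movement=np.zeros(20_000))
        assert {iv.label for iv in pred} == {"QW"}

    def test_movement_marks_aw(self):
        states = [StateInterval("SWS", 0.0, 60.0)]
        cfg = SyntheticConfig(seed=2, total_duration=60.0)
        lfp, _ = gen_lfp(states, cfg)
        movement = np.ones(lfp.n_samples)
        pred = classify_states_from_lfp(lfp, movement=movement)
        assert {iv.label for iv in pred} == {"AW"}


class TestSubtypeRecovery:
    def test_generator_profiles_recovered(self):
        # one unit per subtype, 10 min per state, effect ratio 3
        rng = np.random.default_rng(8)
        intervals = [
            StateInterval(s, 600.0 * i, 600.0 * (i + 1))
            for i, s in enumerate(("AW", "QW", "REM", "SWS"))
        ]
        profiles = {
            1: {"AW": 15.0, "QW": 5.0, "REM": 5.0, "SWS": 5.0},
            2: {"AW": 15.0, "QW": 5.0, "REM": 15.0, "SWS": 5.0},
            3: {"AW": 8.0, "QW": 8.0, "REM": 8.0, "SWS": 8.0},
        }
        for true_subtype, prof in profiles.items():
            times = []
            for iv in intervals:
                n = rng.poisson(prof[iv.label] * iv.duration)
                times.append(rng.uniform(iv.start, iv.end, n))
            spikes = SpikeTrain(np.sort(np.concatenate(times)), f"u{true_subtype}")
            assign = subtype_unit(spikes, intervals)
            assert assign.subtype == true_subtype

    def test_kmedoids_matches_threshold_rule_on_separated_population(self):
        rng = np.random.default_rng(4)
        centers = {1: (3.0, 1.0), 2: (3.0, 3.0), 3: (1.0, 1.0)}
        pairs, truth = [], []
        for subtype, (c_aw, c_rem) in centers.items():
            for _ in range(10):
                pairs.append(
                    (c_aw * rng.lognormal(0, 0.08), c_rem * rng.lognormal(0, 0.08))
                )
                truth.append(subtype)
        labels, _ = cluster_subtypes_kmedoids(np.array(pairs))
        threshold_labels = [assign_subtype(a, r) for a, r in pairs]
        assert labels.tolist() == truth
        assert labels.tolist() == threshold_labels
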