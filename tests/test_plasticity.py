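"""Unit tests for traces, STDP rules, the pairwise oracle and the
retrospective update policy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stdpsim.connectivity import SparseWeightMatrix
from stdpsim.plasticity import (
    PairSTDP,
    PairSTDPParams,
    RetrospectivePairSTDP,
    TraceState,
    TripletSTDP,
    TripletSTDPParams,
    WeightDependence,
    pairwise_oracle,
)

from conftest import step_rule

UNBOUNDED = dict(w_min=-np.inf, w_max=np.inf)


def make_m(w=10.0):
    return SparseWeightMatrix.from_coo(1, 1, [0], [0], [w], dtype=np.float64)


class TestTraces:
    def test_decay_of_zero_stays_zero(self):
        tr = TraceState(3, tau=20.0)
        tr.decay_step(0.1)
        assert np.all(tr.z == 0.0)

    def test_single_decay_step_closed_form(self):
        tr = TraceState(1, tau=20.0)
        tr.z[0] = 1.0
        tr.decay_step(0.1)
        assert tr.z[0] == pytest.approx(np.exp(-1.0 / 200.0), abs=1e-12)

    def test_semigroup_200_small_steps_equal_one_jump(self):
        cont = TraceState(1, tau=20.0, mode="continuous")
        evt = TraceState(1, tau=20.0, mode="event_based")
        cont.z[0] = 1.0
        evt.on_spike([0], now=0.0)
        for _ in range(200):
            cont.decay_step(0.1)
        assert cont.z[0] == pytest.approx(float(evt.get([0], now=20.0)[0]), abs=1e-6)

    def test_first_spike_sets_one(self):
        tr = TraceState(2, tau=20.0, mode="event_based")
        tr.on_spike([1], now=5.0)
        assert tr.get([1], now=5.0)[0] == 1.0

    def test_two_spikes_twenty_ms_apart(self):
        tr = TraceState(1, tau=20.0, mode="event_based")
        tr.on_spike([0], now=0.0)
        tr.on_spike([0], now=20.0)
        assert tr.get([0], now=20.0)[0] == pytest.approx(1 + np.exp(-1.0), abs=1e-12)

    def test_same_timestamp_double_spike(self):
        tr = TraceState(1, tau=20.0, mode="event_based")
        tr.on_spike([0, 0], now=1.0)
        assert tr.get([0], now=1.0)[0] == 2.0

    def test_causality_error(self):
        tr = TraceState(1, tau=20.0, mode="event_based")
        tr.on_spike([0], now=10.0)
        with pytest.raises(ValueError):
            tr.on_spike([0], now=5.0)

    @given(spikes=st.lists(st.integers(0, 400), min_size=1, max_size=30))
    @settings(max_examples=25, deadline=None)
    def test_event_equals_continuous_at_spike_times(self, spikes):
        """Invariant: both trace integration modes agree whenever read."""
        dt, tau = 0.1, 17.0
        steps = sorted(set(spikes))
        cont = TraceState(1, tau=tau, mode="continuous")
        evt = TraceState(1, tau=tau, mode="event_based")
        for step in range(max(steps) + 1):
            now = step * dt
            if step in steps:
                # read before increment, as the engine does
                assert float(cont.z[0]) == pytest.approx(
                    float(evt.get([0], now=now)[0]), abs=1e-5
                )
                evt.on_spike([0], now=now)
                cont.on_spike([0])
            cont.decay_step(dt)


class TestPairSTDP:
    def test_zero_traces_no_change(self):
        m = make_m()
        rule = PairSTDP(m, PairSTDPParams(a_pre=0.0, **UNBOUNDED))
        rule.on_pre_delivered(np.array([0]), now=0.0)
        assert m.weights[0] == 10.0

    def test_depression_closed_form(self):
        # post spiked 10 ms before pre arrival: dw = -exp(-10/20)
        m = make_m()
        p = PairSTDPParams(a_minus=1.0, tau_minus=20.0, learning_rate=1.0, **UNBOUNDED)
        rule = PairSTDP(m, p)
        step_rule(rule, pre_arrival_steps=[100], post_steps=[0], n_steps=101)
        assert m.weights[0] - 10.0 == pytest.approx(-np.exp(-0.5), abs=1e-9)

    def test_potentiation_closed_form(self):
        # pre arrived 10 ms before post: dw = +exp(-10/20)
        m = make_m()
        p = PairSTDPParams(a_plus=1.0, tau_plus=20.0, **UNBOUNDED)
        rule = PairSTDP(m, p)
        step_rule(rule, pre_arrival_steps=[0], post_steps=[100], n_steps=101)
        assert m.weights[0] - 10.0 == pytest.approx(np.exp(-0.5), abs=1e-9)

    def test_same_step_post_acts_before_pre_arrival(self):
        """Pre and post fire in the same step; the pre spike arrives after
        the delay, by which time the post spike is already in the trace:
        the pair is depressing with lag = delay."""
        m = make_m()
        p = PairSTDPParams(a_plus=1.0, a_minus=1.0, tau_plus=20.0, tau_minus=20.0,
                           **UNBOUNDED)
        rule = PairSTDP(m, p)
        # both fire at step 0; axonal delay 8 steps -> arrival at step 8
        step_rule(rule, pre_arrival_steps=[8], post_steps=[0], n_steps=9)
        assert m.weights[0] - 10.0 == pytest.approx(-np.exp(-0.8 / 20.0), abs=1e-9)

    def test_non_hebbian_terms(self):
        m = make_m()
        p = PairSTDPParams(a_pre=0.25, a_post=-0.5, a_plus=0.0, a_minus=0.0,
                           **UNBOUNDED)
        rule = PairSTDP(m, p)
        step_rule(rule, pre_arrival_steps=[0, 10], post_steps=[5], n_steps=11)
        assert m.weights[0] - 10.0 == pytest.approx(2 * 0.25 - 0.5, abs=1e-12)

    def test_weights_stay_clipped(self, rng):
        m = SparseWeightMatrix.from_coo(
            1, 1, [0], [0], [0.5], dtype=np.float64
        )
        p = PairSTDPParams(a_plus=5.0, a_minus=5.0, w_min=0.0, w_max=1.0)
        rule = PairSTDP(m, p)
        pre = rng.choice(300, 30, replace=False)
        post = rng.choice(300, 30, replace=False)
        step_rule(rule, pre_arrival_steps=pre, post_steps=post, n_steps=301)
        assert 0.0 <= m.weights[0] <= 1.0

    def test_multiplicative_weight_dependence_scales_updates(self):
        p = PairSTDPParams(a_plus=1.0, a_minus=1.0, tau_plus=20.0, tau_minus=20.0,
                           w_min=0.0, w_max=2.0)
        wd = WeightDependence(mu=1.0, alpha=1.5)
        m = SparseWeightMatrix.from_coo(1, 1, [0], [0], [0.5], dtype=np.float64)
        rule = PairSTDP(m, p, weight_dependence=wd)
        step_rule(rule, pre_arrival_steps=[0], post_steps=[100], n_steps=101)
        # potentiation scaled by (1 - w/w_max) = 0.75
        assert m.weights[0] - 0.5 == pytest.approx(0.75 * np.exp(-0.5), abs=1e-9)
        m2 = SparseWeightMatrix.from_coo(1, 1, [0], [0], [0.5], dtype=np.float64)
        rule2 = PairSTDP(m2, p, weight_dependence=wd)
        step_rule(rule2, pre_arrival_steps=[100], post_steps=[0], n_steps=101)
        # depression scaled by alpha * w/w_max = 1.5 * 0.25
        assert m2.weights[0] - 0.5 == pytest.approx(
            -1.5 * 0.25 * np.exp(-0.5), abs=1e-9
        )


class TestPairwiseOracle:
    def test_no_spikes_zero(self):
        assert pairwise_oracle([], [], PairSTDPParams()) == 0.0

    def test_single_pair_closed_form(self):
        p = PairSTDPParams(a_plus=1.0, tau_plus=20.0, **UNBOUNDED)
        assert pairwise_oracle([0.0], [10.0], p) == pytest.approx(0.606531, abs=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_oracle_equals_event_driven_implementation(self, seed):
        """The all-to-all trace implementation reproduces the brute-force
        sum over spike pairs for arbitrary spike sets."""
        rng = np.random.default_rng(seed)
        n_pre, n_post = rng.integers(5, 50, size=2)
        p = PairSTDPParams(
            a_plus=0.8, a_minus=1.1, tau_plus=16.0, tau_minus=31.0,
            a_pre=0.02, a_post=-0.01, learning_rate=0.7, **UNBOUNDED
        )
        pre = np.sort(rng.choice(2000, n_pre, replace=False))
        post = np.sort(rng.choice(2000, n_post, replace=False))
        m = make_m()
        rule = PairSTDP(m, p)
        step_rule(rule, pre_arrival_steps=pre, post_steps=post, n_steps=2001)
        expected = pairwise_oracle(pre * 0.1, post * 0.1, p)
        assert m.weights[0] - 10.0 == pytest.approx(expected, abs=1e-6)

    def test_oracle_equals_event_based_trace_mode(self):
        rng = np.random.default_rng(9)
        pre = np.sort(rng.choice(1000, 20, replace=False))
        post = np.sort(rng.choice(1000, 20, replace=False))
        p = PairSTDPParams(a_plus=1.0, a_minus=1.0, **UNBOUNDED)
        m = make_m()
        rule = PairSTDP(m, p, trace_mode="event_based")
        step_rule(rule, pre_arrival_steps=pre, post_steps=post, n_steps=1001)
        expected = pairwise_oracle(pre * 0.1, post * 0.1, p)
        assert m.weights[0] - 10.0 == pytest.approx(expected, abs=1e-6)


class TestTriplet:
    def test_a3_zero_reduces_to_pair_rule(self, rng):
        tp = TripletSTDPParams(a2_plus=0.7, a2_minus=0.9, a3_plus=0.0, a3_minus=0.0,
                               tau_plus=17.0, tau_minus=34.0, **UNBOUNDED)
        pp = PairSTDPParams(a_plus=0.7, a_minus=0.9, tau_plus=17.0, tau_minus=34.0,
                            **UNBOUNDED)
        pre = np.sort(rng.choice(800, 25, replace=False))
        post = np.sort(rng.choice(800, 25, replace=False))
        m1, m2 = make_m(), make_m()
        step_rule(TripletSTDP(m1, tp), pre, post, 801)
        step_rule(PairSTDP(m2, pp), pre, post, 801)
        assert m1.weights[0] == pytest.approx(m2.weights[0], abs=1e-12)

    def test_single_pair_with_zero_slow_traces(self):
        tp = TripletSTDPParams(a2_plus=0.5, a2_minus=0.0, a3_plus=0.9, a3_minus=0.0,
                               tau_plus=20.0, tau_y=40.0, **UNBOUNDED)
        m = make_m()
        # one pre at 0 ms, one post at 10 ms: slow post trace is still zero
        # at the post spike (read before increment), so only a2_plus acts
        step_rule(TripletSTDP(m, tp), [0], [100], 101)
        assert m.weights[0] - 10.0 == pytest.approx(0.5 * np.exp(-0.5), abs=1e-9)

    def test_post_pre_post_triplet_hand_expansion(self):
        """post@0, pre-arrival@5ms, post@10ms against hand-expanded traces."""
        tp = TripletSTDPParams(
            a2_plus=0.3, a2_minus=0.4, a3_plus=0.8, a3_minus=0.0,
            tau_plus=15.0, tau_minus=25.0, tau_x=50.0, tau_y=40.0, **UNBOUNDED
        )
        m = make_m()
        step_rule(TripletSTDP(m, tp), [50], [0, 100], 101)
        dep = -0.4 * np.exp(-5.0 / 25.0)  # pre reads z- from post@0
        pot = np.exp(-5.0 / 15.0) * (0.3 + 0.8 * np.exp(-10.0 / 40.0))
        assert m.weights[0] - 10.0 == pytest.approx(dep + pot, abs=1e-9)

    def test_a3_minus_term_uses_slow_pre_trace(self):
        tp = TripletSTDPParams(a2_plus=0.0, a2_minus=0.2, a3_plus=0.0, a3_minus=0.6,
                               tau_minus=25.0, tau_x=50.0, **UNBOUNDED)
        m = make_m()
        # pre arrivals at 0 and 10 ms, post at 5 ms: the second arrival
        # reads z- = exp(-5/25) and its own slow trace zx = exp(-10/50)
        step_rule(TripletSTDP(m, tp), [0, 100], [50], 101)
        expected = -(0.2 + 0.6 * np.exp(-10.0 / 50.0)) * np.exp(-5.0 / 25.0)
        assert m.weights[0] - 10.0 == pytest.approx(expected, abs=1e-9)


class TestRetrospective:
    P = PairSTDPParams(a_plus=0.9, a_minus=1.2, tau_plus=18.0, tau_minus=27.0,
                       a_pre=0.005, a_post=-0.003, learning_rate=0.5, **UNBOUNDED)

    def test_no_posts_between_arrivals_only_pre_terms(self):
        p = PairSTDPParams(a_pre=0.1, a_plus=1.0, a_minus=1.0, **UNBOUNDED)
        m = make_m()
        rule = RetrospectivePairSTDP(m, p, delay=0.8)
        step_rule(rule, pre_arrival_steps=[10, 20], post_steps=[], n_steps=21)
        assert m.weights[0] - 10.0 == pytest.approx(0.2, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 5])
    def test_equals_immediate_policy_axonal(self, seed):
        rng = np.random.default_rng(seed)
        pre = np.sort(rng.choice(1500, 20, replace=False))
        post = np.sort(rng.choice(1500, 25, replace=False))
        m1, m2 = make_m(), make_m()
        step_rule(PairSTDP(m1, self.P), pre, post, 1501)
        retro = RetrospectivePairSTDP(m2, self.P, delay=0.8, dendritic=False,
                                      history_size=64)
        step_rule(retro, pre, post, 1501, flush=True)
        assert m1.weights[0] == pytest.approx(m2.weights[0], abs=1e-6)

    def test_dendritic_flips_sign_class_of_close_pair(self):
        """Pre fires at 0, post at 0.4 ms, delay 0.8 ms.  Axonal: the post
        spike reaches the synapse first (depression).  Dendritic: the pre
        spike reaches it first (potentiation)."""
        p = PairSTDPParams(a_plus=1.0, a_minus=1.0, tau_plus=20.0, tau_minus=20.0,
                           **UNBOUNDED)
        results = {}
        for dendritic in (False, True):
            m = make_m()
            rule = RetrospectivePairSTDP(m, p, delay=0.8, dendritic=dendritic,
                                         history_size=16)
            # pre fires step 0 -> arrival step 8; post fires step 4
            step_rule(rule, pre_arrival_steps=[8], post_steps=[4], n_steps=400,
                      flush=True)
            results[dendritic] = float(m.weights[0]) - 10.0
        assert results[False] == pytest.approx(-np.exp(-0.4 / 20.0), abs=1e-9)
        assert results[True] == pytest.approx(np.exp(-1.2 / 20.0), abs=1e-9)

    def test_history_overflow_raises(self):
        p = PairSTDPParams(**UNBOUNDED)
        m = make_m()
        rule = RetrospectivePairSTDP(m, p, delay=0.8, history_size=4)
        with pytest.raises(RuntimeError, match="history_size"):
            # 10 post spikes, then a pre arrival needing all of them
            step_rule(rule, pre_arrival_steps=[100],
                      post_steps=list(range(10)), n_steps=101)


def test_lambda_zero_is_inert(rng):
    p = PairSTDPParams(learning_rate=0.0)
    m = make_m()
    rule = PairSTDP(m, p)
    pre = rng.choice(200, 10, replace=False)
    post = rng.choice(200, 10, replace=False)
    step_rule(rule, pre, post, 201)
    assert m.weights[0] == 10.0
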