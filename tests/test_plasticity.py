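"""STDP window, nearest-neighbor accumulation, homeostatic scaling."""

import math

import numpy as np
import pytest

from helpers import oracle_nearest_neighbor, random_event_train
from snnevo.plasticity import (
    HomeostasisState,
    PlasticConnectionState,
    STDPPolarity,
    STDPRule,
    apply_weight_update,
    stability_factor,
    stdp_window,
    update_rate_estimate,
)

EE = STDPRule(a_plus=1e-5, a_minus=1.2e-5, tau_plus=20.0, tau_minus=40.0,
              polarity=STDPPolarity.E_E)
EI = STDPRule(a_plus=1e-5, a_minus=1.2e-5, tau_plus=20.0, tau_minus=40.0,
              polarity=STDPPolarity.E_I)


class TestWindow:
    def test_ee_potentiation_value(self):
        assert stdp_window(10.0, EE) == pytest.approx(1e-5 * math.exp(-0.5))

    def test_ee_depression_sign(self):
        assert stdp_window(-10.0, EE) == pytest.approx(-1.2e-5 * math.exp(-0.25))

    def test_ei_reversed_polarity(self):
        # pre-before-post (dt > 0) depresses an E->I synapse ...
        assert stdp_window(10.0, EI) < 0
        # ... and pre-after-post potentiates it
        assert stdp_window(-10.0, EI) > 0

    @pytest.mark.parametrize("rule", [EE, EI])
    def test_decays_to_zero_at_large_lag(self, rule):
        assert stdp_window(1e6, rule) == pytest.approx(0.0, abs=1e-30)
        assert stdp_window(-1e6, rule) == pytest.approx(0.0, abs=1e-30)

    @pytest.mark.parametrize("rule", [EE, EI])
    def test_simultaneous_spikes_contribute_nothing(self, rule):
        assert stdp_window(0.0, rule) == 0.0


def make_conn(n_pre=3, n_post=2, rule=EE, w_max=1.0):
    return PlasticConnectionState(w=np.zeros((n_pre, n_post)), w_max=w_max, rule=rule)


class TestNearestNeighbor:
    def test_single_nearest_pre_is_paired(self):
        conn = make_conn(n_pre=1, n_post=1)
        conn.on_spikes(0.0, [0], [])
        conn.on_spikes(9.0, [0], [])
        conn.on_spikes(10.0, [], [0])
        # only the 9-ms pre spike pairs with the post spike (dt = 1 ms);
        # no post spike precedes any pre spike, so no depression at all
        assert conn.ltp_acc[0, 0] == pytest.approx(EE.a_plus * math.exp(-1 / EE.tau_plus))
        assert conn.ltd_acc[0, 0] == 0.0

    def test_unpaired_pre_accumulates_nothing(self):
        conn = make_conn()
        conn.on_spikes(5.0, [0, 1, 2], [])
        assert np.all(conn.ltp_acc == 0)
        assert np.all(conn.ltd_acc == 0)

    def test_alternating_train_sums_per_pair(self):
        conn = make_conn(n_pre=1, n_post=1)
        lag = 5.0
        n_pairs = 20
        t = 0.0
        for _ in range(n_pairs):
            conn.on_spikes(t, [0], [])
            conn.on_spikes(t + lag, [], [0])
            t += 100.0  # large gap: each post also pairs with the same pre only
        per_pair_ltp = EE.a_plus * math.exp(-lag / EE.tau_plus)
        assert conn.ltp_acc[0, 0] == pytest.approx(n_pairs * per_pair_ltp)
        # every pre spike after the first also pairs with the previous post
        per_pair_ltd = -EE.a_minus * math.exp(-(100.0 - lag) / EE.tau_minus)
        assert conn.ltd_acc[0, 0] == pytest.approx((n_pairs - 1) * per_pair_ltd)

    def test_time_reversal_rejected(self):
        conn = make_conn()
        conn.on_spikes(10.0, [0], [])
        with pytest.raises(RuntimeError):
            conn.on_spikes(9.0, [0], [])

    @pytest.mark.parametrize("rule", [EE, EI])
    def test_matches_exhaustive_oracle_exactly(self, rule, rng):
        """Random trains of up to 200 events agree with the brute-force
        event-list oracle bit-for-bit."""
        for _ in range(25):
            n_events = int(rng.integers(10, 201))
            events = random_event_train(rng, n_events, n_pre=3, n_post=2)
            conn = make_conn(rule=rule)
            for t, pre_ids, post_ids in events:
                conn.on_spikes(t, pre_ids, post_ids)
            ltp, ltd = oracle_nearest_neighbor(events, 3, 2, rule)
            np.testing.assert_array_equal(conn.ltp_acc, ltp)
            np.testing.assert_array_equal(conn.ltd_acc, ltd)


class TestRateEstimate:
    def test_converges_to_constant_rate(self):
        h = HomeostasisState(r_target=10.0)
        for _ in range(100):  # 100 s >> T = 10 s
            update_rate_estimate(h, 10.0)
        assert h.r_bar == pytest.approx(10.0, rel=0.01)

    def test_decays_to_zero_without_spikes(self):
        h = HomeostasisState(r_target=10.0, r_bar=8.0)
        for _ in range(200):
            update_rate_estimate(h, 0.0)
        assert h.r_bar == pytest.approx(0.0, abs=1e-6)

    def test_step_response_closed_form(self):
        h = HomeostasisState(r_target=10.0)
        for _ in range(10):  # ~T seconds after a 0 -> 20 Hz step
            update_rate_estimate(h, 20.0)
        exact = 20.0 * (1 - (1 - 1 / 10) ** 10)
        assert h.r_bar == pytest.approx(exact)
        assert h.r_bar == pytest.approx(20.0 * (1 - math.exp(-1)), rel=0.05)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            update_rate_estimate(HomeostasisState(r_target=10.0), -1.0)


class TestWeightApplication:
    def test_stability_factor_at_target(self):
        # at Rbar = Rtarget both readings reduce to Rbar / T
        assert stability_factor(10.0, 10.0) == pytest.approx(1.0)
        assert stability_factor(10.0, 10.0, damping_form=False) == pytest.approx(1.0)

    def test_damping_form_numeric_example(self):
        k = stability_factor(5.0, 10.0, gamma=50.0, t_avg_s=10.0)
        assert k == pytest.approx(5.0 / (10.0 * (1 + 0.5 * 50)))

    def test_zero_rate_freezes_updates(self):
        conn = make_conn(n_pre=1, n_post=1, w_max=1.0)
        conn.w[:] = 0.5
        conn.ltp_acc[:] = 1.0  # large accumulators, yet dw must be 0
        h = HomeostasisState(r_target=10.0, r_bar=0.0)
        dw = apply_weight_update(conn, h)
        assert np.all(dw == 0.0)
        assert np.all(conn.w == 0.5)

    def test_numeric_example(self):
        conn = make_conn(n_pre=1, n_post=1, w_max=1.0)
        conn.w[:] = 0.1
        h = HomeostasisState(r_target=10.0, r_bar=5.0)
        dw = apply_weight_update(conn, h)
        k = 5.0 / (10.0 * 26.0)
        assert dw[0, 0] == pytest.approx(0.1 * 0.1 * 0.5 * k)
        assert dw[0, 0] == pytest.approx(9.6e-5, rel=2e-3)

    def test_sign_follows_rate_mismatch(self):
        for r_bar in (2.0, 5.0, 9.9, 10.0, 10.1, 25.0):
            conn = make_conn(n_pre=1, n_post=1, w_max=10.0)
            conn.w[:] = 0.5
            h = HomeostasisState(r_target=10.0, r_bar=r_bar)
            dw = apply_weight_update(conn, h)
            assert np.sign(dw[0, 0]) == np.sign(1 - r_bar / 10.0)

    def test_accumulators_reset_and_bounds_enforced(self, rng):
        conn = make_conn(n_pre=4, n_post=3, w_max=0.02)
        conn.w = rng.uniform(0, 0.02, size=(4, 3))
        for _ in range(50):
            conn.ltp_acc = rng.uniform(0, 1.0, size=(4, 3))
            conn.ltd_acc = -rng.uniform(0, 1.0, size=(4, 3))
            h = HomeostasisState(r_target=20.0, r_bar=float(rng.uniform(0, 60)))
            apply_weight_update(conn, h)
            assert np.all(conn.w >= 0.0)
            assert np.all(conn.w <= 0.02)
            assert np.all(conn.ltp_acc == 0.0)
            assert np.all(conn.ltd_acc == 0.0)

    def test_at_target_rate_only_stdp_term_remains(self):
        conn = make_conn(n_pre=1, n_post=1, w_max=1.0)
        conn.w[:] = 0.3
        conn.ltp_acc[:] = 2e-4
        conn.ltd_acc[:] = -0.5e-4
        h = HomeostasisState(r_target=10.0, r_bar=10.0)
        dw = apply_weight_update(conn, h)
        assert dw[0, 0] == pytest.approx(1.5e-4 * 1.0)  # beta (LTP+LTD) * K, K = 1
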