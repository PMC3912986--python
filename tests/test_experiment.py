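"""Train/test protocol, decoding and receptive-field extraction."""

import numpy as np
import pytest

from helpers import oracle_population_decode, synthetic_population
from snnevo import build_network, decode_genome
from snnevo.experiment import (
    ProtocolConfig,
    evaluate_individual,
    population_decode,
    receptive_field_image,
    run_trial,
    train_individual,
)
from snnevo.experiment import test_tuning as measure_tuning
from snnevo.simulator import Simulator
from snnevo.stimulus import test_angles as orientation_angles

GENOME = np.full(14, 0.8)


class TestProtocol:
    def test_zero_training_duration_leaves_weights_identical(self):
        proto = ProtocolConfig.micro()
        proto = ProtocolConfig(
            n_train_patterns=proto.n_train_patterns,
            pattern_duration_ms=proto.pattern_duration_ms,
            noise_duration_ms=proto.noise_duration_ms,
            train_repeats=0,
            n_test_angles=4,
            test_duration_ms=200,
        )
        params = decode_genome(GENOME)
        reference = build_network(8, params, np.random.default_rng(11))
        net, _ = run_trial(GENOME, 8, proto, seed=11)
        np.testing.assert_array_equal(net.buff_exc.w, reference.buff_exc.w)

    def test_testing_phase_never_mutates_weights(self):
        params = decode_genome(GENOME)
        net = build_network(8, params, np.random.default_rng(0))
        sim = Simulator(net)
        w_before = net.buff_exc.w.copy()
        proto = ProtocolConfig.micro()
        curve = measure_tuning(sim, orientation_angles(8), proto, np.random.default_rng(1))
        np.testing.assert_array_equal(net.buff_exc.w, w_before)
        assert np.all(curve.rates >= 0)
        assert np.all(curve.rates <= 1000.0)  # physical ceiling at the 1-ms tick

    def test_repeat_with_same_seed_reproduces_rates(self):
        proto = ProtocolConfig.micro()
        _, c1 = run_trial(GENOME, 4, proto, seed=5, plastic=False)
        _, c2 = run_trial(GENOME, 4, proto, seed=5, plastic=False)
        np.testing.assert_array_equal(c1.rates, c2.rates)

    def test_evaluate_individual_is_pure_in_genome_and_seed(self):
        proto = ProtocolConfig.micro()
        r1 = evaluate_individual(GENOME, 4, proto, seed=9)
        r2 = evaluate_individual(GENOME, 4, proto, seed=9)
        assert r1.total == r2.total
        assert (r1.decorr, r1.gauss, r1.max_rate) == (r2.decorr, r2.gauss, r2.max_rate)

    def test_lowest_genome_still_yields_finite_fitness(self):
        proto = ProtocolConfig.micro()
        rep = evaluate_individual(np.zeros(14), 4, proto, seed=2)
        assert np.isfinite(rep.total)
        assert rep.total > 0


class TestHomeostasisAtSystemLevel:
    def test_silent_network_weights_frozen(self):
        """No input -> rate estimate 0 -> stability factor 0: the weights
        cannot drift, even over many applications."""
        params = decode_genome(GENOME)
        net = build_network(8, params, np.random.default_rng(3))
        sim = Simulator(net)
        w0 = net.buff_exc.w.copy()
        sim.run_segment(np.zeros(net.n_buffer), 5000, np.random.default_rng(4), plastic=True)
        np.testing.assert_array_equal(net.buff_exc.w, w0)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_subtarget_firing_pulls_input_weights_up(self, seed):
        """Output neurons firing below their homeostatic target: the
        once-per-second applications must scale incoming weights upward
        (the update carries the sign of 1 - Rbar/Rtarget)."""
        params = decode_genome(GENOME)
        net = build_network(8, params, np.random.default_rng(seed))
        sim = Simulator(net)
        w0_mean = net.buff_exc.w.mean()
        rng = np.random.default_rng(seed + 50)
        rates = np.full(net.n_buffer, params["max_poisson_rate"] * 0.5)
        sim.run_segment(rates, 120_000, rng, plastic=True)
        assert np.all(net.homeo_exc.r_bar < params["r_target_exc"])
        assert net.buff_exc.w.mean() > w0_mean


class TestPopulationDecode:
    def test_collinear_population_decodes_exactly(self):
        res = population_decode(np.full(5, 0.8), np.full(5, 30.0), true_angle=0.8)
        assert res.decoded_angle == pytest.approx(0.8, abs=1e-12)
        assert res.error_deg == pytest.approx(0.0, abs=1e-9)
        assert np.hypot(*res.population_vector) == pytest.approx(1.0)

    def test_symmetric_pair_decodes_to_midpoint(self):
        theta = 1.1
        delta = 0.2
        res = population_decode(
            np.array([theta - delta, theta + delta]), np.array([40.0, 40.0]), theta
        )
        assert res.decoded_angle == pytest.approx(theta, abs=1e-12)

    def test_single_neuron_zero_error(self):
        res = population_decode(np.array([2.0]), np.array([10.0]), true_angle=2.0)
        assert res.error_deg == pytest.approx(0.0, abs=1e-9)

    def test_component_lengths_are_half_rates(self):
        res = population_decode(np.array([0.5, 1.0]), np.array([10.0, 20.0]), 0.7)
        np.testing.assert_allclose(res.component_lengths, [5.0, 10.0])

    def test_all_zero_rates_rejected(self):
        with pytest.raises(ValueError, match="undecodable"):
            population_decode(np.array([1.0, 2.0]), np.zeros(2), 1.0)

    def test_matches_vector_sum_oracle_on_synthetic_population(self):
        rng = np.random.default_rng(99)
        preferred, respond = synthetic_population(rng, n_neurons=400)
        errors = []
        for theta in orientation_angles(8):
            rates = respond(theta)
            res = population_decode(preferred, rates, theta)
            dec_oracle, err_oracle = oracle_population_decode(preferred, rates, theta)
            assert res.decoded_angle == pytest.approx(dec_oracle, abs=1e-9)
            assert res.error_deg == pytest.approx(err_oracle, abs=1e-9)
            errors.append(res.error_deg)
        # a dense, well-tuned synthetic population decodes accurately
        assert np.mean(errors) < 5.0

    def test_orientation_wraparound_near_pi(self):
        res = population_decode(
            np.array([np.pi - 0.05, 0.05]), np.array([30.0, 30.0]), np.pi
        )
        # symmetric straddle of the wrap point decodes onto the seam
        assert min(res.error_deg, 90.0 - res.error_deg) < 1e-6 or res.error_deg < 3.0


class TestReceptiveFields:
    def test_reshape_identity(self):
        params = decode_genome(GENOME)
        net = build_network(4, params, np.random.default_rng(0))
        g = net.grid_size
        template = np.arange(g * g, dtype=float) / (g * g) * net.buff_exc.w_max
        net.buff_exc.w[: g * g, 2] = template  # On weights of neuron 2
        maps = receptive_field_image(net)
        assert maps.shape == (4, 2, g, g)
        np.testing.assert_array_equal(maps[2, 0], template.reshape(g, g))

    def test_uniform_weights_give_flat_maps(self):
        params = decode_genome(GENOME)
        net = build_network(4, params, np.random.default_rng(0))
        net.buff_exc.w[:] = 0.01
        maps = receptive_field_image(net)
        assert np.ptp(maps) == 0.0
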