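import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gainfield as gf


class TestInputLayer:
    def test_default_unit_count(self):
        layer = gf.default_input_layer()
        assert layer.n_units == 92
        assert len(layer.eye_units) == 71
        assert len(layer.retinal_units) == 21

    def test_rate_at_preferred_location_saturates(self):
        # h = 2.0 through slope-4.5 sigmoid: within 2e-8 of 1
        layer = gf.default_input_layer()
        rates = gf.input_rates(layer, x=-10.0, y=100.0)
        # retinal units follow the eye units in the vector
        assert rates[71] == pytest.approx(1.0, abs=2e-8)

    def test_rates_bounded_and_sized(self):
        layer = gf.default_input_layer()
        rates = gf.input_rates(layer, 3.0, -17.0)
        assert rates.shape == (92,)
        assert np.all((rates > 0) & (rates < 1))

    def test_non_finite_inputs_rejected(self):
        layer = gf.default_input_layer()
        with pytest.raises(ValueError):
            gf.input_rates(layer, float("nan"), 0.0)


class TestInitNetwork:
    def test_afferent_count_is_floor_of_percentage(self):
        layer = gf.default_input_layer()
        net = gf.init_network(0, layer, 100)
        assert np.all(net.mask.sum(axis=1) == 9)  # floor(0.10 * 92)

    def test_same_seed_identical_networks(self):
        layer = gf.default_input_layer()
        a = gf.init_network(123, layer, 50)
        b = gf.init_network(123, layer, 50)
        assert np.array_equal(a.weights, b.weights)
        assert np.array_equal(a.mask, b.mask)

    def test_full_connectivity(self):
        layer = gf.default_input_layer()
        net = gf.init_network(0, layer, 10, connectivity_fraction=100.0)
        assert net.mask.all()

    def test_rows_start_at_unit_norm(self):
        layer = gf.default_input_layer()
        net = gf.init_network(0, layer, 100)
        assert np.allclose(np.linalg.norm(net.weights, axis=1), 1.0, atol=1e-12)

    def test_zero_afferents_rejected(self):
        layer = gf.default_input_layer()
        with pytest.raises(ValueError):
            gf.init_network(0, layer, 10, connectivity_fraction=0.5)


class TestDynamics:
    def test_single_full_step_reaches_drive(self, small_network):
        net, layer = small_network
        net.dt = net.tau  # dt = tau collapses the Euler step to h = W v
        v = gf.input_rates(layer, 0.0, 0.0)
        h = gf.step_dynamics(net, v)
        assert np.allclose(h, net.weights @ v, atol=1e-15)

    def test_tenth_step_from_rest(self):
        layer = gf.default_input_layer()
        net = gf.init_network(0, layer, 5)
        net.weights = net.mask * 0.0 + np.eye(5, 92)  # drive = v[:5]
        v = np.ones(92)
        h = gf.step_dynamics(net, v)
        assert np.allclose(h, 0.1)  # dt/tau = 0.1 from rest toward drive 1

    def test_converges_to_fixed_point(self, small_network):
        net, layer = small_network
        v = gf.input_rates(layer, -5.0, 10.0)
        target = net.weights @ v
        for _ in range(200):  # 20 tau
            gf.step_dynamics(net, v)
        assert np.allclose(net.h_state, target, atol=1e-4)


class TestCompetitiveRates:
    def test_all_equal_activations_fire_at_half(self, small_network):
        net, _ = small_network
        net.h_state = np.full(net.n_outputs, 0.7)
        assert np.all(gf.competitive_rates(net) == 0.5)

    def test_top_decile_above_half(self, small_network):
        net, _ = small_network
        net.h_state = np.arange(1.0, 101.0)[: net.n_outputs] * 0 + np.arange(
            1.0, net.n_outputs + 1
        )
        net.sparseness_percentile = 90.0
        rates = gf.competitive_rates(net)
        assert int((rates > 0.5).sum()) == net.n_outputs // 10

    def test_nearest_rank_on_1_to_100(self):
        h = np.arange(1.0, 101.0)
        p = gf.nearest_rank_percentile(h, 90.0)
        assert p == 90.0
        rates = gf.sigmoid_rate(h - p, gf.SigmoidSpec(4.5, 0.0))
        assert int((rates > 0.5).sum()) == 10

    def test_zero_percentile_floors_at_minimum(self, small_network):
        net, _ = small_network
        net.h_state = np.linspace(0, 1, net.n_outputs)
        net.sparseness_percentile = 0.0
        assert np.all(gf.competitive_rates(net) >= 0.5)


class TestHebbianUpdate:
    def test_hand_computed_renormalization(self):
        layer = gf.InputLayer(
            eye_preferred=np.array([0.0]), retinal_preferred=np.array([0.0])
        )
        net = gf.init_network(0, layer, 1, connectivity_fraction=100.0)
        net.weights = np.array([[0.6, 0.8]])
        net.mask = np.ones((1, 2), dtype=bool)
        net.dt, net.learning_rate = 0.05, 1.0  # dt * rate = 0.05
        gf.hebbian_update(net, np.array([1.0, 0.0]), np.array([1.0]))
        assert np.allclose(net.weights, [[0.63059, 0.77611]], atol=5e-6)

    def test_silent_output_row_unchanged(self, small_network):
        net, layer = small_network
        before = net.weights.copy()
        v_in = gf.input_rates(layer, 0.0, 0.0)
        v_out = np.zeros(net.n_outputs)
        v_out[0] = 1.0
        gf.hebbian_update(net, v_in, v_out)
        assert np.allclose(net.weights[1:], before[1:], atol=1e-15)
        assert not np.allclose(net.weights[0], before[0])

    @settings(max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 2**16))
    def test_unit_norm_and_dale_law_preserved(self, seed):
        rng = np.random.default_rng(seed)
        layer = gf.default_input_layer()
        net = gf.init_network(seed, layer, 25)
        for _ in range(5):
            v_in = rng.uniform(0, 1, 92)
            v_out = rng.uniform(0, 1, 25)
            gf.hebbian_update(net, v_in, v_out)
            assert np.allclose(np.linalg.norm(net.weights, axis=1), 1.0,
                               atol=1e-12)
            assert np.all(net.weights >= 0)
            assert np.all(net.weights[~net.mask] == 0)


class TestResponseSurfaces:
    def test_matches_stepwise_evaluation(self, small_network):
        net, layer = small_network
        xs, ys = np.array([0.0, 5.0]), np.array([-10.0, 0.0, 10.0])
        R = gf.response_surfaces(net, layer, xs, ys)
        assert R.shape == (net.n_outputs, 2, 3)
        # independently: settle the integrator and apply competition
        v = gf.input_rates(layer, 5.0, 10.0)
        net.h_state = net.weights @ v
        expected = gf.competitive_rates(net)
        assert np.allclose(R[:, 1, 2], expected, atol=1e-12)


class TestCheckpoint:
    def test_round_trip(self, tmp_path, small_network):
        net, _ = small_network
        net.config = {"rho": 15.0}
        gf.save_network(net, tmp_path / "ckpt")
        loaded = gf.load_network(tmp_path / "ckpt")
        assert np.allclose(loaded.weights, net.weights, atol=1e-12)
        assert np.array_equal(loaded.mask, net.mask)
        assert loaded.tau == net.tau
        assert loaded.config == {"rho": 15.0}
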