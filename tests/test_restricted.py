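import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from parsyn.restricted import (
    RestrictedNeuron,
    TrainConfig,
    gradient_step,
    hinge_loss,
    initialize_neuron,
    predict,
    resurrect_synapses,
    somatic_input,
    synapse_response,
    to_sigmoid_form,
    train_restricted,
    violating_set,
)
from parsyn.tasks import PatternSet, generate_patterns


def random_neuron(rng, n_axons=2, n_synapses=2, param_form="sigmoid"):
    return initialize_neuron(n_axons, n_synapses, (0.0, 1.0), rng, param_form)


class TestSynapseResponse:
    def test_at_threshold(self):
        assert synapse_response(1.0, 5.0, 0.5, 0.5) == pytest.approx(0.5)

    def test_zero_slope_constant(self):
        assert synapse_response(2.0, 0.0, 0.3, 0.9) == pytest.approx(2.0)

    def test_high_precision_point(self):
        # a=1, s=10, t=0.5, x=1.0 -> 1/(1+e^-5)
        expected = 1.0 / (1.0 + np.exp(-5.0))
        assert synapse_response(1.0, 10.0, 0.5, 1.0) == pytest.approx(
            expected, abs=1e-12
        )

    def test_negative_slope_rejected(self):
        with pytest.raises(ValueError):
            synapse_response(1.0, -0.1, 0.5, 0.5)

    @given(
        st.floats(-3, 3),
        st.floats(0, 50),
        st.floats(-1, 2),
        st.floats(-1, 2),
        st.floats(-1, 2),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_and_bounded(self, a, s, t, x1, x2):
        lo, hi = sorted((x1, x2))
        r1, r2 = synapse_response(a, s, t, lo), synapse_response(a, s, t, hi)
        assert r1 <= r2 + 1e-12
        assert -1e-12 <= r1 <= a * a + 1e-12


class TestSomaticInput:
    def test_zero_amplitudes(self, small_task):
        neuron = RestrictedNeuron(
            np.zeros((3, 2)), np.ones((3, 2)), np.zeros((3, 2)), 0.0
        )
        np.testing.assert_array_equal(somatic_input(neuron, small_task), 0.0)

    def test_constant_synapses(self):
        ps = generate_patterns(2, 5, seed=0)
        neuron = RestrictedNeuron(
            np.ones((2, 1)), np.zeros((2, 1)), np.zeros((2, 1)), 0.0
        )
        np.testing.assert_allclose(somatic_input(neuron, ps), 1.0)

    def test_matches_per_synapse_sum(self, rng, small_task):
        neuron = random_neuron(rng, n_axons=3, n_synapses=2)
        z = somatic_input(neuron, small_task)
        brute = np.zeros(small_task.n_patterns)
        for mu in range(small_task.n_patterns):
            for i in range(3):
                for j in range(2):
                    brute[mu] += synapse_response(
                        neuron.amp_root[i, j],
                        neuron.slope[i, j],
                        neuron.threshold[i, j],
                        small_task.inputs[mu, i],
                    )
        np.testing.assert_allclose(z, brute, rtol=1e-12)

    def test_dimension_mismatch(self, rng, small_task):
        neuron = random_neuron(rng, n_axons=5)
        with pytest.raises(ValueError):
            somatic_input(neuron, small_task)


class TestPredict:
    def test_tie_maps_to_minus_one(self):
        ps = PatternSet(np.array([[0.5]]), np.array([1.0]))
        neuron = RestrictedNeuron(
            np.zeros((1, 1)), np.ones((1, 1)), np.zeros((1, 1)), 0.0
        )
        assert predict(neuron, ps)[0] == -1.0

    def test_negative_theta_all_positive(self, small_task):
        neuron = RestrictedNeuron(
            np.zeros((3, 1)), np.ones((3, 1)), np.zeros((3, 1)), -1.0
        )
        np.testing.assert_array_equal(predict(neuron, small_task), 1.0)

    def test_compositional(self, rng, small_task):
        neuron = random_neuron(rng, n_axons=3)
        z = somatic_input(neuron, small_task)
        expected = np.where(z - neuron.soma_threshold > 0, 1.0, -1.0)
        np.testing.assert_array_equal(predict(neuron, small_task), expected)


class TestHingeLoss:
    def test_zero_when_margins_met(self):
        assert hinge_loss(np.array([0.2, -0.2]), np.array([1.0, -1.0]), 0.0, 0.1) == 0.0

    def test_partial_margin(self):
        assert hinge_loss(np.array([0.05]), np.array([1.0]), 0.0, 0.1) == pytest.approx(
            0.05
        )

    def test_misclassified(self):
        assert hinge_loss(np.array([-1.0]), np.array([1.0]), 0.0, 0.1) == pytest.approx(
            1.1
        )

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            hinge_loss(np.array([1.0]), np.array([1.0, -1.0]), 0.0, 0.1)


class TestViolatingSet:
    def test_empty_when_all_satisfied(self):
        out = violating_set(np.array([1.0, -1.0]), np.array([1.0, -1.0]), 0.0, 0.1)
        assert out.size == 0

    def test_exact_margin_excluded(self):
        out = violating_set(np.array([0.1]), np.array([1.0]), 0.0, 0.1)
        assert out.size == 0

    def test_matches_enumeration(self, rng):
        z = rng.normal(size=30)
        y = rng.choice([-1.0, 1.0], size=30)
        theta, eps = 0.3, 0.1
        got = set(violating_set(z, y, theta, eps).tolist())
        want = {mu for mu in range(30) if eps - (z[mu] - theta) * y[mu] > 0}
        assert got == want


class TestGradientStep:
    def test_no_violators_no_change(self):
        ps = PatternSet(np.array([[0.9], [0.1]]), np.array([1.0, -1.0]))
        neuron = RestrictedNeuron(
            np.ones((1, 1)) * 2.0, np.full((1, 1), 50.0), np.full((1, 1), 0.5), 2.0
        )
        out = gradient_step(neuron, ps, TrainConfig())
        assert out is neuron

    def test_theta_update_single_pattern(self):
        # one misclassified y=+1 pattern: theta decreases by exactly eta_soma
        ps = PatternSet(np.array([[0.5]]), np.array([1.0]))
        neuron = RestrictedNeuron(
            np.zeros((1, 1)), np.ones((1, 1)), np.zeros((1, 1)), 1.0
        )
        cfg = TrainConfig()
        out = gradient_step(neuron, ps, cfg)
        assert out.soma_threshold == pytest.approx(1.0 - cfg.eta_soma)

    @pytest.mark.parametrize("param_form", ["sigmoid", "tanh"])
    def test_matches_finite_differences(self, param_form):
        # Each update must equal -eta * dL/dparam for the hinge loss.
        rng = np.random.default_rng(99)
        cfg = TrainConfig(eta_amp=0.01, eta_slope=0.01, eta_threshold=0.01, eta_soma=0.01)
        worst = 0.0
        for trial in range(100):
            ps = generate_patterns(1, 3, seed=trial)
            neuron = initialize_neuron(1, 1, (0.0, 1.0), rng, param_form)
            # moderate slope keeps finite differences well-conditioned
            neuron = dataclasses.replace(neuron, slope=rng.uniform(1, 8, (1, 1)))
            new = gradient_step(neuron, ps, cfg)

            def loss_of(n):
                return hinge_loss(
                    somatic_input(n, ps), ps.labels, n.soma_threshold, cfg.margin
                )

            h = 1e-6
            for field, eta in [
                ("amp_root", cfg.eta_amp),
                ("slope", cfg.eta_slope),
                ("threshold", cfg.eta_threshold),
            ]:
                arr = getattr(neuron, field)
                up, dn = arr.copy(), arr.copy()
                up[0, 0] += h
                dn[0, 0] -= h
                fd = (
                    loss_of(dataclasses.replace(neuron, **{field: up}))
                    - loss_of(dataclasses.replace(neuron, **{field: dn}))
                ) / (2 * h)
                if field == "slope" and getattr(new, field)[0, 0] == 0.0:
                    continue  # clipped at zero: update is not the raw gradient
                got = getattr(new, field)[0, 0] - arr[0, 0]
                want = -eta * fd
                if abs(want) > 1e-9:
                    worst = max(worst, abs(got - want) / abs(want))
            fd_theta = (
                loss_of(
                    dataclasses.replace(
                        neuron, soma_threshold=neuron.soma_threshold + h
                    )
                )
                - loss_of(
                    dataclasses.replace(
                        neuron, soma_threshold=neuron.soma_threshold - h
                    )
                )
            ) / (2 * h)
            got = new.soma_threshold - neuron.soma_threshold
            want = -cfg.eta_soma * fd_theta
            if abs(want) > 1e-9:
                worst = max(worst, abs(got - want) / abs(want))
        assert worst < 1e-4

    def test_slope_clipped_nonnegative(self, rng):
        for trial in range(20):
            ps = generate_patterns(2, 6, seed=trial)
            neuron = random_neuron(rng)
            out = gradient_step(
                neuron, ps, TrainConfig(eta_slope=5.0)  # huge rate forces clipping
            )
            assert np.all(out.slope >= 0)


class TestResurrection:
    def test_above_floor_untouched(self):
        neuron = RestrictedNeuron(
            np.array([[np.sqrt(0.02)]]), np.ones((1, 1)), np.array([[0.4]]), 0.0
        )
        out = resurrect_synapses(neuron, 0.01, (0.0, 1.0), seed=0)
        assert out is neuron

    def test_below_floor_raised_exactly(self):
        neuron = RestrictedNeuron(
            np.array([[1e-3]]), np.ones((1, 1)), np.array([[0.4]]), 0.0
        )
        out = resurrect_synapses(neuron, 0.01, (0.0, 1.0), seed=0)
        assert out.amp_root[0, 0] ** 2 == pytest.approx(0.01)
        assert 0.0 <= out.threshold[0, 0] <= 1.0

    def test_edge_biased_resampling(self):
        # Beta(1/2, 1/2): P(edges [0,.1]∪[.9,1]) ≈ 0.41 vs P([.45,.55]) ≈ 0.064;
        # at n=10000 a 5-sigma binomial band keeps the counts far apart.
        n = 10000
        neuron = RestrictedNeuron(
            np.zeros((n, 1)), np.ones((n, 1)), np.full((n, 1), 0.5), 0.0
        )
        out = resurrect_synapses(neuron, 0.01, (0.0, 1.0), seed=5)
        t = out.threshold.ravel()
        edges = np.sum((t <= 0.1) | (t >= 0.9))
        center = np.sum((t >= 0.45) & (t <= 0.55))
        assert edges > center

    def test_empty_range_rejected(self):
        neuron = RestrictedNeuron(
            np.zeros((1, 1)), np.ones((1, 1)), np.zeros((1, 1)), 0.0
        )
        with pytest.raises(ValueError):
            resurrect_synapses(neuron, 0.01, (0.5, 0.5), seed=0)


class TestTraining:
    def test_single_pattern_always_solvable(self):
        for seed in range(3):
            ps = generate_patterns(4, 1, seed=seed)
            _, success, _ = train_restricted(
                ps, 1, TrainConfig(max_epochs=2000, seed=seed)
            )
            assert success

    def test_xor_unsolvable(self, xor_task):
        _, success, _ = train_restricted(
            xor_task, 2, TrainConfig(max_epochs=3000, seed=0)
        )
        assert not success

    def test_low_load_mostly_solved(self):
        # P = 20 patterns on N = 20 axons is far below capacity
        wins = 0
        for seed in range(10):
            ps = generate_patterns(20, 20, seed=seed)
            _, ok, _ = train_restricted(
                ps, 2, TrainConfig(max_epochs=5000, seed=seed)
            )
            wins += ok
        assert wins >= 9

    def test_deterministic_trajectory(self):
        ps = generate_patterns(5, 10, seed=3)
        cfg = TrainConfig(max_epochs=200, seed=11)
        n1, s1, e1 = train_restricted(ps, 2, cfg)
        n2, s2, e2 = train_restricted(ps, 2, cfg)
        assert (s1, e1) == (s2, e2)
        np.testing.assert_array_equal(n1.amp_root, n2.amp_root)
        np.testing.assert_array_equal(n1.threshold, n2.threshold)

    def test_slopes_stay_nonnegative_through_training(self):
        ps = generate_patterns(4, 12, seed=2)
        neuron, _, _ = train_restricted(ps, 2, TrainConfig(max_epochs=500, seed=2))
        assert np.all(neuron.slope >= 0)


class TestFormEquivalence:
    def test_mapping_values(self):
        neuron = RestrictedNeuron(
            np.array([[1.0]]), np.array([[1.0]]), np.array([[0.5]]), 0.0, "tanh"
        )
        out = to_sigmoid_form(neuron)
        assert out.amp_root[0, 0] ** 2 == pytest.approx(2.0)
        assert out.slope[0, 0] == pytest.approx(2.0)
        assert out.threshold[0, 0] == pytest.approx(0.5)

    def test_zero_amplitude_neuron(self, small_task):
        neuron = RestrictedNeuron(
            np.zeros((3, 1)), np.ones((3, 1)), np.zeros((3, 1)), -0.5, "tanh"
        )
        out = to_sigmoid_form(neuron)
        np.testing.assert_array_equal(
            predict(neuron, small_task), predict(out, small_task)
        )

    def test_prediction_identity_random(self, rng):
        for _ in range(10):
            neuron = random_neuron(rng, n_axons=4, n_synapses=3, param_form="tanh")
            neuron = dataclasses.replace(
                neuron, soma_threshold=float(rng.normal())
            )
            sig = to_sigmoid_form(neuron)
            ps = generate_patterns(4, 100, seed=int(rng.integers(1e6)))
            z_tanh = somatic_input(neuron, ps) - neuron.soma_threshold
            z_sig = somatic_input(sig, ps) - sig.soma_threshold
            np.testing.assert_allclose(z_tanh, z_sig, atol=1e-10)
            np.testing.assert_array_equal(
                predict(neuron, ps), predict(sig, ps)
            )

    def test_wrong_form_rejected(self, rng):
        neuron = random_neuron(rng, param_form="sigmoid")
        with pytest.raises(ValueError):
            to_sigmoid_form(neuron)


class TestSerialization:
    def test_json_round_trip(self, rng):
        neuron = random_neuron(rng, n_axons=3, n_synapses=2, param_form="tanh")
        back = RestrictedNeuron.from_json(neuron.to_json())
        np.testing.assert_array_equal(back.amp_root, neuron.amp_root)
        np.testing.assert_array_equal(back.slope, neuron.slope)
        np.testing.assert_array_equal(back.threshold, neuron.threshold)
        assert back.soma_threshold == neuron.soma_threshold
        assert back.param_form == neuron.param_form
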