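"""Core model: convolution stack, weighted potentials, chain algorithms."""
import itertools

import numpy as np
import pytest

from conftest import random_chain, random_model
from deepcnf import reference
from deepcnf.model import (ArchitectureSpec, ModelFormatError, ModelParams,
                           ShapeError, classify, conditional_log_prob,
                           dcnn_forward, partition_log, posterior_marginals,
                           sequence_score, weighted_potentials)
from deepcnf.types import FeatureMatrix, LabelSequence


class TestDcnnForward:
    @pytest.mark.parametrize("activation,expected", [("sigmoid", 0.5), ("tanh", 0.0)])
    def test_zero_weights_give_constant_activation(self, rng, activation, expected):
        arch = ArchitectureSpec.create(input_dim=5, layers=2, neurons=4,
                                       half_window=2, activation=activation)
        params = ModelParams.zeros(arch)
        x, _ = random_chain(rng, 7, 5)
        acts = dcnn_forward(params, x)
        for hidden in acts.layers[1:]:
            assert np.allclose(hidden, expected)

    def test_hand_computed_windowed_sum(self):
        """L=3, M=1, N=1, K=2: match the recursion evaluated by hand with zero padding."""
        arch = ArchitectureSpec.create(input_dim=1, layers=2, neurons=1, half_window=1)
        params = ModelParams.zeros(arch)
        # W^1 offsets (-1, 0, +1) = (0.5, 1.0, -0.5); W^2 = (0.2, 0.3, 0.4)
        params.conv_weights[0] = np.array([0.5, 1.0, -0.5]).reshape(3, 1, 1)
        params.conv_weights[1] = np.array([0.2, 0.3, 0.4]).reshape(3, 1, 1)
        x = np.array([[1.0], [2.0], [-1.0]])
        sig = lambda v: 1.0 / (1.0 + np.exp(-v))
        # layer 2: position i sees 0.5*x[i-1] + 1.0*x[i] - 0.5*x[i+1], ends zero-padded
        a2 = sig(np.array([1.0 * 1 - 0.5 * 2, 0.5 * 1 + 1.0 * 2 - 0.5 * (-1), 0.5 * 2 + 1.0 * (-1)]))
        a3 = sig(np.array([0.3 * a2[0] + 0.4 * a2[1],
                           0.2 * a2[0] + 0.3 * a2[1] + 0.4 * a2[2],
                           0.2 * a2[1] + 0.3 * a2[2]]))
        acts = dcnn_forward(params, FeatureMatrix(x))
        np.testing.assert_allclose(acts.layers[1][:, 0], a2, atol=1e-12)
        np.testing.assert_allclose(acts.top[:, 0], a3, atol=1e-12)

    def test_matches_loop_reference(self, rng):
        params = random_model(input_dim=4, layers=3, neurons=3, half_window=2, seed=9)
        x, _ = random_chain(rng, 9, 4)
        fast = dcnn_forward(params, x)
        slow = reference.naive_forward(params, x.values)
        for a, b in zip(fast.layers, slow):
            np.testing.assert_allclose(a, b, atol=1e-12)

    def test_translation_sharing(self, rng):
        """Position-shared weights: shifting a feature pattern shifts interior activations."""
        params = random_model(input_dim=3, layers=2, neurons=4, half_window=2, seed=4)
        pattern = rng.uniform(-1, 1, size=(40, 3))
        shifted = np.roll(pattern, 5, axis=0)
        a = dcnn_forward(params, FeatureMatrix(pattern)).top
        b = dcnn_forward(params, FeatureMatrix(shifted)).top
        # interior positions away from the zero-padded ends by the total receptive field
        margin = 10
        np.testing.assert_allclose(a[margin:-margin - 5], b[margin + 5:-margin], atol=1e-10)

    def test_shape_mismatch_names_layer(self, rng):
        params = random_model(input_dim=4)
        x, _ = random_chain(rng, 5, 7)
        with pytest.raises(ShapeError, match="input layer"):
            dcnn_forward(params, x)

    def test_hidden_activations_bounded(self, rng):
        for act, lo, hi in (("sigmoid", 0.0, 1.0), ("tanh", -1.0, 1.0)):
            params = random_model(input_dim=3, seed=2, activation=act, scale=2.0)
            x, _ = random_chain(rng, 6, 3)
            for hidden in dcnn_forward(params, x).layers[1:]:
                assert hidden.min() > lo and hidden.max() < hi


class TestPotentials:
    def test_unit_weights_reduce_to_unweighted(self, rng):
        params = random_model(seed=3, label_weights=(1.0, 1.0))
        x, _ = random_chain(rng, 5, 4)
        top = dcnn_forward(params, x).top
        for i, a, b in itertools.product(range(5), range(2), range(2)):
            psi, phi = weighted_potentials(params, top, i, a, b)
            want_phi = float(params.emission[a] @ top[i])
            want_psi = float(params.transition[a, b]) if i < 4 else 0.0
            assert psi == pytest.approx(want_psi, abs=1e-12)
            assert phi == pytest.approx(want_phi, abs=1e-12)

    def test_zero_emission_weights(self, rng):
        params = random_model(seed=3, label_weights=(0.07, 0.93))
        params.emission[:] = 0.0
        x, _ = random_chain(rng, 4, 4)
        top = dcnn_forward(params, x).top
        assert all(weighted_potentials(params, top, i, a, 0)[1] == 0.0
                   for i in range(4) for a in range(2))

    def test_hand_computed_weighted_products(self):
        """Inverse-prevalence weights 0.07/0.93 scale T rows and U dot-products."""
        arch = ArchitectureSpec.create(input_dim=2, layers=1, neurons=2, half_window=0)
        params = ModelParams.zeros(arch, label_weights=(0.07, 0.93))
        params.transition = np.array([[1.0, -2.0], [3.0, 0.5]])
        params.emission = np.array([[2.0, 0.0], [1.0, -1.0]])
        top = np.array([[0.1, 0.2], [0.3, 0.4]])
        psi, phi = weighted_potentials(params, top, 0, 0, 1)
        assert psi == pytest.approx(0.07 * -2.0)
        assert phi == pytest.approx(0.07 * (2.0 * 0.1))
        psi, phi = weighted_potentials(params, top, 0, 1, 0)
        assert psi == pytest.approx(0.93 * 3.0)
        assert phi == pytest.approx(0.93 * (1.0 * 0.3 - 1.0 * 0.4), abs=1e-15)
        # last position: no adjacent pair, transition contribution is zero
        assert weighted_potentials(params, top, 1, 1, 0)[0] == 0.0

    def test_invalid_label_rejected(self, rng):
        params = random_model()
        x, _ = random_chain(rng, 3, 4)
        top = dcnn_forward(params, x).top
        with pytest.raises(IndexError):
            weighted_potentials(params, top, 0, 2, 0)


class TestChainAlgorithms:
    def test_zero_params_score_and_partition(self, rng):
        params = ModelParams.zeros(ArchitectureSpec.create(input_dim=4))
        x, y = random_chain(rng, 6, 4)
        top = dcnn_forward(params, x).top
        assert sequence_score(params, top, y) == 0.0
        assert partition_log(params, top) == pytest.approx(6 * np.log(2), abs=1e-12)
        assert conditional_log_prob(params, x, y) == pytest.approx(-6 * np.log(2), abs=1e-12)

    def test_length_one_chain(self, rng):
        params = random_model(seed=8, label_weights=(0.7, 9.3))
        x, _ = random_chain(rng, 1, 4)
        top = dcnn_forward(params, x).top
        phis = [weighted_potentials(params, top, 0, a, 0)[1] for a in range(2)]
        assert sequence_score(params, top, LabelSequence([1])) == pytest.approx(phis[1])
        from scipy.special import logsumexp
        assert partition_log(params, top) == pytest.approx(logsumexp(phis), abs=1e-12)

    def test_score_matches_bruteforce_sum(self, rng):
        params = random_model(seed=11, label_weights=(0.07, 0.93))
        x, y = random_chain(rng, 4, 4)
        top = dcnn_forward(params, x).top
        manual = 0.0
        for i in range(4):
            b = y.states[i + 1] if i < 3 else 0
            psi, phi = weighted_potentials(params, top, i, int(y.states[i]), int(b))
            manual += psi + phi
        assert sequence_score(params, top, y) == pytest.approx(manual, abs=1e-12)

    @pytest.mark.parametrize("draw", range(20))
    def test_partition_and_marginals_match_enumeration(self, draw):
        """Forward-backward equals exhaustive path enumeration on short chains."""
        rng = np.random.default_rng(100 + draw)
        length = int(rng.integers(2, 9))
        params = random_model(seed=200 + draw, scale=1.0,
                              label_weights=(0.7, 9.3) if draw % 2 else (1.0, 1.0))
        x, _ = random_chain(rng, length, 4)
        top = dcnn_forward(params, x).top
        assert partition_log(params, top) == pytest.approx(
            reference.enumerate_log_partition(params, top), abs=1e-8)
        marg = posterior_marginals(params, x)
        np.testing.assert_allclose(marg, reference.enumerate_marginals(params, top),
                                   atol=1e-8)

    def test_conditional_probabilities_normalize(self):
        for draw in range(5):
            rng = np.random.default_rng(300 + draw)
            length = int(rng.integers(3, 8))
            params = random_model(seed=400 + draw, scale=1.2, label_weights=(0.7, 9.3))
            x, _ = random_chain(rng, length, 4)
            total = sum(
                np.exp(conditional_log_prob(params, x, LabelSequence(np.array(path))))
                for path in itertools.product(range(2), repeat=length))
            assert total == pytest.approx(1.0, abs=1e-10)

    def test_log_prob_nonpositive(self, rng):
        params = random_model(seed=5, scale=2.0, label_weights=(0.7, 9.3))
        x, y = random_chain(rng, 12, 4)
        assert conditional_log_prob(params, x, y) <= 1e-12

    def test_marginals_uniform_for_zero_params(self, rng):
        params = ModelParams.zeros(ArchitectureSpec.create(input_dim=4))
        x, _ = random_chain(rng, 5, 4)
        np.testing.assert_allclose(posterior_marginals(params, x), 0.5, atol=1e-12)

    def test_marginal_rows_sum_to_one(self, rng):
        params = random_model(seed=6, scale=1.5, label_weights=(0.7, 9.3))
        x, _ = random_chain(rng, 30, 4)
        marg = posterior_marginals(params, x)
        np.testing.assert_allclose(marg.sum(axis=1), 1.0, atol=1e-10)

    def test_emission_drives_marginal_direction(self):
        """A strong disorder-emission weight at one position raises its marginal."""
        arch = ArchitectureSpec.create(input_dim=2, layers=1, neurons=2, half_window=0)
        params = ModelParams.zeros(arch)
        params.emission[1, :] = 5.0
        x = np.zeros((5, 2))
        x[2] = 3.0  # only position 2 activates the top layer away from h(0)=0.5
        marg = posterior_marginals(params, FeatureMatrix(x))
        assert marg[2, 1] > 0.5

    def test_no_overflow_on_long_chain_with_large_params(self, rng):
        params = random_model(input_dim=3, layers=1, neurons=4, half_window=1,
                              seed=7, scale=50.0, label_weights=(0.7, 9.3))
        x, _ = random_chain(rng, 2000, 3)
        top = dcnn_forward(params, x).top
        logz = partition_log(params, top)
        marg = posterior_marginals(params, x)
        assert np.isfinite(logz)
        assert np.all(np.isfinite(marg))


class TestClassify:
    def test_threshold_extremes(self, rng):
        marg = rng.random((6, 1))
        marg = np.hstack([1 - marg, marg])
        assert classify(marg, 0.0).states.sum() == 6
        marg[marg[:, 1] >= 1.0, 1] = 0.999
        assert classify(marg, 1.0).states.sum() == 0

    def test_default_threshold_example(self):
        marg = np.array([[0.75, 0.25], [0.85, 0.15], [0.40, 0.60]])
        np.testing.assert_array_equal(classify(marg, 0.2).states, [1, 0, 1])

    def test_threshold_validated(self):
        with pytest.raises(ValueError):
            classify(np.array([[0.5, 0.5]]), 1.5)


class TestSerialization:
    def test_round_trip_bit_exact(self, tmp_path):
        params = random_model(input_dim=6, layers=2, neurons=4, half_window=2,
                              seed=13, label_weights=(0.7, 9.3))
        params.feature_manifest = "v1;mode=full;blocks=ami:78,evo:40,struct:11;pssm_transform=sigmoid"
        path = tmp_path / "model.json"
        params.save(path)
        loaded = ModelParams.load(path)
        assert loaded.arch == params.arch
        assert loaded.feature_manifest == params.feature_manifest
        for a, b in zip(loaded.trainable_arrays(), params.trainable_arrays()):
            assert np.array_equal(a, b)  # exact, not approximate
        assert np.array_equal(loaded.label_weights, params.label_weights)

    def test_bad_version_rejected(self, tmp_path):
        params = random_model()
        text = params.to_json().replace('"format_version": 1', '"format_version": 99')
        with pytest.raises(ModelFormatError, match="version"):
            ModelParams.from_json(text)

    def test_shape_mismatch_rejected(self):
        params = random_model()
        import json
        blob = json.loads(params.to_json())
        blob["weights"]["U"]["data"] = blob["weights"]["U"]["data"][:-1]
        blob["weights"]["U"]["shape"][-1] -= 1
        with pytest.raises(ModelFormatError, match="U"):
            ModelParams.from_json(json.dumps(blob))

    def test_unpack_rejects_wrong_length(self):
        params = random_model()
        with pytest.raises(ShapeError):
            params.unpack(np.zeros(params.pack().size + 1))
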