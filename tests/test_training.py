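"""Training: objective, analytic gradient, L-BFGS fitting, folds, experiment grid."""
import numpy as np
import pytest

from conftest import random_chain, random_model
from deepcnf import reference
from deepcnf.model import ArchitectureSpec, ModelParams, posterior_marginals, sample_path
from deepcnf.synthetic import GeneratorConfig, generate_corpus
from deepcnf.training import (GridSpec, TrainingConfig, TrainingCorpus, fit,
                              gradient, kfold_split, objective,
                              objective_and_gradient, pivot_grid_table,
                              reciprocal_frequency_weights, run_experiment_grid)
from deepcnf.types import FeatureMatrix, LabelSequence
from deepcnf.validation import finite_difference_check


def toy_corpus(seed=0, n=3, dim=6, max_len=10):
    rng = np.random.default_rng(seed)
    items = [random_chain(rng, int(rng.integers(5, max_len + 1)), dim) for _ in range(n)]
    return TrainingCorpus(items=items)


class TestObjective:
    def test_zero_params_single_sequence(self):
        corpus = toy_corpus(n=1)
        length = len(corpus.items[0][0])
        params = ModelParams.zeros(ArchitectureSpec.create(input_dim=6),
                                   label_weights=(0.7, 9.3))
        config = TrainingConfig(l2_factor=200.0)
        assert objective(params, corpus, config) == pytest.approx(-length * np.log(2))

    def test_zero_l2_is_pure_likelihood(self):
        corpus = toy_corpus(seed=2)
        params = random_model(input_dim=6, seed=3, label_weights=(0.7, 9.3))
        from deepcnf.model import conditional_log_prob
        want = sum(conditional_log_prob(params, x, y) for x, y in corpus.items)
        got = objective(params, corpus, TrainingConfig(l2_factor=0.0))
        assert got == pytest.approx(want, abs=1e-10)

    def test_penalty_is_quadratic(self):
        corpus = toy_corpus(seed=4)
        params = random_model(input_dim=6, seed=5, label_weights=(0.7, 9.3))
        config = TrainingConfig(l2_factor=50.0)
        config0 = TrainingConfig(l2_factor=0.0)
        doubled = params.unpack(2 * params.pack())
        pen1 = objective(params, corpus, config0) - objective(params, corpus, config)
        pen2 = objective(doubled, corpus, config0) - objective(doubled, corpus, config)
        assert pen2 == pytest.approx(4 * pen1, rel=1e-10)

    def test_raw_l2_mode_scales_with_corpus_size(self):
        corpus = toy_corpus(seed=6)
        params = random_model(input_dim=6, seed=7, label_weights=(0.7, 9.3))
        theta = params.pack()
        raw = TrainingConfig(l2_factor=10.0, l2_mode="raw")
        scaled = TrainingConfig(l2_factor=10.0, l2_mode="per_residue")
        pure = objective(params, corpus, TrainingConfig(l2_factor=0.0))
        assert objective(params, corpus, raw) == pytest.approx(
            pure - 5.0 * theta @ theta, rel=1e-10)
        assert objective(params, corpus, scaled) == pytest.approx(
            pure - 5.0 * theta @ theta / corpus.n_residues, rel=1e-10)


class TestGradient:
    @pytest.mark.parametrize("layers", [1, 2, 3])
    def test_matches_central_differences(self, layers):
        assert finite_difference_check(layers, seed=layers) < 1e-4

    def test_unit_weights_match_independent_unweighted_path(self):
        """w=(1,1) gradient equals the loop/enumeration-coded plain CNF gradient."""
        rng = np.random.default_rng(17)
        x, y = random_chain(rng, 7, 5)
        params = random_model(input_dim=5, layers=2, neurons=3, half_window=1,
                              seed=18, label_weights=(1.0, 1.0))
        corpus = TrainingCorpus(items=[(x, y)])
        config = TrainingConfig(l2_factor=0.0, label_weights=(1.0, 1.0))
        g = gradient(params, corpus, config)
        d_conv, _, d_em, d_tr = reference.unweighted_gradient(params, x.values, y)
        for a, b in zip(g.conv_weights, d_conv):
            np.testing.assert_allclose(a, b, atol=1e-10)
        np.testing.assert_allclose(g.emission, d_em, atol=1e-10)
        np.testing.assert_allclose(g.transition, d_tr, atol=1e-10)

    def test_bias_gradient_checks_when_enabled(self):
        rng = np.random.default_rng(21)
        corpus = TrainingCorpus(items=[random_chain(rng, 8, 4)])
        arch = ArchitectureSpec.create(input_dim=4, layers=2, neurons=3,
                                       half_window=1, use_bias=True)
        config = TrainingConfig(l2_factor=30.0, label_weights=(0.7, 9.3))
        params = ModelParams.random(arch, seed=22, scale=0.4,
                                    label_weights=config.label_weights)
        _, grad = objective_and_gradient(params, corpus, config)
        theta = params.pack()
        step = 1e-5
        for i in rng.choice(theta.size, size=25, replace=False):
            up, dn = theta.copy(), theta.copy()
            up[i] += step
            dn[i] -= step
            num = (objective(params.unpack(up), corpus, config)
                   - objective(params.unpack(dn), corpus, config)) / (2 * step)
            assert grad[i] == pytest.approx(num, abs=max(1e-4 * abs(num), 1e-7))


class TestFit:
    def make_separable(self, n=12, length=30, seed=0):
        """Disorder driven by one strong feature column."""
        rng = np.random.default_rng(seed)
        items = []
        for _ in range(n):
            y = (rng.random(length) < 0.3).astype(np.int8)
            x = rng.normal(0, 0.3, size=(length, 4))
            x[:, 0] += np.where(y == 1, 1.5, -1.5)
            items.append((FeatureMatrix(x), LabelSequence(y)))
        return TrainingCorpus(items=items)

    def test_recovers_planted_signal(self):
        corpus = self.make_separable()
        arch = ArchitectureSpec.create(input_dim=4, layers=1, neurons=5, half_window=1)
        config = TrainingConfig(max_iterations=60, seed=0)
        result = fit(corpus, arch, config)
        from deepcnf.metrics import roc_auc
        scores = np.concatenate([posterior_marginals(result.params, x)[:, 1]
                                 for x, _ in corpus.items])
        truth = np.concatenate([y.states for _, y in corpus.items])
        _, auc = roc_auc(scores, truth)
        assert auc > 0.95

    def test_refit_is_bit_identical(self):
        corpus = self.make_separable(n=4, length=15, seed=3)
        arch = ArchitectureSpec.create(input_dim=4, layers=1, neurons=3, half_window=1)
        config = TrainingConfig(max_iterations=25, seed=7)
        a = fit(corpus, arch, config).params
        b = fit(corpus, arch, config).params
        assert a.to_json() == b.to_json()

    def test_objective_trace_monotone(self):
        corpus = self.make_separable(n=4, length=20, seed=5)
        arch = ArchitectureSpec.create(input_dim=4, layers=2, neurons=3, half_window=1)
        result = fit(corpus, arch, TrainingConfig(max_iterations=40, seed=1))
        obj = result.trace["objective"].to_numpy()
        assert np.all(np.diff(obj) >= -1e-9)

    def test_penalized_optimum_no_better_than_unpenalized(self):
        corpus = self.make_separable(n=4, length=20, seed=8)
        arch = ArchitectureSpec.create(input_dim=4, layers=1, neurons=3, half_window=1)
        pen = fit(corpus, arch, TrainingConfig(l2_factor=200.0, max_iterations=80, seed=2))
        free = fit(corpus, arch, TrainingConfig(l2_factor=0.0, max_iterations=80, seed=2))
        assert pen.final_objective <= free.final_objective + 1e-6

    def test_gradient_small_at_optimum(self):
        corpus = self.make_separable(n=3, length=12, seed=9)
        arch = ArchitectureSpec.create(input_dim=4, layers=1, neurons=2, half_window=0)
        config = TrainingConfig(max_iterations=500, seed=3, gradient_tol=1e-7,
                                convergence_tol=1e-12)
        result = fit(corpus, arch, config)
        _, grad = objective_and_gradient(result.params, corpus, config)
        assert np.abs(grad).max() < 1e-4

    def test_parameter_recovery_from_known_model(self):
        """Fitting data sampled from a known 1-layer CNF recovers its marginals."""
        rng = np.random.default_rng(31)
        arch = ArchitectureSpec.create(input_dim=8, layers=1, neurons=6, half_window=1)
        truth = ModelParams.random(arch, seed=32, scale=1.0)
        xs = [FeatureMatrix(rng.uniform(-1, 1, size=(100, 8))) for _ in range(50)]
        # sigmoid top activations are all positive, so an arbitrary emission
        # vector mostly shifts every marginal to one side; project it orthogonal
        # to the mean activation so the generator's marginals span (0, 1)
        from deepcnf.model import dcnn_forward
        top = np.vstack([dcnn_forward(truth, x).top for x in xs[:10]])
        hbar = top.mean(axis=0)
        v = rng.normal(size=6)
        v -= (v @ hbar) / (hbar @ hbar) * hbar
        truth.emission = np.vstack([np.zeros(6), 5.0 * v])
        truth.transition = 0.5 * rng.normal(size=(2, 2))
        items = [(x, sample_path(truth, x, rng)) for x in xs[:40]]
        corpus = TrainingCorpus(items=items)
        config = TrainingConfig(l2_factor=20.0, label_weights=(1.0, 1.0),
                                max_iterations=200, seed=33)
        result = fit(corpus, arch, config)
        got, want = [], []
        for x in xs[40:]:
            got.append(posterior_marginals(result.params, x)[:, 1])
            want.append(posterior_marginals(truth, x)[:, 1])
        r = np.corrcoef(np.concatenate(got), np.concatenate(want))[0, 1]
        assert r > 0.9


class TestWeightsAndFolds:
    def test_reciprocal_frequency_weights_imbalanced(self):
        rng = np.random.default_rng(0)
        states = np.zeros(2000, dtype=np.int8)
        states[:140] = 1  # 7% disorder
        rng.shuffle(states)
        corpus = TrainingCorpus(items=[(FeatureMatrix(np.zeros((2000, 1))),
                                        LabelSequence(states))])
        w = reciprocal_frequency_weights(corpus)
        assert w == pytest.approx((0.07, 0.93))

    def test_reciprocal_frequency_weights_balanced_and_derived(self):
        def make(frac):
            n = 1000
            states = np.zeros(n, dtype=np.int8)
            states[: int(frac * n)] = 1
            return TrainingCorpus(items=[(FeatureMatrix(np.zeros((n, 1))),
                                          LabelSequence(states))])
        assert reciprocal_frequency_weights(make(0.5)) == pytest.approx((0.5, 0.5))
        assert reciprocal_frequency_weights(make(0.2)) == pytest.approx((0.2, 0.8))
        with pytest.raises(ValueError, match="single label"):
            reciprocal_frequency_weights(make(0.0))

    def test_kfold_sizes_and_determinism(self):
        a = kfold_split(23, 10, seed=5)
        sizes = np.bincount(a, minlength=10)
        assert sorted(sizes) == [2] * 7 + [3] * 3
        assert np.array_equal(a, kfold_split(23, 10, seed=5))
        assert np.bincount(kfold_split(10, 10, seed=1)).tolist() == [1] * 10
        with pytest.raises(ValueError):
            kfold_split(5, 1, seed=0)
        with pytest.raises(ValueError):
            kfold_split(5, 6, seed=0)


@pytest.fixture(scope="module")
def grid_corpus():
    cfg = GeneratorConfig(n_sequences=20, length_range=(60, 80),
                          disorder_fraction=0.12, signal_strength=3.0, seed=11)
    return generate_corpus(cfg).training_corpus()


class TestExperimentGrid:
    def test_row_count_and_mean_column(self, grid_corpus):
        grid = GridSpec(layers=(1,), weight_ratios=((0.7, 9.3),),
                        feature_modes=("full",), neurons=4, half_window=2, folds=2)
        config = TrainingConfig(max_iterations=20, seed=0)
        table = run_experiment_grid(grid_corpus, grid, config)
        assert len(table) == 2  # 1 config x 2 folds
        wide = pivot_grid_table(table, "auc")
        np.testing.assert_allclose(
            wide["mean"].to_numpy(),
            wide.drop(columns="mean").mean(axis=1).to_numpy(), atol=1e-12)

    def test_all_features_dominate_single_classes(self, grid_corpus):
        """With signal planted in every class, the full model leads each ablation."""
        grid = GridSpec(layers=(1,), weight_ratios=((0.7, 9.3),),
                        feature_modes=("full", "ami_only", "evo_only", "struct_only"),
                        neurons=6, half_window=2, folds=2)
        config = TrainingConfig(max_iterations=40, seed=3)
        table = run_experiment_grid(grid_corpus, grid, config)
        means = table.groupby("mode")["auc"].mean()
        for mode in ("ami_only", "evo_only", "struct_only"):
            assert means["full"] >= means[mode] - 1e-9

    def test_invalid_mode_rejected(self, grid_corpus):
        grid = GridSpec(feature_modes=("nope",))
        with pytest.raises(ValueError, match="nope"):
            run_experiment_grid(grid_corpus, grid, TrainingConfig())
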