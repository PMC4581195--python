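"""Self-contained validation scenarios for the whole pipeline.

Each function here builds its own inputs (tiny random models, enumeration
oracles, planted-signal synthetic corpora), runs the package end to end and
returns measured numbers. They back both the test suite and the
reproducibility script, so every reported figure is recomputed from scratch.
"""
from __future__ import annotations

import numpy as np

from . import metrics as _metrics
from . import reference
from .features import (AminoAcidTables, SequenceProfile, StructurePrediction,
                       assemble_features)
from .labels import label_from_annotation
from .model import (ArchitectureSpec, ModelParams, dcnn_forward,
                    posterior_marginals, partition_log, conditional_log_prob)
from .synthetic import GeneratorConfig, generate_corpus
from .training import (TrainingConfig, TrainingCorpus, fit,
                       objective, objective_and_gradient)
from .types import DISORDER, FeatureMatrix, LabelSequence


def _random_features(rng, length, dim):
    return FeatureMatrix(rng.uniform(-1, 1, size=(length, dim)), sequence_id="toy")


def _random_labels(rng, length):
    return LabelSequence(rng.integers(0, 2, size=length).astype(np.int8))


# ---------------------------------------------------------------------------
# feature widths
# ---------------------------------------------------------------------------


def feature_width_report(seed: int = 0) -> dict:
    """Assemble one synthetic chain in every mode and report the block widths."""
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ARNDCQEGHILKMFPSTWYV"), size=30))
    tables = AminoAcidTables.default()
    profile = SequenceProfile(pssm=rng.integers(-5, 6, size=(30, 20)).astype(float),
                              hhm=rng.dirichlet(np.ones(20), size=30))
    structure = StructurePrediction(ss8=rng.dirichlet(np.ones(8), size=30),
                                    acc3=rng.dirichlet(np.ones(3), size=30))
    widths = {}
    for mode, key in (("full", "width_full"), ("ami_only", "width_amino"),
                      ("evo_only", "width_evolution"), ("struct_only", "width_structure"),
                      ("evo_struct", "width_evo_struct")):
        x = assemble_features(seq, tables=tables, profile=profile,
                              structure=structure, mode=mode)
        widths[key] = x.input_dim
    return widths


# ---------------------------------------------------------------------------
# chain-algorithm correctness against enumeration
# ---------------------------------------------------------------------------


def crf_enumeration_check(seed: int = 0, n_draws: int = 20) -> dict:
    """Partition function, normalization and marginals vs. exhaustive enumeration.

    Random two-label models on chains of length 3..8; reports the worst
    absolute disagreement across all draws.
    """
    rng = np.random.default_rng(seed)
    worst_logz = worst_marg = worst_norm = 0.0
    for draw in range(n_draws):
        length = int(rng.integers(3, 9))
        arch = ArchitectureSpec.create(input_dim=4, layers=int(rng.integers(1, 3)),
                                       neurons=3, half_window=1)
        params = ModelParams.random(arch, seed=int(rng.integers(2**31)), scale=0.8,
                                    label_weights=(0.7, 9.3) if draw % 2 else (1.0, 1.0))
        x = _random_features(rng, length, 4)
        acts = dcnn_forward(params, x)
        log_z = partition_log(params, acts.top)
        log_z_ref = reference.enumerate_log_partition(params, acts.top)
        worst_logz = max(worst_logz, abs(log_z - log_z_ref))
        marg = posterior_marginals(params, x)
        marg_ref = reference.enumerate_marginals(params, acts.top)
        worst_marg = max(worst_marg, float(np.abs(marg - marg_ref).max()))
        total = 0.0
        import itertools
        for path in itertools.product(range(2), repeat=length):
            total += np.exp(conditional_log_prob(params, x, LabelSequence(np.array(path))))
        worst_norm = max(worst_norm, abs(total - 1.0))
    return {"max_abs_err_log_partition": worst_logz,
            "max_abs_err_marginals": worst_marg,
            "max_abs_err_normalization": worst_norm,
            "n_draws": n_draws}


# ---------------------------------------------------------------------------
# gradient checks
# ---------------------------------------------------------------------------


def _toy_corpus(rng, n_seqs=3, max_len=10, dim=6):
    items = []
    for _ in range(n_seqs):
        length = int(rng.integers(5, max_len + 1))
        items.append((_random_features(rng, length, dim), _random_labels(rng, length)))
    return TrainingCorpus(items=items)


def finite_difference_check(layers: int, seed: int = 0, step: float = 1e-5) -> float:
    """Max scaled error between the analytic and central-difference gradients.

    The error of each component is |g_analytic - g_numeric| / max(|g_numeric|, 1e-4),
    so components are compared relatively where they are large and on an
    absolute 1e-4 scale where they vanish.
    """
    rng = np.random.default_rng(seed)
    corpus = _toy_corpus(rng)
    arch = ArchitectureSpec.create(input_dim=6, layers=layers, neurons=4, half_window=2)
    config = TrainingConfig(l2_factor=200.0, label_weights=(0.7, 9.3), seed=seed)
    params = ModelParams.random(arch, seed=seed + 1, scale=0.3,
                                label_weights=config.label_weights)
    _, grad = objective_and_gradient(params, corpus, config)
    theta = params.pack()
    numeric = np.empty_like(theta)
    for i in range(theta.size):
        up, dn = theta.copy(), theta.copy()
        up[i] += step
        dn[i] -= step
        f_up = objective(params.unpack(up), corpus, config)
        f_dn = objective(params.unpack(dn), corpus, config)
        numeric[i] = (f_up - f_dn) / (2 * step)
    err = np.abs(grad - numeric) / np.maximum(np.abs(numeric), 1e-4)
    return float(err.max())


def weight_identity_check(seed: int = 0) -> dict:
    """Unit label weights vs. the independently coded unweighted CNF.

    Compares the conditional log-likelihood and every gradient block of the
    vectorized weighted implementation at w = (1, 1) against the loop-and-
    enumeration reference; reports the worst absolute difference.
    """
    rng = np.random.default_rng(seed)
    length, dim = 6, 5
    arch = ArchitectureSpec.create(input_dim=dim, layers=2, neurons=3, half_window=1)
    params = ModelParams.random(arch, seed=seed + 7, scale=0.5, label_weights=(1.0, 1.0))
    x = _random_features(rng, length, dim)
    y = _random_labels(rng, length)
    corpus = TrainingCorpus(items=[(x, y)])
    config = TrainingConfig(l2_factor=0.0, label_weights=(1.0, 1.0), seed=seed)

    ll_main = objective(params, corpus, config)
    ll_ref = reference.unweighted_log_likelihood(params, x.values, y)
    worst = abs(ll_main - ll_ref)

    _, flat = objective_and_gradient(params, corpus, config)
    g_main = params.unpack(flat)
    d_conv, _, d_em, d_tr = reference.unweighted_gradient(params, x.values, y)
    for a, b in zip(g_main.conv_weights, d_conv):
        worst = max(worst, float(np.abs(a - b).max()))
    worst = max(worst, float(np.abs(g_main.emission - d_em).max()))
    worst = max(worst, float(np.abs(g_main.transition - d_tr).max()))
    return {"max_abs_diff": worst}


# ---------------------------------------------------------------------------
# planted-signal training benchmarks
# ---------------------------------------------------------------------------


def _held_out_auc(result_params, corpus: TrainingCorpus) -> float:
    scores, truth = [], []
    for x, y in corpus.items:
        marg = posterior_marginals(result_params, x)
        scores.append(marg[:, DISORDER])
        truth.append(y.states)
    _, auc = _metrics.roc_auc(np.concatenate(scores), np.concatenate(truth))
    return auc


def planted_signal_benchmark(seed: int = 1, n_train: int = 80, n_test: int = 20,
                             length: int = 200, signal_strength: float = 3.0,
                             max_iterations: int = 80) -> dict:
    """Held-out AUC of default-architecture models on strongly planted signal.

    Generates ``n_train + n_test`` synthetic chains (7% disorder) whose
    sequence, profile and structure features all encode the hidden labels,
    trains a two-layer and a one-layer model with the released default
    hyperparameters, and scores the held-out chains.
    """
    cfg = GeneratorConfig(n_sequences=n_train + n_test, length_range=(length, length),
                          signal_strength=signal_strength, seed=seed % 2**31)
    corpus = generate_corpus(cfg).training_corpus()
    train = corpus.subset(range(n_train))
    test = corpus.subset(range(n_train, n_train + n_test))
    tconf = TrainingConfig(max_iterations=max_iterations, seed=seed % 2**31)
    out = {"n_train": n_train, "n_test": n_test, "length": length}
    for layers, key in ((2, "auc_two_layer"), (1, "auc_one_layer")):
        arch = ArchitectureSpec.create(input_dim=train.input_dim, layers=layers)
        result = fit(train, arch, tconf)
        out[key] = _held_out_auc(result.params, test)
    return out


def imbalance_benchmark(seed: int = 1, n_train: int = 60, n_test: int = 30,
                        length: int = 150, signal_strength: float = 1.5,
                        max_iterations: int = 80) -> dict:
    """Balanced accuracy at threshold 0.5: inverse-prevalence vs. equal label weights.

    Same data, same seed, same one-layer architecture; only the label-weight
    ratio differs (0.7:9.3 vs. 5:5). The label weights act on the penalized
    objective through the L2 geometry — a potential carried by a large weight
    costs less squared-norm — so this comparison uses the raw regularization
    factor (200), under which the penalty binds and the weighting mechanism is
    measurable, mirroring the published weight-ratio experiment.
    """
    cfg = GeneratorConfig(n_sequences=n_train + n_test, length_range=(length, length),
                          signal_strength=signal_strength, seed=(seed + 101) % 2**31)
    corpus = generate_corpus(cfg).training_corpus()
    train = corpus.subset(range(n_train))
    test = corpus.subset(range(n_train, n_train + n_test))
    arch = ArchitectureSpec.create(input_dim=train.input_dim, layers=1, neurons=25)
    out = {"n_train": n_train, "n_test": n_test, "length": length}
    for ratio, key in (((0.7, 9.3), "bacc_weighted"), ((5.0, 5.0), "bacc_equal")):
        tconf = TrainingConfig(max_iterations=max_iterations, seed=seed % 2**31,
                               label_weights=ratio, l2_factor=200.0, l2_mode="raw")
        result = fit(train, arch, tconf)
        scores, truth = [], []
        for x, y in test.items:
            scores.append(posterior_marginals(result.params, x)[:, DISORDER])
            truth.append(y.states)
        tm = _metrics.threshold_metrics(np.concatenate(scores),
                                        np.concatenate(truth), 0.5)
        out[key] = tm["bacc"]
    return out


# ---------------------------------------------------------------------------
# label convention and metric formulas
# ---------------------------------------------------------------------------


def label_convention_report() -> dict:
    """Counts of disorder calls produced by the coordinate-annotation rules."""
    run4 = label_from_annotation("OO" + "D" * 4 + "OO")
    run3 = label_from_annotation("OO" + "D" * 3 + "OO")
    mixed = label_from_annotation("OONXO")
    return {
        "disorder_calls_run_of_4": int((run4.states == 1).sum()),
        "disorder_calls_run_of_3": int((run3.states == 1).sum()),
        "masked_positions_in_OONXO": int((~mixed.mask).sum()),
        "disorder_calls_in_OONXO": int((mixed.states == 1).sum()),
    }


def metric_report(seed: int = 0, n_random: int = 20000) -> dict:
    """Metric formulas on canonical inputs, including the random-predictor AUC."""
    rng = np.random.default_rng(seed)
    truth = rng.integers(0, 2, size=n_random)
    random_scores = rng.random(n_random)
    _, auc_rand = _metrics.roc_auc(random_scores, truth)
    perfect_scores = truth * 0.8 + 0.1
    _, auc_perf = _metrics.roc_auc(perfect_scores, truth)
    c = _metrics.ConfusionCounts(tp=3, fn=1, tn=8, fp=2)
    return {
        "auc_perfect": auc_perf,
        "auc_random": auc_rand,
        "precision_tp3_fp1": _metrics.precision(_metrics.ConfusionCounts(tp=3, fp=1, tn=0, fn=0)),
        "bacc_example": _metrics.balanced_accuracy(c),
        "mcc_example": _metrics.mcc(c),
        "n_random": n_random,
    }
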