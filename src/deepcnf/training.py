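"""Weighted maximum-likelihood training of DeepCNF models.

The objective is the sum over training chains of the weighted conditional
log-likelihood minus an L2 penalty on the trainable weights (conv stacks,
emission, transition — never the fixed label weights). The analytic gradient
combines CRF forward-backward marginals with backpropagation through the
convolution stack, and optimization uses L-BFGS.

The regularization factor is interpreted, by default, as the penalty
multiplier per training residue (``penalty = l2_factor / n_residues * ||theta||^2 / 2``)
so that the same factor behaves comparably on corpora of very different
sizes; the raw multiplier is selectable via ``l2_mode="raw"``.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import metrics as _metrics
from .model import (ArchitectureSpec, ModelParams, _shift, dcnn_forward,
                    posterior_marginals, sequence_score, partition_log,
                    emission_logpot, transition_logpot, _forward, _backward)
from .types import DISORDER, ORDER, FeatureMatrix, LabelSequence
from scipy.special import logsumexp


@dataclass
class TrainingConfig:
    """Hyperparameters of a training run.

    ``label_weights`` is (w_order, w_disorder); the released predictor uses
    0.7 : 9.3, the inverse-prevalence weighting for ~7% disorder scaled by 10.
    ``l2_factor`` defaults to 200 (see module docstring for its scaling).
    """

    l2_factor: float = 200.0
    l2_mode: str = "per_residue"  # or "raw"
    label_weights: tuple = (0.7, 9.3)
    max_iterations: int = 200
    convergence_tol: float = 1e-6
    gradient_tol: float = 1e-5
    lbfgs_history: int = 10
    init_scale: float = 0.1
    seed: int = 42
    folds: int = 10

    def __post_init__(self):
        if self.l2_factor < 0:
            raise ValueError("l2_factor must be >= 0")
        if self.l2_mode not in ("per_residue", "raw"):
            raise ValueError(f"unknown l2_mode {self.l2_mode!r}")
        if len(self.label_weights) != 2 or min(self.label_weights) <= 0:
            raise ValueError("label_weights must be two positive numbers")


@dataclass
class TrainingCorpus:
    """Aligned (features, labels) pairs, optionally with fold assignments."""

    items: list  # list of (FeatureMatrix, LabelSequence)
    ids: list = None  # type: ignore[assignment]
    fold_assignment: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        if not self.items:
            raise ValueError("corpus is empty")
        if self.ids is None:
            self.ids = [getattr(x, "sequence_id", "") or f"seq{i}"
                        for i, (x, _) in enumerate(self.items)]
        for name, (x, y) in zip(self.ids, self.items):
            if len(x) != len(y):
                raise ValueError(
                    f"sequence {name}: features have {len(x)} rows but labels {len(y)}"
                )
            if not y.fully_observed:
                raise ValueError(
                    f"sequence {name}: corpus labels must be fully observed; "
                    f"compress masked positions first"
                )
        if self.fold_assignment is not None:
            self.fold_assignment = np.asarray(self.fold_assignment, dtype=int)
            if self.fold_assignment.shape != (len(self.items),):
                raise ValueError("fold_assignment must have one entry per item")

    def __len__(self) -> int:
        return len(self.items)

    @property
    def n_residues(self) -> int:
        return sum(len(x) for x, _ in self.items)

    @property
    def input_dim(self) -> int:
        return self.items[0][0].input_dim

    def label_frequencies(self) -> np.ndarray:
        counts = np.zeros(2)
        for _, y in self.items:
            counts[0] += np.sum(y.states == ORDER)
            counts[1] += np.sum(y.states == DISORDER)
        return counts / counts.sum()

    def subset(self, indices) -> "TrainingCorpus":
        indices = list(indices)
        return TrainingCorpus(items=[self.items[i] for i in indices],
                              ids=[self.ids[i] for i in indices])

    def column_subset(self, cols: slice, manifest: str = "") -> "TrainingCorpus":
        """Corpus with a contiguous column slice of every feature matrix (ablation)."""
        items = [(FeatureMatrix(x.values[:, cols], x.sequence_id, manifest), y)
                 for x, y in self.items]
        return TrainingCorpus(items=items, ids=list(self.ids),
                              fold_assignment=self.fold_assignment)


# ---------------------------------------------------------------------------
# objective and gradient
# ---------------------------------------------------------------------------


def _penalty_scale(corpus: TrainingCorpus, config: TrainingConfig) -> float:
    if config.l2_mode == "per_residue":
        return config.l2_factor / corpus.n_residues
    return config.l2_factor


def objective(params: ModelParams, corpus: TrainingCorpus, config: TrainingConfig) -> float:
    """Penalized weighted log-likelihood (larger is better)."""
    total = 0.0
    for x, y in corpus.items:
        acts = dcnn_forward(params, x)
        total += sequence_score(params, acts.top, y) - partition_log(params, acts.top)
    lam = _penalty_scale(corpus, config)
    if lam:
        total -= 0.5 * lam * float(params.pack() @ params.pack())
    return total


def _sequence_grad(params: ModelParams, x: FeatureMatrix, y: LabelSequence):
    """Log-likelihood of one chain and its gradient blocks."""
    acts = dcnn_forward(params, x)
    top = acts.top
    length = top.shape[0]
    d = params.arch.num_labels
    w = params.label_weights
    phi = emission_logpot(params, top)
    psi = transition_logpot(params)
    alpha = _forward(phi, psi)
    beta = _backward(phi, psi)
    log_z = float(logsumexp(alpha[-1]))
    node = np.exp(alpha + beta - log_z)

    states = y.states.astype(int)
    onehot = np.zeros((length, d))
    onehot[np.arange(length), states] = 1.0
    ll = float(phi[np.arange(length), states].sum()) - log_z
    if length > 1:
        ll += float(psi[states[:-1], states[1:]].sum())

    dphi = onehot - node  # gradient wrt the weighted emission table entries

    # transitions: empirical pair counts minus expected pair marginals
    if length > 1:
        log_pair = (alpha[:-1, :, None] + psi[None, :, :]
                    + (phi[1:] + beta[1:])[:, None, :] - log_z)
        pair_exp = np.exp(log_pair).sum(axis=0)
        pair_obs = np.zeros((d, d))
        np.add.at(pair_obs, (states[:-1], states[1:]), 1.0)
        d_transition = w[:, None] * (pair_obs - pair_exp)
    else:
        d_transition = np.zeros((d, d))

    d_emission = (dphi * w).T @ top
    d_top = (dphi * w) @ params.emission

    # backprop through the convolution stack
    d_conv = [np.empty_like(wk) for wk in params.conv_weights]
    d_biases = None if params.biases is None else [np.empty_like(b) for b in params.biases]
    d_act = d_top
    for k in range(params.arch.num_hidden_layers - 1, -1, -1):
        a_prev, a_cur = acts.layers[k], acts.layers[k + 1]
        nk = params.arch.half_windows[k]
        wk = params.conv_weights[k]
        if params.arch.activation == "sigmoid":
            d_pre = d_act * a_cur * (1.0 - a_cur)
        else:
            d_pre = d_act * (1.0 - a_cur ** 2)
        if d_biases is not None:
            d_biases[k] = d_pre.sum(axis=0)
        d_prev = np.zeros_like(a_prev)
        for off in range(-nk, nk + 1):
            d_conv[k][off + nk] = d_pre.T @ _shift(a_prev, off)
            d_prev += _shift(d_pre @ wk[off + nk], -off)
        d_act = d_prev
    return ll, d_conv, d_biases, d_emission, d_transition


def objective_and_gradient(params: ModelParams, corpus: TrainingCorpus,
                           config: TrainingConfig):
    """Objective value and its gradient packed as a flat vector (both to maximize)."""
    total = 0.0
    g_conv = [np.zeros_like(w) for w in params.conv_weights]
    g_biases = None if params.biases is None else [np.zeros_like(b) for b in params.biases]
    g_emission = np.zeros_like(params.emission)
    g_transition = np.zeros_like(params.transition)
    for x, y in corpus.items:
        ll, d_conv, d_biases, d_em, d_tr = _sequence_grad(params, x, y)
        if not np.isfinite(ll):
            raise FloatingPointError(
                f"non-finite objective contribution from sequence {x.sequence_id!r}"
            )
        total += ll
        for gk, dk in zip(g_conv, d_conv):
            gk += dk
        if g_biases is not None:
            for gb, db in zip(g_biases, d_biases):
                gb += db
        g_emission += d_em
        g_transition += d_tr
    theta = params.pack()
    grads = list(g_conv)
    if g_biases is not None:
        grads += g_biases
    grads += [g_emission, g_transition]
    flat = np.concatenate([g.ravel() for g in grads])
    lam = _penalty_scale(corpus, config)
    if lam:
        total -= 0.5 * lam * float(theta @ theta)
        flat -= lam * theta
    return total, flat


def gradient(params: ModelParams, corpus: TrainingCorpus, config: TrainingConfig):
    """Gradient of the objective, returned as a ModelParams-shaped structure."""
    _, flat = objective_and_gradient(params, corpus, config)
    return params.unpack(flat)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Fitted parameters plus the optimizer trace (iteration, objective, grad inf-norm)."""

    params: ModelParams
    trace: pd.DataFrame
    converged: bool
    message: str
    final_objective: float


def fit(corpus: TrainingCorpus, arch: ArchitectureSpec, config: TrainingConfig,
        feature_manifest: str = "", verbose: bool = False) -> FitResult:
    """Maximize the penalized weighted log-likelihood with L-BFGS.

    Deterministic given ``config.seed``: initialization is the only source of
    randomness and the optimizer itself is deterministic.
    """
    if arch.input_dim != corpus.input_dim:
        raise ValueError(
            f"architecture input_dim {arch.input_dim} != corpus feature width "
            f"{corpus.input_dim}"
        )
    if not feature_manifest:
        feature_manifest = corpus.items[0][0].manifest
    params0 = ModelParams.random(arch, seed=config.seed, scale=config.init_scale,
                                 label_weights=np.asarray(config.label_weights, float),
                                 feature_manifest=feature_manifest)
    template = params0
    rows = []
    cache = {"theta": None, "val": None, "grad": None}

    def evaluate(theta):
        if cache["theta"] is None or not np.array_equal(cache["theta"], theta):
            p = template.unpack(theta)
            val, grad = objective_and_gradient(p, corpus, config)
            cache.update(theta=theta.copy(), val=val, grad=grad)
        return cache["val"], cache["grad"]

    def negative(theta):
        val, grad = evaluate(theta)
        return -val, -grad

    def callback(theta):
        val, grad = evaluate(theta)
        rows.append((len(rows) + 1, val, float(np.abs(grad).max())))
        if verbose:
            print(f"iter {len(rows):4d}  objective {val:.6f}  |grad|_inf {np.abs(grad).max():.3e}")

    res = minimize(
        negative, params0.pack(), jac=True, method="L-BFGS-B",
        options={"maxiter": config.max_iterations,
                 "maxcor": config.lbfgs_history,
                 "ftol": config.convergence_tol,
                 "gtol": config.gradient_tol},
        callback=callback,
    )
    fitted = template.unpack(res.x)
    trace = pd.DataFrame(rows, columns=["iteration", "objective", "grad_inf_norm"])
    return FitResult(params=fitted, trace=trace, converged=bool(res.success),
                     message=str(res.message), final_objective=float(-res.fun))


# ---------------------------------------------------------------------------
# label weights, cross-validation, experiment grid
# ---------------------------------------------------------------------------


def reciprocal_frequency_weights(corpus: TrainingCorpus) -> tuple:
    """Label weights proportional to the opposite label's frequency, summing to 1.

    A corpus that is 93% order / 7% disorder yields (0.07, 0.93): the rare
    disorder label receives the large weight.
    """
    freq = corpus.label_frequencies()
    if freq.min() == 0:
        raise ValueError("corpus contains a single label; cannot derive weights")
    w = freq[::-1] / freq.sum()
    return float(w[0]), float(w[1])


def kfold_split(n_items: int, folds: int, seed: int) -> np.ndarray:
    """Random equal-sized partition into folds; sizes differ by at most one."""
    if folds < 2:
        raise ValueError("need at least 2 folds")
    if folds > n_items:
        raise ValueError(f"cannot split {n_items} items into {folds} folds")
    rng = np.random.default_rng(seed)
    assignment = np.arange(n_items) % folds
    rng.shuffle(assignment)
    return assignment


@dataclass
class GridSpec:
    """Experiment grid: layers x label-weight ratios x feature-class subsets.

    ``feature_modes`` assumes the corpus carries full-width (129-column)
    features assembled in the standard block order; ablations slice columns.
    """

    layers: tuple = (1, 2, 3)
    weight_ratios: tuple = ((0.7, 9.3),)
    feature_modes: tuple = ("full",)
    neurons: int = 50
    half_window: int = 5
    folds: int = 10
    threshold: float = 0.2
    block_widths: tuple = (78, 40, 11)  # ami, evo, struct

    def mode_slice(self, mode: str):
        from .features import FEATURE_MODES
        if mode not in FEATURE_MODES:
            raise ValueError(f"unknown feature mode {mode!r}")
        blocks = FEATURE_MODES[mode]
        starts = {"ami": 0, "evo": self.block_widths[0],
                  "struct": self.block_widths[0] + self.block_widths[1]}
        widths = dict(zip(("ami", "evo", "struct"), self.block_widths))
        # ablation modes are contiguous only for adjacent blocks; gather columns
        cols = []
        for b in blocks:
            cols.extend(range(starts[b], starts[b] + widths[b]))
        return np.asarray(cols, dtype=int)


def run_experiment_grid(corpus: TrainingCorpus, grid: GridSpec,
                        config: TrainingConfig = None, verbose=False) -> pd.DataFrame:
    """Cross-validated metric table over the grid, one row per (config, fold).

    For each configuration and fold, a model is trained on the other folds and
    scored on the held-out fold; rows report AUC plus threshold metrics.
    """
    if config is None:
        config = TrainingConfig()
    if corpus.fold_assignment is not None and len(np.unique(corpus.fold_assignment)) == grid.folds:
        assignment = corpus.fold_assignment
    else:
        assignment = kfold_split(len(corpus), grid.folds, config.seed)
    full_width = sum(grid.block_widths)
    rows = []
    for layers, ratio, mode in itertools.product(grid.layers, grid.weight_ratios,
                                                 grid.feature_modes):
        cols = grid.mode_slice(mode)
        if corpus.input_dim != full_width:
            raise ValueError(
                f"grid ablation expects full-width ({full_width}) features, "
                f"corpus has {corpus.input_dim}"
            )
        cfg = replace(config, label_weights=tuple(ratio))
        for fold in range(grid.folds):
            train_idx = np.flatnonzero(assignment != fold)
            test_idx = np.flatnonzero(assignment == fold)
            sub_train = corpus.subset(train_idx)
            sub_test = corpus.subset(test_idx)
            tr = TrainingCorpus(
                items=[(FeatureMatrix(x.values[:, cols], x.sequence_id), y)
                       for x, y in sub_train.items], ids=sub_train.ids)
            te_items = [(FeatureMatrix(x.values[:, cols], x.sequence_id), y)
                        for x, y in sub_test.items]
            arch = ArchitectureSpec.create(input_dim=len(cols), layers=layers,
                                           neurons=grid.neurons,
                                           half_window=grid.half_window)
            result = fit(tr, arch, cfg, verbose=False)
            scores, truth = [], []
            for x, y in te_items:
                marg = posterior_marginals(result.params, x)
                scores.append(marg[:, DISORDER])
                truth.append(y.states)
            s = np.concatenate(scores)
            t = np.concatenate(truth)
            _, auc = _metrics.roc_auc(s, t)
            tm = _metrics.threshold_metrics(s, t, grid.threshold)
            label = f"layers={layers};ratio={ratio[0]}:{ratio[1]};mode={mode}"
            if verbose:
                print(f"{label} fold {fold}: AUC {auc:.4f}")
            rows.append({"config": label, "layers": layers,
                         "ratio": f"{ratio[0]}:{ratio[1]}", "mode": mode,
                         "fold": fold, "auc": auc, "mcc": tm["mcc"],
                         "bacc": tm["bacc"], "precision": tm["precision"]})
    return pd.DataFrame(rows)


def pivot_grid_table(table: pd.DataFrame, metric: str = "auc") -> pd.DataFrame:
    """Wide config x fold view with a trailing mean column (layout of the CV tables)."""
    wide = table.pivot(index="config", columns="fold", values=metric)
    wide["mean"] = wide.mean(axis=1)
    return wide
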