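"""Weighted deep convolutional neural field (DeepCNF) over label chains.

The model stacks position-shared convolutional layers on top of the per-residue
input features; the top hidden layer feeds a linear-chain CRF whose emission
and transition potentials are multiplied by fixed per-label weights. With both
label weights equal to 1 the model reduces to an ordinary convolutional neural
field.

All chain-level quantities (partition function, marginals, likelihood) are
computed in log space so long proteins and large parameter magnitudes do not
overflow.
"""
from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit, logsumexp

from .types import DISORDER, ORDER, FeatureMatrix, LabelSequence

MODEL_FORMAT_VERSION = 1

LABEL_NAMES = ("order", "disorder")


class ShapeError(ValueError):
    """Parameter/feature shape disagreement, reported with the offending layer."""


class ModelFormatError(ValueError):
    """Model file fails the version or schema check."""


# ---------------------------------------------------------------------------
# architecture and parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ArchitectureSpec:
    """Fixed structure of a DeepCNF model.

    ``num_hidden_layers`` counts the convolutional layers between the input
    and the label chain; the input itself is layer 1 of the activation stack.
    Each hidden layer k has ``neurons[k]`` units per position and a window of
    ``2 * half_windows[k] + 1`` positions. Defaults follow the released
    disorder predictor: two hidden layers of 50 neurons, window 11.
    """

    input_dim: int
    num_hidden_layers: int = 2
    neurons: tuple = (50, 50)
    half_windows: tuple = (5, 5)
    activation: str = "sigmoid"
    num_labels: int = 2
    use_bias: bool = False

    def __post_init__(self):
        object.__setattr__(self, "neurons", tuple(int(m) for m in self.neurons))
        object.__setattr__(self, "half_windows", tuple(int(n) for n in self.half_windows))
        if self.input_dim < 1:
            raise ValueError("input_dim must be >= 1")
        if self.num_hidden_layers < 1:
            raise ValueError("need at least one hidden layer")
        if len(self.neurons) != self.num_hidden_layers:
            raise ValueError("neurons must list one width per hidden layer")
        if len(self.half_windows) != self.num_hidden_layers:
            raise ValueError("half_windows must list one half-window per hidden layer")
        if any(m < 1 for m in self.neurons):
            raise ValueError("every layer needs >= 1 neuron")
        if any(n < 0 for n in self.half_windows):
            raise ValueError("half windows must be >= 0")
        if self.activation not in ("sigmoid", "tanh"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.num_labels < 2:
            raise ValueError("need >= 2 labels")

    @classmethod
    def create(cls, input_dim, layers=2, neurons=50, half_window=5,
               activation="sigmoid", num_labels=2, use_bias=False):
        """Convenience constructor expanding scalar ``neurons``/``half_window``."""
        if np.isscalar(neurons):
            neurons = (neurons,) * layers
        if np.isscalar(half_window):
            half_window = (half_window,) * layers
        return cls(input_dim=input_dim, num_hidden_layers=layers,
                   neurons=tuple(neurons), half_windows=tuple(half_window),
                   activation=activation, num_labels=num_labels, use_bias=use_bias)

    @property
    def layer_dims(self) -> tuple:
        """Widths of the activation stack, input first."""
        return (self.input_dim,) + self.neurons

    def conv_shapes(self):
        """Shape of each convolution stack W^k: (window, out, in)."""
        dims = self.layer_dims
        return [
            (2 * self.half_windows[k] + 1, dims[k + 1], dims[k])
            for k in range(self.num_hidden_layers)
        ]


@dataclass
class ModelParams:
    """All trainable weights plus the fixed architecture and label weights.

    ``conv_weights[k]`` has shape (2*N_k+1, M_{k+1}, M_k): ``conv_weights[k][N_k + l, j, j']``
    connects neuron j' at position i+l of layer k to neuron j at position i of
    layer k+1. ``emission`` is (D, M_top), ``transition`` is (D, D) and
    ``label_weights`` holds the fixed per-label weights w_a (not trained).
    """

    arch: ArchitectureSpec
    conv_weights: list
    emission: np.ndarray
    transition: np.ndarray
    label_weights: np.ndarray = field(default=None)  # type: ignore[assignment]
    biases: list = None  # type: ignore[assignment]
    feature_manifest: str = ""

    def __post_init__(self):
        if self.label_weights is None:
            self.label_weights = np.ones(self.arch.num_labels)
        self.label_weights = np.asarray(self.label_weights, dtype=float)
        self.emission = np.asarray(self.emission, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        self.conv_weights = [np.asarray(w, dtype=float) for w in self.conv_weights]
        if self.biases is None and self.arch.use_bias:
            self.biases = [np.zeros(m) for m in self.arch.neurons]
        if self.biases is not None:
            self.biases = [np.asarray(b, dtype=float) for b in self.biases]
        self._check_shapes()

    def _check_shapes(self):
        a = self.arch
        shapes = a.conv_shapes()
        if len(self.conv_weights) != a.num_hidden_layers:
            raise ShapeError(
                f"expected {a.num_hidden_layers} convolution stacks, got {len(self.conv_weights)}"
            )
        for k, (w, want) in enumerate(zip(self.conv_weights, shapes), start=1):
            if w.shape != want:
                raise ShapeError(f"conv layer {k}: weight shape {w.shape} != expected {want}")
        d, m_top = a.num_labels, a.neurons[-1]
        if self.emission.shape != (d, m_top):
            raise ShapeError(
                f"emission layer: shape {self.emission.shape} != expected {(d, m_top)}"
            )
        if self.transition.shape != (d, d):
            raise ShapeError(
                f"transition layer: shape {self.transition.shape} != expected {(d, d)}"
            )
        if self.label_weights.shape != (d,) or np.any(self.label_weights <= 0):
            raise ValueError("label_weights must be strictly positive, one per label")
        if self.biases is not None:
            for k, (b, m) in enumerate(zip(self.biases, a.neurons), start=1):
                if b.shape != (m,):
                    raise ShapeError(f"bias layer {k}: shape {b.shape} != expected {(m,)}")

    # -- initialization ----------------------------------------------------

    @classmethod
    def zeros(cls, arch: ArchitectureSpec, label_weights=None, feature_manifest=""):
        return cls(
            arch=arch,
            conv_weights=[np.zeros(s) for s in arch.conv_shapes()],
            emission=np.zeros((arch.num_labels, arch.neurons[-1])),
            transition=np.zeros((arch.num_labels, arch.num_labels)),
            label_weights=label_weights,
            feature_manifest=feature_manifest,
        )

    @classmethod
    def random(cls, arch: ArchitectureSpec, seed=42, scale=0.1,
               label_weights=None, feature_manifest=""):
        """Uniform init in [-scale, scale] from a seeded generator."""
        rng = np.random.default_rng(seed)
        u = lambda s: rng.uniform(-scale, scale, size=s)
        params = cls(
            arch=arch,
            conv_weights=[u(s) for s in arch.conv_shapes()],
            emission=u((arch.num_labels, arch.neurons[-1])),
            transition=u((arch.num_labels, arch.num_labels)),
            label_weights=label_weights,
            feature_manifest=feature_manifest,
        )
        if arch.use_bias:
            params.biases = [u((m,)) for m in arch.neurons]
        return params

    def with_label_weights(self, label_weights) -> "ModelParams":
        return replace(self, label_weights=np.asarray(label_weights, dtype=float))

    # -- flat-vector view (shared with the trainer) ------------------------

    def trainable_arrays(self):
        arrs = list(self.conv_weights)
        if self.biases is not None:
            arrs += list(self.biases)
        arrs += [self.emission, self.transition]
        return arrs

    def pack(self) -> np.ndarray:
        return np.concatenate([a.ravel() for a in self.trainable_arrays()])

    def unpack(self, flat: np.ndarray) -> "ModelParams":
        """Return a copy of self with trainable weights taken from ``flat``."""
        out = replace(self)
        arrs = []
        pos = 0
        for a in self.trainable_arrays():
            n = a.size
            arrs.append(np.asarray(flat[pos:pos + n], dtype=float).reshape(a.shape).copy())
            pos += n
        if pos != flat.size:
            raise ShapeError(f"flat vector has {flat.size} entries, model needs {pos}")
        k = self.arch.num_hidden_layers
        out.conv_weights = arrs[:k]
        if self.biases is not None:
            out.biases = arrs[k:2 * k]
            arrs = arrs[2 * k:]
        else:
            out.biases = None
            arrs = arrs[k:]
        out.emission, out.transition = arrs
        return out

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        a = self.arch
        blob = {
            "format": "deepcnf-model",
            "format_version": MODEL_FORMAT_VERSION,
            "arch": {
                "input_dim": a.input_dim,
                "num_hidden_layers": a.num_hidden_layers,
                "neurons": list(a.neurons),
                "half_windows": list(a.half_windows),
                "activation": a.activation,
                "num_labels": a.num_labels,
                "use_bias": a.use_bias,
            },
            "label_weights": self.label_weights.tolist(),
            "feature_manifest": self.feature_manifest,
            "weights": {
                f"W{k + 1}": {"shape": list(w.shape), "data": w.ravel().tolist()}
                for k, w in enumerate(self.conv_weights)
            },
        }
        blob["weights"]["U"] = {"shape": list(self.emission.shape),
                                "data": self.emission.ravel().tolist()}
        blob["weights"]["T"] = {"shape": list(self.transition.shape),
                                "data": self.transition.ravel().tolist()}
        if self.biases is not None:
            for k, b in enumerate(self.biases):
                blob["weights"][f"b{k + 1}"] = {"shape": list(b.shape),
                                                "data": b.ravel().tolist()}
        return json.dumps(blob, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ModelParams":
        try:
            blob = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ModelFormatError(f"model file is not valid JSON: {exc}") from exc
        if not isinstance(blob, dict) or blob.get("format") != "deepcnf-model":
            raise ModelFormatError("not a deepcnf model file (missing format tag)")
        if blob.get("format_version") != MODEL_FORMAT_VERSION:
            raise ModelFormatError(
                f"unsupported model format version {blob.get('format_version')!r}; "
                f"this build reads version {MODEL_FORMAT_VERSION}"
            )
        arch = ArchitectureSpec(**blob["arch"])

        def take(name, shape):
            entry = blob["weights"].get(name)
            if entry is None:
                raise ModelFormatError(f"model file is missing weight block {name!r}")
            if tuple(entry["shape"]) != tuple(shape):
                raise ModelFormatError(
                    f"weight block {name!r} has shape {tuple(entry['shape'])}, "
                    f"architecture requires {tuple(shape)}"
                )
            return np.asarray(entry["data"], dtype=float).reshape(shape)

        conv = [take(f"W{k + 1}", s) for k, s in enumerate(arch.conv_shapes())]
        emission = take("U", (arch.num_labels, arch.neurons[-1]))
        transition = take("T", (arch.num_labels, arch.num_labels))
        biases = None
        if arch.use_bias:
            biases = [take(f"b{k + 1}", (m,)) for k, m in enumerate(arch.neurons)]
        return cls(arch=arch, conv_weights=conv, emission=emission,
                   transition=transition,
                   label_weights=np.asarray(blob["label_weights"], dtype=float),
                   biases=biases, feature_manifest=blob.get("feature_manifest", ""))

    def save(self, path) -> None:
        with io.open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "ModelParams":
        with io.open(path, "r", encoding="utf-8") as fh:
            return cls.from_json(fh.read())


# ---------------------------------------------------------------------------
# deep convolutional forward pass
# ---------------------------------------------------------------------------


@dataclass
class LayerActivations:
    """Activation stack: ``layers[0]`` is the input features, ``layers[-1]`` the top layer."""

    layers: list

    @property
    def top(self) -> np.ndarray:
        return self.layers[-1]


def _activate(x, kind):
    return expit(x) if kind == "sigmoid" else np.tanh(x)


def _shift(a: np.ndarray, l: int) -> np.ndarray:
    """Row-shifted copy: out[i] = a[i+l], zero where i+l falls outside the chain."""
    out = np.zeros_like(a)
    n = a.shape[0]
    if l >= 0:
        if l < n:
            out[: n - l] = a[l:]
    else:
        if -l < n:
            out[-l:] = a[: n + l]
    return out


def dcnn_forward(params: ModelParams, features) -> LayerActivations:
    """Run the convolution stack over a chain.

    Each hidden activation is h(sum over window offsets l and source neurons j'
    of A[i+l, j'] * W_l[j, j']); positions outside the chain contribute zero
    (zero padding), so every layer keeps L rows.
    """
    x = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    if x.ndim != 2:
        raise ShapeError(f"features must be 2-D, got shape {x.shape}")
    if x.shape[1] != params.arch.input_dim:
        raise ShapeError(
            f"input layer: feature width {x.shape[1]} != architecture input_dim "
            f"{params.arch.input_dim}"
        )
    layers = [x]
    a = x
    for k, w in enumerate(params.conv_weights):
        nk = params.arch.half_windows[k]
        pre = np.zeros((a.shape[0], w.shape[1]))
        for off in range(-nk, nk + 1):
            pre += _shift(a, off) @ w[off + nk].T
        if params.biases is not None:
            pre += params.biases[k]
        a = _activate(pre, params.arch.activation)
        layers.append(a)
    return LayerActivations(layers)


# ---------------------------------------------------------------------------
# weighted CRF potentials and chain algorithms
# ---------------------------------------------------------------------------


def emission_logpot(params: ModelParams, top: np.ndarray) -> np.ndarray:
    """L x D table of weighted emission potentials: phi'[i, a] = w_a * U_a . H_i."""
    return (top @ params.emission.T) * params.label_weights


def transition_logpot(params: ModelParams) -> np.ndarray:
    """D x D table of weighted transition potentials: psi'[a, b] = w_a * T_{a,b}."""
    return params.transition * params.label_weights[:, None]


def weighted_potentials(params: ModelParams, top, i: int, a: int, b: int):
    """Scalar weighted potentials (psi', phi') at 0-based position ``i``.

    ``psi'`` scores the label pair (Y_i = a, Y_{i+1} = b) and is defined as 0
    at the last position, where no following residue exists; ``phi'`` scores
    label a against the top-layer activations at position i. With all label
    weights equal to 1 these are the plain CNF potentials.
    """
    top = top.top if isinstance(top, LayerActivations) else np.asarray(top, float)
    length, d = top.shape[0], params.arch.num_labels
    if not (0 <= i < length):
        raise IndexError(f"position {i} outside chain of length {length}")
    if not (0 <= a < d and 0 <= b < d):
        raise IndexError(f"label pair ({a}, {b}) invalid for {d} labels")
    w = params.label_weights
    phi = w[a] * float(params.emission[a] @ top[i])
    psi = w[a] * float(params.transition[a, b]) if i < length - 1 else 0.0
    return psi, phi


def sequence_score(params: ModelParams, top, labels: LabelSequence) -> float:
    """Log of the unnormalized path score: sum over i of psi' + phi' for the given labels."""
    top = top.top if isinstance(top, LayerActivations) else np.asarray(top, float)
    y = labels.states if isinstance(labels, LabelSequence) else np.asarray(labels)
    if isinstance(labels, LabelSequence) and not labels.fully_observed:
        raise ValueError("sequence_score requires fully observed labels; compress masks first")
    if y.shape[0] != top.shape[0]:
        raise ShapeError(f"labels length {y.shape[0]} != chain length {top.shape[0]}")
    phi = emission_logpot(params, top)
    psi = transition_logpot(params)
    idx = np.arange(y.shape[0])
    score = float(phi[idx, y].sum())
    if y.shape[0] > 1:
        score += float(psi[y[:-1], y[1:]].sum())
    return score


def _chain_tables(params: ModelParams, top: np.ndarray):
    phi = emission_logpot(params, top)
    if not np.all(np.isfinite(phi)):
        bad = int(np.argwhere(~np.isfinite(phi))[0, 0])
        raise FloatingPointError(f"non-finite emission potential at position {bad}")
    return phi, transition_logpot(params)


def _lse_cols(m):
    """logsumexp over axis 0 of a small D x D array (cheap, loop-friendly)."""
    mx = m.max(axis=0)
    return mx + np.log(np.exp(m - mx).sum(axis=0))


def _forward(phi, psi):
    length, d = phi.shape
    alpha = np.empty((length, d))
    alpha[0] = phi[0]
    for i in range(1, length):
        alpha[i] = phi[i] + _lse_cols(alpha[i - 1][:, None] + psi)
    return alpha


def _backward(phi, psi):
    length, d = phi.shape
    beta = np.zeros((length, d))
    for i in range(length - 2, -1, -1):
        beta[i] = _lse_cols((psi + (phi[i + 1] + beta[i + 1])[None, :]).T)
    return beta


def partition_log(params: ModelParams, top) -> float:
    """log Z(X) by the forward recursion in log space."""
    top = top.top if isinstance(top, LayerActivations) else np.asarray(top, float)
    phi, psi = _chain_tables(params, top)
    return float(logsumexp(_forward(phi, psi)[-1]))


def conditional_log_prob(params: ModelParams, features, labels) -> float:
    """log P(Y | X) under the weighted model; always <= 0 up to rounding."""
    acts = dcnn_forward(params, features)
    return sequence_score(params, acts.top, labels) - partition_log(params, acts.top)


def posterior_marginals(params: ModelParams, features, return_pairwise=False):
    """Per-position posteriors P(Y_i = a | X) by forward-backward in log space.

    With ``return_pairwise`` also returns the (L-1) x D x D adjacent-pair
    posteriors used by the training gradient.
    """
    acts = dcnn_forward(params, features)
    phi, psi = _chain_tables(params, acts.top)
    alpha = _forward(phi, psi)
    beta = _backward(phi, psi)
    log_z = logsumexp(alpha[-1])
    node = np.exp(alpha + beta - log_z)
    node /= node.sum(axis=1, keepdims=True)  # remove residual rounding
    if not return_pairwise:
        return node
    if phi.shape[0] > 1:
        log_pair = (alpha[:-1, :, None] + psi[None, :, :]
                    + (phi[1:] + beta[1:])[:, None, :] - log_z)
        pair = np.exp(log_pair)
    else:
        pair = np.zeros((0, phi.shape[1], phi.shape[1]))
    return node, pair


def sample_path(params: ModelParams, features, rng) -> LabelSequence:
    """Draw one label path from P(Y | X) (forward filtering, backward sampling)."""
    acts = dcnn_forward(params, features)
    phi, psi = _chain_tables(params, acts.top)
    alpha = _forward(phi, psi)
    length, d = phi.shape
    y = np.empty(length, dtype=np.int8)
    p = np.exp(alpha[-1] - logsumexp(alpha[-1]))
    y[-1] = rng.choice(d, p=p / p.sum())
    for i in range(length - 2, -1, -1):
        logits = alpha[i] + psi[:, y[i + 1]]
        p = np.exp(logits - logsumexp(logits))
        y[i] = rng.choice(d, p=p / p.sum())
    return LabelSequence(y)


def classify(marginals: np.ndarray, threshold: float = 0.2) -> LabelSequence:
    """Threshold the disorder posterior: disorder iff P(disorder) >= threshold.

    The default of 0.2 follows the released predictor's operating point,
    chosen for best MCC on training data.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    marginals = np.asarray(marginals, dtype=float)
    return LabelSequence((marginals[:, DISORDER] >= threshold).astype(np.int8))
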