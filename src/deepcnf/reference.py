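"""Slow, independently coded verification routines.

Everything here is written with explicit Python loops and exhaustive
enumeration, deliberately avoiding the vectorized code paths in
:mod:`deepcnf.model` and :mod:`deepcnf.training`, so the two routes can be
compared in tests. The unweighted functions implement the plain (no
label-weight) convolutional neural field as a separate code path.

Only suitable for tiny problems (chain length <= ~12, two labels).
"""
from __future__ import annotations

import itertools
import math

import numpy as np

from .model import ModelParams
from .types import LabelSequence


def naive_forward(params: ModelParams, x: np.ndarray):
    """Convolution stack evaluated with explicit index loops; returns all layers."""
    act = params.arch.activation
    h = (lambda v: 1.0 / (1.0 + math.exp(-v))) if act == "sigmoid" else math.tanh
    layers = [np.asarray(x, dtype=float)]
    for k, w in enumerate(params.conv_weights):
        nk = params.arch.half_windows[k]
        a = layers[-1]
        length = a.shape[0]
        out = np.zeros((length, w.shape[1]))
        for i in range(length):
            for j in range(w.shape[1]):
                s = 0.0
                for l in range(-nk, nk + 1):
                    if 0 <= i + l < length:
                        for jp in range(w.shape[2]):
                            s += a[i + l, jp] * w[l + nk, j, jp]
                if params.biases is not None:
                    s += params.biases[k][j]
                out[i, j] = h(s)
        layers.append(out)
    return layers


def _path_score(params: ModelParams, top: np.ndarray, y, weighted: bool) -> float:
    w = params.label_weights if weighted else np.ones_like(params.label_weights)
    length = top.shape[0]
    s = 0.0
    for i in range(length):
        s += w[y[i]] * float(np.dot(params.emission[y[i]], top[i]))
        if i + 1 < length:
            s += w[y[i]] * float(params.transition[y[i], y[i + 1]])
    return s


def enumerate_log_partition(params: ModelParams, top: np.ndarray, weighted=True) -> float:
    """log Z by brute-force summation over all D^L label paths."""
    d = params.arch.num_labels
    length = top.shape[0]
    scores = [
        _path_score(params, top, y, weighted)
        for y in itertools.product(range(d), repeat=length)
    ]
    m = max(scores)
    return m + math.log(sum(math.exp(s - m) for s in scores))


def enumerate_marginals(params: ModelParams, top: np.ndarray, weighted=True) -> np.ndarray:
    """Per-position posteriors by enumerating every label path."""
    d = params.arch.num_labels
    length = top.shape[0]
    log_z = enumerate_log_partition(params, top, weighted)
    node = np.zeros((length, d))
    for y in itertools.product(range(d), repeat=length):
        p = math.exp(_path_score(params, top, y, weighted) - log_z)
        for i, a in enumerate(y):
            node[i, a] += p
    return node


def enumerate_pair_marginals(params: ModelParams, top: np.ndarray, weighted=True) -> np.ndarray:
    d = params.arch.num_labels
    length = top.shape[0]
    log_z = enumerate_log_partition(params, top, weighted)
    pair = np.zeros((max(length - 1, 0), d, d))
    for y in itertools.product(range(d), repeat=length):
        p = math.exp(_path_score(params, top, y, weighted) - log_z)
        for i in range(length - 1):
            pair[i, y[i], y[i + 1]] += p
    return pair


def unweighted_log_likelihood(params: ModelParams, x: np.ndarray, labels) -> float:
    """log P(Y | X) of the plain CNF (all label weights treated as 1)."""
    y = labels.states if isinstance(labels, LabelSequence) else np.asarray(labels)
    top = naive_forward(params, x)[-1]
    return _path_score(params, top, y, weighted=False) - enumerate_log_partition(
        params, top, weighted=False
    )


def unweighted_gradient(params: ModelParams, x: np.ndarray, labels):
    """Analytic gradient of the plain-CNF log-likelihood, coded with loops.

    Returns (d_conv, d_biases, d_emission, d_transition) matching the shapes in
    ``params``; marginals come from path enumeration, the convolution stack is
    differentiated with explicit index loops.
    """
    y = labels.states if isinstance(labels, LabelSequence) else np.asarray(labels)
    layers = naive_forward(params, x)
    top = layers[-1]
    length = top.shape[0]
    d = params.arch.num_labels
    node = enumerate_marginals(params, top, weighted=False)
    pair = enumerate_pair_marginals(params, top, weighted=False)

    d_emission = np.zeros_like(params.emission)
    for i in range(length):
        for a in range(d):
            d_emission[a] += ((1.0 if y[i] == a else 0.0) - node[i, a]) * top[i]
    d_transition = np.zeros_like(params.transition)
    for i in range(length - 1):
        for a in range(d):
            for b in range(d):
                obs = 1.0 if (y[i] == a and y[i + 1] == b) else 0.0
                d_transition[a, b] += obs - pair[i, a, b]

    # error signal on the top layer
    d_top = np.zeros_like(top)
    for i in range(length):
        for a in range(d):
            d_top[i] += ((1.0 if y[i] == a else 0.0) - node[i, a]) * params.emission[a]

    d_conv = [np.zeros_like(w) for w in params.conv_weights]
    d_biases = None if params.biases is None else [np.zeros_like(b) for b in params.biases]
    d_act = d_top
    for k in range(params.arch.num_hidden_layers - 1, -1, -1):
        a_prev, a_cur = layers[k], layers[k + 1]
        nk = params.arch.half_windows[k]
        w = params.conv_weights[k]
        if params.arch.activation == "sigmoid":
            d_pre = d_act * a_cur * (1.0 - a_cur)
        else:
            d_pre = d_act * (1.0 - a_cur ** 2)
        d_prev = np.zeros_like(a_prev)
        for i in range(length):
            for j in range(w.shape[1]):
                g = d_pre[i, j]
                if d_biases is not None:
                    d_biases[k][j] += g
                for l in range(-nk, nk + 1):
                    if 0 <= i + l < length:
                        for jp in range(w.shape[2]):
                            d_conv[k][l + nk, j, jp] += g * a_prev[i + l, jp]
                            d_prev[i + l, jp] += g * w[l + nk, j, jp]
        d_act = d_prev
    return d_conv, d_biases, d_emission, d_transition
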