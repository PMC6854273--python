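"""Two-layer logistic edge-detection network with table-lookup activation.

Every unit computes ``O = 1 / (1 + exp(-(sum_j W_j I_j + b)))``.  The
activation and its derivative are read from lookup tables indexed by the
weighted sum rounded to the nearest integer index; the index scale ``Is``
(the index corresponding to an argument of 1) is 200, the tables span
arguments [-8, +8] and saturate beyond.  Training is per-pattern stochastic
gradient descent on a sum-squared-error loss with targets 1 (edge) and 0
(no edge); with these targets the trained output estimates the posterior
probability of the edge class, so classification thresholds the output at
1/2 (Bayes rule, strict inequality).

The learning rate decays hyperbolically over epochs,
``eta = eta0 / (1 + eta_e * k_e)``, and de-novo training is multi-start:
several random initializations are trained briefly and the one with the
lowest training loss is continued.  Weights are stored in argument units;
an initialization standard deviation of ``Is / (1.33 N)`` table-index units
(N = hidden count) is therefore ``1 / (1.33 N)`` in stored units.

A continuous-activation mode (``use_table=False``) bypasses the tables and
rounding; it exists so gradients and outputs can be checked against exact
logistic arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from numba import njit

__all__ = [
    "TABLE_INDEX_SCALE",
    "TABLE_RANGE",
    "EdgeNetwork",
    "TrainConfig",
    "init_network",
    "forward",
    "classify",
    "score",
    "sse_loss",
    "train",
    "split_dataset",
]

TABLE_INDEX_SCALE = 200  # Is: table index for an argument of unity
TABLE_RANGE = 8.0  # tables span arguments [-8, +8]
_HALF = int(TABLE_RANGE * TABLE_INDEX_SCALE)  # 1600


def _build_tables():
    args = np.arange(-_HALF, _HALF + 1) / TABLE_INDEX_SCALE
    table = 1.0 / (1.0 + np.exp(-args))
    dtable = table * (1.0 - table)
    return table, dtable

_TABLE, _DTABLE = _build_tables()


@dataclass
class TrainConfig:
    """SGD protocol parameters.

    Defaults follow the reference protocol: eta0 and eta_e at the midpoints
    of their nominal ranges (0.75-2.0 and 0.005-0.01), five multi-start
    initializations of 50 epochs each, and a 3/4 training fraction.
    """

    eta0: float = 1.0
    etae: float = 0.0075
    epochs: int = 900
    n_starts: int = 5
    start_epochs: int = 50
    seed: int = 0
    train_fraction: float = 0.75


@dataclass
class EdgeNetwork:
    """Weights and biases of the two-layer lookup-table logistic network."""

    W1: np.ndarray  # (n_hidden, n_inputs)
    b1: np.ndarray  # (n_hidden,)
    W2: np.ndarray  # (n_hidden,)
    b2: float
    use_table: bool = True
    feature_names: Optional[list] = None

    @property
    def n_inputs(self) -> int:
        return self.W1.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.W1.shape[0]

    def copy(self) -> "EdgeNetwork":
        return EdgeNetwork(
            self.W1.copy(),
            self.b1.copy(),
            self.W2.copy(),
            float(self.b2),
            self.use_table,
            None if self.feature_names is None else list(self.feature_names),
        )


def init_network(n_inputs: int, n_hidden: int = 32, seed=0) -> EdgeNetwork:
    """Gaussian initialization, sigma = Is/(1.33*N) in table-index units."""
    if n_inputs <= 0 or n_hidden <= 0:
        raise ValueError("network sizes must be positive")
    rng = np.random.default_rng(seed)
    sigma = 1.0 / (1.33 * n_hidden)  # argument units
    return EdgeNetwork(
        W1=rng.normal(0.0, sigma, (n_hidden, n_inputs)),
        b1=rng.normal(0.0, sigma, n_hidden),
        W2=rng.normal(0.0, sigma, n_hidden),
        b2=float(rng.normal(0.0, sigma)),
    )


def _activate(a: np.ndarray, use_table: bool) -> np.ndarray:
    if use_table:
        idx = np.clip(np.rint(a * TABLE_INDEX_SCALE).astype(np.int64), -_HALF, _HALF)
        return _TABLE[idx + _HALF]
    return 1.0 / (1.0 + np.exp(-a))


def forward(net: EdgeNetwork, x: np.ndarray, return_hidden: bool = False):
    """Network output(s) in (0, 1) for one pattern or a batch (N, P)."""
    x = np.asarray(x, dtype=np.float64)
    single = x.ndim == 1
    X = x[None, :] if single else x
    if X.shape[1] != net.n_inputs:
        raise ValueError("feature vector length does not match the network")
    H = _activate(X @ net.W1.T + net.b1, net.use_table)
    out = _activate(H @ net.W2 + net.b2, net.use_table)
    if single:
        out, H = out[0], H[0]
    return (out, H) if return_hidden else out


def classify(net: EdgeNetwork, x: np.ndarray) -> np.ndarray:
    """1 (edge) iff the output strictly exceeds the Bayes threshold 1/2."""
    return (forward(net, x) > 0.5).astype(np.int8)


def score(net: EdgeNetwork, X: np.ndarray, y: np.ndarray) -> float:
    """Fraction of patterns whose classification matches the label."""
    y = np.asarray(y)
    if y.size == 0:
        raise ValueError("empty dataset")
    return float(np.mean(classify(net, X) == y))


def sse_loss(net: EdgeNetwork, X: np.ndarray, y: np.ndarray) -> float:
    """Half sum of squared output errors (the training objective)."""
    out = forward(net, X)
    return float(0.5 * np.sum((out - np.asarray(y, dtype=np.float64)) ** 2))


@njit(cache=True, fastmath=True)
def _sgd_epochs(
    X, y, W1, b1, W2, b2, perms, eta0, etae, k0, table, dtable, use_table
):  # pragma: no cover - numba
    """Per-pattern SGD over ``perms.shape[0]`` epochs; mutates the weights.

    b2 is a length-1 array so the scalar bias can be updated in place.
    Returns the per-epoch summed loss.
    """
    n_epochs, N = perms.shape
    H, P = W1.shape
    h = np.empty(H)
    dh = np.empty(H)
    losses = np.empty(n_epochs)
    half = _HALF
    Is = float(TABLE_INDEX_SCALE)
    for e in range(n_epochs):
        eta = eta0 / (1.0 + etae * (k0 + e))
        sse = 0.0
        for n in range(N):
            i = perms[e, n]
            for j in range(H):
                a = b1[j]
                for p in range(P):
                    a += W1[j, p] * X[i, p]
                if use_table:
                    k = int(round(a * Is))
                    if k < -half:
                        k = -half
                    elif k > half:
                        k = half
                    h[j] = table[k + half]
                    dh[j] = dtable[k + half]
                else:
                    o = 1.0 / (1.0 + np.exp(-a))
                    h[j] = o
                    dh[j] = o * (1.0 - o)
            a2 = b2[0]
            for j in range(H):
                a2 += W2[j] * h[j]
            if use_table:
                k = int(round(a2 * Is))
                if k < -half:
                    k = -half
                elif k > half:
                    k = half
                o2 = table[k + half]
                do2 = dtable[k + half]
            else:
                o2 = 1.0 / (1.0 + np.exp(-a2))
                do2 = o2 * (1.0 - o2)
            err = o2 - y[i]
            sse += 0.5 * err * err
            d2 = err * do2
            for j in range(H):
                d1 = d2 * W2[j] * dh[j]
                W2[j] -= eta * d2 * h[j]
                b1[j] -= eta * d1
                for p in range(P):
                    W1[j, p] -= eta * d1 * X[i, p]
            b2[0] -= eta * d2
        losses[e] = sse
    return losses


def _run_sgd(net, X, y, cfg, n_epochs, k0, rng):
    perms = np.empty((n_epochs, X.shape[0]), dtype=np.int64)
    for e in range(n_epochs):
        perms[e] = rng.permutation(X.shape[0])
    b2 = np.array([net.b2])
    losses = _sgd_epochs(
        np.ascontiguousarray(X, dtype=np.float64),
        np.ascontiguousarray(y, dtype=np.float64),
        net.W1,
        net.b1,
        net.W2,
        b2,
        perms,
        cfg.eta0,
        cfg.etae,
        k0,
        _TABLE,
        _DTABLE,
        net.use_table,
    )
    net.b2 = float(b2[0])
    return losses


def train(
    net: Optional[EdgeNetwork],
    X: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig,
    n_hidden: int = 32,
):
    """Train a network on labeled feature vectors.

    If ``net`` is None, the multi-start protocol runs: ``cfg.n_starts``
    random initializations are each trained for ``cfg.start_epochs`` epochs
    and the one with the lowest final training loss is continued until
    ``cfg.epochs`` total epochs.  If ``net`` is given, training continues
    from its weights for ``cfg.epochs`` epochs with no multi-start (used
    for single-edge-type refinement and for retraining during pruning).

    Returns ``(net, history)`` with a per-epoch DataFrame of the learning
    rate and summed SSE loss.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("training data must be a non-empty (N, P) array")
    seed = cfg.seed
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    if net is None:
        children = ss.spawn(2 * cfg.n_starts)
        starts = []
        for k in range(cfg.n_starts):
            cand = init_network(X.shape[1], n_hidden, children[2 * k])
            rng = np.random.default_rng(children[2 * k + 1])
            losses = _run_sgd(cand, X, y, cfg, cfg.start_epochs, 0, rng)
            starts.append((losses[-1], k, cand, losses, rng))
        starts.sort(key=lambda s: (s[0], s[1]))
        _, _, net, head, rng = starts[0]
        remaining = max(cfg.epochs - cfg.start_epochs, 0)
        tail = _run_sgd(net, X, y, cfg, remaining, cfg.start_epochs, rng)
        losses = np.concatenate([head, tail])
    else:
        net = net.copy()
        rng = np.random.default_rng(ss)
        losses = _run_sgd(net, X, y, cfg, cfg.epochs, 0, rng)
    epochs = np.arange(losses.size)
    history = pd.DataFrame(
        {
            "epoch": epochs,
            "eta": cfg.eta0 / (1.0 + cfg.etae * epochs),
            "loss": losses,
        }
    )
    return net, history


def split_dataset(X, y, seed, train_fraction: float = 0.75):
    """Stratified random train/test split (3/4 : 1/4 by default).

    Returns index arrays (train_idx, test_idx); deterministic given seed.
    """
    y = np.asarray(y)
    if y.size < 4:
        raise ValueError("need at least 4 patterns to split")
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for label in np.unique(y):
        idx = np.flatnonzero(y == label)
        idx = idx[rng.permutation(idx.size)]
        n_train = int(round(train_fraction * idx.size))
        train_idx.append(idx[:n_train])
        test_idx.append(idx[n_train:])
    train_idx = np.sort(np.concatenate(train_idx))
    test_idx = np.sort(np.concatenate(test_idx))
    return train_idx, test_idx
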