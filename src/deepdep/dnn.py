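"""Feed-forward classifier with denoising-autoencoder pretraining (numpy).

The classifier maps a perturbed transcriptome (features scaled to [0, 1]) to
the probability that the profile is associated with cell death (dependency).
Training follows the scheme:

* layer-wise stacked denoising autoencoder (SdA) pretraining: each hidden
  layer reconstructs its (mask-corrupted) input through tied weights,
  y = f(W x + b), z = f(W^T y + b'), minimising the batch reconstruction cost
  (squared error for ReLU activations, cross-entropy for sigmoid) by plain
  stochastic gradient descent;
* supervised fine-tuning of the full stack plus a 2-unit softmax output,
  minimising Loss = NLL + lambda1*||w||_1 + lambda2*||w||_2 (elastic net on
  the weights, L2 as the norm itself, not its square), by mini-batch gradient
  descent with momentum: v_{t+1} = mu*v_t - eps*grad, theta_{t+1} = theta_t
  + v_{t+1}, v_0 = 0;
* patience-based early stopping on a held-out stop-control split: patience
  starts at 200 epochs; whenever the stop-control loss improves below
  0.99 x best, the model is checkpointed and patience becomes
  max(initial patience, 2 x current epoch); training halts once the epoch
  counter reaches patience.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

logger = logging.getLogger(__name__)

ACTIVATIONS = ("relu", "sigmoid")
INIT_SCHEMES = ("uniform_scaled", "normal_scaled")


@dataclass(frozen=True)
class Hyperparameters:
    hidden_nodes: tuple[int, ...] = (128,)
    learning_rate: float = 0.01
    momentum: float = 0.5
    batch_size: int = 32
    activation: str = "relu"
    init_scheme: str = "uniform_scaled"
    l1: float = 0.0
    l2: float = 0.0
    dropout_rate: float = 0.0

    def __post_init__(self) -> None:
        if not self.hidden_nodes or any(h < 1 for h in self.hidden_nodes):
            raise ValueError("hidden_nodes must be >= 1 per layer")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must lie in [0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.init_scheme not in INIT_SCHEMES:
            raise ValueError(f"unknown init scheme {self.init_scheme!r}")
        if self.l1 < 0 or self.l2 < 0:
            raise ValueError("regularization weights must be >= 0")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")

    @property
    def n_hidden_layers(self) -> int:
        return len(self.hidden_nodes)


@dataclass
class EarlyStopConfig:
    """Patience-based stopping with multiplicative improvement threshold."""

    patience: int = 200
    improvement_threshold: float = 0.99
    max_epochs: Optional[int] = None  # optional hard cap on top of patience


@dataclass
class NetworkParams:
    """Weights/biases of the stack; the last layer is the 2-unit softmax output."""

    weights: list[np.ndarray]  # layer l: (n_out, n_in)
    biases: list[np.ndarray]  # layer l: (n_out,)

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            weights=[w.copy() for w in self.weights],
            biases=[b.copy() for b in self.biases],
        )


def _act(a: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return np.maximum(a, 0.0)
    return 1.0 / (1.0 + np.exp(-np.clip(a, -30, 30)))


def _act_grad_from_output(h: np.ndarray, a: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return (a > 0).astype(a.dtype)
    return h * (1.0 - h)


def _init_matrix(rng: np.random.Generator, n_out: int, n_in: int, scheme: str) -> np.ndarray:
    scale = np.sqrt(6.0 / (n_in + n_out))
    if scheme == "uniform_scaled":
        return rng.uniform(-scale, scale, size=(n_out, n_in))
    return rng.normal(0.0, np.sqrt(2.0 / (n_in + n_out)), size=(n_out, n_in))


def init_params(n_features: int, hp: Hyperparameters, rng: np.random.Generator) -> NetworkParams:
    sizes = [n_features, *hp.hidden_nodes, 2]
    weights = [
        _init_matrix(rng, sizes[i + 1], sizes[i], hp.init_scheme) for i in range(len(sizes) - 1)
    ]
    biases = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
    return NetworkParams(weights=weights, biases=biases)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def forward(
    params: NetworkParams,
    X: np.ndarray,
    hp: Hyperparameters,
    rng: Optional[np.random.Generator] = None,
    train: bool = False,
) -> tuple[np.ndarray, list]:
    """Return class probabilities (n, 2) and the per-layer cache for backprop.

    During training, inverted dropout at ``hp.dropout_rate`` is applied to the
    hidden activations.
    """
    h = X
    cache = []
    n_hidden = len(params.weights) - 1
    for l in range(n_hidden):
        a = h @ params.weights[l].T + params.biases[l]
        out = _act(a, hp.activation)
        mask = None
        if train and hp.dropout_rate > 0:
            assert rng is not None
            mask = (rng.random(out.shape) >= hp.dropout_rate) / (1.0 - hp.dropout_rate)
            out = out * mask
        cache.append((h, a, out, mask))
        h = out
    logits = h @ params.weights[-1].T + params.biases[-1]
    probs = _softmax(logits)
    cache.append((h, logits, probs, None))
    return probs, cache


def predict_proba(params: NetworkParams, X: np.ndarray, hp: Hyperparameters) -> np.ndarray:
    """Class-1 (dependency) probability per row."""
    probs, _ = forward(params, X, hp, train=False)
    return probs[:, 1]


def nll(probs1: np.ndarray, y: np.ndarray, eps: float = 1e-12) -> float:
    """Mean negative log likelihood of binary labels given class-1 probabilities."""
    p = np.clip(probs1, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def _global_l2_norm(weights: list[np.ndarray]) -> float:
    return float(np.sqrt(sum(float((w**2).sum()) for w in weights)))


def regularization(params: NetworkParams, hp: Hyperparameters) -> float:
    """Elastic-net penalty lambda1*||w||_1 + lambda2*||w||_2 over all weights."""
    l1 = sum(float(np.abs(w).sum()) for w in params.weights)
    l2 = _global_l2_norm(params.weights)
    return hp.l1 * l1 + hp.l2 * l2


def _backward(
    params: NetworkParams,
    cache: list,
    y: np.ndarray,
    hp: Hyperparameters,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Gradients of NLL + elastic net wrt every weight and bias."""
    B = len(y)
    h_last, _, probs, _ = cache[-1]
    onehot = np.zeros_like(probs)
    onehot[np.arange(B), y.astype(int)] = 1.0
    delta = (probs - onehot) / B  # gradient at the softmax logits
    gw = [np.zeros_like(w) for w in params.weights]
    gb = [np.zeros_like(b) for b in params.biases]
    gw[-1] = delta.T @ h_last
    gb[-1] = delta.sum(axis=0)
    grad_h = delta @ params.weights[-1]
    for l in range(len(params.weights) - 2, -1, -1):
        h_in, a, out, mask = cache[l]
        if mask is not None:
            grad_h = grad_h * mask
        grad_a = grad_h * _act_grad_from_output(out if mask is None else _act(a, hp.activation), a, hp.activation)
        gw[l] = grad_a.T @ h_in
        gb[l] = grad_a.sum(axis=0)
        if l > 0:
            grad_h = grad_a @ params.weights[l]
    if hp.l1 > 0 or hp.l2 > 0:
        norm = _global_l2_norm(params.weights)
        for l, w in enumerate(params.weights):
            if hp.l1 > 0:
                gw[l] = gw[l] + hp.l1 * np.sign(w)
            if hp.l2 > 0 and norm > 0:
                gw[l] = gw[l] + hp.l2 * w / norm
    return gw, gb


def pretrain_sda(
    X: np.ndarray,
    hp: Hyperparameters,
    seed: int,
    epochs: int = 15,
) -> NetworkParams:
    """Layer-wise denoising-autoencoder pretraining of the hidden stack.

    Each layer corrupts its input by masking entries to zero at
    ``hp.dropout_rate``, encodes y = f(Wx + b), decodes z = f(W^T y + b')
    through tied weights, and minimises the reconstruction cost by plain SGD
    at the model learning rate.  The softmax output layer is left at its
    random initialisation.  Raises on a non-finite cost.
    """
    if hp.dropout_rate >= 1.0:
        raise ValueError("masking rate must be < 1")
    rng = np.random.default_rng(seed)
    params = init_params(X.shape[1], hp, rng)
    h = X
    for l, n_out in enumerate(hp.hidden_nodes):
        W = params.weights[l]
        b = params.biases[l]
        b_prime = np.zeros(h.shape[1])
        n = h.shape[0]
        for _epoch in range(epochs):
            order = rng.permutation(n)
            for start in range(0, n, hp.batch_size):
                idx = order[start : start + hp.batch_size]
                x = h[idx]
                B = len(idx)
                corrupt = x * (rng.random(x.shape) >= hp.dropout_rate)
                a1 = corrupt @ W.T + b
                y_enc = _act(a1, hp.activation)
                a2 = y_enc @ W + b_prime
                z = _act(a2, hp.activation)
                if hp.activation == "relu":
                    cost = float(((x - z) ** 2).sum()) / B
                    g2 = 2.0 * (z - x) / B * _act_grad_from_output(z, a2, "relu")
                else:
                    zc = np.clip(z, 1e-12, 1 - 1e-12)
                    cost = float(-(x * np.log(zc) + (1 - x) * np.log(1 - zc)).sum()) / B
                    g2 = (z - x) / B  # CE + sigmoid cancel
                if not np.isfinite(cost):
                    raise FloatingPointError(
                        f"non-finite pretraining cost at layer {l}, epoch {_epoch}"
                    )
                gW = y_enc.T @ g2  # decode contribution, shape (n_out, n_in)
                gb_prime = g2.sum(axis=0)
                g_y = g2 @ W.T
                g1 = g_y * _act_grad_from_output(y_enc, a1, hp.activation)
                gW += g1.T @ corrupt
                gb = g1.sum(axis=0)
                W -= hp.learning_rate * gW
                b -= hp.learning_rate * gb
                b_prime -= hp.learning_rate * gb_prime
        h = _act(h @ W.T + b, hp.activation)
    return params


def reconstruction_cost(
    params: NetworkParams, X: np.ndarray, hp: Hyperparameters, layer: int = 0
) -> float:
    """Clean-input reconstruction cost of one pretrained layer (diagnostics)."""
    W, b = params.weights[layer], params.biases[layer]
    y_enc = _act(X @ W.T + b, hp.activation)
    z = _act(y_enc @ W, hp.activation)
    if hp.activation == "relu":
        return float(((X - z) ** 2).sum()) / len(X)
    zc = np.clip(z, 1e-12, 1 - 1e-12)
    return float(-(X * np.log(zc) + (1 - X) * np.log(1 - zc)).sum()) / len(X)


@dataclass
class FitResult:
    params: NetworkParams
    hp: Hyperparameters
    n_epochs: int = 0
    final_patience: int = 0
    best_stop_loss: float = np.inf
    stop_loss_trace: list[float] = field(default_factory=list)


def finetune(
    params0: NetworkParams,
    X: np.ndarray,
    y: np.ndarray,
    hp: Hyperparameters,
    seed: int,
    stop: Optional[EarlyStopConfig] = None,
    learning_fraction: float = 0.75,
    groups: Optional[np.ndarray] = None,
) -> FitResult:
    """Supervised fine-tuning with momentum SGD, elastic net, and early stopping.

    The provided data are split (stratified by label, and additionally within
    ``groups`` when given, seeded) into a learning part (3/4) and a
    stop-control part (1/4); improvement is measured on the stop-control mean
    negative log likelihood.
    """
    if stop is None:
        stop = EarlyStopConfig()
    rng = np.random.default_rng(seed)
    n = len(y)
    if groups is None:
        strata = [np.flatnonzero(y == cls) for cls in np.unique(y)]
    else:
        groups = np.asarray(groups)
        strata = [
            np.flatnonzero((y == cls) & (groups == g))
            for cls in np.unique(y)
            for g in dict.fromkeys(groups)
        ]
    learn_parts = []
    for idx in strata:
        if len(idx) == 0:
            continue
        idx = idx.copy()
        rng.shuffle(idx)
        learn_parts.append(idx[: max(1, int(round(len(idx) * learning_fraction)))])
    learn_idx = np.concatenate(learn_parts)
    stop_idx = np.setdiff1d(np.arange(n), learn_idx)
    if len(stop_idx) == 0:  # tiny datasets: trace on the learning set itself
        stop_idx = learn_idx
    X_learn, y_learn = X[learn_idx], y[learn_idx]
    X_stop, y_stop = X[stop_idx], y[stop_idx]

    params = params0.copy()
    velocity_w = [np.zeros_like(w) for w in params.weights]
    velocity_b = [np.zeros_like(b) for b in params.biases]
    best_params = params.copy()
    best_loss = np.inf
    patience = stop.patience
    trace: list[float] = []
    epoch = 0
    while epoch < patience:
        epoch += 1
        order = rng.permutation(len(y_learn))
        for start in range(0, len(order), hp.batch_size):
            idx = order[start : start + hp.batch_size]
            _, cache = forward(params, X_learn[idx], hp, rng=rng, train=True)
            gw, gb = _backward(params, cache, y_learn[idx], hp)
            for l in range(len(params.weights)):
                velocity_w[l] = hp.momentum * velocity_w[l] - hp.learning_rate * gw[l]
                velocity_b[l] = hp.momentum * velocity_b[l] - hp.learning_rate * gb[l]
                params.weights[l] += velocity_w[l]
                params.biases[l] += velocity_b[l]
        stop_loss = nll(predict_proba(params, X_stop, hp), y_stop)
        if not np.isfinite(stop_loss):
            raise FloatingPointError(f"training diverged at epoch {epoch}")
        trace.append(stop_loss)
        if stop_loss < best_loss * stop.improvement_threshold:
            best_loss = stop_loss
            best_params = params.copy()
            patience = max(stop.patience, 2 * epoch)
        if stop.max_epochs is not None and epoch >= stop.max_epochs:
            break
    return FitResult(
        params=best_params,
        hp=hp,
        n_epochs=epoch,
        final_patience=patience,
        best_stop_loss=best_loss,
        stop_loss_trace=trace,
    )


def simulate_early_stopping(
    losses: list[float],
    patience: int = 200,
    improvement_threshold: float = 0.99,
) -> tuple[int, int, int]:
    """Replay the patience rule on a precomputed loss trace.

    Returns (epochs run, final patience, 1-based epoch of the checkpointed
    best loss; 0 when no improvement was ever seen).  Used to verify the
    stopping semantics independently of network training.
    """
    best = np.inf
    best_epoch = 0
    current_patience = patience
    epoch = 0
    for loss in losses:
        if epoch >= current_patience:
            break
        epoch += 1
        if loss < best * improvement_threshold:
            best = loss
            best_epoch = epoch
            current_patience = max(patience, 2 * epoch)
    return epoch, current_patience, best_epoch
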