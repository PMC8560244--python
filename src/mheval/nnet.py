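"""Multilayer perceptron with two training rules.

The network is the classic three-layer (configurable-depth) perceptron with
sigmoid hidden units. Two heads/objectives are supported:

* ``cross_entropy_gd`` — a softmax output head trained by full-batch gradient
  descent on the cross-entropy loss with optional L2 weight decay
  (λ/(2m))·Σθ² over weights (biases excluded).
* ``sse_lm`` — sigmoid output units trained by the Levenberg–Marquardt rule
  on the sum-squared error E = ½·Σ(d − y)². Each step solves
  (JᵀJ + µI)Δ = −Jᵀe with J the residual Jacobian assembled from per-sample
  reverse-mode passes; µ shrinks after an accepted step and grows after a
  rejected one, interpolating between Gauss–Newton (µ→0) and a small
  gradient-descent step (µ→∞).

All routines are deterministic given the seed and configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .datasets import Dataset, split_train_test
from .encoding import DatasetEncoder

__all__ = [
    "MLPParams",
    "TrainConfig",
    "TrainingError",
    "init_network",
    "softmax",
    "sigmoid",
    "forward",
    "cross_entropy_loss",
    "backprop_gradients",
    "train_gd",
    "sse_loss",
    "residuals_and_jacobian",
    "lm_step",
    "train_lm",
    "NeuralNetModel",
    "NeuralNetResults",
]

_EPS = 1e-12
_MU_MAX = 1e12


class TrainingError(RuntimeError):
    pass


@dataclass
class MLPParams:
    """Layer weight matrices (fan_in × fan_out) and bias vectors."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (self.weights[0].shape[0],) + tuple(w.shape[1] for w in self.weights)

    @property
    def n_params(self) -> int:
        return sum(w.size for w in self.weights) + sum(b.size for b in self.biases)

    def to_vector(self) -> np.ndarray:
        parts = []
        for w, b in zip(self.weights, self.biases):
            parts.append(w.ravel())
            parts.append(b.ravel())
        return np.concatenate(parts)

    def from_vector(self, vec: np.ndarray) -> "MLPParams":
        weights, biases, k = [], [], 0
        for w, b in zip(self.weights, self.biases):
            weights.append(vec[k : k + w.size].reshape(w.shape).copy())
            k += w.size
            biases.append(vec[k : k + b.size].copy())
            k += b.size
        if k != vec.size:
            raise ValueError("vector length does not match parameter count")
        return MLPParams(weights=weights, biases=biases)

    def copy(self) -> "MLPParams":
        return MLPParams(
            weights=[w.copy() for w in self.weights],
            biases=[b.copy() for b in self.biases],
        )


@dataclass(frozen=True)
class TrainConfig:
    objective: str = "sse_lm"
    learning_rate: float = 0.1
    lam: float = 0.0
    mu0: float = 1e-3
    mu_factor: float = 10.0
    max_iters: int = 200
    tol: float = 1e-8
    seed: int = 0
    validation_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.objective not in ("cross_entropy_gd", "sse_lm"):
            raise ValueError(f"unknown objective {self.objective!r}")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.mu0 <= 0 or self.mu_factor <= 1:
            raise ValueError("need mu0 > 0 and mu_factor > 1")
        if not (0.0 <= self.validation_fraction < 0.5):
            raise ValueError("validation_fraction must lie in [0, 0.5)")


def init_network(layer_sizes: Sequence[int], seed: int) -> MLPParams:
    """Glorot-uniform weights in [−r, r], r = √(6/(fan_in+fan_out)); zero biases."""
    sizes = tuple(int(s) for s in layer_sizes)
    if len(sizes) < 3 or any(s < 1 for s in sizes):
        raise ValueError("need at least input, hidden and output layers, all >= 1")
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        r = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-r, r, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return MLPParams(weights=weights, biases=biases)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax with max-subtraction for overflow safety."""
    arr = np.asarray(logits, dtype=float)
    if arr.size == 0:
        raise ValueError("softmax of an empty vector")
    one_d = arr.ndim == 1
    if one_d:
        arr = arr[None, :]
    shifted = arr - arr.max(axis=1, keepdims=True)
    ez = np.exp(shifted)
    out = ez / ez.sum(axis=1, keepdims=True)
    return out[0] if one_d else out


@dataclass
class ForwardPass:
    activations: list[np.ndarray] = field(repr=False)  # input + hidden layers
    logits: np.ndarray = field(repr=False)  # final pre-activation
    probs: np.ndarray = field(repr=False)  # softmax head
    sigmoid_out: np.ndarray = field(repr=False)  # sigmoid head (SSE/LM)


def forward(params: MLPParams, inputs: np.ndarray) -> ForwardPass:
    """Run the network on a batch; returns both output heads."""
    X = np.atleast_2d(np.asarray(inputs, dtype=float))
    if X.shape[1] != params.layer_sizes[0]:
        raise ValueError(
            f"input width {X.shape[1]} != first layer size {params.layer_sizes[0]}"
        )
    acts = [X]
    a = X
    for w, b in zip(params.weights[:-1], params.biases[:-1]):
        a = sigmoid(a @ w + b)
        acts.append(a)
    logits = a @ params.weights[-1] + params.biases[-1]
    return ForwardPass(
        activations=acts,
        logits=logits,
        probs=softmax(logits),
        sigmoid_out=sigmoid(logits),
    )


def _check_one_hot(Y: np.ndarray) -> None:
    if not (
        np.all((Y == 0) | (Y == 1)) and np.allclose(Y.sum(axis=1), 1.0)
    ):
        raise ValueError("targets must be one-hot rows")


def cross_entropy_loss(
    params: MLPParams, X: np.ndarray, Y: np.ndarray, lam: float = 0.0
) -> float:
    """−ΣΣ y ln ŷ over the batch, plus (λ/(2m))·Σθ² over weights."""
    Y = np.atleast_2d(Y)
    _check_one_hot(Y)
    probs = np.clip(forward(params, X).probs, _EPS, 1.0 - _EPS)
    m = Y.shape[0]
    loss = -float(np.sum(Y * np.log(probs)))
    if lam:
        loss += lam / (2.0 * m) * sum(float(np.sum(w * w)) for w in params.weights)
    return loss


def backprop_gradients(
    params: MLPParams, X: np.ndarray, Y: np.ndarray, lam: float = 0.0
) -> MLPParams:
    """Gradient of the cross-entropy objective, packaged like the parameters.

    The softmax/cross-entropy pair collapses the output-layer error to
    (ŷ − y); hidden layers propagate through the sigmoid derivative a(1−a).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(Y)
    _check_one_hot(Y)
    fp = forward(params, X)
    m = X.shape[0]
    delta = fp.probs - Y
    grads_w: list[np.ndarray] = [None] * len(params.weights)
    grads_b: list[np.ndarray] = [None] * len(params.biases)
    for layer in range(len(params.weights) - 1, -1, -1):
        a_prev = fp.activations[layer]
        grads_w[layer] = a_prev.T @ delta
        grads_b[layer] = delta.sum(axis=0)
        if lam:
            grads_w[layer] = grads_w[layer] + (lam / m) * params.weights[layer]
        if layer > 0:
            a = fp.activations[layer]
            delta = (delta @ params.weights[layer].T) * a * (1.0 - a)
    return MLPParams(weights=grads_w, biases=grads_b)


def train_gd(
    params: MLPParams,
    X: np.ndarray,
    Y: np.ndarray,
    config: TrainConfig,
    callback: Callable[[int, MLPParams], None] | None = None,
) -> tuple[MLPParams, list[float]]:
    """Full-batch gradient descent on the cross-entropy objective.

    Returns the final parameters and the loss trace (initial loss first).
    Raises :class:`TrainingError` if the loss becomes non-finite.
    """
    if config.objective != "cross_entropy_gd":
        raise ValueError("train_gd requires objective='cross_entropy_gd'")
    params = params.copy()
    trace = [cross_entropy_loss(params, X, Y, config.lam)]
    for it in range(config.max_iters):
        g = backprop_gradients(params, X, Y, config.lam)
        for w, gw in zip(params.weights, g.weights):
            w -= config.learning_rate * gw
        for b, gb in zip(params.biases, g.biases):
            b -= config.learning_rate * gb
        loss = cross_entropy_loss(params, X, Y, config.lam)
        if not np.isfinite(loss):
            raise TrainingError(f"gradient descent diverged at iteration {it}")
        trace.append(loss)
        if callback is not None:
            callback(it, params)
        if abs(trace[-2] - trace[-1]) < config.tol:
            break
    return params, trace


def sse_loss(params: MLPParams, X: np.ndarray, D: np.ndarray) -> float:
    """E = ½·Σ (d − y)² with y the sigmoid output activations."""
    D = np.atleast_2d(D)
    _check_one_hot(D)
    y = forward(params, X).sigmoid_out
    return 0.5 * float(np.sum((D - y) ** 2))


def residuals_and_jacobian(
    params: MLPParams, X: np.ndarray, D: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Residual vector e = d − y and its Jacobian J = ∂e/∂x.

    Rows are ordered sample-major (all outputs of sample 0, then sample 1, …);
    columns follow :meth:`MLPParams.to_vector`. Assembled from per-sample,
    per-output reverse-mode passes, vectorized over the batch.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    D = np.atleast_2d(D)
    fp = forward(params, X)
    y = fp.sigmoid_out
    m, n_out = y.shape
    W = params.n_params
    e = (D - y).ravel()
    J = np.zeros((m, n_out, W))
    for k in range(n_out):
        # seed: derivative of output unit k w.r.t. its own pre-activation
        delta = np.zeros((m, n_out))
        delta[:, k] = y[:, k] * (1.0 - y[:, k])
        col = W
        d = delta
        for layer in range(len(params.weights) - 1, -1, -1):
            w = params.weights[layer]
            a_prev = fp.activations[layer]
            nb = d.shape[1]
            col_b0 = col - nb
            col_w0 = col_b0 - w.size
            # per-sample dy_k/dW = a_prev ⊗ d ; dy_k/db = d
            J[:, k, col_w0:col_b0] = np.einsum("mi,mj->mij", a_prev, d).reshape(m, -1)
            J[:, k, col_b0:col] = d
            col = col_w0
            if layer > 0:
                a = fp.activations[layer]
                d = (d @ w.T) * a * (1.0 - a)
        assert col == 0
    # e = d − y, so ∂e/∂x = −∂y/∂x
    return e, -J.reshape(m * n_out, W)


def lm_step(jacobian: np.ndarray, residuals: np.ndarray, mu: float) -> np.ndarray:
    """Solve (JᵀJ + µI)Δ = −Jᵀe for the Levenberg–Marquardt update Δ."""
    J = np.asarray(jacobian, dtype=float)
    e = np.asarray(residuals, dtype=float)
    A = J.T @ J
    if mu > 0:
        A = A + mu * np.eye(A.shape[0])
    rhs = -(J.T @ e)
    try:
        return np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:
        raise TrainingError(f"singular LM system at mu={mu!r}") from exc


def train_lm(
    params: MLPParams,
    X: np.ndarray,
    D: np.ndarray,
    config: TrainConfig,
    callback: Callable[[int, MLPParams], None] | None = None,
) -> tuple[MLPParams, list[float], dict]:
    """Levenberg–Marquardt training on the SSE objective.

    A candidate step is accepted only if it strictly lowers E, so the trace of
    accepted losses is strictly decreasing. µ divides by ``mu_factor`` after
    acceptance and multiplies after rejection; if µ exceeds 1e12 without an
    acceptable step the run stops with status ``"mu_overflow"``.

    Returns (params, accepted-loss trace, info) with info carrying ``status``
    and ``n_iterations``.
    """
    if config.objective != "sse_lm":
        raise ValueError("train_lm requires objective='sse_lm'")
    params = params.copy()
    x = params.to_vector()
    loss = sse_loss(params, X, D)
    trace = [loss]
    mu = config.mu0
    status = "max_iters"
    it = 0
    while it < config.max_iters:
        e, J = residuals_and_jacobian(params, X, D)
        grad = J.T @ e
        if loss <= config.tol or float(np.linalg.norm(grad)) < 1e-14:
            status = "converged"
            break
        accepted = False
        while mu <= _MU_MAX:
            try:
                delta = lm_step(J, e, mu)
            except TrainingError:
                # numerically singular at this damping: treat as a rejection
                mu *= config.mu_factor
                continue
            cand = params.from_vector(x + delta)
            cand_loss = sse_loss(cand, X, D)
            if np.isfinite(cand_loss) and cand_loss < loss:
                accepted = True
                break
            mu *= config.mu_factor
        if not accepted:
            status = "mu_overflow"
            break
        params = cand
        x = x + delta
        prev, loss = loss, cand_loss
        trace.append(loss)
        mu = max(mu / config.mu_factor, 1e-12)
        it += 1
        if callback is not None:
            callback(it, params)
        if abs(prev - loss) < config.tol:
            status = "converged"
            break
    return params, trace, {"status": status, "n_iterations": len(trace) - 1}


class NeuralNetModel:
    """Perceptron classifier over a :class:`~mheval.datasets.Dataset`.

    Continuous attributes are standardized and categorical ones one-hot
    encoded before training; the label head width equals the number of
    classes. ``config.objective`` picks the softmax/cross-entropy gradient
    trainer or the sigmoid/SSE Levenberg–Marquardt trainer.
    """

    def __init__(
        self,
        data: Dataset,
        hidden_layer_sizes: Sequence[int] = (12,),
        config: TrainConfig | None = None,
    ):
        if data.n_records == 0:
            raise ValueError("empty training data")
        self.data = data
        self.hidden_layer_sizes = tuple(int(h) for h in hidden_layer_sizes)
        self.config = config or TrainConfig()

    def fit(self) -> "NeuralNetResults":
        cfg = self.config
        val = None
        fit_data = self.data
        if cfg.validation_fraction > 0:
            # hold out ~validation_fraction of the records; the returned model
            # is the iterate with the best validation accuracy (early stopping
            # in the classic LM-backprop style, applied to either trainer)
            n_parts = max(2, round(1.0 / cfg.validation_fraction))
            fit_data, val = split_train_test(
                self.data, n_parts=n_parts, n_train=n_parts - 1, seed=cfg.seed
            )
        enc = DatasetEncoder().fit(fit_data)
        X = enc.transform(fit_data)
        Y = enc.one_hot_labels(fit_data)
        sizes = (X.shape[1],) + self.hidden_layer_sizes + (len(enc.class_names),)
        params = init_network(sizes, seed=cfg.seed)

        callback = None
        best: dict = {}
        if val is not None:
            Xv = enc.transform(val)
            yv = val.label_indices()
            sigmoid_head = cfg.objective == "sse_lm"

            def callback(it, p):  # noqa: ARG001 - callback signature
                fp = forward(p, Xv)
                out = fp.sigmoid_out if sigmoid_head else fp.probs
                acc = float(np.mean(out.argmax(axis=1) == yv))
                if acc > best.get("acc", -1.0):
                    best["acc"] = acc
                    best["params"] = p.copy()

        if cfg.objective == "cross_entropy_gd":
            params, trace = train_gd(params, X, Y, cfg, callback=callback)
            info = {"status": "finished", "n_iterations": len(trace) - 1}
        else:
            params, trace, info = train_lm(params, X, Y, cfg, callback=callback)
        if best.get("params") is not None:
            params = best["params"]
            info["best_validation_accuracy"] = best["acc"]
        return NeuralNetResults(self, params, trace, info, enc)


class NeuralNetResults:
    """Fitted network parameters plus the training trace and diagnostics."""

    def __init__(self, model, params: MLPParams, trace, info, encoder: DatasetEncoder):
        self.model = model
        self.params = params
        self.loss_trace = list(trace)
        self.info = dict(info)
        self.encoder = encoder
        self.class_names = encoder.class_names

    @property
    def n_iterations(self) -> int:
        return int(self.info.get("n_iterations", len(self.loss_trace) - 1))

    def predict_proba(self, data: Dataset) -> np.ndarray:
        X = self.encoder.transform(data)
        fp = forward(self.params, X)
        if self.model.config.objective == "cross_entropy_gd":
            return fp.probs
        # sigmoid outputs trained toward one-hot targets: normalize to a
        # probability vector, uniform if everything saturated to zero
        s = fp.sigmoid_out
        tot = s.sum(axis=1, keepdims=True)
        out = np.where(tot > _EPS, s / np.maximum(tot, _EPS), 1.0 / s.shape[1])
        return out

    def predict(self, data: Dataset) -> np.ndarray:
        probs = self.predict_proba(data)
        idx = probs.argmax(axis=1)
        return np.array([self.class_names[i] for i in idx], dtype=object)

    def summary(self) -> str:
        cfg = self.model.config
        sizes = self.params.layer_sizes
        lines = [
            "Neural Network Results",
            "=" * 42,
            f"objective:        {cfg.objective}",
            f"layer sizes:      {sizes}",
            f"parameters:       {self.params.n_params}",
            f"iterations:       {self.n_iterations}",
            f"status:           {self.info.get('status')}",
            f"initial loss:     {self.loss_trace[0]:.6g}",
            f"final loss:       {self.loss_trace[-1]:.6g}",
        ]
        return "\n".join(lines)

    def save(self, path) -> None:
        import json

        payload = {
            "layer_sizes": list(self.params.layer_sizes),
            "weights": [w.tolist() for w in self.params.weights],
            "biases": [b.tolist() for b in self.params.biases],
            "objective": self.model.config.objective,
            "encoder": self.encoder.state(),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)
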