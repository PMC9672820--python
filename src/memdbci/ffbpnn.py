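"""Feed-forward neural network trained by back-propagation of sensitivities.

This is the multilayer generalization of Widrow-Hoff (LMS) learning,
written exactly in the sensitivity formulation:

forward pass
    ``a^0 = input;  a^{n+1} = f^{n+1}(W^{n+1} a^n + b^{n+1})``

sensitivities (backward pass), with ``x^n`` the pre-activation of layer n
and ``F^n`` the diagonal matrix of transfer-function derivatives at it:
    ``s^L = -2 F^L(x^L) (t - a^L)``
    ``s^n = F^n(x^n) (W^{n+1})^T s^{n+1}``

steepest-descent updates with learning rate alpha:
    ``W^n <- W^n - alpha s^n (a^{n-1})^T``
    ``b^n <- b^n - alpha s^n``

The -2 in the output sensitivity is d(e^2)/da, so the assembled quantity
is the exact gradient of the summed squared error (verified against
finite differences in the tests).

Training is full-batch by default: the per-sample update steps are
accumulated over every sample of an epoch and applied once, which makes
training deterministic for a fixed seed and matches stopping on the epoch
mean-squared error against an error goal. Per-sample ("online") updates
are available behind a flag. No momentum, adaptive rates or
regularization — plain steepest descent.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .exceptions import DivergenceError, InvalidSpecError

__all__ = [
    "TRANSFER_FUNCTIONS",
    "transfer",
    "transfer_deriv",
    "NetParams",
    "TrainConfig",
    "TrainResult",
    "init_params",
    "forward",
    "sensitivities",
    "update",
    "train",
    "classify",
    "one_hot",
]

TRANSFER_FUNCTIONS = ("purelin", "logsig", "tansig")


def transfer(tag: str, v):
    """Apply the named transfer function elementwise."""
    v = np.asarray(v, dtype=float)
    if tag == "purelin":
        return v
    if tag == "logsig":
        return 1.0 / (1.0 + np.exp(-v))
    if tag == "tansig":
        return np.tanh(v)
    raise InvalidSpecError(f"unknown transfer function {tag!r}")


def transfer_deriv(tag: str, v):
    """Analytic derivative of the named transfer function at ``v``."""
    v = np.asarray(v, dtype=float)
    if tag == "purelin":
        return np.ones_like(v)
    if tag == "logsig":
        s = 1.0 / (1.0 + np.exp(-v))
        return s * (1.0 - s)
    if tag == "tansig":
        return 1.0 - np.tanh(v) ** 2
    raise InvalidSpecError(f"unknown transfer function {tag!r}")


@dataclass
class NetParams:
    """Layer sizes, weights (rows = units, cols = inputs), biases and
    transfer-function tags of the network."""

    layer_sizes: list[int]
    W: list[np.ndarray]
    b: list[np.ndarray]
    tf: list[str]

    def __post_init__(self) -> None:
        L = len(self.layer_sizes) - 1
        if not (len(self.W) == len(self.b) == len(self.tf) == L):
            raise InvalidSpecError("W, b, tf must have one entry per layer")
        for k in range(L):
            if self.tf[k] not in TRANSFER_FUNCTIONS:
                raise InvalidSpecError(f"unknown transfer function {self.tf[k]!r}")
            exp = (self.layer_sizes[k + 1], self.layer_sizes[k])
            if self.W[k].shape != exp:
                raise InvalidSpecError(
                    f"layer {k + 1} weight shape {self.W[k].shape}, expected {exp}"
                )
            if self.b[k].shape != (self.layer_sizes[k + 1],):
                raise InvalidSpecError(f"layer {k + 1} bias shape {self.b[k].shape}")

    @property
    def n_layers(self) -> int:
        return len(self.W)


@dataclass
class TrainConfig:
    """Learning rate, MSE error goal, epoch cap, seed and init scale."""

    alpha: float = 1e-3
    error_goal: float = 1e-2
    max_epochs: int = 2000
    seed: int = 0
    init_scale: float = 0.5
    mode: str = "batch"  # "batch" | "online"

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise InvalidSpecError("alpha must be > 0")
        if self.error_goal <= 0:
            raise InvalidSpecError("error_goal must be > 0")
        if self.max_epochs < 1:
            raise InvalidSpecError("max_epochs must be >= 1")


@dataclass
class TrainResult:
    params: NetParams
    mse_history: list[float] = field(default_factory=list)
    stopped_by: str = "max_epochs"  # "goal" | "max_epochs"
    epochs_run: int = 0


def init_params(
    layer_sizes: list[int], tf: list[str] | str, seed: int, init_scale: float = 0.5
) -> NetParams:
    """Seeded uniform(-init_scale, +init_scale) weights and biases."""
    if isinstance(tf, str):
        tf = [tf] * (len(layer_sizes) - 1)
    rng = np.random.default_rng(seed)
    W = [
        rng.uniform(-init_scale, init_scale, size=(layer_sizes[k + 1], layer_sizes[k]))
        for k in range(len(layer_sizes) - 1)
    ]
    b = [
        rng.uniform(-init_scale, init_scale, size=layer_sizes[k + 1])
        for k in range(len(layer_sizes) - 1)
    ]
    return NetParams(layer_sizes=list(layer_sizes), W=W, b=b, tf=list(tf))


def forward(params: NetParams, x) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Propagate ``x`` through the network.

    ``x`` may be a single vector or a ``features x samples`` matrix.
    Returns ``(activations a^0..a^L, pre-activations x^1..x^L)``.
    """
    a = np.asarray(x, dtype=float)
    if a.shape[0] != params.layer_sizes[0]:
        raise InvalidSpecError(
            f"input size {a.shape[0]} != network input {params.layer_sizes[0]}"
        )
    activations = [a]
    preacts = []
    for Wk, bk, tag in zip(params.W, params.b, params.tf):
        bias = bk[:, None] if a.ndim == 2 else bk
        v = Wk @ a + bias
        preacts.append(v)
        a = transfer(tag, v)
        activations.append(a)
    return activations, preacts


def sensitivities(
    params: NetParams,
    activations: list[np.ndarray],
    preacts: list[np.ndarray],
    target,
) -> list[np.ndarray]:
    """Back-propagated sensitivities ``s^1 .. s^L`` for the given target."""
    t = np.asarray(target, dtype=float)
    a_L = activations[-1]
    if t.shape != a_L.shape:
        raise InvalidSpecError(f"target shape {t.shape} != output shape {a_L.shape}")
    L = params.n_layers
    s = [None] * L
    s[L - 1] = -2.0 * transfer_deriv(params.tf[L - 1], preacts[L - 1]) * (t - a_L)
    for k in range(L - 2, -1, -1):
        s[k] = transfer_deriv(params.tf[k], preacts[k]) * (params.W[k + 1].T @ s[k + 1])
    return s


def update(
    params: NetParams,
    sens: list[np.ndarray],
    activations: list[np.ndarray],
    alpha: float,
) -> NetParams:
    """One steepest-descent step; pure (the input params are not modified).

    With matrix-valued sensitivities/activations (columns = samples) the
    outer products sum over samples, i.e. the per-sample steps accumulate.
    """
    new = copy.deepcopy(params)
    for k in range(params.n_layers):
        s_k = np.atleast_2d(sens[k].T).T  # (units, n_samples)
        a_prev = np.atleast_2d(activations[k].T).T
        new.W[k] = params.W[k] - alpha * (s_k @ a_prev.T)
        new.b[k] = params.b[k] - alpha * s_k.sum(axis=1)
    return new


def train(X, T, layer_sizes: list[int] | None = None, cfg: TrainConfig | None = None,
          tf: list[str] | str = "tansig", params: NetParams | None = None) -> TrainResult:
    """Train on samples ``X`` (rows) against targets ``T`` (rows).

    The default architecture is input - 10 hidden - output with tansig
    everywhere. Each epoch the MSE (mean over samples and output units of
    the squared error) is evaluated first; training stops as soon as it
    reaches ``cfg.error_goal``, else the accumulated batch step (or the
    sequence of online steps) is applied, up to ``cfg.max_epochs`` epochs.
    """
    cfg = cfg or TrainConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    T = np.atleast_2d(np.asarray(T, dtype=float))
    if X.shape[0] != T.shape[0] or X.shape[0] < 1:
        raise InvalidSpecError("X and T must have the same (positive) number of rows")
    if params is None:
        if layer_sizes is None:
            layer_sizes = [X.shape[1], 10, T.shape[1]]
        params = init_params(layer_sizes, tf, cfg.seed, cfg.init_scale)

    Xc, Tc = X.T, T.T  # columns = samples
    history: list[float] = []
    stopped_by = "max_epochs"
    epochs = 0
    for _ in range(cfg.max_epochs):
        activations, preacts = forward(params, Xc)
        err = Tc - activations[-1]
        if not np.all(np.isfinite(err)):
            raise DivergenceError(epochs + 1)
        mse = float(np.mean(err**2))
        history.append(mse)
        epochs += 1
        if mse <= cfg.error_goal:
            stopped_by = "goal"
            break
        if cfg.mode == "online":
            for i in range(X.shape[0]):
                acts_i, pre_i = forward(params, X[i])
                s = sensitivities(params, acts_i, pre_i, T[i])
                params = update(params, s, acts_i, cfg.alpha)
        else:
            s = sensitivities(params, activations, preacts, Tc)
            params = update(params, s, activations, cfg.alpha)
    return TrainResult(params=params, mse_history=history, stopped_by=stopped_by, epochs_run=epochs)


def classify(params: NetParams, X) -> np.ndarray:
    """Predicted labels: index of the maximum output unit (ties -> lowest)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    activations, _ = forward(params, X.T)
    return np.argmax(activations[-1], axis=0)


def one_hot(labels, n_classes: int, low: float = -1.0, high: float = 1.0) -> np.ndarray:
    """One-hot target rows in ``{low, high}`` (defaults match tansig range)."""
    labels = np.asarray(labels, dtype=int)
    T = np.full((labels.size, n_classes), low)
    T[np.arange(labels.size), labels] = high
    return T
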