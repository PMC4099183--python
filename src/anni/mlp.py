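"""Three-layer backpropagation perceptron with sigmoid units and momentum.

Each gene model is a fully connected N-H-1 network: N inputs (every gene
except the target), H sigmoid hidden units (2 by default) and a single
sigmoid output predicting the held-out gene. Training is per-sample
("online") gradient descent on half the squared prediction error, with a
momentum term: the weight update at learning cycle ``T`` is

    dw(T) = eta * delta * input_signal + alpha * dw(T-1)

where ``delta`` is the standard backpropagated error term for logistic
units with slope ``a`` (output unit: ``(d - y) * a * y * (1 - y)``).
Training stops at the epoch cap, when the monitored mean squared error
drops below the MSE threshold, or when it has not improved over a
patience window of epochs.

The inner loop is compiled with numba when available; a pure-Python
execution of the identical code is used otherwise. All randomness
(initial weights, per-epoch sample orders) is pre-generated with NumPy,
so results are independent of the execution path and bitwise
reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.special import expit

from .config import AnniConfig

try:  # pragma: no cover - exercised implicitly on import
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

__all__ = [
    "MLPModel",
    "TrainState",
    "sigmoid",
    "forward",
    "sse_error",
    "backprop_step",
    "train_mlp",
    "predict",
]


@dataclass
class MLPModel:
    """Weight set of one N-H-1 network.

    ``w_ih`` has shape ``(n_inputs + 1, n_hidden)``; the last row is the
    hidden-unit bias, implemented as a constant input of 1. ``w_ho`` has
    length ``n_hidden + 1`` with the output bias last.
    """

    w_ih: np.ndarray
    w_ho: np.ndarray
    sigmoid_slope: float = 1.0

    def __post_init__(self) -> None:
        self.w_ih = np.asarray(self.w_ih, dtype=float)
        self.w_ho = np.asarray(self.w_ho, dtype=float)
        if self.w_ih.ndim != 2 or self.w_ho.ndim != 1:
            raise ValueError("w_ih must be 2-D and w_ho 1-D")
        if self.w_ho.shape[0] != self.w_ih.shape[1] + 1:
            raise ValueError("w_ho length must be n_hidden + 1")
        if self.sigmoid_slope <= 0:
            raise ValueError("sigmoid_slope must be positive")

    @property
    def n_inputs(self) -> int:
        return self.w_ih.shape[0] - 1

    @property
    def n_hidden(self) -> int:
        return self.w_ih.shape[1]

    def copy(self) -> "MLPModel":
        return MLPModel(self.w_ih.copy(), self.w_ho.copy(), self.sigmoid_slope)

    @classmethod
    def initialize(
        cls,
        n_inputs: int,
        n_hidden: int,
        rng: np.random.Generator,
        init_range: Tuple[float, float] = (-1.0, 1.0),
        sigmoid_slope: float = 1.0,
    ) -> "MLPModel":
        """Draw every connection weight uniformly from ``init_range``."""
        lo, hi = init_range
        w_ih = rng.uniform(lo, hi, size=(n_inputs + 1, n_hidden))
        w_ho = rng.uniform(lo, hi, size=n_hidden + 1)
        return cls(w_ih, w_ho, sigmoid_slope)

    def dump(self, path) -> None:
        """Plain-text weight dump: a shape header, then one weight per line."""
        with open(path, "w") as fh:
            fh.write(f"# n_inputs={self.n_inputs} n_hidden={self.n_hidden} "
                     f"sigmoid_slope={self.sigmoid_slope!r}\n")
            for w in self.w_ih.ravel():
                fh.write(f"{float(w)!r}\n")
            for w in self.w_ho:
                fh.write(f"{float(w)!r}\n")

    @classmethod
    def load(cls, path) -> "MLPModel":
        with open(path) as fh:
            header = fh.readline().lstrip("#").split()
            meta = dict(kv.split("=") for kv in header)
            weights = np.array([float(line) for line in fh])
        ni, nh = int(meta["n_inputs"]), int(meta["n_hidden"])
        w_ih = weights[: (ni + 1) * nh].reshape(ni + 1, nh)
        w_ho = weights[(ni + 1) * nh:]
        return cls(w_ih, w_ho, float(meta["sigmoid_slope"]))


@dataclass
class TrainState:
    """Mutable companion of a model during training.

    ``prev_ih``/``prev_ho`` hold the previous weight updates dw(T-1)
    feeding the momentum term; both are zero before the first update.
    ``mse_trace`` records the monitored MSE of each completed epoch.
    """

    prev_ih: np.ndarray
    prev_ho: np.ndarray
    epoch: int = 0
    mse_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    @classmethod
    def zeros_like(cls, model: MLPModel) -> "TrainState":
        return cls(np.zeros_like(model.w_ih), np.zeros_like(model.w_ho))

    def copy(self) -> "TrainState":
        return TrainState(
            self.prev_ih.copy(), self.prev_ho.copy(), self.epoch, self.mse_trace.copy()
        )


def sigmoid(v, a: float = 1.0):
    """Logistic activation ``1 / (1 + exp(-a v))`` with slope ``a``.

    Numerically stable for arbitrarily large ``|v|``.
    """
    if a <= 0:
        raise ValueError("sigmoid slope must be positive")
    return expit(a * np.asarray(v, dtype=float)) if np.ndim(v) else float(expit(a * v))


def forward(model: MLPModel, x: Sequence[float]) -> Tuple[np.ndarray, float]:
    """One forward pass; returns (hidden activations, output)."""
    x = np.asarray(x, dtype=float)
    if x.shape != (model.n_inputs,):
        raise ValueError(
            f"expected {model.n_inputs} inputs, got {x.shape}"
        )
    a = model.sigmoid_slope
    hidden = expit(a * (x @ model.w_ih[:-1] + model.w_ih[-1]))
    y = float(expit(a * (hidden @ model.w_ho[:-1] + model.w_ho[-1])))
    return hidden, y


def predict(model: MLPModel, X: np.ndarray) -> np.ndarray:
    """Vectorized forward pass over the rows of ``X``."""
    X = np.asarray(X, dtype=float)
    a = model.sigmoid_slope
    hidden = expit(a * (X @ model.w_ih[:-1] + model.w_ih[-1]))
    return expit(a * (hidden @ model.w_ho[:-1] + model.w_ho[-1]))


def sse_error(y: Sequence[float], d: Sequence[float]) -> float:
    """Half sum-of-squares error ``0.5 * sum((d - y)**2)``.

    The factor 1/2 makes the backpropagated delta take its textbook
    form; the per-epoch stopping rule uses the mean squared error
    ``sum((d - y)**2) / N`` instead.
    """
    y = np.asarray(y, dtype=float)
    d = np.asarray(d, dtype=float)
    if y.size == 0:
        raise ValueError("sse_error requires at least one sample")
    if y.shape != d.shape:
        raise ValueError("y and d must have equal length")
    return float(0.5 * np.sum((d - y) ** 2))


def backprop_step(
    model: MLPModel,
    state: TrainState,
    x: Sequence[float],
    d: float,
    cfg: AnniConfig,
) -> Tuple[MLPModel, TrainState]:
    """One online weight update for a single sample pattern.

    Returns updated copies of the model and state. If the network
    output equals the target exactly, no adjustment is made and the
    previous deltas are left untouched.
    """
    x = np.asarray(x, dtype=float)
    hidden, y = forward(model, x)
    if y == d:
        return model.copy(), state.copy()
    a = model.sigmoid_slope
    eta, alpha = cfg.learning_rate, cfg.momentum

    delta_o = (d - y) * a * y * (1.0 - y)
    delta_h = model.w_ho[:-1] * delta_o * a * hidden * (1.0 - hidden)

    dw_ho = eta * delta_o * np.append(hidden, 1.0) + alpha * state.prev_ho
    dw_ih = eta * np.outer(np.append(x, 1.0), delta_h) + alpha * state.prev_ih

    new_model = MLPModel(model.w_ih + dw_ih, model.w_ho + dw_ho, a)
    new_state = TrainState(dw_ih, dw_ho, state.epoch, state.mse_trace.copy())
    return new_model, new_state


@njit(cache=True)
def _sig(z: float) -> float:
    if z >= 0.0:
        return 1.0 / (1.0 + np.exp(-z))
    e = np.exp(z)
    return e / (1.0 + e)


@njit(cache=True)
def _monitor_mse(X, d, w_ih, w_ho, a) -> float:
    n, ni = X.shape
    nh = w_ih.shape[1]
    total = 0.0
    for s in range(n):
        zsum = w_ho[nh]
        for h in range(nh):
            z = w_ih[ni, h]
            for i in range(ni):
                z += w_ih[i, h] * X[s, i]
            zsum += w_ho[h] * _sig(a * z)
        err = d[s] - _sig(a * zsum)
        total += err * err
    return total / n


@njit(cache=True)
def _train_kernel(
    X, d, Xm, dm, w_ih, w_ho, prev_ih, prev_ho, orders,
    eta, alpha, a, mse_threshold, window, improve_tol, max_epochs,
):
    """Online backpropagation with momentum; weights updated in place.

    Monitored MSE is computed on (Xm, dm) after every epoch; training
    stops at the epoch cap, below the MSE threshold, or after `window`
    epochs without an improvement greater than `improve_tol`.
    """
    n, ni = X.shape
    nh = w_ih.shape[1]
    trace = np.empty(max_epochs)
    hid = np.empty(nh)
    dh = np.empty(nh)
    best = np.inf
    best_epoch = -1
    n_epochs = 0
    for ep in range(max_epochs):
        for si in range(n):
            s = orders[ep, si]
            for h in range(nh):
                z = w_ih[ni, h]
                for i in range(ni):
                    z += w_ih[i, h] * X[s, i]
                hid[h] = _sig(a * z)
            zsum = w_ho[nh]
            for h in range(nh):
                zsum += w_ho[h] * hid[h]
            y = _sig(a * zsum)
            if y == d[s]:
                continue
            delta_o = (d[s] - y) * a * y * (1.0 - y)
            for h in range(nh):
                dh[h] = w_ho[h] * delta_o * a * hid[h] * (1.0 - hid[h])
            for h in range(nh):
                dw = eta * delta_o * hid[h] + alpha * prev_ho[h]
                w_ho[h] += dw
                prev_ho[h] = dw
            dw = eta * delta_o + alpha * prev_ho[nh]
            w_ho[nh] += dw
            prev_ho[nh] = dw
            for h in range(nh):
                for i in range(ni):
                    dw = eta * dh[h] * X[s, i] + alpha * prev_ih[i, h]
                    w_ih[i, h] += dw
                    prev_ih[i, h] = dw
                dw = eta * dh[h] + alpha * prev_ih[ni, h]
                w_ih[ni, h] += dw
                prev_ih[ni, h] = dw
        mse = _monitor_mse(Xm, dm, w_ih, w_ho, a)
        trace[ep] = mse
        n_epochs = ep + 1
        if mse < best - improve_tol:
            best = mse
            best_epoch = ep
        if mse < mse_threshold:
            break
        if ep - best_epoch >= window:
            break
    return n_epochs, trace[:n_epochs]


def train_mlp(
    X: np.ndarray,
    d: np.ndarray,
    cfg: AnniConfig,
    seed,
    monitor: Optional[Tuple[np.ndarray, np.ndarray]] = None,
) -> Tuple[MLPModel, TrainState]:
    """Train one N-H-1 network on scaled data.

    Parameters
    ----------
    X : array, shape (n_samples, n_inputs)
        Scaled input patterns (values in [0, 1]).
    d : array, shape (n_samples,)
        Scaled target outputs.
    cfg : AnniConfig
        Training hyperparameters.
    seed : int or numpy.random.Generator
        Source for weight initialization and per-epoch sample orders.
    monitor : (X_mon, d_mon), optional
        Held-out patterns whose MSE drives the stopping rules. Defaults
        to the training patterns themselves.

    Returns
    -------
    (MLPModel, TrainState)
        The trained weights and the training state with the full
        per-epoch MSE trace.
    """
    X = np.ascontiguousarray(X, dtype=float)
    d = np.ascontiguousarray(d, dtype=float)
    if X.ndim != 2 or d.shape != (X.shape[0],):
        raise ValueError("X must be 2-D with one target per row")
    if X.shape[0] < 2:
        raise ValueError("training requires at least 2 samples")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    model = MLPModel.initialize(
        X.shape[1], cfg.n_hidden, rng, cfg.weight_init_range, cfg.sigmoid_slope
    )
    orders = rng.permuted(
        np.tile(np.arange(X.shape[0]), (cfg.epochs, 1)), axis=1
    ).astype(np.int64)
    if monitor is None:
        Xm, dm = X, d
    else:
        Xm = np.ascontiguousarray(monitor[0], dtype=float)
        dm = np.ascontiguousarray(monitor[1], dtype=float)

    state = TrainState.zeros_like(model)
    n_epochs, trace = _train_kernel(
        X, d, Xm, dm, model.w_ih, model.w_ho, state.prev_ih, state.prev_ho,
        orders, cfg.learning_rate, cfg.momentum, cfg.sigmoid_slope,
        cfg.mse_threshold, cfg.mse_window, cfg.mse_improve_tol, cfg.epochs,
    )
    state.epoch = int(n_epochs)
    state.mse_trace = np.asarray(trace, dtype=float)
    return model, state
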