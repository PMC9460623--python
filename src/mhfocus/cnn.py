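"""Two-stage convolutional excitation regressor.

The optimizer is a pair of small CNNs sharing one architecture: three 3x3
convolution layers (16, 64, 128 filters, ReLU, 'same' padding), each
followed by 2x2 max pooling, then batch normalization, flatten, and three
dense layers. The first network (phase stage) regresses the sin/cos pairs
of the scheme's free phases from a normalized heating-potential map; the
second (voltage stage) regresses per-channel voltages, rescaled to [0, 1],
from maps generated at the phase stage's fixed solution. Both are trained
with the Adam optimizer on a mean-absolute-error loss. At planning time a
binary masked-target map is fed to both networks, and the voltage
prediction is rescaled so the total input power is 6 W.

The networks are implemented directly on NumPy (forward and backward passes
as batched matrix products), wrapped in a scikit-learn style estimator so
they compose with sklearn tooling.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .dataset import VOLTAGE_LEVELS, TrainingSet, decode_phases
from .errors import DegenerateExcitationError
from .excitation import Excitation, expand_free_phases, scale_to_total_power

__all__ = [
    "CNNSpec",
    "CNNRegressor",
    "build_model",
    "train",
    "predict_phases",
    "predict_voltages",
    "save_model",
    "load_model",
]

_DTYPE = np.float32


@dataclass(frozen=True)
class CNNSpec:
    """Architecture and training hyperparameters shared by both stages."""

    conv_filters: Tuple[int, ...] = (16, 64, 128)
    kernel_size: int = 3
    pool_size: int = 2
    dense_units: Tuple[int, ...] = (256, 64)
    output_dim: int = 4
    learning_rate: float = 1e-4
    batch_size: int = 100
    epochs: int = 100
    patience: int = 10


# ---------------------------------------------------------------------------
# Layers (NHWC, float32)
# ---------------------------------------------------------------------------


class _Conv2DReLU:
    """3x3 'same' convolution + bias + ReLU, as 9 shifted matrix products."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (k * k * c_in + k * k * c_out))
        self.w = rng.uniform(-limit, limit, size=(k, k, c_in, c_out)).astype(_DTYPE)
        self.b = np.zeros(c_out, dtype=_DTYPE)
        self.k = k
        self._cache = None

    def weights(self) -> List[np.ndarray]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        k, p = self.k, self.k // 2
        b_, h, w_, c_in = x.shape
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        y = np.broadcast_to(self.b, (b_, h, w_, self.b.shape[0])).copy()
        flat_y = y.reshape(-1, self.b.shape[0])
        for di in range(k):
            for dj in range(k):
                patch = xp[:, di : di + h, dj : dj + w_, :].reshape(-1, c_in)
                flat_y += patch @ self.w[di, dj]
        mask = y > 0
        if training:
            self._cache = (xp, mask, x.shape)
        return np.where(mask, y, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp, mask, x_shape = self._cache
        self._cache = None
        k, p = self.k, self.k // 2
        b_, h, w_, c_in = x_shape
        c_out = self.b.shape[0]
        dy = np.where(mask, dy, 0.0)
        dy_flat = dy.reshape(-1, c_out)
        self.db = dy_flat.sum(axis=0)
        self.dw = np.empty_like(self.w)
        dxp = np.zeros_like(xp)
        for di in range(k):
            for dj in range(k):
                patch = xp[:, di : di + h, dj : dj + w_, :].reshape(-1, c_in)
                self.dw[di, dj] = patch.T @ dy_flat
                dxp[:, di : di + h, dj : dj + w_, :] += (dy_flat @ self.w[di, dj].T).reshape(
                    b_, h, w_, c_in
                )
        return dxp[:, p : p + h, p : p + w_, :]

    def grads(self) -> List[np.ndarray]:
        return [self.dw, self.db]


class _MaxPool2:
    """2x2 max pooling with floor division (trailing odd row/col dropped)."""

    def weights(self):
        return []

    def grads(self):
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        b_, h, w_, c = x.shape
        h2, w2 = h // 2, w_ // 2
        xr = x[:, : 2 * h2, : 2 * w2, :].reshape(b_, h2, 2, w2, 2, c)
        y = xr.max(axis=(2, 4))
        if training:
            self._cache = (xr, y, x.shape)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xr, y, x_shape = self._cache
        self._cache = None
        b_, h, w_, c = x_shape
        h2, w2 = h // 2, w_ // 2
        mask = xr == y[:, :, None, :, None, :]
        counts = mask.sum(axis=(2, 4), keepdims=True)
        dxr = mask * (dy[:, :, None, :, None, :] / counts)
        dx = np.zeros(x_shape, dtype=dy.dtype)
        dx[:, : 2 * h2, : 2 * w2, :] = dxr.reshape(b_, 2 * h2, 2 * w2, c)
        return dx


class _BatchNorm:
    """Per-channel batch normalization over (batch, height, width)."""

    # Momentum 0.9 lets the running statistics track the batch statistics
    # within tens of updates; training runs here are a few hundred updates.
    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-3):
        self.gamma = np.ones(c, dtype=_DTYPE)
        self.beta = np.zeros(c, dtype=_DTYPE)
        self.running_mean = np.zeros(c, dtype=_DTYPE)
        self.running_var = np.ones(c, dtype=_DTYPE)
        self.momentum = momentum
        self.eps = eps

    def weights(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(_DTYPE)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(_DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean) / std
        if training:
            self._cache = (xhat, std, axes)
        return self.gamma * xhat + self.beta

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, std, axes = self._cache
        self._cache = None
        self.dgamma = (dy * xhat).sum(axis=axes)
        self.dbeta = dy.sum(axis=axes)
        dxhat = dy * self.gamma
        dx = (
            dxhat
            - dxhat.mean(axis=axes)
            - xhat * (dxhat * xhat).mean(axis=axes)
        ) / std
        return dx.astype(dy.dtype, copy=False)


class _Flatten:
    def weights(self):
        return []

    def grads(self):
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class _Dense:
    def __init__(self, n_in: int, n_out: int, relu: bool, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.w = rng.uniform(-limit, limit, size=(n_in, n_out)).astype(_DTYPE)
        self.b = np.zeros(n_out, dtype=_DTYPE)
        self.relu = relu

    def weights(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        y = x @ self.w + self.b
        mask = (y > 0) if self.relu else None
        if training:
            self._cache = (x, mask)
        if self.relu:
            y = np.where(mask, y, 0.0)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, mask = self._cache
        self._cache = None
        if self.relu:
            dy = np.where(mask, dy, 0.0)
        self.dw = x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.w.T


class _Adam:
    def __init__(self, params: List[np.ndarray], lr: float, beta1=0.9, beta2=0.999, eps=1e-7):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: List[np.ndarray], grads: List[np.ndarray]) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.beta2**self.t) / (1 - self.beta1**self.t)
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m += (1 - self.beta1) * (g - m)
            v += (1 - self.beta2) * (g * g - v)
            p -= lr_t * m / (np.sqrt(v) + self.eps)


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------


class CNNRegressor(BaseEstimator, RegressorMixin):
    """Convolutional regressor mapping 2D maps to label vectors.

    Parameters mirror :class:`CNNSpec`; ``output_dim`` is inferred from the
    training labels when None. Fitted attributes carry a trailing
    underscore: ``layers_``, ``history_`` (per-epoch train/validation MAE),
    ``n_epochs_``, ``input_shape_``, ``n_parameters_``.
    """

    def __init__(
        self,
        conv_filters: Tuple[int, ...] = (16, 64, 128),
        kernel_size: int = 3,
        dense_units: Tuple[int, ...] = (256, 64),
        output_dim: Optional[int] = None,
        learning_rate: float = 1e-4,
        batch_size: int = 100,
        epochs: int = 100,
        patience: int = 10,
        random_state: Optional[int] = None,
        verbose: int = 0,
    ):
        self.conv_filters = conv_filters
        self.kernel_size = kernel_size
        self.dense_units = dense_units
        self.output_dim = output_dim
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.patience = patience
        self.random_state = random_state
        self.verbose = verbose

    # -- construction -------------------------------------------------------

    def build(self, input_shape: Tuple[int, int], output_dim: Optional[int] = None) -> "CNNRegressor":
        """Initialize layers for a given (n_rows, n_cols) input grid."""
        h, w = input_shape
        n_pools = len(self.conv_filters)
        if h < 2**n_pools or w < 2**n_pools:
            raise ValueError(
                f"grid {input_shape} too small for {n_pools} 2x pooling stages"
            )
        out_dim = output_dim or self.output_dim
        if out_dim is None:
            raise ValueError("output_dim must be set before building")
        rng = np.random.default_rng(self.random_state)
        layers: List = []
        c_in = 1
        hh, ww = h, w
        for c_out in self.conv_filters:
            layers.append(_Conv2DReLU(c_in, c_out, self.kernel_size, rng))
            layers.append(_MaxPool2())
            hh, ww, c_in = hh // 2, ww // 2, c_out
        layers.append(_BatchNorm(c_in))
        layers.append(_Flatten())
        n_in = hh * ww * c_in
        for n_out in self.dense_units:
            layers.append(_Dense(n_in, n_out, relu=True, rng=rng))
            n_in = n_out
        layers.append(_Dense(n_in, out_dim, relu=False, rng=rng))
        self.layers_ = layers
        self.input_shape_ = (h, w)
        self.output_dim_ = out_dim
        self.n_parameters_ = int(
            sum(p.size for layer in layers for p in layer.weights())
        )
        self.history_ = {"train_loss": [], "val_loss": []}
        return self

    # -- internal passes ----------------------------------------------------

    def _forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        out = x
        for layer in self.layers_:
            out = layer.forward(out, training)
        return out

    def _backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers_):
            grad = layer.backward(grad)

    def _as_batch(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=_DTYPE)
        if X.ndim != 3 or X.shape[1:] != self.input_shape_:
            raise ValueError(
                f"expected maps shaped (n, {self.input_shape_[0]}, {self.input_shape_[1]})"
            )
        return X[..., None]  # NHWC with one channel

    def _eval_loss(self, X: np.ndarray, y: np.ndarray) -> float:
        pred = self.predict(X)
        return float(np.mean(np.abs(pred - y)))

    # -- sklearn API --------------------------------------------------------

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        validation_data: Optional[Tuple[np.ndarray, np.ndarray]] = None,
    ) -> "CNNRegressor":
        """Train with Adam on mean absolute error.

        ``validation_data`` drives per-epoch validation loss and early
        stopping (best weights restored after ``patience`` stagnant epochs).
        """
        X = np.asarray(X, dtype=_DTYPE)
        y = np.asarray(y, dtype=_DTYPE)
        if X.ndim != 3:
            raise ValueError("X must be (n_samples, n_rows, n_cols)")
        if y.ndim != 2 or y.shape[0] != X.shape[0]:
            raise ValueError("y must be (n_samples, output_dim)")
        if not hasattr(self, "layers_") or self.input_shape_ != X.shape[1:]:
            self.build(X.shape[1:], output_dim=y.shape[1])
        rng = np.random.default_rng(
            None if self.random_state is None else self.random_state + 1
        )
        params = [p for layer in self.layers_ for p in layer.weights()]
        opt = _Adam(params, self.learning_rate)
        n = X.shape[0]
        best_val = np.inf
        best_state = None
        stagnant = 0
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb = X[idx][..., None]
                yb = y[idx]
                pred = self._forward(xb, training=True)
                resid = pred - yb
                epoch_loss += float(np.abs(resid).sum())
                grad = np.sign(resid, dtype=_DTYPE) / resid.size
                self._backward(grad)
                grads = [g for layer in self.layers_ for g in layer.grads()]
                opt.step(params, grads)
            train_loss = epoch_loss / (n * y.shape[1])
            self.history_["train_loss"].append(train_loss)
            if not np.isfinite(train_loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: history={self.history_}"
                )
            if validation_data is not None:
                val_loss = self._eval_loss(*validation_data)
                self.history_["val_loss"].append(val_loss)
                if self.verbose:
                    print(f"epoch {epoch + 1}: train {train_loss:.4f} val {val_loss:.4f}")
                if val_loss < best_val - 1e-6:
                    best_val = val_loss
                    best_state = copy.deepcopy(self.layers_)
                    stagnant = 0
                else:
                    stagnant += 1
                    if stagnant >= self.patience:
                        break
            elif self.verbose:
                print(f"epoch {epoch + 1}: train {train_loss:.4f}")
        if best_state is not None:
            self.layers_ = best_state
        self.n_epochs_ = len(self.history_["train_loss"])
        return self

    def fit_training_set(self, ts: TrainingSet) -> "CNNRegressor":
        """Fit on a TrainingSet's 80-20 split."""
        return self.fit(
            ts.inputs[ts.train_idx],
            ts.labels[ts.train_idx],
            validation_data=(ts.inputs[ts.val_idx], ts.labels[ts.val_idx]),
        )

    def predict(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        xb = self._as_batch(X)
        out = [
            self._forward(xb[i : i + batch_size], training=False)
            for i in range(0, xb.shape[0], batch_size)
        ]
        return np.concatenate(out, axis=0).astype(float)


# ---------------------------------------------------------------------------
# Functional surface
# ---------------------------------------------------------------------------


def build_model(spec: CNNSpec, input_shape: Tuple[int, int], seed: Optional[int] = None) -> CNNRegressor:
    """Instantiate and initialize a regressor from an architecture spec."""
    model = CNNRegressor(
        conv_filters=spec.conv_filters,
        kernel_size=spec.kernel_size,
        dense_units=spec.dense_units,
        output_dim=spec.output_dim,
        learning_rate=spec.learning_rate,
        batch_size=spec.batch_size,
        epochs=spec.epochs,
        patience=spec.patience,
        random_state=seed,
    )
    return model.build(input_shape)


def train(model: CNNRegressor, ts: TrainingSet) -> CNNRegressor:
    """Train a built model on a TrainingSet's 80-20 split."""
    return model.fit_training_set(ts)


def predict_phases(model: CNNRegressor, mask: np.ndarray, scheme: str) -> np.ndarray:
    """Full phase vector (degrees) for a masked-target input.

    The model's sin/cos outputs are decoded per free phase (off-circle
    pairs are projected radially by atan2) and expanded through the
    scheme's constraint, so the result satisfies it by construction.
    """
    out = model.predict(np.asarray(mask, dtype=_DTYPE)[None])[0]
    free = decode_phases(out)
    return expand_free_phases(scheme, free)


def save_model(model: CNNRegressor, path) -> None:
    """Checkpoint a built/trained model as a single .npz file.

    Stores every layer weight plus batch-norm running statistics and the
    constructor parameters needed to rebuild the architecture.
    """
    import json

    arrays = {}
    for li, layer in enumerate(model.layers_):
        for pi, p in enumerate(layer.weights()):
            arrays[f"w_{li}_{pi}"] = p
        if isinstance(layer, _BatchNorm):
            arrays[f"rm_{li}"] = layer.running_mean
            arrays[f"rv_{li}"] = layer.running_var
    meta = {
        "params": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in model.get_params().items()},
        "input_shape": list(model.input_shape_),
        "output_dim": model.output_dim_,
        "history": model.history_,
    }
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_model(path) -> CNNRegressor:
    """Rebuild a model from a checkpoint written by :func:`save_model`."""
    import json

    with np.load(path) as data:
        meta = json.loads(bytes(data["meta_json"]).decode())
        params = meta["params"]
        for key in ("conv_filters", "dense_units"):
            params[key] = tuple(params[key])
        model = CNNRegressor(**params)
        model.build(tuple(meta["input_shape"]), output_dim=meta["output_dim"])
        for li, layer in enumerate(model.layers_):
            for pi, p in enumerate(layer.weights()):
                p[...] = data[f"w_{li}_{pi}"]
            if isinstance(layer, _BatchNorm):
                layer.running_mean = data[f"rm_{li}"]
                layer.running_var = data[f"rv_{li}"]
        model.history_ = meta["history"]
    return model


def predict_voltages(
    model: CNNRegressor,
    mask: np.ndarray,
    scheme: str,
    fixed_phases: np.ndarray,
    total_w: float = 6.0,
) -> Excitation:
    """6 W-scaled excitation from the voltage stage's masked-target output.

    Raw outputs are clipped to [0, 1], rescaled by the 9 V label scale, and
    the voltages are renormalized to the total input power.
    """
    raw = model.predict(np.asarray(mask, dtype=_DTYPE)[None])[0]
    volts = np.clip(raw, 0.0, 1.0) * (VOLTAGE_LEVELS - 1)
    if not volts.any():
        raise DegenerateExcitationError("voltage stage predicted an all-zero drive")
    exc = Excitation(scheme=scheme, voltages=volts, phases=fixed_phases)
    return scale_to_total_power(exc, total_w)
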