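"""Recurrent-network VO2 regressor.

The network maps a window of 70 breaths × 4 normalized channels (power,
cadence, heart rate, respiratory frequency) to the normalized VO2 of the
next breath.  Architecture: three LSTM layers of 32 units (the first two
returning full sequences), a 10-unit leaky-ReLU hidden layer, and a single
linear output — 21717 trainable parameters in total, counted per layer by
``4·(d_in + d_units + 1)·d_units`` for an LSTM and ``d_in·d_units +
d_units`` for a dense layer.

The whole network — forward pass, backpropagation through time, and the
Adagrad optimizer — is implemented here on numpy arrays, with the
recurrent time-stepping compiled by numba.  Training
follows the study recipe: samples shuffled every epoch, batch size 10,
20 epochs, weights drawn from seeded uniform initializers with biases
initialized to small random *positive* values.  Everything is driven by a
single seed, so training is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .preprocess import WindowedDataset

__all__ = [
    "NetworkSpec",
    "TrainingReport",
    "LSTMRegressor",
    "count_parameters",
    "train",
    "predict",
]


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture and training recipe of the regressor."""

    n_past: int = 70
    n_channels: int = 4
    lstm_units: tuple[int, ...] = (32, 32, 32)
    dense_hidden: int = 10
    n_outputs: int = 1
    batch_size: int = 10
    epochs: int = 20
    learning_rate: float = 0.05
    loss: str = "mse"  # "mse" | "bce"
    grad_clip: float = 1.0

    def __post_init__(self) -> None:
        if min(self.lstm_units) < 1 or self.dense_hidden < 1 or self.n_outputs < 1:
            raise ValueError("layer sizes must be positive")
        if self.loss not in ("mse", "bce"):
            raise ValueError("loss must be 'mse' or 'bce'")


@dataclass
class TrainingReport:
    epoch_losses: list[float]
    seed: int | None
    spec: NetworkSpec


def count_parameters(spec: NetworkSpec = NetworkSpec()) -> dict[str, int]:
    """Per-layer trainable-parameter counts and their total.

    An LSTM layer holds four gate blocks, each with input weights, recurrent
    weights and a bias: ``4·(d_in + d_units + 1)·d_units``.  A dense layer
    holds ``d_in·d_units + d_units``.
    """
    counts: dict[str, int] = {}
    d_in = spec.n_channels
    for i, units in enumerate(spec.lstm_units, start=1):
        counts[f"lstm_{i}"] = 4 * (d_in + units + 1) * units
        d_in = units
    counts["dense_1"] = d_in * spec.dense_hidden + spec.dense_hidden
    counts["dense_2"] = spec.dense_hidden * spec.n_outputs + spec.n_outputs
    counts["total"] = sum(counts.values())
    return counts


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


# The recurrent time-stepping is the hot loop of training (tens of
# thousands of 70-step windows); the per-step gate arithmetic is compiled
# with numba, with arrays laid out time-major so every per-step slice is
# contiguous.  Results are deterministic for a fixed seed.

@njit(cache=False)
def _lstm_fwd_kernel(pre, U):  # pre: (T, B, 4H) = x·W + b
    T, B, H4 = pre.shape
    H = H4 // 4
    h = np.zeros((T, B, H))
    c = np.zeros((T, B, H))
    gates = np.empty((T, B, H4))
    tanh_c = np.empty((T, B, H))
    h_prev = np.zeros((B, H))
    for t in range(T):
        z = pre[t] + h_prev @ U
        for bi in range(B):
            for j in range(H):
                zi = min(max(z[bi, j], -60.0), 60.0)
                zf = min(max(z[bi, H + j], -60.0), 60.0)
                zo = min(max(z[bi, 3 * H + j], -60.0), 60.0)
                gi = 1.0 / (1.0 + np.exp(-zi))
                gf = 1.0 / (1.0 + np.exp(-zf))
                gg = np.tanh(z[bi, 2 * H + j])
                go = 1.0 / (1.0 + np.exp(-zo))
                c_prev = c[t - 1, bi, j] if t > 0 else 0.0
                cc = gf * c_prev + gi * gg
                tc = np.tanh(cc)
                gates[t, bi, j] = gi
                gates[t, bi, H + j] = gf
                gates[t, bi, 2 * H + j] = gg
                gates[t, bi, 3 * H + j] = go
                c[t, bi, j] = cc
                tanh_c[t, bi, j] = tc
                h[t, bi, j] = go * tc
        h_prev = h[t]
    return h, c, gates, tanh_c


@njit(cache=False)
def _lstm_bwd_kernel(dh_seq, gates, c, tanh_c, U_T):
    # dh_seq: (T, B, H) upstream gradient on every hidden state
    T, B, H = dh_seq.shape
    dZ = np.empty((T, B, 4 * H))
    dh_next = np.zeros((B, H))
    dc_next = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        for bi in range(B):
            for j in range(H):
                gi = gates[t, bi, j]
                gf = gates[t, bi, H + j]
                gg = gates[t, bi, 2 * H + j]
                go = gates[t, bi, 3 * H + j]
                c_prev = c[t - 1, bi, j] if t > 0 else 0.0
                dh = dh_seq[t, bi, j] + dh_next[bi, j]
                tc = tanh_c[t, bi, j]
                dc = dc_next[bi, j] + dh * go * (1.0 - tc * tc)
                dZ[t, bi, j] = dc * gg * gi * (1.0 - gi)
                dZ[t, bi, H + j] = dc * c_prev * gf * (1.0 - gf)
                dZ[t, bi, 2 * H + j] = dc * gi * (1.0 - gg * gg)
                dZ[t, bi, 3 * H + j] = dh * tc * go * (1.0 - go)
                dc_next[bi, j] = dc * gf
        dh_next = dZ[t] @ U_T
    return dZ


class _LSTMLayer:
    """One LSTM layer with gate order (i, f, g, o) in the fused weight blocks."""

    def __init__(self, d_in: int, units: int, rng: np.random.Generator):
        self.d_in = d_in
        self.units = units
        lim_w = np.sqrt(6.0 / (d_in + units))
        lim_u = np.sqrt(6.0 / (2 * units))
        self.W = rng.uniform(-lim_w, lim_w, (d_in, 4 * units))
        self.U = rng.uniform(-lim_u, lim_u, (units, 4 * units))
        self.b = rng.uniform(0.0, 0.05, 4 * units)  # random positive biases

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W, self.U, self.b]

    def forward(self, x: np.ndarray):
        """x: (B, T, d_in) → h: (B, T, units) plus a cache for backward."""
        B, T, _ = x.shape
        pre = np.ascontiguousarray((x @ self.W + self.b).transpose(1, 0, 2))
        h, c, gates, tanh_c = _lstm_fwd_kernel(pre, self.U)
        cache = (x, h, c, gates, tanh_c)
        return np.ascontiguousarray(h.transpose(1, 0, 2)), cache

    def backward(self, dh_seq: np.ndarray, cache):
        """dh_seq: (B, T, units) upstream gradient on every hidden state."""
        x, h, c, gates, tanh_c = cache
        B, T, _ = x.shape
        H = self.units
        dh_t = np.ascontiguousarray(dh_seq.transpose(1, 0, 2))
        dZ = _lstm_bwd_kernel(dh_t, gates, c, tanh_c,
                              np.ascontiguousarray(self.U.T))
        dZ2 = dZ.transpose(1, 0, 2).reshape(B * T, 4 * H)
        # recurrent-weight gradient in one matmul: dU = sum_t h_{t-1}^T dz_t
        h_shift = np.concatenate((np.zeros((1, B, H)), h[:-1]), axis=0)
        dU = h_shift.transpose(1, 0, 2).reshape(B * T, H).T @ dZ2
        dW = x.reshape(B * T, self.d_in).T @ dZ2
        db = dZ2.sum(axis=0)
        dx = (dZ2 @ self.W.T).reshape(B, T, self.d_in)
        return dx, [dW, dU, db]


class _DenseLayer:
    def __init__(self, d_in: int, units: int, rng: np.random.Generator,
                 activation: str):
        lim = np.sqrt(6.0 / (d_in + units))
        self.W = rng.uniform(-lim, lim, (d_in, units))
        self.b = rng.uniform(0.0, 0.05, units)
        self.activation = activation

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray):
        z = x @ self.W + self.b
        if self.activation == "lrelu":
            a = np.where(z > 0, z, 0.01 * z)
        elif self.activation == "sigmoid":
            a = _sigmoid(z)
        else:
            a = z
        return a, (x, z, a)

    def backward(self, da: np.ndarray, cache):
        x, z, a = cache
        if self.activation == "lrelu":
            dz = da * np.where(z > 0, 1.0, 0.01)
        elif self.activation == "sigmoid":
            dz = da * a * (1.0 - a)
        else:
            dz = da
        dW = x.T @ dz
        db = dz.sum(axis=0)
        dx = dz @ self.W.T
        return dx, [dW, db]


class LSTMRegressor:
    """Stacked-LSTM regressor; batch size is a free dimension at inference."""

    def __init__(self, spec: NetworkSpec, seed: int | None = None):
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.lstm_layers: list[_LSTMLayer] = []
        d_in = spec.n_channels
        for units in spec.lstm_units:
            self.lstm_layers.append(_LSTMLayer(d_in, units, rng))
            d_in = units
        out_act = "sigmoid" if spec.loss == "bce" else "linear"
        # leaky rather than hard rectification: a 10-unit hidden layer can
        # otherwise die outright on unlucky seeds and freeze the output
        self.dense_hidden = _DenseLayer(d_in, spec.dense_hidden, rng, "lrelu")
        self.dense_out = _DenseLayer(spec.dense_hidden, spec.n_outputs, rng,
                                     out_act)

    @property
    def layers(self):
        return [*self.lstm_layers, self.dense_hidden, self.dense_out]

    @property
    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters)

    def _forward(self, X: np.ndarray):
        caches = []
        h = X
        for layer in self.lstm_layers:
            h, cache = layer.forward(h)
            caches.append(cache)
        last = h[:, -1]  # final LSTM layer contributes its last hidden state
        a1, c1 = self.dense_hidden.forward(last)
        out, c2 = self.dense_out.forward(a1)
        return out[:, 0], (caches, c1, c2, h.shape)

    def _backward(self, dout: np.ndarray, cache):
        caches, c1, c2, h_shape = cache
        da1, g_out = self.dense_out.backward(dout[:, None], c2)
        dlast, g_hidden = self.dense_hidden.backward(da1, c1)
        dh_seq = np.zeros(h_shape)
        dh_seq[:, -1] = dlast
        lstm_grads = []
        for layer, lcache in zip(reversed(self.lstm_layers), reversed(caches)):
            dh_seq, grads = layer.backward(dh_seq, lcache)
            lstm_grads.append(grads)
        grads: list[np.ndarray] = []
        for g in reversed(lstm_grads):
            grads.extend(g)
        grads.extend(g_hidden)
        grads.extend(g_out)
        return grads

    def predict(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[1] != self.spec.n_past \
                or X.shape[2] != self.spec.n_channels:
            raise ValueError(
                f"X must be (n, {self.spec.n_past}, {self.spec.n_channels})")
        outs = [self._forward(X[i:i + batch_size])[0]
                for i in range(0, X.shape[0], batch_size)]
        return np.concatenate(outs) if outs else np.empty(0)


def _loss_and_grad(pred: np.ndarray, y: np.ndarray, kind: str):
    n = y.size
    if kind == "mse":
        diff = pred - y
        return float(np.mean(diff ** 2)), 2.0 * diff / n
    # bce on [0,1] targets; predictions already squashed by the sigmoid output
    yc = np.clip(y, 0.0, 1.0)
    pc = np.clip(pred, 1e-7, 1.0 - 1e-7)
    loss = float(-np.mean(yc * np.log(pc) + (1 - yc) * np.log(1 - pc)))
    return loss, (pc - yc) / (pc * (1 - pc)) / n


def train(spec: NetworkSpec, dataset: WindowedDataset,
          seed: int | None = None) -> tuple[LSTMRegressor, TrainingReport]:
    """Train a fresh regressor on a windowed dataset.

    Adagrad with per-parameter accumulated squared gradients; the global
    gradient norm is clipped to ``spec.grad_clip`` before each update to
    survive the abrupt all-out sprint segments.  Raises if the dataset is
    empty or the loss goes non-finite.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    if dataset.X.shape[1] != spec.n_past or dataset.X.shape[2] != spec.n_channels:
        raise ValueError("dataset window shape does not match the spec")
    rng = np.random.default_rng(seed)
    model = LSTMRegressor(spec, seed=int(rng.integers(2 ** 31)))
    params = model.parameters
    accum = [np.zeros_like(p) for p in params]
    eps = 1e-8
    n = len(dataset)
    epoch_losses: list[float] = []
    for _ in range(spec.epochs):
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, spec.batch_size):
            idx = order[start:start + spec.batch_size]
            pred, cache = model._forward(dataset.X[idx])
            loss, dout = _loss_and_grad(pred, dataset.y[idx], spec.loss)
            total += loss * idx.size
            grads = model._backward(dout, cache)
            gnorm = np.sqrt(sum(float((g * g).sum()) for g in grads))
            if spec.grad_clip and gnorm > spec.grad_clip:
                grads = [g * (spec.grad_clip / gnorm) for g in grads]
            for p, g, a in zip(params, grads, accum):
                a += g * g
                p -= spec.learning_rate * g / (np.sqrt(a) + eps)
        epoch_loss = total / n
        if not np.isfinite(epoch_loss):
            raise FloatingPointError(
                f"non-finite training loss at epoch {len(epoch_losses) + 1}")
        epoch_losses.append(epoch_loss)
    return model, TrainingReport(epoch_losses=epoch_losses, seed=seed, spec=spec)


def predict(model: LSTMRegressor, X: np.ndarray) -> np.ndarray:
    """One normalized VO2 prediction per window."""
    return model.predict(X)
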