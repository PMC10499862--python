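"""Minimal NumPy neural-network core for per-residue sequence regression.

Implements exactly what the regressor needs and nothing more: fully
connected stacks, a multi-layer bidirectional LSTM with backpropagation
through time, a masked per-protein mean-squared-error loss, and Adam.
Everything is float64 and deterministic for a fixed seed, which keeps
gradient checks tight and training runs bit-reproducible on one machine.

Sequences are batch-major ``(B, T, D)`` with per-sequence lengths; padding
always sits at the end of a row.  The reverse LSTM direction is realized by
reversing each sequence *within its own length* (padding stays in place),
so a sequence's prediction never depends on how much padding its batch
happened to carry.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Dense", "LSTMLayer", "BiLSTM", "Adam", "masked_mse", "reverse_within_length"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


_ACTIVATIONS = {
    "relu": (lambda a: np.maximum(a, 0.0), lambda a: (a > 0).astype(float)),
    "tanh": (np.tanh, lambda a: 1.0 - np.tanh(a) ** 2),
    "identity": (lambda a: a, lambda a: np.ones_like(a)),
}


def _uniform_init(rng: np.random.Generator, fan_in: int, shape: tuple[int, ...]) -> np.ndarray:
    k = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-k, k, size=shape)


class Dense:
    """One affine layer with an elementwise activation."""

    def __init__(self, d_in: int, d_out: int, activation: str, rng: np.random.Generator):
        if activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {activation!r}")
        self.W = _uniform_init(rng, d_in, (d_in, d_out))
        self.b = _uniform_init(rng, d_in, (d_out,))
        self.activation = activation
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (..., d_in) -> (..., d_out)."""
        act, _ = _ACTIVATIONS[self.activation]
        a = x @ self.W + self.b
        self._cache = (x, a)
        return act(a)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, a = self._cache
        _, dact = _ACTIVATIONS[self.activation]
        da = dy * dact(a)
        x2 = x.reshape(-1, x.shape[-1])
        da2 = da.reshape(-1, da.shape[-1])
        self.dW = x2.T @ da2
        self.db = da2.sum(axis=0)
        return da @ self.W.T

    def params(self) -> dict[str, np.ndarray]:
        return {"W": self.W, "b": self.b}

    def grads(self) -> dict[str, np.ndarray]:
        return {"W": self.dW, "b": self.db}


class LSTMLayer:
    """One unidirectional LSTM layer over batch-major padded sequences.

    Gate order in the stacked weight matrices is (input, forget, cell,
    output).  States start at zero; padded timesteps are processed but
    contribute nothing to the loss and their upstream gradient is zero, and
    because padding sits at the sequence tail their states never reach a
    real position.
    """

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator):
        self.hidden = hidden
        self.W = _uniform_init(rng, hidden, (d_in, 4 * hidden))
        self.U = _uniform_init(rng, hidden, (hidden, 4 * hidden))
        self.b = _uniform_init(rng, hidden, (4 * hidden,))
        self._cache: dict | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, _ = x.shape
        H = self.hidden
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        steps = []
        out = np.empty((B, T, H))
        for t in range(T):
            z = x[:, t] @ self.W + h @ self.U + self.b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            steps.append((h, c, i, f, g, o, tc))
            h, c = h_new, c_new
            out[:, t] = h
        self._cache = {"x": x, "steps": steps}
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._cache["x"]
        steps = self._cache["steps"]
        B, T, D = x.shape
        H = self.hidden
        self.dW = np.zeros_like(self.W)
        self.dU = np.zeros_like(self.U)
        self.db = np.zeros_like(self.b)
        dx = np.empty_like(x)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc = steps[t]
            dh = dy[:, t] + dh_next
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc**2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g**2),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            self.dW += x[:, t].T @ dz
            self.dU += h_prev.T @ dz
            self.db += dz.sum(axis=0)
            dx[:, t] = dz @ self.W.T
            dh_next = dz @ self.U.T
            dc_next = dc * f
        return dx

    def params(self) -> dict[str, np.ndarray]:
        return {"W": self.W, "U": self.U, "b": self.b}

    def grads(self) -> dict[str, np.ndarray]:
        return {"W": self.dW, "U": self.dU, "b": self.db}


def reverse_within_length(x: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Reverse each padded row of ``x`` within its own length.

    Padding at the tail stays in place, so the operation is an involution.
    """
    B, T = x.shape[0], x.shape[1]
    idx = np.tile(np.arange(T), (B, 1))
    for r, L in enumerate(lengths):
        idx[r, :L] = np.arange(L - 1, -1, -1)
    return np.take_along_axis(x, idx.reshape(B, T, *([1] * (x.ndim - 2))), axis=1)


class BiLSTM:
    """A stack of (optionally) bidirectional LSTM layers."""

    def __init__(
        self,
        d_in: int,
        hidden: int,
        n_layers: int,
        bidirectional: bool,
        rng: np.random.Generator,
    ):
        self.bidirectional = bidirectional
        self.layers: list[tuple[LSTMLayer, LSTMLayer | None]] = []
        d = d_in
        for _ in range(n_layers):
            fwd = LSTMLayer(d, hidden, rng)
            bwd = LSTMLayer(d, hidden, rng) if bidirectional else None
            self.layers.append((fwd, bwd))
            d = hidden * (2 if bidirectional else 1)
        self.d_out = d

    def forward(self, x: np.ndarray, lengths: np.ndarray) -> np.ndarray:
        self._lengths = lengths
        for fwd, bwd in self.layers:
            y_f = fwd.forward(x)
            if bwd is not None:
                x_r = reverse_within_length(x, lengths)
                y_b = reverse_within_length(bwd.forward(x_r), lengths)
                x = np.concatenate([y_f, y_b], axis=2)
            else:
                x = y_f
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        lengths = self._lengths
        for fwd, bwd in reversed(self.layers):
            H = fwd.hidden
            if bwd is not None:
                dy_f, dy_b = dy[:, :, :H], dy[:, :, H:]
                dx = fwd.backward(dy_f)
                dx += reverse_within_length(
                    bwd.backward(reverse_within_length(dy_b, lengths)), lengths
                )
            else:
                dx = fwd.backward(dy)
            dy = dx
        return dy

    def iter_layers(self):
        for li, (fwd, bwd) in enumerate(self.layers):
            yield f"l{li}_fwd", fwd
            if bwd is not None:
                yield f"l{li}_bwd", bwd


def masked_mse(
    pred: np.ndarray, target: np.ndarray, lengths: np.ndarray
) -> tuple[float, np.ndarray]:
    """Per-protein MSE averaged over the batch, with its gradient.

    For each sequence p the loss is ``mean_i (pred_i - target_i)^2`` over
    that sequence's own length; the batch loss is the unweighted mean over
    sequences.  Padded positions contribute nothing to loss or gradient.
    """
    B, T = pred.shape
    mask = np.arange(T)[None, :] < np.asarray(lengths)[:, None]
    diff = np.where(mask, pred - target, 0.0)
    per_seq = (diff**2).sum(axis=1) / np.asarray(lengths)
    loss = float(per_seq.mean())
    dpred = 2.0 * diff / np.asarray(lengths)[:, None] / B
    return loss, dpred


class Adam:
    """Adam optimizer over a flat name→array parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g**2
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
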