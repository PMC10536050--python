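"""Trainable layers with explicit forward/backward passes.

Every layer keeps its weights in ``self.params`` and accumulates
matching gradients in ``self.grads``; ``backward`` consumes the upstream
gradient and returns the gradient with respect to the layer input.
Weights are initialized with a uniform fan-in scheme from a seeded
generator so whole-network builds are reproducible.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .functional import lstm_cell_forward, sigmoid

__all__ = ["Layer", "Dense", "Conv2D", "MaxPool2D", "Dropout", "BiLSTM"]


def _fan_in_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Layer:
    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def zero_grad(self) -> None:
        for k in self.params:
            self.grads[k] = np.zeros_like(self.params[k])

    def n_params(self) -> int:
        return sum(p.size for p in self.params.values())

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    """Affine map over the last axis, optional activation ('relu' or None)."""

    def __init__(
        self, in_features: int, out_features: int, rng: np.random.Generator,
        activation: str | None = None,
    ) -> None:
        super().__init__()
        self.activation = activation
        self.params = {
            "W": _fan_in_uniform(rng, (in_features, out_features), in_features),
            "b": _fan_in_uniform(rng, (out_features,), in_features),
        }
        self.zero_grad()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        y = x @ self.params["W"] + self.params["b"]
        if self.activation == "relu":
            self._mask = y > 0
            y = y * self._mask
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self.activation == "relu":
            grad = grad * self._mask
        x2 = self._x.reshape(-1, self._x.shape[-1])
        g2 = grad.reshape(-1, grad.shape[-1])
        self.grads["W"] += x2.T @ g2
        self.grads["b"] += g2.sum(axis=0)
        return grad @ self.params["W"].T


class Conv2D(Layer):
    """Stride-1, same-padded 2-D convolution on (B, H, W, C) tensors."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: tuple[int, int],
        rng: np.random.Generator,
        activation: str | None = "relu",
    ) -> None:
        super().__init__()
        kh, kw = kernel
        if kh % 2 == 0 or kw % 2 == 0:
            raise ValueError("kernel dims must be odd for same padding at stride 1")
        self.kernel = (kh, kw)
        self.activation = activation
        fan_in = kh * kw * in_channels
        self.params = {
            "W": _fan_in_uniform(rng, (kh, kw, in_channels, out_channels), fan_in),
            "b": _fan_in_uniform(rng, (out_channels,), fan_in),
        }
        self.zero_grad()

    @staticmethod
    def _conv_same(x: np.ndarray, W: np.ndarray) -> np.ndarray:
        kh, kw = W.shape[:2]
        xp = np.pad(x, ((0, 0), (kh // 2, kh // 2), (kw // 2, kw // 2), (0, 0)))
        win = sliding_window_view(xp, (kh, kw), axis=(1, 2))  # B,H,W,C,kh,kw
        return np.tensordot(win, W, axes=([4, 5, 3], [0, 1, 2]))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        y = self._conv_same(x, self.params["W"]) + self.params["b"]
        if self.activation == "relu":
            self._mask = y > 0
            y = y * self._mask
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self.activation == "relu":
            grad = grad * self._mask
        kh, kw = self.kernel
        xp = np.pad(self._x, ((0, 0), (kh // 2, kh // 2), (kw // 2, kw // 2), (0, 0)))
        win = sliding_window_view(xp, (kh, kw), axis=(1, 2))  # B,H,W,Cin,kh,kw
        # dW[a,b,ci,co] = sum_{B,H,W} win[B,H,W,ci,a,b] * grad[B,H,W,co]
        dW = np.tensordot(win, grad, axes=([0, 1, 2], [0, 1, 2]))  # Cin,kh,kw,Cout
        self.grads["W"] += dW.transpose(1, 2, 0, 3)
        self.grads["b"] += grad.sum(axis=(0, 1, 2))
        # dx: same-padded convolution of grad with the spatially flipped,
        # channel-transposed kernel (valid for stride 1).
        Wt = self.params["W"][::-1, ::-1].transpose(0, 1, 3, 2)
        return self._conv_same(grad, Wt)


class MaxPool2D(Layer):
    """Same-padded max pooling; stride 1 preserves spatial dims, stride 2 halves them."""

    def __init__(self, kernel: tuple[int, int] = (3, 3), stride: int = 1) -> None:
        super().__init__()
        self.kernel = kernel
        self.stride = stride

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        kh, kw = self.kernel
        s = self.stride
        B, H, W, C = x.shape
        Ho, Wo = -(-H // s), -(-W // s)  # ceil
        ph = max((Ho - 1) * s + kh - H, 0)
        pw = max((Wo - 1) * s + kw - W, 0)
        pt, pl = ph // 2, pw // 2
        xp = np.pad(
            x, ((0, 0), (pt, ph - pt), (pl, pw - pl), (0, 0)),
            constant_values=-np.inf,
        )
        win = sliding_window_view(xp, (kh, kw), axis=(1, 2))[:, ::s, ::s]
        flat = win.reshape(B, Ho, Wo, C, kh * kw)
        self._arg = flat.argmax(axis=-1)
        self._pad_shape = xp.shape
        self._crop = (pt, pt + H, pl, pl + W)
        return flat.max(axis=-1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        kh, kw = self.kernel
        s = self.stride
        B, Ho, Wo, C = grad.shape
        _, Hp, Wp, _ = self._pad_shape
        bi, ii, ji, ci = np.indices(grad.shape, sparse=False)
        pi = ii * s + self._arg // kw
        pj = ji * s + self._arg % kw
        dxp = np.zeros(self._pad_shape)
        np.add.at(dxp, (bi, pi, pj, ci), grad)
        t, b2, l, r = self._crop
        return dxp[:, t:b2, l:r, :]


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, p: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0 <= p < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad if self._mask is None else grad * self._mask


class BiLSTM(Layer):
    """Bidirectional LSTM over (B, T, F); returns full sequences (B, T, 2H).

    Runs the gated cell forward and backward over time and concatenates
    the two hidden sequences, so the feature width doubles the hidden
    size.  Gate blocks in the weight matrices follow (f, i, g, o) order.
    """

    def __init__(self, in_features: int, hidden: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.hidden = hidden
        self.in_features = in_features
        self.params = {}
        for d in ("fw", "bw"):
            self.params[f"Wx_{d}"] = _fan_in_uniform(rng, (in_features, 4 * hidden), in_features)
            self.params[f"Wh_{d}"] = _fan_in_uniform(rng, (hidden, 4 * hidden), hidden)
            self.params[f"b_{d}"] = np.zeros(4 * hidden)
        self.zero_grad()

    def _run_direction(self, x: np.ndarray, d: str) -> tuple[np.ndarray, list]:
        B, T, _ = x.shape
        H = self.hidden
        Wx, Wh, b = self.params[f"Wx_{d}"], self.params[f"Wh_{d}"], self.params[f"b_{d}"]
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        hs = np.empty((B, T, H))
        caches = []
        order = range(T) if d == "fw" else range(T - 1, -1, -1)
        for t in order:
            h, c, cache = lstm_cell_forward(x[:, t], h, c, Wx, Wh, b)
            hs[:, t] = h
            caches.append((t, cache, h))
        return hs, caches

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.shape[-1] != self.in_features:
            raise ValueError(f"expected feature width {self.in_features}, got {x.shape[-1]}")
        self._x = x
        out_f, self._cache_f = self._run_direction(x, "fw")
        out_b, self._cache_b = self._run_direction(x, "bw")
        return np.concatenate([out_f, out_b], axis=-1)

    def _bptt(self, dhs: np.ndarray, caches: list, d: str) -> np.ndarray:
        x = self._x
        B, T, F = x.shape
        H = self.hidden
        Wx, Wh = self.params[f"Wx_{d}"], self.params[f"Wh_{d}"]
        dWx = self.grads[f"Wx_{d}"]
        dWh = self.grads[f"Wh_{d}"]
        db = self.grads[f"b_{d}"]
        dx = np.zeros_like(x)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for step in range(len(caches) - 1, -1, -1):
            t, (f, i, g, o, tc, c_prev), _h = caches[step]
            h_prev = caches[step - 1][2] if step > 0 else np.zeros((B, H))
            dh = dhs[:, t] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc**2) + dc_next
            df = dc * c_prev
            di = dc * g
            dg = dc * i
            dc_next = dc * f
            dz = np.concatenate(
                [df * f * (1 - f), di * i * (1 - i), dg * (1 - g**2), do * o * (1 - o)],
                axis=-1,
            )
            dWx += x[:, t].T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t] += dz @ Wx.T
            dh_next = dz @ Wh.T
        return dx

    def backward(self, grad: np.ndarray) -> np.ndarray:
        H = self.hidden
        dx = self._bptt(grad[..., :H], self._cache_f, "fw")
        dx += self._bptt(grad[..., H:], self._cache_b, "bw")
        return dx
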