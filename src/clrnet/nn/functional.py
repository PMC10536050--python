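"""Stateless numerical primitives for the network core.

The LSTM cell here is the published gated recurrence: forget, input and
output gates through the logistic sigmoid, a tanh candidate, cell state
``c_t = f * c_{t-1} + i * tanh(Wxc x + Whc h + bc)`` and hidden state
``h_t = o * tanh(c_t)``.  Gate blocks are packed in (f, i, g, o) order in
all weight matrices.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "sigmoid",
    "lstm_cell_forward",
    "softmax",
    "softmax_cross_entropy",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable two-branch logistic
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def lstm_cell_forward(
    x_t: np.ndarray,
    h_prev: np.ndarray,
    c_prev: np.ndarray,
    Wx: np.ndarray,
    Wh: np.ndarray,
    b: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, tuple]:
    """One LSTM step for a batch.

    Shapes: ``x_t (B, F)``, ``h_prev``/``c_prev`` ``(B, H)``,
    ``Wx (F, 4H)``, ``Wh (H, 4H)``, ``b (4H,)`` with gate blocks packed
    as (forget, input, candidate, output).  Returns ``h_t``, ``c_t`` and
    the gate cache needed for backpropagation through time.
    """
    H = h_prev.shape[-1]
    if Wx.shape != (x_t.shape[-1], 4 * H) or Wh.shape != (H, 4 * H) or b.shape != (4 * H,):
        raise ValueError(
            f"inconsistent LSTM shapes: x {x_t.shape}, h {h_prev.shape}, "
            f"Wx {Wx.shape}, Wh {Wh.shape}, b {b.shape}"
        )
    z = x_t @ Wx + h_prev @ Wh + b
    f = sigmoid(z[..., :H])
    i = sigmoid(z[..., H : 2 * H])
    g = np.tanh(z[..., 2 * H : 3 * H])
    o = sigmoid(z[..., 3 * H :])
    c_t = f * c_prev + i * g
    tc = np.tanh(c_t)
    h_t = o * tc
    return h_t, c_t, (f, i, g, o, tc, c_prev)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Mean cross-entropy over the batch; returns (loss, probs, dlogits)."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.log(p[np.arange(n), labels] + 1e-300).mean())
    d = p.copy()
    d[np.arange(n), labels] -= 1.0
    return loss, p, d / n
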