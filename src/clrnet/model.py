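"""The CLRNet architecture and its ablation variants.

CLRNet stacks a small-kernel CNN front-end on the epoch treated as a
single-plane ``channels x samples`` image, feeds the per-timestep feature
columns through five bidirectional LSTM blocks (B1..B5, full-sequence
outputs), and sums the outputs of B1, B3 and B5 through parameter-free
residual cross-layer connections (``RES1 = B1 + B3``,
``RES2 = RES1 + B5``) before a four-way softmax head reads the last time
step.  Ablation variants drop pieces of this topology:

* ``cnn``        — CNN front-end + flatten + dense softmax head.
* ``bilstm``     — raw epochs (time-major) into the five BiLSTM blocks.
* ``cnn_bilstm`` — CNN + BiLSTM blocks, no residual sums (B5 feeds the head).
* ``clrnet``     — the full model with the residual sums.

The residual sums add no trainable parameters, so ``clrnet`` and
``cnn_bilstm`` have identical parameter counts.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .nn.functional import lstm_cell_forward, softmax
from .nn.layers import BiLSTM, Conv2D, Dense, Dropout, Layer, MaxPool2D

__all__ = [
    "ConvSpec",
    "ModelConfig",
    "VARIANTS",
    "recurrent_cell_step",
    "residual_combine",
    "build_cnn",
    "build_clrnet",
    "CLRNetNetwork",
]

VARIANTS = ("cnn", "bilstm", "cnn_bilstm", "clrnet")


@dataclasses.dataclass(frozen=True)
class ConvSpec:
    n_filters: int
    kernel: tuple[int, int]

    def __post_init__(self) -> None:
        if self.n_filters <= 0:
            raise ValueError("n_filters must be positive")
        if any(k % 2 == 0 for k in self.kernel):
            raise ValueError("kernel dims must be odd")


@dataclasses.dataclass(frozen=True)
class ModelConfig:
    """Architecture description.

    Defaults follow the published full-size model: conv filters
    (128, 128, 256, 256) with 3x3 / 5x5 kernels at stride 1 and same
    padding, 3x3 max pooling after conv layers 2 and 4 (stride 1, i.e.
    no downsampling, as printed; a stride-2 option is exposed), dropout
    0.5, five BiLSTM blocks of 100 hidden units with tanh gates and
    full-sequence outputs, dense-4 softmax head.  The linear projection
    bridging the CNN feature columns to the BiLSTM input is always
    ``2 * hidden`` wide so residual summands share one feature width.
    """

    conv_layers: tuple[ConvSpec, ...] = (
        ConvSpec(128, (3, 3)),
        ConvSpec(128, (3, 3)),
        ConvSpec(256, (5, 5)),
        ConvSpec(256, (5, 5)),
    )
    pool_kernel: tuple[int, int] = (3, 3)
    pool_stride: int = 1
    pool_positions: tuple[int, ...] = (2, 4)  # after these conv layers (1-based)
    dropout: float = 0.5
    n_bilstm: int = 5
    hidden: int = 100
    n_classes: int = 4
    variant: str = "clrnet"

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if self.n_bilstm < 1 or self.hidden < 1:
            raise ValueError("need at least one BiLSTM block with positive hidden size")
        if self.variant == "clrnet" and self.n_bilstm < 5:
            raise ValueError("residual topology RES2 = B1 + B3 + B5 needs 5 blocks")

    @classmethod
    def reduced(cls, variant: str = "clrnet") -> "ModelConfig":
        """Desk-scale preset: same topology, narrower layers, stride-2 pools."""
        return cls(
            conv_layers=(
                ConvSpec(8, (3, 3)),
                ConvSpec(8, (3, 3)),
                ConvSpec(16, (5, 5)),
                ConvSpec(16, (5, 5)),
            ),
            pool_stride=2,
            hidden=32,
            variant=variant,
        )

    def replace(self, **kw) -> "ModelConfig":
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
# Contracts exposed for testing and reuse
# ---------------------------------------------------------------------------

def recurrent_cell_step(
    x_t: np.ndarray,
    h_prev: np.ndarray,
    c_prev: np.ndarray,
    weights: dict[str, np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """One step of the gated recurrent cell used inside every BiLSTM block.

    ``weights`` holds ``Wx (F, 4H)``, ``Wh (H, 4H)`` and ``b (4H,)`` with
    gate blocks packed in (forget, input, candidate, output) order;
    sigmoid gates, tanh candidate, ``c_t = f*c_prev + i*g``,
    ``h_t = o * tanh(c_t)``.
    """
    h, c, _ = lstm_cell_forward(x_t, h_prev, c_prev, weights["Wx"], weights["Wh"], weights["b"])
    return h, c


def residual_combine(b1_out: np.ndarray, b3_out: np.ndarray, b5_out: np.ndarray) -> np.ndarray:
    """Parameter-free cross-layer sum RES2 = (B1 + B3) + B5."""
    for name, arr in (("B3", b3_out), ("B5", b5_out)):
        if arr.shape != b1_out.shape:
            raise ValueError(
                f"residual summand {name} has shape {arr.shape}, expected {b1_out.shape}"
            )
    return (b1_out + b3_out) + b5_out


def build_cnn(
    cfg: ModelConfig,
    input_shape: tuple[int, int],
    rng: np.random.Generator | None = None,
) -> list[Layer]:
    """The CNN front-end as an ordered layer list.

    The epoch is treated as a 1-deep 2-D image (channels x samples); with
    stride-1, same-padded convolution and pooling the spatial dims are
    preserved.  When ``cfg.variant == 'cnn'`` a flatten + dense softmax
    head is appended by :class:`CLRNetNetwork`, not here.
    """
    if min(input_shape) < 1:
        raise ValueError("input_shape must be positive")
    rng = rng or np.random.default_rng(0)
    layers: list[Layer] = []
    in_ch = 1
    for i, spec in enumerate(cfg.conv_layers, start=1):
        layers.append(Conv2D(in_ch, spec.n_filters, spec.kernel, rng))
        in_ch = spec.n_filters
        if i in cfg.pool_positions:
            layers.append(MaxPool2D(cfg.pool_kernel, stride=cfg.pool_stride))
    layers.append(Dropout(cfg.dropout, rng))
    return layers


# ---------------------------------------------------------------------------
# Full network
# ---------------------------------------------------------------------------

class CLRNetNetwork:
    """A built, trainable network for one variant and input shape.

    ``forward`` maps a batch of epochs ``(B, channels, samples)`` to
    logits ``(B, n_classes)``; ``backward`` consumes the logit gradient
    and accumulates parameter gradients in every layer.  All weights are
    drawn from one seeded generator, so identical (config, input_shape,
    seed) triples build identical networks.
    """

    def __init__(self, cfg: ModelConfig, input_shape: tuple[int, int], seed: int = 0) -> None:
        self.cfg = cfg
        self.input_shape = tuple(input_shape)
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        n_ch, n_samp = self.input_shape
        self.conv_layers: list[Layer] = []
        self.proj: Dense | None = None
        self.blocks: list[BiLSTM] = []

        if cfg.variant in ("cnn", "cnn_bilstm", "clrnet"):
            self.conv_layers = build_cnn(cfg, self.input_shape, rng)
            s = cfg.pool_stride
            h_out, w_out = n_ch, n_samp
            for _ in range(len(cfg.pool_positions)):
                h_out, w_out = -(-h_out // s), -(-w_out // s)
            self._feat_hw = (h_out, w_out, cfg.conv_layers[-1].n_filters)

        if cfg.variant == "cnn":
            h, w, f = self._feat_hw
            self.head = Dense(h * w * f, cfg.n_classes, rng)
        elif cfg.variant == "bilstm":
            width = n_ch  # raw epochs, time-major, one feature per channel
            for _ in range(cfg.n_bilstm):
                self.blocks.append(BiLSTM(width, cfg.hidden, rng))
                width = 2 * cfg.hidden
            self.head = Dense(2 * cfg.hidden, cfg.n_classes, rng)
        else:  # cnn_bilstm / clrnet
            h, w, f = self._feat_hw
            width = 2 * cfg.hidden
            self.proj = Dense(h * f, width, rng)  # per-timestep linear bridge
            for _ in range(cfg.n_bilstm):
                self.blocks.append(BiLSTM(width, cfg.hidden, rng))
            self.head = Dense(2 * cfg.hidden, cfg.n_classes, rng)

    # -- bookkeeping --------------------------------------------------------

    @property
    def layers(self) -> list[Layer]:
        out = list(self.conv_layers)
        if self.proj is not None:
            out.append(self.proj)
        out.extend(self.blocks)
        out.append(self.head)
        return out

    @property
    def n_params(self) -> int:
        return sum(l.n_params() for l in self.layers)

    def zero_grad(self) -> None:
        for l in self.layers:
            l.zero_grad()

    # -- forward / backward -------------------------------------------------

    def _check_input(self, x: np.ndarray) -> None:
        if x.ndim != 3 or x.shape[1:] != self.input_shape:
            raise ValueError(
                f"expected batch of shape (B, {self.input_shape[0]}, "
                f"{self.input_shape[1]}), got {x.shape}"
            )

    def _cnn_features(self, x: np.ndarray, train: bool) -> np.ndarray:
        h = x[..., None].transpose(0, 1, 2, 3)  # (B, H=channels, W=samples, 1)
        for layer in self.conv_layers:
            h = layer.forward(h, train=train)
        return h

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._check_input(x)
        cfg = self.cfg
        if cfg.variant == "cnn":
            feat = self._cnn_features(x, train)
            self._feat_shape = feat.shape
            return self.head.forward(feat.reshape(feat.shape[0], -1), train=train)

        if cfg.variant == "bilstm":
            seq = x.transpose(0, 2, 1)  # (B, T=samples, F=channels)
        else:
            feat = self._cnn_features(x, train)  # (B, H', T, F)
            self._feat_shape = feat.shape
            B, H, T, F = feat.shape
            cols = feat.transpose(0, 2, 1, 3).reshape(B, T, H * F)
            seq = self.proj.forward(cols, train=train)

        outs = []
        h = seq
        for blk in self.blocks:
            h = blk.forward(h, train=train)
            outs.append(h)
        if cfg.variant == "clrnet":
            res = residual_combine(outs[0], outs[2], outs[4])
        else:
            res = outs[-1]
        self._readout_T = res.shape[1]
        return self.head.forward(res[:, -1], train=train)

    def backward(self, dlogits: np.ndarray) -> None:
        cfg = self.cfg
        g = self.head.backward(dlogits)
        if cfg.variant == "cnn":
            g = g.reshape(self._feat_shape)
            for layer in reversed(self.conv_layers):
                g = layer.backward(g)
            return

        # gradient flows only through the last time step of the read-out
        B = g.shape[0]
        width = g.shape[-1]
        gseq = np.zeros((B, self._readout_T, width))
        gseq[:, -1] = g

        if cfg.variant == "clrnet":
            # RES2 = o1 + o3 + o5 taps outputs of B1, B3, B5
            d5 = gseq
            d = self.blocks[4].backward(d5)
            d = self.blocks[3].backward(d)
            d3 = gseq + d
            d = self.blocks[2].backward(d3)
            d = self.blocks[1].backward(d)
            d1 = gseq + d
            g = self.blocks[0].backward(d1)
        else:
            for blk in reversed(self.blocks):
                gseq = blk.backward(gseq)
            g = gseq

        if cfg.variant == "bilstm":
            return
        g = self.proj.backward(g)
        B, H, T, F = self._feat_shape
        g = g.reshape(B, T, H, F).transpose(0, 2, 1, 3)
        for layer in reversed(self.conv_layers):
            g = layer.backward(g)

    def predict_proba(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Class probabilities, evaluation mode (no dropout)."""
        probs = []
        for a in range(0, x.shape[0], batch_size):
            probs.append(softmax(self.forward(x[a : a + batch_size], train=False)))
        return np.concatenate(probs) if probs else np.zeros((0, self.cfg.n_classes))

    def predict(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        return self.predict_proba(x, batch_size).argmax(axis=1)

    # -- checkpointing ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Single-file checkpoint with the config embedded."""
        meta = {
            "config": dataclasses.asdict(self.cfg),
            "input_shape": list(self.input_shape),
            "seed": self.seed,
        }
        arrays = {
            f"p{i}_{k}": v
            for i, layer in enumerate(self.layers)
            for k, v in layer.params.items()
        }
        np.savez(Path(path), meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "CLRNetNetwork":
        with np.load(Path(path), allow_pickle=False) as f:
            meta = json.loads(str(f["meta"]))
            c = dict(meta["config"])
            c["conv_layers"] = tuple(
                ConvSpec(n, tuple(k)) for n, k in c["conv_layers"]
            ) if c["conv_layers"] and isinstance(c["conv_layers"][0], list) else tuple(
                ConvSpec(d["n_filters"], tuple(d["kernel"])) for d in c["conv_layers"]
            )
            for key in ("pool_kernel", "pool_positions"):
                c[key] = tuple(c[key])
            cfg = ModelConfig(**c)
            net = cls(cfg, tuple(meta["input_shape"]), seed=meta["seed"])
            for i, layer in enumerate(net.layers):
                for k in layer.params:
                    layer.params[k][...] = f[f"p{i}_{k}"]
        return net


def build_clrnet(
    cfg: ModelConfig, input_shape: tuple[int, int], seed: int = 0
) -> CLRNetNetwork:
    """Build any variant for a given (channels, samples) input shape."""
    return CLRNetNetwork(cfg, input_shape, seed=seed)
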