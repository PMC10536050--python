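"""Raw recording -> model-ready epochs.

The default chain reproduces the standard motor-imagery preparation for
IV-2a-style data: zero-phase 8-30 Hz Butterworth band-pass on the
continuous signal, exclusion of the three EOG channels (25 -> 22), cutting
the 3-6 s imagery window of every trial (750 samples at 250 Hz), and a
five-level wavelet-packet reconstruction that keeps only the leaves
covering 7.8125-23.4375 Hz — the Mu (8-14 Hz) and Beta (16-24 Hz)
sensorimotor rhythms — followed by polyphase resampling to 240 samples
(80 Hz; lossless for content below the 23.4375 Hz band edge).

The wavelet-packet tree uses frequency-ordered (sequency) leaf indexing:
leaf ``k`` of ``2^L`` passes the ``k``-th band of width ``fs/2^(L+1)``
counted from DC.  The natural filter-tree (Paley) order would scramble
the node -> band mapping because the high-pass branch mirrors the
spectrum at each split.
"""

from __future__ import annotations

import dataclasses
from math import gcd
from typing import Sequence

import numpy as np
import pywt
from scipy import signal as sps

from .io import EpochSet, RawRecording

__all__ = [
    "FilterSpec",
    "WPDConfig",
    "PipelineConfig",
    "bandpass",
    "remove_eog",
    "extract_epochs",
    "select_channels",
    "wpd_band_edges",
    "wpd_decompose",
    "wpd_reconstruct",
    "preprocess_pipeline",
]

EOG_CHANNELS = ("EOG-left", "EOG-central", "EOG-right")


@dataclasses.dataclass(frozen=True)
class FilterSpec:
    """Band-pass specification; zero-phase 4th-order Butterworth by default."""

    band: tuple[float, float] = (8.0, 30.0)
    family: str = "butterworth"
    order: int = 4
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        lo, hi = self.band
        if not 0 < lo < hi < fs / 2:
            raise ValueError(
                f"band {self.band} invalid for fs={fs} (need 0 < lo < hi < Nyquist)"
            )
        if self.family != "butterworth":
            raise ValueError(f"unsupported filter family {self.family!r}")


@dataclasses.dataclass(frozen=True)
class WPDConfig:
    """Wavelet-packet band-selection settings.

    ``retained_band`` leaves are kept (a leaf survives iff its passband
    lies inside the retained band); everything else is zeroed before the
    inverse transform.  ``output_samples`` triggers polyphase resampling
    of the reconstructed epoch; set it to ``None`` to keep the original
    length.
    """

    wavelet: str = "db4"
    level: int = 5
    retained_band: tuple[float, float] = (7.8125, 23.4375)
    output_samples: int | None = 240

    def __post_init__(self) -> None:
        if self.level < 1:
            raise ValueError("level must be >= 1")
        if self.output_samples is not None and self.output_samples <= 0:
            raise ValueError("output_samples must be positive")


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    """Composition: bandpass -> remove_eog -> extract_epochs -> wpd (-> channels)."""

    filter_spec: FilterSpec = FilterSpec()
    epoch_window: tuple[float, float] = (3.0, 6.0)
    wpd: WPDConfig = WPDConfig()
    channels: tuple[str, ...] | None = None


# ---------------------------------------------------------------------------
# Stage 1: band-pass
# ---------------------------------------------------------------------------

def bandpass(rec: RawRecording, spec: FilterSpec = FilterSpec()) -> RawRecording:
    """Band-pass the continuous recording; shape, names and events unchanged."""
    spec.validate(rec.fs)
    sos = sps.butter(spec.order, spec.band, btype="bandpass", fs=rec.fs, output="sos")
    filt = sps.sosfiltfilt if spec.zero_phase else sps.sosfilt
    return RawRecording(
        signal=filt(sos, rec.signal, axis=1),
        channel_names=list(rec.channel_names),
        fs=rec.fs,
        events=list(rec.events),
        subject_id=rec.subject_id,
    )


# ---------------------------------------------------------------------------
# Stage 2: EOG channel exclusion
# ---------------------------------------------------------------------------

def remove_eog(
    rec: RawRecording,
    eog_names: Sequence[str] = EOG_CHANNELS,
    strict: bool = True,
) -> RawRecording:
    """Drop the named EOG channels, preserving the order of the rest.

    With ``strict`` (default) all named channels must be present — a
    25-channel IV-2a-style recording yields exactly 22 channels.  With
    ``strict=False`` a recording already lacking them passes through
    unchanged.  Remaining rows are untouched bit-for-bit.
    """
    missing = [c for c in eog_names if c not in rec.channel_names]
    if missing and strict:
        raise ValueError(
            f"EOG channels {missing} not found; recording has {rec.channel_names}"
        )
    keep = [i for i, c in enumerate(rec.channel_names) if c not in eog_names]
    return RawRecording(
        signal=rec.signal[keep],
        channel_names=[rec.channel_names[i] for i in keep],
        fs=rec.fs,
        events=list(rec.events),
        subject_id=rec.subject_id,
    )


# ---------------------------------------------------------------------------
# Stage 3: epoch extraction
# ---------------------------------------------------------------------------

def extract_epochs(
    rec: RawRecording,
    window: tuple[float, float] = (3.0, 6.0),
    labels: Sequence[int] | None = None,
) -> EpochSet:
    """Cut the trial-relative ``window`` (seconds) around every event.

    Samples are taken half-open, ``[onset + round(w0*fs), ...)``, with
    exactly ``round((w1-w0)*fs)`` samples per trial — 750 for a 3 s
    window at 250 Hz.  Labels come from the event codes unless a
    side-car ``labels`` sequence overrides them.
    """
    w0, w1 = window
    if not w1 > w0:
        raise ValueError("epoch window must have positive length")
    n = int(round((w1 - w0) * rec.fs))
    start_off = int(round(w0 * rec.fs))
    starts = [onset + start_off for onset, _ in rec.events]
    bad = [t for t, s in enumerate(starts) if s < 0 or s + n > rec.n_samples]
    if bad:
        raise ValueError(f"epoch window exceeds recording for trials {bad}")
    data = np.stack([rec.signal[:, s : s + n] for s in starts]) if starts else np.zeros(
        (0, rec.n_channels, n)
    )
    if labels is not None:
        if len(labels) != len(rec.events):
            raise ValueError(f"{len(labels)} labels for {len(rec.events)} trials")
        lab = np.asarray(labels, dtype=np.int64)
    else:
        lab = np.asarray([code for _, code in rec.events], dtype=np.int64)
        if lab.size and lab.min() < 0:
            raise ValueError(
                "events carry no class labels (unknown-cue codes); "
                "pass a side-car labels sequence"
            )
    return EpochSet(data=data, labels=lab, fs=rec.fs, channel_names=list(rec.channel_names))


def select_channels(epochs: EpochSet, names: Sequence[str]) -> EpochSet:
    """Restrict to the named channels, in the given order."""
    unknown = [c for c in names if c not in epochs.channel_names]
    if unknown:
        raise ValueError(f"unknown channel(s) {unknown}")
    idx = [epochs.channel_names.index(c) for c in names]
    return EpochSet(
        data=epochs.data[:, idx],
        labels=epochs.labels.copy(),
        fs=epochs.fs,
        channel_names=list(names),
        class_names=epochs.class_names,
    )


# ---------------------------------------------------------------------------
# Stage 4: wavelet-packet band selection
# ---------------------------------------------------------------------------

def wpd_band_edges(fs: float, n_bands: int) -> list[tuple[float, float]]:
    """Equal-width frequency bands tiling [0, fs/2], frequency-ordered.

    At ``fs=250`` with 16 bands the first three are (0, 7.8125),
    (7.8125, 15.625) and (15.625, 23.4375) Hz.
    """
    if n_bands < 1 or n_bands & (n_bands - 1):
        raise ValueError(f"n_bands must be a power of two, got {n_bands}")
    width = fs / 2.0 / n_bands
    return [(k * width, (k + 1) * width) for k in range(n_bands)]


def wpd_decompose(
    x: np.ndarray, wavelet: str, level: int, mode: str = "symmetric"
) -> tuple[list[np.ndarray], list[list[int]]]:
    """Full wavelet-packet tree along the last axis, leaves frequency-ordered.

    Returns the ``2^level`` leaf coefficient arrays (leaf ``k`` passes
    band ``k`` of :func:`wpd_band_edges`) and the per-level signal
    lengths needed to invert exactly.  At every split the high-pass
    branch mirrors the spectrum, so children of a node with frequency
    index ``f`` swap roles when ``f`` is odd — this is what turns the
    natural (Paley) tree order into frequency (sequency) order.
    """
    nodes = [x]
    lengths: list[list[int]] = []
    for _ in range(level):
        lengths.append([n.shape[-1] for n in nodes])
        nxt: list[np.ndarray | None] = [None] * (2 * len(nodes))
        for f, node in enumerate(nodes):
            ca, cd = pywt.dwt(node, wavelet, mode=mode, axis=-1)
            if f % 2 == 0:
                nxt[2 * f], nxt[2 * f + 1] = ca, cd
            else:
                nxt[2 * f], nxt[2 * f + 1] = cd, ca
        nodes = nxt  # type: ignore[assignment]
    return nodes, lengths


def wpd_inverse(
    leaves: Sequence[np.ndarray | None],
    lengths: list[list[int]],
    wavelet: str,
    mode: str = "symmetric",
) -> np.ndarray:
    """Invert :func:`wpd_decompose`; ``None`` leaves count as all-zero."""
    nodes = list(leaves)
    for lens in reversed(lengths):
        parents: list[np.ndarray | None] = []
        for f in range(len(nodes) // 2):
            a, b = nodes[2 * f], nodes[2 * f + 1]
            if a is None and b is None:
                parents.append(None)
                continue
            if a is None:
                a = np.zeros_like(b)
            if b is None:
                b = np.zeros_like(a)
            ca, cd = (a, b) if f % 2 == 0 else (b, a)
            rec = pywt.idwt(ca, cd, wavelet, mode=mode, axis=-1)
            parents.append(rec[..., : lens[f]])
        nodes = parents
    out = nodes[0]
    if out is None:
        raise ValueError("all leaves empty")
    return out


def wpd_reconstruct(epochs: EpochSet, cfg: WPDConfig = WPDConfig()) -> EpochSet:
    """Keep only wavelet-packet leaves inside ``cfg.retained_band``.

    Every epoch is decomposed to ``cfg.level`` (frequency-ordered
    leaves), leaves whose passband falls outside the retained band are
    zeroed, the signal is inverted back to the time domain at its
    original length, and finally resampled to ``cfg.output_samples``
    (polyphase; skipped when ``None``).  With the defaults a 750-sample
    epoch at 250 Hz comes back as 240 samples at 80 Hz.
    """
    n_leaves = 2**cfg.level
    n_in = epochs.n_samples
    if n_in < n_leaves:
        raise ValueError(f"epoch length {n_in} shorter than 2^level = {n_leaves}")
    edges = wpd_band_edges(epochs.fs, n_leaves)
    lo, hi = cfg.retained_band
    eps = 1e-9
    keep = [k for k, (a, b) in enumerate(edges) if a >= lo - eps and b <= hi + eps]
    if not keep:
        raise ValueError(
            f"retained_band {cfg.retained_band} selects no leaves; "
            f"leaf width is {edges[0][1]:.5g} Hz"
        )
    leaves, lengths = wpd_decompose(epochs.data, cfg.wavelet, cfg.level)
    kept: list[np.ndarray | None] = [
        leaves[k] if k in set(keep) else None for k in range(n_leaves)
    ]
    out = wpd_inverse(kept, lengths, cfg.wavelet)[..., :n_in]
    fs = epochs.fs
    if cfg.output_samples is not None and cfg.output_samples != n_in:
        g = gcd(cfg.output_samples, n_in)
        out = sps.resample_poly(out, cfg.output_samples // g, n_in // g, axis=-1)
        fs = epochs.fs * cfg.output_samples / n_in
    return EpochSet(
        data=out,
        labels=epochs.labels.copy(),
        fs=fs,
        channel_names=list(epochs.channel_names),
        class_names=epochs.class_names,
    )


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def preprocess_pipeline(
    rec: RawRecording,
    cfg: PipelineConfig = PipelineConfig(),
    labels: Sequence[int] | None = None,
) -> EpochSet:
    """Run the full default chain on a continuous recording.

    A simulated 25-channel, 288-trial subject at 250 Hz yields a
    288 x 22 x 240 :class:`~clrnet.io.EpochSet`.  Errors are re-raised
    with the failing stage named.
    """
    stages = [
        ("bandpass", lambda r: bandpass(r, cfg.filter_spec)),
        ("remove_eog", remove_eog),
        ("extract_epochs", lambda r: extract_epochs(r, cfg.epoch_window, labels)),
        ("wpd_reconstruct", lambda e: wpd_reconstruct(e, cfg.wpd)),
    ]
    if cfg.channels is not None:
        stages.append(("select_channels", lambda e: select_channels(e, cfg.channels)))
    out = rec
    for name, fn in stages:
        try:
            out = fn(out)
        except ValueError as exc:
            raise ValueError(f"[{name}] {exc}") from exc
    return out
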