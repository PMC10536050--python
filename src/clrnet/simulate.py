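"""Synthetic motor-imagery EEG with known class structure.

The generator emulates the BCI Competition IV-2a layout: 25 named channels
(22 EEG + 3 EOG) at 250 Hz, 288 cue-annotated trials per subject, cue at
2 s and imagery from 3 s to 6 s within each trial.  The physiology it
injects is event-related desynchronization/synchronization (ERD/ERS) of
the sensorimotor Mu (8-14 Hz) and Beta (16-24 Hz) rhythms at the motor
channels C3, Cz and C4:

* left hand  -> Mu+Beta attenuation at the contralateral C4,
* right hand -> attenuation at C3,
* foot       -> attenuation at Cz,
* tongue     -> bilateral Beta enhancement at C3 and C4.

Rhythms are amplitude-modulated narrowband processes (band-filtered white
noise), not pure sines, superposed on 1/f background noise plus a white
floor; EOG channels carry occasional low-frequency blink-like transients.
Identical configuration (including seed) yields bit-identical output.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .io import CLASS_NAMES, RawRecording

__all__ = ["SimConfig", "TrialLayout", "simulate_subject", "band_power", "IV2A_CHANNELS"]

#: 22 EEG channels in an IV-2a-like montage plus the three EOG channels.
IV2A_CHANNELS: tuple[str, ...] = (
    "Fz",
    "FC3", "FC1", "FCz", "FC2", "FC4",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "CP3", "CP1", "CPz", "CP2", "CP4",
    "P1", "Pz", "P2", "POz",
    "EOG-left", "EOG-central", "EOG-right",
)

MOTOR_CHANNELS = ("C3", "Cz", "C4")
EOG_CHANNELS = ("EOG-left", "EOG-central", "EOG-right")


@dataclasses.dataclass(frozen=True)
class TrialLayout:
    """Within-trial timing in seconds (cue-relative paradigm)."""

    prep_end_s: float = 2.0
    cue_s: float = 2.0
    mi_start_s: float = 3.0
    mi_end_s: float = 6.0
    trial_dur_s: float = 7.0
    iti_s: float = 1.5  # inter-trial rest; paradigm figures show only within-trial timing

    def __post_init__(self) -> None:
        if not self.mi_start_s < self.mi_end_s <= self.trial_dur_s:
            raise ValueError("need mi_start < mi_end <= trial duration")


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Conditions for one simulated subject.

    ``erd_depth`` is the fractional rhythm-power attenuation during the
    imagery window at the class-mapped channel (1 = rhythm fully
    suppressed); ``snr`` is the ratio of total rhythm power (Mu + Beta)
    to background (1/f + white) power at a motor channel.
    """

    n_trials_per_class: int = 72
    fs: float = 250.0
    channel_names: tuple[str, ...] = IV2A_CHANNELS
    trial_layout: TrialLayout = TrialLayout()
    mu_band: tuple[float, float] = (8.0, 14.0)
    beta_band: tuple[float, float] = (16.0, 24.0)
    erd_depth: float = 0.8
    snr: float = 4.0
    background_rms_uv: float = 10.0
    eog_rate: float = 4.0  # artifacts per minute
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ValueError("erd_depth must be in [0, 1]")
        if self.fs <= 2.0 * self.beta_band[1]:
            raise ValueError("fs must exceed twice the beta band upper edge")
        for ch in MOTOR_CHANNELS + EOG_CHANNELS:
            if ch not in self.channel_names:
                raise ValueError(f"channel list is missing required channel {ch!r}")

    @property
    def n_trials(self) -> int:
        return 4 * self.n_trials_per_class


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int], fs: float) -> np.ndarray:
    """1/f^1 power background via spectral shaping, unit variance per row."""
    n = shape[1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.ones_like(freqs)
    nz = freqs > 0
    amp[nz] = 1.0 / np.sqrt(freqs[nz])
    amp[0] = 0.0
    x = np.fft.irfft(spec * amp, n=n, axis=1)
    x /= x.std(axis=1, keepdims=True)
    return x


def _narrowband(
    rng: np.random.Generator, n: int, fs: float, band: tuple[float, float]
) -> np.ndarray:
    """Unit-variance band-limited noise (4th-order Butterworth on white noise)."""
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n))
    return x / x.std()


def _smooth_gate(n: int, start: int, stop: int, ramp: int) -> np.ndarray:
    """0/1 window over [start, stop) with raised-cosine ramps of ``ramp`` samples."""
    g = np.zeros(n)
    g[start:stop] = 1.0
    if ramp > 0:
        up = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
        a = max(start - ramp // 2, 0)
        g[a : a + ramp] = up[: n - a]
        b = min(stop - ramp // 2, n - ramp)
        if b > 0:
            g[b : b + ramp] = up[::-1][: n - b]
    return g


def _blink(fs: float, rng: np.random.Generator) -> np.ndarray:
    """A single smooth blink-like transient, ~0.4 s, 50-150 microvolts."""
    dur = int(0.4 * fs)
    t = np.linspace(-1, 1, dur)
    amp = rng.uniform(50.0, 150.0) * rng.choice([-1.0, 1.0])
    return amp * np.exp(-(t**2) / 0.18)


def simulate_subject(cfg: SimConfig) -> tuple[RawRecording, dict]:
    """Generate one subject's continuous recording plus ground truth.

    Returns
    -------
    rec
        25-channel :class:`~clrnet.io.RawRecording` whose events mark
        trial starts with the true class code.
    ground_truth
        Dict with ``labels`` (per trial), ``onsets`` (trial-start
        samples) and the config used.
    """
    rng = np.random.default_rng(cfg.seed)
    layout = cfg.trial_layout
    fs = cfg.fs
    trial_len = int(round(layout.trial_dur_s * fs))
    iti_len = int(round(layout.iti_s * fs))
    n_trials = cfg.n_trials
    n_samples = n_trials * (trial_len + iti_len) + iti_len
    n_ch = len(cfg.channel_names)

    # Balanced, shuffled label sequence: exactly n_trials_per_class per class.
    labels = np.repeat(np.arange(4), cfg.n_trials_per_class)
    rng.shuffle(labels)
    onsets = iti_len + np.arange(n_trials) * (trial_len + iti_len)

    bg = cfg.background_rms_uv
    sig = bg * _pink_noise(rng, (n_ch, n_samples), fs)
    sig += 0.1 * bg * rng.standard_normal((n_ch, n_samples))
    bg_power = sig.var(axis=1).mean()

    # Ongoing Mu and Beta rhythms at motor channels; total rhythm power
    # (Mu + Beta) = snr x background power, split equally between bands.
    rhythm_rms = np.sqrt(cfg.snr * bg_power / 2.0)
    ch_index = {name: i for i, name in enumerate(cfg.channel_names)}
    mi_a = int(round(layout.mi_start_s * fs))
    mi_b = int(round(layout.mi_end_s * fs))
    ramp = int(0.25 * fs)

    # Per-channel envelope, flat at 1 outside imagery windows.
    for ch in MOTOR_CHANNELS:
        mu = rhythm_rms * _narrowband(rng, n_samples, fs, cfg.mu_band)
        beta = rhythm_rms * _narrowband(rng, n_samples, fs, cfg.beta_band)
        env_mu = np.ones(n_samples)
        env_beta = np.ones(n_samples)
        for onset, lab in zip(onsets, labels):
            gate = _smooth_gate(n_samples, onset + mi_a, onset + mi_b, ramp)
            erd = np.sqrt(1.0 - cfg.erd_depth)  # amplitude factor for power drop
            ers = np.sqrt(1.0 + cfg.erd_depth)  # amplitude factor for power rise
            if lab == 0 and ch == "C4":  # left hand -> contralateral ERD
                env_mu -= gate * (1.0 - erd)
                env_beta -= gate * (1.0 - erd)
            elif lab == 1 and ch == "C3":  # right hand
                env_mu -= gate * (1.0 - erd)
                env_beta -= gate * (1.0 - erd)
            elif lab == 2 and ch == "Cz":  # foot
                env_mu -= gate * (1.0 - erd)
                env_beta -= gate * (1.0 - erd)
            elif lab == 3 and ch in ("C3", "C4"):  # tongue -> bilateral Beta ERS
                env_beta += gate * (ers - 1.0)
        sig[ch_index[ch]] += env_mu * mu + env_beta * beta

    # EOG transients: Poisson arrivals shared across the three EOG channels.
    n_blinks = rng.poisson(cfg.eog_rate * n_samples / fs / 60.0)
    blink_starts = np.sort(rng.integers(0, max(n_samples - int(0.4 * fs), 1), n_blinks))
    for start in blink_starts:
        pulse = _blink(fs, rng)
        stop = min(start + pulse.size, n_samples)
        for ch in EOG_CHANNELS:
            gain = rng.uniform(0.7, 1.0)
            sig[ch_index[ch], start:stop] += gain * pulse[: stop - start]

    rec = RawRecording(
        signal=sig,
        channel_names=list(cfg.channel_names),
        fs=fs,
        events=[(int(o), int(l)) for o, l in zip(onsets, labels)],
        subject_id=f"sim-seed{cfg.seed}",
    )
    ground_truth = {
        "labels": np.asarray(labels),
        "onsets": np.asarray(onsets),
        "class_names": CLASS_NAMES,
        "config": cfg,
    }
    return rec, ground_truth


def band_power(
    rec: RawRecording,
    channel: str,
    band: tuple[float, float],
    window: tuple[float, float] | None = None,
) -> float:
    """Integrated Welch PSD of one channel over a frequency band.

    ``window`` is ``(t0, t1)`` in seconds; omit it to use the whole
    recording.  Units are signal-units squared (power), non-negative.
    """
    if channel not in rec.channel_names:
        raise ValueError(f"channel {channel!r} not in recording")
    x = rec.signal[rec.channel_names.index(channel)]
    if window is not None:
        a = int(round(window[0] * rec.fs))
        b = int(round(window[1] * rec.fs))
        if not 0 <= a < b <= rec.n_samples:
            raise ValueError(f"window {window} empty or outside recording")
        x = x[a:b]
    nperseg = min(x.size, int(2 * rec.fs))
    freqs, psd = sps.welch(x, fs=rec.fs, nperseg=nperseg)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not mask.any():
        return 0.0
    return float(np.trapezoid(psd[mask], freqs[mask]))


def trial_band_powers(
    rec: RawRecording,
    channels: Sequence[str] = MOTOR_CHANNELS,
    bands: Sequence[tuple[float, float]] = ((8.0, 14.0), (16.0, 24.0)),
    window: tuple[float, float] = (3.0, 6.0),
) -> np.ndarray:
    """Per-trial log band-power feature matrix (trials x channels*bands).

    A cheap, fixed feature extractor used as an oracle decoder input in
    separability checks; ``window`` is trial-relative seconds.
    """
    feats = np.empty((len(rec.events), len(channels) * len(bands)))
    a = int(round(window[0] * rec.fs))
    b = int(round(window[1] * rec.fs))
    idx = [rec.channel_names.index(c) for c in channels]
    for t, (onset, _) in enumerate(rec.events):
        seg = rec.signal[:, onset + a : onset + b]
        col = 0
        for ci in idx:
            freqs, psd = sps.welch(seg[ci], fs=rec.fs, nperseg=min(seg.shape[1], 512))
            for lo, hi in bands:
                m = (freqs >= lo) & (freqs <= hi)
                feats[t, col] = np.log(np.trapezoid(psd[m], freqs[m]) + 1e-12)
                col += 1
    return feats
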