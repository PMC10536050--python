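"""Reading and writing EEG recordings and epoch archives.

Two containers flow through the package:

* :class:`RawRecording` — a continuous multichannel signal with named
  channels, a sampling rate and cue events, as delivered by a GDF file
  (BCI Competition IV-2a layout: 25 channels = 22 EEG + 3 EOG at 250 Hz)
  or by the bundled motor-imagery simulator.
* :class:`EpochSet` — trials x channels x samples with one class label
  per trial; the unit every preprocessing stage and the network consume.

GDF files are read through :mod:`mne`.  The internal "epoch archive" is a
single self-describing NumPy ``.npz`` file with named arrays, so tests and
pipelines need no EEG-format dependency.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "RawRecording",
    "EpochSet",
    "CLASS_NAMES",
    "GDF_CLASS_EVENTS",
    "read_raw",
    "write_raw",
    "save_epochs",
    "load_epochs",
]

#: Fixed class-code mapping; keeps confusion-matrix layout deterministic.
CLASS_NAMES: tuple[str, ...] = ("left_hand", "right_hand", "foot", "tongue")

#: BCI IV-2a GDF annotation codes for the four cue classes -> class index.
GDF_CLASS_EVENTS: dict[int, int] = {769: 0, 770: 1, 771: 2, 772: 3}


class FormatError(ValueError):
    """A file exists but does not parse as the named format."""


class IntegrityError(ValueError):
    """Loaded arrays violate a container invariant (shape/label mismatch)."""


@dataclasses.dataclass
class RawRecording:
    """Continuous multichannel recording in microvolts.

    Parameters
    ----------
    signal
        Array of shape ``(n_channels, n_samples)``.
    channel_names
        Unique channel names, one per row of ``signal``.
    fs
        Sampling rate in Hz, strictly positive.
    events
        ``(onset_sample, code)`` pairs; for motor-imagery recordings the
        onset marks the trial start and the code is the class index.
    """

    signal: np.ndarray
    channel_names: list[str]
    fs: float
    events: list[tuple[int, int]] = dataclasses.field(default_factory=list)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels x samples)")
        self.channel_names = [str(c) for c in self.channel_names]
        if len(self.channel_names) != self.signal.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.signal.shape[0]} signal rows"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        self.events = [(int(o), int(c)) for o, c in self.events]
        for onset, _ in self.events:
            if not 0 <= onset < self.n_samples:
                raise ValueError(f"event onset {onset} outside [0, {self.n_samples})")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RawRecording):
            return NotImplemented
        return (
            np.array_equal(self.signal, other.signal)
            and self.channel_names == other.channel_names
            and self.fs == other.fs
            and self.events == other.events
            and self.subject_id == other.subject_id
        )


@dataclasses.dataclass
class EpochSet:
    """Labelled trials ready for (or emitted by) preprocessing.

    ``data`` has shape ``(n_trials, n_channels, n_samples)``; ``labels``
    holds one class index per trial, each below ``len(class_names)``.
    """

    data: np.ndarray
    labels: np.ndarray
    fs: float
    channel_names: list[str]
    class_names: tuple[str, ...] = CLASS_NAMES

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (trials x channels x samples)")
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.shape != (self.data.shape[0],):
            raise IntegrityError(
                f"labels shape {self.labels.shape} does not match "
                f"{self.data.shape[0]} trials"
            )
        self.channel_names = [str(c) for c in self.channel_names]
        if len(self.channel_names) != self.data.shape[1]:
            raise IntegrityError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[1]} data channels"
            )
        self.class_names = tuple(str(c) for c in self.class_names)
        if self.labels.size and self.labels.max() >= len(self.class_names):
            raise IntegrityError("label exceeds number of classes")
        if self.labels.size and self.labels.min() < 0:
            raise IntegrityError("negative class label")
        if not self.fs > 0:
            raise ValueError("fs must be positive")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EpochSet):
            return NotImplemented
        return (
            np.array_equal(self.data, other.data)
            and np.array_equal(self.labels, other.labels)
            and self.fs == other.fs
            and self.channel_names == other.channel_names
            and self.class_names == other.class_names
        )


# ---------------------------------------------------------------------------
# Raw recordings
# ---------------------------------------------------------------------------

def read_raw(
    path: str | Path,
    format: str = "epoch_archive",
    labels: Sequence[int] | None = None,
) -> RawRecording:
    """Read a continuous recording.

    Parameters
    ----------
    path
        File to read.
    format
        ``"gdf"`` for BCI IV-2a files (via mne) or ``"epoch_archive"``
        for the internal ``.npz`` container written by :func:`write_raw`.
    labels
        Optional side-car class labels for evaluation-session GDF files
        whose cue annotations carry the "unknown" code; attached in trial
        order when given.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "gdf":
        return _read_gdf(path, labels)
    if format == "epoch_archive":
        return _read_raw_npz(path)
    raise ValueError(f"unknown raw format {format!r}; expected 'gdf' or 'epoch_archive'")


def _read_gdf(path: Path, labels: Sequence[int] | None) -> RawRecording:
    import mne

    try:
        raw = mne.io.read_raw_gdf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted types on truncated files
        raise FormatError(f"cannot parse {path} as GDF: {exc}") from exc
    signal = raw.get_data() * 1e6  # mne returns volts; store microvolts
    fs = float(raw.info["sfreq"])
    # Cue annotations: either the four class codes (session T) or the
    # "unknown cue" code 783 (session E); both mark trial starts.
    events: list[tuple[int, int]] = []
    cue_onsets: list[int] = []
    for onset_s, desc in zip(raw.annotations.onset, raw.annotations.description):
        try:
            code = int(desc)
        except ValueError:
            continue
        if code in GDF_CLASS_EVENTS or code == 783:
            onset = int(round(onset_s * fs))
            cue_onsets.append(onset)
            events.append((onset, GDF_CLASS_EVENTS.get(code, -1)))
    if labels is not None:
        if len(labels) != len(events):
            raise IntegrityError(
                f"side-car has {len(labels)} labels for {len(events)} trials"
            )
        events = [(o, int(l)) for (o, _), l in zip(events, labels)]
    return RawRecording(
        signal=signal,
        channel_names=list(raw.ch_names),
        fs=fs,
        events=events,
        subject_id=path.stem,
    )


def write_raw(rec: RawRecording, path: str | Path, format: str = "epoch_archive") -> None:
    """Write a recording so that :func:`read_raw` recovers it bit-identically."""
    if format != "epoch_archive":
        raise ValueError(f"cannot write format {format!r}; only 'epoch_archive'")
    path = Path(path)
    events = np.asarray(rec.events, dtype=np.int64).reshape(-1, 2)
    np.savez(
        path,
        kind="raw",
        signal=rec.signal,
        channel_names=np.asarray(rec.channel_names, dtype=object),
        fs=np.float64(rec.fs),
        events=events,
        subject_id=rec.subject_id,
    )


def _read_raw_npz(path: Path) -> RawRecording:
    try:
        with np.load(path, allow_pickle=True) as f:
            if str(f["kind"]) != "raw":
                raise FormatError(f"{path} is not a raw archive (kind={f['kind']})")
            events = [(int(o), int(c)) for o, c in f["events"]]
            return RawRecording(
                signal=f["signal"],
                channel_names=list(f["channel_names"]),
                fs=float(f["fs"]),
                events=events,
                subject_id=str(f["subject_id"]),
            )
    except (KeyError, OSError, ValueError) as exc:
        if isinstance(exc, FormatError):
            raise
        raise FormatError(f"cannot parse {path} as raw archive: {exc}") from exc


# ---------------------------------------------------------------------------
# Epoch archives
# ---------------------------------------------------------------------------

def save_epochs(epochs: EpochSet, path: str | Path) -> None:
    """Losslessly store an :class:`EpochSet` as a single ``.npz`` file."""
    np.savez(
        Path(path),
        kind="epochs",
        data=epochs.data,
        labels=epochs.labels,
        fs=np.float64(epochs.fs),
        channel_names=np.asarray(epochs.channel_names, dtype=object),
        class_names=np.asarray(epochs.class_names, dtype=object),
    )


def load_epochs(path: str | Path) -> EpochSet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with np.load(path, allow_pickle=True) as f:
            if str(f["kind"]) != "epochs":
                raise FormatError(f"{path} is not an epoch archive (kind={f['kind']})")
            return EpochSet(
                data=f["data"],
                labels=f["labels"],
                fs=float(f["fs"]),
                channel_names=list(f["channel_names"]),
                class_names=tuple(f["class_names"]),
            )
    except KeyError as exc:
        raise FormatError(f"cannot parse {path} as epoch archive: {exc}") from exc
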