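"""Domain model for multi-day surface-EMG recordings.

A recording session is organised as subject x day x motion x trial.  Each
trial is one repetition of one motion, stored as a (channels x samples)
matrix.  This module provides the trial/window containers, sliding-window
segmentation, raw-signal persistence (HDF5 hierarchy or per-trial CSV) and
feature-matrix persistence (flat CSV).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd
from scipy import signal as _signal

#: Muscles under the seven electrodes, proximal to distal.
DEFAULT_CHANNEL_NAMES: tuple[str, ...] = (
    "anterior_deltoid",
    "middle_deltoid",
    "posterior_deltoid",
    "biceps",
    "triceps",
    "brachioradialis",
    "flexor_carpi_radialis",
)

#: The eleven shoulder/elbow motion classes (five single motions and six
#: shoulder+elbow combinations).
MOTION_NAMES: tuple[str, ...] = (
    "SF", "SA", "SPF", "EF", "EE",
    "SFEF", "SFEE", "SAEF", "SAEE", "SPFEF", "SPFEE",
)


class SchemaError(ValueError):
    """A stored session file does not match the expected trial schema."""


@dataclass(frozen=True)
class EmgTrial:
    """One multichannel recording of one motion repetition.

    Parameters
    ----------
    samples
        Real matrix of shape ``(channels, n_samples)`` in the recording's
        native amplitude units.
    sampling_rate
        Sampling frequency in Hz.
    motion
        Motion class label, an integer in ``1..n_motions``.
    trial_index
        Repetition number within (subject, day, motion), starting at 1.
    day
        Recording day (1 = the training day).
    subject
        Subject identifier.
    channel_names
        One muscle name per channel.
    """

    samples: np.ndarray
    sampling_rate: float
    motion: int
    trial_index: int
    day: int
    subject: str
    channel_names: tuple[str, ...] = DEFAULT_CHANNEL_NAMES

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 2:
            raise ValueError("samples must be a (channels, n_samples) matrix")
        if not np.all(np.isfinite(samples)):
            raise ValueError("trial contains non-finite samples")
        if len(self.channel_names) != samples.shape[0]:
            raise ValueError(
                f"{samples.shape[0]} channels but "
                f"{len(self.channel_names)} channel names"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: 250 ms windows advanced in 50 ms steps.

    The defaults segment a 5-s trial at 1500 Hz into 96 overlapping windows
    of N = 375 samples.  ``step_ms`` is the advance between consecutive
    window starts; consecutive windows overlap by ``length_ms - step_ms``.
    """

    length_ms: float = 250.0
    step_ms: float = 50.0

    def __post_init__(self) -> None:
        if not (0 < self.step_ms <= self.length_ms):
            raise ValueError("require 0 < step_ms <= length_ms")

    def n_samples(self, sampling_rate: float) -> int:
        n = self.length_ms * sampling_rate / 1000.0
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"window length {self.length_ms} ms is not a whole number of "
                f"samples at {sampling_rate} Hz"
            )
        return int(round(n))

    def step_samples(self, sampling_rate: float) -> int:
        s = self.step_ms * sampling_rate / 1000.0
        if abs(s - round(s)) > 1e-9:
            raise ValueError(
                f"window step {self.step_ms} ms is not a whole number of "
                f"samples at {sampling_rate} Hz"
            )
        return int(round(s))


@dataclass(frozen=True)
class Window:
    """One analysis window cut from a trial, with full provenance."""

    samples: np.ndarray  # (channels, N)
    motion: int
    subject: str
    day: int
    trial_index: int
    window_index: int

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]


def n_windows(kept_samples: int, window_samples: int, step_samples: int) -> int:
    """Number of sliding windows fitting in ``kept_samples`` samples."""
    if kept_samples < window_samples:
        raise ValueError("signal shorter than one window")
    return (kept_samples - window_samples) // step_samples + 1


def central_slice(n_samples: int, sampling_rate: float, keep_s: float) -> slice:
    """Index slice of the central ``keep_s`` seconds of an ``n_samples`` signal.

    The start offset is rounded down to a whole sample; ``keep_s`` itself must
    be representable as a whole number of samples.
    """
    keep = keep_s * sampling_rate
    if abs(keep - round(keep)) > 1e-9:
        raise ValueError(
            f"keep_central_s={keep_s} is not a whole number of samples at "
            f"{sampling_rate} Hz"
        )
    keep = int(round(keep))
    if keep > n_samples:
        raise ValueError(
            f"trial has {n_samples} samples but {keep} were requested"
        )
    start = (n_samples - keep) // 2
    return slice(start, start + keep)


def segment_trial(
    trial: EmgTrial,
    spec: WindowSpec = WindowSpec(),
    keep_central_s: float | None = 5.0,
) -> list[Window]:
    """Cut a trial into overlapping windows over its central span.

    With the defaults (250 ms / 50 ms step, keep the central 5 s of a 7-s
    trial at 1500 Hz) this yields 96 windows of 375 samples each.

    Parameters
    ----------
    trial
        The recording to segment.
    spec
        Window length and step.
    keep_central_s
        Span (seconds) centred in the trial to segment; ``None`` keeps the
        whole trial.
    """
    if keep_central_s is None:
        kept = trial.samples
    else:
        kept = trial.samples[:, central_slice(
            trial.n_samples, trial.sampling_rate, keep_central_s)]
    N = spec.n_samples(trial.sampling_rate)
    step = spec.step_samples(trial.sampling_rate)
    count = n_windows(kept.shape[1], N, step)
    return [
        Window(
            samples=kept[:, k * step: k * step + N],
            motion=trial.motion,
            subject=trial.subject,
            day=trial.day,
            trial_index=trial.trial_index,
            window_index=k,
        )
        for k in range(count)
    ]


def segment_trials_array(
    trials: Sequence[EmgTrial],
    spec: WindowSpec = WindowSpec(),
    keep_central_s: float | None = 5.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Segment many trials into one dense array, the fast path for extraction.

    Returns
    -------
    windows : ndarray, shape (n_windows_total, channels, N)
    meta : DataFrame with columns label, subject, day, trial, window
    """
    blocks: list[np.ndarray] = []
    meta_rows: list[tuple] = []
    for trial in trials:
        wins = segment_trial(trial, spec, keep_central_s)
        blocks.append(np.stack([w.samples for w in wins]))
        meta_rows.extend(
            (w.motion, w.subject, w.day, w.trial_index, w.window_index)
            for w in wins
        )
    meta = pd.DataFrame(
        meta_rows, columns=["label", "subject", "day", "trial", "window"]
    )
    return np.concatenate(blocks, axis=0), meta


# ---------------------------------------------------------------------------
# Raw-signal persistence
# ---------------------------------------------------------------------------

def save_session(path: str | Path, trials: Iterable[EmgTrial]) -> None:
    """Write trials to an HDF5 container.

    Layout: one dataset per trial at ``/S{subject}/D{day}/M{motion}/T{trial}``
    of shape (channels, samples), with ``sampling_rate`` and ``channel_names``
    stored as file-level attributes (they are homogeneous across a session).
    """
    trials = list(trials)
    if not trials:
        raise ValueError("no trials to save")
    rate = trials[0].sampling_rate
    names = trials[0].channel_names
    with h5py.File(path, "w") as f:
        f.attrs["sampling_rate"] = rate
        f.attrs["channel_names"] = list(names)
        for t in trials:
            if t.sampling_rate != rate or t.channel_names != names:
                raise SchemaError(
                    "all trials in a session must share sampling rate and "
                    "channel names"
                )
            f.create_dataset(
                f"S{t.subject}/D{t.day}/M{t.motion}/T{t.trial_index}",
                data=t.samples,
            )


def load_session(
    path: str | Path, expected_channels: int | None = 7
) -> list[EmgTrial]:
    """Read trials back from :func:`save_session`'s HDF5 layout.

    Raises :class:`SchemaError` on missing metadata or a channel-count
    mismatch with ``expected_channels`` (pass ``None`` to skip the check).
    """
    trials: list[EmgTrial] = []
    with h5py.File(path, "r") as f:
        if "sampling_rate" not in f.attrs or "channel_names" not in f.attrs:
            raise SchemaError(
                "session file lacks sampling_rate/channel_names attributes"
            )
        rate = float(f.attrs["sampling_rate"])
        names = tuple(
            n.decode() if isinstance(n, bytes) else str(n)
            for n in f.attrs["channel_names"]
        )
        for skey, sgrp in f.items():
            for dkey, dgrp in sgrp.items():
                for mkey, mgrp in dgrp.items():
                    for tkey, dset in mgrp.items():
                        samples = np.asarray(dset)
                        if (expected_channels is not None
                                and samples.shape[0] != expected_channels):
                            raise SchemaError(
                                f"trial {skey}/{dkey}/{mkey}/{tkey} has "
                                f"{samples.shape[0]} channels, expected "
                                f"{expected_channels}"
                            )
                        trials.append(EmgTrial(
                            samples=samples,
                            sampling_rate=rate,
                            motion=int(mkey[1:]),
                            trial_index=int(tkey[1:]),
                            day=int(dkey[1:]),
                            subject=skey[1:],
                            channel_names=names,
                        ))
    trials.sort(key=lambda t: (t.subject, t.day, t.motion, t.trial_index))
    return trials


def save_trial_csv(path: str | Path, trial: EmgTrial) -> None:
    """CSV fallback: one file per trial, columns = channels, header = muscles."""
    pd.DataFrame(trial.samples.T, columns=list(trial.channel_names)).to_csv(
        path, index=False
    )


def load_trial_csv(
    path: str | Path,
    sampling_rate: float,
    motion: int,
    trial_index: int,
    day: int,
    subject: str,
) -> EmgTrial:
    df = pd.read_csv(path)
    return EmgTrial(
        samples=df.to_numpy().T,
        sampling_rate=sampling_rate,
        motion=motion,
        trial_index=trial_index,
        day=day,
        subject=subject,
        channel_names=tuple(df.columns),
    )


# ---------------------------------------------------------------------------
# Feature-matrix persistence
# ---------------------------------------------------------------------------

def feature_frame(values: np.ndarray, meta: pd.DataFrame) -> pd.DataFrame:
    """Assemble a feature matrix and its provenance into one DataFrame.

    Columns are ``dim_0001..dim_NNNN`` followed by
    ``label, subject, day, trial, window``.
    """
    n, d = values.shape
    if len(meta) != n:
        raise ValueError("meta rows must match feature rows")
    cols = [f"dim_{i + 1:04d}" for i in range(d)]
    df = pd.DataFrame(values, columns=cols)
    for c in ["label", "subject", "day", "trial", "window"]:
        df[c] = meta[c].to_numpy()
    return df


def save_features(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


def load_features(path: str | Path) -> tuple[np.ndarray, pd.DataFrame]:
    """Load a feature CSV; returns (values, meta)."""
    df = pd.read_csv(path)
    meta_cols = ["label", "subject", "day", "trial", "window"]
    missing = [c for c in meta_cols if c not in df.columns]
    if missing:
        raise SchemaError(f"feature file lacks columns {missing}")
    dim_cols = [c for c in df.columns if c.startswith("dim_")]
    return df[dim_cols].to_numpy(dtype=float), df[meta_cols].copy()


# ---------------------------------------------------------------------------
# Acquisition-style filtering (utility for external raw data; synthetic
# signals are generated band-limited and do not pass through here)
# ---------------------------------------------------------------------------

def bandpass_notch(
    x: np.ndarray,
    sampling_rate: float,
    low_hz: float = 20.0,
    high_hz: float = 450.0,
    notch_hz: float | None = 50.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase band-pass (Butterworth) plus optional mains notch."""
    sos = _signal.butter(
        order, [low_hz, high_hz], btype="bandpass", fs=sampling_rate,
        output="sos",
    )
    y = _signal.sosfiltfilt(sos, x, axis=-1)
    if notch_hz is not None:
        b, a = _signal.iirnotch(notch_hz, Q=30.0, fs=sampling_rate)
        y = _signal.filtfilt(b, a, y, axis=-1)
    return y
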