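"""Synthetic multi-day, multi-subject surface-EMG with electrode-shift drift.

The signal model is the standard phenomenological one: each channel is
band-limited Gaussian noise whose amplitude tracks muscle activation.  A
subject is a profile of per-motion x per-channel activation amplitudes
(11 x 7) plus per-channel spectral bands; the five single motions (SF, SA,
SPF, EF, EE) get distinct 2-4 channel synergy patterns over the seven
muscles and the six compound motions are sums of their shoulder and elbow
constituents, which makes neighbouring classes naturally confusable.

Day-to-day drift emulates electrode re-donning with three components, all
scaled by a single shift magnitude ``s``:

* per-channel gain (lognormal, sigma = 0.25 s) — electrode moved along the
  muscle belly / impedance changed;
* channel crosstalk (near-identity row-stochastic mixing, off-diagonal
  mass kappa = 0.15 s) — electrode moved toward a neighbouring muscle;
* spectral offset (normal, sigma = 10 s Hz) — changed electrode-fibre
  geometry shifts the power spectrum.

Day 1 is always the identity shift, and ``s = 0`` makes every day
identically distributed.  Signal amplitudes are calibrated so typical
sample magnitudes are of order 10-100 native units, which keeps the
default slope-sign-change (10) and zero-crossing (25) thresholds
meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
from scipy import signal as _signal

from .data import DEFAULT_CHANNEL_NAMES, EmgTrial

#: Channel synergies of the five single motions (channel indices into
#: DEFAULT_CHANNEL_NAMES): strong activations per motion.
_BASE_SYNERGIES: dict[str, tuple[int, ...]] = {
    "SF": (0, 1),        # anterior + middle deltoid
    "SA": (1, 2),        # middle + posterior deltoid
    "SPF": (2, 4),       # posterior deltoid + triceps
    "EF": (3, 5),        # biceps + brachioradialis
    "EE": (4, 6),        # triceps + flexor carpi radialis
}
_SHOULDER = ("SF", "SA", "SPF")
_ELBOW = ("EF", "EE")


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject activation patterns and spectral characteristics."""

    amplitudes: np.ndarray      # (n_motions, channels), positive
    center_freqs: np.ndarray    # (channels,), Hz
    bandwidths: np.ndarray      # (channels,), Hz
    noise_floor: float          # RMS of the additive white noise floor
    seed: int


@dataclass(frozen=True)
class ShiftModel:
    """Per-day electrode-shift parameters (identity on day 1)."""

    gains: np.ndarray           # (channels,)
    mixing: np.ndarray          # (channels, channels), rows sum to ~1
    freq_offsets: np.ndarray    # (channels,), Hz
    magnitude: float


@dataclass(frozen=True)
class BenchmarkConfig:
    """The study conditions of the multi-day benchmark.

    Defaults: 12 subjects x 5 days x 11 motions x 5 trials, 7-s trials at
    1500 Hz over 7 channels, of which the central 5 s are analysed.
    ``shift`` is the electrode-shift magnitude ``s``.
    """

    n_subjects: int = 12
    n_days: int = 5
    n_motions: int = 11
    n_trials: int = 5
    trial_s: float = 7.0
    keep_central_s: float = 5.0
    sampling_rate: float = 1500.0
    n_channels: int = 7
    shift: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_days", "n_motions", "n_trials"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def _rng_for(master_seed: int, *key: int) -> np.random.Generator:
    """Independent stream per (subject, day, motion, trial) tuple."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(master_seed), spawn_key=tuple(key))
    )


def generate_subject_profile(
    seed: int,
    n_motions: int = 11,
    n_channels: int = 7,
    strong_lo: float = 45.0,
    strong_hi: float = 85.0,
    weak_lo: float = 6.0,
    weak_hi: float = 12.0,
    max_pattern_corr: float = 0.95,
) -> SubjectProfile:
    """Draw one subject's activation-amplitude matrix and channel spectra.

    Each single motion activates its 2-channel synergy strongly (uniform
    ``strong_lo..strong_hi``) over a weak baseline; compound motions sum
    their constituents' activations channel-wise.  Profiles are redrawn
    until all pairwise motion-pattern correlations fall below
    ``max_pattern_corr``.
    """
    rng = _rng_for(seed, 0)
    names = list(_BASE_SYNERGIES)
    for _attempt in range(100):
        base = {}
        for m in names:
            amp = rng.uniform(weak_lo, weak_hi, size=n_channels)
            for ch in _BASE_SYNERGIES[m]:
                amp[ch] = rng.uniform(strong_lo, strong_hi)
            base[m] = amp
        rows = [base[m] for m in names]
        for sh in _SHOULDER:
            for el in _ELBOW:
                # compound motions share effort: constituents at ~75%
                rows.append(0.75 * (base[sh] + base[el]))
        amplitudes = np.array(rows[:n_motions])
        if n_motions > len(rows):
            extra = rng.uniform(weak_lo, strong_hi, size=(n_motions - len(rows), n_channels))
            amplitudes = np.vstack([amplitudes, extra])
        corr = np.corrcoef(amplitudes)
        off = corr[~np.eye(len(corr), dtype=bool)]
        if np.all(off < max_pattern_corr):
            break
    else:
        raise RuntimeError("could not draw sufficiently distinct motion patterns")
    center = rng.uniform(60.0, 150.0, size=n_channels)
    bw = rng.uniform(50.0, 90.0, size=n_channels)
    # noise floor at -20 dB relative to the weakest strong activation
    weakest_active = amplitudes.max(axis=1).min()
    return SubjectProfile(
        amplitudes=amplitudes,
        center_freqs=center,
        bandwidths=bw,
        noise_floor=float(weakest_active / 10.0),
        seed=int(seed),
    )


def generate_shift_model(
    master_seed: int,
    subject: int,
    day: int,
    s: float,
    n_channels: int = 7,
    sigma_gain: float = 0.25,
    kappa: float = 0.15,
    sigma_freq: float = 10.0,
) -> ShiftModel:
    """Electrode-shift parameters of one (subject, day); day 1 is identity."""
    if day == 1 or s == 0:
        return ShiftModel(
            gains=np.ones(n_channels),
            mixing=np.eye(n_channels),
            freq_offsets=np.zeros(n_channels),
            magnitude=0.0,
        )
    rng = _rng_for(master_seed, subject, day)
    gains = rng.lognormal(mean=0.0, sigma=sigma_gain * s, size=n_channels)
    mix = np.eye(n_channels) + kappa * s * np.abs(
        rng.normal(size=(n_channels, n_channels))
    ) * (1 - np.eye(n_channels))
    mix /= mix.sum(axis=1, keepdims=True)
    offsets = rng.normal(scale=sigma_freq * s, size=n_channels)
    return ShiftModel(
        gains=gains, mixing=mix, freq_offsets=offsets, magnitude=float(s)
    )


def _activation_envelope(
    rng: np.random.Generator,
    n: int,
    rate: float,
    sigma: float,
    cutoff_hz: float = 1.5,
) -> np.ndarray:
    """Slow lognormal amplitude-modulation envelope (mean ~1).

    Models the second-to-second effort fluctuation of a held contraction;
    ``sigma`` is the log-scale standard deviation of the modulation.
    """
    sos = _signal.butter(2, cutoff_hz, btype="lowpass", fs=rate, output="sos")
    z = _signal.sosfilt(sos, rng.normal(size=n))
    z = z / max(np.std(z), 1e-12)
    return np.exp(sigma * z - sigma**2 / 2.0)


def _band_limited_noise(
    rng: np.random.Generator,
    n: int,
    rate: float,
    center: float,
    bandwidth: float,
) -> np.ndarray:
    """Unit-RMS Gaussian noise band-passed around ``center`` Hz."""
    lo = max(center - bandwidth / 2.0, 20.0)
    hi = min(center + bandwidth / 2.0, 450.0)
    sos = _signal.butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")
    x = _signal.sosfilt(sos, rng.normal(size=n))
    return x / np.sqrt(np.mean(x * x))


def synthesize_trial(
    profile: SubjectProfile,
    shift: ShiftModel,
    motion: int,
    day: int,
    trial_index: int,
    subject: str = "1",
    master_seed: int = 0,
    trial_s: float = 7.0,
    sampling_rate: float = 1500.0,
    trial_jitter_sigma: float = 0.08,
    envelope_sigma: float = 0.45,
) -> EmgTrial:
    """Synthesize one 7-s trial of one motion under a day's electrode shift.

    Per channel: band-limited unit-RMS noise (channel band plus the day's
    spectral offset), amplitude-modulated by a slow effort envelope and
    scaled by activation amplitude x day gain x a lognormal trial-to-trial
    jitter; channels are then mixed by the day's crosstalk matrix and a
    white-noise floor is added.
    """
    if not 1 <= motion <= profile.amplitudes.shape[0]:
        raise ValueError(f"motion {motion} out of range")
    n_channels = profile.amplitudes.shape[1]
    n = int(round(trial_s * sampling_rate))
    rng = _rng_for(master_seed, int(subject), day, motion, trial_index)
    clean = np.empty((n_channels, n))
    for c in range(n_channels):
        carrier = _band_limited_noise(
            rng, n, sampling_rate,
            profile.center_freqs[c] + shift.freq_offsets[c],
            profile.bandwidths[c],
        )
        envelope = _activation_envelope(rng, n, sampling_rate, envelope_sigma)
        jitter = rng.lognormal(mean=0.0, sigma=trial_jitter_sigma)
        clean[c] = (
            profile.amplitudes[motion - 1, c] * shift.gains[c] * jitter
        ) * envelope * carrier
    mixed = shift.mixing @ clean
    mixed += rng.normal(scale=profile.noise_floor, size=mixed.shape)
    return EmgTrial(
        samples=mixed,
        sampling_rate=sampling_rate,
        motion=motion,
        trial_index=trial_index,
        day=day,
        subject=str(subject),
        channel_names=DEFAULT_CHANNEL_NAMES[:n_channels],
    )


def generate_subject_day(
    config: BenchmarkConfig, subject: int, day: int
) -> list[EmgTrial]:
    """All trials (n_motions x n_trials) of one subject on one day."""
    profile = generate_subject_profile(
        _subject_profile_seed(config, subject),
        n_motions=config.n_motions,
        n_channels=config.n_channels,
    )
    shift = generate_shift_model(
        config.seed, subject, day, config.shift, config.n_channels
    )
    return [
        synthesize_trial(
            profile, shift, motion, day, trial,
            subject=str(subject), master_seed=config.seed,
            trial_s=config.trial_s, sampling_rate=config.sampling_rate,
        )
        for motion in range(1, config.n_motions + 1)
        for trial in range(1, config.n_trials + 1)
    ]


def _subject_profile_seed(config: BenchmarkConfig, subject: int) -> int:
    # profile seed derived from the master seed; kept below 2**31
    return (config.seed * 1_000 + subject) % (2**31 - 1)


def generate_benchmark(
    config: BenchmarkConfig = BenchmarkConfig(),
) -> Iterator[tuple[int, int, list[EmgTrial]]]:
    """Yield ``(subject, day, trials)`` for the whole benchmark grid.

    Fully reproducible from the master seed: every trial draws from its own
    derived stream, so any (subject, day, motion, trial) regenerates
    identically in isolation.
    """
    for subject in range(1, config.n_subjects + 1):
        for day in range(1, config.n_days + 1):
            yield subject, day, generate_subject_day(config, subject, day)
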