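"""The 14 window-level EMG features and the 294-dimensional feature vector.

Per channel the features are, in layout order:

====== ====== =====================================================
name   dims   description
====== ====== =====================================================
MAV    1      mean absolute value
VAR    1      uncentred variance, sum(x^2)/(N-1)
RMS    1      root mean square
SSC    1      slope-sign changes above an amplitude-product threshold
ZC     1      zero crossings with an amplitude-difference threshold
WL     1      waveform length, sum |x[i+1]-x[i]|
AR5    5      5th-order autoregressive coefficients (Burg)
AR6    6      6th-order autoregressive coefficients (Burg)
CC     5      cepstral coefficients from the AR6 fit
MNF    1      mean frequency of the boxcar periodogram
MDF    1      median frequency of the boxcar periodogram
WTWL   6      waveform length of db2 wavelet sub-bands cA5, cD1..cD5
WTVAR  6      uncentred variance of the same sub-bands
WTMAV  6      mean absolute value of the same sub-bands
====== ====== =====================================================

42 values per channel, 294 for a 7-channel window.  The full vector is
channel-major: all 42 features of channel 1, then channel 2, and so on.

VAR is deliberately the *uncentred* second moment: band-passed EMG is
essentially zero-mean, and the uncentred form is the convention in the
myoelectric-control feature literature this package follows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt
from scipy import signal as _signal

from .data import Window, feature_frame

#: (feature name, dimensions per channel) in canonical order.
FEATURE_DIMS: tuple[tuple[str, int], ...] = (
    ("MAV", 1), ("VAR", 1), ("RMS", 1), ("SSC", 1), ("ZC", 1), ("WL", 1),
    ("AR5", 5), ("AR6", 6), ("CC", 5), ("MNF", 1), ("MDF", 1),
    ("WTWL", 6), ("WTVAR", 6), ("WTMAV", 6),
)

FEATURE_NAMES: tuple[str, ...] = tuple(name for name, _ in FEATURE_DIMS)

#: Wavelet sub-bands used for the time-frequency features, in layout order.
WT_BANDS: tuple[str, ...] = ("cA5", "cD1", "cD2", "cD3", "cD4", "cD5")


@dataclass(frozen=True)
class FeatureParams:
    """Tunable constants of the extractors.

    ``ssc_threshold`` (amplitude-squared units) and ``zc_threshold``
    (amplitude units) suppress noise-driven counts; their defaults of 10 and
    25 assume signals whose typical sample magnitudes are of order 10-100
    native units.  ``ar_method`` may be "burg" (default; stable on short
    windows) or "yule-walker".
    """

    ssc_threshold: float = 10.0
    zc_threshold: float = 25.0
    ar_orders: tuple[int, ...] = (5, 6)
    cc_order: int = 5
    wavelet_name: str = "db2"
    wavelet_levels: int = 5
    wavelet_mode: str = "symmetric"
    ar_method: str = "burg"
    cc_literal_recursion: bool = False

    def __post_init__(self) -> None:
        if self.ssc_threshold < 0 or self.zc_threshold < 0:
            raise ValueError("thresholds must be non-negative")
        if self.cc_order > max(self.ar_orders):
            raise ValueError("cc_order cannot exceed the largest AR order")
        if self.wavelet_levels < 1:
            raise ValueError("wavelet_levels must be >= 1")


class FeatureLayout:
    """Index map of the concatenated feature vector.

    Channel-major: channel ``c`` occupies the 42-dim block
    ``[42*c, 42*(c+1))``, ordered per :data:`FEATURE_DIMS` within the block.
    """

    def __init__(self, n_channels: int = 7):
        self.n_channels = int(n_channels)
        self.per_channel = sum(d for _, d in FEATURE_DIMS)
        self.total = self.per_channel * self.n_channels
        offsets: dict[str, int] = {}
        pos = 0
        for name, dim in FEATURE_DIMS:
            offsets[name] = pos
            pos += dim
        self._offsets = offsets
        self._dims = dict(FEATURE_DIMS)

    def index(self, feature: str, channel: int, component: int = 0) -> int:
        """Flat index of one feature component of one channel (0-based)."""
        if feature not in self._dims:
            raise KeyError(f"unknown feature {feature!r}")
        if not 0 <= channel < self.n_channels:
            raise IndexError(f"channel {channel} out of range")
        if not 0 <= component < self._dims[feature]:
            raise IndexError(
                f"{feature} has {self._dims[feature]} components"
            )
        return channel * self.per_channel + self._offsets[feature] + component

    def slice(self, feature: str, channel: int) -> slice:
        start = self.index(feature, channel, 0)
        return slice(start, start + self._dims[feature])

    def group_indices(self, feature: str) -> np.ndarray:
        """All flat indices of one feature across every channel."""
        return np.concatenate([
            np.arange(self.slice(feature, c).start, self.slice(feature, c).stop)
            for c in range(self.n_channels)
        ])

    def column_names(self) -> list[str]:
        names = []
        for c in range(self.n_channels):
            for fname, dim in FEATURE_DIMS:
                if dim == 1:
                    names.append(f"ch{c + 1}_{fname}")
                else:
                    names.extend(f"ch{c + 1}_{fname}_{k + 1}" for k in range(dim))
        return names


# ---------------------------------------------------------------------------
# Time-domain features
# ---------------------------------------------------------------------------

def amplitude_features(x: np.ndarray) -> dict[str, float]:
    """MAV, VAR, RMS and WL of one window channel.

    VAR is the uncentred second moment ``sum(x^2)/(N-1)``.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if n < 2:
        raise ValueError("need at least 2 samples (VAR undefined)")
    return {
        "MAV": float(np.mean(np.abs(x))),
        "VAR": float(np.sum(x * x) / (n - 1)),
        "RMS": float(np.sqrt(np.mean(x * x))),
        "WL": float(np.sum(np.abs(np.diff(x)))),
    }


def threshold_features(
    x: np.ndarray, params: FeatureParams = FeatureParams()
) -> dict[str, int]:
    """Slope-sign-change and zero-crossing counts.

    SSC counts interior samples where the product of the backward and
    forward differences reaches ``ssc_threshold`` (a local extremum sharp
    enough to exceed the noise floor).  ZC counts adjacent sign changes
    whose amplitude step reaches ``zc_threshold``.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 3:
        raise ValueError("SSC needs at least 3 samples")
    ssc = int(np.count_nonzero(
        (x[1:-1] - x[:-2]) * (x[1:-1] - x[2:]) >= params.ssc_threshold
    ))
    zc = int(np.count_nonzero(
        (x[:-1] * x[1:] < 0)
        & (np.abs(x[:-1] - x[1:]) >= params.zc_threshold)
    ))
    return {"SSC": ssc, "ZC": zc}


def _ssc_batch(X: np.ndarray, threshold: float) -> np.ndarray:
    d1 = X[..., 1:-1] - X[..., :-2]
    d2 = X[..., 1:-1] - X[..., 2:]
    return np.count_nonzero(d1 * d2 >= threshold, axis=-1).astype(float)


def _zc_batch(X: np.ndarray, threshold: float) -> np.ndarray:
    prod = X[..., :-1] * X[..., 1:]
    step = np.abs(X[..., :-1] - X[..., 1:])
    return np.count_nonzero((prod < 0) & (step >= threshold), axis=-1).astype(float)


# ---------------------------------------------------------------------------
# Autoregressive and cepstral features
# ---------------------------------------------------------------------------

def ar_burg_batch(X: np.ndarray, order: int) -> np.ndarray:
    """Burg AR coefficients for a batch of signals.

    Coefficients are in prediction convention, ``x[i] ~ sum_k a_k x[i-k]``,
    so an AR(1) process with coefficient 0.9 yields ``a_1`` near +0.9.
    Constant (zero-variance) signals yield an all-zero coefficient vector
    with a warning rather than an error.

    Parameters
    ----------
    X : ndarray (..., N)
    order : model order p < N
    """
    X = np.asarray(X, dtype=float)
    lead, N = X.shape[:-1], X.shape[-1]
    if N <= order:
        raise ValueError(f"need more than {order} samples, got {N}")
    x = X.reshape(-1, N)
    B = x.shape[0]
    # lattice recursion; a holds the polynomial A(z) = 1 + a1 z^-1 + ...
    a = np.zeros((B, 0))
    ef = x[:, 1:].copy()
    eb = x[:, :-1].copy()
    dead = np.zeros(B, dtype=bool)
    for _ in range(order):
        den = np.einsum("ij,ij->i", ef, ef) + np.einsum("ij,ij->i", eb, eb)
        dead |= den <= 0
        den = np.where(dead, 1.0, den)
        k = -2.0 * np.einsum("ij,ij->i", ef, eb) / den
        k[dead] = 0.0
        a = np.concatenate([a + k[:, None] * a[:, ::-1], k[:, None]], axis=1)
        ef, eb = (
            ef[:, 1:] + k[:, None] * eb[:, 1:],
            eb[:, :-1] + k[:, None] * ef[:, :-1],
        )
    if dead.any():
        warnings.warn(
            "constant signal(s) encountered; AR coefficients set to zero",
            RuntimeWarning,
            stacklevel=2,
        )
        a[dead] = 0.0
    return (-a).reshape(*lead, order)


def _ar_yule_walker_batch(X: np.ndarray, order: int) -> np.ndarray:
    """Yule-Walker AR fit (biased autocovariance), batch version."""
    X = np.asarray(X, dtype=float)
    lead, N = X.shape[:-1], X.shape[-1]
    if N <= order:
        raise ValueError(f"need more than {order} samples, got {N}")
    x = X.reshape(-1, N)
    # biased autocovariances r_0..r_p
    r = np.stack(
        [np.einsum("ij,ij->i", x[:, : N - k], x[:, k:]) / N
         for k in range(order + 1)],
        axis=1,
    )
    out = np.zeros((x.shape[0], order))
    from scipy.linalg import solve_toeplitz

    for b in range(x.shape[0]):
        if r[b, 0] <= 0:
            warnings.warn(
                "constant signal; AR coefficients set to zero",
                RuntimeWarning, stacklevel=2,
            )
            continue
        out[b] = solve_toeplitz(r[b, :order], r[b, 1:])
    return out.reshape(*lead, order)


def ar_coefficients(
    x: np.ndarray, order: int, method: str = "burg"
) -> np.ndarray:
    """AR coefficients of one window channel (see :func:`ar_burg_batch`)."""
    x = np.asarray(x, dtype=float)
    if method == "burg":
        return ar_burg_batch(x[None, :], order)[0]
    if method in ("yule-walker", "yw"):
        return _ar_yule_walker_batch(x[None, :], order)[0]
    raise ValueError(f"unknown AR method {method!r}")


def cepstral_coefficients(
    ar: np.ndarray, k_max: int, literal: bool = False
) -> np.ndarray:
    """Cepstral coefficients from AR coefficients.

    Standard recursion: ``c_1 = -a_1`` and for k >= 2

        c_k = -a_k - sum_{i=1}^{k-1} (1 - i/k) a_i c_{k-i}.

    ``literal=True`` switches to a variant that keeps the a-index fixed at k
    inside the sum (retained for comparison; not recommended).
    """
    ar = np.asarray(ar, dtype=float)
    if k_max > ar.shape[-1]:
        raise ValueError("k_max cannot exceed the AR order")
    return _cepstral_batch(ar, k_max, literal)


def _cepstral_batch(ar: np.ndarray, k_max: int, literal: bool = False) -> np.ndarray:
    ar = np.asarray(ar, dtype=float)
    lead = ar.shape[:-1]
    a2 = ar.reshape(-1, ar.shape[-1])
    c = np.zeros((a2.shape[0], k_max))
    for k in range(1, k_max + 1):
        acc = np.zeros(a2.shape[0])
        for i in range(1, k):
            coef = 1.0 - i / k
            a_term = a2[:, k - 1] if literal else a2[:, i - 1]
            c_term = c[:, k - 2] if literal else c[:, k - i - 1]
            acc += coef * a_term * c_term
        c[:, k - 1] = -a2[:, k - 1] - acc
    return c.reshape(*lead, k_max)


# ---------------------------------------------------------------------------
# Frequency-domain features
# ---------------------------------------------------------------------------

def _periodogram(X: np.ndarray, sampling_rate: float):
    """One-sided boxcar periodogram, no detrending; bin width rate/N."""
    return _signal.periodogram(
        X, fs=sampling_rate, window="boxcar", detrend=False, axis=-1
    )


def spectral_features(
    x: np.ndarray, sampling_rate: float
) -> dict[str, float]:
    """Mean (MNF) and median (MDF) frequency of the window's power spectrum.

    MNF is the power-weighted mean of the bin frequencies; MDF is the bin
    frequency at which cumulative power first reaches half of the total.
    ``half_total_power`` (half the summed spectrum, a power) is included for
    completeness.
    """
    x = np.asarray(x, dtype=float)
    f, p = _periodogram(x, sampling_rate)
    total = p.sum()
    if total <= 0:
        raise ValueError("all-zero window: spectral moments undefined")
    mnf = float((f * p).sum() / total)
    mdf_idx = int(np.searchsorted(np.cumsum(p), total / 2.0))
    return {
        "MNF": mnf,
        "MDF": float(f[mdf_idx]),
        "half_total_power": float(total / 2.0),
    }


def _spectral_batch(X: np.ndarray, sampling_rate: float):
    f, p = _periodogram(X, sampling_rate)
    total = p.sum(axis=-1)
    if np.any(total <= 0):
        raise ValueError("all-zero window: spectral moments undefined")
    mnf = (p * f).sum(axis=-1) / total
    cum = np.cumsum(p, axis=-1)
    half = total / 2.0
    idx = (cum < half[..., None]).sum(axis=-1)
    mdf = f[idx]
    return mnf, mdf


# ---------------------------------------------------------------------------
# Wavelet (time-frequency) features
# ---------------------------------------------------------------------------

def _wavedec_bands(
    X: np.ndarray, params: FeatureParams
) -> list[np.ndarray]:
    """db2 decomposition coefficients ordered as :data:`WT_BANDS`."""
    wavelet = pywt.Wavelet(params.wavelet_name)
    min_len = (wavelet.dec_len - 1) * 2 ** params.wavelet_levels
    if X.shape[-1] < min_len:
        raise ValueError(
            f"window of {X.shape[-1]} samples too short for "
            f"{params.wavelet_levels}-level {params.wavelet_name} "
            f"decomposition (need >= {min_len})"
        )
    coeffs = pywt.wavedec(
        X, wavelet, mode=params.wavelet_mode, level=params.wavelet_levels,
        axis=-1,
    )
    # wavedec returns [cA_L, cD_L, ..., cD1]; reorder to cA5, cD1..cD5
    return [coeffs[0]] + coeffs[1:][::-1]


def wavelet_features(
    x: np.ndarray, params: FeatureParams = FeatureParams()
) -> dict[str, np.ndarray]:
    """WTWL, WTVAR, WTMAV over the six db2 sub-bands of one window channel.

    Each value is a length-6 vector ordered (cA5, cD1, cD2, cD3, cD4, cD5).
    """
    x = np.asarray(x, dtype=float)
    bands = _wavedec_bands(x, params)
    wl = np.array([np.sum(np.abs(np.diff(b))) for b in bands])
    var = np.array([np.sum(b * b) / (b.shape[-1] - 1) for b in bands])
    mav = np.array([np.mean(np.abs(b)) for b in bands])
    return {"WTWL": wl, "WTVAR": var, "WTMAV": mav}


def _wavelet_batch(X: np.ndarray, params: FeatureParams):
    bands = _wavedec_bands(X, params)
    wl = np.stack(
        [np.sum(np.abs(np.diff(b, axis=-1)), axis=-1) for b in bands], axis=-1
    )
    var = np.stack(
        [np.sum(b * b, axis=-1) / (b.shape[-1] - 1) for b in bands], axis=-1
    )
    mav = np.stack([np.mean(np.abs(b), axis=-1) for b in bands], axis=-1)
    return wl, var, mav


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def extract_feature_matrix(
    windows: np.ndarray,
    sampling_rate: float,
    layout: FeatureLayout | None = None,
    params: FeatureParams = FeatureParams(),
) -> np.ndarray:
    """Feature matrix for a batch of windows.

    Parameters
    ----------
    windows : ndarray, shape (n_windows, channels, N)

    Returns
    -------
    ndarray, shape (n_windows, layout.total), channel-major layout order.
    """
    windows = np.asarray(windows, dtype=float)
    if windows.ndim != 3:
        raise ValueError("windows must have shape (n_windows, channels, N)")
    n_win, n_ch, N = windows.shape
    if layout is None:
        layout = FeatureLayout(n_ch)
    if layout.n_channels != n_ch:
        raise ValueError(
            f"layout expects {layout.n_channels} channels, window has {n_ch}"
        )
    if N < 2:
        raise ValueError("windows must hold at least 2 samples")

    X = windows  # (n_win, ch, N)
    out = np.empty((n_win, layout.total))

    mav = np.mean(np.abs(X), axis=-1)
    var = np.sum(X * X, axis=-1) / (N - 1)
    rms = np.sqrt(np.mean(X * X, axis=-1))
    wl = np.sum(np.abs(np.diff(X, axis=-1)), axis=-1)
    ssc = _ssc_batch(X, params.ssc_threshold)
    zc = _zc_batch(X, params.zc_threshold)
    ar_fit = ar_burg_batch if params.ar_method == "burg" else _ar_yule_walker_batch
    ar5 = ar_fit(X, 5)
    ar6 = ar_fit(X, 6)
    cc = _cepstral_batch(ar6, params.cc_order, params.cc_literal_recursion)
    mnf, mdf = _spectral_batch(X, sampling_rate)
    wtwl, wtvar, wtmav = _wavelet_batch(X, params)

    per_channel_values = {
        "MAV": mav[..., None], "VAR": var[..., None], "RMS": rms[..., None],
        "SSC": ssc[..., None], "ZC": zc[..., None], "WL": wl[..., None],
        "AR5": ar5, "AR6": ar6, "CC": cc,
        "MNF": mnf[..., None], "MDF": mdf[..., None],
        "WTWL": wtwl, "WTVAR": wtvar, "WTMAV": wtmav,
    }
    for c in range(n_ch):
        for fname, _dim in FEATURE_DIMS:
            out[:, layout.slice(fname, c)] = per_channel_values[fname][:, c]
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite feature values produced")
    return out


def extract_feature_vector(
    window: Window,
    layout: FeatureLayout | None = None,
    params: FeatureParams = FeatureParams(),
    sampling_rate: float = 1500.0,
) -> np.ndarray:
    """The concatenated feature vector of one :class:`~emgadapt.data.Window`."""
    return extract_feature_matrix(
        window.samples[None, :, :], sampling_rate, layout, params
    )[0]


def extract_features_frame(
    windows: np.ndarray,
    meta: pd.DataFrame,
    sampling_rate: float,
    layout: FeatureLayout | None = None,
    params: FeatureParams = FeatureParams(),
) -> pd.DataFrame:
    """Feature matrix plus provenance as one persistable DataFrame."""
    values = extract_feature_matrix(windows, sampling_rate, layout, params)
    return feature_frame(values, meta)
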