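"""Time–frequency PSD frames and log band-power features.

The spectral pipeline is: per-second periodogram frames at 1-Hz
resolution over 1–40 Hz (:func:`psd_frames`), three-bin temporal
smoothing (:func:`smooth_frames`), band powers by summing 1-Hz bins
(:func:`band_powers`), and finally one ``log10(mean band power)``
feature per band and channel (:func:`band_features`) — 6 bands × 2
channels = 12 EEG features per subject.

Band edges follow the conventional clinical definitions used here:
delta 1–3, theta 3–7, alpha 8–13, beta 13–30, sigma 12–15 and gamma
25–40 Hz.  Sigma deliberately overlaps alpha and beta.  Shared printed
edges (3, 13, 25 Hz) are resolved with a half-open ``[lo, hi)``
convention: the 1-Hz bin starting at ``f`` Hz belongs to a band iff
``lo <= f < hi``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import ConfigurationError, InsufficientDataError

#: Canonical band edges in Hz, in feature order.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1, 3),
    "theta": (3, 7),
    "alpha": (8, 13),
    "beta": (13, 30),
    "sigma": (12, 15),
    "gamma": (25, 40),
}

#: Channel suffixes: AF7 is the left electrode, AF8 the right.
CHANNEL_SUFFIX = ("L", "R")

#: Canonical order of the 12 EEG feature names.
FEATURE_NAMES: list[str] = [
    f"{band}_{side}" for band in BANDS for side in CHANNEL_SUFFIX
]

F_LO, F_HI = 1, 40  # analysed frequency range, Hz

__all__ = [
    "BANDS",
    "FEATURE_NAMES",
    "SpectralFrames",
    "psd_frames",
    "smooth_frames",
    "band_powers",
    "band_bins",
    "band_features",
    "eeg_features",
]


@dataclass
class SpectralFrames:
    """PSD frames ``power[channel, time_bin, freq_bin]`` in µV²/Hz.

    Frequency bins are 1 Hz wide; ``freqs[k]`` is the left edge of bin k
    (1..40 Hz).  Time bins excluded by an artifact mask hold NaN.
    """

    power: np.ndarray  # (n_channels, n_bins, 40)
    fs: float
    freqs: np.ndarray = field(
        default_factory=lambda: np.arange(F_LO, F_HI + 1, dtype=float)
    )

    @property
    def n_bins(self) -> int:
        return self.power.shape[1]

    def valid_bins(self, channel: int) -> np.ndarray:
        return ~np.isnan(self.power[channel, :, 0])


def _segment_data(seg) -> tuple[np.ndarray, float]:
    """Accept a Segment or an EEGRecording."""
    return np.asarray(seg.data, dtype=float), float(seg.fs)


def psd_frames(segment, mask=None, window: str = "hann") -> SpectralFrames:
    """Per-second periodogram frames binned at 1 Hz over 1–40 Hz.

    Each 1-s time bin is an independent windowed periodogram (density
    scaling, µV²/Hz).  ``mask`` is an :class:`~frontoboost.preprocess.
    ArtifactMask`; its excluded bins become NaN frames.  At least three
    valid bins are required.
    """
    data, fs = _segment_data(segment)
    if abs(fs - round(fs)) > 1e-9:
        raise ConfigurationError("psd_frames requires an integer sampling rate")
    spr = int(round(fs))
    if spr < 2 * F_HI:
        raise ConfigurationError(
            f"fs={fs} cannot resolve the {F_HI} Hz analysis ceiling"
        )
    n_bins = data.shape[1] // spr
    frames_in = data[:, : n_bins * spr].reshape(data.shape[0], n_bins, spr)
    _, pxx = signal.periodogram(
        frames_in, fs=fs, window=window, detrend=False, scaling="density",
        axis=-1,
    )
    power = pxx[..., F_LO : F_HI + 1]  # 40 bins with left edges 1..40 Hz
    power = np.ascontiguousarray(power)

    if mask is not None:
        excl = np.asarray(mask.excluded, dtype=bool)
        m = min(n_bins, excl.shape[1])
        for ch in range(power.shape[0]):
            power[ch, :m][excl[ch, :m]] = np.nan
    valid = np.sum(~np.isnan(power[:, :, 0]), axis=1)
    if valid.min() < 3:
        raise InsufficientDataError(
            f"need >=3 valid 1-s bins per channel, got {valid.tolist()}"
        )
    return SpectralFrames(power=power, fs=fs)


def smooth_frames(frames: SpectralFrames) -> SpectralFrames:
    """Average each time bin with its two neighbours.

    The smoothed frame is the mean of the available members of
    ``{P[t-1], P[t], P[t+1]}`` — boundary bins and masked neighbours are
    simply skipped.  Bins that are themselves masked stay missing.
    """
    p = frames.power
    missing = np.isnan(p)
    padded = np.concatenate(
        [np.full_like(p[:, :1], np.nan), p, np.full_like(p[:, :1], np.nan)],
        axis=1,
    )
    stack = np.stack([padded[:, :-2], padded[:, 1:-1], padded[:, 2:]])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        sm = np.nanmean(stack, axis=0)
    sm[missing] = np.nan
    return SpectralFrames(power=sm, fs=frames.fs, freqs=frames.freqs.copy())


def band_bins(lo: float, hi: float) -> np.ndarray:
    """Indices into the 1..40 Hz frame axis for band ``[lo, hi)``."""
    if not (F_LO <= lo < hi <= F_HI):
        raise ConfigurationError(
            f"band [{lo}, {hi}) outside the {F_LO}–{F_HI} Hz analysis range"
        )
    f_left = np.arange(F_LO, F_HI + 1)  # left edge of each 1-Hz bin
    return np.where((f_left >= lo) & (f_left < hi))[0]


def band_powers(
    frames: SpectralFrames, bands: dict[str, tuple[float, float]] | None = None
) -> dict[str, np.ndarray]:
    """Per-bin band power (µV²) by summing 1-Hz bins under ``[lo, hi)``."""
    bands = BANDS if bands is None else bands
    out = {}
    for name, (lo, hi) in bands.items():
        idx = band_bins(lo, hi)
        out[name] = frames.power[:, :, idx].sum(axis=2)
    return out


def band_features(
    powers: dict[str, np.ndarray],
    eps: float = 1e-12,
    feature_names: bool = True,
    averaging: str = "log_of_mean",
):
    """12 log band-power features: ``log10(mean over valid bins)``.

    By default the temporal mean is taken before the logarithm;
    ``averaging="mean_of_log"`` instead averages the per-bin log
    powers, since either reading of "log PSD averaged over the test"
    is defensible.  Non-positive band power (possible only for
    degenerate signals) is floored at ``eps`` µV² with a warning.
    Returns a pandas Series indexed by ``{band}_{L|R}``.
    """
    import pandas as pd

    if averaging not in ("log_of_mean", "mean_of_log"):
        raise ConfigurationError(f"unknown averaging {averaging!r}")
    values, names = [], []
    for band, bp in powers.items():
        for ch, side in enumerate(CHANNEL_SUFFIX[: bp.shape[0]]):
            x = bp[ch]
            if averaging == "log_of_mean":
                m = np.nanmean(x)
                if not m > 0:
                    warnings.warn(
                        f"non-positive mean {band} power on channel {side}; "
                        f"flooring at {eps} µV²",
                        stacklevel=2,
                    )
                    m = eps
                values.append(np.log10(m))
            else:
                if np.nanmin(x) <= 0:
                    warnings.warn(
                        f"non-positive {band} power bins on channel {side}; "
                        f"flooring at {eps} µV²",
                        stacklevel=2,
                    )
                values.append(float(np.nanmean(np.log10(np.maximum(x, eps)))))
            names.append(f"{band}_{side}")
    return pd.Series(values, index=names if feature_names else None)


def eeg_features(segment, mask=None, window: str = "hann", smooth: bool = True,
                 averaging: str = "log_of_mean"):
    """Full spectral pipeline: frames → smoothing → band powers → features."""
    frames = psd_frames(segment, mask=mask, window=window)
    if smooth:
        frames = smooth_frames(frames)
    return band_features(band_powers(frames), averaging=averaging)
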