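"""Bandpass filtering and artifact detection.

Artifact handling is removal, not correction: each detector produces an
:class:`ArtifactMask` over 1-s time bins (the same bins the spectral
stage uses), and masked bins are simply excluded from feature
extraction.  Detectors run on the *unfiltered* signal — the EMG monitor
band (70–128 Hz) lies above the 100 Hz low-pass corner, and saturation
plateaus are only exactly at the rail before filtering.

The manual-inspection step of a clinical workflow is replaced by a
reproducible override table (force-include / force-exclude per bin).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage, signal

from .errors import ConfigurationError, InsufficientDataError
from .io import EEGRecording

MASK_KINDS = ("saturation", "excursion", "emg", "blink", "spike", "manual")

__all__ = [
    "ArtifactMask",
    "MaskEvent",
    "bandpass",
    "detect_saturation_excursion",
    "detect_emg",
    "detect_blinks",
    "combine_masks",
    "run_all_detectors",
    "event_recall",
]


@dataclass(frozen=True)
class MaskEvent:
    kind: str
    channel: str  # channel label or "both"
    start_sample: int
    end_sample: int


@dataclass
class ArtifactMask:
    """Per-channel boolean exclusion over 1-s bins, with event records.

    ``excluded[ch, t]`` is True when bin t of channel ch is removed from
    the analysis.  Every excluded bin is covered by at least one event.
    """

    excluded: np.ndarray  # (n_channels, n_bins) bool
    fs: float
    events: list[MaskEvent] = field(default_factory=list)
    forced_included: list[int] = field(default_factory=list)

    @property
    def n_bins(self) -> int:
        return self.excluded.shape[1]

    def n_excluded(self) -> int:
        return int(self.excluded.sum())

    @classmethod
    def empty(cls, n_channels: int, n_bins: int, fs: float) -> "ArtifactMask":
        return cls(np.zeros((n_channels, n_bins), dtype=bool), fs)

    def to_interval_table(self):
        import pandas as pd

        return pd.DataFrame(
            [
                (e.channel, e.start_sample, e.end_sample, e.kind)
                for e in self.events
            ],
            columns=["channel", "start_sample", "end_sample", "kind"],
        )


def _rec_data(rec) -> tuple[np.ndarray, float, tuple[str, ...]]:
    data = np.asarray(rec.data, dtype=float)
    chans = getattr(rec, "channels", None) or getattr(
        rec.recording, "channels", ("ch0", "ch1")
    )
    return data, float(rec.fs), tuple(chans)


def _bins_from_samples(sample_mask: np.ndarray, fs: int, n_bins: int):
    """True for every 1-s bin containing a flagged sample."""
    m = sample_mask[: n_bins * fs].reshape(n_bins, fs)
    return m.any(axis=1)


def _runs(mask: np.ndarray):
    """Contiguous True runs as half-open (start, end) index pairs."""
    idx = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
    return list(zip(idx[0::2], idx[1::2]))


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def bandpass(
    rec: EEGRecording, lo_hz: float = 0.1, hi_hz: float = 100.0
) -> EEGRecording:
    """Zero-phase 4th-order Butterworth bandpass (default 0.1–100 Hz).

    Applied forward–backward so time-bin alignment is preserved; output
    length equals input length.
    """
    if rec.fs <= 2 * hi_hz:
        raise ConfigurationError(
            f"fs={rec.fs} Hz too low for a {hi_hz} Hz low-pass corner"
        )
    sos = signal.butter(4, [lo_hz, hi_hz], btype="bandpass", fs=rec.fs,
                        output="sos")
    out = rec.copy()
    out.data = signal.sosfiltfilt(sos, out.data, axis=-1)
    return out


# ---------------------------------------------------------------------------
# detectors
# ---------------------------------------------------------------------------

def detect_saturation_excursion(
    rec,
    rail_uV: float = 400.0,
    excursion_uV: float = 200.0,
    spike_delta_uV: float = 100.0,
    dilate_s: float = 0.5,
) -> ArtifactMask:
    """Flag saturations, large excursions and single-sample spikes.

    Saturation: runs of >= 3 consecutive samples with ``|v|`` at the
    rail.  Excursion: any sample with ``|v| >= excursion_uV``.  Spikes
    (``|Δv| > spike_delta_uV`` between successive samples) are folded
    into this detector as their own event kind.  All flagged samples are
    dilated by ±``dilate_s`` before mapping to 1-s bins.
    """
    if min(rail_uV, excursion_uV, spike_delta_uV) <= 0:
        raise ConfigurationError("detector thresholds must be positive")
    data, fs, chans = _rec_data(rec)
    spr = int(round(fs))
    n_bins = data.shape[1] // spr
    mask = ArtifactMask.empty(data.shape[0], n_bins, fs)
    dil = int(round(dilate_s * fs))
    struct = np.ones(2 * dil + 1, dtype=bool)
    for ch in range(data.shape[0]):
        v = data[ch]
        at_rail = np.abs(v) >= rail_uV * (1 - 1e-6)
        sat = np.zeros_like(at_rail)
        for s, e in _runs(at_rail):
            if e - s >= 3:
                sat[s:e] = True
        exc = np.abs(v) >= excursion_uV
        spike = np.zeros_like(exc)
        big_jump = np.abs(np.diff(v)) > spike_delta_uV
        spike[1:][big_jump] = True
        spike[:-1][big_jump] = True
        for kind, m in (("saturation", sat), ("excursion", exc),
                        ("spike", spike)):
            if not m.any():
                continue
            md = ndimage.binary_dilation(m, structure=struct)
            mask.excluded[ch] |= _bins_from_samples(md, spr, n_bins)
            for s, e in _runs(md):
                mask.events.append(MaskEvent(kind, chans[ch], int(s), int(e)))
    return mask


def detect_emg(
    rec,
    k_mad: float = 5.0,
    hf_band: tuple[float, float] = (70.0, 128.0),
    lf_band: tuple[float, float] = (35.0, 40.0),
    min_power_uV2: float = 0.01,
) -> ArtifactMask:
    """Flag muscle-activity bins by monitoring out-of-band power.

    Per 1-s bin and channel, power in the high-frequency (70–128 Hz)
    and low-frequency-EMG (35–40 Hz) monitor bands is computed on the
    raw signal; a bin is flagged when either power exceeds the segment's
    ``median + k_mad * MAD`` (unscaled MAD) *and* the absolute floor
    ``min_power_uV2`` — the floor keeps numerically silent monitor
    bands from registering as outliers.  The relative threshold needs
    no calibration data but requires >= 5 s of signal.
    """
    data, fs, chans = _rec_data(rec)
    spr = int(round(fs))
    n_bins = data.shape[1] // spr
    if n_bins < 5:
        raise InsufficientDataError(
            f"EMG baseline undefined for segments < 5 s (got {n_bins} s)"
        )
    frames = data[:, : n_bins * spr].reshape(data.shape[0], n_bins, spr)
    freqs, pxx = signal.periodogram(
        frames, fs=fs, window="hann", detrend=False, scaling="density",
        axis=-1,
    )
    mask = ArtifactMask.empty(data.shape[0], n_bins, fs)
    for lo, hi in (hf_band, lf_band):
        sel = (freqs >= lo) & (freqs < hi)
        bandp = pxx[..., sel].sum(axis=-1)  # (n_channels, n_bins)
        med = np.median(bandp, axis=1, keepdims=True)
        mad = np.median(np.abs(bandp - med), axis=1, keepdims=True)
        flagged = (bandp > med + k_mad * mad) & (bandp > min_power_uV2)
        mask.excluded |= flagged
    for ch in range(data.shape[0]):
        for s, e in _runs(mask.excluded[ch]):
            mask.events.append(
                MaskEvent("emg", chans[ch], int(s * spr), int(e * spr))
            )
    return mask


def detect_blinks(
    rec,
    p2p_uV: float = 60.0,
    band_hz: tuple[float, float] = (0.5, 5.0),
    window_s: float = 0.5,
    k_mad: float = 5.0,
) -> ArtifactMask:
    """Flag blink-like low-frequency transients.

    A simplified surrogate for published template detectors: the signal
    is restricted to the blink band (0.5–5 Hz) and any 500-ms window
    whose peak-to-peak amplitude exceeds the threshold on either
    channel marks a blink.  The threshold is ``p2p_uV`` or, for
    subjects with unusually strong slow activity, a robust per-segment
    baseline (median + ``k_mad``·MAD of the windowed peak-to-peak),
    whichever is larger.  Blinks are frontopolar events visible on both
    channels, so the two channels are combined and flagged jointly.
    """
    data, fs, _ = _rec_data(rec)
    spr = int(round(fs))
    n_bins = data.shape[1] // spr
    sos = signal.butter(4, band_hz, btype="bandpass", fs=fs, output="sos")
    low = signal.sosfiltfilt(sos, data, axis=-1)
    w = max(2, int(round(window_s * fs)))
    p2p = np.maximum.reduce([
        ndimage.maximum_filter1d(low[ch], size=w)
        - ndimage.minimum_filter1d(low[ch], size=w)
        for ch in range(data.shape[0])
    ])
    med = float(np.median(p2p))
    mad = float(np.median(np.abs(p2p - med)))
    flagged = p2p > max(p2p_uV, med + k_mad * mad)
    mask = ArtifactMask.empty(data.shape[0], n_bins, fs)
    bins = _bins_from_samples(flagged, spr, n_bins)
    mask.excluded[:, bins] = True
    for s, e in _runs(flagged):
        mask.events.append(MaskEvent("blink", "both", int(s), int(e)))
    return mask


# ---------------------------------------------------------------------------
# combination and overrides
# ---------------------------------------------------------------------------

def combine_masks(*masks: ArtifactMask, overrides=None) -> ArtifactMask:
    """Union of exclusions, with optional per-bin overrides.

    ``overrides`` is an iterable of ``(bin_index, action)`` with action
    ``"include"`` (retain a flagged bin on all channels, logged) or
    ``"exclude"`` (force removal, recorded as a ``manual`` event), or a
    path to a CSV with columns ``bin_index, action``.
    """
    if not masks:
        raise ValueError("need at least one mask")
    shape = masks[0].excluded.shape
    fs = masks[0].fs
    for m in masks[1:]:
        if m.excluded.shape != shape or m.fs != fs:
            raise ConfigurationError(
                f"mask geometry mismatch: {m.excluded.shape}@{m.fs} "
                f"vs {shape}@{fs}"
            )
    out = ArtifactMask(
        excluded=np.logical_or.reduce([m.excluded for m in masks]),
        fs=fs,
        events=[e for m in masks for e in m.events],
    )
    if overrides is not None:
        if isinstance(overrides, (str, Path)):
            with open(overrides, newline="") as fh:
                overrides = [
                    (int(row["bin_index"]), row["action"].strip())
                    for row in csv.DictReader(fh)
                ]
        spr = int(round(fs))
        for bin_idx, action in overrides:
            if not 0 <= bin_idx < out.n_bins:
                raise ConfigurationError(f"override bin {bin_idx} out of range")
            if action == "include":
                if out.excluded[:, bin_idx].any():
                    warnings.warn(
                        f"override retains flagged bin {bin_idx}", stacklevel=2
                    )
                out.excluded[:, bin_idx] = False
                out.forced_included.append(bin_idx)
            elif action == "exclude":
                out.excluded[:, bin_idx] = True
                out.events.append(
                    MaskEvent("manual", "both", bin_idx * spr,
                              (bin_idx + 1) * spr)
                )
            else:
                raise ConfigurationError(f"unknown override action {action!r}")
    return out


# ---------------------------------------------------------------------------
# convenience / evaluation
# ---------------------------------------------------------------------------

def run_all_detectors(
    rec,
    rail_uV: float = 400.0,
    excursion_uV: float = 200.0,
) -> dict[str, ArtifactMask]:
    """Run every detector; returns masks keyed by detector name."""
    return {
        "saturation_excursion": detect_saturation_excursion(
            rec, rail_uV=rail_uV, excursion_uV=excursion_uV
        ),
        "emg": detect_emg(rec),
        "blink": detect_blinks(rec),
    }


#: which detector's mask answers for each injected artifact kind
_KIND_TO_DETECTOR = {
    "saturation": "saturation_excursion",
    "excursion": "saturation_excursion",
    "spike": "saturation_excursion",
    "emg": "emg",
    "blink": "blink",
}


def event_recall(
    annotations, masks: dict[str, ArtifactMask], kind: str, channels=None
) -> float:
    """Fraction of injected events of ``kind`` whose span is flagged.

    An event counts as recovered when any 1-s bin it overlaps is
    excluded (on the annotated channel) by the matching detector's
    mask.  Returns NaN when no event of that kind was injected.
    """
    mask = masks[_KIND_TO_DETECTOR[kind]]
    spr = int(round(mask.fs))
    hits = total = 0
    for a in annotations:
        if a.kind != kind:
            continue
        total += 1
        b0 = a.start_sample // spr
        b1 = min(mask.n_bins, -(-a.end_sample // spr))
        if b1 <= b0:
            b1 = b0 + 1
        if b0 >= mask.n_bins:
            continue
        if a.channel == "both":
            ch_rows = mask.excluded[:, b0:b1].any(axis=0)
        else:
            ch_idx = 0 if a.channel.startswith("AF7") else 1
            ch_rows = mask.excluded[ch_idx, b0:b1]
        if ch_rows.any():
            hits += 1
    return hits / total if total else float("nan")
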