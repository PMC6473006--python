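"""Synthetic mTBI/control cohort generator.

No public dataset accompanies this analysis, so every downstream stage
is exercised on simulated subjects carrying ground truth.  A subject is
a two-channel frontopolar recording (AF7–FpZ, AF8–FpZ at 256 Hz) built
as a sum of band-limited oscillatory processes — one narrowband
Gaussian process per canonical band, with per-subject amplitudes drawn
from a class-dependent log-normal profile — on top of 1/f-like
background noise, plus a symptom questionnaire drawn from class-
dependent item probabilities.  The class signal enters the EEG as a
standardized shift of the band log-amplitudes (``eeg_class_effect``,
in within-class SD units; mTBI subjects are shifted *down*, giving the
weak anti-correlation of band powers with the class vector) and enters
the questionnaire as strongly class-separated endorsement
probabilities.

Artifacts (blinks, EMG bursts, saturation plateaus, slow excursions,
single-sample spikes) are injected at configurable events/min rates and
recorded as ground-truth annotations, so detector recall and false-
positive rates are measurable exactly.

This generative model is a stand-in chosen because the analysis
consumes only band PSDs and binary symptoms; it makes no claim of
physiological forward modelling.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal

from .errors import SpecError
from .io import EEGRecording, write_recording
from .spectral import BANDS
from .symptoms import SYMPTOM_ITEMS, SymptomReport

ARTIFACT_KINDS = ("blink", "emg", "saturation", "excursion", "spike")

__all__ = [
    "CohortSpec",
    "SyntheticSubject",
    "ArtifactAnnotation",
    "generate_subject",
    "generate_cohort",
    "inject_artifacts",
    "write_cohort",
]


@dataclass(frozen=True)
class BandProfile:
    """Per-band oscillator profile: RMS amplitude (µV) and log10-SD."""

    amp_uV: float
    log10_sd: float = 0.2


# Resting eyes-closed frontopolar profile: modest alpha, dominant slow
# activity, little gamma.  Values are RMS µV of the band-limited process.
DEFAULT_BAND_PROFILE: dict[str, BandProfile] = {
    "delta": BandProfile(6.0),
    "theta": BandProfile(4.0),
    "alpha": BandProfile(6.0),
    "beta": BandProfile(3.0),
    "sigma": BandProfile(2.0),
    "gamma": BandProfile(1.5),
}

# P(yes) per item as (control, mtbi): strongly class-separated, per the
# screening picture where symptom variables correlate strongly with class.
DEFAULT_SYMPTOM_PROB: dict[str, tuple[float, float]] = {
    "loss_of_consciousness": (0.05, 0.25),
    "headache": (0.35, 0.70),
    "nausea_vomiting": (0.15, 0.40),
    "light_sensitivity": (0.20, 0.50),
    "sound_sensitivity": (0.20, 0.45),
    "confusion": (0.15, 0.55),
    "memory_dysfunction": (0.15, 0.45),
}

DEFAULT_ARTIFACT_RATES: dict[str, float] = {
    "blink": 2.0,       # events/min; eyes closed, so only a few
    "emg": 1.0,
    "saturation": 0.5,
    "excursion": 0.5,
    "spike": 1.0,
}


@dataclass
class CohortSpec:
    """Study conditions for the synthetic cohort.

    Defaults mirror the study composition: 38 mTBI and 47 controls, one
    minute of eyes-closed recording at 256 Hz.  ``eeg_class_effect`` is
    the standardized (within-class SD units) downward shift of mTBI
    band log-amplitudes; the default 0.35 keeps the EEG–class
    correlations weak relative to the symptom–class correlations.
    """

    n_mtbi: int = 38
    n_control: int = 47
    duration_s: float = 60.0
    fs: float = 256.0
    band_profile: dict[str, BandProfile] = field(
        default_factory=lambda: dict(DEFAULT_BAND_PROFILE)
    )
    symptom_prob: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SYMPTOM_PROB)
    )
    # truncated-geometric severity parameter per class (control, mtbi);
    # smaller p -> heavier severities
    severity_geom_p: tuple[float, float] = (0.60, 0.50)
    artifact_rates: dict[str, float] = field(
        default_factory=lambda: dict.fromkeys(ARTIFACT_KINDS, 0.0)
    )
    eeg_class_effect: float = 0.35
    noise_sd_uV: float = 5.0
    rail_uV: float = 400.0
    oscillator: str = "narrowband"  # or "sinusoid"
    sinusoid_freqs: dict[str, float] = field(default_factory=dict)
    lr_jitter_log10: float = 0.05  # per-channel amplitude jitter (dex)
    seed: int = 0

    def validate(self) -> None:
        if self.n_mtbi < 0 or self.n_control < 0:
            raise SpecError("cohort sizes must be non-negative")
        if not self.duration_s > 0:
            raise SpecError(f"duration_s must be positive, got {self.duration_s}")
        if not self.fs > 0:
            raise SpecError(f"fs must be positive, got {self.fs}")
        highest = max(hi for _, hi in BANDS.values())
        if self.fs <= 2 * highest:
            raise SpecError(
                f"fs={self.fs} must exceed twice the highest synthesized "
                f"band edge ({highest} Hz)"
            )
        for item, (pc, pm) in self.symptom_prob.items():
            if not (0 <= pc <= 1 and 0 <= pm <= 1):
                raise SpecError(f"{item}: probabilities must lie in [0,1]")
        for kind, rate in self.artifact_rates.items():
            if rate < 0:
                raise SpecError(f"{kind}: artifact rate must be >= 0")
            if kind not in ARTIFACT_KINDS:
                raise SpecError(f"unknown artifact kind {kind!r}")
        if self.oscillator not in ("narrowband", "sinusoid"):
            raise SpecError(f"unknown oscillator model {self.oscillator!r}")


@dataclass(frozen=True)
class ArtifactAnnotation:
    """Ground-truth injected artifact: half-open sample interval."""

    kind: str
    channel: str  # "AF7-FpZ", "AF8-FpZ", or "both"
    start_sample: int
    end_sample: int


@dataclass
class SyntheticSubject:
    subject_id: str
    label: str  # "mtbi" | "control"
    recording: EEGRecording
    symptoms: SymptomReport
    artifacts: list[ArtifactAnnotation] = field(default_factory=list)
    band_amps_uV: dict[str, tuple[float, float]] = field(default_factory=dict)


def _narrowband(rng, n, fs, lo, hi) -> np.ndarray:
    """Unit-RMS band-limited Gaussian process."""
    white = rng.standard_normal(n + 2 * int(fs))  # pad to wash out edges
    hi = min(hi, 0.99 * fs / 2)
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, white)[int(fs) : int(fs) + n]
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _pink_noise(rng, n, fs) -> np.ndarray:
    """Unit-RMS 1/f-amplitude background (flat below 1 Hz)."""
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, d=1 / fs)
    shaping = 1.0 / np.sqrt(np.maximum(f, 1.0))
    x = np.fft.irfft(spec * shaping, n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def generate_subject(
    label: str, spec: CohortSpec, seed: int, subject_id: str | None = None
) -> SyntheticSubject:
    """Generate one labelled subject (recording + questionnaire).

    Deterministic given ``(label, spec, seed)``.  The recording carries
    ``eyes_closed_begin``/``eyes_closed_end`` markers spanning the full
    duration.  Artifacts are *not* injected here; see
    :func:`inject_artifacts` and :func:`generate_cohort`.
    """
    spec.validate()
    if label not in ("mtbi", "control"):
        raise SpecError(f"label must be 'mtbi' or 'control', got {label!r}")
    rng = np.random.default_rng(seed)
    n = int(round(spec.duration_s * spec.fs))
    t = np.arange(n) / spec.fs

    shift = -spec.eeg_class_effect if label == "mtbi" else 0.0
    data = np.zeros((2, n))
    band_amps: dict[str, tuple[float, float]] = {}
    for band, (lo, hi) in BANDS.items():
        prof = spec.band_profile.get(band)
        if prof is None or prof.amp_uV <= 0:
            band_amps[band] = (0.0, 0.0)
            continue
        # subject-level log-amplitude, shared across channels, plus a
        # small per-channel jitter so L and R correlate but differ;
        # draws are truncated at ±2.5 SD — unbounded log-normal tails
        # produce physiologically absurd band amplitudes
        z = float(np.clip(rng.standard_normal(), -2.5, 2.5))
        base = math.log10(prof.amp_uV) + prof.log10_sd * (z + shift)
        zj = np.clip(rng.standard_normal(2), -2.5, 2.5)
        amps = 10.0 ** (base + spec.lr_jitter_log10 * zj)
        band_amps[band] = (float(amps[0]), float(amps[1]))
        if spec.oscillator == "sinusoid":
            f0 = spec.sinusoid_freqs.get(band, 0.5 * (lo + hi))
            for ch in range(2):
                phase = rng.uniform(0, 2 * np.pi)
                data[ch] += amps[ch] * np.sin(2 * np.pi * f0 * t + phase)
        else:
            for ch in range(2):
                data[ch] += amps[ch] * _narrowband(rng, n, spec.fs, lo, hi)
    if spec.noise_sd_uV > 0:
        for ch in range(2):
            data[ch] += spec.noise_sd_uV * _pink_noise(rng, n, spec.fs)

    answers, severities = {}, {}
    p_geom = spec.severity_geom_p[1 if label == "mtbi" else 0]
    for item in SYMPTOM_ITEMS:
        pc, pm = spec.symptom_prob.get(item, (0.0, 0.0))
        p_yes = pm if label == "mtbi" else pc
        yes = bool(rng.random() < p_yes)
        answers[item] = yes
        severities[item] = _truncated_geometric(rng, p_geom) if yes else 0

    rec = EEGRecording(
        data=data,
        fs=spec.fs,
        markers=[("eyes_closed_begin", 0), ("eyes_closed_end", n)],
    )
    return SyntheticSubject(
        subject_id=subject_id or f"{label[0]}{seed:08d}",
        label=label,
        recording=rec,
        symptoms=SymptomReport(answers, severities),
        band_amps_uV=band_amps,
    )


def _truncated_geometric(rng, p: float, max_val: int = 6) -> int:
    """Geometric on 1..max_val: P(k) ∝ (1-p)^(k-1) p."""
    probs = np.array([(1 - p) ** (k - 1) * p for k in range(1, max_val + 1)])
    probs /= probs.sum()
    return int(rng.choice(np.arange(1, max_val + 1), p=probs))


def generate_cohort(spec: CohortSpec) -> list[SyntheticSubject]:
    """Generate the full cohort, reproducibly from ``spec.seed``.

    Per-subject seeds derive from ``spec.seed``; artifact injection runs
    automatically for every kind with a positive rate.
    """
    spec.validate()
    n_total = spec.n_mtbi + spec.n_control
    if n_total == 0:
        return []
    seeds = np.random.SeedSequence(spec.seed).generate_state(2 * n_total)
    subjects = []
    labels = ["mtbi"] * spec.n_mtbi + ["control"] * spec.n_control
    for i, label in enumerate(labels):
        sid = f"{'m' if label == 'mtbi' else 'c'}{i + 1:03d}"
        subj = generate_subject(label, spec, int(seeds[2 * i]), subject_id=sid)
        if any(r > 0 for r in spec.artifact_rates.values()):
            subj = inject_artifacts(subj, spec, int(seeds[2 * i + 1]))
        subjects.append(subj)
    return subjects


# ---------------------------------------------------------------------------
# artifact injection
# ---------------------------------------------------------------------------

def _place_events(rng, n_events, dur_samples_fn, n, fs, occupied, pad_s=1.0):
    """Uniformly place non-overlapping events; returns (start, end) list."""
    pad = int(pad_s * fs)
    spans = []
    for _ in range(n_events):
        for _attempt in range(200):
            dur = dur_samples_fn()
            start = int(rng.integers(pad, max(pad + 1, n - dur - pad)))
            lo, hi = start - pad, start + dur + pad
            if all(hi <= s or lo >= e for s, e in occupied):
                occupied.append((start, start + dur))
                spans.append((start, start + dur))
                break
    return spans


def inject_artifacts(
    subject: SyntheticSubject, spec: CohortSpec, seed: int
) -> SyntheticSubject:
    """Return a copy of ``subject`` with artifacts injected and annotated.

    Event counts are deterministic — ``round(rate * duration_min)`` per
    kind — with seeded random placement and morphology.  Injected:

    * ``blink``: biphasic Gaussian-derivative pulse, 300–500 ms,
      50–150 µV peak, same deflection on both channels;
    * ``emg``: 35–128 Hz band-limited noise burst, 0.5–2 s, ~25 µV RMS;
    * ``saturation``: recorder-rail plateau at ±``rail_uV``, 0.3–1.5 s;
    * ``excursion``: slow half-sine excursion, 250–350 µV, 0.5–2 s;
    * ``spike``: single-sample outlier of ±150–300 µV.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    rec = subject.recording.copy()
    data = rec.data
    n, fs = rec.n_samples, rec.fs
    minutes = n / fs / 60.0
    annots: list[ArtifactAnnotation] = list(subject.artifacts)
    occupied: list[tuple[int, int]] = [
        (a.start_sample, a.end_sample) for a in annots
    ]

    def count(kind):
        return int(round(spec.artifact_rates.get(kind, 0.0) * minutes))

    # blinks: both channels
    for start, end in _place_events(
        rng, count("blink"), lambda: int(rng.uniform(0.3, 0.5) * fs), n, fs,
        occupied,
    ):
        dur = end - start
        tt = np.linspace(-3, 3, dur)
        pulse = -tt * np.exp(-(tt**2) / 2)  # Gaussian derivative, biphasic
        pulse *= rng.uniform(50, 150) / np.abs(pulse).max()
        data[0, start:end] += pulse
        data[1, start:end] += pulse
        annots.append(ArtifactAnnotation("blink", "both", start, end))

    # EMG bursts: one channel
    for start, end in _place_events(
        rng, count("emg"), lambda: int(rng.uniform(0.5, 2.0) * fs), n, fs,
        occupied,
    ):
        ch = int(rng.integers(2))
        dur = end - start
        burst = _narrowband(rng, dur, fs, 35, 128) * 25.0
        burst *= signal.windows.tukey(dur, 0.25)  # soft onset/offset
        data[ch, start:end] += burst
        annots.append(
            ArtifactAnnotation("emg", rec.channels[ch], start, end)
        )

    # saturation plateaus: replace signal with the rail value
    for start, end in _place_events(
        rng, count("saturation"), lambda: int(rng.uniform(0.3, 1.5) * fs), n,
        fs, occupied,
    ):
        ch = int(rng.integers(2))
        sign = 1 if rng.random() < 0.5 else -1
        data[ch, start:end] = sign * spec.rail_uV
        annots.append(
            ArtifactAnnotation("saturation", rec.channels[ch], start, end)
        )

    # slow excursions: additive half-sine
    for start, end in _place_events(
        rng, count("excursion"), lambda: int(rng.uniform(0.5, 2.0) * fs), n,
        fs, occupied,
    ):
        ch = int(rng.integers(2))
        dur = end - start
        sign = 1 if rng.random() < 0.5 else -1
        data[ch, start:end] += (
            sign * rng.uniform(250, 350) * np.sin(np.linspace(0, np.pi, dur))
        )
        annots.append(
            ArtifactAnnotation("excursion", rec.channels[ch], start, end)
        )

    # single-sample spikes
    for start, end in _place_events(
        rng, count("spike"), lambda: 1, n, fs, occupied
    ):
        ch = int(rng.integers(2))
        sign = 1 if rng.random() < 0.5 else -1
        data[ch, start] += sign * rng.uniform(150, 300)
        annots.append(
            ArtifactAnnotation("spike", rec.channels[ch], start, end)
        )

    for a in annots:
        if not (0 <= a.start_sample < a.end_sample <= n):
            raise SpecError(f"annotation outside the recording: {a}")
    return replace(subject, recording=rec, artifacts=annots)


# ---------------------------------------------------------------------------
# disk layout
# ---------------------------------------------------------------------------

def write_cohort(
    subjects: list[SyntheticSubject], outdir, format: str = "csv"
) -> Path:
    """Write a cohort directory.

    One recording per subject (``<id>.csv`` or ``<id>.edf`` with a
    marker sidecar), one cohort-level ``symptoms.csv`` (subject_id,
    label, 7 yes/no columns, 7 severity columns), and one
    ``<id>.annotations.json`` ground-truth file per subject.
    """
    import csv as _csv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ext = "edf" if format == "edf" else "csv"
    with open(outdir / "symptoms.csv", "w", newline="") as fh:
        w = _csv.writer(fh)
        w.writerow(
            ["subject_id", "label"]
            + SYMPTOM_ITEMS
            + [f"{i}_severity" for i in SYMPTOM_ITEMS]
        )
        for s in subjects:
            write_recording(s.recording, outdir / f"{s.subject_id}.{ext}", format)
            w.writerow(
                [s.subject_id, s.label]
                + [int(s.symptoms.answers[i]) for i in SYMPTOM_ITEMS]
                + [s.symptoms.severities[i] for i in SYMPTOM_ITEMS]
            )
            ann = [
                {
                    "kind": a.kind,
                    "channel": a.channel,
                    "start_sample": a.start_sample,
                    "end_sample": a.end_sample,
                }
                for a in s.artifacts
            ]
            with open(outdir / f"{s.subject_id}.annotations.json", "w") as jh:
                json.dump(
                    {"subject_id": s.subject_id, "label": s.label,
                     "artifacts": ann},
                    jh, indent=1,
                )
    return outdir
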