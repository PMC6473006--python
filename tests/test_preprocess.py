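"""Filtering and artifact detectors against constructed and annotated truth."""

import dataclasses

import numpy as np
import pytest

from frontoboost.errors import ConfigurationError, InsufficientDataError
from frontoboost.io import EEGRecording
from frontoboost.preprocess import (
    ArtifactMask,
    bandpass,
    combine_masks,
    detect_blinks,
    detect_emg,
    detect_saturation_excursion,
    event_recall,
    run_all_detectors,
)
from frontoboost.synthetic import CohortSpec, generate_subject, inject_artifacts

FS = 256.0


def _rec(data):
    return EEGRecording(np.atleast_2d(data).repeat(2, axis=0)[:2], fs=FS)


def _tone(freq, amp, seconds, fs=FS):
    t = np.arange(int(seconds * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


class TestBandpass:
    def test_zero_in_zero_out(self):
        out = bandpass(_rec(np.zeros(int(10 * FS))))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_dc_offset_removed_after_settling(self):
        out = bandpass(_rec(np.full(int(30 * FS), 10.0)))
        assert np.abs(out.data[:, int(10 * FS):]).max() < 0.1

    def test_passband_10hz_unity_gain(self):
        x = _tone(10.0, 1.0, 30)
        out = bandpass(_rec(x))
        # steady-state amplitude over an integer number of mid-signal
        # cycles (the 0.1 Hz corner's transient lives at the edges)
        mid = out.data[0, int(10 * FS) : int(20 * FS)]
        amp = np.sqrt(2.0) * np.sqrt(np.mean(mid**2))
        assert amp == pytest.approx(1.0, rel=0.01)

    def test_low_fs_rejected(self):
        with pytest.raises(ConfigurationError):
            bandpass(EEGRecording(np.zeros((2, 100)), fs=128.0))

    def test_length_preserved(self):
        out = bandpass(_rec(_tone(5, 1, 7)))
        assert out.n_samples == int(7 * FS)


class TestSaturationExcursion:
    def test_clean_sinusoid_empty_mask(self):
        mask = detect_saturation_excursion(_rec(_tone(10, 30, 10)))
        assert mask.n_excluded() == 0
        assert mask.events == []

    def test_injected_plateau_masks_bin_and_neighbors(self):
        x = _tone(10, 20, 10)
        x[int(4 * FS) : int(5 * FS)] = 400.0  # 1-s plateau at the rail
        mask = detect_saturation_excursion(_rec(x))
        assert mask.excluded[0, 3] and mask.excluded[0, 4] and mask.excluded[0, 5]
        kinds = {e.kind for e in mask.events}
        assert "saturation" in kinds

    def test_spike_folded_into_detector(self):
        x = _tone(10, 20, 10)
        x[1280] += 180.0  # single-sample jump ≫ 100 µV
        mask = detect_saturation_excursion(_rec(x))
        assert mask.excluded[0, 5]
        assert any(e.kind == "spike" for e in mask.events)

    def test_annotated_saturations_sample_coverage(self):
        """>= 95% of injected saturated samples fall in masked bins."""
        spec = dataclasses.replace(
            CohortSpec(), duration_s=30.0, noise_sd_uV=0.0,
            band_profile={b: dataclasses.replace(p, log10_sd=0.0)
                          for b, p in CohortSpec().band_profile.items()},
            artifact_rates={"saturation": 4.0},
        )
        s = inject_artifacts(generate_subject("control", spec, 3), spec, 4)
        mask = detect_saturation_excursion(s.recording)
        spr = int(FS)
        covered = total = 0
        for a in s.artifacts:
            ch = 0 if a.channel.startswith("AF7") else 1
            for smp in range(a.start_sample, a.end_sample):
                total += 1
                covered += bool(mask.excluded[ch, min(smp // spr,
                                                      mask.n_bins - 1)])
        assert total > 0
        assert covered / total >= 0.95


class TestEMG:
    def test_pure_alpha_not_flagged(self):
        mask = detect_emg(_rec(_tone(10, 30, 20)))
        assert mask.n_excluded() == 0

    def test_broadband_burst_flagged(self, rng):
        x = _tone(10, 20, 20)
        burst = rng.standard_normal(int(FS))
        from scipy import signal as sg
        sos = sg.butter(4, [35, 127], btype="bandpass", fs=FS, output="sos")
        x[int(7 * FS) : int(8 * FS)] += 30.0 * sg.sosfiltfilt(sos, burst)
        mask = detect_emg(_rec(x))
        assert mask.excluded[0, 7]

    def test_identical_bins_not_flagged(self, rng):
        one = rng.standard_normal(int(FS))
        x = np.tile(one, 20)  # every bin identical -> no outliers
        mask = detect_emg(_rec(x))
        assert mask.n_excluded() == 0

    def test_short_segment_rejected(self):
        with pytest.raises(InsufficientDataError):
            detect_emg(_rec(_tone(10, 10, 3)))


class TestBlinks:
    @staticmethod
    def _blink_wave(amp, seconds=20.0):
        x = np.zeros(int(seconds * FS))
        tt = np.linspace(-3, 3, int(0.4 * FS))
        pulse = -tt * np.exp(-(tt**2) / 2)
        pulse *= amp / np.abs(pulse).max()
        return x, pulse

    def test_blink_free_empty(self):
        mask = detect_blinks(_rec(_tone(10, 20, 20)))
        assert mask.n_excluded() == 0

    def test_three_blinks_three_events(self):
        x, pulse = self._blink_wave(120.0)
        for start_s in (3, 9, 15):
            i = int(start_s * FS)
            x[i : i + len(pulse)] += pulse
        mask = detect_blinks(_rec(x))
        assert len(mask.events) == 3
        assert all(e.kind == "blink" for e in mask.events)

    def test_subthreshold_blink_not_flagged(self):
        x, pulse = self._blink_wave(15.0)  # well below 60 µV p2p
        x[int(5 * FS) : int(5 * FS) + len(pulse)] += pulse
        mask = detect_blinks(_rec(x))
        assert mask.n_excluded() == 0


class TestCombine:
    def test_union_with_empty_is_identity(self):
        m = detect_blinks(_rec(_tone(10, 20, 10)))
        empty = ArtifactMask.empty(2, m.n_bins, FS)
        combined = combine_masks(m, empty)
        np.testing.assert_array_equal(combined.excluded, m.excluded)

    def test_union_bound(self):
        a = ArtifactMask.empty(2, 10, FS)
        b = ArtifactMask.empty(2, 10, FS)
        a.excluded[:, 2:5] = True
        b.excluded[:, 4:7] = True
        c = combine_masks(a, b)
        assert c.n_excluded() <= a.n_excluded() + b.n_excluded()
        assert c.excluded[0, 4]

    def test_geometry_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            combine_masks(ArtifactMask.empty(2, 10, FS),
                          ArtifactMask.empty(2, 12, FS))

    def test_override_force_include_and_exclude(self):
        a = ArtifactMask.empty(2, 10, FS)
        a.excluded[:, 3] = True
        with pytest.warns(UserWarning):
            c = combine_masks(a, overrides=[(3, "include"), (7, "exclude")])
        assert not c.excluded[:, 3].any()
        assert c.excluded[:, 7].all()
        assert 3 in c.forced_included
        assert any(e.kind == "manual" for e in c.events)


class TestDetectorQuality:
    """Recall and false-flag behaviour on annotated synthetic subjects."""

    def test_recall_and_false_flags_small_mc(self):
        clean = dataclasses.replace(CohortSpec(), duration_s=20.0)
        arty = dataclasses.replace(
            clean, artifact_rates=dict.fromkeys(
                ("blink", "emg", "saturation", "excursion", "spike"), 3.0)
        )
        recalls = {k: [] for k in arty.artifact_rates}
        false_flags = []
        for seed in range(5):
            s = generate_subject("control", clean, seed=100 + seed)
            masks = run_all_detectors(s.recording)
            false_flags.append(
                np.mean([m.excluded.mean() for m in masks.values()])
            )
            sa = inject_artifacts(s, arty, seed=200 + seed)
            masks = run_all_detectors(sa.recording)
            for kind in recalls:
                r = event_recall(sa.artifacts, masks, kind)
                if not np.isnan(r):
                    recalls[kind].append(r)
        for kind, vals in recalls.items():
            assert np.mean(vals) >= 0.9, kind
        assert np.mean(false_flags) <= 0.05

    def test_masking_only_removes_bins(self):
        spec = dataclasses.replace(
            CohortSpec(), duration_s=15.0,
            artifact_rates={"blink": 3.0, "emg": 2.0},
        )
        s = inject_artifacts(generate_subject("mtbi", spec, 5), spec, 6)
        masks = run_all_detectors(s.recording)
        combined = combine_masks(*masks.values())
        from frontoboost.spectral import psd_frames

        unmasked = psd_frames(s.recording)
        masked = psd_frames(s.recording, mask=combined)
        valid_m = ~np.isnan(masked.power[:, :, 0])
        valid_u = ~np.isnan(unmasked.power[:, :, 0])
        assert np.all(valid_u[valid_m])  # masked-valid ⊂ unmasked-valid
        np.testing.assert_array_equal(
            masked.power[valid_m], unmasked.power[valid_m]
        )
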