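"""Synthetic-signal generator: spectral content, amplitudes, bookkeeping."""

import numpy as np
import pytest
from scipy import signal as sps

from hybridbci import (SessionPlan, generate_calibration_eeg,
                       generate_hov_calibration_eog, generate_task_session)
from hybridbci.preprocessing import bipolar_eog
from hybridbci.simulate import default_profile
from hybridbci.types import EEG_CHANNELS


def band_power_periodogram(x, fs, band):
    """FFT periodogram band power: the independent spectral oracle."""
    f, p = sps.periodogram(x, fs)
    mask = (f >= band[0]) & (f <= band[1])
    return np.trapezoid(p[mask], f[mask])


def segment_samples(rec, which):
    ons = sorted(a.time for a in rec.events("imagery_on"))
    offs = sorted(a.time for a in rec.events("imagery_off"))
    c3 = rec.channel("C3")
    segs = []
    if which == "imagery":
        pairs = zip(ons, offs)
    else:
        pairs = zip(offs, ons[1:] + [rec.duration])
    for a, b in pairs:
        segs.append(c3[int((a + 0.3) * rec.fs): int((b - 0.05) * rec.fs)])
    return np.concatenate(segs)


class TestCalibrationEeg:
    def test_duration_is_trials_times_cycle(self):
        prof = default_profile(seed=0)
        rec = generate_calibration_eeg(prof, n_trials=42, trial_len=5.0, iti=4.0)
        assert rec.duration == pytest.approx(42 * 9.0)
        assert len(rec.events("imagery_on")) == 42

    def test_rejects_nonpositive_durations(self):
        prof = default_profile(seed=0)
        with pytest.raises(ValueError):
            generate_calibration_eeg(prof, n_trials=5, trial_len=0.0, iti=4.0)
        with pytest.raises(ValueError):
            generate_calibration_eeg(prof, n_trials=0)

    def test_erd_depth_halves_amplitude_quarters_power(self):
        """ERD depth 0.5 -> imagery/rest SMR band power ratio ~ 0.25."""
        prof = default_profile(seed=3, erd_depth=0.5, noise_level=0.05)
        rec = generate_calibration_eeg(prof, n_trials=8, trial_len=4.0, iti=3.0)
        band = (prof.smr_center_freq - 1.5, prof.smr_center_freq + 1.5)
        p_rest = band_power_periodogram(segment_samples(rec, "rest"), rec.fs, band)
        p_imag = band_power_periodogram(segment_samples(rec, "imagery"), rec.fs, band)
        assert p_imag / p_rest == pytest.approx(0.25, rel=0.10)

    def test_zero_erd_depth_leaves_band_power_unchanged(self):
        prof = default_profile(seed=4, erd_depth=0.0, noise_level=0.05)
        rec = generate_calibration_eeg(prof, n_trials=8, trial_len=4.0, iti=3.0)
        band = (prof.smr_center_freq - 1.5, prof.smr_center_freq + 1.5)
        p_rest = band_power_periodogram(segment_samples(rec, "rest"), rec.fs, band)
        p_imag = band_power_periodogram(segment_samples(rec, "imagery"), rec.fs, band)
        assert p_imag / p_rest == pytest.approx(1.0, rel=0.10)

    def test_rest_spectrum_peaks_at_programmed_frequency(self):
        """In-band periodogram maximum within 0.5 Hz of the SMR frequency."""
        prof = default_profile(seed=5, smr_center_freq=9.5)
        rec = generate_calibration_eeg(prof, n_trials=10, trial_len=3.0, iti=4.0)
        rest = segment_samples(rec, "rest")
        assert rest.shape[0] >= 60 * rec.fs * 0.4
        f, p = sps.periodogram(rest, rec.fs)
        inband = (f >= 8.0) & (f <= 13.0)
        peak = f[inband][np.argmax(p[inband])]
        assert abs(peak - 9.5) <= 0.5

    def test_seed_makes_generation_bit_reproducible(self):
        prof = default_profile(seed=9)
        a = generate_calibration_eeg(prof, n_trials=2, trial_len=2.0, iti=1.0)
        b = generate_calibration_eeg(prof, n_trials=2, trial_len=2.0, iti=1.0)
        assert np.array_equal(a.samples, b.samples)


class TestHovCalibrationEog:
    def test_noiseless_deflections_have_requested_peak(self):
        prof = default_profile(seed=0, noise_level=0.0, hov_amplitude=120.0)
        rec = generate_hov_calibration_eog(prof, 10, ["right"] * 10)
        bip = bipolar_eog(rec).samples[0]
        peaks = [bip[int(a.time * rec.fs): int((a.time + 2) * rec.fs)].max()
                 for a in rec.events("hov")]
        assert np.allclose(peaks, 120.0, rtol=1e-6)

    def test_alternating_directions_alternate_sign(self):
        prof = default_profile(seed=0, noise_level=0.0)
        rec = generate_hov_calibration_eog(prof, 4, ["left", "right"] * 2)
        bip = bipolar_eog(rec).samples[0]
        signed = []
        for a in rec.events("hov"):
            seg = bip[int(a.time * rec.fs): int((a.time + 2) * rec.fs)]
            signed.append(seg[np.argmax(np.abs(seg))])
        assert np.all(np.sign(signed) == [-1, 1, -1, 1])

    def test_noisy_peaks_average_to_amplitude(self):
        """Mean detected peak close to hov_amplitude at study-default noise.

        Peak-picking over a window is upward-biased by the expected noise
        maximum, so the tolerance is 3 standard errors plus 5% of the
        amplitude (the bias bound at this noise level) on the band-passed
        derivation the calibrator actually measures.
        """
        prof = default_profile(seed=6, noise_level=2.0, hov_amplitude=150.0)
        rec = generate_hov_calibration_eog(prof, 20, ["right"] * 20)
        bip = bipolar_eog(rec).samples[0]
        # sample the plateau midpoint (50 ms rise + 1 s hold): unbiased by the
        # noise maximum that a max-over-window peak estimate would pick up
        mids = np.array([bip[int((a.time + 0.5) * rec.fs)] for a in rec.events("hov")])
        se = mids.std(ddof=1) / np.sqrt(mids.shape[0])
        assert abs(mids.mean() - 150.0) <= 3 * se

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            generate_hov_calibration_eog(default_profile(), 0, [])


class TestTaskSession:
    def make(self, seed=0, **profile_kw):
        prof = default_profile(seed=seed, **profile_kw)
        plan = SessionPlan(n_repetitions=3, seed=seed)
        return prof, generate_task_session(prof, plan)

    def intent_vs_cue(self, anns):
        """(cue, intent) pairs for the four timed sub-tasks of each repetition."""
        pairs = []
        for rep in sorted({a.trial_index for a in anns}):
            rec = [a for a in anns if a.trial_index == rep]
            cues = {a.label.split(":")[1]: a.time for a in rec
                    if a.label.startswith("cue:")}
            hovs = sorted(a.time for a in rec if a.label.startswith("hov_intent"))
            erds = sorted(a.time for a in rec if a.label == "erd_intent_on")
            pairs += [(cues["S2"], hovs[0]), (cues["S3"], erds[0]),
                      (cues["S4"], hovs[1]), (cues["S5"], erds[1])]
        return pairs

    def test_no_preactivation_means_all_onsets_after_cue(self):
        _, (_, _, anns) = self.make(seed=1, pre_activation_prob=0.0)
        assert all(intent >= cue for cue, intent in self.intent_vs_cue(anns))

    def test_full_preactivation_means_all_onsets_before_cue(self):
        _, (_, _, anns) = self.make(seed=2, pre_activation_prob=1.0)
        assert all(intent < cue for cue, intent in self.intent_vs_cue(anns))

    def test_degenerate_latency_gives_exact_onsets(self):
        _, (_, _, anns) = self.make(seed=3, latency_mean=1.0, latency_sd=0.0,
                                    pre_activation_prob=0.0)
        for cue, intent in self.intent_vs_cue(anns):
            assert intent - cue == pytest.approx(1.0, abs=1e-9)

    def test_intent_epochs_match_subtask_count(self):
        """1 gaze + 2 HOV + 2 ERD intents per repetition."""
        _, (_, _, anns) = self.make(seed=4)
        for rep in range(3):
            rec = [a for a in anns if a.trial_index == rep]
            assert len([a for a in rec if a.label.startswith("gaze:")]) == 1
            assert len([a for a in rec if a.label.startswith("hov_intent")]) == 2
            assert len([a for a in rec if a.label == "erd_intent_on"]) == 2

    def test_unknown_condition_rejected(self):
        prof = default_profile(seed=0, latency_mean={"exoskeleton:synchronous": 1.0})
        plan = SessionPlan(device="manipulator", n_repetitions=1)
        with pytest.raises(KeyError):
            generate_task_session(prof, plan)
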