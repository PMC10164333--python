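"""Synthetic participants, calibration recordings and task sessions.

This module generates every signal the decoding chain consumes, with the
statistical structure the decoders assume:

* 5-channel EEG at 1 kHz (F3, T3, C3, Cz, P3).  C3 carries a subject-specific
  sensorimotor rhythm (an amplitude-modulated sinusoid) whose amplitude is
  attenuated by a fractional *ERD depth* during motor-imagery epochs, on top
  of 1/f-shaped Gaussian background noise.  All channels additionally share a
  common-mode noise component, so the surface Laplacian has something to
  remove.
* 2-channel EOG at 1 kHz (EOGL, EOGR) with smoothed step deflections for
  horizontal oculoversions (HOV); rightward gaze gives a positive bipolar
  (EOGR - EOGL) deflection.
* Full task sessions: per repetition, a gaze-selection marker, two HOV
  intents (reach / place-back) and two sustained ERD intents (grasp /
  release), with onsets drawn from condition-specific log-normal latency
  distributions and optional pre-activations (intent preceding the cue by an
  exponential lead).

Ground truth for every intent is recorded in the annotation stream, so
decoder and metric recovery can be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .fsm import DeviceModel, device_model
from .types import EEG_CHANNELS, EOG_CHANNELS, Annotation, SignalRecording

__all__ = [
    "ParticipantProfile",
    "SessionPlan",
    "default_profile",
    "generate_calibration_eeg",
    "generate_hov_calibration_eog",
    "generate_task_session",
]

DEVICES = ("exoskeleton", "manipulator")
MODES = ("synchronous", "asynchronous")
TASKS = ("drinking", "pouring")

#: ERD amplitude ramps (s); keeps epoch edges from splattering across windows.
ERD_RAMP = 0.2
#: HOV waveform: sigmoid rise time and sustained plateau (s).
HOV_RISE = 0.05
HOV_HOLD = 1.0
#: Scheduling margin between nominal readiness of a sub-task and its cue (s).
#: Must exceed decoder detection lag plus the largest plausible pre-activation
#: lead, so that pre-activations still land inside the correct machine state.
CUE_MARGIN = 3.0
#: Pre-activation leads are clamped below the cue margin.
LEAD_CAP = CUE_MARGIN - 0.2
#: Extra sustained-ERD time beyond the device open/close time (s), emulating
#: users holding the imagery until the motion visibly completes.
ERD_EPOCH_SLACK = 2.0


def _cond_key(device: str, mode: str) -> str:
    return f"{device}:{mode}"


def _per_condition(value) -> dict[str, float]:
    """Broadcast a scalar to all device x mode conditions; pass dicts through."""
    if isinstance(value, dict):
        return {str(k): float(v) for k, v in value.items()}
    return {_cond_key(d, m): float(value) for d in DEVICES for m in MODES}


@dataclass
class ParticipantProfile:
    """Generative parameters of one virtual user.

    Latency / pre-activation fields may be a scalar (applied to every
    condition) or a ``{"device:mode": value}`` mapping.
    """

    id: str = "P01"
    smr_center_freq: float = 11.0       # Hz, within the 8-13 Hz mu band
    smr_amplitude: float = 5.0          # microvolt RMS of the resting SMR at C3
    erd_depth: float = 0.5              # fractional SMR attenuation during imagery
    noise_level: float = 2.0            # microvolt RMS broadband background
    hov_amplitude: float = 200.0        # microvolt peak of a maximal oculoversion
    latency_mean: float | dict = 1.5    # s, cue -> intent onset, per condition
    latency_sd: float | dict = 0.5
    pre_activation_prob: float | dict = 0.0
    pre_activation_lead_mean: float | dict = 1.5  # s before the cue
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (8.0 <= self.smr_center_freq <= 13.0):
            raise ValueError("smr_center_freq must lie in [8, 13] Hz")
        if not (0.0 <= self.erd_depth <= 1.0):
            raise ValueError("erd_depth must lie in [0, 1]")
        if self.smr_amplitude <= 0 or self.hov_amplitude <= 0:
            raise ValueError("amplitudes must be positive")
        if self.noise_level < 0:
            raise ValueError("noise_level must be non-negative")
        self.latency_mean = _per_condition(self.latency_mean)
        self.latency_sd = _per_condition(self.latency_sd)
        self.pre_activation_prob = _per_condition(self.pre_activation_prob)
        self.pre_activation_lead_mean = _per_condition(self.pre_activation_lead_mean)
        for cond, sd in self.latency_sd.items():
            if sd < 0:
                raise ValueError(f"latency_sd[{cond}] must be >= 0")
        for cond, p in self.pre_activation_prob.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"pre_activation_prob[{cond}] must lie in [0, 1]")

    def condition_params(self, device: str, mode: str) -> tuple[float, float, float, float]:
        key = _cond_key(device, mode)
        try:
            return (self.latency_mean[key], self.latency_sd[key],
                    self.pre_activation_prob[key], self.pre_activation_lead_mean[key])
        except KeyError:
            raise KeyError(f"unknown condition {key!r} in profile {self.id!r}") from None


@dataclass
class SessionPlan:
    """One experimental session: task x mode x device, repeated."""

    task: str = "drinking"
    mode: str = "synchronous"
    device: str = "exoskeleton"
    n_repetitions: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.device not in DEVICES:
            raise ValueError(f"device must be one of {DEVICES}")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")


def default_profile(pid: str = "P01", seed: int = 0, **overrides) -> ParticipantProfile:
    """A participant with study-default condition parameters.

    Latency and anticipation defaults emulate the tendencies of the measured
    feasibility metrics (faster, more anticipatory control with the wearable
    exoskeleton than with the external manipulator); they are assumptions, not
    estimates of any real population.
    """
    params = dict(
        id=pid,
        rng_seed=seed,
        latency_mean={"exoskeleton:synchronous": 1.5, "exoskeleton:asynchronous": 1.0,
                      "manipulator:synchronous": 2.0, "manipulator:asynchronous": 1.8},
        latency_sd=0.8,
        pre_activation_prob={"exoskeleton:synchronous": 0.25, "exoskeleton:asynchronous": 0.35,
                             "manipulator:synchronous": 0.15, "manipulator:asynchronous": 0.20},
        pre_activation_lead_mean={"exoskeleton:synchronous": 2.0, "exoskeleton:asynchronous": 2.0,
                                  "manipulator:synchronous": 0.9, "manipulator:asynchronous": 0.9},
    )
    params.update(overrides)
    return ParticipantProfile(**params)


# ---------------------------------------------------------------------------
# noise / waveform primitives
# ---------------------------------------------------------------------------

def _pink_noise(rng: np.random.Generator, n: int, fs: float, rms: float,
                corner_hz: float = 1.0) -> np.ndarray:
    """Gaussian noise with a 1/f amplitude spectrum above ``corner_hz``.

    The spectrum is flat below the corner to keep the variance finite; the
    output is rescaled to the requested RMS.
    """
    if rms == 0.0 or n == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = 1.0 / np.sqrt(np.maximum(freqs, corner_hz))
    x = np.fft.irfft(spec * shaping, n=n)
    return x * (rms / np.std(x))


def _smr_wave(rng: np.random.Generator, envelope_rms: np.ndarray, freq: float,
              fs: float) -> np.ndarray:
    """Phase-continuous sinusoid with a time-varying RMS envelope."""
    n = envelope_rms.shape[0]
    phase0 = rng.uniform(0, 2 * np.pi)
    t = np.arange(n) / fs
    return envelope_rms * math.sqrt(2.0) * np.sin(2 * np.pi * freq * t + phase0)


def _erd_envelope(n: int, fs: float, rest_rms: float, erd_rms: float,
                  epochs: Sequence[tuple[float, float]], ramp: float = ERD_RAMP) -> np.ndarray:
    """RMS envelope: rest level with ramped attenuation inside each epoch."""
    env = np.full(n, rest_rms, dtype=float)
    t = np.arange(n) / fs
    for on, off in epochs:
        if off <= on:
            continue
        ramp_eff = min(ramp, (off - on) / 2.0)
        seg = (t >= on) & (t < off)
        local = t[seg]
        frac = np.ones(local.shape)
        if ramp_eff > 0:
            frac = np.minimum(frac, (local - on) / ramp_eff)
            frac = np.minimum(frac, (off - local) / ramp_eff)
            frac = np.clip(frac, 0.0, 1.0)
        env[seg] = rest_rms + (erd_rms - rest_rms) * frac
    return env


def _hov_shape(fs: float, rise: float = HOV_RISE, hold: float = HOV_HOLD) -> np.ndarray:
    """Unit-peak smoothed step: sigmoid rise, plateau, sigmoid return."""
    n_rise = max(int(round(rise * fs)), 2)
    n_hold = int(round(hold * fs))
    k = np.linspace(-6.0, 6.0, n_rise)
    up = 1.0 / (1.0 + np.exp(-k))
    up = (up - up[0]) / (up[-1] - up[0])
    return np.concatenate([up, np.ones(n_hold), up[::-1]])


def _add_hov(samples: np.ndarray, fs: float, onset: float, direction: str,
             amplitude: float, left_row: int, right_row: int) -> None:
    """Write one oculoversion into EOGL/EOGR rows (in place)."""
    shape = _hov_shape(fs)
    i0 = int(round(onset * fs))
    i1 = min(i0 + shape.shape[0], samples.shape[1])
    if i1 <= i0:
        return
    seg = shape[: i1 - i0]
    sign = 1.0 if direction == "right" else -1.0
    # split symmetrically so the bipolar EOGR-EOGL peak equals +/- amplitude
    samples[right_row, i0:i1] += sign * 0.5 * amplitude * seg
    samples[left_row, i0:i1] -= sign * 0.5 * amplitude * seg


def _eeg_background(rng: np.random.Generator, n: int, fs: float,
                    noise_rms: float, n_channels: int) -> np.ndarray:
    """Independent pink noise per channel plus a shared common-mode component."""
    out = np.empty((n_channels, n), dtype=float)
    for c in range(n_channels):
        out[c] = _pink_noise(rng, n, fs, noise_rms)
    common = _pink_noise(rng, n, fs, 0.5 * noise_rms)
    out += common[None, :]
    return out


# ---------------------------------------------------------------------------
# calibration protocols
# ---------------------------------------------------------------------------

def generate_calibration_eeg(profile: ParticipantProfile, n_trials: int = 42,
                             trial_len: float = 5.0, iti: float = 4.0,
                             fs: float = 1000.0,
                             seed: int | None = None) -> SignalRecording:
    """Paced motor-imagery calibration run.

    Each trial is ``trial_len`` seconds of imagined hand opening/closing
    (SMR attenuated by the profile's ERD depth) followed by an ``iti``-second
    rest interval; total duration is ``n_trials * (trial_len + iti)``.
    Annotations mark every imagery onset/offset.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if trial_len <= 0 or iti <= 0:
        raise ValueError("trial_len and iti must be positive")
    rng = np.random.default_rng(
        np.random.SeedSequence([profile.rng_seed if seed is None else seed, 101]))
    n = int(round(n_trials * (trial_len + iti) * fs))
    epochs = [(k * (trial_len + iti), k * (trial_len + iti) + trial_len)
              for k in range(n_trials)]

    samples = _eeg_background(rng, n, fs, profile.noise_level, len(EEG_CHANNELS))
    rest_rms = profile.smr_amplitude
    erd_rms = rest_rms * (1.0 - profile.erd_depth)
    env = _erd_envelope(n, fs, rest_rms, erd_rms, epochs)
    c3 = EEG_CHANNELS.index("C3")
    samples[c3] += _smr_wave(rng, env, profile.smr_center_freq, fs)

    anns = []
    for k, (on, off) in enumerate(epochs):
        anns.append(Annotation(on, "imagery_on", k))
        anns.append(Annotation(off, "imagery_off", k))
    return SignalRecording(list(EEG_CHANNELS), fs, samples, anns)


def generate_hov_calibration_eog(profile: ParticipantProfile,
                                 n_movements: int = 10,
                                 direction_sequence: Sequence[str] | None = None,
                                 pace: float = 4.0, fs: float = 1000.0,
                                 seed: int | None = None) -> SignalRecording:
    """Externally paced maximal horizontal oculoversions.

    One smoothed step deflection of ``+/- hov_amplitude`` (bipolar) per paced
    movement; annotations carry ground-truth onset and direction.
    """
    if direction_sequence is None:
        direction_sequence = ["right" if k % 2 == 0 else "left" for k in range(n_movements)]
    direction_sequence = list(direction_sequence)
    if len(direction_sequence) == 0:
        raise ValueError("direction_sequence must not be empty")
    if n_movements != len(direction_sequence):
        raise ValueError("n_movements must equal len(direction_sequence)")
    if any(d not in ("left", "right") for d in direction_sequence):
        raise ValueError("directions must be 'left' or 'right'")
    rng = np.random.default_rng(
        np.random.SeedSequence([profile.rng_seed if seed is None else seed, 202]))
    dur = 2.0 + n_movements * pace
    n = int(round(dur * fs))
    samples = np.empty((2, n))
    samples[0] = _pink_noise(rng, n, fs, profile.noise_level)
    samples[1] = _pink_noise(rng, n, fs, profile.noise_level)
    left_row, right_row = 0, 1
    anns = []
    for k, direction in enumerate(direction_sequence):
        onset = 1.0 + k * pace
        _add_hov(samples, fs, onset, direction, profile.hov_amplitude, left_row, right_row)
        anns.append(Annotation(onset, f"hov:{direction}", k))
    return SignalRecording(list(EOG_CHANNELS), fs, samples, anns)


# ---------------------------------------------------------------------------
# task sessions
# ---------------------------------------------------------------------------

def _draw_latency(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Log-normal reaction latency with the given arithmetic mean and sd."""
    if sd == 0.0:
        return mean
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, math.sqrt(sigma2)))


def _draw_onset(rng: np.random.Generator, cue: float, lat_mean: float, lat_sd: float,
                pre_p: float, pre_lead_mean: float) -> float:
    """Intent onset: reactive (after cue) or anticipatory (before cue)."""
    if pre_p > 0 and rng.random() < pre_p:
        lead = min(rng.exponential(pre_lead_mean), LEAD_CAP)
        return cue - lead
    return cue + _draw_latency(rng, lat_mean, lat_sd)


def generate_task_session(profile: ParticipantProfile, plan: SessionPlan,
                          device_timing: DeviceModel | None = None,
                          session_erd_depth: float | None = None,
                          fs: float = 1000.0,
                          ) -> tuple[SignalRecording, SignalRecording, list[Annotation]]:
    """Simulate one full session (EEG, EOG, ground-truth annotations).

    Every repetition contains the five sub-task intents in order: gaze
    selection (S1), rightward HOV (S2 reach), sustained ERD (S3 grasp),
    rightward HOV (S4 place back), sustained ERD (S5 release).  Cue times are
    scheduled so each intent falls inside the correct machine state even after
    decoder latency; ``cue:<state>`` annotations are the timing reference for
    the feasibility metrics in both modes.

    ``session_erd_depth`` defaults to ``min(1, 1.5 * erd_depth)``: during
    actual device control users sustain a deeper, more committed
    desynchronization than on average across calibration trials, which is what
    lets the commanded motion run with few interruptions.
    """
    if device_timing is None:
        device_timing = device_model(plan.device)
    if session_erd_depth is None:
        session_erd_depth = min(1.0, 1.5 * profile.erd_depth)
    lat_mean, lat_sd, pre_p, pre_lead = profile.condition_params(plan.device, plan.mode)
    rng = np.random.default_rng(
        np.random.SeedSequence([profile.rng_seed, plan.seed, 303]))

    obj = "glass" if plan.task == "drinking" else "bottle"
    erd_epoch_len = device_timing.erd_duration + ERD_EPOCH_SLACK
    margin = CUE_MARGIN

    anns: list[Annotation] = []
    erd_epochs: list[tuple[float, float]] = []
    hov_events: list[tuple[float, str]] = []
    t = 0.5
    for rep in range(plan.n_repetitions):
        anns.append(Annotation(t, "rep_start", rep))
        cue1 = t + 0.5
        anns.append(Annotation(cue1, "cue:S1", rep))
        gaze = cue1 + _draw_latency(rng, lat_mean, lat_sd)
        anns.append(Annotation(gaze, f"gaze:{obj}", rep))

        cue2 = gaze + margin
        anns.append(Annotation(cue2, "cue:S2", rep))
        hov2 = _draw_onset(rng, cue2, lat_mean, lat_sd, pre_p, pre_lead)
        hov_events.append((hov2, "right"))
        anns.append(Annotation(hov2, "hov_intent:right", rep))

        cue3 = max(hov2, cue2) + device_timing.reach_duration + margin
        anns.append(Annotation(cue3, "cue:S3", rep))
        erd3 = _draw_onset(rng, cue3, lat_mean, lat_sd, pre_p, pre_lead)
        erd_epochs.append((erd3, erd3 + erd_epoch_len))
        anns.append(Annotation(erd3, "erd_intent_on", rep))
        anns.append(Annotation(erd3 + erd_epoch_len, "erd_intent_off", rep))

        cue4 = erd3 + erd_epoch_len + 0.5 + device_timing.transport_duration + margin
        anns.append(Annotation(cue4, "cue:S4", rep))
        hov4 = _draw_onset(rng, cue4, lat_mean, lat_sd, pre_p, pre_lead)
        hov_events.append((hov4, "right"))
        anns.append(Annotation(hov4, "hov_intent:right", rep))

        cue5 = max(hov4, cue4) + device_timing.return_duration + margin
        anns.append(Annotation(cue5, "cue:S5", rep))
        erd5 = _draw_onset(rng, cue5, lat_mean, lat_sd, pre_p, pre_lead)
        erd_epochs.append((erd5, erd5 + erd_epoch_len))
        anns.append(Annotation(erd5, "erd_intent_on", rep))
        anns.append(Annotation(erd5 + erd_epoch_len, "erd_intent_off", rep))

        rep_end = erd5 + erd_epoch_len + 0.5 + device_timing.return_duration + 1.0
        anns.append(Annotation(rep_end, "rep_end", rep))
        t = rep_end + 1.0

    duration = t + 1.0
    n = int(round(duration * fs))

    eeg_samples = _eeg_background(rng, n, fs, profile.noise_level, len(EEG_CHANNELS))
    rest_rms = profile.smr_amplitude
    erd_rms = rest_rms * (1.0 - session_erd_depth)
    env = _erd_envelope(n, fs, rest_rms, erd_rms, erd_epochs)
    eeg_samples[EEG_CHANNELS.index("C3")] += _smr_wave(rng, env, profile.smr_center_freq, fs)

    eog_samples = np.empty((2, n))
    eog_samples[0] = _pink_noise(rng, n, fs, profile.noise_level)
    eog_samples[1] = _pink_noise(rng, n, fs, profile.noise_level)
    for onset, direction in hov_events:
        _add_hov(eog_samples, fs, onset, direction, profile.hov_amplitude, 0, 1)

    anns.sort(key=lambda a: (a.time, a.label))
    eeg = SignalRecording(list(EEG_CHANNELS), fs, eeg_samples, list(anns))
    eog = SignalRecording(list(EOG_CHANNELS), fs, eog_samples, list(anns))
    return eeg, eog, list(anns)
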