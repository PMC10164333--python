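"""Horizontal-oculoversion (HOV) detection on bipolar EOG.

Calibration measures the mean absolute peak of the 0.1-5 Hz band-passed
bipolar signal across paced maximal eye movements and sets the detection
threshold at 70% of it.  Online, an event fires at the first sample whose
absolute amplitude crosses the threshold; the sign gives the direction
(positive = rightward under the fixed polarity convention), and a refractory
period enforces one saccade per command.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .preprocessing import EOG_BAND, FilterSpec, bandpass, bipolar_eog
from .types import SignalRecording

__all__ = ["HovCalibration", "HovEvent", "HovDecoder", "calibrate_hov", "detect_hov"]

THRESHOLD_FRACTION = 0.70
#: window after each paced-movement onset within which the peak is measured (s)
_PEAK_WINDOW = 2.0


@dataclass
class HovCalibration:
    """Frozen HOV decoder state."""

    threshold: float                     # microvolts, positive magnitude
    refractory: float = 1.0              # s, one saccade per command
    polarity_right_positive: bool = True
    mean_max_peak: float = float("nan")  # microvolts, mean calibration peak

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.refractory < 0:
            raise ValueError("refractory must be >= 0")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "HovCalibration":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass(frozen=True)
class HovEvent:
    time: float            # s, threshold-crossing sample
    direction: str         # 'left' | 'right'
    peak_amplitude: float  # microvolts, signed peak within the refractory span


def _bipolar_filtered(recording: SignalRecording, mode: str) -> np.ndarray:
    if len(recording.channel_labels) == 1:
        return recording.samples[0]
    spec = FilterSpec(*EOG_BAND, mode=mode)
    return bipolar_eog(bandpass(recording, spec)).samples[0]


def calibrate_hov(calib: SignalRecording, refractory: float = 1.0,
                  peak_window: float = _PEAK_WINDOW) -> HovCalibration:
    """Set the detection threshold to 70% of the mean paced-movement peak."""
    movements = calib.events("hov")
    if not movements:
        raise ValueError("no paced hov:<direction> annotations present")
    x = _bipolar_filtered(calib, "offline_zero_phase")
    fs = calib.fs
    peaks = []
    for ann in movements:
        i0 = int(round(ann.time * fs))
        i1 = min(i0 + int(round(peak_window * fs)), x.shape[0])
        if i1 > i0:
            peaks.append(np.max(np.abs(x[i0:i1])))
    mean_peak = float(np.mean(peaks))
    if mean_peak <= 0:
        raise ValueError("no measurable deflection in calibration recording")
    return HovCalibration(threshold=THRESHOLD_FRACTION * mean_peak,
                          refractory=refractory, mean_max_peak=mean_peak)


def detect_hov(stream: SignalRecording | np.ndarray, cal: HovCalibration,
               fs: float | None = None) -> list[HovEvent]:
    """Threshold-crossing HOV events on a causal bipolar stream."""
    if isinstance(stream, SignalRecording):
        fs = stream.fs
        x = _bipolar_filtered(stream, "online_causal")
    else:
        if fs is None:
            raise ValueError("fs required when passing a bare sample array")
        x = np.asarray(stream, dtype=float)
    sign = 1.0 if cal.polarity_right_positive else -1.0
    above = np.abs(x) >= cal.threshold
    events: list[HovEvent] = []
    refr = int(round(cal.refractory * fs))
    i, n = 0, x.shape[0]
    idx = np.flatnonzero(above)
    k = 0
    while k < idx.shape[0]:
        i = idx[k]
        j1 = min(i + max(refr, 1), n)
        seg = x[i:j1]
        peak = seg[np.argmax(np.abs(seg))]
        direction = "right" if sign * x[i] > 0 else "left"
        events.append(HovEvent(time=i / fs, direction=direction,
                               peak_amplitude=float(peak)))
        # skip to the first sample after the refractory period
        k = np.searchsorted(idx, i + refr)
    return events


class HovDecoder:
    """fit/decode wrapper around the HOV calibration and detection."""

    def __init__(self, refractory: float = 1.0):
        self.refractory = refractory
        self.calibration_: HovCalibration | None = None

    def fit(self, calib: SignalRecording) -> HovCalibration:
        self.calibration_ = calibrate_hov(calib, self.refractory)
        return self.calibration_

    def decode(self, eog: SignalRecording) -> list[HovEvent]:
        if self.calibration_ is None:
            raise RuntimeError("decoder is not calibrated; call fit() first")
        return detect_hov(eog, self.calibration_)
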