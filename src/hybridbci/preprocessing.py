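"""Spatial and temporal filtering for the online interface.

EEG is band-passed 0.1-30 Hz and reduced to a surface-Laplacian C3
derivation (Hjorth-style small Laplacian: C3 minus the mean of F3, T3, Cz,
P3).  EOG is band-passed 0.1-5 Hz and reduced to the bipolar EOGR - EOGL
derivation, with rightward gaze positive.  Filters are 4th-order Butterworth;
calibration uses zero-phase forward-backward filtering, online simulation the
causal variant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .types import SignalRecording

__all__ = ["FilterSpec", "bandpass", "laplacian", "bipolar_eog",
           "EEG_BAND", "EOG_BAND"]

EEG_BAND = (0.1, 30.0)
EOG_BAND = (0.1, 5.0)


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass filter specification.

    ``mode`` selects zero-phase forward-backward filtering (offline
    calibration) or single-pass causal filtering (online simulation, which
    introduces only causal delay).
    """

    low_cut: float
    high_cut: float
    order: int = 4
    mode: str = "offline_zero_phase"

    def __post_init__(self) -> None:
        if not (0 <= self.low_cut < self.high_cut):
            raise ValueError("need 0 <= low_cut < high_cut")
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.mode not in ("offline_zero_phase", "online_causal"):
            raise ValueError("mode must be 'offline_zero_phase' or 'online_causal'")

    def sos(self, fs: float) -> np.ndarray:
        if self.high_cut >= fs / 2:
            raise ValueError(
                f"high_cut {self.high_cut} Hz >= Nyquist ({fs / 2} Hz)")
        return sps.butter(self.order, [self.low_cut, self.high_cut],
                          btype="bandpass", fs=fs, output="sos")


def bandpass(recording: SignalRecording, spec: FilterSpec) -> SignalRecording:
    """Band-pass every channel; annotations are preserved."""
    sos = spec.sos(recording.fs)
    if spec.mode == "offline_zero_phase":
        filtered = sps.sosfiltfilt(sos, recording.samples, axis=1)
    else:
        filtered = sps.sosfilt(sos, recording.samples, axis=1)
    return SignalRecording(list(recording.channel_labels), recording.fs,
                           np.ascontiguousarray(filtered), list(recording.annotations))


def laplacian(recording: SignalRecording, center: str = "C3",
              neighbors: Sequence[str] = ("F3", "T3", "Cz", "P3")) -> SignalRecording:
    """Surface-Laplacian derivation: center minus the mean of its neighbors."""
    missing = [ch for ch in [center, *neighbors] if ch not in recording.channel_labels]
    if missing:
        raise KeyError(f"channel(s) missing from recording: {missing}")
    out = recording.channel(center) - np.mean(
        [recording.channel(ch) for ch in neighbors], axis=0)
    return SignalRecording([f"{center}-lap"], recording.fs, out[None, :],
                           list(recording.annotations))


def bipolar_eog(recording: SignalRecording) -> SignalRecording:
    """Bipolar EOG derivation EOGR - EOGL; positive deflections = rightward gaze."""
    for ch in ("EOGL", "EOGR"):
        if ch not in recording.channel_labels:
            raise KeyError(f"channel {ch!r} missing from recording")
    out = recording.channel("EOGR") - recording.channel("EOGL")
    return SignalRecording(["EOG-bipolar"], recording.fs, out[None, :],
                           list(recording.annotations))
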