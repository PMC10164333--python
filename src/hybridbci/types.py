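"""Core containers shared across the pipeline.

A :class:`SignalRecording` is a deliberately small in-memory container: an
ordered set of channels, a fixed sampling rate, a ``(n_channels, n_samples)``
float array in microvolts, and a flat list of timestamped annotations.
Conversion helpers to/from :mod:`mne` are provided for interoperability with
the wider EEG ecosystem, but the pipeline itself only relies on the array.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Annotation", "SignalRecording"]

EEG_CHANNELS = ["F3", "T3", "C3", "Cz", "P3"]
EOG_CHANNELS = ["EOGL", "EOGR"]


@dataclass(frozen=True)
class Annotation:
    """A timestamped event marker.

    Parameters
    ----------
    time : float
        Event time in seconds from recording onset.
    label : str
        Event label.  Structured labels use ``kind:detail`` form, e.g.
        ``"hov_intent:right"`` or ``"cue:S3"``.
    trial_index : int
        Trial / repetition the event belongs to; ``-1`` when not applicable.
    """

    time: float
    label: str
    trial_index: int = -1


@dataclass
class SignalRecording:
    """Annotated multichannel time series at a fixed sampling rate (microvolts)."""

    channel_labels: list[str]
    fs: float
    samples: np.ndarray
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (channels x time) array")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError(
                f"channel count mismatch: {len(self.channel_labels)} labels for "
                f"{self.samples.shape[0]} rows"
            )
        dur = self.duration
        for ann in self.annotations:
            if not (0.0 <= ann.time <= dur + 1e-9):
                raise ValueError(
                    f"annotation {ann.label!r} at {ann.time:.3f} s outside [0, {dur:.3f}]"
                )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.samples.shape[1] / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def channel(self, label: str) -> np.ndarray:
        """Return one channel as a 1-D view, by label."""
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording "
                           f"(have {self.channel_labels})") from None
        return self.samples[idx]

    def copy_with(self, **changes) -> "SignalRecording":
        rec = replace(self, **changes)
        return rec

    def events(self, prefix: str) -> list[Annotation]:
        """Annotations whose label equals ``prefix`` or starts with ``prefix + ':'``."""
        return [a for a in self.annotations
                if a.label == prefix or a.label.startswith(prefix + ":")]

    # -- interoperability -------------------------------------------------
    def to_mne(self):
        """Convert to an :class:`mne.io.RawArray` (data scaled to volts)."""
        import mne

        info = mne.create_info(self.channel_labels, self.fs,
                               ch_types=["eeg"] * len(self.channel_labels))
        raw = mne.io.RawArray(self.samples * 1e-6, info, verbose="error")
        if self.annotations:
            raw.set_annotations(mne.Annotations(
                onset=[a.time for a in self.annotations],
                duration=[0.0] * len(self.annotations),
                description=[a.label for a in self.annotations]))
        return raw

    @classmethod
    def from_mne(cls, raw) -> "SignalRecording":
        """Build from an mne Raw object (assumed volts; converted to microvolts)."""
        anns = [Annotation(float(on), str(desc))
                for on, desc in zip(raw.annotations.onset,
                                    raw.annotations.description)]
        return cls(channel_labels=list(raw.ch_names), fs=float(raw.info["sfreq"]),
                   samples=raw.get_data() * 1e6, annotations=anns)
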