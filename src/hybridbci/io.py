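"""File interfaces: headered signal CSV, event tables, configs, EDF import.

Signals are written as headered CSV (``time_s`` plus one column per channel,
microvolts) and events as a ``time_s, label, trial_index`` table.  Real
recordings, when available, can enter the pipeline from EDF files through
:func:`read_edf` (requires the optional :mod:`mne` dependency).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import Annotation, SignalRecording

__all__ = ["write_signal_csv", "read_signal_csv", "write_events_csv",
           "read_events_csv", "read_edf", "load_config", "dump_config"]


def write_signal_csv(recording: SignalRecording, path, float_format: str = "%.6f") -> None:
    """Write samples as a headered CSV; annotations go to a sidecar
    ``<name>.events.csv`` when present."""
    path = Path(path)
    df = pd.DataFrame(recording.samples.T, columns=recording.channel_labels)
    df.insert(0, "time_s", recording.times)
    df.to_csv(path, index=False, float_format=float_format)
    if recording.annotations:
        write_events_csv(recording.annotations, path.with_suffix(".events.csv"))


def read_signal_csv(path, fs: float | None = None) -> SignalRecording:
    """Read a headered signal CSV (first column ``time_s``); picks up a
    ``<name>.events.csv`` sidecar when present."""
    path = Path(path)
    df = pd.read_csv(path)
    if df.columns[0] != "time_s":
        raise ValueError("signal CSV must start with a time_s column")
    t = df["time_s"].to_numpy()
    if fs is None:
        fs = 1.0 / float(np.median(np.diff(t)))
    samples = df.drop(columns="time_s").to_numpy().T
    anns: list[Annotation] = []
    sidecar = path.with_suffix(".events.csv")
    if sidecar.exists():
        anns = read_events_csv(sidecar)
    return SignalRecording(list(df.columns[1:]), fs, samples, anns)


def write_events_csv(annotations: list[Annotation], path) -> None:
    pd.DataFrame(
        [(a.time, a.label, a.trial_index) for a in annotations],
        columns=["time_s", "label", "trial_index"],
    ).to_csv(path, index=False, float_format="%.6f")


def read_events_csv(path) -> list[Annotation]:
    df = pd.read_csv(path)
    return [Annotation(float(r.time_s), str(r.label), int(r.trial_index))
            for r in df.itertuples()]


def read_edf(path) -> SignalRecording:
    """Import an EDF recording (scaled to microvolts) via mne."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF import requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return SignalRecording.from_mne(raw)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def dump_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
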