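"""Shared human-robot control: the five-state task supervisor.

The finite-state machine sequences each repetition of a drinking or pouring
task through five sub-tasks,

    S1 object selection (gaze; left HOV vetoes the selection)
    S2 reaching (right HOV triggers an automatic reach)
    S3 grasping + transport (hand closes while ERD is active; transport auto)
    S4 placing back (right HOV triggers an automatic return)
    S5 releasing + homing (hand opens while ERD is active; homing auto)

running at 100 Hz.  Hand motion in S3/S5 advances only while the SMR-ERD
signal is at or below the detection threshold and pauses otherwise; it
completes once the cumulative commanded time reaches the device's mechanism
open/close time (1.5 s hand exoskeleton, 1.2 s gripper).  Inputs irrelevant
to the current state are logged and ignored, which forbids concurrent
triggering of arm and hand movements.  The machine is pure: replays on
identical inputs are bit-identical.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import Annotation, SignalRecording

__all__ = ["DeviceModel", "Phase", "TickInput", "TaskLog", "SharedControlFsm",
           "device_model", "fsm_step", "run_trial", "run_session", "TICK"]

#: FSM tick period (s); the supervisor runs at 100 Hz.
TICK = 0.01


@dataclass(frozen=True)
class DeviceModel:
    """Timing constants representing a robotic device in the pipeline."""

    name: str
    erd_duration: float          # s of cumulative commanded motion to open/close
    reach_duration: float = 5.0  # s, automatic reach (S2)
    return_duration: float = 5.0  # s, automatic return/homing (S4, S5)
    transport_duration: float = 5.0  # s, automatic transport (S3)

    def __post_init__(self) -> None:
        for attr in ("erd_duration", "reach_duration", "return_duration",
                     "transport_duration"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be positive")


def device_model(name: str, **overrides) -> DeviceModel:
    """Standard device models: hand exoskeleton (1.5 s) and gripper (1.2 s)."""
    if name == "exoskeleton":
        return DeviceModel(name="exoskeleton", erd_duration=1.5, **overrides)
    if name == "manipulator":
        return DeviceModel(name="manipulator", erd_duration=1.2, **overrides)
    raise ValueError(f"unknown device {name!r}")


class Phase(enum.Enum):
    """Machine phase: the five states plus their automatic-motion sub-phases."""

    S1_SELECT = "S1"
    S2_AWAIT_HOV = "S2"
    S2_REACH = "S2_motion"
    S3_GRASP = "S3"
    S3_TRANSPORT = "S3_motion"
    S4_AWAIT_HOV = "S4"
    S4_RETURN = "S4_motion"
    S5_RELEASE = "S5"
    S5_HOME = "S5_motion"

    @property
    def state(self) -> str:
        """The S1..S5 state this phase belongs to."""
        return self.value.split("_")[0]


@dataclass(frozen=True)
class TickInput:
    """Decoded interface outputs for one 10 ms tick."""

    gaze_id: str | None = None       # selected object label, if any
    hov_event: str | None = None     # 'left' | 'right'
    erd_active: bool = False

    def __post_init__(self) -> None:
        if self.hov_event not in (None, "left", "right"):
            raise ValueError(f"malformed hov_event {self.hov_event!r}")


@dataclass(frozen=True)
class LogRecord:
    time: float
    event: str    # cue_issued | gaze_select | veto | hov | erd_on | erd_off |
                  # motion_start | motion_pause | motion_complete | state_enter |
                  # input_ignored
    state: str
    detail: str = ""
    trial_index: int = -1


@dataclass
class TaskLog:
    """Ordered, timestamped record of one or more repetitions."""

    records: list[LogRecord] = field(default_factory=list)

    def append(self, rec: LogRecord) -> None:
        if self.records and rec.time < self.records[-1].time - 1e-9:
            raise ValueError("log times must be non-decreasing")
        self.records.append(rec)

    def filter(self, event: str, trial_index: int | None = None) -> list[LogRecord]:
        return [r for r in self.records if r.event == event
                and (trial_index is None or r.trial_index == trial_index)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.time, r.event, r.state, r.detail, r.trial_index) for r in self.records],
            columns=["time_s", "event", "state", "detail", "trial_index"])

    @property
    def n_repetitions(self) -> int:
        return len({r.trial_index for r in self.records if r.trial_index >= 0})


class SharedControlFsm:
    """The 100 Hz supervisor for one repetition."""

    def __init__(self, device: DeviceModel, mode: str = "synchronous",
                 trial_index: int = -1):
        if mode not in ("synchronous", "asynchronous"):
            raise ValueError("mode must be 'synchronous' or 'asynchronous'")
        self.device = device
        self.mode = mode
        self.trial_index = trial_index
        self.phase = Phase.S1_SELECT
        self.selected: str | None = None
        self.commanded_time = 0.0    # cumulative hand-motion command (s)
        self.phase_elapsed = 0.0     # time in current automatic-motion phase (s)
        self.hand_moving = False
        self.repetition_complete = False

    # -- helpers ----------------------------------------------------------
    def _log(self, out: list[LogRecord], t: float, event: str, detail: str = "") -> None:
        out.append(LogRecord(t, event, self.phase.state, detail, self.trial_index))

    def _enter(self, out: list[LogRecord], t: float, phase: Phase, detail: str = "") -> None:
        prev_state = self.phase.state
        self.phase = phase
        self.phase_elapsed = 0.0
        if phase.state != prev_state or phase in (Phase.S1_SELECT,):
            self._log(out, t, "state_enter", detail or phase.state)

    # -- one tick ---------------------------------------------------------
    def step(self, t: float, tick: TickInput) -> list[LogRecord]:
        """Advance the machine by one 10 ms tick; returns emitted log records."""
        out: list[LogRecord] = []
        dev = self.device
        ph = self.phase

        if ph is Phase.S1_SELECT:
            if tick.hov_event == "left":
                if self.selected is not None:
                    self.selected = None
                    self._log(out, t, "veto", "selection aborted")
                else:
                    self._log(out, t, "input_ignored", "hov:left")
            if tick.gaze_id is not None:
                self.selected = tick.gaze_id
                self._log(out, t, "gaze_select", tick.gaze_id)
                self._enter(out, t, Phase.S2_AWAIT_HOV)
            elif tick.hov_event == "right":
                self._log(out, t, "input_ignored", "hov:right")
            if tick.erd_active:
                pass  # ERD carries no meaning outside S3/S5
            return out

        if ph is Phase.S2_AWAIT_HOV:
            if tick.hov_event == "left":
                # veto window: selection can be aborted until a reach is triggered
                self._log(out, t, "hov", "left")
                self.selected = None
                self._log(out, t, "veto", "selection aborted")
                self._enter(out, t, Phase.S1_SELECT)
            elif tick.hov_event == "right":
                self._log(out, t, "hov", "right")
                self._log(out, t, "motion_start", "reach")
                self._enter(out, t, Phase.S2_REACH)
            elif tick.gaze_id is not None:
                self._log(out, t, "input_ignored", f"gaze:{tick.gaze_id}")
            return out

        if ph in (Phase.S2_REACH, Phase.S3_TRANSPORT, Phase.S4_RETURN, Phase.S5_HOME):
            if tick.hov_event is not None:
                self._log(out, t, "input_ignored", f"hov:{tick.hov_event}")
            if tick.gaze_id is not None:
                self._log(out, t, "input_ignored", f"gaze:{tick.gaze_id}")
            self.phase_elapsed += TICK
            dur = {Phase.S2_REACH: dev.reach_duration,
                   Phase.S3_TRANSPORT: dev.transport_duration,
                   Phase.S4_RETURN: dev.return_duration,
                   Phase.S5_HOME: dev.return_duration}[ph]
            if self.phase_elapsed >= dur - 1e-9:
                te = t + TICK  # the motion runs through the end of this tick
                name = {Phase.S2_REACH: "reach", Phase.S3_TRANSPORT: "transport",
                        Phase.S4_RETURN: "return", Phase.S5_HOME: "home"}[ph]
                self._log(out, te, "motion_complete", name)
                nxt = {Phase.S2_REACH: Phase.S3_GRASP,
                       Phase.S3_TRANSPORT: Phase.S4_AWAIT_HOV,
                       Phase.S4_RETURN: Phase.S5_RELEASE,
                       Phase.S5_HOME: Phase.S1_SELECT}[ph]
                if ph is Phase.S5_HOME:
                    self.repetition_complete = True
                    self.selected = None
                    self.commanded_time = 0.0
                    self._enter(out, te, nxt, "S1 (repetition complete)")
                else:
                    if nxt is Phase.S3_GRASP:
                        self.commanded_time = 0.0
                        self.hand_moving = False
                    self._enter(out, te, nxt)
            return out

        if ph in (Phase.S3_GRASP, Phase.S5_RELEASE):
            motion = "grasp" if ph is Phase.S3_GRASP else "release"
            if tick.hov_event is not None:
                self._log(out, t, "input_ignored", f"hov:{tick.hov_event}")
            if tick.gaze_id is not None:
                self._log(out, t, "input_ignored", f"gaze:{tick.gaze_id}")
            if tick.erd_active:
                if not self.hand_moving:
                    self.hand_moving = True
                    self._log(out, t, "motion_start", motion)
                self.commanded_time += TICK
                if self.commanded_time >= dev.erd_duration - 1e-9:
                    te = t + TICK
                    self.hand_moving = False
                    self._log(out, te, "motion_complete", motion)
                    if ph is Phase.S3_GRASP:
                        self._log(out, te, "motion_start", "transport")
                        self._enter(out, te, Phase.S3_TRANSPORT)
                        self.commanded_time = 0.0
                    else:
                        self._log(out, te, "motion_start", "home")
                        self._enter(out, te, Phase.S5_HOME)
            else:
                if self.hand_moving:
                    self.hand_moving = False
                    self._log(out, t, "motion_pause", motion)
            return out

        if ph is Phase.S4_AWAIT_HOV:
            if tick.hov_event == "right":
                self._log(out, t, "hov", "right")
                self._log(out, t, "motion_start", "return")
                self._enter(out, t, Phase.S4_RETURN)
            elif tick.hov_event == "left":
                self._log(out, t, "input_ignored", "hov:left")
            if tick.gaze_id is not None:
                self._log(out, t, "input_ignored", f"gaze:{tick.gaze_id}")
            return out

        raise RuntimeError(f"unhandled phase {ph}")  # pragma: no cover


def fsm_step(fsm: SharedControlFsm, t: float, tick: TickInput) -> tuple[Phase, list[LogRecord]]:
    """Functional wrapper: advance ``fsm`` one tick, return (phase, records)."""
    records = fsm.step(t, tick)
    return fsm.phase, records


# ---------------------------------------------------------------------------
# driving the machine from decoded signals
# ---------------------------------------------------------------------------

def run_trial(erd_intervals: list[tuple[float, float]],
              hov_events: list,
              annotations: list[Annotation],
              device: DeviceModel, mode: str,
              t0: float, t1: float, trial_index: int = 0) -> TaskLog:
    """Drive the supervisor over one repetition window [t0, t1).

    ``erd_intervals`` and ``hov_events`` are the decoder outputs (absolute
    times); gaze selections and cue markers are taken from the ground-truth
    annotation stream (the vision system is outside the pipeline).  In
    synchronous mode ``cue_issued`` records reflect the visual cue; in
    asynchronous mode they silently mark the timing reference used by the
    feasibility metrics.
    """
    n_ticks = int(np.ceil((t1 - t0) / TICK))
    erd_active = np.zeros(n_ticks, dtype=bool)
    for on, off in erd_intervals:
        i0 = max(int(np.ceil((on - t0) / TICK)), 0)
        i1 = min(int(np.ceil((off - t0) / TICK)), n_ticks)
        if i1 > i0:
            erd_active[i0:i1] = True

    hov_at: dict[int, str] = {}
    for ev in hov_events:
        i = int(round((ev.time - t0) / TICK))
        if 0 <= i < n_ticks:
            hov_at.setdefault(i, ev.direction)

    gaze_at: dict[int, str] = {}
    cue_at: dict[int, str] = {}
    for ann in annotations:
        if not (t0 - 1e-9 <= ann.time < t1):
            continue
        i = int(round((ann.time - t0) / TICK))
        if i >= n_ticks:
            continue
        if ann.label.startswith("gaze:"):
            gaze_at[i] = ann.label.split(":", 1)[1]
        elif ann.label.startswith("cue:"):
            cue_at[i] = ann.label.split(":", 1)[1]

    fsm = SharedControlFsm(device, mode, trial_index)
    log = TaskLog()
    log.append(LogRecord(t0, "state_enter", "S1", "S1 (repetition start)", trial_index))
    # decoder activation boundaries are logged even when the state ignores
    # them, so the metrics can see every interface activation
    erd_edge_on = {int(np.ceil((on - t0) / TICK)) for on, _ in erd_intervals
                   if t0 <= on < t1}
    erd_edge_off = {int(np.ceil((off - t0) / TICK)) for _, off in erd_intervals
                    if t0 <= off < t1}
    for i in range(n_ticks):
        t = t0 + i * TICK
        if i in cue_at:
            silent = " (silent)" if mode == "asynchronous" else ""
            log.append(LogRecord(t, "cue_issued", fsm.phase.state,
                                 cue_at[i] + silent, trial_index))
        if i in erd_edge_on:
            log.append(LogRecord(t, "erd_on", fsm.phase.state, "decoder", trial_index))
        if i in erd_edge_off:
            log.append(LogRecord(t, "erd_off", fsm.phase.state, "decoder", trial_index))
        if i in hov_at:
            log.append(LogRecord(t, "hov", fsm.phase.state,
                                 f"decoder:{hov_at[i]}", trial_index))
        tick = TickInput(gaze_id=gaze_at.get(i), hov_event=hov_at.get(i),
                         erd_active=bool(erd_active[i]))
        for rec in fsm.step(t, tick):
            log.append(rec)
        if fsm.repetition_complete:
            break
    status = "complete" if fsm.repetition_complete else "incomplete"
    log.append(LogRecord(min(t0 + n_ticks * TICK, t1), "trial_end", fsm.phase.state,
                         status, trial_index))
    return log


def run_session(eeg: SignalRecording, eog: SignalRecording,
                annotations: list[Annotation], erd_cal, hov_cal,
                device: DeviceModel, mode: str,
                erd_dwell: float = 0.2) -> TaskLog:
    """Decode a full session and run the supervisor repetition by repetition.

    Each repetition window (``rep_start`` .. ``rep_end`` annotations) gets a
    fresh machine, so a stalled trial is marked incomplete without cascading
    into the next one.
    """
    from .eog import detect_hov
    from .erd import _c3_derivation, detect_erd_online

    c3 = _c3_derivation(eeg, "online_causal")
    erd_intervals = detect_erd_online(c3.samples[0], erd_cal, erd_dwell)
    hov_events = detect_hov(eog, hov_cal)

    reps = sorted({a.trial_index for a in annotations if a.label == "rep_start"})
    log = TaskLog()
    for rep in reps:
        t0 = next(a.time for a in annotations
                  if a.label == "rep_start" and a.trial_index == rep)
        t1 = next(a.time for a in annotations
                  if a.label == "rep_end" and a.trial_index == rep)
        trial_log = run_trial(erd_intervals, hov_events, annotations,
                              device, mode, t0, t1, trial_index=rep)
        log.records.extend(trial_log.records)
    return log
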