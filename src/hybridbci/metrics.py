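"""Per-trial and per-condition feasibility measures.

Three quantities summarize how fluently the interface drives the robot:

* **normalized open/close time** (grasp/release sub-tasks): the elapsed hand
  open/close time relative to the mechanism's own open/close time
  (``(t_elapsed - ERD_duration) / ERD_duration``; 0 means the motion ran
  without a single interruption),
* **TTI** (time to initialize): cue -> first decoder activation, >= 0,
* **Pre-TTI**: when the interface was already activated before the cue, the
  (negative) interval from the cue back to the last prior activation onset.

Exactly one of TTI / Pre-TTI exists per successful sub-task initialization;
their union (TTI+Pre-TTI) is the reaction measure pooled per condition.
A condition is *fluent* when the median TTI+Pre-TTI stays below 3 s and
*reliable* when the 75th percentile stays below 5 s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fsm import DeviceModel, TaskLog

__all__ = ["TrialMetrics", "ConditionSummary", "open_close_norm",
           "tti_or_pre_tti", "trial_metrics_from_log", "summarize_condition",
           "metrics_frame"]

FLUENT_CUT = 3.0     # s, median criterion
RELIABLE_CUT = 5.0   # s, 75th-percentile criterion

#: sub-task -> (interface modality, cue label)
SUBTASK_MODALITY = {"S2": "hov", "S3": "erd", "S4": "hov", "S5": "erd"}


@dataclass
class TrialMetrics:
    """Timing measures of one sub-task initialization within one repetition."""

    subtask: str
    trial_index: int = -1
    successful: bool = True
    tti: float | None = None             # s, >= 0
    pre_tti: float | None = None         # s, <= 0
    t_open_close_norm: float | None = None  # grasp/release only

    def __post_init__(self) -> None:
        if self.tti is not None and self.pre_tti is not None:
            raise ValueError("exactly one of tti/pre_tti may be set")
        if self.tti is not None and self.tti < 0:
            raise ValueError("tti must be >= 0")
        if self.pre_tti is not None and self.pre_tti > 0:
            raise ValueError("pre_tti must be <= 0")

    @property
    def tti_plus_pre_tti(self) -> float | None:
        return self.tti if self.tti is not None else self.pre_tti


@dataclass
class ConditionSummary:
    """Pooled TTI+Pre-TTI summary for one device x mode condition."""

    condition: tuple[str, str]
    median: float
    q25: float
    q75: float
    fluent: bool
    reliable: bool
    n_trials: int          # successful initializations pooled
    n_attempted: int = -1  # including unsuccessful sub-tasks

    def __post_init__(self) -> None:
        if not (self.q25 <= self.median <= self.q75):
            raise ValueError("quartiles must be ordered q25 <= median <= q75")


def open_close_norm(t_elapsed: float, erd_duration: float) -> float:
    """Normalized open/close time: ``(t_elapsed - erd_duration) / erd_duration``.

    0 means the elapsed opening/closing time equals the mechanism time; values
    above 0 measure how much the user's interruptions stretched the motion.
    """
    if erd_duration <= 0:
        raise ValueError("erd_duration must be positive")
    if t_elapsed <= 0:
        raise ValueError("t_elapsed must be positive")
    return (t_elapsed - erd_duration) / erd_duration


def tti_or_pre_tti(cue_time: float, activations: list[tuple[float, float]],
                   window_end: float, window_start: float = -np.inf,
                   subtask: str = "", trial_index: int = -1) -> TrialMetrics:
    """Classify one sub-task initialization as TTI, Pre-TTI or unsuccessful.

    ``activations`` are decoder activation intervals (onset, offset); for
    instantaneous events pass ``onset == offset``.  Only activations whose
    onset lies in ``[window_start, window_end)`` are in scope (activations
    from before the previous sub-task's completion carry no intent for this
    one).
    """
    onsets = sorted(on for on, _ in activations
                    if window_start - 1e-9 <= on < window_end)
    prior = [on for on in onsets if on <= cue_time]
    if prior:
        return TrialMetrics(subtask=subtask, trial_index=trial_index,
                            pre_tti=prior[-1] - cue_time)
    later = [on for on in onsets if on > cue_time]
    if later:
        return TrialMetrics(subtask=subtask, trial_index=trial_index,
                            tti=later[0] - cue_time)
    return TrialMetrics(subtask=subtask, trial_index=trial_index, successful=False)


# ---------------------------------------------------------------------------
# extraction from task logs
# ---------------------------------------------------------------------------

def _decoder_erd_intervals(log: TaskLog, rep: int) -> list[tuple[float, float]]:
    ons = [r.time for r in log.records if r.event == "erd_on"
           and r.detail == "decoder" and r.trial_index == rep]
    offs = [r.time for r in log.records if r.event == "erd_off"
            and r.detail == "decoder" and r.trial_index == rep]
    out = []
    for on in ons:
        later = [o for o in offs if o > on]
        out.append((on, later[0] if later else np.inf))
    return out


def _decoder_hov_times(log: TaskLog, rep: int) -> list[tuple[float, float]]:
    return [(r.time, r.time) for r in log.records if r.event == "hov"
            and r.detail.startswith("decoder:right") and r.trial_index == rep]


def trial_metrics_from_log(log: TaskLog, device: DeviceModel) -> list[TrialMetrics]:
    """All per-sub-task metrics of a (possibly multi-repetition) task log."""
    out: list[TrialMetrics] = []
    reps = sorted({r.trial_index for r in log.records if r.trial_index >= 0})
    for rep in reps:
        recs = [r for r in log.records if r.trial_index == rep]
        cues = {}
        for r in recs:
            if r.event == "cue_issued":
                cues[r.detail.split(" ")[0]] = r.time
        trial_end = max((r.time for r in recs if r.event == "trial_end"),
                        default=max(r.time for r in recs))
        completions = {r.detail: r.time for r in recs if r.event == "motion_complete"}
        gaze = next((r.time for r in recs if r.event == "gaze_select"), None)
        rep_start = min(r.time for r in recs)
        window_starts = {"S2": gaze if gaze is not None else rep_start,
                         "S3": completions.get("reach", cues.get("S3", rep_start)),
                         "S4": completions.get("transport", cues.get("S4", rep_start)),
                         "S5": completions.get("return", cues.get("S5", rep_start))}
        erd_acts = _decoder_erd_intervals(log, rep)
        hov_acts = _decoder_hov_times(log, rep)
        order = ["S2", "S3", "S4", "S5"]
        for idx, st in enumerate(order):
            if st not in cues:
                continue
            nxt = next((cues[s] for s in order[idx + 1:] if s in cues), trial_end)
            acts = erd_acts if SUBTASK_MODALITY[st] == "erd" else hov_acts
            tm = tti_or_pre_tti(cues[st], acts, nxt, window_starts[st],
                                subtask=st, trial_index=rep)
            if st in ("S3", "S5"):
                motion = "grasp" if st == "S3" else "release"
                starts = [r.time for r in recs if r.event == "motion_start"
                          and r.detail == motion]
                if motion in completions and starts:
                    tm.t_open_close_norm = open_close_norm(
                        completions[motion] - starts[0], device.erd_duration)
            out.append(tm)
    return out


def metrics_frame(metrics: list[TrialMetrics], **constants) -> pd.DataFrame:
    """Tidy per-trial table; ``constants`` (participant, device, ...) become columns."""
    rows = []
    for m in metrics:
        rows.append({**constants, "repetition": m.trial_index, "subtask": m.subtask,
                     "successful": m.successful, "tti": m.tti, "pre_tti": m.pre_tti,
                     "tti_plus_pre_tti": m.tti_plus_pre_tti,
                     "open_close_norm": m.t_open_close_norm})
    df = pd.DataFrame(rows)
    for col in ("tti", "pre_tti", "tti_plus_pre_tti", "open_close_norm"):
        if col in df:
            df[col] = df[col].astype(float)
    return df


def summarize_condition(metrics: list[TrialMetrics] | list[float],
                        condition: tuple[str, str] = ("", ""),
                        fluent_cut: float = FLUENT_CUT,
                        reliable_cut: float = RELIABLE_CUT) -> ConditionSummary:
    """Median / quartile summary of pooled TTI+Pre-TTI with the fluency and
    reliability verdicts (median < 3 s; 75th percentile < 5 s).

    Quantiles use linear interpolation between order statistics.
    """
    if metrics and isinstance(metrics[0], TrialMetrics):
        values = [m.tti_plus_pre_tti for m in metrics if m.tti_plus_pre_tti is not None]
        n_attempted = len(metrics)
    else:
        values = [float(v) for v in metrics]
        n_attempted = len(values)
    if not values:
        raise ValueError("no successful initializations to summarize")
    q25, med, q75 = np.percentile(values, [25, 50, 75])
    return ConditionSummary(condition=condition, median=float(med),
                            q25=float(q25), q75=float(q75),
                            fluent=bool(med < fluent_cut),
                            reliable=bool(q75 < reliable_cut),
                            n_trials=len(values), n_attempted=n_attempted)
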