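"""Shared-control supervisor: transition table, motion accounting, determinism."""

import numpy as np
import pytest

from hybridbci.eog import HovEvent
from hybridbci.fsm import (TICK, DeviceModel, Phase, SharedControlFsm, TickInput,
                           device_model, fsm_step, run_trial)
from hybridbci.types import Annotation

DEV = device_model("exoskeleton", reach_duration=0.5, return_duration=0.5,
                   transport_duration=0.5)


def drive(fsm, inputs):
    """Feed a list of TickInputs; returns all emitted records."""
    out = []
    for i, tick in enumerate(inputs):
        out += fsm.step(i * TICK, tick)
    return out


def quiet(n):
    return [TickInput()] * n


class TestTransitions:
    def test_happy_path_visits_all_states_in_order(self):
        fsm = SharedControlFsm(DEV, "synchronous")
        recs = drive(fsm, [TickInput(gaze_id="glass")] + quiet(5)
                     + [TickInput(hov_event="right")] + quiet(60)     # reach 0.5 s
                     + [TickInput(erd_active=True)] * 160 + quiet(60)  # grasp 1.5 s + transport
                     + [TickInput(hov_event="right")] + quiet(60)     # return
                     + [TickInput(erd_active=True)] * 160 + quiet(60))  # release + home
        states = [r.detail for r in recs if r.event == "state_enter"]
        assert [s.split(" ")[0] for s in states] == ["S2", "S3", "S4", "S5", "S1"]
        assert fsm.repetition_complete

    def test_gaze_then_left_hov_aborts_selection(self):
        fsm = SharedControlFsm(DEV, "synchronous")
        recs = drive(fsm, [TickInput(gaze_id="glass"), TickInput(hov_event="left")])
        assert fsm.phase is Phase.S1_SELECT
        assert fsm.selected is None
        assert any(r.event == "veto" for r in recs)

    def test_hov_during_grasp_is_ignored(self):
        fsm = SharedControlFsm(DEV, "synchronous")
        drive(fsm, [TickInput(gaze_id="glass"), TickInput(hov_event="right")]
              + quiet(60))
        assert fsm.phase is Phase.S3_GRASP
        recs = fsm.step(1.0, TickInput(hov_event="right"))
        assert fsm.phase is Phase.S3_GRASP
        assert any(r.event == "input_ignored" for r in recs)

    def test_left_hov_outside_s1_s2_is_ignored(self):
        fsm = SharedControlFsm(DEV, "synchronous")
        drive(fsm, [TickInput(gaze_id="glass"), TickInput(hov_event="right")]
              + quiet(60) + [TickInput(erd_active=True)] * 160 + quiet(60))
        assert fsm.phase is Phase.S4_AWAIT_HOV
        fsm.step(5.0, TickInput(hov_event="left"))
        assert fsm.phase is Phase.S4_AWAIT_HOV

    def test_malformed_input_rejected(self):
        with pytest.raises(ValueError):
            TickInput(hov_event="up")

    def test_exhaustive_state_input_table(self):
        """Every (phase, input) pair transitions exactly as the hand-written
        table prescribes; arm and hand triggers can never interleave."""
        inputs = {"gaze": TickInput(gaze_id="glass"),
                  "left": TickInput(hov_event="left"),
                  "right": TickInput(hov_event="right"),
                  "erd": TickInput(erd_active=True),
                  "none": TickInput()}
        # phase -> input -> phase after one tick (auto phases tick forward at
        # their own pace; one tick never completes a >= 0.5 s motion)
        expected = {
            Phase.S1_SELECT: {"gaze": Phase.S2_AWAIT_HOV, "left": Phase.S1_SELECT,
                              "right": Phase.S1_SELECT, "erd": Phase.S1_SELECT,
                              "none": Phase.S1_SELECT},
            Phase.S2_AWAIT_HOV: {"gaze": Phase.S2_AWAIT_HOV, "left": Phase.S1_SELECT,
                                 "right": Phase.S2_REACH, "erd": Phase.S2_AWAIT_HOV,
                                 "none": Phase.S2_AWAIT_HOV},
            Phase.S2_REACH: dict.fromkeys(inputs, Phase.S2_REACH),
            Phase.S3_GRASP: {"gaze": Phase.S3_GRASP, "left": Phase.S3_GRASP,
                             "right": Phase.S3_GRASP, "erd": Phase.S3_GRASP,
                             "none": Phase.S3_GRASP},
            Phase.S3_TRANSPORT: dict.fromkeys(inputs, Phase.S3_TRANSPORT),
            Phase.S4_AWAIT_HOV: {"gaze": Phase.S4_AWAIT_HOV, "left": Phase.S4_AWAIT_HOV,
                                 "right": Phase.S4_RETURN, "erd": Phase.S4_AWAIT_HOV,
                                 "none": Phase.S4_AWAIT_HOV},
            Phase.S4_RETURN: dict.fromkeys(inputs, Phase.S4_RETURN),
            Phase.S5_RELEASE: dict.fromkeys(inputs, Phase.S5_RELEASE),
            Phase.S5_HOME: dict.fromkeys(inputs, Phase.S5_HOME),
        }
        for phase, row in expected.items():
            for name, tick in inputs.items():
                fsm = SharedControlFsm(DEV, "synchronous")
                fsm.phase = phase
                if phase is not Phase.S1_SELECT:
                    fsm.selected = "glass"
                new_phase, _ = fsm_step(fsm, 0.0, tick)
                assert new_phase is row[name], (phase, name, new_phase)


class TestMotionAccounting:
    @pytest.mark.parametrize("device,duration", [("exoskeleton", 1.5),
                                                 ("manipulator", 1.2)])
    def test_continuous_erd_completes_in_mechanism_time(self, device, duration):
        dev = device_model(device, reach_duration=0.5, return_duration=0.5,
                          transport_duration=0.5)
        fsm = SharedControlFsm(dev, "synchronous")
        fsm.phase = Phase.S3_GRASP
        recs = drive(fsm, [TickInput(erd_active=True)] * 200)
        start = next(r.time for r in recs if r.event == "motion_start"
                     and r.detail == "grasp")
        done = next(r.time for r in recs if r.event == "motion_complete"
                    and r.detail == "grasp")
        assert done - start == pytest.approx(duration, abs=TICK)

    def test_pause_resume_accumulates_commanded_time(self):
        """ERD 1.0 s on, 0.5 s off, then on: grasp completes at 1.5 s commanded."""
        fsm = SharedControlFsm(DEV, "synchronous")
        fsm.phase = Phase.S3_GRASP
        seq = [TickInput(erd_active=True)] * 100 + quiet(50) \
            + [TickInput(erd_active=True)] * 100
        recs = drive(fsm, seq)
        assert any(r.event == "motion_pause" for r in recs)
        done = next(r.time for r in recs if r.event == "motion_complete")
        # 100 + 50 pause + 50 more active ticks -> completes at tick 200
        assert done == pytest.approx(2.0, abs=TICK)
        active_ticks = 100 + 50
        assert active_ticks * TICK == pytest.approx(DEV.erd_duration, abs=TICK)

    def test_no_erd_stalls_in_grasp(self):
        fsm = SharedControlFsm(DEV, "synchronous")
        fsm.phase = Phase.S3_GRASP
        drive(fsm, quiet(500))
        assert fsm.phase is Phase.S3_GRASP
        assert fsm.commanded_time == 0.0


class TestRunTrial:
    ANNS = [Annotation(0.5, "rep_start", 0), Annotation(1.0, "cue:S1", 0),
            Annotation(1.5, "gaze:glass", 0), Annotation(4.5, "cue:S2", 0),
            Annotation(7.0, "cue:S3", 0), Annotation(12.0, "cue:S4", 0),
            Annotation(14.5, "cue:S5", 0), Annotation(20.0, "rep_end", 0)]

    def run(self, erd, hov):
        return run_trial(erd, hov, self.ANNS, DEV, "synchronous", 0.5, 20.0, 0)

    def test_aligned_intents_complete_and_enter_states_in_order(self):
        log = self.run([(7.5, 11.0), (15.0, 18.0)],
                       [HovEvent(5.0, "right", 100.0), HovEvent(13.0, "right", 100.0)])
        states = [r.detail.split(" ")[0] for r in log.records
                  if r.event == "state_enter"]
        assert states[0] == "S1"
        assert [s for s in states[1:]] == ["S2", "S3", "S4", "S5", "S1"]
        assert log.records[-1].detail == "complete"

    def test_no_erd_stalls_trial_incomplete(self):
        log = self.run([], [HovEvent(5.0, "right", 100.0)])
        assert log.records[-1].detail == "incomplete"
        assert not [r for r in log.records if r.event == "motion_complete"
                    and r.detail == "grasp"]

    def test_replay_is_bit_identical(self):
        a = self.run([(7.5, 11.0), (15.0, 18.0)], [HovEvent(5.0, "right", 100.0),
                                                   HovEvent(13.0, "right", 100.0)])
        b = self.run([(7.5, 11.0), (15.0, 18.0)], [HovEvent(5.0, "right", 100.0),
                                                   HovEvent(13.0, "right", 100.0)])
        assert a.records == b.records
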