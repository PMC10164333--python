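"""Shared fixtures.

The expensive end-to-end simulations (participant sweeps, latency-recovery
sessions, repeated studies) are session-scoped so that property tests and
the acceptance suite reuse one computation.  Problem sizes are scaled-down
versions of the study protocol (shorter calibration runs, fewer repetitions)
chosen to keep the statistical checks well-powered.
"""

from __future__ import annotations

import numpy as np
import pytest

from hybridbci import (ErdDecoder, HovDecoder, SessionPlan, StudyConfig,
                       generate_calibration_eeg, generate_hov_calibration_eog,
                       generate_task_session, metrics_frame, run_session,
                       run_study, trial_metrics_from_log)
from hybridbci.fsm import device_model
from hybridbci.simulate import default_profile

#: scaled-down calibration protocol used throughout the suite
CAL_KW = dict(n_trials=10, trial_len=3.0, iti=2.5)


@pytest.fixture(scope="session")
def depth_threshold_sweep():
    """Calibrated ERD thresholds for 20 participants with graded ERD depth."""
    depths = np.linspace(0.3, 0.7, 20)
    rows = []
    for i, depth in enumerate(depths):
        prof = default_profile(f"S{i:02d}", seed=100 + i, erd_depth=float(depth))
        calib = generate_calibration_eeg(prof, **CAL_KW)
        cal = ErdDecoder().fit(calib)
        rows.append((float(depth), cal.threshold, cal.center_freq,
                     prof.smr_center_freq))
    return rows


@pytest.fixture(scope="session")
def calibrated_decoders():
    """One participant's frozen ERD + HOV calibrations (default profile)."""
    prof = default_profile("P01", seed=42)
    erd_cal = ErdDecoder().fit(generate_calibration_eeg(prof, **CAL_KW))
    hov_cal = HovDecoder().fit(generate_hov_calibration_eog(prof))
    return prof, erd_cal, hov_cal


def run_latency_session(latency_mean: float, seed: int, n_repetitions: int = 10,
                        latency_sd: float = 0.2):
    """Full pipeline for one session with programmed reaction latencies.

    Returns (per-trial metrics frame, erd calibration, profile).
    10 repetitions x 4 timed sub-tasks = 40 initializations.
    """
    prof = default_profile("L", seed=seed, latency_mean=latency_mean,
                           latency_sd=latency_sd, pre_activation_prob=0.0)
    erd_cal = ErdDecoder().fit(generate_calibration_eeg(prof, **CAL_KW))
    hov_cal = HovDecoder().fit(generate_hov_calibration_eog(prof))
    dev = device_model("exoskeleton", reach_duration=2.0, return_duration=2.0,
                       transport_duration=2.0)
    plan = SessionPlan(task="drinking", mode="synchronous", device="exoskeleton",
                       n_repetitions=n_repetitions, seed=seed)
    eeg, eog, anns = generate_task_session(prof, plan, device_timing=dev)
    log = run_session(eeg, eog, anns, erd_cal, hov_cal, dev, "synchronous")
    return metrics_frame(trial_metrics_from_log(log, dev)), erd_cal, prof


@pytest.fixture(scope="session")
def latency_recovery():
    """Recovered per-trial metrics at three programmed latency levels."""
    return {lat: run_latency_session(lat, seed=7 + i)
            for i, lat in enumerate((0.6, 1.0, 1.6))}


@pytest.fixture(scope="session")
def small_study_config():
    return StudyConfig(n_participants=3, n_repetitions=2, calibration_trials=10,
                       calibration_trial_len=3.0, calibration_iti=2.5,
                       tasks=("drinking",), auto_motion_duration=2.0,
                       master_seed=11)


@pytest.fixture(scope="session")
def study_pair(small_study_config, tmp_path_factory):
    """The same small study run twice into different directories."""
    d1 = tmp_path_factory.mktemp("study_run1")
    d2 = tmp_path_factory.mktemp("study_run2")
    r1 = run_study(small_study_config, out_dir=d1)
    r2 = run_study(small_study_config, out_dir=d2)
    return r1, r2, d1, d2
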