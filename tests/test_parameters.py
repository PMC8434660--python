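"""Parameter estimation rules and recovery against generator ground truth."""

import numpy as np
import pytest

from gaitpath import AnalysisWindow, SessionMeta, SyntheticGaitSpec, analyze_sequence, simulate_gait
from gaitpath.errors import InsufficientDataError
from gaitpath.parameters import (
    cadence,
    com_sway,
    double_support,
    mean_velocity,
    stance_pct,
    step_length,
    step_width,
)
from gaitpath.segmentation import GaitEvents, Onset, Step, StepPhaseArray
from gaitpath.vgap import ComTrajectory


def events_from_steps(steps, onsets=None):
    ev = GaitEvents(
        onsets=onsets or {"left": [], "right": []},
        offsets={"left": [], "right": []},
        steps=steps,
    )
    return ev


def test_step_length_per_side_mean():
    ev = events_from_steps(
        [Step("left", 1.0, 0.5, 0.6), Step("right", 1.6, 0.5, 0.6)]
    )
    assert step_length(ev) == {"left": pytest.approx(0.5), "right": pytest.approx(0.5)}


def test_step_length_same_lead_mean_and_absent_side():
    ev = events_from_steps([Step("left", 1.0, 0.4, 0.6), Step("left", 2.2, 0.6, 0.6)])
    out = step_length(ev)
    assert out["left"] == pytest.approx(0.5)
    assert out["right"] is None  # absent, not zero


def test_stance_pct_explicit_cycle():
    dt = 0.01
    n = 250
    t = np.arange(n) * dt
    phase = np.ones(n, dtype=int)
    phase[100:165] = 0          # stationary 0.65 s
    phase[200:220] = 0          # next stance, defines next onset
    arr = StepPhaseArray(leg="left", t=t, phase=phase, z_held=np.zeros(n))
    ev = events_from_steps(
        [],
        onsets={
            "left": [Onset("left", 1.0, 3.0, 0.0), Onset("left", 2.0, 2.5, 0.0)],
            "right": [],
        },
    )
    assert stance_pct(arr, ev) == pytest.approx(65.0, abs=0.5)


def test_stance_needs_two_onsets():
    arr = StepPhaseArray(leg="left", t=np.arange(10.0), phase=np.zeros(10, int), z_held=np.zeros(10))
    ev = events_from_steps([], onsets={"left": [Onset("left", 1.0, 3.0, 0.0)], "right": []})
    assert stance_pct(arr, ev) is None


def test_fully_stationary_cycle_flagged_invalid(caplog):
    n = 300
    t = np.arange(n) * 0.01
    arr = StepPhaseArray(leg="left", t=t, phase=np.zeros(n, int), z_held=np.zeros(n))
    ev = events_from_steps(
        [],
        onsets={
            "left": [Onset("left", 0.5, 3.0, 0.0), Onset("left", 1.5, 2.5, 0.0)],
            "right": [],
        },
    )
    assert stance_pct(arr, ev) is None  # the 100% cycle is skipped


def test_double_support_interval_intersection():
    dt = 0.01
    n = 200
    t = np.arange(n) * dt
    left = np.ones(n, int)
    left[0:101] = 0             # stationary [0, 1] s
    right = np.ones(n, int)
    right[80:181] = 0           # stationary [0.8, 1.8] s
    la = StepPhaseArray(leg="left", t=t, phase=left, z_held=np.zeros(n))
    ra = StepPhaseArray(leg="right", t=t, phase=right, z_held=np.zeros(n))
    win = AnalysisWindow(t_i=0.0, t_f=t[-1])
    assert double_support(la, ra, win) == pytest.approx(0.21, abs=0.005)  # 0.2 s + 1 frame


def test_double_support_disjoint_warns_zero():
    n = 100
    t = np.arange(n) * 0.01
    left = np.ones(n, int)
    left[:30] = 0
    right = np.ones(n, int)
    right[60:] = 0
    la = StepPhaseArray(leg="left", t=t, phase=left, z_held=np.zeros(n))
    ra = StepPhaseArray(leg="right", t=t, phase=right, z_held=np.zeros(n))
    with pytest.warns(UserWarning, match="double-support"):
        assert double_support(la, ra, AnalysisWindow(t_i=0.0, t_f=t[-1])) == 0.0


def test_double_support_is_intersection_of_stationary_sets(default_trial):
    _, _, res = default_trial
    left, right = res.phases["left"], res.phases["right"]
    mask = res.window.contains(left.t)
    both = (left.phase == 0) & (right.phase == 0) & mask
    # recompute the mean maximal True-run duration from the definition
    runs = []
    start = None
    for k, b in enumerate(both):
        if b and start is None:
            start = k
        if not b and start is not None:
            runs.append(k - start)
            start = None
    if start is not None:
        runs.append(len(both) - start)
    expected = np.mean(runs) * left.dt
    assert res.parameters.double_support_s == pytest.approx(expected, abs=1e-9)


def test_mean_velocity_ratio():
    ev = events_from_steps([Step("left", 1.0, 0.5, 0.575)])
    assert mean_velocity(ev)["left"] == pytest.approx(0.8696, abs=1e-4)


def test_mean_velocity_identical_steps():
    ev = events_from_steps([Step("left", 1.0, 0.5, 0.5), Step("left", 2.0, 0.5, 0.5)])
    assert mean_velocity(ev)["left"] == pytest.approx(1.0)


def test_cadence_counts_onsets_over_window():
    onsets = {
        "left": [Onset("left", t, 3.0, 0.0) for t in (0.5, 2.0)],
        "right": [Onset("right", t, 3.0, 0.0) for t in (1.25, 2.75)],
    }
    ev = events_from_steps([], onsets=onsets)
    win = AnalysisWindow(t_i=0.0, t_f=3.0)
    assert cadence(ev, win) == pytest.approx(80.0)  # 4 steps in 3 s


def test_cadence_single_step_long_window():
    ev = events_from_steps([], onsets={"left": [Onset("left", 30.0, 3.0, 0.0)], "right": []})
    assert cadence(ev, AnalysisWindow(t_i=0.0, t_f=60.0)) == pytest.approx(1.0)


def test_step_width_from_onset_lines():
    onsets = {
        "left": [Onset("left", 1.0, 4.0, -0.10), Onset("left", 2.0, 3.0, -0.10)],
        "right": [Onset("right", 1.5, 3.5, 0.10)],
    }
    assert step_width(events_from_steps([], onsets=onsets)) == pytest.approx(0.20)


def test_step_width_degenerate_same_line():
    onsets = {
        "left": [Onset("left", 1.0, 4.0, 0.05)],
        "right": [Onset("right", 1.5, 3.5, 0.05)],
    }
    assert step_width(events_from_steps([], onsets=onsets)) == pytest.approx(0.0)


def test_com_sway_sinusoid_peak_to_peak():
    t = np.arange(0, 4, 1 / 30)
    a = 0.05
    pos = np.stack([a * np.sin(2 * np.pi * t / 1.0), 0.02 * np.cos(2 * np.pi * t / 0.5), 3 - 0.5 * t], axis=-1)
    com = ComTrajectory(t=t, position=pos, kind="hip")
    ml, v = com_sway(com, AnalysisWindow(t_i=0.0, t_f=4.0))
    assert ml == pytest.approx(2 * a, abs=1e-3)
    assert v == pytest.approx(0.04, abs=1e-3)


def test_com_sway_constant_zero():
    t = np.arange(0, 2, 1 / 30)
    com = ComTrajectory(t=t, position=np.tile((0.1, 0.9, 3.0), (len(t), 1)), kind="hip")
    assert com_sway(com, AnalysisWindow(t_i=0.0, t_f=2.0)) == (0.0, 0.0)


def test_com_sway_short_window_raises():
    t = np.arange(0, 2, 1 / 30)
    com = ComTrajectory(t=t, position=np.zeros((len(t), 3)), kind="hip")
    with pytest.raises(InsufficientDataError):
        com_sway(com, AnalysisWindow(t_i=0.5, t_f=0.51))


# ---------------------------------------------------------------------------
# assembled parameters
# ---------------------------------------------------------------------------

def test_sides_relabeled_paretic(impaired_trial):
    seq, _, _ = impaired_trial
    from gaitpath.analysis import analyze_sequence as run

    res = run(seq, meta=SessionMeta(paretic_side="left"))
    assert set(res.parameters.step_length_m) == {"paretic", "non_paretic"}
    # the generator gives the left (paretic) leg the shorter step
    assert res.parameters.step_length_m["paretic"] < res.parameters.step_length_m["non_paretic"]


def test_sides_stay_left_right_without_paretic(default_trial):
    _, _, res = default_trial
    assert set(res.parameters.step_length_m) == {"left", "right"}


def test_dimensional_consistency_symmetric_gait(default_trial):
    """cadence x mean step length ~ 60 x mean velocity (symmetric gait)."""
    _, _, res = default_trial
    p = res.parameters
    mean_len = np.mean([v for v in p.step_length_m.values()])
    mean_vel = np.mean([v for v in p.mean_velocity_mps.values()])
    assert p.cadence_spm * mean_len == pytest.approx(60.0 * mean_vel, rel=0.10)


@pytest.mark.parametrize("seed", [3, 7])
def test_parameter_recovery_single_specs(seed):
    """Spot-check full recovery for one asymmetric spec (grid in acceptance)."""
    spec = SyntheticGaitSpec(
        step_length_left_m=0.40,
        step_length_right_m=0.48,
        cadence_spm=88.0,
        stance_fraction_left=0.66,
        stance_fraction_right=0.64,
        seed=seed,
    )
    seq, gt = simulate_gait(spec)
    res = analyze_sequence(seq)
    e, p = gt.expected, res.parameters
    for side in ("left", "right"):
        assert p.step_length_m[side] == pytest.approx(e.step_length_m[side], abs=0.02)
        assert p.stance_pct[side] == pytest.approx(e.stance_pct[side], abs=2.0)
        assert p.mean_velocity_mps[side] == pytest.approx(e.mean_velocity_mps[side], abs=0.05)
    assert p.double_support_s == pytest.approx(e.double_support_s, abs=0.05)
    assert p.cadence_spm == pytest.approx(e.cadence_spm, abs=5.0)
    assert p.step_width_m == pytest.approx(e.step_width_m, abs=0.01)
    assert p.ml_sway_m == pytest.approx(e.ml_sway_m, abs=0.005)
    assert p.v_sway_m == pytest.approx(e.v_sway_m, abs=0.005)
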