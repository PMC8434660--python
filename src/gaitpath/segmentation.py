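"""Step segmentation by binary depth thresholding of the ankle trajectories.

The core detection rule: on the uniform, filtered grid, a frame of an ankle
is *stationary* (label 0) when the absolute difference between its depth and
the previous frame's depth is below a threshold (default 2 cm), otherwise
*in movement* (label 1).  The first frame inherits the second frame's label.
Within every stationary run the depth is forced to the run's initial value
and held constant (the "stationary hold"), which removes residual depth
flutter during stance; held depths at stationary-run starts are the
initial-contact depth readings from which step lengths are measured.

Depth noise of 2-4 mm near the threshold produces label chatter the raw
rule does not address; runs shorter than ``min_run_frames`` (default 3,
~0.1 s at 30 Hz) that do not touch the array edges are therefore merged
into their surroundings.  When several short runs compete, the shortest is
flipped first; among equal-length candidates a *moving* run flips before a
stationary one (ties favor stationary), then the leftmost.

Events are detected on the whole filtered recording and clipped to the
analysis window afterwards, so a stationary run straddling the window edge
contributes an onset only if the onset itself lies inside — this avoids
truncation bias where tracking activation precedes the window entry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, NamedTuple

import numpy as np

from .errors import InsufficientDataError, NoStepsError, ValidationError
from .vgap import AnalysisWindow

logger = logging.getLogger(__name__)

Leg = Literal["left", "right"]


@dataclass(frozen=True)
class SegmentationConfig:
    """Threshold (m) of the per-frame depth difference and debounce length."""

    threshold_m: float = 0.02
    min_run_frames: int = 3

    def __post_init__(self) -> None:
        if not self.threshold_m > 0:
            raise ValidationError(f"threshold_m must be > 0, got {self.threshold_m}")
        if self.min_run_frames < 1:
            raise ValidationError(f"min_run_frames must be >= 1, got {self.min_run_frames}")


@dataclass
class StepPhaseArray:
    """Per-leg binary stationary(0)/in-movement(1) labeling plus held depth."""

    leg: Leg
    t: np.ndarray         # (n,) uniform grid
    phase: np.ndarray     # (n,) int8 in {0, 1}
    z_held: np.ndarray    # (n,) depth with stationary-hold applied

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.phase = np.asarray(self.phase, dtype=np.int8)
        self.z_held = np.asarray(self.z_held, dtype=float)
        if not (self.t.shape == self.phase.shape == self.z_held.shape):
            raise ValidationError("t, phase and z_held must share one shape")
        if not np.all((self.phase == 0) | (self.phase == 1)):
            raise ValidationError("phase labels must be binary")

    @property
    def dt(self) -> float:
        return float(np.mean(np.diff(self.t)))


class StationaryRun(NamedTuple):
    """A maximal stationary run: [start, stop) frame indices and held depth."""

    start: int
    stop: int
    z: float


class Step(NamedTuple):
    """One step: the landing (lead) leg, its onset, and spatial/temporal size."""

    lead_leg: Leg
    onset_time: float
    step_length_m: float
    step_time_s: float


class Onset(NamedTuple):
    """Start of a stationary run: the initial-contact analog."""

    leg: Leg
    t: float
    z: float     # held depth at onset
    x: float     # ankle lateral position at onset


@dataclass
class GaitEvents:
    """Per-leg gait events plus the paired step list, clipped to the window."""

    onsets: dict[Leg, list[Onset]]
    offsets: dict[Leg, list[float]]   # stationary-run end (toe-off analog) times
    steps: list[Step] = field(default_factory=list)
    window: AnalysisWindow | None = None

    def onset_times(self, leg: Leg) -> np.ndarray:
        return np.array([o.t for o in self.onsets[leg]], dtype=float)

    @property
    def n_onsets(self) -> int:
        return sum(len(v) for v in self.onsets.values())


# ---------------------------------------------------------------------------
# binarization
# ---------------------------------------------------------------------------

def _runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs of equal label as (start, stop, value), stop exclusive."""
    n = labels.shape[0]
    if n == 0:
        return []
    bounds = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], bounds))
    stops = np.concatenate((bounds, [n]))
    return [(int(a), int(b), int(labels[a])) for a, b in zip(starts, stops)]


def merge_short_runs(labels: np.ndarray, min_run: int) -> np.ndarray:
    """Debounce a binary label array.

    Interior runs shorter than ``min_run`` are flipped into their
    surroundings, shortest first; equal-length ties flip a moving run before
    a stationary one, then the leftmost.  Runs touching either array edge
    are exempt.  Deterministic.
    """
    labels = np.asarray(labels).astype(np.int8).copy()
    n = labels.shape[0]
    if min_run <= 1 or n == 0:
        return labels
    while True:
        runs = _runs(labels)
        candidates = [
            (stop - start, -value, start)
            for (start, stop, value) in runs
            if start > 0 and stop < n and stop - start < min_run
        ]
        if not candidates:
            return labels
        _, neg_value, start = min(candidates)
        stop = next(b for (a, b, _) in runs if a == start)
        labels[start:stop] = 1 - (-neg_value)


def binarize_ankle(
    z: np.ndarray,
    cfg: SegmentationConfig | None = None,
    *,
    t: np.ndarray | None = None,
    leg: Leg = "left",
) -> StepPhaseArray:
    """Label each frame of an ankle depth series stationary/in-movement.

    Frame ``k`` (k >= 1) is stationary when ``|z[k] - z[k-1]| < threshold_m``;
    the first frame inherits the second's label.  After debouncing, the depth
    within each stationary run is forced to the run's initial value.
    """
    cfg = cfg or SegmentationConfig()
    z = np.asarray(z, dtype=float)
    if z.ndim != 1 or z.shape[0] < 2:
        raise InsufficientDataError(f"need a 1-D depth series of >= 2 frames, got shape {z.shape}")
    moving = (np.abs(np.diff(z)) >= cfg.threshold_m).astype(np.int8)
    phase = np.concatenate(([moving[0]], moving))
    phase = merge_short_runs(phase, cfg.min_run_frames)

    z_held = z.copy()
    for start, stop, value in _runs(phase):
        if value == 0:
            z_held[start:stop] = z[start]

    if t is None:
        t = np.arange(z.shape[0], dtype=float)
    return StepPhaseArray(leg=leg, t=np.asarray(t, dtype=float), phase=phase, z_held=z_held)


def stationary_runs(arr: StepPhaseArray) -> list[StationaryRun]:
    """Maximal stationary runs of a phase array with their held depths."""
    return [
        StationaryRun(start, stop, float(arr.z_held[start]))
        for (start, stop, value) in _runs(arr.phase)
        if value == 0
    ]


# ---------------------------------------------------------------------------
# event extraction
# ---------------------------------------------------------------------------

def extract_events(
    left: StepPhaseArray,
    right: StepPhaseArray,
    win: AnalysisWindow,
    *,
    x_left: np.ndarray | None = None,
    x_right: np.ndarray | None = None,
) -> GaitEvents:
    """Turn two phase arrays into per-leg gait events and paired steps.

    Onsets/offsets are stationary-run boundaries whose own time lies inside
    the window.  Steps pair each onset with the nearest preceding onset of
    the opposite leg: the step length is the absolute difference of the two
    held depths, the step time the interval between the onsets, and the step
    belongs to the leg whose onset terminates it (the landing leg).
    Consecutive same-leg onsets with no interleaved opposite onset produce
    no step and a logged warning.
    """
    if left.t.shape != right.t.shape or not np.allclose(left.t, right.t):
        raise ValidationError("left and right phase arrays must share one time grid")
    n = left.t.shape[0]

    onsets: dict[Leg, list[Onset]] = {"left": [], "right": []}
    offsets: dict[Leg, list[float]] = {"left": [], "right": []}
    for arr, xs in ((left, x_left), (right, x_right)):
        for run in stationary_runs(arr):
            t_on = float(arr.t[run.start])
            if win.contains(t_on):
                x_on = float(xs[run.start]) if xs is not None else float("nan")
                onsets[arr.leg].append(Onset(arr.leg, t_on, run.z, x_on))
            t_off = float(arr.t[min(run.stop, n - 1)])
            if run.stop < n and win.contains(t_off):
                offsets[arr.leg].append(t_off)

    for leg in ("left", "right"):
        if not onsets[leg]:
            raise NoStepsError(f"no stationary onsets for the {leg} leg inside the window")

    merged = sorted(onsets["left"] + onsets["right"], key=lambda o: o.t)
    steps: list[Step] = []
    for prev, cur in zip(merged, merged[1:]):
        if prev.leg == cur.leg:
            logger.warning(
                "consecutive %s-leg onsets at t=%.3f and t=%.3f with no interleaved "
                "opposite onset; no step formed",
                cur.leg, prev.t, cur.t,
            )
            continue
        steps.append(
            Step(
                lead_leg=cur.leg,
                onset_time=cur.t,
                step_length_m=abs(prev.z - cur.z),
                step_time_s=cur.t - prev.t,
            )
        )
    return GaitEvents(onsets=onsets, offsets=offsets, steps=steps, window=win)
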