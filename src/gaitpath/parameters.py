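"""Spatiotemporal and COM-sway gait parameters from segmented events.

Six spatiotemporal parameters (step length, stance percentage, double
support duration, mean velocity, cadence, step width) and two center-of-mass
sway parameters (mediolateral and vertical peak-to-peak excursion of the hip
midpoint) are estimated per trial; step length, stance, velocity and step
counts are reported per body side and relabeled paretic/non-paretic when
the session metadata names a paretic side.

Estimation rules:

* step length — depth distance between the start of the stationary period
  of one ankle and the start of the stationary period of the opposite
  ankle; per-step values averaged per lead (landing) leg.
* stance — duration of the stationary condition of one ankle as a
  percentage of its gait cycle (onset-to-next-same-leg-onset).
* double support — mean duration of the maximal intervals in which both
  ankles are simultaneously stationary, in seconds.
* mean velocity — per-step length/time ratio, averaged per lead leg.
* cadence — number of steps (stationary onsets of both legs) inside the
  analysis window, divided by the window duration, in steps/min.
* step width — distance between the two ankles' lines of progression, read
  as the difference of the mean lateral onset positions.
* ML / V sway — peak-to-peak excursion of the hip-midpoint trajectory along
  x / y inside the window.

Parameters whose preconditions fail for a side are reported absent (None),
never as zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .errors import GaitPathError, InsufficientDataError, NoStepsError, ValidationError
from .io_skeleton import SessionMeta
from .segmentation import GaitEvents, StepPhaseArray, _runs
from .vgap import AnalysisWindow, ComTrajectory

logger = logging.getLogger(__name__)

_SIDES = ("left", "right")


@dataclass
class GaitParameters:
    """The per-trial parameter set.  Per-side dicts are keyed by body side
    ('left'/'right', or 'paretic'/'non_paretic' after relabeling)."""

    step_length_m: dict[str, Optional[float]] = field(default_factory=dict)
    stance_pct: dict[str, Optional[float]] = field(default_factory=dict)
    double_support_s: Optional[float] = None
    mean_velocity_mps: dict[str, Optional[float]] = field(default_factory=dict)
    cadence_spm: Optional[float] = None
    step_width_m: Optional[float] = None
    ml_sway_m: Optional[float] = None
    v_sway_m: Optional[float] = None
    n_steps: dict[str, int] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def step_length(ev: GaitEvents) -> dict[str, Optional[float]]:
    """Mean step length per lead leg, meters; a side with no steps is absent."""
    out: dict[str, Optional[float]] = {}
    for side in _SIDES:
        lengths = [s.step_length_m for s in ev.steps if s.lead_leg == side]
        out[side] = float(np.mean(lengths)) if lengths else None
    return out


def stance_pct(phases: StepPhaseArray, ev: GaitEvents) -> Optional[float]:
    """Mean stance percentage for the leg of ``phases``.

    Per gait cycle [onset_k, onset_{k+1}): stationary time divided by cycle
    duration, x100; needs at least two same-leg onsets.  A fully stationary
    cycle (would read 100%) is flagged invalid and skipped.
    """
    times = ev.onset_times(phases.leg)
    if times.size < 2:
        return None
    dt = phases.dt
    vals = []
    for a, b in zip(times, times[1:]):
        in_cycle = (phases.t >= a) & (phases.t < b)
        frac = float(np.mean(phases.phase[in_cycle] == 0)) * 100.0
        if frac >= 100.0:
            logger.warning("fully stationary gait cycle [%.2f, %.2f) s skipped", a, b)
            continue
        if b - a < 2 * dt:
            raise InsufficientDataError(f"degenerate gait cycle of {b - a:.3f} s")
        vals.append(frac)
    return float(np.mean(vals)) if vals else None


def double_support(
    left: StepPhaseArray, right: StepPhaseArray, win: AnalysisWindow
) -> float:
    """Mean duration (s) of intervals where both ankles are stationary."""
    if left.t.shape != right.t.shape or not np.allclose(left.t, right.t):
        raise ValidationError("phase arrays must share one time grid")
    mask = win.contains(left.t)
    both = ((left.phase == 0) & (right.phase == 0) & mask).astype(np.int8)
    dt = left.dt
    durations = [(stop - start) * dt for (start, stop, v) in _runs(both) if v == 1]
    if not durations:
        warnings.warn("no double-support interval inside the window (pathological for walking)", stacklevel=2)
        return 0.0
    return float(np.mean(durations))


def mean_velocity(ev: GaitEvents) -> dict[str, Optional[float]]:
    """Mean of per-step length/time ratios per lead leg, m/s."""
    out: dict[str, Optional[float]] = {}
    for side in _SIDES:
        ratios = []
        for s in ev.steps:
            if s.lead_leg != side:
                continue
            if s.step_time_s <= 0:
                raise GaitPathError(f"zero step time at t={s.onset_time:.3f} s (duplicate onsets?)")
            ratios.append(s.step_length_m / s.step_time_s)
        out[side] = float(np.mean(ratios)) if ratios else None
    return out


def cadence(ev: GaitEvents, win: AnalysisWindow) -> float:
    """Steps per minute: initial contacts of both legs inside the window,
    normalized by the window duration."""
    n = sum(1 for leg in _SIDES for o in ev.onsets[leg] if win.contains(o.t))
    if n == 0:
        raise NoStepsError("no step onsets inside the analysis window")
    return 60.0 * n / win.duration_s


def step_width(ev: GaitEvents) -> Optional[float]:
    """Lateral distance between the two ankles' lines of progression.

    Each leg's line of progression is read as the mean lateral (x) position
    of its ankle over the stationary onsets in the window; with the 2-4
    steps a short path yields, a fitted regression line would be
    ill-conditioned, so the mean is the stable estimate.
    """
    means = {}
    for side in _SIDES:
        xs = [o.x for o in ev.onsets[side] if np.isfinite(o.x)]
        if not xs:
            return None
        means[side] = float(np.mean(xs))
    return abs(means["left"] - means["right"])


def com_sway(com: ComTrajectory, win: AnalysisWindow) -> tuple[float, float]:
    """Peak-to-peak ML (x) and vertical (y) excursion of the COM proxy
    inside the window, meters."""
    mask = win.contains(com.t)
    if int(np.sum(mask)) < 2:
        raise InsufficientDataError("window shorter than 2 frames for sway estimation")
    x = com.position[mask, 0]
    y = com.position[mask, 1]
    return float(np.ptp(x)), float(np.ptp(y))


def _relabel(d: dict[str, Optional[float]], paretic: str) -> dict[str, Optional[float]]:
    other = "right" if paretic == "left" else "left"
    return {"paretic": d[paretic], "non_paretic": d[other]}


def assemble_parameters(
    ev: GaitEvents,
    left: StepPhaseArray,
    right: StepPhaseArray,
    com_hip: ComTrajectory,
    win: AnalysisWindow,
    meta: SessionMeta | None = None,
) -> GaitParameters:
    """Compute the full parameter set for one trial.

    Sides are relabeled paretic/non-paretic when ``meta.paretic_side`` names
    one; otherwise they stay left/right.
    """
    meta = meta or SessionMeta()
    ml, v = com_sway(com_hip, win)
    params = GaitParameters(
        step_length_m=step_length(ev),
        stance_pct={"left": stance_pct(left, ev), "right": stance_pct(right, ev)},
        double_support_s=double_support(left, right, win),
        mean_velocity_mps=mean_velocity(ev),
        cadence_spm=cadence(ev, win),
        step_width_m=step_width(ev),
        ml_sway_m=ml,
        v_sway_m=v,
        n_steps={side: sum(1 for s in ev.steps if s.lead_leg == side) for side in _SIDES},
    )
    if win is not None and not win.compliant:
        params.flags.append("non_compliant_window")
    if meta.paretic_side in ("left", "right"):
        p = meta.paretic_side
        params.step_length_m = _relabel(params.step_length_m, p)
        params.stance_pct = _relabel(params.stance_pct, p)
        params.mean_velocity_mps = _relabel(params.mean_velocity_mps, p)
        params.n_steps = {k: int(v2) for k, v2 in _relabel(params.n_steps, p).items()}  # type: ignore[arg-type]
    return params
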