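"""Center-of-mass trajectories and the virtual gait analysis path (VGAP).

The analysis window of a walk toward the sensor is delimited on the 3D
distance of a whole-body center-of-mass proxy from the sensor origin: the
window opens when that distance first drops below ``d_enter`` (default
4.2 m) and closes when it first drops below ``d_exit`` (default 1.5 m), so
a straight walk traverses ``d_enter - d_exit`` = 2.7 m of depth inside the
window.  Body tracking typically activates around 4.5 m, so the entry time
falls strictly after the first tracked frame and start-up skeleton
artifacts stay outside the window.

Two COM proxies are provided: the unweighted trunk-joint centroid (default,
used for windowing) and an anthropometric segment-mass-weighted estimate;
the hip midpoint (``COM_HIP``) serves the sway parameters downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import InsufficientDataError, MissingJointError, WindowNotFoundError, ValidationError
from .io_skeleton import SkeletonSequence
from .joints import STATE_CODE, TRUNK_JOINTS

DEFAULT_D_ENTER_M = 4.2
DEFAULT_D_EXIT_M = 1.5

#: minimum fraction of frames in which a required joint must be tracked
MIN_TRACKED_FRACTION = 0.9

# Winter-style anthropometric segment model: (proximal joint, distal joint,
# mass fraction, COM position as fraction of segment from proximal joint).
# Bilateral segments are listed once and expanded for both sides.
_AXIAL_SEGMENTS = (
    ("Neck", "Head", 0.081, 0.5),          # head + neck
    ("SpineShoulder", "SpineBase", 0.497, 0.5),  # trunk
)
_BILATERAL_SEGMENTS = (
    ("Shoulder", "Elbow", 0.028, 0.436),   # upper arm
    ("Elbow", "Wrist", 0.016, 0.430),      # forearm
    ("Wrist", "HandTip", 0.006, 0.506),    # hand
    ("Hip", "Knee", 0.100, 0.433),         # thigh
    ("Knee", "Ankle", 0.0465, 0.433),      # shank
    ("Ankle", "Foot", 0.0145, 0.5),        # foot
)


@dataclass
class ComTrajectory:
    """A center-of-mass proxy trajectory on the sequence's time grid."""

    t: np.ndarray            # (n,) seconds
    position: np.ndarray     # (n, 3) meters
    kind: Literal["body", "hip"]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (self.t.shape[0], 3):
            raise ValidationError("ComTrajectory position must be (n, 3) matching t")


@dataclass
class DistanceSeries:
    """Euclidean distance of a COM trajectory from the sensor origin."""

    t: np.ndarray
    d: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        if np.any(self.d < 0):
            raise ValidationError("distances must be non-negative")


@dataclass
class AnalysisWindow:
    """The [t_i, t_f] window during which the body is inside the VGAP."""

    t_i: float
    t_f: float
    d_enter: float = DEFAULT_D_ENTER_M
    d_exit: float = DEFAULT_D_EXIT_M
    compliant: bool = True

    def __post_init__(self) -> None:
        if not self.t_i < self.t_f:
            raise ValidationError(f"window requires t_i < t_f, got [{self.t_i}, {self.t_f}]")
        if not self.d_exit < self.d_enter:
            raise ValidationError("window requires d_exit < d_enter")

    @property
    def duration_s(self) -> float:
        return self.t_f - self.t_i

    @property
    def path_length_m(self) -> float:
        """Depth traversed between thresholds for a straight walk."""
        return self.d_enter - self.d_exit

    def contains(self, t: np.ndarray | float) -> np.ndarray | bool:
        return (np.asarray(t) >= self.t_i) & (np.asarray(t) <= self.t_f)


def _check_tracked(seq: SkeletonSequence, names: tuple[str, ...]) -> None:
    bad = [n for n in names if seq.tracked_fraction(n) < MIN_TRACKED_FRACTION]
    if bad:
        raise MissingJointError(
            bad, f"joint(s) tracked in < {MIN_TRACKED_FRACTION:.0%} of frames: {', '.join(bad)}"
        )


def compute_com_body(
    seq: SkeletonSequence,
    strategy: Literal["trunk_centroid", "weighted_segments"] = "trunk_centroid",
) -> ComTrajectory:
    """Whole-body COM proxy used for VGAP windowing.

    ``trunk_centroid`` (default) is the unweighted centroid of SpineBase,
    SpineMid, HipLeft and HipRight.  ``weighted_segments`` is a
    segment-mass-weighted average of anthropometric segment COMs (Winter
    mass fractions), offered for sensitivity checks; only windowing consumes
    this trajectory, so the choice shifts the window by at most a few frames.
    """
    if strategy == "trunk_centroid":
        _check_tracked(seq, TRUNK_JOINTS)
        pos = np.mean([seq.joint(n) for n in TRUNK_JOINTS], axis=0)
    elif strategy == "weighted_segments":
        segments = list(_AXIAL_SEGMENTS) + [
            (f"{p}{side}", f"{d}{side}", m / 1.0, f)
            for (p, d, m, f) in _BILATERAL_SEGMENTS
            for side in ("Left", "Right")
        ]
        needed = tuple({j for (p, d, _, _) in segments for j in (p, d)})
        _check_tracked(seq, needed)
        total = sum(m for (_, _, m, _) in segments)
        pos = np.zeros((len(seq), 3))
        for prox, dist, mass, frac in segments:
            seg_com = (1 - frac) * seq.joint(prox) + frac * seq.joint(dist)
            pos += (mass / total) * seg_com
    else:
        raise ValidationError(f"unknown COM strategy {strategy!r}")
    return ComTrajectory(t=seq.t, position=pos, kind="body")


def compute_com_hip(seq: SkeletonSequence) -> ComTrajectory:
    """Hip-midpoint COM proxy (``COM_HIP``), used for the sway parameters."""
    _check_tracked(seq, ("HipLeft", "HipRight"))
    pos = 0.5 * (seq.joint("HipLeft") + seq.joint("HipRight"))
    return ComTrajectory(t=seq.t, position=pos, kind="hip")


def com_distance(com: ComTrajectory) -> DistanceSeries:
    """3D Euclidean distance of the COM from the sensor origin (``COM_D``)."""
    if not np.all(np.isfinite(com.position)):
        raise ValidationError("COM trajectory contains non-finite values")
    return DistanceSeries(t=com.t, d=np.linalg.norm(com.position, axis=1))


def find_analysis_window(
    ds: DistanceSeries,
    d_enter: float = DEFAULT_D_ENTER_M,
    d_exit: float = DEFAULT_D_EXIT_M,
) -> AnalysisWindow:
    """Delimit the VGAP window on a COM distance series.

    ``t_i`` is the first time the (filtered) distance is strictly below
    ``d_enter``; ``t_f`` the first subsequent time it is strictly below
    ``d_exit``.  No hysteresis is applied: compliant trials approach the
    sensor monotonically.  If the distance re-crosses ``d_enter`` after
    entry (backtracking/hesitation) the window is flagged non-compliant
    rather than re-windowed.
    """
    if not d_exit < d_enter:
        raise ValidationError("d_exit must be smaller than d_enter")
    below_enter = ds.d < d_enter
    if not np.any(below_enter):
        raise WindowNotFoundError(d_enter, "enter")
    i = int(np.argmax(below_enter))
    below_exit = ds.d[i:] < d_exit
    if not np.any(below_exit):
        raise WindowNotFoundError(d_exit, "exit")
    j = i + int(np.argmax(below_exit))
    compliant = not np.any(ds.d[i:j] > d_enter)
    if not compliant:
        warnings.warn(
            "COM distance re-crossed the entry threshold inside the window; "
            "trial flagged non-compliant",
            stacklevel=2,
        )
    if j <= i:
        raise InsufficientDataError("degenerate window: exit at or before entry")
    return AnalysisWindow(
        t_i=float(ds.t[i]), t_f=float(ds.t[j]), d_enter=d_enter, d_exit=d_exit, compliant=compliant
    )
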