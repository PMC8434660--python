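"""Radar-chart and step-plot reporting.

The radar chart summarizes the five spatiotemporal parameters that track
functional mobility most closely (step length, stance, double support,
velocity, cadence — step width is excluded as the least reliable), each
min-max normalized to [0, 1] over a session collection so longitudinal
charts share one scale.  The step plot is the overhead x-z view of a trial:
VGAP boundaries, sensor mark, per-leg step (initial contact) positions and
the hip-midpoint COM trace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

from .errors import ValidationError
from .segmentation import GaitEvents
from .vgap import AnalysisWindow, ComTrajectory

#: the strongly TUG-correlated subset shown on radar charts by default
RADAR_PARAMETERS = (
    "step_length_m",
    "stance_pct",
    "double_support_s",
    "mean_velocity_mps",
    "cadence_spm",
)


#: parameters for which a *lower* raw value means better gait; their radar
#: radius is 1 - normalized value so a larger polygon always reads "better"
LOWER_IS_BETTER = ("stance_pct", "double_support_s")


@dataclass
class RadarSpec:
    """Parameter subset and per-parameter (min, max) normalization bounds.

    Parameters in ``invert`` are displayed on a performance scale (1 -
    normalized value), so a healthier gait traces a polygon that encloses a
    more impaired one.
    """

    parameters: tuple[str, ...] = RADAR_PARAMETERS
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    invert: tuple[str, ...] = LOWER_IS_BETTER

    @classmethod
    def from_collection(cls, rows: list[dict[str, float]], parameters=RADAR_PARAMETERS) -> "RadarSpec":
        """Bounds = min/max of each parameter across a session collection.

        A parameter constant across the collection (e.g. a single trial)
        gets bounds padded by 10% around its value so the chart still
        renders, with the value landing mid-scale.
        """
        bounds = {}
        for p in parameters:
            vals = [r[p] for r in rows if r.get(p) is not None]
            if not vals:
                raise ValidationError(f"no values for parameter {p!r} in the collection")
            lo, hi = min(vals), max(vals)
            if not hi > lo:
                pad = 0.1 * abs(hi) if hi != 0 else 0.5
                lo, hi = lo - pad, hi + pad
            bounds[p] = (lo, hi)
        return cls(parameters=tuple(parameters), bounds=bounds)


def normalize_minmax(values: dict[str, float], bounds: dict[str, tuple[float, float]]) -> dict[str, float]:
    """Scale each value to [0, 1] with (v - min) / (max - min), clipped.

    Out-of-bounds values warn and clip; a zero-width bound is an error.
    """
    out = {}
    for name, v in values.items():
        lo, hi = bounds[name]
        if not hi > lo:
            raise ValidationError(f"undefined scale for {name!r}: max must exceed min")
        z = (v - lo) / (hi - lo)
        if z < 0 or z > 1:
            warnings.warn(f"{name} value {v:g} outside bounds [{lo:g}, {hi:g}]; clipped", stacklevel=2)
        out[name] = float(np.clip(z, 0.0, 1.0))
    return out


def _scalarize(params, name: str) -> float:
    """Reduce a per-side dict parameter to its mean; pass scalars through."""
    v = getattr(params, name)
    if isinstance(v, dict):
        vals = [x for x in v.values() if x is not None]
        if not vals:
            raise ValidationError(f"parameter {name!r} absent on all sides")
        return float(np.mean(vals))
    if v is None:
        raise ValidationError(f"parameter {name!r} absent")
    return float(v)


def radar_vector(params, spec: RadarSpec) -> dict[str, float]:
    """Normalized radar values for one trial's GaitParameters."""
    raw = {p: _scalarize(params, p) for p in spec.parameters}
    norm = normalize_minmax(raw, spec.bounds)
    return {p: (1.0 - v if p in spec.invert else v) for p, v in norm.items()}


def render_radar(spec: RadarSpec, params, path: str | Path, label: str = "") -> Path:
    """Write a polygon radar chart (SVG/PNG by suffix) for one trial."""
    values = radar_vector(params, spec)
    names = list(values)
    if len(names) < 3:
        raise ValidationError("radar layout needs at least 3 parameters")
    vals = [values[n] for n in names]
    angles = np.linspace(0, 2 * np.pi, len(names), endpoint=False).tolist()
    vals_c = vals + vals[:1]
    angles_c = angles + angles[:1]
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(5, 5))
    ax.plot(angles_c, vals_c, "o-", lw=2)
    ax.fill(angles_c, vals_c, alpha=0.25)
    ax.set_xticks(angles)
    ax.set_xticklabels(names, fontsize=8)
    ax.set_ylim(0, 1)
    if label:
        ax.set_title(label)
    path = Path(path)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
    return path


def render_steps(
    ev: GaitEvents, com_hip: ComTrajectory, win: AnalysisWindow, path: str | Path
) -> Path:
    """Overhead x-z step plot: VGAP boundaries, sensor, steps, COM trace."""
    if ev.n_onsets == 0:
        raise ValidationError("no step events to plot")
    fig, ax = plt.subplots(figsize=(7, 4))
    mask = win.contains(com_hip.t)
    ax.plot(com_hip.position[mask, 2], com_hip.position[mask, 0], "m-", lw=1.5, label="COM (hip)")
    for leg, marker, color in (("left", "o", "tab:red"), ("right", "s", "tab:blue")):
        onsets = ev.onsets[leg]
        if onsets:
            ax.plot(
                [o.z for o in onsets], [o.x for o in onsets],
                marker, color=color, ls="none", ms=8, label=f"{leg} steps",
            )
    for d, style in ((win.d_enter, "k--"), (win.d_exit, "k--")):
        ax.axvline(d, ls=style[1:], color=style[0], lw=1)
    ax.plot([0], [0], "kx", ms=10, label="sensor")
    ax.set_xlabel("depth from sensor z [m]")
    ax.set_ylabel("lateral x [m]")
    ax.invert_xaxis()
    ax.legend(fontsize=8, loc="best")
    path = Path(path)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
    return path
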