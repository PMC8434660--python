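"""End-to-end trial analysis: raw skeleton stream -> gait parameters.

Chains the pipeline stages in their canonical order — resample, low-pass,
COM/window delimitation, ankle binarization, event extraction, parameter
assembly — and bundles the intermediate products so the CLI and plots can
reuse them.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_skeleton import SessionMeta, SkeletonSequence
from .parameters import GaitParameters, assemble_parameters
from .preprocess import PreprocessConfig, preprocess
from .segmentation import (
    GaitEvents,
    SegmentationConfig,
    StepPhaseArray,
    binarize_ankle,
    extract_events,
)
from .vgap import (
    AnalysisWindow,
    ComTrajectory,
    DEFAULT_D_ENTER_M,
    DEFAULT_D_EXIT_M,
    com_distance,
    compute_com_body,
    compute_com_hip,
    find_analysis_window,
)


@dataclass
class TrialResult:
    """Everything one trial produces, from filtered stream to parameters."""

    sequence: SkeletonSequence          # preprocessed (uniform, filtered)
    window: AnalysisWindow
    com_body: ComTrajectory
    com_hip: ComTrajectory
    phases: dict[str, StepPhaseArray]   # 'left'/'right'
    events: GaitEvents
    parameters: GaitParameters

    def to_dict(self) -> dict:
        return {
            "source_id": self.sequence.source_id,
            "window": {
                "t_i": self.window.t_i,
                "t_f": self.window.t_f,
                "d_enter": self.window.d_enter,
                "d_exit": self.window.d_exit,
                "compliant": self.window.compliant,
            },
            "parameters": self.parameters.to_dict(),
            "steps": [
                {
                    "lead_leg": s.lead_leg,
                    "onset_time_s": s.onset_time,
                    "step_length_m": s.step_length_m,
                    "step_time_s": s.step_time_s,
                }
                for s in self.events.steps
            ],
        }


def analyze_sequence(
    seq: SkeletonSequence,
    meta: SessionMeta | None = None,
    pre_cfg: PreprocessConfig | None = None,
    seg_cfg: SegmentationConfig | None = None,
    d_enter: float = DEFAULT_D_ENTER_M,
    d_exit: float = DEFAULT_D_EXIT_M,
    com_strategy: str = "trunk_centroid",
) -> TrialResult:
    """Run the full single-trial pipeline on a raw skeleton recording.

    The whole recording is filtered before windowing (filtering a short
    window would amplify edge effects), and ankle events are detected on
    the whole filtered stream then clipped to the window.
    """
    pre_cfg = pre_cfg or PreprocessConfig()
    seg_cfg = seg_cfg or SegmentationConfig()

    smooth = preprocess(seq, pre_cfg)

    com_body = compute_com_body(smooth, strategy=com_strategy)  # type: ignore[arg-type]
    window = find_analysis_window(com_distance(com_body), d_enter=d_enter, d_exit=d_exit)
    com_hip = compute_com_hip(smooth)

    phases: dict[str, StepPhaseArray] = {}
    for leg, joint in (("left", "AnkleLeft"), ("right", "AnkleRight")):
        traj = smooth.joint(joint)
        phases[leg] = binarize_ankle(traj[:, 2], seg_cfg, t=smooth.t, leg=leg)  # type: ignore[arg-type]

    events = extract_events(
        phases["left"],
        phases["right"],
        window,
        x_left=smooth.joint("AnkleLeft")[:, 0],
        x_right=smooth.joint("AnkleRight")[:, 0],
    )
    params = assemble_parameters(events, phases["left"], phases["right"], com_hip, window, meta)
    return TrialResult(
        sequence=smooth,
        window=window,
        com_body=com_body,
        com_hip=com_hip,
        phases=phases,
        events=events,
        parameters=params,
    )
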