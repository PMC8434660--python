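"""Kinect-v2 25-joint vocabulary and tracking states.

The joint order below is the canonical column order of the skeleton file
dialects and of the (n, 25, 3) coordinate array.  Axis convention, fixed at
the format level: x lateral (+ toward the subject's left as seen by the
sensor), y vertical up, z depth increasing away from the sensor; the sensor
sits at the origin.  Units are meters and seconds everywhere.
"""

from __future__ import annotations

# Canonical Kinect-v2 skeletal model: 25 named joints.
JOINT_NAMES: tuple[str, ...] = (
    "SpineBase",
    "SpineMid",
    "Neck",
    "Head",
    "ShoulderLeft",
    "ElbowLeft",
    "WristLeft",
    "HandLeft",
    "ShoulderRight",
    "ElbowRight",
    "WristRight",
    "HandRight",
    "HipLeft",
    "KneeLeft",
    "AnkleLeft",
    "FootLeft",
    "HipRight",
    "KneeRight",
    "AnkleRight",
    "FootRight",
    "SpineShoulder",
    "HandTipLeft",
    "ThumbLeft",
    "HandTipRight",
    "ThumbRight",
)

N_JOINTS = len(JOINT_NAMES)  # 25

JOINT_INDEX: dict[str, int] = {name: i for i, name in enumerate(JOINT_NAMES)}

# Tracking-state vocabulary, stored per joint per frame.
TRACKING_STATES: tuple[str, ...] = ("not_tracked", "inferred", "tracked")
STATE_CODE: dict[str, int] = {s: i for i, s in enumerate(TRACKING_STATES)}

# Joints the pipeline cannot do without.
REQUIRED_JOINTS: tuple[str, ...] = ("AnkleLeft", "AnkleRight", "HipLeft", "HipRight")

# Trunk joints whose centroid serves as the default whole-body COM proxy.
TRUNK_JOINTS: tuple[str, ...] = ("SpineBase", "SpineMid", "HipLeft", "HipRight")
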