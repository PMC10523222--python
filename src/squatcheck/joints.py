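"""Joint vocabulary and the 10-joint subset used by the classifier.

The canonical vocabulary is OpenPose BODY_25. The classifier consumes only
the trunk and leg landmarks: arms, head and feet carry little information
about squat correctness, and dropping them keeps the input at 20 channels
(10 joints x 2 coordinates).

Coordinates are image coordinates throughout: origin top-left, y increases
downward. The normalization step makes the model indifferent to global
translation and scale, so no axis flip is ever applied.
"""

from __future__ import annotations

# BODY_25 landmark names in OpenPose output order.
BODY_25: tuple[str, ...] = (
    "nose", "neck",
    "r_shoulder", "r_elbow", "r_wrist",
    "l_shoulder", "l_elbow", "l_wrist",
    "mid_hip",
    "r_hip", "r_knee", "r_ankle",
    "l_hip", "l_knee", "l_ankle",
    "r_eye", "l_eye", "r_ear", "l_ear",
    "l_big_toe", "l_small_toe", "l_heel",
    "r_big_toe", "r_small_toe", "r_heel",
)

# The 10 joints kept for classification, in the fixed channel order used by
# the feature tensor: [neck, mid_hip, L/R shoulder, L/R hip, L/R knee,
# L/R ankle] x (x then y) = 20 channels.  Trained models are only portable
# across installations because this order is fixed.
MODEL_JOINTS: tuple[str, ...] = (
    "neck", "mid_hip",
    "l_shoulder", "r_shoulder",
    "l_hip", "r_hip",
    "l_knee", "r_knee",
    "l_ankle", "r_ankle",
)

N_CHANNELS: int = 2 * len(MODEL_JOINTS)

# Translation table for other skeleton vocabularies (COCO-17 style names ->
# BODY_25 names). COCO has no neck or mid-hip; those are synthesized upstream
# if needed, so only directly mappable landmarks appear here.
ALIASES: dict[str, str] = {
    "left_shoulder": "l_shoulder", "right_shoulder": "r_shoulder",
    "left_hip": "l_hip", "right_hip": "r_hip",
    "left_knee": "l_knee", "right_knee": "r_knee",
    "left_ankle": "l_ankle", "right_ankle": "r_ankle",
    "left_elbow": "l_elbow", "right_elbow": "r_elbow",
    "left_wrist": "l_wrist", "right_wrist": "r_wrist",
    "left_eye": "l_eye", "right_eye": "r_eye",
    "left_ear": "l_ear", "right_ear": "r_ear",
}


def canonical_name(name: str) -> str:
    """Map a joint name from a foreign vocabulary onto BODY_25 naming."""
    name = name.lower()
    return ALIASES.get(name, name)
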