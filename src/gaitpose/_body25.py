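"""BODY_25 keypoint layout constants.

Index order follows the OpenPose BODY_25 model output: each person is a flat
``[x1, y1, c1, ..., x25, y25, c25]`` array in image pixels with per-keypoint
confidences in [0, 1].
"""

BODY25_NAMES = (
    "nose",
    "neck",
    "shoulder_R",
    "elbow_R",
    "wrist_R",
    "shoulder_L",
    "elbow_L",
    "wrist_L",
    "pelvis",  # MidHip
    "hip_R",
    "knee_R",
    "ankle_R",
    "hip_L",
    "knee_L",
    "ankle_L",
    "eye_R",
    "eye_L",
    "ear_R",
    "ear_L",
    "big_toe_L",
    "small_toe_L",
    "heel_L",
    "big_toe_R",
    "small_toe_R",
    "heel_R",
)

N_KEYPOINTS = 25

NAME_TO_INDEX = {name: i for i, name in enumerate(BODY25_NAMES)}

#: Left/right leg keypoint pairs affected by limb-identity swaps.
LEG_PAIRS = (
    ("hip_L", "hip_R"),
    ("knee_L", "knee_R"),
    ("ankle_L", "ankle_R"),
    ("heel_L", "heel_R"),
    ("big_toe_L", "big_toe_R"),
    ("small_toe_L", "small_toe_R"),
)

LEG_LANDMARKS_L = tuple(left for left, _ in LEG_PAIRS)
LEG_LANDMARKS_R = tuple(right for _, right in LEG_PAIRS)
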