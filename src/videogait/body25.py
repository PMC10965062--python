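"""BODY_25 keypoint model: names, indices and bilateral pairings.

The 25-keypoint body model used by the OpenPose demo. Index order is fixed
by the OpenPose output format and must never be reordered.
"""

from __future__ import annotations

N_KEYPOINTS = 25

KEYPOINT_NAMES = (
    "nose",          # 0
    "neck",          # 1
    "r_shoulder",    # 2
    "r_elbow",       # 3
    "r_wrist",       # 4
    "l_shoulder",    # 5
    "l_elbow",       # 6
    "l_wrist",       # 7
    "mid_hip",       # 8
    "r_hip",         # 9
    "r_knee",        # 10
    "r_ankle",       # 11
    "l_hip",         # 12
    "l_knee",        # 13
    "l_ankle",       # 14
    "r_eye",         # 15
    "l_eye",         # 16
    "r_ear",         # 17
    "l_ear",         # 18
    "l_big_toe",     # 19
    "l_small_toe",   # 20
    "l_heel",        # 21
    "r_big_toe",     # 22
    "r_small_toe",   # 23
    "r_heel",        # 24
)

INDEX = {name: i for i, name in enumerate(KEYPOINT_NAMES)}

NOSE = 0
NECK = 1
R_SHOULDER, R_ELBOW, R_WRIST = 2, 3, 4
L_SHOULDER, L_ELBOW, L_WRIST = 5, 6, 7
MID_HIP = 8
R_HIP, R_KNEE, R_ANKLE = 9, 10, 11
L_HIP, L_KNEE, L_ANKLE = 12, 13, 14
R_EYE, L_EYE, R_EAR, L_EAR = 15, 16, 17, 18
L_BIG_TOE, L_SMALL_TOE, L_HEEL = 19, 20, 21
R_BIG_TOE, R_SMALL_TOE, R_HEEL = 22, 23, 24

#: (left_index, right_index) pairs of the lower-limb keypoints that are
#: subject to left/right identity errors during leg crossing.
LOWER_LIMB_PAIRS = (
    (L_HIP, R_HIP),
    (L_KNEE, R_KNEE),
    (L_ANKLE, R_ANKLE),
    (L_HEEL, R_HEEL),
    (L_BIG_TOE, R_BIG_TOE),
    (L_SMALL_TOE, R_SMALL_TOE),
)

#: All bilateral pairs, used by the synthetic corruption model.
ALL_BILATERAL_PAIRS = LOWER_LIMB_PAIRS + (
    (L_SHOULDER, R_SHOULDER),
    (L_ELBOW, R_ELBOW),
    (L_WRIST, R_WRIST),
    (L_EYE, R_EYE),
    (L_EAR, R_EAR),
)
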