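"""Combined full-body marker protocol and exposure-point definitions.

The marker set merges lower-limb/pelvis, trunk/shoulder and head/upper-limb
conventions into 47 labelled skin markers.  Six of them are anatomical
calibration markers: they are placed only for a single static double-leg
stance trial and removed before the dynamic task trials.

Eleven body segments each carry a cluster of at least three markers; the
per-frame arithmetic mean of a cluster is that segment's centroid.  Exposure
is assessed at 23 representative body points: the 11 segment centroids plus
12 individual markers on head, trunk and pelvis.  Five of the 23 (the head
centroid and the four head markers) form the head subset used for the
sensory-effect limit.
"""

from __future__ import annotations

from dataclasses import dataclass

#: segment -> cluster marker labels (>= 3 each), dynamic trials
SEGMENT_CLUSTERS: dict[str, tuple[str, ...]] = {
    "head": ("RTEMP", "LTEMP", "ROCC", "LOCC"),
    "trunk": ("T2", "MAI", "JUG", "XIPH"),
    "pelvis": ("RASI", "LASI", "RPSI", "LPSI"),
    "r_thigh": ("RGT", "RLE", "RTHI"),
    "l_thigh": ("LGT", "LLE", "LTHI"),
    "r_tibia": ("RHF", "RTT", "RLM"),
    "l_tibia": ("LHF", "LTT", "LLM"),
    "r_foot": ("RCA", "RFM", "RVM"),
    "l_foot": ("LCA", "LFM", "LVM"),
    "r_hand": ("RWRA", "RWRB", "RFIN"),
    "l_hand": ("LWRA", "LWRB", "LFIN"),
}

#: tracked markers not part of any exposure cluster
EXTRA_DYNAMIC_MARKERS: tuple[str, ...] = ("C7", "RSHO", "LSHO", "RELB", "LELB")

#: anatomical-calibration markers, present only in the static trial
CALIBRATION_ONLY_MARKERS: tuple[str, ...] = (
    "RME", "LME", "RMM", "LMM", "RMEL", "LMEL",
)

DYNAMIC_MARKERS: tuple[str, ...] = tuple(
    label for cluster in SEGMENT_CLUSTERS.values() for label in cluster
) + EXTRA_DYNAMIC_MARKERS

#: the full 47-marker set
ALL_MARKERS: tuple[str, ...] = DYNAMIC_MARKERS + CALIBRATION_ONLY_MARKERS


@dataclass(frozen=True)
class ExposurePoint:
    """One of the 23 representative body points."""

    number: int  # 1-based point number
    kind: str  # "centroid" | "marker"
    source: str  # segment name or marker label
    description: str


EXPOSURE_POINTS: tuple[ExposurePoint, ...] = (
    ExposurePoint(1, "centroid", "head", "Head"),
    ExposurePoint(2, "centroid", "trunk", "Trunk"),
    ExposurePoint(3, "centroid", "pelvis", "Pelvis"),
    ExposurePoint(4, "centroid", "r_thigh", "Right thigh"),
    ExposurePoint(5, "centroid", "l_thigh", "Left thigh"),
    ExposurePoint(6, "centroid", "r_tibia", "Right tibia"),
    ExposurePoint(7, "centroid", "l_tibia", "Left tibia"),
    ExposurePoint(8, "centroid", "r_foot", "Right foot"),
    ExposurePoint(9, "centroid", "l_foot", "Left foot"),
    ExposurePoint(10, "centroid", "r_hand", "Right hand"),
    ExposurePoint(11, "centroid", "l_hand", "Left hand"),
    ExposurePoint(12, "marker", "RTEMP", "Right temple"),
    ExposurePoint(13, "marker", "LTEMP", "Left temple"),
    ExposurePoint(14, "marker", "ROCC", "Right occipital"),
    ExposurePoint(15, "marker", "LOCC", "Left occipital"),
    ExposurePoint(16, "marker", "T2", "Second thoracic vertebra"),
    ExposurePoint(17, "marker", "MAI", "Mid inferior scapular angles"),
    ExposurePoint(18, "marker", "JUG", "Jugular notch"),
    ExposurePoint(19, "marker", "XIPH", "Xiphoid process"),
    ExposurePoint(20, "marker", "RASI", "Right anterior superior iliac spine"),
    ExposurePoint(21, "marker", "LASI", "Left anterior superior iliac spine"),
    ExposurePoint(22, "marker", "RPSI", "Right posterior superior iliac spine"),
    ExposurePoint(23, "marker", "LPSI", "Left posterior superior iliac spine"),
)

#: 1-based numbers of the five head points (centroid + 4 head markers)
HEAD_POINT_NUMBERS: frozenset[int] = frozenset({1, 12, 13, 14, 15})

#: 1-based numbers of the foot points (the two foot-cluster centroids)
FOOT_POINT_NUMBERS: frozenset[int] = frozenset({8, 9})
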