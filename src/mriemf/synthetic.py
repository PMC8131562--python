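"""Seeded synthetic data: stray-field maps and operator task trajectories.

Two generators make every pipeline stage testable without access to the
original laboratory recordings:

* :func:`make_field_map` samples the dipole model on a measurement grid and
  adds multiplicative Gaussian noise, emulating a Hall-magnetometer survey
  whose error scales with the reading.

* :func:`make_task_recording` synthesises a full 47-marker recording at
  100 Hz for a scripted operator task.  The pelvis follows the scripted
  waypoints with a U-shaped speed profile (fast at the doors, slow near the
  magnet); feet and hands oscillate about the pelvis with gait-like phase so
  that their speed maxima approach but respect the observed caps (feet up to
  5 m/s, hands up to 3.5 m/s, head below 2 m/s for radiographers and 1 m/s
  for the cleaner); segment geometry scales with operator stature; every
  marker carries seeded Gaussian noise (SD 2 mm).

The trajectories are plausibility fixtures with the reported statistical
envelope, not biomechanically validated gait.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.integrate import cumulative_trapezoid

from . import markers as mk
from .field_model import DipoleModel, FieldMap, GridSpec, generate_grid, predict_map
from .kinematics import Recording


class ScriptError(ValueError):
    """Raised for an infeasible or unsafe task script."""


@dataclass(frozen=True)
class OperatorProfile:
    """An MRI-room worker, as observed in the measurement campaign."""

    id: str
    job: str  # "radiographer" | "cleaner"
    height: float  # [m]
    weight: float  # [kg]

    def __post_init__(self) -> None:
        if not 1.2 <= self.height <= 2.2:
            raise ValueError("height outside the plausible [1.2, 2.2] m range")


#: the three observed operators (tall male radiographer, small-stature
#: female radiographer, cleaner)
PROFILES: dict[str, OperatorProfile] = {
    "MRIR1": OperatorProfile("MRIR1", "radiographer", 1.89, 115.0),
    "MRIR2": OperatorProfile("MRIR2", "radiographer", 1.50, 49.0),
    "MRIC": OperatorProfile("MRIC", "cleaner", 1.72, 61.0),
}


@dataclass(frozen=True)
class MotionConstraints:
    """Speed caps and magnet standoff enforced by the generator."""

    max_foot_speed: float = 5.0  # [m/s]
    max_hand_speed: float = 3.5  # [m/s]
    max_head_speed: float = 2.0  # [m/s]; 1.0 for the cleaner
    min_standoff: float = 0.7  # any body point vs dipole position [m]

    def __post_init__(self) -> None:
        for v in (
            self.max_foot_speed,
            self.max_hand_speed,
            self.max_head_speed,
            self.min_standoff,
        ):
            if v <= 0:
                raise ValueError("constraints must be positive")


def constraints_for(profile: OperatorProfile) -> MotionConstraints:
    if profile.job == "cleaner":
        return MotionConstraints(max_head_speed=1.0)
    return MotionConstraints()


@dataclass(frozen=True)
class Action:
    """An in-place activity at a waypoint (pelvis stationary)."""

    kind: str  # "hold" | "bend" | "extract" | "place"
    duration: float  # [s]
    waypoint: int  # index into the script's waypoint list


@dataclass(frozen=True)
class RoomGeometry:
    """Laboratory mock-up of the MRI room (metres, z up)."""

    width: float = 4.0
    depth: float = 6.0
    doors: dict = field(
        default_factory=lambda: {"A": (0.6, 0.0), "B": (3.4, 0.0), "C": (0.0, 3.0)}
    )
    magnet_xy: tuple[float, float] = (2.0, 5.0)
    magnet_height: float = 1.0


@dataclass(frozen=True)
class TaskScript:
    """A scripted operator task: waypoints, speed envelope, actions."""

    code: str
    door: str
    waypoints: tuple[tuple[float, float], ...]
    v_far: float  # walking speed far from the magnet [m/s]
    v_near: float  # walking speed at nearest approach [m/s]
    actions: tuple[Action, ...] = ()
    sweep: bool = False  # continuous hand sweeping (cleaner tasks)
    title: str = ""

    def __post_init__(self) -> None:
        if self.v_near > self.v_far:
            raise ScriptError(
                f"{self.code}: infeasible envelope v_near > v_far"
            )
        for a in self.actions:
            if not 0 <= a.waypoint < len(self.waypoints):
                raise ScriptError(f"{self.code}: action at bad waypoint index")


def task_scripts(room: RoomGeometry | None = None) -> dict[str, TaskScript]:
    """The shipped task catalogue: N1-N6, E1-E4 (radiographers), C1, C2."""
    room = room or RoomGeometry()
    A, B, C = (room.doors[k] for k in "ABC")
    panel = (1.0, 4.2)  # control panel on the magnet housing
    bore = (2.0, 3.75)  # standing position at the bore entrance
    couch = (2.0, 3.75)  # couch end

    def entering(code, door, title, v_far=1.5):
        return TaskScript(
            code, door, (room.doors[door], panel, room.doors[door]),
            v_far=v_far, v_near=0.3,
            actions=(Action("hold", 2.0, 1),), title=title,
        )

    def emergency(code, door, title):
        return TaskScript(
            code, door, (room.doors[door], bore, room.doors[door]),
            v_far=1.7, v_near=0.35,
            actions=(Action("hold", 1.5, 1),), title=title,
        )

    scripts = {
        "N1": entering("N1", "A", "Entering/Leaving A"),
        "N2": entering("N2", "B", "Entering/Leaving B"),
        "N3": entering("N3", "C", "Entering/Leaving C"),
        "N4": TaskScript(
            "N4", "A", (A, couch, A), v_far=1.5, v_near=0.3,
            actions=(Action("place", 2.0, 1),), title="Head coil preparation",
        ),
        "N5": TaskScript(
            "N5", "A", (bore, A), v_far=1.5, v_near=0.3,
            actions=(Action("bend", 3.0, 0),), title="Patient centering",
        ),
        "N6": TaskScript(
            "N6", "A", (A, couch, A), v_far=1.5, v_near=0.3,
            actions=(Action("bend", 3.0, 1),), title="Object recovering",
        ),
        "E1": emergency("E1", "A", "Emergency entering A"),
        "E2": emergency("E2", "B", "Emergency entering B"),
        "E3": emergency("E3", "C", "Emergency entering C"),
        "E4": TaskScript(
            "E4", "A", (A, bore, (2.0, 2.9), A), v_far=1.7, v_near=0.35,
            actions=(Action("extract", 3.0, 1),),
            title="Emergency patient extraction",
        ),
        "C1": TaskScript(
            "C1", "A",
            (A, (1.0, 1.5), (3.0, 2.1), (1.0, 2.7), (3.0, 3.3), (2.0, 3.8), A),
            v_far=0.8, v_near=0.3, sweep=True, title="Floor sweeping",
        ),
        "C2": TaskScript(
            "C2", "A",
            (A, (2.0, 3.8), (3.0, 3.3), (1.0, 2.7), (3.0, 2.1), A),
            v_far=0.8, v_near=0.3, sweep=True, title="Floor mopping",
        ),
    }
    return scripts


# ---------------------------------------------------------------------------
# field maps


def make_field_map(
    model: DipoleModel,
    spec: GridSpec,
    noise_rel: float = 0.02,
    seed: int = 0,
    scanner_label: str = "Machine 3.0",
) -> FieldMap:
    """Sample |B| of ``model`` on the grid with multiplicative noise.

    Each reading is |B| * (1 + eps), eps ~ N(0, noise_rel^2), clipped so the
    recorded modulus stays positive.
    """
    if noise_rel < 0:
        raise ValueError("noise_rel must be >= 0")
    positions = generate_grid(spec)
    b = predict_map(model, positions)
    rng = np.random.default_rng(seed)
    factor = np.clip(1.0 + rng.normal(0.0, noise_rel, b.shape), 0.05, None)
    records = np.column_stack([positions, b * factor])
    return FieldMap(records, scanner_label=scanner_label)


# ---------------------------------------------------------------------------
# task trajectories

_DT = 0.01  # 100 Hz
_FOOT_GAIN = 1.8  # peak foot swing speed as multiple of pelvis speed
_HAND_GAIN = 1.1
_CAP_FRACTION = 0.93  # stay below the cap with margin for noise/smoothing

# local marker offsets per segment, (forward, rightward, up) at 1.72 m
# stature; left-side labels mirror the rightward component
_SEGMENT_OFFSETS: dict[str, dict[str, tuple[float, float, float]]] = {
    "head": {
        "RTEMP": (0.07, 0.08, 0.00),
        "LTEMP": (0.07, -0.08, 0.00),
        "ROCC": (-0.08, 0.06, 0.01),
        "LOCC": (-0.08, -0.06, 0.01),
    },
    "trunk": {
        "JUG": (0.09, 0.0, 0.14),
        "XIPH": (0.10, 0.0, 0.02),
        "T2": (-0.10, 0.0, 0.16),
        "MAI": (-0.11, 0.0, 0.00),
        "C7": (-0.09, 0.0, 0.20),
        "RSHO": (0.0, 0.20, 0.17),
        "LSHO": (0.0, -0.20, 0.17),
    },
    "pelvis": {
        "RASI": (0.11, 0.12, 0.02),
        "LASI": (0.11, -0.12, 0.02),
        "RPSI": (-0.10, 0.04, 0.03),
        "LPSI": (-0.10, -0.04, 0.03),
    },
    "r_thigh": {"RGT": (0.0, 0.07, 0.16), "RLE": (0.01, 0.05, -0.18), "RTHI": (0.03, 0.06, 0.0)},
    "l_thigh": {"LGT": (0.0, -0.07, 0.16), "LLE": (0.01, -0.05, -0.18), "LTHI": (0.03, -0.06, 0.0)},
    "r_tibia": {"RHF": (0.0, 0.04, 0.15), "RTT": (0.04, 0.0, 0.10), "RLM": (0.0, 0.045, -0.18)},
    "l_tibia": {"LHF": (0.0, -0.04, 0.15), "LTT": (0.04, 0.0, 0.10), "LLM": (0.0, -0.045, -0.18)},
    "r_foot": {"RCA": (-0.06, 0.0, 0.03), "RFM": (0.12, -0.02, 0.0), "RVM": (0.08, 0.05, 0.0)},
    "l_foot": {"LCA": (-0.06, 0.0, 0.03), "LFM": (0.12, 0.02, 0.0), "LVM": (0.08, -0.05, 0.0)},
    "r_hand": {"RWRA": (0.0, 0.03, 0.02), "RWRB": (0.0, -0.03, 0.02), "RFIN": (0.08, 0.0, -0.02)},
    "l_hand": {"LWRA": (0.0, -0.03, 0.02), "LWRB": (0.0, 0.03, 0.02), "LFIN": (0.08, 0.0, -0.02)},
}

_CALIBRATION_OFFSETS: dict[str, tuple[str, tuple[float, float, float]]] = {
    "RME": ("r_thigh", (0.01, -0.05, -0.18)),
    "LME": ("l_thigh", (0.01, 0.05, -0.18)),
    "RMM": ("r_tibia", (0.0, -0.045, -0.18)),
    "LMM": ("l_tibia", (0.0, 0.045, -0.18)),
    "RMEL": ("r_elbow", (0.0, -0.04, 0.0)),
    "LMEL": ("l_elbow", (0.0, 0.04, 0.0)),
}


def _speed_envelope(dist: np.ndarray, v_near: float, v_far: float) -> np.ndarray:
    """Smoothstep between v_near (d <= 1.3 m) and v_far (d >= 3.0 m)."""
    u = np.clip((dist - 1.3) / (3.0 - 1.3), 0.0, 1.0)
    return v_near + (v_far - v_near) * u * u * (3.0 - 2.0 * u)


def _ramp(n: int, n_up: int, n_down: int) -> np.ndarray:
    """0 -> 1 -> 0 activity profile with cosine ramps over n frames."""
    beta = np.ones(n)
    up = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_up) / max(n_up, 1)))
    down = up[::-1]
    beta[:n_up] = up
    beta[n - n_down:] = down[:n_down]
    return beta


def _lowpass(x: np.ndarray, rate: float, cutoff: float) -> np.ndarray:
    n = x.shape[0]
    if n < 13:
        return x
    sos = signal.butter(2, cutoff / (rate / 2.0), output="sos")
    return signal.sosfiltfilt(sos, x, axis=0, padlen=min(12, n - 1))


def _pelvis_track(
    script: TaskScript, room: RoomGeometry
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pelvis xy at 100 Hz plus per-frame activity levels per action.

    Returns (xy, beta, reach, extract): the bend, reach (hold/place) and
    couch-extraction activity levels, each in [0, 1].  An action of any
    other kind (e.g. "still") dwells without activity.
    """
    magnet = np.asarray(room.magnet_xy)
    frames: list[np.ndarray] = [np.asarray(script.waypoints[0], dtype=float)[None, :]]
    beta_parts: list[np.ndarray] = [np.zeros(1)]
    reach_parts: list[np.ndarray] = [np.zeros(1)]
    extract_parts: list[np.ndarray] = [np.zeros(1)]

    def add_dwell(action: Action) -> None:
        n = int(round(action.duration / _DT))
        p = frames[-1][-1]
        frames.append(np.repeat(p[None, :], n, axis=0))
        act = _ramp(n, int(0.45 * n), int(0.45 * n))
        beta_parts.append(act if action.kind == "bend" else np.zeros(n))
        reach_parts.append(
            act if action.kind in ("hold", "place") else np.zeros(n)
        )
        extract_parts.append(act if action.kind == "extract" else np.zeros(n))

    actions_at = {a.waypoint: a for a in script.actions}
    if 0 in actions_at:
        add_dwell(actions_at[0])
    for i in range(len(script.waypoints) - 1):
        p0 = np.asarray(script.waypoints[i], dtype=float)
        p1 = np.asarray(script.waypoints[i + 1], dtype=float)
        length = float(np.linalg.norm(p1 - p0))
        if length < 1e-9:
            continue
        s = np.linspace(0.0, length, max(3, int(length / 0.005)))
        pts = p0 + np.outer(s / length, p1 - p0)
        v = _speed_envelope(
            np.linalg.norm(pts - magnet, axis=1), script.v_near, script.v_far
        )
        t = cumulative_trapezoid(1.0 / v, s, initial=0.0)
        n = max(1, int(round(t[-1] / _DT)))
        t_reg = (np.arange(n) + 1) * _DT
        s_reg = np.interp(t_reg, t, s)
        xy = p0 + np.outer(s_reg / length, p1 - p0)
        frames.append(xy)
        z = np.zeros(n)
        beta_parts.append(z)
        reach_parts.append(z)
        extract_parts.append(z)
        if (i + 1) in actions_at:
            add_dwell(actions_at[i + 1])
    xy = np.vstack(frames)
    return (
        xy,
        np.concatenate(beta_parts),
        np.concatenate(reach_parts),
        np.concatenate(extract_parts),
    )


def _heading(
    xy_smooth: np.ndarray, rate: float, max_turn_rate: float = 2.0
) -> np.ndarray:
    """Unit forward direction per frame.

    The heading tracks the travel direction, is held through near-zero
    speed, and its angular velocity is limited to ``max_turn_rate`` [rad/s]
    so that body-fixed markers do not acquire unphysical tangential speeds
    at path corners and turnarounds.
    """
    vel = np.gradient(xy_smooth, 1.0 / rate, axis=0)
    speed = np.linalg.norm(vel, axis=1)
    moving = speed > 0.05
    angles = np.arctan2(vel[:, 1], vel[:, 0])
    target = np.zeros(len(vel))
    current = np.pi / 2.0
    if moving.any():
        current = angles[np.argmax(moving)]
    for i in range(len(vel)):
        if moving[i]:
            current = angles[i]
        target[i] = current
    # slew-rate-limited pursuit of the target heading
    theta = np.empty_like(target)
    theta[0] = target[0]
    max_step = max_turn_rate / rate
    for i in range(1, len(target)):
        err = (target[i] - theta[i - 1] + np.pi) % (2.0 * np.pi) - np.pi
        theta[i] = theta[i - 1] + np.clip(err, -max_step, max_step)
    fwd = np.column_stack([np.cos(theta), np.sin(theta)])
    fwd = _lowpass(fwd, rate, 1.5)
    norms = np.linalg.norm(fwd, axis=1)
    norms[norms < 1e-9] = 1.0
    return fwd / norms[:, None]


def make_task_recording(
    profile: OperatorProfile,
    script: TaskScript,
    constraints: MotionConstraints | None = None,
    seed: int = 0,
    room: RoomGeometry | None = None,
    noise_sd: float = 0.002,
    include_calibration: bool = False,
) -> Recording:
    """Synthesise a 100 Hz full-marker-set recording of one task execution."""
    room = room or RoomGeometry()
    constraints = constraints or constraints_for(profile)
    magnet = np.asarray(room.magnet_xy)

    # waypoints must keep the whole body clear of the magnet: allow for
    # forward reach and marker extent on top of the point standoff
    for wp in script.waypoints:
        if np.linalg.norm(np.asarray(wp) - magnet) < constraints.min_standoff + 0.4:
            raise ScriptError(
                f"{script.code}: waypoint {wp} violates the "
                f"{constraints.min_standoff} m magnet standoff"
            )

    rate = 1.0 / _DT
    H = profile.height
    sc = H / 1.72

    xy_raw, beta, reach, extract = _pelvis_track(script, room)
    n = len(xy_raw)
    t = np.arange(n) * _DT
    xy = _lowpass(xy_raw, rate, 1.2)
    v_s = _lowpass(
        np.linalg.norm(np.gradient(xy, _DT, axis=0), axis=1)[:, None], rate, 1.0
    )[:, 0]
    v_s = np.clip(v_s, 0.0, None)
    fwd = _heading(xy, rate)
    right = np.column_stack([fwd[:, 1], -fwd[:, 0]])
    # the head stabilizes in space during locomotion: its segment frame
    # turns more slowly than the trunk/pelvis frame
    fwd_head = _heading(xy, rate, max_turn_rate=1.0)
    right_head = np.column_stack([fwd_head[:, 1], -fwd_head[:, 0]])

    # gait phase
    f_stride = np.clip(0.9 * v_s + 0.6, 0.5, 2.2)
    phase = cumulative_trapezoid(2.0 * np.pi * f_stride, t, initial=0.0)

    def swing_amp(gain: float, cap: float) -> np.ndarray:
        """Swing amplitude so peak extra speed = min(gain*v, margin to cap)."""
        extra = np.minimum(gain * v_s, np.clip(_CAP_FRACTION * cap - v_s, 0.0, None))
        return extra / (2.0 * np.pi * f_stride)

    A_foot = swing_amp(_FOOT_GAIN, constraints.max_foot_speed)
    A_hand = swing_amp(_HAND_GAIN, constraints.max_hand_speed)

    # anchors ---------------------------------------------------------------
    pelvis_z = 0.53 * H - 0.14 * beta + 0.012 * np.minimum(v_s, 1.0) * np.sin(
        2.0 * phase
    )
    pelvis = np.column_stack([xy, pelvis_z])

    head_z = (1.0 - beta) * 0.93 * H + beta * 0.92
    head_xy = xy + fwd_head * (0.01 + 0.30 * beta)[:, None]
    head = np.column_stack([head_xy, head_z])

    trunk_z = pelvis_z + 0.55 * (head_z - pelvis_z)
    trunk_xy = xy + fwd * (0.01 + 0.22 * beta)[:, None]
    trunk = np.column_stack([trunk_xy, trunk_z])

    anchors: dict[str, np.ndarray] = {
        "pelvis": pelvis, "trunk": trunk, "head": head,
    }

    for side, sign, ph in (("r", +1.0, 0.0), ("l", -1.0, np.pi)):
        swing = A_foot * np.sin(phase + ph)
        lat = sign * 0.09 * H
        foot_xy = xy + right * lat + fwd * swing[:, None]
        foot_z = 0.045 * H + 0.03 * v_s * np.clip(np.sin(phase + ph), 0.0, None)
        anchors[f"{side}_foot"] = np.column_stack([foot_xy, foot_z])
        anchors[f"{side}_tibia"] = np.column_stack(
            [xy + right * lat + fwd * (0.7 * swing)[:, None],
             np.full(n, 0.225 * H) - 0.08 * beta]
        )
        anchors[f"{side}_thigh"] = np.column_stack(
            [xy + right * (lat * 0.95) + fwd * (0.35 * swing)[:, None],
             0.41 * H - 0.10 * beta]
        )
        # arms swing in anti-phase with the same-side leg; actions move the
        # hands forward/down (reach, bend) or pull cyclically (extract)
        arm = A_hand * np.sin(phase + ph + np.pi)
        hand_z = (
            0.52 * H
            + reach * (0.95 - 0.52 * H)
            + beta * (0.18 - 0.52 * H)
        )
        hand_fwd = arm + 0.30 * reach + 0.30 * beta + extract * (
            -0.25 * np.sin(2.0 * np.pi * 0.6 * t)
        )
        hand_xy = xy + right * (sign * 0.13 * H) + fwd * hand_fwd[:, None]
        if script.sweep:
            sweep_off = 0.28 * np.sin(2.0 * np.pi * 0.8 * t + (0 if sign > 0 else np.pi / 3))
            hand_xy = hand_xy + right * sweep_off[:, None] + fwd * 0.25
            hand_z = hand_z - 0.10 * H
        anchors[f"{side}_hand"] = np.column_stack([hand_xy, hand_z])

    # markers ---------------------------------------------------------------
    rng = np.random.default_rng(seed)
    up = np.zeros((n, 3))
    up[:, 2] = 1.0
    fwd3 = np.column_stack([fwd, np.zeros(n)])
    right3 = np.column_stack([right, np.zeros(n)])
    fwd3_head = np.column_stack([fwd_head, np.zeros(n)])
    right3_head = np.column_stack([right_head, np.zeros(n)])

    def place(
        anchor: np.ndarray,
        off: tuple[float, float, float],
        head_frame: bool = False,
    ) -> np.ndarray:
        f, r, u = (c * sc for c in off)
        if head_frame:
            return anchor + f * fwd3_head + r * right3_head + u * up
        return anchor + f * fwd3 + r * right3 + u * up

    markers: dict[str, np.ndarray] = {}
    for segment, offs in _SEGMENT_OFFSETS.items():
        for label, off in offs.items():
            markers[label] = place(
                anchors[segment], off, head_frame=(segment == "head")
            )

    # elbows interpolate between shoulder and hand
    for side, sho, elb in (("r", "RSHO", "RELB"), ("l", "LSHO", "LELB")):
        elbow = 0.5 * (markers[sho] + anchors[f"{side}_hand"])
        markers[elb] = elbow

    if include_calibration:
        for label, (parent, off) in _CALIBRATION_OFFSETS.items():
            if parent.endswith("elbow"):
                base = markers["RELB" if parent.startswith("r") else "LELB"]
                markers[label] = place(base, off)
            else:
                markers[label] = place(anchors[parent], off)

    for label in markers:
        markers[label] = markers[label] + rng.normal(0.0, noise_sd, (n, 3))

    # verify the standoff on the realised markers
    dipole = np.array([*room.magnet_xy, room.magnet_height])
    dmin = min(
        float(np.linalg.norm(arr - dipole, axis=1).min())
        for arr in markers.values()
    )
    if dmin < constraints.min_standoff:
        raise ScriptError(
            f"{script.code}: generated body point came within {dmin:.2f} m "
            f"of the magnet (standoff {constraints.min_standoff} m)"
        )

    return Recording(
        rate=rate,
        markers=markers,
        meta={
            "operator": profile.id,
            "task": script.code,
            "seed": seed,
            "title": script.title,
        },
    )


def make_static_trial(
    profile: OperatorProfile,
    seed: int = 0,
    room: RoomGeometry | None = None,
    noise_sd: float = 0.002,
) -> Recording:
    """1 s static double-leg stance with all 47 markers (calibration set
    included); motion is measurement noise only."""
    stand = TaskScript(
        "STATIC", "A", ((1.0, 1.0), (1.0, 1.0001)), v_far=0.3, v_near=0.3,
        actions=(Action("still", 1.2, 0),), title="Static calibration",
    )
    rec = make_task_recording(
        profile, stand, seed=seed, room=room, noise_sd=noise_sd,
        include_calibration=True,
    )
    # trim to exactly 1 s
    n = int(rec.rate)
    return Recording(
        rate=rec.rate,
        markers={k: v[:n] for k, v in rec.markers.items()},
        meta=rec.meta,
    )
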