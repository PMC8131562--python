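"""Motion-induced electromotive-field exposure and ELV compliance.

A conducting body moving with velocity v through a static magnetic field B
experiences, per unit charge, the Lorentz electromotive field v x B.  Its
magnitude |v x B| is the exposure metric tested here against the exposure
limit values (ELVs) of Directive 2013/35/EU:

* health-effects ELV: 1.1 V/m on the whole-body peak;
* sensory-effects ELV: 0.7/f V/m on the head peak, where f is the
  motion-related frequency, estimated as the spectral centroid of the
  periodogram of the head exposure pulse.

Neglecting the reaction electrostatic field inside tissue makes |v x B| an
overestimate of the net induced field, i.e. a precautionary bound.  The
ICNIRP conversion-factor estimator E_i = C * dB/dt is provided only for
side-by-side comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .field_model import DipoleModel, dipole_field
from .kinematics import PointKinematics


@dataclass(frozen=True)
class ELVSpec:
    """Directive 2013/35/EU limit parameters for f < a few Hz."""

    health_elv: float = 1.1  # [V/m]
    sensory_coefficient: float = 0.7  # [V.Hz/m]; sensory ELV(f) = 0.7/f

    def __post_init__(self) -> None:
        if self.health_elv <= 0 or self.sensory_coefficient <= 0:
            raise ValueError("ELV parameters must be > 0")


@dataclass(frozen=True)
class FrequencyEstimate:
    """Motion-related frequency from a spectral centroid [Hz]."""

    f: float
    method: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.f <= 0:
            raise ValueError("frequency must be > 0")


@dataclass(frozen=True)
class IcnirpParams:
    """Conversion factor C [m] for the estimator E_i = C * dB/dt."""

    C: float = 0.2

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("conversion factor must be > 0")


@dataclass
class ExposureResult:
    """Per-frame |v x B| for every assessed point, with peak series.

    ``E`` has shape (T, n_points) [V/m].  ``body_peak_series`` is the
    per-frame max over all 23 points, ``head_peak_series`` over the 5 head
    points; ``task_peak`` is the overall maximum.
    """

    rate: float
    E: np.ndarray
    body_peak_series: np.ndarray
    head_peak_series: np.ndarray

    @property
    def task_peak(self) -> float:
        return float(self.body_peak_series.max())

    @property
    def head_task_peak(self) -> float:
        return float(self.head_peak_series.max())


@dataclass(frozen=True)
class ComplianceVerdict:
    """Outcome of testing one task against the ELVs."""

    health_pass: bool
    sensory_pass: bool
    health_margin: float  # health ELV - whole-body peak [V/m], signed
    sensory_margin: float  # sensory ELV(f) - head peak [V/m], signed
    sensory_elv: float
    frequency_hz: float


def emf(v, B) -> float | np.ndarray:
    """|v x B| [V/m] for velocity v [m/s] and magnetic field B [T]."""
    v = np.asarray(v, dtype=float)
    B = np.asarray(B, dtype=float)
    return np.linalg.norm(np.cross(v, B), axis=-1)


def assess_task(
    kin: PointKinematics,
    model: DipoleModel,
    point_subset: str = "all",
) -> ExposureResult:
    """Exposure E[t, i] = |v_i(t) x B(p_i(t))| at every assessed point.

    B is evaluated from the dipole model at each point's instantaneous
    position, frame by frame.  ``point_subset='head'`` restricts the
    assessment to the five head points.
    """
    if point_subset not in ("all", "head"):
        raise ValueError("point_subset must be 'all' or 'head'")
    pos = kin.positions
    vel = kin.velocities
    if point_subset == "head":
        idx = kin.point_set.head_indices
        pos, vel = pos[:, idx], vel[:, idx]
    T, n, _ = pos.shape
    B = dipole_field(pos.reshape(-1, 3), model).reshape(T, n, 3)
    E = emf(vel, B)
    if point_subset == "head":
        head = E.max(axis=1)
        return ExposureResult(
            rate=kin.rate, E=E, body_peak_series=head, head_peak_series=head
        )
    head_idx = kin.point_set.head_indices
    return ExposureResult(
        rate=kin.rate,
        E=E,
        body_peak_series=E.max(axis=1),
        head_peak_series=E[:, head_idx].max(axis=1),
    )


def spectral_centroid_frequency(x, rate: float) -> FrequencyEstimate:
    """Power-weighted mean frequency of the mean-removed periodogram.

    The periodogram is computed over the full window with no taper
    (frequency resolution rate/N); the centroid is taken over the strictly
    positive frequencies up to Nyquist.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 16:
        raise ValueError("need at least 16 samples for a frequency estimate")
    if rate <= 0:
        raise ValueError("rate must be > 0")
    f, P = signal.periodogram(
        x - x.mean(), fs=rate, window="boxcar", detrend=False
    )
    f, P = f[1:], P[1:]  # drop DC
    total = P.sum()
    if total <= 0 or not np.isfinite(total):
        raise ValueError("signal has no power after mean removal")
    centroid = float((f * P).sum() / total)
    return FrequencyEstimate(
        f=centroid,
        method={
            "estimator": "periodogram spectral centroid",
            "window": "boxcar",
            "detrend": "mean removal",
            "resolution_hz": rate / x.size,
        },
    )


def sensory_elv(f: float, spec: ELVSpec = ELVSpec()) -> float:
    """Frequency-adjusted sensory-effects ELV, 0.7/f [V/m]."""
    if f <= 0:
        raise ValueError("frequency must be > 0")
    return spec.sensory_coefficient / f


def check_compliance(
    result: ExposureResult,
    f: FrequencyEstimate | None = None,
    spec: ELVSpec = ELVSpec(),
) -> ComplianceVerdict:
    """Test a task's peaks against the health and sensory ELVs.

    If no frequency estimate is supplied it is derived from the head
    peak-exposure series of the task (the plotted induced pulse).
    Comparisons are strict: a peak equal to the limit does not pass.
    """
    if f is None:
        f = spectral_centroid_frequency(result.head_peak_series, result.rate)
    s_elv = sensory_elv(f.f, spec)
    body_peak = result.task_peak
    head_peak = result.head_task_peak
    return ComplianceVerdict(
        health_pass=body_peak < spec.health_elv,
        sensory_pass=head_peak < s_elv,
        health_margin=spec.health_elv - body_peak,
        sensory_margin=s_elv - head_peak,
        sensory_elv=s_elv,
        frequency_hz=f.f,
    )


def icnirp_estimate(
    b_series, rate: float, params: IcnirpParams = IcnirpParams()
) -> np.ndarray:
    """Comparison-only ICNIRP estimator E_i = C * d|B|/dt [V/m].

    Uses central differences (one-sided at the endpoints).  This coarse
    conversion-factor approximation is reported only alongside the
    electromotive-field results, never instead of them.
    """
    b_series = np.asarray(b_series, dtype=float)
    if b_series.size < 3:
        raise ValueError("need at least 3 samples")
    return params.C * np.abs(np.gradient(b_series, 1.0 / rate))
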