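"""Point-dipole model of the static stray field of a closed-bore MRI magnet.

The field outside the magnet housing is approximated by a single point
magnetic dipole of moment ``m`` located near the isocenter at height ``h``
above the floor.  The dipole position in the horizontal plane is not known a
priori: it is estimated, as planar offsets (dx, dy) from a nominal origin, by
least-squares fitting of predicted |B| against a measured grid map of field
moduli.  The moment magnitude can optionally be refined in the same fit.

Units are SI throughout: metres, teslas, A.m^2.  The room frame is
right-handed with z up and the origin at the map corner nearest Door A.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

MU0 = 4.0e-7 * np.pi  # magnetic constant [T.m/A]

#: preliminary dipole moment for the 3.0 T closed-bore machine [A.m^2]
DEFAULT_MOMENT = 1.06e6
#: preliminary dipole height above the floor [m]
DEFAULT_HEIGHT = 1.0


class SingularFieldError(ValueError):
    """Raised when the dipole field is evaluated at the dipole position."""


class FitError(RuntimeError):
    """Raised when the dipole fit fails to converge."""


@dataclass(frozen=True)
class DipoleModel:
    """A point magnetic dipole generating the stray field.

    Parameters
    ----------
    moment_magnitude : dipole moment m [A.m^2], > 0.
    moment_axis : unit 3-vector along the bore axis (dimensionless).
    position : (x, y, z) of the dipole in the room frame [m]; z = height
        above the floor, > 0.
    """

    moment_magnitude: float = DEFAULT_MOMENT
    moment_axis: tuple[float, float, float] = (0.0, 1.0, 0.0)
    position: tuple[float, float, float] = (2.0, 5.0, DEFAULT_HEIGHT)

    def __post_init__(self) -> None:
        if self.moment_magnitude <= 0:
            raise ValueError("moment_magnitude must be > 0")
        axis = np.asarray(self.moment_axis, dtype=float)
        norm = np.linalg.norm(axis)
        if abs(norm - 1.0) > 1e-12:
            if norm == 0:
                raise ValueError("moment_axis must be non-zero")
            object.__setattr__(self, "moment_axis", tuple(axis / norm))
        if self.position[2] <= 0:
            raise ValueError("dipole height above floor must be > 0")

    @property
    def moment_vector(self) -> np.ndarray:
        """m = moment_magnitude * moment_axis [A.m^2]."""
        return self.moment_magnitude * np.asarray(self.moment_axis)

    def with_offsets(self, dx: float, dy: float) -> "DipoleModel":
        """Return a copy displaced by (dx, dy) in the horizontal plane."""
        x0, y0, h = self.position
        return replace(self, position=(x0 + dx, y0 + dy, h))


@dataclass(frozen=True)
class GridSpec:
    """Planar measurement grid replicated at several heights.

    ``planar_points`` are (x, y) pairs [m]; ``heights`` are z values [m].
    ``step_short``/``step_long`` document the two mesh steps of the layout.
    """

    planar_points: tuple[tuple[float, float], ...]
    heights: tuple[float, ...]
    step_short: float = 0.20
    step_long: float = 0.40

    def __post_init__(self) -> None:
        if len(set(self.planar_points)) != len(self.planar_points):
            raise ValueError("planar points must be unique")
        if len(set(self.heights)) != len(self.heights):
            raise ValueError("heights must be distinct")
        if any(h <= 0 for h in self.heights):
            raise ValueError("heights must be > 0")

    @property
    def n_positions(self) -> int:
        return len(self.planar_points) * len(self.heights)


@dataclass
class FieldMap:
    """Grid map of measured |B| values.

    ``records`` is an (N, 4) array with columns x, y, z [m], B [T].
    """

    records: np.ndarray
    scanner_label: str = ""

    def __post_init__(self) -> None:
        self.records = np.atleast_2d(np.asarray(self.records, dtype=float))
        if self.records.shape[1] != 4:
            raise ValueError("records must have columns x, y, z, B")
        if np.any(self.records[:, 3] <= 0):
            raise ValueError("every measured |B| must be > 0")

    @property
    def positions(self) -> np.ndarray:
        return self.records[:, :3]

    @property
    def b_measured(self) -> np.ndarray:
        return self.records[:, 3]

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.records, columns=["x_m", "y_m", "z_m", "B_T"])
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, scanner_label: str = "") -> "FieldMap":
        df = pd.read_csv(path)
        cols = ["x_m", "y_m", "z_m", "B_T"]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"field-map CSV missing columns: {missing}")
        return cls(df[cols].to_numpy(), scanner_label=scanner_label)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a dipole fit to a field map."""

    delta_x: float
    delta_y: float
    moment_estimate: float
    pearson_r: float
    residuals: np.ndarray

    def __post_init__(self) -> None:
        if not -1.0 <= self.pearson_r <= 1.0:
            raise ValueError("pearson_r outside [-1, 1]")


def dipole_field(point: Sequence[float], model: DipoleModel) -> np.ndarray:
    """Magnetic field of the point dipole at ``point`` [T].

    B(r) = (mu0 / 4 pi) * (3 (m . rhat) rhat - m) / |r|^3,
    with r the vector from the dipole to the field point.
    """
    pts = np.atleast_2d(np.asarray(point, dtype=float))
    r = pts - np.asarray(model.position)
    rnorm = np.linalg.norm(r, axis=1)
    if np.any(rnorm < 1e-12):
        bad = int(np.argmin(rnorm))
        raise SingularFieldError(
            f"field evaluated at the dipole position (record {bad})"
        )
    rhat = r / rnorm[:, None]
    m = model.moment_vector
    mdot = rhat @ m
    b = (MU0 / (4 * np.pi)) * (3 * mdot[:, None] * rhat - m) / rnorm[:, None] ** 3
    return b[0] if np.ndim(point) == 1 else b


def generate_grid(spec: GridSpec) -> np.ndarray:
    """All measurement positions: planar points x heights, row-major by
    planar index then height ascending within each planar point."""
    if not spec.planar_points or not spec.heights:
        raise ValueError("grid spec needs at least one planar point and height")
    heights = sorted(spec.heights)
    return np.array(
        [(x, y, z) for (x, y) in spec.planar_points for z in heights]
    )


def predict_map(model: DipoleModel, positions: np.ndarray) -> np.ndarray:
    """|B| predicted by the dipole model at each position, order preserved."""
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    return np.linalg.norm(dipole_field(positions, model), axis=1)


def pearson_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Sample Pearson correlation coefficient of two equal-length series."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("series must have equal length >= 2")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("correlation undefined: zero variance")
    return float(stats.pearsonr(a, b).statistic)


def fit_dipole(
    fmap: FieldMap,
    preliminary: DipoleModel,
    refine_moment: bool = False,
) -> FitResult:
    """Least-squares fit of the dipole planar offsets (dx, dy) to a map.

    Minimises sum of squared (predicted - measured) |B| starting from
    offsets (0, 0) at the preliminary position.  With ``refine_moment`` the
    moment magnitude is refined too (third parameter, started at the
    preliminary value); height and axis stay fixed at the preliminaries.
    """
    if fmap.records.shape[0] < 3:
        raise ValueError("need at least 3 map records")
    if len(np.unique(fmap.positions[:, 2])) < 2:
        raise ValueError("need records at >= 2 distinct heights")
    positions = fmap.positions
    b_meas = fmap.b_measured
    m0 = preliminary.moment_magnitude

    # collinearity makes the planar offsets weakly identifiable
    xy = positions[:, :2]
    if np.linalg.matrix_rank(xy - xy.mean(axis=0), tol=1e-9) < 2:
        import warnings

        warnings.warn("map positions are collinear; fit may be rank-deficient")

    def residual(theta: np.ndarray) -> np.ndarray:
        dx, dy = theta[0], theta[1]
        model = preliminary.with_offsets(dx, dy)
        if refine_moment:
            model = replace(model, moment_magnitude=theta[2] * m0)
        return predict_map(model, positions) - b_meas

    def solve(start: list[float]):
        return optimize.least_squares(
            residual, start, method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14
        )

    x0 = [0.0, 0.0, 1.0] if refine_moment else [0.0, 0.0]
    sol = solve(x0)
    # the objective is multimodal when the true dipole sits close to the
    # grid; fall back to the best coarse-grid start if (0, 0) stalled high
    grid_1d = np.linspace(-1.2, 1.2, 13)
    coarse = [
        [dx, dy] + ([1.0] if refine_moment else [])
        for dx in grid_1d
        for dy in grid_1d
    ]
    costs = [0.5 * np.sum(residual(np.asarray(c)) ** 2) for c in coarse]
    best = coarse[int(np.argmin(costs))]
    if min(costs) < sol.cost:
        alt = solve(best)
        if alt.cost < sol.cost:
            sol = alt
    if not sol.success:
        raise FitError(f"dipole fit did not converge: {sol.message}")
    dx, dy = float(sol.x[0]), float(sol.x[1])
    m_est = float(sol.x[2] * m0) if refine_moment else m0
    fitted = preliminary.with_offsets(dx, dy)
    if refine_moment:
        fitted = replace(fitted, moment_magnitude=m_est)
    b_pred = predict_map(fitted, positions)
    return FitResult(
        delta_x=dx,
        delta_y=dy,
        moment_estimate=m_est,
        pearson_r=pearson_correlation(b_pred, b_meas),
        residuals=b_pred - b_meas,
    )


def default_grid_spec() -> GridSpec:
    """The shipped 70-point / 3-height layout (210 positions)."""
    text = resources.files("mriemf.data").joinpath("grid_layout.yaml").read_text()
    return load_grid_spec_from_text(text)


def load_grid_spec(path) -> GridSpec:
    with open(path) as fh:
        return load_grid_spec_from_text(fh.read())


def load_grid_spec_from_text(text: str) -> GridSpec:
    doc = yaml.safe_load(text)
    pts = tuple((float(x), float(y)) for x, y in doc["planar_points"])
    heights = tuple(float(h) for h in doc["heights"])
    return GridSpec(
        planar_points=pts,
        heights=heights,
        step_short=float(doc.get("step_short", 0.20)),
        step_long=float(doc.get("step_long", 0.40)),
    )
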