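"""Topographic sheet geometry: bump codes and the virtual eye/workspace.

Every neural population in the model is a square *sheet* of units with a fixed
linear map between grid indices and degrees of visual angle (positive x =
right, positive y = up).  A location is represented as an isotropic Gaussian
bump of activity; a location is read out as the activity-weighted centroid of
unit centers.  The workspace is treated with a small-angle planar
approximation, so projecting a workspace point onto the retina is a
component-wise subtraction of the eye pose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SheetSpec",
    "NO_SIGNAL",
    "PointingError",
    "OutOfRangeError",
    "TargetNotVisibleError",
    "as_point",
    "encode_bump",
    "decode_centroid",
    "project_to_retina",
    "to_workspace",
    "saccade_profile",
    "pointing_error",
]

#: Sentinel returned by :func:`decode_centroid` when total activity is below
#: the floor -- distinct from a genuine (0, 0) decode.
NO_SIGNAL = None


class OutOfRangeError(ValueError):
    """A point falls outside the span a sheet can represent."""


class TargetNotVisibleError(ValueError):
    """A projected retinal point falls off the retina sheet."""


def as_point(p) -> np.ndarray:
    """Coerce ``(x_deg, y_deg)`` to a float64 length-2 array."""
    a = np.asarray(p, dtype=float)
    if a.shape != (2,):
        raise ValueError(f"expected a 2-vector (x_deg, y_deg), got shape {a.shape}")
    return a


@dataclass(frozen=True)
class SheetSpec:
    """Geometry of one topographic sheet.

    Parameters
    ----------
    n_units_per_side
        Odd integer >= 5 so that one unit sits exactly at 0 deg.
    span_deg
        Half-width of the represented space; unit centers run from
        ``-span_deg`` to ``+span_deg`` on both axes.
    sigma_deg
        Width of the Gaussian encoding bump.
    """

    n_units_per_side: int = 21
    span_deg: float = 50.0
    sigma_deg: float = 3.0

    def __post_init__(self):
        if self.n_units_per_side < 5 or self.n_units_per_side % 2 == 0:
            raise ValueError("n_units_per_side must be an odd integer >= 5")
        if self.span_deg <= 0 or self.sigma_deg <= 0:
            raise ValueError("span_deg and sigma_deg must be positive")

    @property
    def spacing_deg(self) -> float:
        return 2.0 * self.span_deg / (self.n_units_per_side - 1)

    @property
    def axis_deg(self) -> np.ndarray:
        """Unit-center coordinates along one axis, ascending."""
        return np.linspace(-self.span_deg, self.span_deg, self.n_units_per_side)

    @property
    def n_units(self) -> int:
        return self.n_units_per_side ** 2

    def contains(self, p) -> bool:
        p = as_point(p)
        return bool(np.all(np.abs(p) <= self.span_deg + 1e-9))

    def nearest_unit(self, p) -> tuple[int, int]:
        """(row, col) index of the unit whose center is nearest ``p``.

        Rows index y from bottom (-span) to top (+span); columns index x.
        """
        p = as_point(p)
        if not self.contains(p):
            raise OutOfRangeError(f"point {p} outside +/-{self.span_deg} deg span")
        col = int(round((p[0] + self.span_deg) / self.spacing_deg))
        row = int(round((p[1] + self.span_deg) / self.spacing_deg))
        return row, col

    def unit_center(self, row: int, col: int) -> np.ndarray:
        ax = self.axis_deg
        return np.array([ax[col], ax[row]])

    def bump_total(self) -> float:
        """Total activity of a reference bump centered on the sheet."""
        return float(encode_bump((0.0, 0.0), self).sum())


def encode_bump(p, spec: SheetSpec) -> np.ndarray:
    """Encode a point as a unit-peak isotropic Gaussian bump of activity.

    Returns an ``(n, n)`` array; row 0 is the bottom of the sheet (y = -span).
    """
    p = as_point(p)
    if not spec.contains(p):
        raise OutOfRangeError(f"point {p} outside +/-{spec.span_deg} deg span")
    ax = spec.axis_deg
    dx2 = (ax[None, :] - p[0]) ** 2          # columns: x
    dy2 = (ax[:, None] - p[1]) ** 2          # rows: y
    return np.exp(-(dx2 + dy2) / (2.0 * spec.sigma_deg ** 2))


def decode_centroid(a: np.ndarray, spec: SheetSpec, *, floor_frac: float = 0.01):
    """Activity-weighted center of mass of unit centers, in degrees.

    Returns :data:`NO_SIGNAL` when total activity is below ``floor_frac`` of
    the total of a single reference bump (a sheet that is effectively silent
    carries no location).
    """
    a = np.asarray(a, dtype=float)
    if a.shape != (spec.n_units_per_side, spec.n_units_per_side):
        raise ValueError("activity shape does not match sheet spec")
    total = a.sum()
    if not np.isfinite(total) or total <= 1e-12 or total < floor_frac * spec.bump_total():
        return NO_SIGNAL
    ax = spec.axis_deg
    x = float((a.sum(axis=0) * ax).sum() / total)
    y = float((a.sum(axis=1) * ax).sum() / total)
    return np.array([x, y])


def project_to_retina(ball, eye, spec: SheetSpec | None = None) -> np.ndarray:
    """Retinal location of a workspace point given the eye pose.

    Planar small-angle model: ``retinal = ball - eye``.  A rightward eye
    rotation therefore shifts the image leftward on the retina (and a
    downward saccade shifts it upward).
    """
    r = as_point(ball) - as_point(eye)
    if spec is not None and not spec.contains(r):
        raise TargetNotVisibleError(
            f"retinal point {r} off the +/-{spec.span_deg} deg sheet"
        )
    return r


def to_workspace(retinal, eye) -> np.ndarray:
    """Inverse of :func:`project_to_retina`: ``workspace = retinal + eye``."""
    return as_point(retinal) + as_point(eye)


def saccade_profile(start, vector, speed_deg_per_s: float = 400.0,
                    dt_ms: float = 10.0) -> np.ndarray:
    """Eye poses along a constant-speed straight saccade, one per time step.

    Returns an ``(m + 1, 2)`` array: the start pose followed by ``m``
    movement steps, where ``m = ceil(|vector| / speed / dt)``.  The final
    pose equals ``start + vector`` exactly.
    """
    if speed_deg_per_s <= 0 or dt_ms <= 0:
        raise ValueError("speed and dt must be positive")
    start = as_point(start)
    vector = as_point(vector)
    amp = float(np.hypot(*vector))
    if amp == 0.0:
        return start[None, :].copy()
    n_steps = math.ceil(amp / speed_deg_per_s / (dt_ms / 1000.0))
    frac = np.minimum(np.arange(n_steps + 1) * speed_deg_per_s * dt_ms / 1000.0 / amp, 1.0)
    poses = start[None, :] + frac[:, None] * vector[None, :]
    poses[-1] = start + vector  # exact endpoint
    return poses


@dataclass(frozen=True)
class PointingError:
    """Signed per-component pointing error and its magnitude, in degrees.

    ``x_deg > 0`` means the decoded (arm) location is right of the true ball.
    """

    x_deg: float
    y_deg: float

    @property
    def magnitude_deg(self) -> float:
        return float(np.hypot(self.x_deg, self.y_deg))

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.x_deg, self.y_deg])


def pointing_error(decoded, true_ball) -> PointingError | None:
    """Error of a decoded pointing coordinate relative to the true ball.

    Returns ``None`` when ``decoded`` is the :data:`NO_SIGNAL` sentinel.
    """
    if decoded is NO_SIGNAL:
        return None
    d = as_point(decoded) - as_point(true_ball)
    return PointingError(float(d[0]), float(d[1]))
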