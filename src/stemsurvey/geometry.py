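"""Tree DBH from two angle sensors via tangent-arc caliper geometry.

The instrument is a caliper-like frame: a middle beam with a small vertex
block at its centre and two arms hinged on angle sensors, one at each end of
the beam.  When the frame is pressed against a stem, the vertex tip touches
the trunk at the beam middle and each arm swings until its inner face rests
against the bark.  Each hinge reports the arm-to-beam angle (α₁, α₂).

Because the two arms touch the stem on different sides, the cross-section is
modelled as two circular arcs that share the vertex contact point but may
have different radii — an eccentric stem.  For one side, the arc is the
circle tangent to the vertex-tip line (offset ``h`` from the beam axis) at
the beam middle (distance ``s`` from the hinge) and tangent to the arm's
inner face (offset ``w`` from the arm axis).  Elementary tangent geometry
gives the tangent offset along the beam

    s_i = s − (h·cosθ + w) / sinθ,          θ = α·π/180

and the arc radius

    r_i = s_i · tan(θ/2)    (= s − w at α = 90°),

so DBH = r₁ + r₂.  Summing two independent radii is what lets the device
absorb stem eccentricity that a single-width caliper cannot.

A ``series`` evaluation mode reproduces the device firmware's fixed-point
arithmetic, which evaluates sin and cos by 4-term truncated Maclaurin
series (and tan(θ/2) as the ratio of the half-angle series).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

from scipy.optimize import brentq

from .errors import InvalidCalibrationError, OutOfRangeStemError

Mode = Literal["exact", "series"]

__all__ = [
    "DeviceGeometry",
    "AngleCalibration",
    "AnglePair",
    "DbhEstimate",
    "adc_to_angle",
    "tangent_offset",
    "arc_radius",
    "dbh_from_angles",
    "average_dbh",
]


def _sin_series(x: float) -> float:
    """4-term truncated Maclaurin sine, as the firmware computes it."""
    return x - x**3 / math.factorial(3) + x**5 / math.factorial(5) - x**7 / math.factorial(7)


def _cos_series(x: float) -> float:
    """4-term truncated Maclaurin cosine."""
    return 1.0 - x**2 / math.factorial(2) + x**4 / math.factorial(4) - x**6 / math.factorial(6)


@dataclass(frozen=True)
class DeviceGeometry:
    """Fixed mechanical constants of the caliper frame, in centimetres.

    Parameters
    ----------
    s : float
        Half the distance between the two angle-sensor axes; the beam middle
        (and vertex) sits at distance ``s`` from each hinge.
    w : float
        Half width of the arms and beam; the contact faces are offset ``w``
        from the member axes.
    h : float
        ``w`` plus the maximum width of the vertex block; the vertex-tip
        contact line is offset ``h`` from the beam axis.
    """

    s: float = 15.0
    w: float = 2.5
    h: float = 3.5

    # smallest contact angle (radians) with a positive tangent offset;
    # solved once at construction from s·sinθ − h·cosθ − w = 0
    theta_min: float = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not (self.s > self.h > self.w > 0):
            raise ValueError(f"require s > h > w > 0, got s={self.s}, h={self.h}, w={self.w}")
        tmin = brentq(lambda t: self.s * math.sin(t) - self.h * math.cos(t) - self.w,
                      1e-9, math.pi / 2)
        object.__setattr__(self, "theta_min", float(tmin))


@dataclass(frozen=True)
class AngleCalibration:
    """ADC calibration constants of the two angle sensors (raw counts).

    ``U_n`` is the ADC reading of the sensors' current supply voltage,
    ``V_z1``/``V_z2`` the per-channel output readings at α = 0°, and ``V_r``
    the supply reading recorded at initialisation.  The ratio U_n/V_r
    rescales the zero offsets when the supply drifts.
    """

    U_n: float
    V_z1: float
    V_z2: float
    V_r: float

    def __post_init__(self) -> None:
        if self.U_n <= 0 or self.V_r <= 0:
            raise InvalidCalibrationError(
                f"reference counts must be positive (U_n={self.U_n}, V_r={self.V_r})")
        if self.V_z1 <= 0 or self.V_z2 <= 0:
            raise InvalidCalibrationError("zero-angle references must be positive")


@dataclass(frozen=True)
class AnglePair:
    """One DBH observation: the two arm-to-beam contact angles in degrees."""

    alpha1: float
    alpha2: float

    @property
    def theta1(self) -> float:
        return math.radians(self.alpha1)

    @property
    def theta2(self) -> float:
        return math.radians(self.alpha2)


@dataclass(frozen=True)
class DbhEstimate:
    """Per-arc tangent offsets and radii (cm); ``dbh`` is exactly r1 + r2."""

    s1: float
    s2: float
    r1: float
    r2: float

    @property
    def dbh(self) -> float:
        return self.r1 + self.r2

    @property
    def dbh_mm(self) -> float:
        return 10.0 * (self.r1 + self.r2)


def adc_to_angle(cal: AngleCalibration, U_c: float, channel: Literal[1, 2]) -> float:
    """Convert a raw angle-sensor ADC reading to degrees.

    α = (360 / U_n) · (U_c − V_z · U_n / V_r): linear in the output count,
    with the zero offset rescaled by the supply ratio so supply drift between
    initialisation and measurement cancels.
    """
    V_z = cal.V_z1 if channel == 1 else cal.V_z2
    return 360.0 / cal.U_n * (U_c - V_z * cal.U_n / cal.V_r)


def tangent_offset(geom: DeviceGeometry, theta: float, mode: Mode = "exact") -> float:
    """Distance s_i (cm) from the hinge to the arc's tangent point on the beam.

    s_i = s − (h·cosθ + w)/sinθ for θ ≠ π/2; exactly s − w at θ = π/2.
    Raises :class:`OutOfRangeStemError` when the offset is nonpositive: the
    stem is too small (or the angle too shallow) for the frame.
    """
    if not math.isfinite(theta) or not (0.0 < theta < math.pi):
        raise OutOfRangeStemError(f"contact angle {theta} rad outside (0, pi)")
    if math.isclose(theta, math.pi / 2, abs_tol=1e-12):
        s_i = geom.s - geom.w
    else:
        sin_t, cos_t = (
            (math.sin(theta), math.cos(theta)) if mode == "exact"
            else (_sin_series(theta), _cos_series(theta))
        )
        s_i = geom.s - (geom.h * cos_t + geom.w) / sin_t
    if s_i <= 0:
        raise OutOfRangeStemError(
            f"tangent offset {s_i:.3f} cm <= 0 at theta={math.degrees(theta):.2f} deg")
    return s_i


def arc_radius(geom: DeviceGeometry, theta: float, mode: Mode = "exact") -> float:
    """Radius r_i (cm) of the stem arc seen by one arm: r_i = s_i·tan(θ/2).

    In ``series`` mode tan(θ/2) is the ratio of 4-term half-angle series,
    mirroring the firmware.  At θ = π/2 the closed branch s − w applies.
    """
    if math.isclose(theta, math.pi / 2, abs_tol=1e-12):
        return geom.s - geom.w
    s_i = tangent_offset(geom, theta, mode)
    half = theta / 2.0
    if mode == "exact":
        tan_half = math.tan(half)
    else:
        tan_half = _sin_series(half) / _cos_series(half)
    r_i = s_i * tan_half
    if r_i <= 0:
        raise OutOfRangeStemError(
            f"arc radius {r_i:.3f} cm <= 0 at theta={math.degrees(theta):.2f} deg")
    return r_i


def dbh_from_angles(geom: DeviceGeometry, angles: AnglePair, mode: Mode = "exact") -> DbhEstimate:
    """DBH estimate from one angle-pair observation: DBH = r₁ + r₂ (cm).

    The two radii come from different arcs, so an eccentric cross-section
    contributes its two half-widths independently.
    """
    t1, t2 = angles.theta1, angles.theta2
    s1 = geom.s - geom.w if math.isclose(t1, math.pi / 2, abs_tol=1e-12) else tangent_offset(geom, t1, mode)
    s2 = geom.s - geom.w if math.isclose(t2, math.pi / 2, abs_tol=1e-12) else tangent_offset(geom, t2, mode)
    return DbhEstimate(s1=s1, s2=s2, r1=arc_radius(geom, t1, mode), r2=arc_radius(geom, t2, mode))


def average_dbh(m1: DbhEstimate, m2: DbhEstimate) -> float:
    """Mean DBH (cm) of the two field measurements (major/minor directions)."""
    return 0.5 * (m1.dbh + m2.dbh)
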