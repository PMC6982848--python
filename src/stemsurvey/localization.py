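"""Tree position estimation from four UWB anchor ranges plus altitudes.

The plot frame OXY is horizontal (perpendicular to gravity) with anchor A at
the origin and the x-axis along the horizontal projection of A→B.  All
measured distances are slope (3-D) distances; combining each with the
altitude difference of its endpoints projects it into the plane:

    dis = sqrt(Dis² − ΔH²).

Anchors B, C, D are then fixed by planar triangulation, a tag's four
projected ranges define four circles, and each anchor triple (ABC, ABD,
ACD, BCD) yields a trilateration point — the radical centre of its three
circles, which exists and is consistent even when ranges are inflated by
non-line-of-sight (NLOS) delay.  The four points are fused by an
RSSI-motivated inverse-total-range weighting: the triple whose ranges are
shortest (strongest signal, least NLOS inflation) gets the most weight.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateGeometryError, ImaginaryProjectionError

__all__ = [
    "AnchorSurvey",
    "AnchorFrame",
    "TagRanges",
    "PlanarRanges",
    "Position",
    "project_anchor_distances",
    "build_frame",
    "project_tag_ranges",
    "trilaterate",
    "fuse_quadrilateral",
    "locate",
    "average_positions",
]

#: anchor triples contributing the four trilateration points, in fusion order
TRIPLES = (("A", "B", "C"), ("A", "B", "D"), ("A", "C", "D"), ("B", "C", "D"))


def _project(slope_dist: float, dh: float, label: str) -> float:
    rad = slope_dist * slope_dist - dh * dh
    if rad < 0:
        raise ImaginaryProjectionError(
            f"{label}: slope distance {slope_dist:.2f} cm shorter than "
            f"altitude difference {abs(dh):.2f} cm")
    return math.sqrt(rad)


@dataclass(frozen=True)
class AnchorSurvey:
    """Corner-anchor survey: four altitudes and six slope distances (cm)."""

    H_A: float
    H_B: float
    H_C: float
    H_D: float
    Dis_AB: float
    Dis_AC: float
    Dis_AD: float
    Dis_BC: float
    Dis_BD: float
    Dis_CD: float


@dataclass(frozen=True)
class AnchorFrame:
    """Planar anchor coordinates (cm) in the OXY frame, A at the origin."""

    A: tuple[float, float]
    B: tuple[float, float]
    C: tuple[float, float]
    D: tuple[float, float]
    dis_AB: float
    dis_AC: float
    dis_AD: float
    dis_BC: float
    dis_BD: float

    def coords(self, label: str) -> tuple[float, float]:
        return getattr(self, label)


@dataclass(frozen=True)
class TagRanges:
    """One position observation: four slope ranges and the device altitude (cm)."""

    A_n: float
    B_n: float
    C_n: float
    D_n: float
    H_n: float


@dataclass(frozen=True)
class PlanarRanges:
    """Horizontal projections of a tag's four anchor ranges (cm)."""

    a_n: float
    b_n: float
    c_n: float
    d_n: float

    def of(self, label: str) -> float:
        return getattr(self, label.lower() + "_n")


@dataclass(frozen=True)
class Position:
    """Fused tag position (cm) plus the four contributing trilateration points."""

    X_n: float
    Y_n: float
    Q: tuple[tuple[float, float], ...]
    triples: tuple[tuple[str, str, str], ...] = TRIPLES

    @property
    def xy(self) -> tuple[float, float]:
        return (self.X_n, self.Y_n)


def project_anchor_distances(survey: AnchorSurvey) -> dict[str, float]:
    """Project the five frame-defining inter-anchor slope distances to OXY.

    Returns the planar distances for AB, AC, AD, BC, BD; CD is projected too
    but only used as a consistency check in :func:`build_frame`.
    """
    H = {"A": survey.H_A, "B": survey.H_B, "C": survey.H_C, "D": survey.H_D}
    out = {}
    for pair in ("AB", "AC", "AD", "BC", "BD", "CD"):
        slope = getattr(survey, f"Dis_{pair}")
        out[pair] = _project(slope, H[pair[0]] - H[pair[1]], f"Dis_{pair}")
    return out


def build_frame(survey: AnchorSurvey, cd_tolerance_cm: float = 5.0) -> AnchorFrame:
    """Fix planar anchor coordinates from the surveyed distances and altitudes.

    A = (0,0), B = (dis_AB, 0); C and D are placed by the two-circle
    intersection X = (dis_AB² + dis_A·² − dis_B·²)/(2·dis_AB),
    Y = +sqrt(dis_A·² − X²), taking the positive root (plot interior on the
    +y side, anchors labelled counterclockwise).  The surveyed C–D distance,
    unused by the construction, is checked against the frame and a warning
    is emitted beyond ``cd_tolerance_cm``.
    """
    d = project_anchor_distances(survey)
    ab = d["AB"]
    if ab <= 0:
        raise DegenerateGeometryError("anchors A and B coincide in the plane")

    def place(ax_dist: float, bx_dist: float, label: str) -> tuple[float, float]:
        x = (ab * ab + ax_dist * ax_dist - bx_dist * bx_dist) / (2.0 * ab)
        rad = ax_dist * ax_dist - x * x
        if rad < -1e-9 * max(1.0, ax_dist * ax_dist):
            raise DegenerateGeometryError(
                f"anchor {label}: triangle inequality violated "
                f"(dis_A{label}={ax_dist:.2f}, dis_B{label}={bx_dist:.2f}, dis_AB={ab:.2f})")
        y = math.sqrt(max(rad, 0.0))
        if y <= 1e-9 * max(1.0, ab):
            raise DegenerateGeometryError(f"anchor {label} collinear with A and B")
        return (x, y)

    C = place(d["AC"], d["BC"], "C")
    D = place(d["AD"], d["BD"], "D")
    cd_planar = math.hypot(C[0] - D[0], C[1] - D[1])
    if abs(cd_planar - d["CD"]) > cd_tolerance_cm:
        warnings.warn(
            f"surveyed C-D projection {d['CD']:.1f} cm disagrees with frame "
            f"C-D distance {cd_planar:.1f} cm; check anchor labelling/side convention",
            stacklevel=2)
    return AnchorFrame(A=(0.0, 0.0), B=(ab, 0.0), C=C, D=D,
                       dis_AB=ab, dis_AC=d["AC"], dis_AD=d["AD"],
                       dis_BC=d["BC"], dis_BD=d["BD"])


def project_tag_ranges(frame: AnchorFrame, survey: AnchorSurvey, tag: TagRanges) -> PlanarRanges:
    """Project the tag's four slope ranges into the OXY plane.

    a_n = sqrt(A_n² − (H_A − H_n)²) and likewise for b, c, d.  Observations
    whose range is shorter than the altitude difference (possible under
    noise) are rejected with :class:`ImaginaryProjectionError`.
    """
    return PlanarRanges(
        a_n=_project(tag.A_n, survey.H_A - tag.H_n, "A_n"),
        b_n=_project(tag.B_n, survey.H_B - tag.H_n, "B_n"),
        c_n=_project(tag.C_n, survey.H_C - tag.H_n, "C_n"),
        d_n=_project(tag.D_n, survey.H_D - tag.H_n, "D_n"),
    )


def trilaterate(frame: AnchorFrame, triple: Sequence[str], ranges: PlanarRanges) -> tuple[float, float]:
    """Radical centre of the three circles of one anchor triple.

    Subtracting the circle equations pairwise yields three linear equations
    (the radical axes) in the tag coordinates.  The three axes are
    concurrent, so the 3x2 system is rank-2 consistent — its least-squares
    solution has ~zero residual even when all ranges are inflated by NLOS
    delay — which is why the radical centre remains well defined for
    non-intersecting circles.
    """
    pts = [np.asarray(frame.coords(lbl), dtype=float) for lbl in triple]
    rng = [ranges.of(lbl) for lbl in triple]
    rows, rhs = [], []
    for (i, j) in ((0, 1), (1, 2), (0, 2)):
        Pi, Pj = pts[i], pts[j]
        rows.append(2.0 * (Pi - Pj))
        rhs.append(rng[j] ** 2 - rng[i] ** 2 + Pi @ Pi - Pj @ Pj)
    A = np.vstack(rows)
    if np.linalg.matrix_rank(A, tol=1e-9 * max(1.0, np.abs(A).max())) < 2:
        raise DegenerateGeometryError(f"anchors {tuple(triple)} are collinear")
    sol, *_ = np.linalg.lstsq(A, np.asarray(rhs), rcond=None)
    return (float(sol[0]), float(sol[1]))


def fuse_quadrilateral(Q: Sequence[tuple[float, float]], ranges: PlanarRanges) -> Position:
    """Fuse the four trilateration points by inverse-total-range weighting.

    Weights are 1/(a+b+c), 1/(a+b+d), 1/(a+c+d), 1/(b+c+d) for the ABC,
    ABD, ACD, BCD points respectively: a triple with a shorter total range
    (stronger received signal) contributes more.  The fused point is a convex
    combination, so it lies inside the hull of the four points.
    """
    if len(Q) != 4:
        raise ValueError("exactly four trilateration points required")
    a, b, c, d = ranges.a_n, ranges.b_n, ranges.c_n, ranges.d_n
    denoms = (a + b + c, a + b + d, a + c + d, b + c + d)
    if any(s <= 0 for s in denoms):
        raise DegenerateGeometryError("zero total range in fusion weight")
    w = np.array([1.0 / s for s in denoms])
    pts = np.asarray(Q, dtype=float)
    fused = (w[:, None] * pts).sum(axis=0) / w.sum()
    return Position(X_n=float(fused[0]), Y_n=float(fused[1]),
                    Q=tuple((float(p[0]), float(p[1])) for p in pts))


def locate(frame: AnchorFrame, survey: AnchorSurvey, tag: TagRanges) -> Position:
    """Full single-observation pipeline: project, trilaterate four triples, fuse."""
    planar = project_tag_ranges(frame, survey, tag)
    Q = [trilaterate(frame, triple, planar) for triple in TRIPLES]
    return fuse_quadrilateral(Q, planar)


def average_positions(p1: Position, p2: Position) -> tuple[float, float]:
    """Component-wise mean of two repeated position observations of one tree."""
    return (0.5 * (p1.X_n + p2.X_n), 0.5 * (p1.Y_n + p2.Y_n))
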