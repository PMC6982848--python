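"""Shared fixtures and independent oracles.

The tangent-circle oracle reconstructs the arc radius by brute-force
numerical geometry — root-finding on the raw tangency conditions, with the
point-to-line distance itself obtained by numerical minimisation — so it
shares no algebra with the closed-form implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy.optimize import brentq, minimize_scalar

from stemsurvey import AnchorSurvey, DeviceGeometry, SyntheticPlot


@pytest.fixture(scope="session")
def geom() -> DeviceGeometry:
    return DeviceGeometry()  # s=15, w=2.5, h=3.5 cm


def dist_point_to_arm_face(px: float, py: float, theta: float, w: float) -> float:
    """Distance from (px, py) to the arm's inner face, found numerically.

    The face is the line traced by t*(cos t., sin t.) + w*(sin t., -cos t.):
    the arm axis through the hinge, shifted by w along its inward normal.
    """
    def sq(t: float) -> float:
        qx = t * math.cos(theta) + w * math.sin(theta)
        qy = t * math.sin(theta) - w * math.cos(theta)
        return (qx - px) ** 2 + (qy - py) ** 2

    res = minimize_scalar(sq, bounds=(-100.0, 100.0), method="bounded",
                          options={"xatol": 1e-13})
    return math.sqrt(res.fun)


def oracle_arc_radius(g: DeviceGeometry, theta: float) -> float:
    """Brute-force tangent-circle construction of the arc radius.

    The stem arc touches the vertex tip at the beam middle, so its centre is
    at (s, h + r); r is found as the root of ``distance(centre, arm face)
    − r`` by bisection.  Independent of the closed-form implementation.
    """
    def f(r: float) -> float:
        return dist_point_to_arm_face(g.s, g.h + r, theta, g.w) - r

    return brentq(f, 1e-9, 200.0, xtol=1e-12)


@pytest.fixture(scope="session")
def flat_square_survey() -> AnchorSurvey:
    """Flat 10 x 10 m plot: projections equal slope distances."""
    s = 1000.0
    return AnchorSurvey(H_A=0, H_B=0, H_C=0, H_D=0,
                        Dis_AB=s, Dis_AC=s * math.sqrt(2), Dis_AD=s,
                        Dis_BC=s, Dis_BD=s * math.sqrt(2), Dis_CD=s)


@pytest.fixture(scope="session")
def sloped_plot() -> SyntheticPlot:
    """Empty 20-degree sloped plot for placing arbitrary test tags."""
    return SyntheticPlot(side=1000.0, slope_deg=20.0, aspect_deg=30.0)


def true_tag_ranges(plot: SyntheticPlot, x: float, y: float):
    """Exact slope ranges and altitude for a tag at (x, y) on the terrain."""
    from stemsurvey import TagRanges

    z = plot.altitude(x, y)
    d = {}
    for label, (ax, ay) in plot.anchors.items():
        az = plot.altitude(ax, ay)
        d[label] = math.dist((x, y, z), (ax, ay, az))
    return TagRanges(A_n=d["A"], B_n=d["B"], C_n=d["C"], D_n=d["D"], H_n=z)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260919)
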