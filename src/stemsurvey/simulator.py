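"""Synthetic sample plots and noisy sensor observations for recovery testing.

No field dataset accompanies the method, so this module stands in for it:
it generates 10 x 10 m square plots on a planar slope, populates them with
stems (circular, eccentric two-arc, or elliptical cross-sections), and
simulates what the instrument would record — contact-angle pairs for the
caliper frame and slope ranges plus altitudes for the UWB/altimeter unit —
under an explicit noise model.  Because the ground truth is known, every
estimator in the package can be checked for exact recovery at zero noise
and for bias/RMSE behaviour under realistic noise.

The noise model mirrors what the hardware is known to do: Gaussian ranging
jitter, a nonnegative additive non-line-of-sight (NLOS) delay (exponential,
so observed ranges are biased high, as obstructed UWB paths are), Gaussian
altimeter noise, and Gaussian angle-sensor noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import ImaginaryProjectionError, OutOfRangeStemError
from .geometry import AnglePair, DeviceGeometry, arc_radius, average_dbh, dbh_from_angles
from .localization import AnchorSurvey, TagRanges, average_positions, build_frame, locate
from .metrics import per_plot_position_summary, per_plot_summary, position_errors
from .ranging import SPEED_OF_LIGHT_AIR_CM_S, TwrExchange

ShapeKind = Literal["circular", "two_arc", "elliptical"]

__all__ = [
    "StemShape", "SyntheticPlot", "NoiseModel",
    "generate_plot", "contact_angle", "simulate_dbh_observation",
    "simulate_tag_observation", "simulate_twr_exchange", "run_recovery_experiment",
]


@dataclass(frozen=True)
class StemShape:
    """One stem cross-section at breast height, in the plot frame (cm).

    ``two_arc`` is the instrument's own eccentricity model: two circular
    arcs of radii r1 >= r2 meeting at the contact meridian.  ``elliptical``
    lies outside that model class and exists to stress-test it.  The true
    DBH follows the caliper convention — the mean of the major and minor
    widths — which for a circle is 2r, for two arcs r1 + r2, and for an
    ellipse a + b.
    """

    center: tuple[float, float]
    kind: ShapeKind = "circular"
    r: float = 10.0
    r1: float = 10.0
    r2: float = 10.0
    a: float = 10.0
    b: float = 10.0

    def __post_init__(self) -> None:
        if self.kind == "two_arc" and self.r1 < self.r2:
            raise ValueError("two_arc requires r1 >= r2")
        for v in (self.r, self.r1, self.r2, self.a, self.b):
            if v <= 0:
                raise ValueError("all radii/semi-axes must be positive")

    @property
    def true_dbh_cm(self) -> float:
        if self.kind == "circular":
            return 2.0 * self.r
        if self.kind == "two_arc":
            return self.r1 + self.r2
        return self.a + self.b

    @property
    def footprint_radius(self) -> float:
        """Radius of the disc bounding the cross-section (for packing)."""
        if self.kind == "circular":
            return self.r
        if self.kind == "two_arc":
            return self.r1
        return max(self.a, self.b)


@dataclass(frozen=True)
class SyntheticPlot:
    """Ground truth for one square plot: terrain, anchors, and stems.

    The plot frame OXY is horizontal; the terrain is a planar ramp of the
    given slope, rising in the ``aspect`` direction, sampled by the altitude
    field ``altitude(x, y)``.  Anchors A..D sit at the corners, labelled
    counterclockwise from the origin.
    """

    side: float = 1000.0
    slope_deg: float = 10.0
    aspect_deg: float = 0.0
    trees: tuple[StemShape, ...] = ()
    tree_codes: tuple[str, ...] = ()
    plot_id: str = "YN0001"

    @property
    def anchors(self) -> dict[str, tuple[float, float]]:
        s = self.side
        return {"A": (0.0, 0.0), "B": (s, 0.0), "C": (s, s), "D": (0.0, s)}

    def altitude(self, x: float, y: float) -> float:
        g = math.tan(math.radians(self.slope_deg))
        ux, uy = math.cos(math.radians(self.aspect_deg)), math.sin(math.radians(self.aspect_deg))
        return g * (ux * x + uy * y)

    def anchor_survey(self) -> AnchorSurvey:
        """Exact (noise-free) corner survey: altitudes and 3-D slope distances."""
        P = {k: (x, y, self.altitude(x, y)) for k, (x, y) in self.anchors.items()}

        def dist(i, j):
            return math.dist(P[i], P[j])

        return AnchorSurvey(
            H_A=P["A"][2], H_B=P["B"][2], H_C=P["C"][2], H_D=P["D"][2],
            Dis_AB=dist("A", "B"), Dis_AC=dist("A", "C"), Dis_AD=dist("A", "D"),
            Dis_BC=dist("B", "C"), Dis_BD=dist("B", "D"), Dis_CD=dist("C", "D"),
        )

    def summary(self) -> dict[str, float]:
        """Plot descriptives: tree count and DBH mean/max/min/std in mm."""
        dbh = np.array([10.0 * t.true_dbh_cm for t in self.trees])
        return {
            "n_trees": len(self.trees),
            "slope_deg": self.slope_deg,
            "dbh_mean_mm": float(dbh.mean()) if dbh.size else float("nan"),
            "dbh_max_mm": float(dbh.max()) if dbh.size else float("nan"),
            "dbh_min_mm": float(dbh.min()) if dbh.size else float("nan"),
            "dbh_std_mm": float(dbh.std(ddof=1)) if dbh.size > 1 else float("nan"),
        }


@dataclass(frozen=True)
class NoiseModel:
    """Sensor noise scales; all zero gives exact observations.

    range_gauss_sd : Gaussian jitter on each UWB slope range, cm.
    nlos_delay_mean : mean of the exponential nonnegative NLOS delay added
        to each range, cm (obstructions only lengthen the path).
    altitude_sd : Gaussian altimeter noise, cm.
    angle_sd : Gaussian angle-sensor noise, degrees.
    """

    range_gauss_sd: float = 10.0
    nlos_delay_mean: float = 10.0
    altitude_sd: float = 2.0
    angle_sd: float = 0.1

    def __post_init__(self) -> None:
        if min(self.range_gauss_sd, self.nlos_delay_mean,
               self.altitude_sd, self.angle_sd) < 0:
            raise ValueError("noise scales must be nonnegative")

    def scaled(self, k: float) -> "NoiseModel":
        """Multiply the ranging noise scales by k (altitude/angle unchanged)."""
        return replace(self, range_gauss_sd=k * self.range_gauss_sd,
                       nlos_delay_mean=k * self.nlos_delay_mean)


ZERO_NOISE = NoiseModel(0.0, 0.0, 0.0, 0.0)


def generate_plot(n_trees: int = 20,
                  dbh_mean_mm: float = 130.0,
                  dbh_std_mm: float = 50.0,
                  dbh_range_mm: tuple[float, float] = (51.0, 341.0),
                  slope_deg: float = 10.0,
                  aspect_deg: float = 0.0,
                  shape_mix: dict[str, float] | None = None,
                  side: float = 1000.0,
                  plot_id: str = "YN0001",
                  seed: int | np.random.Generator = 0,
                  max_tries: int = 10_000) -> SyntheticPlot:
    """Draw a reproducible synthetic plot.

    DBH is truncated-normal within ``dbh_range_mm``; positions are uniform
    in the plot interior with non-overlapping stems (bounded rejection
    sampling).  ``shape_mix`` gives the probability of each cross-section
    kind; the default mixes circular, two-arc and elliptical stems.  Two-arc
    eccentricity and ellipse aspect are drawn so the minor width is 70-100%
    of the major, a realistic departure from circularity.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mix = shape_mix or {"circular": 0.5, "two_arc": 0.3, "elliptical": 0.2}
    kinds = list(mix)
    probs = np.array([mix[k] for k in kinds], dtype=float)
    probs /= probs.sum()

    trees: list[StemShape] = []
    tries = 0
    while len(trees) < n_trees:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(f"could not pack {n_trees} stems in {max_tries} tries")
        dbh = rng.normal(dbh_mean_mm, dbh_std_mm)
        if not (dbh_range_mm[0] <= dbh <= dbh_range_mm[1]):
            continue
        half = dbh / 20.0  # mean radius, cm
        margin = half + 20.0
        x = rng.uniform(margin, side - margin)
        y = rng.uniform(margin, side - margin)
        kind = kinds[rng.choice(len(kinds), p=probs)]
        ecc = rng.uniform(0.7, 1.0)  # minor/major width ratio
        if kind == "circular":
            shape = StemShape(center=(x, y), kind="circular", r=half)
        elif kind == "two_arc":
            # r1 + r2 = dbh/10 (cm), r2/r1 = ecc
            r1 = (dbh / 10.0) / (1.0 + ecc)
            shape = StemShape(center=(x, y), kind="two_arc", r1=r1, r2=ecc * r1)
        else:
            a = (dbh / 10.0) / (1.0 + ecc)
            shape = StemShape(center=(x, y), kind="elliptical", a=a, b=ecc * a)
        if any(math.dist(shape.center, t.center) < shape.footprint_radius + t.footprint_radius + 30.0
               for t in trees):
            continue
        trees.append(shape)

    codes = tuple(f"TN{i + 1:04d}|{plot_id}" for i in range(n_trees))
    return SyntheticPlot(side=side, slope_deg=slope_deg, aspect_deg=aspect_deg,
                         trees=tuple(trees), tree_codes=codes, plot_id=plot_id)


def contact_angle(geom: DeviceGeometry, r: float, tol: float = 1e-12) -> float:
    """Contact angle α (degrees) at which one arm sees an arc of radius r.

    Inverts the arc-radius relation by bisection; the radius is strictly
    increasing in the angle over the frame's valid domain, so the root is
    unique.  Raises :class:`OutOfRangeStemError` for radii the frame cannot
    represent.
    """
    if r <= 0:
        raise OutOfRangeStemError(f"radius {r} cm must be positive")
    # arms cannot open much past flat against the beam; 170 degrees is a
    # generous mechanical limit (radii to ~2.3 m with the default frame)
    lo, hi = geom.theta_min + 1e-9, math.radians(170.0)
    f = lambda t: arc_radius(geom, t) - r
    if f(hi) < 0:
        raise OutOfRangeStemError(f"radius {r} cm exceeds the frame's range")
    theta = brentq(f, lo, hi, xtol=tol)
    return math.degrees(theta)


def _ellipse_contact_angle(geom: DeviceGeometry, a: float, b: float) -> float:
    """Contact angle (degrees) of one arm against an axis-aligned ellipse.

    The ellipse (horizontal semi-axis a, vertical b) rests on the vertex-tip
    line with its lowest point at the beam middle, so its centre is at
    (s, h + b).  The arm face (offset w from the arm axis) is tangent when
    the centre's distance to the face equals the ellipse support function in
    the face normal:  s·sinθ − (h+b)·cosθ − w = sqrt((a·sinθ)² + (b·cosθ)²).
    """
    cx, cy = geom.s, geom.h + b

    def g(theta: float) -> float:
        return (math.sin(theta) * cx - math.cos(theta) * cy - geom.w
                - math.hypot(a * math.sin(theta), b * math.cos(theta)))

    lo, hi = geom.theta_min + 1e-9, math.pi - 1e-6
    if g(lo) > 0 or g(hi) < 0:
        raise OutOfRangeStemError(f"ellipse ({a}, {b}) cm outside the frame's range")
    return math.degrees(brentq(g, lo, hi, xtol=1e-12))


def simulate_dbh_observation(geom: DeviceGeometry, stem: StemShape,
                             noise: NoiseModel = ZERO_NOISE,
                             direction: Literal[1, 2] = 1,
                             rng: np.random.Generator | int | None = None) -> AnglePair:
    """One caliper observation: the angle pair the two sensors would report.

    Direction 2 rotates the instrument 90 degrees around the stem (the
    field protocol's minor-axis measurement): for a two-arc stem this swaps
    which arm sees which arc; for an ellipse it swaps the axes.  Gaussian
    angle noise is added per sensor.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if stem.kind == "circular":
        a1 = a2 = contact_angle(geom, stem.r)
    elif stem.kind == "two_arc":
        ra, rb = (stem.r1, stem.r2) if direction == 1 else (stem.r2, stem.r1)
        a1, a2 = contact_angle(geom, ra), contact_angle(geom, rb)
    else:
        ax, bx = (stem.a, stem.b) if direction == 1 else (stem.b, stem.a)
        a1 = a2 = _ellipse_contact_angle(geom, ax, bx)
    if noise.angle_sd > 0:
        a1 += rng.normal(0.0, noise.angle_sd)
        a2 += rng.normal(0.0, noise.angle_sd)
    return AnglePair(alpha1=a1, alpha2=a2)


def simulate_tag_observation(plot: SyntheticPlot, tree_index: int,
                             noise: NoiseModel = ZERO_NOISE,
                             rng: np.random.Generator | int | None = None) -> TagRanges:
    """One UWB/altimeter observation at a tree's base.

    True 3-D distances from the stem centre (on the terrain ramp) to each
    corner anchor get Gaussian jitter plus an exponential NLOS delay, so
    observed ranges are biased high; the altimeter reading gets Gaussian
    noise.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    x, y = plot.trees[tree_index].center
    z = plot.altitude(x, y)
    obs = {}
    for label, (ax, ay) in plot.anchors.items():
        az = plot.altitude(ax, ay)
        true = math.dist((x, y, z), (ax, ay, az))
        d = true
        if noise.range_gauss_sd > 0:
            d += rng.normal(0.0, noise.range_gauss_sd)
        if noise.nlos_delay_mean > 0:
            d += rng.exponential(noise.nlos_delay_mean)
        obs[label] = max(d, 0.0)
    h = z + (rng.normal(0.0, noise.altitude_sd) if noise.altitude_sd > 0 else 0.0)
    return TagRanges(A_n=obs["A"], B_n=obs["B"], C_n=obs["C"], D_n=obs["D"], H_n=h)


def simulate_twr_exchange(true_distance_cm: float,
                          reply1_s: float = 1e-3, reply2_s: float = 1e-3,
                          drift_ppm_A: float = 0.0, drift_ppm_B: float = 0.0,
                          c: float = SPEED_OF_LIGHT_AIR_CM_S) -> TwrExchange:
    """Timestamps of one DS-TWR exchange between nodes with drifting clocks.

    Events are laid out on the true timeline (flight time tp = d/c, the
    stated reply delays), then each node's timestamps are read on its local
    clock running at rate (1 + drift·1e-6).
    """
    if true_distance_cm < 0 or reply1_s < 0 or reply2_s < 0:
        raise ValueError("distance and reply times must be nonnegative")
    tp = true_distance_cm / c
    t1, t2 = 0.0, tp
    t3 = tp + reply1_s
    t4 = 2.0 * tp + reply1_s
    t5 = 2.0 * tp + reply1_s + reply2_s
    t6 = 3.0 * tp + reply1_s + reply2_s
    ka, kb = 1.0 + drift_ppm_A * 1e-6, 1.0 + drift_ppm_B * 1e-6
    return TwrExchange(T1=ka * t1, T2=kb * t2, T3=kb * t3,
                       T4=ka * t4, T5=ka * t5, T6=kb * t6)


@dataclass
class RecoveryResult:
    """Outcome of one simulated plot survey against its ground truth."""

    records: pd.DataFrame
    dbh_summary: pd.DataFrame
    position_summary: pd.DataFrame
    position_stats: dict


def run_recovery_experiment(plot: SyntheticPlot,
                            noise: NoiseModel = ZERO_NOISE,
                            geom: DeviceGeometry | None = None,
                            seed: int | np.random.Generator = 0,
                            max_retries: int = 50) -> RecoveryResult:
    """Simulate the full field protocol on a plot and score the recovery.

    Per tree: two caliper observations (major/minor directions) averaged to
    one DBH, and two UWB observations located and averaged component-wise to
    one position — then DBH and position accuracy statistics against the
    known truth.  Observations whose noisy range falls below the altitude
    difference (unprojectable) are redrawn, up to ``max_retries``.
    """
    geom = geom or DeviceGeometry()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    survey = plot.anchor_survey()
    frame = build_frame(survey)

    rows = []
    for i, stem in enumerate(plot.trees):
        m1 = dbh_from_angles(geom, simulate_dbh_observation(geom, stem, noise, 1, rng))
        m2 = dbh_from_angles(geom, simulate_dbh_observation(geom, stem, noise, 2, rng))
        dbh_cm = average_dbh(m1, m2)

        positions = []
        for _ in range(2):
            for attempt in range(max_retries):
                tag = simulate_tag_observation(plot, i, noise, rng)
                try:
                    positions.append(locate(frame, survey, tag))
                    break
                except ImaginaryProjectionError:
                    if attempt == max_retries - 1:
                        raise
        x_est, y_est = average_positions(positions[0], positions[1])

        rows.append({
            "tree_code": plot.tree_codes[i] if plot.tree_codes else f"TN{i + 1:04d}",
            "plot_id": plot.plot_id,
            "dbh_mm": 10.0 * dbh_cm,
            "dbh_ref_mm": 10.0 * stem.true_dbh_cm,
            "x_cm": x_est, "y_cm": y_est,
            "x_ref_cm": stem.center[0], "y_ref_cm": stem.center[1],
        })

    records = pd.DataFrame(rows)
    pos_stats = position_errors(records["x_cm"], records["y_cm"],
                                records["x_ref_cm"], records["y_ref_cm"])
    return RecoveryResult(
        records=records,
        dbh_summary=per_plot_summary(records),
        position_summary=per_plot_position_summary(records),
        position_stats=pos_stats,
    )
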