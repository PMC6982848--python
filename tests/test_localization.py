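"""Anchor frame construction, projections, trilateration and fusion."""

import math

import numpy as np
import pytest

from stemsurvey import (AnchorSurvey, PlanarRanges, TagRanges, build_frame,
                        fuse_quadrilateral, locate, project_anchor_distances,
                        project_tag_ranges, trilaterate)
from stemsurvey.localization import TRIPLES
from stemsurvey.errors import DegenerateGeometryError, ImaginaryProjectionError

from conftest import true_tag_ranges


class TestProjections:
    def test_three_four_five_triangle(self):
        survey = AnchorSurvey(H_A=300, H_B=0, H_C=0, H_D=0,
                              Dis_AB=500, Dis_AC=1000, Dis_AD=1000,
                              Dis_BC=800, Dis_BD=800, Dis_CD=600)
        assert project_anchor_distances(survey)["AB"] == pytest.approx(400.0)

    def test_flat_plot_identity(self, flat_square_survey):
        d = project_anchor_distances(flat_square_survey)
        assert d["AB"] == pytest.approx(1000.0)
        assert d["AC"] == pytest.approx(1000.0 * math.sqrt(2))

    def test_range_shorter_than_altitude_difference_rejected(self):
        survey = AnchorSurvey(H_A=120, H_B=0, H_C=0, H_D=0,
                              Dis_AB=100, Dis_AC=1000, Dis_AD=1000,
                              Dis_BC=1000, Dis_BD=1000, Dis_CD=1000)
        with pytest.raises(ImaginaryProjectionError):
            project_anchor_distances(survey)

    def test_tag_projection_three_four_five(self, flat_square_survey):
        frame = build_frame(flat_square_survey)
        tag = TagRanges(A_n=500, B_n=900, C_n=1300, D_n=1100, H_n=-300)
        planar = project_tag_ranges(frame, flat_square_survey, tag)
        assert planar.a_n == pytest.approx(400.0)


class TestBuildFrame:
    def test_flat_square_plot_coordinates(self, flat_square_survey):
        frame = build_frame(flat_square_survey)
        assert frame.A == (0.0, 0.0)
        assert frame.B[0] == pytest.approx(1000.0)
        assert frame.B[1] == 0.0
        assert frame.C[0] == pytest.approx(1000.0, abs=1e-9)
        assert frame.C[1] == pytest.approx(1000.0, abs=1e-9)
        assert frame.D[0] == pytest.approx(0.0, abs=1e-9)
        assert frame.D[1] == pytest.approx(1000.0, abs=1e-9)

    def test_frame_reproduces_projected_distances(self, sloped_plot):
        survey = sloped_plot.anchor_survey()
        d = project_anchor_distances(survey)
        frame = build_frame(survey)
        pts = {"A": frame.A, "B": frame.B, "C": frame.C, "D": frame.D}
        for pair, expected in d.items():
            if pair == "CD":
                continue
            got = math.dist(pts[pair[0]], pts[pair[1]])
            assert got == pytest.approx(expected, abs=1e-9), pair

    def test_collinear_anchor_degenerate(self):
        survey = AnchorSurvey(H_A=0, H_B=0, H_C=0, H_D=0,
                              Dis_AB=1000, Dis_AC=1500, Dis_AD=1000,
                              Dis_BC=500, Dis_BD=1414.2135623730951, Dis_CD=1000)
        with pytest.raises(DegenerateGeometryError):
            build_frame(survey)  # C on the A-B line

    def test_mislabelled_survey_triggers_cd_warning(self, flat_square_survey):
        from dataclasses import replace
        bad = replace(flat_square_survey, Dis_CD=1500.0)
        with pytest.warns(UserWarning, match="C-D"):
            build_frame(bad)


class TestTrilateration:
    def test_exact_ranges_recover_the_point(self, flat_square_survey):
        frame = build_frame(flat_square_survey)
        p = (320.0, 740.0)
        pts = {"A": frame.A, "B": frame.B, "C": frame.C, "D": frame.D}
        rng = PlanarRanges(*(math.dist(p, pts[k]) for k in "ABCD"))
        for triple in TRIPLES:
            q = trilaterate(frame, triple, rng)
            assert q[0] == pytest.approx(p[0], abs=1e-9)
            assert q[1] == pytest.approx(p[1], abs=1e-9)

    def test_radical_center_residual_for_inflated_ranges(self, flat_square_survey):
        # the three radical axes stay concurrent even for non-intersecting
        # circles: the 3x2 system is rank-2 consistent
        frame = build_frame(flat_square_survey)
        pts = {"A": frame.A, "B": frame.B, "C": frame.C, "D": frame.D}
        p = (250.0, 600.0)
        delta = 37.5
        rng = PlanarRanges(*(math.dist(p, pts[k]) + delta for k in "ABCD"))
        for triple in TRIPLES:
            q = np.asarray(trilaterate(frame, triple, rng))
            rows, rhs = [], []
            P = [np.asarray(pts[k], dtype=float) for k in triple]
            r = [rng.of(k) for k in triple]
            for (i, j) in ((0, 1), (1, 2), (0, 2)):
                rows.append(2.0 * (P[i] - P[j]))
                rhs.append(r[j] ** 2 - r[i] ** 2 + P[i] @ P[i] - P[j] @ P[j])
            resid = np.asarray(rows) @ q - np.asarray(rhs)
            assert np.abs(resid).max() < 1e-9 * max(1.0, abs(max(rhs)))

    def test_equation_system_third_row_is_sum_of_first_two(self, flat_square_survey):
        # algebraic identity behind the consistency: (A,B) + (B,C) = (A,C)
        frame = build_frame(flat_square_survey)
        pts = [np.asarray(frame.coords(k), dtype=float) for k in ("A", "B", "C")]
        r = [400.0, 700.0, 1000.0]
        rows, rhs = [], []
        for (i, j) in ((0, 1), (1, 2), (0, 2)):
            rows.append(2.0 * (pts[i] - pts[j]))
            rhs.append(r[j] ** 2 - r[i] ** 2 + pts[i] @ pts[i] - pts[j] @ pts[j])
        assert np.allclose(rows[0] + rows[1], rows[2])
        assert rhs[0] + rhs[1] == pytest.approx(rhs[2])

    def test_tag_at_anchor_a(self, flat_square_survey):
        frame = build_frame(flat_square_survey)
        rng = PlanarRanges(0.0, 1000.0, 1000.0 * math.sqrt(2), 1000.0)
        q = trilaterate(frame, ("A", "B", "C"), rng)
        assert q == pytest.approx((0.0, 0.0), abs=1e-9)


class TestFusion:
    def test_identical_points_fuse_to_themselves(self):
        rng = PlanarRanges(100.0, 200.0, 300.0, 400.0)
        p = (123.0, 456.0)
        pos = fuse_quadrilateral([p] * 4, rng)
        assert pos.xy == pytest.approx(p)

    def test_equal_range_sums_give_centroid(self):
        rng = PlanarRanges(100.0, 100.0, 100.0, 100.0)
        Q = [(0.0, 0.0), (4.0, 0.0), (4.0, 4.0), (0.0, 4.0)]
        pos = fuse_quadrilateral(Q, rng)
        assert pos.xy == pytest.approx((2.0, 2.0))

    def test_fused_point_inside_hull_of_contributors(self):
        rng = PlanarRanges(120.0, 80.0, 150.0, 90.0)
        Q = [(0.0, 0.0), (10.0, 0.0), (10.0, 10.0), (0.0, 10.0)]
        pos = fuse_quadrilateral(Q, rng)
        assert 0.0 <= pos.X_n <= 10.0 and 0.0 <= pos.Y_n <= 10.0

    def test_shorter_ranges_weight_more(self):
        # Q1's triple (a+b+c) is much shorter, so the fused point leans to Q1
        rng = PlanarRanges(10.0, 10.0, 10.0, 1000.0)
        Q = [(0.0, 0.0), (9.0, 0.0), (9.0, 9.0), (0.0, 9.0)]
        pos = fuse_quadrilateral(Q, rng)
        assert math.dist(pos.xy, Q[0]) < math.dist(pos.xy, Q[2])


class TestLocatePipeline:
    def test_zero_noise_exact_recovery_on_slope(self, sloped_plot, rng):
        survey = sloped_plot.anchor_survey()
        frame = build_frame(survey)
        for _ in range(100):
            x, y = rng.uniform(50, 950, size=2)
            tag = true_tag_ranges(sloped_plot, x, y)
            pos = locate(frame, survey, tag)
            assert math.dist(pos.xy, (x, y)) < 1e-6

    def test_inflating_one_range_moves_estimate_monotonically(self, flat_square_survey):
        frame = build_frame(flat_square_survey)
        p = (400.0, 400.0)
        errs = []
        for delta in (0.0, 5.0, 10.0, 20.0, 40.0):
            tag = TagRanges(A_n=math.dist(p, frame.A) + delta,
                            B_n=math.dist(p, frame.B),
                            C_n=math.dist(p, frame.C),
                            D_n=math.dist(p, frame.D), H_n=0.0)
            pos = locate(frame, flat_square_survey, tag)
            errs.append(math.dist(pos.xy, p))
        assert all(b > a for a, b in zip(errs, errs[1:]))
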