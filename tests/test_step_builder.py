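import math

import pytest

import kmrecover as kr
from kmrecover.errors import StepFunctionError
from kmrecover.ps_extract import PathSegment, StrokeAttrs
from kmrecover.step_builder import (
    CurveGroup,
    StepCurve,
    Tolerances,
    build_step_curve,
    detect_censor_marks,
    group_curves,
    snap_monotone,
)
from kmrecover.synthetic import RenderSpec, marks_from_ipd, render_postscript


def seg(x0, y0, x1, y1, path_id=0, attrs=StrokeAttrs()):
    dot = math.hypot(x1 - x0, y1 - y0) <= 1e-6
    return PathSegment(x0, y0, x1, y1, path_id=path_id, is_dot=dot, stroke_attrs=attrs)


class TestBuildStepCurve:
    def test_worked_two_segment_example(self, paper_calib):
        """The horizontal run at S=(360-300)/108 over t in [2.5, 2.6] and the
        adjacent vertical of data magnitude 3/108 at t=2.6."""
        # drawn upward-consistently (device y falls as the incidence rises);
        # the jump magnitude 3 points / 108 points is the quantity of interest
        group = [
            seg(72, 360, 144, 360),  # origin run at S=0 so the curve has a start
            seg(144, 360, 144, 300),
            seg(144, 300, 146.88, 300),
            seg(146.88, 300, 146.88, 297),
        ]
        curve = build_step_curve(group, paper_calib, "cumulative_incidence")
        jumps = curve.jumps()
        t_last, j_last = jumps[-1]
        assert math.isclose(t_last, 2.6, abs_tol=1e-6)
        assert math.isclose(j_last, 3 / 108, abs_tol=1e-9)
        # the horizontal run before the final jump sits at (360-300)/108
        assert math.isclose(curve.heights[-2], 60 / 108, abs_tol=1e-9)

    def test_split_run_merges_to_same_curve(self, paper_calib):
        whole = [seg(72, 360, 144, 360), seg(144, 360, 144, 330)]
        split = [seg(72 + 1.8 * i, 360, 72 + 1.8 * (i + 1), 360) for i in range(40)]
        split.append(seg(144, 360, 144, 330))
        a = build_step_curve(whole, paper_calib, "cumulative_incidence")
        b = build_step_curve(split, paper_calib, "cumulative_incidence")
        assert a.times == pytest.approx(b.times)
        assert a.heights == pytest.approx(b.heights)

    def test_diagonal_segment_rejected(self, paper_calib):
        group = [seg(72, 360, 144, 360), seg(144, 360, 160, 330)]
        with pytest.raises(StepFunctionError, match="not a step function"):
            build_step_curve(group, paper_calib, "survival")

    def test_idempotent_on_own_output(self, aml_ipd, aml_curve, aml_truth):
        spec = RenderSpec(decimals=6)
        ps = kr.render_postscript(aml_curve, [], spec, risk_table=aml_truth)
        calib = spec.calibration(aml_curve)
        segs = [s for s in kr.extract_segments(ps) if s.stroke_attrs == StrokeAttrs()]
        once = build_step_curve(segs, calib, "survival",
                                Tolerances.from_geometry(calib, decimals=6))
        assert once.times == pytest.approx(aml_curve.times, abs=1e-5)
        assert once.heights == pytest.approx(aml_curve.heights, abs=1e-7)

    def test_jump_conservation(self, aml_curve):
        total = sum(j for _, j in aml_curve.jumps())
        assert math.isclose(total, aml_curve.heights[0] - aml_curve.heights[-1])


class TestSnapMonotone:
    def test_already_monotone_unchanged(self):
        c = StepCurve("survival", (0, 1, 2), (1.0, 0.8, 0.5))
        assert snap_monotone(c, 1e-3) is c

    def test_pool_adjacent_violators(self):
        c = StepCurve("survival", (0, 1, 2, 3), (1.0, 0.90001, 0.90002, 0.85))
        snapped = snap_monotone(c, 1e-3)
        assert snapped.heights == pytest.approx((1.0, 0.900015, 0.900015, 0.85))

    def test_violation_beyond_bound_raises(self):
        c = StepCurve("survival", (0, 1, 2), (1.0, 0.8, 0.85))
        with pytest.raises(StepFunctionError, match="monotonicity violation"):
            snap_monotone(c, 1e-3)

    def test_increasing_direction_for_hazard(self):
        c = StepCurve("cumulative_hazard", (0, 1, 2, 3), (0.0, 0.2, 0.1999, 0.4))
        snapped = snap_monotone(c, 1e-3)
        assert snapped.heights[1] == pytest.approx(snapped.heights[2])


class TestGroupCurves:
    def test_two_colors_two_groups(self):
        red = StrokeAttrs(1.0, (1, 0, 0))
        blue = StrokeAttrs(1.0, (0, 0, 1))
        segs = [seg(0, 0, 10, 0, 0, red), seg(10, 0, 10, 5, 0, red),
                seg(0, 1, 10, 1, 1, blue), seg(10, 1, 10, 6, 1, blue)]
        groups = group_curves(segs)
        assert len(groups) == 2

    def test_single_path_one_group(self):
        segs = [seg(0, 0, 10, 0), seg(10, 0, 10, 5)]
        assert len(group_curves(segs)) == 1

    def test_no_curve_like_path(self):
        with pytest.raises(StepFunctionError, match="no curve-like"):
            group_curves([seg(0, 0, 1, 0)])

    def test_overlapping_same_style_arms_flagged(self):
        a = [seg(0, 100, 10, 100), seg(10, 100, 10, 90), seg(10, 90, 20, 90),
             seg(20, 90, 20, 80), seg(20, 80, 30, 80)]
        b = [seg(0, 50, 12, 50), seg(12, 50, 12, 40), seg(12, 40, 22, 40),
             seg(22, 40, 22, 30), seg(22, 30, 32, 30)]
        groups = group_curves(a + b)
        assert len(groups) == 1 and groups[0].ambiguous


class TestCensorMarks:
    def test_aml_tick_rendering_has_three_marks(self, aml_ipd, aml_curve, aml_truth):
        marks = marks_from_ipd(aml_ipd, aml_curve, kind="tick")
        spec = RenderSpec()
        ps = render_postscript(aml_curve, marks, spec, risk_table=aml_truth)
        calib = spec.calibration(aml_curve)
        segs = [s for s in kr.extract_segments(ps) if s.stroke_attrs == StrokeAttrs()]
        curve = build_step_curve(segs, calib, "survival")
        found = detect_censor_marks(segs, curve, calib)
        assert len(found) == 3
        assert [round(m.t) for m in found] == [28, 45, 161]

    def test_per_observation_dots_match_censored_subjects(self, aml_ipd, aml_curve, aml_truth):
        spec = RenderSpec(dialect="per_observation_dots")
        marks = marks_from_ipd(aml_ipd, aml_curve, kind="dot")
        ps = render_postscript(aml_curve, marks, spec, risk_table=aml_truth)
        segs = [s for s in kr.extract_segments(ps) if s.stroke_attrs == StrokeAttrs()]
        # the file carries one zero-length element per censored subject
        assert sum(1 for s in segs if s.is_dot) == 4
        calib = spec.calibration(aml_curve)
        curve = build_step_curve(segs, calib, "survival")
        found = detect_censor_marks(segs, curve, calib)
        # the dot tied at the event time 13 sits on a corner: part of the curve
        assert len(found) == 3
        assert all(m.kind == "dot" for m in found)

    def test_no_censoring_no_marks(self):
        study = kr.simulate_study(kr.StudyParams(n0=20, censoring="none"), seed=3)
        curve, truth = kr.km_estimate(study.ipd)
        spec = RenderSpec()
        ps = render_postscript(curve, [], spec, risk_table=truth)
        segs = [s for s in kr.extract_segments(ps) if s.stroke_attrs == StrokeAttrs()]
        calib = spec.calibration(curve)
        built = build_step_curve(segs, calib, "survival")
        assert detect_censor_marks(segs, built, calib) == []
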