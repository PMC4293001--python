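import math

import numpy as np
import pytest

import kmrecover as kr
from kmrecover.errors import ReconstructionError
from kmrecover.reconstruct import detect_multiplicities
from kmrecover.step_builder import StepCurve


def product_limit_raw_under_d1(n0, d_seq, c_seq=None):
    """Oracle: run the product-limit forward with known (n, d), then invert
    each jump under the d=1 assumption."""
    c_seq = c_seq or [0] * len(d_seq)
    n, s_prev, raw = n0, 1.0, []
    for d, c in zip(d_seq, c_seq):
        s = s_prev * (1 - d / n)
        raw.append(1.0 / (1.0 - s / s_prev))
        n, s_prev = n - d - c, s
    return raw


class TestJumpInversion:
    def test_aml_jumps(self, aml_curve):
        jr = kr.jumps_and_ratios(aml_curve)
        assert round(jr[0][1], 5) == 0.09091
        assert round(jr[1][1], 5) == 0.09091
        assert round(jr[2][1], 5) == 0.10227

    @pytest.mark.parametrize(
        "fn, args, expected",
        [
            (kr.infer_n_km, (1.0, 1 - 1 / 11, 1), 11.0),
            (kr.infer_n_km, (1.0, 0.5, 1), 2.0),
            (kr.infer_n_na, (0.0, 0.1, 1), 10.0),
            (kr.infer_n_na, (0.2, 0.21, 2), 200.0),
            (kr.infer_n_ci, (0.0, 0.1, 1), 10.0),
            (kr.infer_n_ci, (0.5, 0.75, 1), 2.0),
        ],
    )
    def test_inversion_formulas(self, fn, args, expected):
        assert fn(*args) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "fn, args",
        [
            (kr.infer_n_km, (0.5, 0.5, 1)),  # no jump
            (kr.infer_n_km, (0.5, 0.6, 1)),  # rising survival
            (kr.infer_n_na, (0.3, 0.3, 1)),  # flat hazard
            (kr.infer_n_ci, (0.4, 0.3, 1)),  # falling incidence
        ],
    )
    def test_invalid_jumps_raise(self, fn, args):
        with pytest.raises(ReconstructionError):
            fn(*args)

    def test_km_inversion_recovers_simulator_counts(self):
        study = kr.simulate_study(kr.StudyParams(n0=40, censoring="uniform"), seed=11)
        curve, truth = kr.km_estimate(study.ipd)
        heights = [curve.start_height] + [h for h in curve.heights[1:]]
        prev = curve.start_height
        got = []
        for t, s in zip(curve.times[1:], curve.heights[1:]):
            if s != prev:
                got.append(kr.infer_n_km(prev, s))
                prev = s
        assert np.allclose(got, truth.n, atol=1e-9)

    def test_na_inversion_is_exact(self):
        study = kr.simulate_study(kr.StudyParams(n0=60, censoring="admin"), seed=2)
        curve, truth = kr.na_estimate(study.ipd)
        prev, got = 0.0, []
        for s in curve.heights[1:]:
            if s != prev:
                got.append(kr.infer_n_na(prev, s, 1))
                prev = s
        # with d=1 assumed the estimate is n_j / d_j, exactly
        assert np.allclose(got, np.asarray(truth.n) / np.asarray(truth.d), atol=1e-9)


class TestDetectMultiplicities:
    def test_double_event_stands_out(self):
        # oracle: product-limit from n0=50 with 2 tied deaths at the third event
        raw = product_limit_raw_under_d1(50, [1, 1, 2, 1, 1])
        assert np.allclose(raw, [50, 49, 24, 46, 45])
        d, corrected, _ = detect_multiplicities(raw)
        assert d == [1, 1, 2, 1, 1]
        assert np.allclose(corrected, [50, 49, 48, 46, 45])

    def test_strictly_decreasing_sequence_unchanged(self):
        raw = [30.0, 29.0, 28.0, 27.0]
        d, corrected, _ = detect_multiplicities(raw)
        assert d == [1, 1, 1, 1]
        assert corrected == raw

    def test_triple_event_detected(self):
        raw = product_limit_raw_under_d1(30, [1, 1, 3, 1, 1])
        assert np.allclose(raw, [30, 29, 28 / 3, 25, 24])
        d, corrected, _ = detect_multiplicities(raw)
        assert d == [1, 1, 3, 1, 1]
        assert np.allclose(corrected, [30, 29, 28, 25, 24])

    def test_multiplicity_at_first_event(self):
        raw = product_limit_raw_under_d1(25, [2, 1, 1, 1])
        d, corrected, _ = detect_multiplicities(raw)
        assert d == [2, 1, 1, 1]
        assert np.allclose(corrected, [25, 23, 22, 21])


class TestReconstructTable:
    def test_aml_from_heights_alone(self, aml_curve):
        table = kr.reconstruct_risk_table(aml_curve)
        assert table.n == (11, 10, 8, 7, 5, 4, 2)
        assert table.d == (1,) * 7
        assert table.c == (0, 1, 0, 1, 0, 1, 1)

    def test_equal_jumps_mean_no_censoring(self):
        study = kr.simulate_study(kr.StudyParams(n0=12, censoring="none"), seed=9)
        curve, truth = kr.km_estimate(study.ipd)
        table = kr.reconstruct_risk_table(curve)
        assert sum(table.c) == 0
        assert table.n == truth.n

    def test_bookkeeping_identity_enforced(self):
        with pytest.raises(ValueError, match="bookkeeping"):
            kr.RiskSetTable(times=(1.0, 2.0), n=(10, 8), d=(1, 1), c=(0, 7))

    def test_reported_at_risk_overrides(self, aml_curve):
        table = kr.reconstruct_risk_table(aml_curve, reported_at_risk=[(18.0, 8)])
        assert table.n[2] == 8

    def test_lower_bound_aml(self, aml_curve):
        marks = [kr.CensorMark(28, 0.61, "tick"), kr.CensorMark(45, 0.37, "tick"),
                 kr.CensorMark(161, 0.18, "tick")]
        assert kr.infer_n0_lower_bound(aml_curve, marks) == 10

    def test_lower_bound_no_marks(self):
        c = StepCurve("survival", (0, 1, 2, 3, 4, 5), (1.0, 0.8, 0.6, 0.4, 0.2, 0.0))
        assert kr.infer_n0_lower_bound(c) == 5


class TestIPD:
    def test_aml_record_counts(self, aml_curve):
        table = kr.reconstruct_risk_table(aml_curve)
        records = kr.reconstruct_ipd(table)
        assert len(records) == 11
        assert sum(r.status for r in records) == 7
        assert sum(1 - r.status for r in records) == 4

    def test_no_censoring_gives_event_times_only(self):
        table = kr.RiskSetTable(times=(1.0, 2.0, 3.0), n=(3, 2, 1), d=(1, 1, 1), c=(0, 0, 0))
        records = kr.reconstruct_ipd(table)
        assert [(r.time, r.status) for r in records] == [(1.0, 1), (2.0, 1), (3.0, 1)]

    def test_km_of_reconstructed_ipd_matches_curve(self, aml_curve):
        table = kr.reconstruct_risk_table(aml_curve)
        records = kr.reconstruct_ipd(table)
        curve2, _ = kr.km_estimate(records)
        for t, s in zip(aml_curve.times, aml_curve.heights):
            assert curve2.height_at(t) == pytest.approx(s, abs=1e-9)

    def test_marked_censoring_placed_at_marks(self, aml_curve):
        table = kr.reconstruct_risk_table(aml_curve)
        marks = [kr.CensorMark(28, 0.61, "tick"), kr.CensorMark(45, 0.37, "tick"),
                 kr.CensorMark(161, 0.18, "tick")]
        records = kr.reconstruct_ipd(table, marks)
        censored_times = sorted(r.time for r in records if r.status == 0)
        assert censored_times[1:] == [28, 45, 161]
        assert censored_times[0] == pytest.approx(13, abs=1e-5)  # the unmarked "13+"


class TestPersonTime:
    def test_two_subject_example(self):
        records = [kr.IPDRecord(1.0, 1), kr.IPDRecord(2.0, 0)]
        pt = kr.person_time(records, [0, 2])
        assert pt.events == (1,)
        assert pt.person_time == (3.0,)

    def test_aml_intervals_match_brute_force(self, aml_ipd):
        bounds = [0, 12, 24, 36, 48, 60, 180]
        pt = kr.person_time(aml_ipd, bounds)
        for (a, b, ev, p) in zip(pt.starts, pt.ends, pt.events, pt.person_time):
            ev_ref = sum(1 for r in aml_ipd if r.status == 1 and a <= r.time < b)
            p_ref = sum(max(0.0, min(r.time, b) - a) for r in aml_ipd)
            assert ev == ev_ref
            assert p == pytest.approx(p_ref)
        assert sum(pt.person_time) == pytest.approx(sum(r.time for r in aml_ipd))

    def test_event_on_boundary_counts_right(self):
        records = [kr.IPDRecord(2.0, 1)]
        pt = kr.person_time(records, [0, 2, 4])
        assert pt.events == (0, 1)

    @pytest.mark.parametrize("bounds", [[1, 2], [0], [0, 2, 1]])
    def test_bad_boundaries_raise(self, bounds):
        with pytest.raises(ValueError):
            kr.person_time([kr.IPDRecord(1.0, 1)], bounds)


class TestValidate:
    def test_exact_heights_pass(self, aml_curve):
        table = kr.reconstruct_risk_table(aml_curve)
        report = kr.validate_reconstruction(aml_curve, table)
        assert report.passed and report.max_abs_dev < 1e-9

    def test_perturbed_n_is_detected_at_its_time(self, aml_curve):
        table = kr.reconstruct_risk_table(aml_curve)
        n = list(table.n)
        n[3] -= 1  # keeps the bookkeeping identity satisfiable via c
        c = [n[j] - table.d[j] - n[j + 1] for j in range(len(n) - 1)] + [n[-1] - table.d[-1]]
        bad = kr.RiskSetTable(times=table.times, n=tuple(n), d=table.d, c=tuple(c))
        report = kr.validate_reconstruction(aml_curve, bad, noise_bound=1e-6)
        assert not report.passed
        assert report.offending_times[0] == table.times[3]
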