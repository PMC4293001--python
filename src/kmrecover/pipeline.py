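"""End-to-end workflows: extract -> calibrate -> build -> reconstruct, and
the simulate -> render -> recover round trip used for validation."""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .calibration import AxisCalibration
from .ps_extract import extract_segments
from .reconstruct import RiskSetTable, reconstruct_risk_table, validate_reconstruction
from .step_builder import (
    CensorMark,
    CurveGroup,
    StepCurve,
    Tolerances,
    build_step_curve,
    detect_censor_marks,
    group_curves,
)
from .synthetic import RenderSpec, SimulatedStudy, render_study

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RecoveryResult:
    curve: StepCurve
    marks: list[CensorMark]
    table: RiskSetTable
    group: CurveGroup


def recover_from_postscript(
    ps_text: str | bytes,
    calib: AxisCalibration,
    curve_type: str = "survival",
    decimals: int = 3,
    group_index: int = 0,
    n0: int | None = None,
    d_max: int = 5,
) -> RecoveryResult:
    """Run the whole recovery on PostScript text with known axis anchors.

    ``decimals`` declares the coordinate precision of the file and sets the
    geometric tolerances; ``group_index`` selects the candidate curve group
    (largest first) when the figure contains several arms.
    """
    segments = extract_segments(ps_text)
    groups = group_curves(segments)
    group = groups[group_index]
    tol = Tolerances.from_geometry(calib, decimals=decimals)
    curve = build_step_curve(group, calib, curve_type, tol)
    marks = detect_censor_marks(group, curve, calib, tol)
    table = reconstruct_risk_table(curve, marks, n0=n0, d_max=d_max)
    return RecoveryResult(curve=curve, marks=marks, table=table, group=group)


@dataclass(frozen=True)
class RoundTripReport:
    study: SimulatedStudy
    recovered: RiskSetTable
    exact: bool
    mismatch: str = ""

    def __str__(self) -> str:
        verdict = "exact recovery" if self.exact else f"MISMATCH: {self.mismatch}"
        return (
            f"round trip (n0={self.study.params.n0}, seed={self.study.seed}, "
            f"{self.study.truth.k} event times): {verdict}"
        )


def roundtrip_study(
    study: SimulatedStudy,
    spec: RenderSpec = RenderSpec(),
    estimator: str = "km",
    supply_n0: bool = True,
) -> RoundTripReport:
    """Render a simulated study, recover it, and compare with the truth."""
    ps, _, _ = render_study(study, spec, estimator=estimator)
    curve_type = {"km": "survival", "na": "cumulative_hazard", "ci": "cumulative_incidence"}[
        estimator
    ]
    result = recover_from_postscript(
        ps,
        spec.calibration(km_curve_for_axis(study, estimator)),
        curve_type=curve_type,
        decimals=spec.decimals,
        n0=study.params.n0 if supply_n0 else None,
    )
    truth = study.truth
    rec = result.table
    mismatch = ""
    calib = spec.calibration(km_curve_for_axis(study, estimator))
    time_tol = 2 * 10.0 ** (-spec.decimals) / abs(calib.x_scale)
    if rec.k != truth.k:
        mismatch = f"{rec.k} event times recovered, truth has {truth.k}"
    elif any(abs(a - b) > time_tol for a, b in zip(rec.times, truth.times)):
        mismatch = f"event times differ beyond tolerance: {rec.times} vs {truth.times}"
    elif tuple(rec.n) != tuple(truth.n):
        mismatch = f"n differs: {rec.n} vs {truth.n}"
    elif tuple(rec.d) != tuple(truth.d):
        mismatch = f"d differs: {rec.d} vs {truth.d}"
    elif tuple(rec.c) != tuple(truth.c):
        mismatch = f"c differs: {rec.c} vs {truth.c}"
    elif supply_n0 and rec.c0 != truth.c0:
        mismatch = f"c0 differs: {rec.c0} vs {truth.c0}"
    report = RoundTripReport(study=study, recovered=rec, exact=not mismatch, mismatch=mismatch)
    if mismatch:
        check = validate_reconstruction(result.curve, rec, noise_bound=1e-3)
        logger.warning("%s (%s)", report, check)
    return report


def km_curve_for_axis(study: SimulatedStudy, estimator: str) -> StepCurve:
    """The curve whose extent defines the default time axis for rendering."""
    from .synthetic import ci_estimate, km_estimate, na_estimate

    fn = {"km": km_estimate, "na": na_estimate, "ci": ci_estimate}[estimator]
    curve, _ = fn(study.ipd)
    return curve
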