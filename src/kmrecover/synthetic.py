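"""Ground-truth study simulation and PostScript rendering.

This is the fixture engine: it generates survival studies with known
risk-set bookkeeping, computes the product-limit (Kaplan-Meier) and
Nelson-Aalen estimators from first principles, and renders the curves to
PostScript text in the rendering dialects found in published figures —

``segments``
    minimal alternating horizontal/vertical strokes (one stroked path);
``per_observation_dots``
    one element per subject: each event a vertical sub-segment, each
    censored subject a zero-length (invisible) dot on the curve — the
    data-disclosing style some statistical packages emit;
``elaborate``
    every horizontal/vertical piece overdrawn as several redundant collinear
    sub-segments, emulating post-processed figures that need thousands of
    segments for a few dozen events.

Coordinates are written with a configurable number of decimals so tests can
probe the effect of rounding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .calibration import AxisCalibration, calibrate, data_to_device
from .reconstruct import IPDRecord, RiskSetTable
from .step_builder import CensorMark, StepCurve

logger = logging.getLogger(__name__)

DIALECTS = ("segments", "per_observation_dots", "elaborate")
CENSOR_STYLES = ("tick", "dot", "none")


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StudyParams:
    """Study design for the simulator.

    Event times are exponential with the given hazard rate (per time unit).
    Censoring models: ``none``; ``uniform`` — random loss to follow-up,
    uniform on (0, uniform_cmax); ``admin`` — staggered entry in
    ``admin_cohorts`` equal calendar-year cohorts with a common closing
    date, so censored times cluster at exactly ``admin_cohorts`` distinct
    follow-up durations.  ``tie_grid`` rounds all times up to a discrete
    grid, forcing tied event times (d_j > 1).
    """

    n0: int
    hazard: float = 0.1
    censoring: str = "uniform"
    uniform_cmax: float = 20.0
    admin_cohorts: int = 4
    admin_total_follow: float = 12.0  # follow-up of the earliest cohort
    tie_grid: float | None = None

    def __post_init__(self) -> None:
        if self.n0 < 2:
            raise ValueError("n0 must be >= 2")
        if self.hazard <= 0:
            raise ValueError("hazard must be positive")
        if self.censoring not in ("none", "uniform", "admin"):
            raise ValueError(f"unknown censoring model {self.censoring!r}")


@dataclass(frozen=True)
class SimulatedStudy:
    ipd: tuple[IPDRecord, ...]
    truth: RiskSetTable
    params: StudyParams
    seed: int


def simulate_study(params: StudyParams, seed: int) -> SimulatedStudy:
    """Generate one reproducible study; truth derived by direct counting."""
    rng = np.random.default_rng(seed)
    event = rng.exponential(1.0 / params.hazard, size=params.n0)
    if params.censoring == "none":
        cens = np.full(params.n0, np.inf)
    elif params.censoring == "uniform":
        cens = rng.uniform(0.0, params.uniform_cmax, size=params.n0)
    else:  # staggered-entry administrative censoring
        cohort = rng.integers(0, params.admin_cohorts, size=params.n0)
        cens = params.admin_total_follow - cohort.astype(float)
    time = np.minimum(event, cens)
    status = (event <= cens).astype(int)
    if params.tie_grid:
        g = params.tie_grid
        time = np.ceil(time / g - 1e-12) * g
    ipd = tuple(IPDRecord(float(t), int(s)) for t, s in zip(time, status))
    return SimulatedStudy(ipd=ipd, truth=risk_table_from_ipd(ipd), params=params, seed=seed)


def battery_params(n0: int, censoring: str, hazard: float = 0.1) -> StudyParams:
    """Study conditions for the validation battery.

    Tied event times are forced by a discrete reporting grid whose spacing
    keeps multiplicities occasional (about 0.25 expected events per grid
    cell at entry): the inversion identifies a multiplicity by how it stands
    out against singleton-based neighbours, so pervasively tied data — every
    jump a multiplicity — is outside its design domain, as is true of the
    underlying reasoning itself.
    """
    tie_grid = 0.25 / (n0 * hazard)
    return StudyParams(n0=n0, hazard=hazard, censoring=censoring, tie_grid=tie_grid)


def study_battery(
    n_studies: int = 200,
    seed: int = 20_140,
    n0_range: tuple[int, int] = (10, 200),
    censoring_models: Sequence[str] = ("uniform", "admin"),
) -> list[SimulatedStudy]:
    """The fixed battery of simulated studies used for round-trip validation:
    sample sizes drawn across ``n0_range``, exponential events, alternating
    censoring models, occasional forced ties."""
    rng = np.random.default_rng(seed)
    studies = []
    for i in range(n_studies):
        n0 = int(rng.integers(n0_range[0], n0_range[1] + 1))
        censoring = censoring_models[i % len(censoring_models)]
        params = battery_params(n0, censoring)
        studies.append(simulate_study(params, seed=int(rng.integers(0, 2**31 - 1))))
    return studies


def risk_table_from_ipd(ipd: Sequence[IPDRecord]) -> RiskSetTable:
    """Direct-counting risk-set table.

    Convention: censoring tied with an event time is processed *after* the
    event — such subjects are still at risk at that time and are counted as
    censored in the interval starting there.
    """
    times = np.array([r.time for r in ipd])
    status = np.array([r.status for r in ipd])
    event_times = np.unique(times[status == 1])
    n, d, c = [], [], []
    for j, t in enumerate(event_times):
        n.append(int(np.sum(times >= t)))
        d.append(int(np.sum((times == t) & (status == 1))))
        t_next = event_times[j + 1] if j + 1 < len(event_times) else np.inf
        c.append(int(np.sum((status == 0) & (times >= t) & (times < t_next))))
    c0 = int(np.sum((status == 0) & (times < event_times[0]))) if len(event_times) else len(ipd)
    return RiskSetTable(
        times=tuple(float(t) for t in event_times),
        n=tuple(n),
        d=tuple(d),
        c=tuple(c),
        n0=len(ipd),
        c0=c0,
        end_time=float(times.max()) if len(ipd) else None,
    )


# ---------------------------------------------------------------------------
# estimators (first principles; cross-checked against lifelines in tests)
# ---------------------------------------------------------------------------


def km_estimate(ipd: Sequence[IPDRecord]) -> tuple[StepCurve, RiskSetTable]:
    """Product-limit estimator, right-continuous, ties summed."""
    truth = risk_table_from_ipd(ipd)
    if truth.k == 0:
        logger.warning("all observations censored: survival curve has no jumps")
        t_end = truth.end_time or 0.0
        ts = (0.0, t_end) if t_end > 0 else (0.0,)
        return StepCurve("survival", ts, (1.0,) * len(ts), source="km_estimate"), truth
    heights = truth.km_heights()
    times = [0.0] + list(truth.times)
    s = [1.0] + [float(v) for v in heights]
    if truth.end_time is not None and truth.end_time > times[-1]:
        times.append(truth.end_time)
        s.append(s[-1])
    return StepCurve("survival", tuple(times), tuple(s), source="km_estimate"), truth


def na_estimate(ipd: Sequence[IPDRecord]) -> tuple[StepCurve, RiskSetTable]:
    """Nelson-Aalen cumulative hazard estimator (increments d_j / n_j)."""
    truth = risk_table_from_ipd(ipd)
    if truth.k == 0:
        logger.warning("all observations censored: hazard curve has no jumps")
        t_end = truth.end_time or 0.0
        ts = (0.0, t_end) if t_end > 0 else (0.0,)
        return StepCurve("cumulative_hazard", ts, (0.0,) * len(ts), source="na_estimate"), truth
    heights = truth.na_heights()
    times = [0.0] + list(truth.times)
    h = [0.0] + [float(v) for v in heights]
    if truth.end_time is not None and truth.end_time > times[-1]:
        times.append(truth.end_time)
        h.append(h[-1])
    return StepCurve("cumulative_hazard", tuple(times), tuple(h), source="na_estimate"), truth


def ci_estimate(ipd: Sequence[IPDRecord]) -> tuple[StepCurve, RiskSetTable]:
    """Cumulative incidence as the complement 1 - S of the product-limit."""
    km, truth = km_estimate(ipd)
    return (
        StepCurve(
            "cumulative_incidence",
            km.times,
            tuple(1.0 - s for s in km.heights),
            source="ci_estimate",
        ),
        truth,
    )


def marks_from_ipd(ipd: Sequence[IPDRecord], curve: StepCurve, kind: str = "tick") -> list[CensorMark]:
    """Censor marks as figures draw them.

    ``tick``: only censored times not coinciding with an event time get a
    mark (packages omit marks for censoring tied just after an event);
    ``dot``: every censored subject gets a dot on the curve.
    """
    event_times = {r.time for r in ipd if r.status == 1}
    marks = []
    for r in ipd:
        if r.status == 1:
            continue
        if kind == "tick" and r.time in event_times:
            continue
        marks.append(CensorMark(r.time, curve.height_at(r.time), kind))
    marks.sort(key=lambda m: m.t)
    return marks


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RenderSpec:
    """Page geometry and rendering dialect.

    The default geometry mirrors a small worked layout: a 144-point x-axis
    at device x 72..216, and a 108-point y-axis with S=0 at device y 360 and
    S=1 at 252 (vertical positions measured from the top of the page, hence
    the negative y direction).
    """

    x_device: tuple[float, float] = (72.0, 216.0)
    y_device: tuple[float, float] = (360.0, 252.0)
    t_axis: tuple[float, float] | None = None  # None: (0, curve end time)
    s_axis: tuple[float, float] = (0.0, 1.0)
    decimals: int = 3
    dialect: str = "segments"
    censor_style: str = "tick"
    draw_axes: bool = True
    tick_halflen_pt: float = 2.5
    elaborate_pieces: int = 3

    def __post_init__(self) -> None:
        if self.decimals < 0:
            raise ValueError("decimals must be >= 0")
        if self.dialect not in DIALECTS:
            raise ValueError(f"unknown dialect {self.dialect!r}")
        if self.censor_style not in CENSOR_STYLES:
            raise ValueError(f"unknown censor style {self.censor_style!r}")

    @classmethod
    def full_page(cls, **kw) -> "RenderSpec":
        """A typical full-size published figure: 5 x 4 inch plot box."""
        kw.setdefault("x_device", (72.0, 432.0))
        kw.setdefault("y_device", (648.0, 360.0))
        return cls(**kw)

    def calibration(self, curve: StepCurve | None = None) -> AxisCalibration:
        t_axis = self.t_axis
        if t_axis is None:
            if curve is None:
                raise ValueError("t_axis not set and no curve supplied")
            t_axis = (0.0, float(curve.end_time))
        return calibrate(
            ((self.x_device[0], t_axis[0]), (self.x_device[1], t_axis[1])),
            ((self.y_device[0], self.s_axis[0]), (self.y_device[1], self.s_axis[1])),
        )


def render_postscript(
    curve: StepCurve,
    marks: Sequence[CensorMark] = (),
    spec: RenderSpec = RenderSpec(),
    risk_table: RiskSetTable | None = None,
) -> str:
    """Render a step curve (plus censor marks) as PostScript text.

    Emits only the operator subset the extractor interprets.  The
    ``per_observation_dots`` dialect needs the risk-set table to know how
    many stacked sub-segments each jump carries, and draws censored
    subjects from ``marks`` (pass dot-style marks for every censored
    subject).
    """
    calib = spec.calibration(curve)

    def dev(t: float, s: float) -> tuple[float, float]:
        return data_to_device((t, s), calib)

    def fmt(v: float) -> str:
        return f"{v:.{spec.decimals}f}"

    def seg(p: tuple[float, float], q: tuple[float, float]) -> str:
        return (
            f"{fmt(p[0])} {fmt(p[1])} moveto {fmt(q[0])} {fmt(q[1])} lineto stroke\n"
        )

    out: list[str] = ["%!PS-Adobe-3.0\n", "% synthetic step-curve figure\n"]
    if spec.draw_axes:
        x0, x1 = spec.x_device
        y0, y1 = spec.y_device
        out.append("gsave 0.5 setgray 0.75 setlinewidth\n")
        out.append(f"{x0} {y0} moveto {x1} {y0} lineto stroke\n")
        out.append(f"{x0} {y0} moveto {x0} {y1} lineto stroke\n")
        out.append("grestore\n")
    out.append("0 setgray 1 setlinewidth\n")

    corners: list[tuple[float, float]] = [dev(curve.times[0], curve.heights[0])]
    for (tp, sp), (t, s) in zip(
        zip(curve.times, curve.heights), zip(curve.times[1:], curve.heights[1:])
    ):
        corners.append(dev(t, sp))  # horizontal to the new time at the old height
        if s != sp:
            corners.append(dev(t, s))  # vertical jump

    if spec.dialect == "segments":
        out.append(f"newpath {fmt(corners[0][0])} {fmt(corners[0][1])} moveto\n")
        for p in corners[1:]:
            out.append(f"{fmt(p[0])} {fmt(p[1])} lineto\n")
        out.append("stroke\n")
    elif spec.dialect == "elaborate":
        for p, q in zip(corners, corners[1:]):
            for i in range(spec.elaborate_pieces):
                a = (
                    p[0] + (q[0] - p[0]) * i / spec.elaborate_pieces,
                    p[1] + (q[1] - p[1]) * i / spec.elaborate_pieces,
                )
                b = (
                    p[0] + (q[0] - p[0]) * (i + 1) / spec.elaborate_pieces,
                    p[1] + (q[1] - p[1]) * (i + 1) / spec.elaborate_pieces,
                )
                out.append(seg(a, b))
            out.append(seg(p, q))  # full piece overdrawn once more
    else:  # per_observation_dots
        if risk_table is None:
            raise ValueError("per_observation_dots dialect requires the risk-set table")
        prev_s = curve.start_height
        sign = -1.0 if curve.curve_type == "survival" else 1.0
        heights_at = dict(zip(risk_table.times, _post_jump_heights(curve)))
        for t in risk_table.times:
            s_post = heights_at[t]
            dj = risk_table.d[risk_table.times.index(t)]
            for i in range(dj):
                a = dev(t, prev_s + (s_post - prev_s) * i / dj)
                b = dev(t, prev_s + (s_post - prev_s) * (i + 1) / dj)
                out.append(seg(a, b))
            prev_s = s_post
        for m in marks:  # one invisible dot per censored subject
            p = dev(m.t, m.S)
            out.append(seg(p, p))

    if spec.dialect != "per_observation_dots" and spec.censor_style != "none":
        for m in marks:
            p = dev(m.t, m.S)
            if spec.censor_style == "tick":
                a = (p[0], p[1] - spec.tick_halflen_pt)
                b = (p[0], p[1] + spec.tick_halflen_pt)
                out.append(seg(a, b))
            else:
                out.append(seg(p, p))

    out.append("showpage\n")
    return "".join(out)


def _post_jump_heights(curve: StepCurve) -> list[float]:
    heights = []
    prev = curve.start_height
    for s in curve.heights[1:]:
        if s != prev:
            heights.append(s)
            prev = s
    return heights


def render_study(
    study: SimulatedStudy,
    spec: RenderSpec = RenderSpec(),
    estimator: str = "km",
) -> tuple[str, StepCurve, list[CensorMark]]:
    """Estimate a curve from a simulated study and render it.

    Returns (postscript text, true curve, marks as drawn).
    """
    if estimator == "km":
        curve, truth = km_estimate(study.ipd)
    elif estimator == "na":
        curve, truth = na_estimate(study.ipd)
    elif estimator == "ci":
        curve, truth = ci_estimate(study.ipd)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    mark_kind = "dot" if spec.dialect == "per_observation_dots" else spec.censor_style
    if mark_kind == "none":
        marks: list[CensorMark] = []
    else:
        marks = marks_from_ipd(study.ipd, curve, kind=mark_kind)
    ps = render_postscript(curve, marks, spec, risk_table=truth)
    return ps, curve, marks
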