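"""Build a clean step function from calibrated segments.

Published figures draw what the eye sees as a simple step function in
surprisingly elaborate ways: horizontal runs split into dozens of collinear
sub-segments, pieces overdrawn several times, one element per subject, censor
ticks as tiny verticals, censored subjects as zero-length dots.  This module
tolerates all of that: it merges collinear/duplicated pieces, decomposes the
path into alternating horizontal runs and vertical jumps, separates censor
marks from the curve, and snaps small rounding-induced monotonicity
violations with an isotonic (pool-adjacent-violators) adjustment.

Conventions: a :class:`StepCurve` stores the right-continuous step function as
its corner vertices ``(t_j, S_j)`` where ``S_j`` is the post-jump height; the
pre-jump height is the previous vertex's height.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression

from .calibration import AxisCalibration, device_to_data
from .errors import StepFunctionError
from .ps_extract import PathSegment, StrokeAttrs

logger = logging.getLogger(__name__)

CURVE_TYPES = ("survival", "cumulative_incidence", "cumulative_hazard")
#: curve types that increase over time
_INCREASING = {"cumulative_incidence", "cumulative_hazard"}


@dataclass(frozen=True)
class Tolerances:
    """Geometric tolerances in data units.

    ``time_tol`` merges vertices closer than one coordinate-rounding quantum
    on the time axis; ``height_tol`` plays the same role on the height axis
    and doubles as the classification threshold between horizontal and
    vertical pieces; ``noise_bound`` caps the size of monotonicity violations
    attributed to coordinate rounding.
    """

    time_tol: float
    height_tol: float
    noise_bound: float

    @classmethod
    def from_geometry(
        cls, calib: AxisCalibration, decimals: int = 3, noise_factor: float = 2.0
    ) -> "Tolerances":
        """Defaults from the rounding model: coordinates carry ``decimals``
        decimal places, so each is off by at most ``0.5 * 10^-decimals``
        points; height differences by twice that."""
        q = 10.0 ** (-decimals)
        return cls(
            time_tol=q / abs(calib.x_scale),
            height_tol=noise_factor * q / abs(calib.y_scale),
            noise_bound=noise_factor * q / abs(calib.y_scale),
        )


@dataclass(frozen=True)
class StepCurve:
    """Ordered step-function corners with declared curve type."""

    curve_type: str
    times: tuple[float, ...]  # t_0 < t_1 < ... (t_0 = curve start)
    heights: tuple[float, ...]  # post-jump heights S(t_j)
    source: str = ""

    def __post_init__(self) -> None:
        if self.curve_type not in CURVE_TYPES:
            raise ValueError(f"unknown curve_type {self.curve_type!r}")
        if len(self.times) != len(self.heights):
            raise ValueError("times and heights differ in length")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("times must be strictly increasing")

    @property
    def increasing(self) -> bool:
        return self.curve_type in _INCREASING

    @property
    def start_height(self) -> float:
        return self.heights[0]

    @property
    def end_time(self) -> float:
        return self.times[-1]

    def jumps(self) -> list[tuple[float, float]]:
        """``(t_j, J_j)`` for every vertex where the height changes.

        ``J_j = |S_{j-1} - S_j|`` is the jump magnitude; vertices with equal
        consecutive heights (e.g. a terminal extension run) carry no jump.
        """
        out = []
        for (t, s), (_, sp) in zip(
            zip(self.times[1:], self.heights[1:]), zip(self.times, self.heights)
        ):
            j = abs(sp - s)
            if j > 0:
                out.append((t, j))
        return out

    def height_at(self, t: float) -> float:
        """Right-continuous evaluation."""
        idx = np.searchsorted(np.asarray(self.times), t, side="right") - 1
        idx = max(0, min(idx, len(self.heights) - 1))
        return self.heights[int(idx)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.times, "S": self.heights})


@dataclass(frozen=True)
class CensorMark:
    t: float
    S: float
    kind: str  # "tick" | "dot"


@dataclass
class CurveGroup:
    """Candidate curve: segments sharing stroke attributes."""

    attrs: StrokeAttrs
    segments: list[PathSegment]
    ambiguous: bool = False  # multiple overlapping curve-sized components

    @property
    def size(self) -> int:
        return len(self.segments)


def group_curves(
    segments: Sequence[PathSegment],
    calib: AxisCalibration | None = None,
    connect_tol: float = 0.05,
) -> list[CurveGroup]:
    """Partition segments into candidate curve groups.

    Segments are grouped by stroke attributes (colour, line width) first;
    within one attribute class, endpoint connectivity is examined and a
    warning is attached when two curve-sized connected components overlap in
    x — two same-styled arms that the caller must separate by ``path_id``.
    Groups are ordered largest first.
    """
    by_attrs: dict[StrokeAttrs, list[PathSegment]] = {}
    for seg in segments:
        by_attrs.setdefault(seg.stroke_attrs, []).append(seg)
    groups = [CurveGroup(attrs, segs) for attrs, segs in by_attrs.items()]
    if not any(g.size >= 2 for g in groups):
        raise StepFunctionError("no curve-like path found (no group with >= 2 segments)")

    for g in groups:
        comps = _connected_components(g.segments, connect_tol)
        big = [c for c in comps if len(c) >= 4]
        if len(big) > 1 and _x_ranges_overlap(big):
            g.ambiguous = True
            logger.warning(
                "group with attrs %s contains %d overlapping curve-sized "
                "components; select by path_id manually",
                g.attrs, len(big),
            )
    groups.sort(key=lambda g: -g.size)
    return groups


def _connected_components(
    segments: Sequence[PathSegment], tol: float
) -> list[list[PathSegment]]:
    def key(x: float, y: float) -> tuple[int, int]:
        return (round(x / tol), round(y / tol))

    parent: dict = {}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for i, s in enumerate(segments):
        for node in (("s", i), key(s.x0, s.y0), key(s.x1, s.y1)):
            parent.setdefault(node, node)
        union(("s", i), key(s.x0, s.y0))
        union(("s", i), key(s.x1, s.y1))
    comps: dict = {}
    for i, s in enumerate(segments):
        comps.setdefault(find(("s", i)), []).append(s)
    return list(comps.values())


def _x_ranges_overlap(components: list[list[PathSegment]]) -> bool:
    ranges = [
        (min(min(s.x0, s.x1) for s in c), max(max(s.x0, s.x1) for s in c))
        for c in components
    ]
    ranges.sort()
    return any(b0 < a1 for (_, a1), (b0, _) in zip(ranges, ranges[1:]))


# ---------------------------------------------------------------------------
# decomposition into runs / jumps / ticks / dots (shared by curve building
# and censor-mark detection)
# ---------------------------------------------------------------------------


@dataclass
class _Decomposition:
    runs: list[tuple[float, float, float]] = field(default_factory=list)  # (t0, t1, S)
    jumps: list[tuple[float, float, float]] = field(default_factory=list)  # (t, S_lo, S_hi)
    ticks: list[tuple[float, float, float]] = field(default_factory=list)  # (t, S_lo, S_hi)
    dots: list[tuple[float, float]] = field(default_factory=list)  # (t, S)


def _decompose(
    segments: Iterable[PathSegment], calib: AxisCalibration, tol: Tolerances
) -> _Decomposition:
    horizontals: list[tuple[float, float, float]] = []  # (t0, t1, S-mean)
    verticals: list[tuple[float, float, float]] = []  # (t-mean, S_lo, S_hi)
    dots: list[tuple[float, float]] = []
    for seg in segments:
        (t0, s0) = device_to_data((seg.x0, seg.y0), calib)
        (t1, s1) = device_to_data((seg.x1, seg.y1), calib)
        if seg.is_dot:
            dots.append((0.5 * (t0 + t1), 0.5 * (s0 + s1)))
            continue
        if abs(s1 - s0) <= tol.height_tol:
            horizontals.append((min(t0, t1), max(t0, t1), 0.5 * (s0 + s1)))
        elif abs(t1 - t0) <= tol.time_tol:
            verticals.append((0.5 * (t0 + t1), min(s0, s1), max(s0, s1)))
        else:
            raise StepFunctionError(
                f"not a step function near t={min(t0, t1):.6g}: diagonal segment "
                f"({t0:.6g},{s0:.6g})->({t1:.6g},{s1:.6g})"
            )

    dec = _Decomposition(dots=dots)
    dec.runs = _merge_runs(horizontals, tol)
    v_clusters = _cluster_verticals(verticals, tol)

    # a vertical whose extent *crosses* a run's height at an interior-or-end
    # time of that run is a censor tick; jumps connect run levels instead
    for (t, lo, hi) in v_clusters:
        is_tick = False
        for (r0, r1, rs) in dec.runs:
            if r0 - tol.time_tol <= t <= r1 + tol.time_tol and (
                lo + tol.height_tol < rs < hi - tol.height_tol
            ):
                is_tick = True
                break
        (dec.ticks if is_tick else dec.jumps).append((t, lo, hi))
    dec.jumps.sort()
    return dec


def _merge_runs(
    horizontals: list[tuple[float, float, float]], tol: Tolerances
) -> list[tuple[float, float, float]]:
    """Merge collinear, overlapping/adjacent horizontal pieces into runs."""
    merged: list[tuple[float, float, float]] = []
    for h in sorted(horizontals):
        for i, (r0, r1, rs) in enumerate(merged):
            if abs(h[2] - rs) <= tol.height_tol and (
                h[0] <= r1 + 2 * tol.time_tol and h[1] >= r0 - 2 * tol.time_tol
            ):
                merged[i] = (min(r0, h[0]), max(r1, h[1]), rs)
                break
        else:
            merged.append(h)
    merged.sort()
    return merged


def _cluster_verticals(
    verticals: list[tuple[float, float, float]], tol: Tolerances
) -> list[tuple[float, float, float]]:
    """Cluster verticals by time; each cluster's extent is the union."""
    out: list[tuple[float, float, float]] = []
    for t, lo, hi in sorted(verticals):
        if out and t - out[-1][0] <= tol.time_tol:
            pt, plo, phi = out[-1]
            out[-1] = (pt, min(plo, lo), max(phi, hi))
        else:
            out.append((t, lo, hi))
    return out


# ---------------------------------------------------------------------------
# curve assembly
# ---------------------------------------------------------------------------


def build_step_curve(
    group: CurveGroup | Sequence[PathSegment],
    calib: AxisCalibration,
    curve_type: str,
    tolerances: Tolerances | None = None,
    snap: bool = True,
) -> StepCurve:
    """Assemble the maximal alternating horizontal/vertical step function.

    Handles redundant and per-observation renderings: collinear sub-segments
    are merged, stacked sub-jumps at one time are unioned, censor ticks and
    dots are excluded from the curve geometry.  Output satisfies the step
    curve invariants (strictly increasing times, monotone heights after
    snapping) or the call fails with a diagnostic naming the offending
    location.
    """
    segments = group.segments if isinstance(group, CurveGroup) else list(group)
    tol = tolerances or Tolerances.from_geometry(calib)
    dec = _decompose(segments, calib, tol)
    if not dec.jumps:
        raise StepFunctionError("no vertical jump found; not a step curve")

    increasing = curve_type in _INCREASING
    times: list[float] = []
    heights: list[float] = []

    # pre-jump height of jump j must chain to post-jump height of jump j-1
    pre = [hi if not increasing else lo for (_, lo, hi) in dec.jumps]
    post = [lo if not increasing else hi for (_, lo, hi) in dec.jumps]
    jump_ts = [t for (t, _, _) in dec.jumps]
    for k in range(1, len(dec.jumps)):
        if abs(pre[k] - post[k - 1]) > 3 * tol.height_tol:
            logger.warning(
                "height chain break at t=%.6g: post-jump %.6g vs next pre-jump %.6g",
                jump_ts[k], post[k - 1], pre[k],
            )

    start_candidates = [r[0] for r in dec.runs] + [t for (t, _) in dec.dots]
    pre_candidates = [c for c in start_candidates if c < jump_ts[0] - tol.time_tol]
    if pre_candidates:
        t_start = min(pre_candidates)
    elif jump_ts[0] > tol.time_tol:
        t_start = 0.0  # no drawn origin (per-observation dialects): curve starts at time zero
    else:
        raise StepFunctionError(
            f"curve begins with a jump at t={jump_ts[0]:.6g}; no origin run found"
        )
    times.append(t_start)
    heights.append(pre[0])

    s0_expected = 0.0 if increasing else 1.0
    if abs(pre[0] - s0_expected) > max(0.02, 10 * tol.height_tol):
        logger.warning(
            "%s curve starts at S=%.4f, expected %.0f — check calibration/curve type",
            curve_type, pre[0], s0_expected,
        )

    for t, s in zip(jump_ts, post):
        times.append(t)
        heights.append(s)

    # terminal horizontal extension (trailing censored observations)
    final_s = heights[-1]
    t_end = times[-1]
    for (r0, r1, rs) in dec.runs:
        if abs(rs - final_s) <= 3 * tol.height_tol:
            t_end = max(t_end, r1)
    for (t, s) in dec.dots:
        if abs(s - final_s) <= 3 * tol.height_tol:
            t_end = max(t_end, t)
    if t_end > times[-1] + tol.time_tol:
        times.append(t_end)
        heights.append(final_s)

    times, heights = _merge_duplicate_times(times, heights, tol.time_tol)
    curve = StepCurve(curve_type, tuple(times), tuple(heights), source="built from segments")
    if snap:
        curve = snap_monotone(curve, tol.noise_bound)
    return curve


def _merge_duplicate_times(
    times: list[float], heights: list[float], time_tol: float
) -> tuple[list[float], list[float]]:
    out_t: list[float] = []
    out_s: list[float] = []
    for t, s in zip(times, heights):
        if out_t and t - out_t[-1] <= time_tol:
            out_s[-1] = s  # later (post-jump) height wins
        else:
            out_t.append(t)
            out_s.append(s)
    return out_t, out_s


def snap_monotone(curve: StepCurve, noise_bound: float) -> StepCurve:
    """Isotonic (pool-adjacent-violators) repair of rounding-induced
    monotonicity violations.

    Every violation must individually be at most ``noise_bound``; larger ones
    indicate a wrong curve type or calibration and raise.
    """
    h = np.asarray(curve.heights, dtype=float)
    sign = 1.0 if curve.increasing else -1.0
    viol = sign * np.diff(h)
    bad = np.where(viol < -1e-15)[0]
    if bad.size == 0:
        return curve
    worst = float(-viol[bad].min())
    if worst > noise_bound:
        t_bad = curve.times[int(bad[np.argmin(viol[bad])]) + 1]
        raise StepFunctionError(
            f"monotonicity violation of {worst:.6g} at t={t_bad:.6g} exceeds "
            f"noise bound {noise_bound:.6g} (wrong curve type or calibration?)"
        )
    res = isotonic_regression(sign * h, increasing=True)
    snapped = sign * np.asarray(res.x)
    total = float(np.abs(snapped - h).sum())
    logger.info("snap_monotone adjusted heights by %.3g in total", total)
    if curve.curve_type in ("survival", "cumulative_incidence"):
        snapped = np.clip(snapped, 0.0, 1.0)
    return replace(curve, heights=tuple(float(v) for v in snapped))


def detect_censor_marks(
    group: CurveGroup | Sequence[PathSegment],
    curve: StepCurve,
    calib: AxisCalibration,
    tolerances: Tolerances | None = None,
) -> list[CensorMark]:
    """Find censor marks: short ticks crossing the curve and zero-length dots
    on horizontal runs.

    Marks coinciding with jump times are excluded (such censoring is handled
    downstream as unmarked "t+" censoring), and a dot sitting exactly on a
    step corner is treated as part of the curve, not a mark.
    """
    segments = group.segments if isinstance(group, CurveGroup) else list(group)
    tol = tolerances or Tolerances.from_geometry(calib)
    dec = _decompose(segments, calib, tol)
    jump_times = [t for t, _ in curve.jumps()]

    def at_jump(t: float) -> bool:
        return any(abs(t - tj) <= tol.time_tol for tj in jump_times)

    marks: list[CensorMark] = []
    for (t, _lo, _hi) in dec.ticks:
        if at_jump(t):
            continue
        marks.append(CensorMark(t, curve.height_at(t), "tick"))
    for (t, s) in dec.dots:
        if at_jump(t):
            continue  # corner dot: part of the curve (per-observation dialect)
        if abs(s - curve.height_at(t)) <= 3 * tol.height_tol:
            marks.append(CensorMark(t, s, "dot"))
    marks.sort(key=lambda m: m.t)
    return marks


# ---------------------------------------------------------------------------
# CSV interoperability (digitizer workflows)
# ---------------------------------------------------------------------------


def write_curve_csv(curve: StepCurve, path) -> None:
    curve.to_frame().to_csv(path, index=False)


def read_curve_csv(path, curve_type: str, source: str = "csv") -> StepCurve:
    """Read a digitizer-exported (t, S) table as a StepCurve.

    Entry point for digitizer-based workflows: rows are the step corners with
    post-jump heights, ordered by time.
    """
    df = pd.read_csv(path)
    if not {"t", "S"}.issubset(df.columns):
        raise ValueError("curve CSV must have columns t,S")
    df = df.sort_values("t")
    return StepCurve(curve_type, tuple(df["t"]), tuple(df["S"]), source=source)


def write_marks_csv(marks: Sequence[CensorMark], path) -> None:
    pd.DataFrame(
        [{"t": m.t, "S": m.S, "kind": m.kind} for m in marks],
        columns=["t", "S", "kind"],
    ).to_csv(path, index=False)


def read_marks_csv(path) -> list[CensorMark]:
    df = pd.read_csv(path)
    return [CensorMark(r.t, r.S, r.kind) for r in df.itertuples()]
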