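"""Invert a step curve into risk sets, individual records and person-time.

The key identity: for a product-limit (Kaplan-Meier) survival curve, the
ratio of successive heights at an event time is the conditional survival
probability 1 - d_j/n_j, so the number at risk follows from the heights
alone,

    n_j = d_j / (1 - S_j / S_{j-1}).

For a Nelson-Aalen cumulative hazard curve the increment is d_j/n_j exactly
(n_j = d_j / dH_j), and for a cumulative incidence curve plotted as
CI = 1 - S the same ratio identity gives n_j = d_j (1 - CI_{j-1}) /
(CI_j - CI_{j-1}).

Event multiplicities are found by first assuming a single event at each jump
(d_j = 1): a jump that actually carries d tied events then yields an inferred
n at 1/d of its neighbours and stands out from the otherwise monotone
sequence.  Censoring counts follow by subtraction from the bookkeeping
identity n_{j+1} = n_j - d_j - c_j, and censored observations without a
visible mark between events are attributed to censoring immediately after an
event time ("t+", tied with the event but processed after it).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ReconstructionError
from .step_builder import CensorMark, StepCurve

logger = logging.getLogger(__name__)

DEFAULT_D_MAX = 5
#: fractional part above which an inferred n is suspect
ROUNDING_RESIDUE_WARN = 0.25


@dataclass(frozen=True)
class RiskSetTable:
    """Recovered integer risk-set data: one row per distinct event time."""

    times: tuple[float, ...]
    n: tuple[int, ...]  # at risk just before each event time
    d: tuple[int, ...]  # events at each event time
    c: tuple[int, ...]  # censored in [t_j, t_{j+1}) (last row: after t_k)
    n0: int | None = None  # initial sample size, when known/derivable
    c0: int = 0  # censored before the first event
    end_time: float | None = None  # horizontal extent of the source curve
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        k = len(self.times)
        if not (len(self.n) == len(self.d) == len(self.c) == k):
            raise ValueError("times, n, d, c must have equal length")
        for j in range(k):
            if self.d[j] < 1 or self.n[j] < self.d[j] or self.c[j] < 0:
                raise ValueError(f"invalid row {j}: n={self.n[j]}, d={self.d[j]}, c={self.c[j]}")
        for j in range(k - 1):
            if self.n[j + 1] != self.n[j] - self.d[j] - self.c[j]:
                raise ValueError(
                    f"bookkeeping identity violated at row {j}: "
                    f"{self.n[j]} - {self.d[j]} - {self.c[j]} != {self.n[j + 1]}"
                )

    @property
    def k(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.times, "n": self.n, "d": self.d, "c": self.c})

    def km_heights(self) -> np.ndarray:
        """Product-limit heights S(t_j) recomputed from (n_j, d_j)."""
        return np.cumprod([1.0 - dj / nj for nj, dj in zip(self.n, self.d)])

    def na_heights(self) -> np.ndarray:
        """Nelson-Aalen heights H(t_j) recomputed from (n_j, d_j)."""
        return np.cumsum([dj / nj for nj, dj in zip(self.n, self.d)])


@dataclass(frozen=True)
class IPDRecord:
    time: float
    status: int  # 1 event, 0 censored


@dataclass(frozen=True)
class PersonTimeTable:
    starts: tuple[float, ...]
    ends: tuple[float, ...]
    events: tuple[int, ...]
    person_time: tuple[float, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "start": self.starts,
                "end": self.ends,
                "events": self.events,
                "person_time": self.person_time,
            }
        )


# ---------------------------------------------------------------------------
# per-jump inversion
# ---------------------------------------------------------------------------


def jumps_and_ratios(curve: StepCurve) -> list[tuple[float, float, float]]:
    """``(t_j, J_j, ratio_j)`` per jump; for survival curves the ratio is
    the conditional survival S_j / S_{j-1}."""
    out = []
    prev = curve.start_height
    for t, s in zip(curve.times[1:], curve.heights[1:]):
        if s == prev:
            continue
        if curve.curve_type == "survival":
            if prev <= 0:
                raise ReconstructionError(f"curve reached 0 before the jump at t={t:.6g}")
            out.append((t, prev - s, s / prev))
        else:
            out.append((t, s - prev, s - prev))
        prev = s
    if not out:
        raise ReconstructionError("curve has no jumps")
    return out


def infer_n_km(S_prev: float, S_curr: float, d: int = 1) -> float:
    """Number at risk from successive Kaplan-Meier heights."""
    if d < 1:
        raise ValueError("d must be >= 1")
    if not (0 <= S_curr < S_prev <= 1):
        raise ReconstructionError(f"no jump: S {S_prev:.6g} -> {S_curr:.6g}")
    return d / (1.0 - S_curr / S_prev)


def infer_n_na(H_prev: float, H_curr: float, d: int = 1) -> float:
    """Number at risk from a Nelson-Aalen increment (exact: dH = d/n)."""
    if d < 1:
        raise ValueError("d must be >= 1")
    if H_curr <= H_prev or H_prev < 0:
        raise ReconstructionError(f"non-positive hazard increment: {H_prev:.6g} -> {H_curr:.6g}")
    return d / (H_curr - H_prev)


def infer_n_ci(CI_prev: float, CI_curr: float, d: int = 1) -> float:
    """Number at risk from successive cumulative-incidence (1 - S) heights."""
    if d < 1:
        raise ValueError("d must be >= 1")
    if not (0 <= CI_prev < CI_curr <= 1):
        raise ReconstructionError(f"non-increasing CI: {CI_prev:.6g} -> {CI_curr:.6g}")
    return d * (1.0 - CI_prev) / (CI_curr - CI_prev)


def _raw_n_d1(curve: StepCurve) -> tuple[list[float], list[float]]:
    """Per-jump n estimates under the d_j = 1 assumption."""
    times: list[float] = []
    raw: list[float] = []
    prev = curve.start_height
    for t, s in zip(curve.times[1:], curve.heights[1:]):
        if s == prev:
            continue
        if curve.curve_type == "survival":
            raw.append(infer_n_km(prev, s))
        elif curve.curve_type == "cumulative_hazard":
            raw.append(infer_n_na(prev, s))
        else:
            raw.append(infer_n_ci(prev, s))
        times.append(t)
        prev = s
    return times, raw


# ---------------------------------------------------------------------------
# multiplicity detection
# ---------------------------------------------------------------------------


def detect_multiplicities(
    raw_n_under_d1: Sequence[float],
    d_max: int = DEFAULT_D_MAX,
    rel_tol: float = 0.35,
) -> tuple[list[int], list[float], list[str]]:
    """Assign event multiplicities d_j from the d=1-first n estimates.

    A jump carrying d tied events yields a raw estimate at 1/d of its
    singleton-based neighbours.  Entries plausible as singletons against the
    monotone bounds of the raw sequence are accepted first; each remaining
    entry is then matched against a local monotone reference built from the
    nearest accepted neighbours (the later accepted value plus one per
    intervening event, capped by the earlier accepted value minus its
    events), choosing the d in 1..d_max that brings d * raw closest to the
    reference, subject to the feasibility constraints
    n_j <= n_{j-1} - d_{j-1} and n_j >= n_{j+1} + d_j.  Ties break toward
    smaller d.

    Returns (d, corrected_n, warnings).
    """
    raw = [float(v) for v in raw_n_under_d1]
    k = len(raw)
    if d_max < 1:
        raise ValueError("d_max must be >= 1")
    d = [0] * k
    corrected = [0.0] * k
    warnings: list[str] = []
    slack = 0.5  # absolute slack for feasibility, covers rounding noise

    # phase 1: accept entries plausible as singletons.  Any true n satisfies
    # n_j >= n_{j+i} + i >= raw_{j+i} + i, so a singleton's raw value must
    # dominate the backward running bound R_j = max_i (raw_{j+i} + i); an
    # entry carrying d tied events sits near 1/d of its true n and fails it.
    bound = [-math.inf] * k  # R_j
    for j in range(k - 2, -1, -1):
        bound[j] = max(raw[j + 1], bound[j + 1]) + 1.0
    accepted = [False] * k
    for j in range(k):
        left_ok = j == 0 or raw[j - 1] >= raw[j] - slack
        right_ok = raw[j] >= bound[j] - slack
        if left_ok and right_ok:
            accepted[j] = True
            d[j] = 1
            corrected[j] = raw[j]

    if not any(accepted):
        # pathological: nothing locally monotone; fall back to all-singleton
        for j in range(k):
            accepted[j] = True
            d[j] = 1
            corrected[j] = raw[j]
        warnings.append("no locally monotone reference found; assumed all d_j = 1")
        return d, corrected, warnings

    # phase 2: resolve flagged entries against accepted neighbours
    for j in range(k):
        if accepted[j]:
            continue
        m = _monotone_reference(j, accepted, corrected)
        prev_cap = math.inf
        for i in range(j - 1, -1, -1):
            if accepted[i]:
                prev_cap = corrected[i] - d[i] + slack
                break
        next_floor = -math.inf
        for i in range(j + 1, k):
            if accepted[i]:
                # corrected n of a later accepted entry bounds n_j from below
                next_floor = corrected[i]
                break

        best_d, best_err = None, math.inf
        for cand in range(1, d_max + 1):
            val = cand * raw[j]
            if val > prev_cap or val + slack < next_floor + cand:
                continue
            err = abs(val - m)
            if err < best_err - 1e-12:
                best_d, best_err = cand, err
        if best_d is None:
            # no feasible candidate: report the nearest-to-reference one
            best_d = min(range(1, d_max + 1), key=lambda cand: abs(cand * raw[j] - m))
            warnings.append(
                f"entry {j}: no multiplicity 1..{d_max} satisfies the monotone "
                f"constraints; using d={best_d} (raw n={raw[j]:.3f})"
            )
        elif best_err > max(2.0, rel_tol * m):
            warnings.append(
                f"entry {j}: best multiplicity d={best_d} is far from the local "
                f"reference ({best_d * raw[j]:.2f} vs {m:.2f})"
            )
        d[j] = best_d
        corrected[j] = best_d * raw[j]
        accepted[j] = True

    for w in warnings:
        logger.warning("detect_multiplicities: %s", w)
    return d, corrected, warnings


def _monotone_reference(j: int, accepted: Sequence[bool], values: Sequence[float]) -> float:
    """Local monotone reference for a flagged entry.

    n declines by exactly one per intervening singleton event when no
    censoring occurs, so the tightest unbiased guess is anchored on the
    nearest *later* accepted value plus one per index (censoring between
    would only raise the true value toward the left-hand cap); interpolating
    across a heavy censoring drop instead would bias the reference high.
    """
    k = len(values)
    li = next((i for i in range(j - 1, -1, -1) if accepted[i]), None)
    ri = next((i for i in range(j + 1, k) if accepted[i]), None)
    cap = values[li] - (j - li) if li is not None else math.inf
    if ri is not None:
        return min(values[ri] + (ri - j), cap)
    assert li is not None
    return cap


# ---------------------------------------------------------------------------
# table reconstruction
# ---------------------------------------------------------------------------


def reconstruct_risk_table(
    curve: StepCurve,
    marks: Sequence[CensorMark] = (),
    n0: int | None = None,
    reported_at_risk: Sequence[tuple[float, int]] = (),
    d_max: int = DEFAULT_D_MAX,
    time_tol: float = 0.0,
) -> RiskSetTable:
    """Full inversion pipeline: jumps -> d=1 inversion -> multiplicity
    detection -> integer rounding -> censoring by subtraction."""
    times, raw = _raw_n_d1(curve)
    d, corrected, warnings = detect_multiplicities(raw, d_max=d_max)
    k = len(times)

    # Repair pass: a jump carrying d tied events has the same height ratio
    # as one with (2d, 2n), so locally under-assigned multiplicities can
    # slip through — most visibly at or near the last event, where no later
    # jump constrains them.  Two hard floors expose them: the bookkeeping
    # identity requires n_j >= n_{j+1} + d_j, and the visible censor marks
    # inside (t_j, t_{j+1}) put a floor on c_j (marks can under-count tied
    # censoring, never over-count).  Walk backward raising d where a floor
    # is violated.
    mark_floor = [0] * k
    for m in marks:
        for j in range(k - 1, -1, -1):
            if m.t > times[j]:
                if j == k - 1 or m.t < times[j + 1]:
                    mark_floor[j] += 1
                break
    slack = 0.5
    for j in range(k - 1, -1, -1):
        raw_j = corrected[j] / d[j]
        nxt = corrected[j + 1] if j + 1 < k else 0.0
        while corrected[j] < nxt + d[j] + mark_floor[j] - slack:
            if d[j] >= d_max:
                warnings.append(
                    f"entry {j} (t={times[j]:.6g}): floor {nxt + d[j] + mark_floor[j]:.1f} "
                    f"unsatisfiable within d_max={d_max}"
                )
                break
            d[j] += 1
            corrected[j] = d[j] * raw_j
            warnings.append(
                f"entry {j} (t={times[j]:.6g}): multiplicity raised to d={d[j]} to "
                "satisfy bookkeeping/censor-mark floors"
            )

    n_int: list[int] = []
    high_residue = 0
    for j, v in enumerate(corrected):
        r = round(v)
        if abs(v - r) > ROUNDING_RESIDUE_WARN:
            high_residue += 1
            warnings.append(f"entry {j} (t={times[j]:.6g}): rounding residue {abs(v - r):.3f}")
        n_int.append(int(r))
    if k > 0 and high_residue > 0.10 * k:
        raise ReconstructionError(
            f"insufficient precision: {high_residue}/{k} inferred n values "
            "have rounding residue > 0.25 — use a vector (PostScript) source if possible"
        )

    # reported numbers at risk override inferred values at their exact times
    for t_anchor, n_anchor in reported_at_risk:
        tol = time_tol if time_tol > 0 else 1e-9 * max(abs(t) for t in times)
        for j, t in enumerate(times):
            if abs(t - t_anchor) <= tol:
                if n_int[j] != n_anchor:
                    warnings.append(
                        f"anchor at t={t_anchor:.6g} overrides inferred n "
                        f"{n_int[j]} -> {n_anchor}"
                    )
                n_int[j] = int(n_anchor)

    c: list[int] = []
    for j in range(len(times) - 1):
        cj = n_int[j] - d[j] - n_int[j + 1]
        if cj < 0:
            raise ReconstructionError(
                f"negative censoring count at t={times[j]:.6g}: "
                f"n={n_int[j]}, d={d[j]}, next n={n_int[j + 1]}"
            )
        c.append(cj)
    c.append(n_int[-1] - d[-1])  # everyone left after the last event is censored

    c0 = 0
    if n0 is not None:
        c0 = n0 - n_int[0]
        if c0 < 0:
            raise ReconstructionError(
                f"supplied n0={n0} is smaller than the inferred first risk set {n_int[0]}"
            )
    else:
        n0 = n_int[0]

    table = RiskSetTable(
        times=tuple(times),
        n=tuple(n_int),
        d=tuple(d),
        c=tuple(c),
        n0=n0,
        c0=c0,
        end_time=curve.end_time,
        warnings=tuple(warnings),
    )
    _check_marks_consistency(table, marks)
    return table


def _check_marks_consistency(table: RiskSetTable, marks: Sequence[CensorMark]) -> None:
    if not marks:
        return
    total_marks = len(marks)
    total_c = table.c0 + sum(table.c)
    if total_marks > total_c:
        logger.warning(
            "figure shows %d censor marks but subtraction yields %d censored; "
            "check calibration", total_marks, total_c,
        )


def infer_n0_lower_bound(curve: StepCurve, marks: Sequence[CensorMark] = (),
                         d: Sequence[int] | None = None) -> int:
    """Jumps (counted with multiplicity when known) plus visible censor marks.

    A lower bound only: censoring without a visible mark (tied "t+"
    censoring, unmarked trailing censoring) is invisible to this count.
    """
    jumps = curve.jumps()
    n_events = sum(d) if d is not None else len(jumps)
    return n_events + len(marks)


# ---------------------------------------------------------------------------
# individual-level data and person-time
# ---------------------------------------------------------------------------


def reconstruct_ipd(
    table: RiskSetTable,
    marks: Sequence[CensorMark] = (),
    censor_placement: str = "marks",
) -> list[IPDRecord]:
    """Expand a risk-set table into per-subject (time, status) records.

    Event records are placed at the event times with multiplicity d_j.
    Censored records are placed at the marked times when marks are supplied
    and consistent; otherwise uniformly within their interval.  Censoring
    deduced at "t_j+" (no mark within the interval) is placed immediately
    after the event time; censored subjects remaining after the last event
    are placed at the curve's end time.
    """
    if censor_placement not in ("marks", "uniform"):
        raise ValueError("censor_placement must be 'marks' or 'uniform'")
    k = table.k
    t_end = table.end_time if table.end_time is not None else table.times[-1]
    eps = 1e-9 * max(t_end, 1e-12)
    records: list[IPDRecord] = []

    # censored before the first event: uniform in (0, t_1)
    for i in range(table.c0):
        records.append(IPDRecord(table.times[0] * (i + 1) / (table.c0 + 1), 0))

    for j in range(k):
        tj = table.times[j]
        records.extend(IPDRecord(tj, 1) for _ in range(table.d[j]))
        cj = table.c[j]
        if cj == 0:
            continue
        t_next = table.times[j + 1] if j + 1 < k else t_end
        in_interval = [m.t for m in marks if tj + eps < m.t <= t_next + eps] \
            if censor_placement == "marks" else []
        if censor_placement == "marks" and marks and len(in_interval) != cj:
            if len(in_interval) > cj:
                logger.warning(
                    "interval [%.6g, %.6g): %d marks but %d censored by subtraction; "
                    "falling back to uniform placement", tj, t_next, len(in_interval), cj,
                )
                in_interval = []
        have_marks = censor_placement == "marks" and len(marks) > 0
        if have_marks and len(in_interval) == cj:
            records.extend(IPDRecord(t, 0) for t in sorted(in_interval))
        elif have_marks and len(in_interval) == cj - 1:
            # one censoring with no mark: the "t+" convention, tied just after the event
            records.append(IPDRecord(tj + eps, 0))
            records.extend(IPDRecord(t, 0) for t in sorted(in_interval))
        elif j == k - 1:
            # trailing censored subjects sit at the end of the drawn curve
            records.extend(IPDRecord(t_end, 0) for _ in range(cj))
        else:
            records.extend(
                IPDRecord(tj + (i + 1) / (cj + 1) * (t_next - tj), 0) for i in range(cj)
            )
    records.sort(key=lambda r: (r.time, -r.status))
    return records


def ipd_to_frame(records: Sequence[IPDRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {"time": [r.time for r in records], "status": [r.status for r in records]}
    )


def person_time(
    source: Sequence[IPDRecord] | RiskSetTable,
    boundaries: Sequence[float],
    marks: Sequence[CensorMark] = (),
) -> PersonTimeTable:
    """Events and person-time per half-open interval [a, b).

    Exact for individual-level input; a risk-set table is first expanded via
    :func:`reconstruct_ipd` so within-interval censoring contributes its
    placed times.  An event on a boundary counts in the interval starting
    there.
    """
    b = [float(x) for x in boundaries]
    if len(b) < 2 or any(y <= x for x, y in zip(b, b[1:])):
        raise ValueError("boundaries must be an increasing grid with >= 2 points")
    if b[0] != 0:
        raise ValueError("boundaries must start at 0")
    if isinstance(source, RiskSetTable):
        records = reconstruct_ipd(source, marks=marks)
    else:
        records = list(source)

    starts, ends, events, pt = [], [], [], []
    for a, bb in zip(b, b[1:]):
        starts.append(a)
        ends.append(bb)
        events.append(sum(1 for r in records if r.status == 1 and a <= r.time < bb))
        pt.append(sum(max(0.0, min(r.time, bb) - a) for r in records))
    return PersonTimeTable(tuple(starts), tuple(ends), tuple(events), tuple(pt))


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ValidationReport:
    max_abs_dev: float
    offending_times: tuple[float, ...]
    passed: bool

    def __str__(self) -> str:
        status = "pass" if self.passed else "FAIL"
        return f"reconstruction check: max |dS| = {self.max_abs_dev:.3g} [{status}]"


def validate_reconstruction(
    curve: StepCurve, table: RiskSetTable, noise_bound: float = 1e-6
) -> ValidationReport:
    """Recompute the estimator from (n_j, d_j) and compare to the curve."""
    if table.k == 0:
        return ValidationReport(0.0, (), True)
    if curve.curve_type == "survival":
        est = table.km_heights()
    elif curve.curve_type == "cumulative_hazard":
        est = table.na_heights()
    else:
        est = 1.0 - table.km_heights()
    jump_heights = []
    prev = curve.start_height
    for s in curve.heights[1:]:
        if s != prev:
            jump_heights.append(s)
            prev = s
    dev = np.abs(np.asarray(jump_heights) - est)
    offending = tuple(
        t for t, dv in zip(table.times, dev) if dv > noise_bound
    )
    return ValidationReport(float(dev.max()), offending, not offending)


def write_table_csv(table: RiskSetTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


def write_ipd_csv(records: Sequence[IPDRecord], path) -> None:
    ipd_to_frame(records).to_csv(path, index=False)
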