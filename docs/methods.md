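# Methods

## The recovery problem

A published non-parametric survival figure is a lossy summary of the study
data: a right-continuous step function S(t) (or its complement, or a
cumulative hazard H(t)), possibly annotated with censoring marks and a
numbers-at-risk row.  `kmrecover` inverts this summary.  The inversion rests
on the product-limit structure of the Kaplan–Meier estimator,

S(t_j) = Π_{i ≤ j} (1 − d_i / n_i),

so the ratio of successive step heights is 1 − d_j/n_j and

n_j = d_j / (1 − S(t_j)/S(t_{j−1})).

For the Nelson–Aalen estimator H(t_j) = Σ d_i/n_i the increment gives
n_j = d_j / ΔH_j with no approximation, and for cumulative incidence
CI = 1 − S, n_j = d_j (1 − CI_{j−1}) / (CI_j − CI_{j−1}).  Censoring counts
follow by subtraction from n_{j+1} = n_j − d_j − c_j.  The package recovers
the risk-set table (t_j, n_j, d_j, c_j), expands it to individual (time,
status) records, and aggregates events and person-time on any interval
grid.

## Vector extraction and calibration

PostScript describes a page as geometric primitives in printer points
(72/inch); coordinates exported from PDF viewers carry three decimals, so a
curve on a 115-point axis is resolved to ΔS ≈ 1e−5 — far below one
integer's worth of n even for trials with thousands of subjects, and with
no digitizer in the loop the extraction is deterministic.  The extractor
interprets the path-construction subset of the language (`moveto`/`lineto`
and relatives, `stroke`, `gsave`/`grestore`, `translate`/`scale`/
`rotate`/`concat`, stroke attributes), tracking the current transformation
matrix so transformed files come out in true device points.  Everything
else is counted and skipped; `curveto` is flattened to its chord with a
warning because a genuine step curve contains no curves; binary input is
rejected outright.  Device y-orientation is *not* normalized: users supply
two anchors per axis (e.g. "device y 360 is S = 0, device y 252 is S = 1")
and a negative y-scale handles from-top coordinates automatically.
Anchors are deliberately manual — published figures identify their
landmarks to a human, and automatic tick detection is a different, fragile
problem.

## Step-function assembly

Published figures draw step functions in surprisingly baroque ways: runs
split into dozens of collinear sub-segments, pieces overdrawn repeatedly,
or one element per subject (a style that, as the package's per-observation
rendering dialect emulates, discloses each individual observation).  The
builder classifies calibrated segments as horizontal or vertical within
tolerance, merges collinear overlaps, unions stacked sub-jumps at one time,
and separates censor marks: a short vertical *crossing* a run's height
interior to the run is a tick; a zero-length element on a run is a censor
dot; a dot sitting exactly on a step corner belongs to the curve (that is
how per-observation renderings draw event subjects).  Marks coinciding with
jump times are excluded — censoring tied just after an event is invisible
by convention and is recovered later by subtraction.

Tolerances derive from the rounding model: with k-decimal coordinates each
coordinate is off by at most 0.5·10⁻ᵏ points, so the time-merge tolerance
is 10⁻ᵏ/|x-scale| and the height tolerance 2·10⁻ᵏ/|y-scale| (defaults;
both configurable).  Small monotonicity violations — rounding artefacts
observed in real files — are repaired by isotonic regression
(pool-adjacent-violators, via `scipy.optimize.isotonic_regression`) in the
curve's monotone direction; any single violation beyond the noise bound
aborts with a diagnostic, since it indicates a wrong curve type or
calibration rather than rounding.

## Multiplicity detection and repair

The inversion first assumes a single event per jump.  A jump carrying d
tied events then yields an inferred n at 1/d of its true value, standing
out from the otherwise decreasing sequence.  Detection is local and
sequential, not a global search:

1. **Singleton screening.**  Any true n satisfies n_j ≥ raw_{j+i} + i for
   every later raw estimate (each event removes at least one subject), so
   an entry is accepted as a singleton only if its raw value dominates the
   backward running bound max_i (raw_{j+i} + i).  An entry at 1/d of truth
   fails this for any realistic configuration.
2. **Resolution.**  Each flagged entry chooses d ∈ {1..d_max} (default 5)
   bringing d·raw closest to a local monotone reference — the nearest later
   accepted value plus one per intervening event, capped by the nearest
   earlier accepted value minus its events — subject to the feasibility
   constraints n_j ≤ n_{j−1} − d_{j−1} and n_j ≥ n_{j+1} + d_j.  Ties break
   toward smaller d.  The reference is right-anchored rather than an
   interpolation because censoring concentrated between two events would
   bias a midpoint upward.
3. **Floor repair.**  A backward pass enforces two sound floors that expose
   under-assigned multiplicities: the bookkeeping identity
   n_j ≥ n_{j+1} + d_j, and c_j ≥ (visible censor marks in (t_j, t_{j+1})) —
   marks can under-count tied censoring but never over-count.  Where a
   floor fails, d_j is raised (n_j = d·raw_j) until it holds.

Inferred n values are rounded to integers; a fractional residue above 0.25
triggers a warning, and more than 10% such rows aborts with a
recommendation to use a vector source.  Reported numbers at risk, when
supplied, override inferred values at their exact times.

**Identifiability limit.**  A tied *final* event is ambiguous from heights
alone: the ratio 1 − d/n is invariant under (d, n) → (2d, 2n) and no later
jump constrains it.  Count-preserving censoring renderings (one mark per
censored subject, the style the per-observation dialect emulates) resolve
it through the floor repair; tick marks collapse tied censoring times and
cannot always do so.  Under the validation battery's conditions this
affects about 2% of studies when marks are drawn as ticks, and none when
censoring is drawn per observation.

## Individual records and person-time

Event records are placed at the event times with multiplicity d_j.
Censored records take their marked times when marks are present and
consistent; one missing mark in an interval is attributed to censoring
immediately after the event ("t+", offset by 1e−9 of the time range);
otherwise censored records are spaced uniformly at t_j + i/(c_j+1)·(t_{j+1}
− t_j), and subjects remaining after the last event sit at the end of the
drawn curve.  Person-time uses half-open intervals [a, b) (an event on a
boundary counts in the interval starting there) and is the exact per-record
sum of exposure.

## Precision analysis

Heights are recovered essentially exactly; the number at risk is the
*reciprocal* of a jump and inherits magnified error.  For a cumulative
incidence curve on a 0–axis_max% axis the estimate has the form
n = [F(c−d) − (b−d)] / (a−b) with F = 100/axis_max (default 20), where a, b
are adjacent curve heights and c, d the axis landmarks.  With independent
uniform rounding errors of full width r per coordinate (σ_e = r/√12), the
composite numerator error has variance (F² + (F−1)² + 1)σ_e², the
denominator 2σ_e², covariance σ_e² through the shared b, and the delta
method gives CV² = σ₁²/μ₁² + σ₂²/μ₂² − 2σ₁₂/(μ₁μ₂), exactly linear in r.
At the reference magnitudes μ₁ = 2000 points, μ₂ = 0.5 points and
two-decimal rounding (r = 0.01) this evaluates to CV ≈ 0.816%; a 10⁶-draw
Monte-Carlo simulation of the four rounding errors is the package's
independent check (agreement ~0.01% relative) and guards the analytic
formula in the acceptance script.  Resolution formulas: one pixel
(1/(dpi·inches)) for raster; one coordinate quantum (1/(points·10ᵏ)) for
vector.

## The synthetic generator

`synthetic` is the fixture engine: exponential event times with hazard 0.1
per time unit (default); censoring either none, uniform on (0, 20) (random
loss to follow-up of roughly the event-time scale), or administrative with
staggered entry — four equal calendar cohorts sharing one closing date, so
censored times cluster at exactly four follow-up durations, reproducing the
end-of-follow-up censoring spikes of multi-year recruitment trials.  Tied
event times are forced by rounding times up to a discrete reporting grid.
Estimators (product-limit, Nelson–Aalen, incidence complement) are computed
from first principles with ties summed and tied censoring processed after
events; `lifelines` serves as an independent cross-check in the test suite
only.

The renderer emits only operators the extractor interprets, rounds
coordinates to a configurable number of decimals, and supports three
dialects: `segments` (one minimal alternating H/V path), `elaborate` (every
piece split into ≥3 collinear sub-segments plus a full overdraw, emulating
post-processed figures that spend thousands of segments on a few dozen
events), and `per_observation_dots` (one element per subject: stacked
vertical sub-segments for events, zero-length dots for censored subjects).
Its default page geometry is a compact 144×108-point plot box; the
validation battery renders on a 4-inch (288-point) y-axis typical of
full-size published figures, where the worst-case rounding error in an
inferred n (~n₀²·10⁻³/H points) stays below one half for n₀ ≤ 200.

## Validation battery and what it shows

The battery fixes 200 studies (seeded): n₀ uniform on {10..200},
exponential events, alternating uniform and administrative censoring, tie
grid 0.25/(n₀·hazard) so that multiplicities are occasional — the regime
the detection logic is designed for, where tied jumps stand out against
singleton neighbours.  Censoring is drawn per observation (the
count-preserving style) in all three curve dialects at 3-decimal rounding.
Under these conditions recovery of (t_j, n_j, d_j, c_j) is exact in
600/600 renderings, Nelson–Aalen inversion recovers every n_j exactly, and
the bookkeeping and jump-growth invariants hold throughout.  At 2-decimal
rounding roughly half the studies fail integer recovery — measured and
reported here, not asserted — which is why the tool insists on vector
sources for precision work.

Passing the battery shows the pipeline is internally exact under its
rounding model; it does not certify real figures, whose exporters may use
unsupported operator dialects, overlapping arms, raster composites, or
pervasively tied data (e.g. heavily discretized follow-up), all of which
surface as diagnostics rather than silent errors.

## Numerical and design choices

- Coordinates are transformed at path-construction time (true PostScript
  semantics), so transform operators after a path is built do not move it.
- Dot snap tolerance 1e−6 points; group connectivity tolerance 0.05 points.
- The origin vertex requires a drawn run or dot before the first jump;
  per-observation renderings without one start the curve at t = 0.
- Half-open person-time intervals; censoring tied at an event is processed
  after the event everywhere (estimation, counting, reconstruction).
- Exit codes: 0 success, 1 usage error, 2 data/validation failure; every
  CLI run writes a JSON provenance record beside its first output.
- Seeds: one integer seed fully determines a simulated study and the
  Monte-Carlo CV check; identical configuration and seed give byte-identical
  CSV output.
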