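# kmrecover

Recover the raw data behind published non-parametric survival curves.

Researchers often need the patient-level time-to-event data underlying a
published Kaplan–Meier or cumulative-incidence figure — for meta-analysis,
for time-specific event rates, or to re-analyse a trial — and cannot obtain
it from the authors.  `kmrecover` reconstructs it from the figure itself.
Instead of digitizing a raster image by hand, it reads the PostScript text
of a vector figure: the stored coordinates carry three decimal places of a
printer point, a resolution some 200 times finer than a 300-dpi bitmap, and
the extraction is exactly replicable (no observer variation).

## What it computes

For a right-continuous step curve with heights S(t_j) at the distinct event
times t_1 < … < t_k, the product-limit structure of the Kaplan–Meier
estimator gives the ratio of successive heights as the conditional survival
probability, so the number at risk follows from the heights alone:

    S(t_j) / S(t_{j-1}) = 1 − d_j / n_j        ⇒        n_j = d_j / (1 − S(t_j)/S(t_{j-1}))

For a Nelson–Aalen cumulative hazard curve, ΔH_j = d_j / n_j exactly; for a
cumulative incidence curve CI = 1 − S, n_j = d_j (1 − CI_{j-1}) / (CI_j −
CI_{j-1}).  Event multiplicities d_j are found by first assuming d_j = 1
everywhere: a jump carrying d tied events then yields an inferred n at 1/d
of its neighbours and stands out from the otherwise monotone sequence.
Censoring counts follow by subtraction from the bookkeeping identity
n_{j+1} = n_j − d_j − c_j, and individual records and person-time per
interval are assembled from the result.  A delta-method error analysis
quantifies how coordinate rounding propagates into the recovered counts.

The pipeline: `ps_extract` (PostScript text → line segments/dots, with full
graphics-transform tracking) → `calibration` (device points ↔ (t, S) via two
axis anchors) → `step_builder` (clean step function + censor marks, tolerant
of redundant and per-observation renderings) → `reconstruct` (risk-set
table, IPD, person-time).  `synthetic` simulates ground-truth studies and
renders them back to PostScript so every step is testable end to end, and
`precision` implements the resolution/CV analysis.

## Worked example

The classic 11-subject AML "maintained" arm (times 9, 13, 13, 18, 23, 28,
31, 34, 45, 48, 161; status 1 = relapse, 0 = censored) is embedded as a
fixture.  Estimate its survival curve, render it to PostScript, and run the
whole recovery:

```python
import kmrecover as kr

ipd = [kr.IPDRecord(t, s) for t, s in kr.load_aml_maintained()]
curve, truth = kr.km_estimate(ipd)
marks = kr.marks_from_ipd(ipd, curve, kind="tick")
spec = kr.RenderSpec(decimals=3, censor_style="tick")
ps = kr.render_postscript(curve, marks, spec, risk_table=truth)

result = kr.recover_from_postscript(ps, spec.calibration(curve), "survival")
print("jumps:", [(t, round(j, 5)) for t, j in curve.jumps()][:3])
print("n:", result.table.n)
print("c:", result.table.c)
print("lower bound on n0:", kr.infer_n0_lower_bound(result.curve, result.marks))
```

prints

```
jumps: [(9.0, 0.09091), (13.0, 0.09091), (18.0, 0.10227)]
n: (11, 10, 8, 7, 5, 4, 2)
c: (0, 1, 0, 1, 0, 1, 1)
lower bound on n0: 10
```

Reading it: the first two jumps equal 1/11, so 11 subjects were initially at
risk; the third jump is larger (0.10227 = 1/11 + (1/8)(1/11)), which reveals
a censored subject between the second and third event even though no tick
marks it — by convention it was censored immediately after the event at
t = 13 ("13+").  Seven jumps plus three visible ticks bound n0 from below
by 10; the full reconstruction recovers all 11 subjects, 7 events and 4
censorings.  `kr.reconstruct_ipd(result.table, result.marks)` expands the
table back into the 11 individual records, and `kr.person_time` aggregates
events and exposure over any interval grid.

The same workflow runs from the shell:

```sh
recover simulate --n 50 --seed 1 --out ipd.csv
recover render --ipd ipd.csv --dialect segments --out fig.ps --out-curve curve.csv
recover extract fig.ps --out segments.csv
recover reconstruct --curve curve.csv --curve-type km --n0 50 --out-table table.csv
recover roundtrip --n 50 --seed 1        # simulate → render → recover, verify exact
```

Digitizer users can skip the PostScript stage entirely: `recover
reconstruct` accepts any (t, S) table as `--curve`.

## Limitations

Raster images are out of scope (use a digitizer and the CSV entry point);
PDF must be exported to PostScript text first.  Multiplicity detection
assumes tied events are occasional among singleton jumps, as the underlying
reasoning requires; a tied *final* event is provably ambiguous from heights
alone and is resolved only when the figure's censor marks preserve counts.
See `docs/methods.md` for the full model, tolerances and design choices.
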