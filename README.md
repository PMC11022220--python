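# evdassess

Objective skill assessment for simulator-based **external ventricular drain
(EVD) placement** training, paired with a classical **spatial-reasoning**
(same/different mental-rotation) test.

EVD placement asks a trainee to study a stack of 2D CT slices, form a 3D
mental model of the ventricular system, and then drive a catheter from a
skull entry point along a planned direction and depth into a ventricle. This
package scores that targeting task with purely geometric metrics, emulates
the consultant's 1–6 subjective ranking, scores the companion
Shepard–Metzler same/different sessions, and correlates the two resulting
speed+accuracy performance indices across a cohort — the analysis chain used
to argue that simulator targeting skill reflects a common 3D spatial
reasoning ability.

## The metrics

With the ventricular target approximated as a sphere of radius *R* and the
catheter path a segment (entry point, unit direction, depth):

- **Engagement** *E* — length of the path's intersection with the target
  ball; for a through-pass, the chord with *R² = (E/2)² + d²*.
- **Closest approach** *d* — minimum distance from the target centre to the
  clamped segment (a drain that stops short is scored at its tip).
- **Distance metric** *D = R − √(R² − d²)* — 0 for a dead-centre pass,
  rising steeply to *R* at the wall (inside the target,
  *1 − D/R = √(1 − d²/R²)*, a Lorentz-transformation form). Past the wall
  the square root is continued as an imaginary number: the non-zero
  imaginary part flags the miss and |D| = d for every d ≥ R, so |D| is
  continuous and monotone in d.
- **Angulation** — unsigned angles between actual and ideal directions
  projected into the sagittal and coronal planes.
- **MDM** — signed distance from the catheter tip to the nearest ventricle
  wall (negative inside).
- **Index of accuracy (IA)** — the expert's 1–6 rank (1 best), emulated
  from explicit thresholds on the clauses "well within the ventricle",
  "close to the wall", "slightly outside", "wide miss", "good approach
  angle".

Per-participant performance on each task is an accuracy component in [0, 1]
divided by a mean completion time (accuracy per second); the cohort-level
association between the EVD index and the spatial-reasoning index is a
Spearman correlation with a seeded bootstrap confidence interval.

Because no trainee data are distributable, the package ships a synthetic
cohort generator in which a single latent spatial ability drives both tasks
(miss distances and task times on the simulator; error rates, a
response-bias-corrupted guessing stage, and reaction times on the
same/different test). Every analysis is exercised end-to-end against it.

## Worked example

```bash
evdassess simulate --seed 7 --out fixture
evdassess score-evd fixture/evd_trials.csv --out measures.csv
evdassess score-smr fixture/smr_trials.csv --out-dir smr
evdassess analyze --measures measures.csv --summaries smr/smr_summaries.csv \
                  --out-dir analysis --seed 7
evdassess report --performance analysis/performance.csv \
                 --correlation analysis/correlation.json --out-dir report
```

`measures.csv` holds one row per targeting trial:

```
participant_id,trial_id,engagement_mm,d_mm,D_real_mm,D_imag_mm,D_mag_mm,outside,...,ia
P001,T01,0,12.851,10,-8.07146,12.851,True,...,3
P001,T02,12.7572,7.70153,3.62141,0,3.62141,False,...,1
```

Trial T01 missed (closest approach 12.85 mm > R = 10 mm): engagement is 0,
the metric's imaginary part −8.07 mm flags the miss, |D| equals the miss
distance, and the emulated expert rank is 3 (slightly outside, good angle).
Trial T02 passed 7.7 mm off-centre through the target: a 12.8 mm engagement,
a real D of 3.6 mm, rank 1.

`smr/smr_report.json` (same seed) shows the session-level structure:
the population says "same" to different pairs 167 times versus 75 reversed
(the classic "same" bias), correct "same" responses run ~2.15 s slower
than correct "different" ones, RT rises with each pair's population index
of difficulty (positive slopes for both truth classes), and errors
anti-correlate with mean RT (Spearman −0.42): the speed–accuracy tradeoff.

`report/report.txt` then gives the headline cohort result:

```
Cohort of 25 participants
EVD-vs-spatial correlation (spearman): 0.727  95% CI [0.433, 0.887]
```

i.e. in this coupled synthetic cohort, trainees who score higher on the
spatial-reasoning test also place the EVD faster and more accurately.

## Layout

- `src/evdassess/geometry.py` — trajectories, target spheres, E, d, D, angles, MDM
- `src/evdassess/rubric.py` — feature thresholds and the 1–6 IA emulation
- `src/evdassess/smr.py` — same/different session scoring and regressions
- `src/evdassess/performance.py` — composite indices, bootstrap correlation
- `src/evdassess/cohort.py` — latent-ability synthetic cohort generator
- `src/evdassess/io.py`, `cli.py`, `pipeline.py` — formats, CLI, stage plumbing
- `docs/methods.md` — models, assumptions, parameter choices, limitations
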