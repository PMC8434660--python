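# gaitpath

Markerless gait analysis from a single RGB-D camera, for clinicians and
movement scientists who need spatiotemporal gait parameters outside the
motion-capture laboratory — rehabilitation clinics, home monitoring of
post-stroke hemiparesis, longitudinal follow-up.

A subject walks straight toward a depth sensor along a short walkway. From
the sensor's 25-joint skeletal stream, `gaitpath`:

1. resamples the jittery ~30 FPS stream onto a uniform grid and low-pass
   filters it (Butterworth, 3rd order, 10 Hz, zero-phase);
2. delimits a **virtual gait analysis path**: the analysis window opens
   when the body center of mass comes within 4.2 m of the sensor and
   closes at 1.5 m — a 2.7 m path compatible with domestic spaces;
3. segments steps by **binary depth thresholding of the ankle
   trajectories**: a frame is *stationary* (stance) when the ankle depth
   changes less than 2 cm from the previous frame, *in movement* (swing)
   otherwise; the depth is held constant during stance, and held-depth
   differences between opposite-leg contacts are the step lengths;
4. estimates, per body side where applicable: step length [m], stance
   duration [% of gait cycle], double support duration [s], mean velocity
   [m/s], cadence [steps/min], step width [m], and the mediolateral and
   vertical peak-to-peak sway of the hip-midpoint COM proxy [m];
5. provides the full method-agreement battery for validating one system
   against another (Kolmogorov–Smirnov gate, paired Wilcoxon with effect
   size r = |Z|/√n, Spearman, ICC(2,1), Bland–Altman limits of agreement
   mean ± 1.96 SD, percentage error ACC% = |REF−CUR|/|REF|), plus
   Spearman correlations against Timed Up and Go (TUG) times;
6. renders radar charts (min-max normalized over a session collection) and
   overhead step plots.

A first-class synthetic gait generator produces skeletal recordings with
closed-form ground truth (configurable step lengths, cadence, stance
fractions, step width, sway amplitudes, 2–4 mm depth noise, frame-rate
jitter), so the entire pipeline is testable with no external data.

## Worked example

Simulate a severely impaired hemiparetic walk (short slow steps, prolonged
stance) and analyze it:

```python
from gaitpath import SessionMeta, analyze_sequence, simulate_gait
from gaitpath.synthetic import impaired_pattern

spec = impaired_pattern(seed=7)                    # 0.15/0.23 m steps, 46 steps/min
seq, truth = simulate_gait(spec)                   # 25-joint stream + ground truth
res = analyze_sequence(seq, meta=SessionMeta(subject_id="S01", paretic_side="left"))
p = res.parameters
print(f"window       : [{res.window.t_i:.2f}, {res.window.t_f:.2f}] s "
      f"({res.window.path_length_m:.1f} m path)")
print(f"step length  : paretic {p.step_length_m['paretic']:.3f} m, "
      f"non-paretic {p.step_length_m['non_paretic']:.3f} m")
print(f"stance       : paretic {p.stance_pct['paretic']:.1f} %, "
      f"non-paretic {p.stance_pct['non_paretic']:.1f} %")
print(f"double supp. : {p.double_support_s:.2f} s")
print(f"velocity     : paretic {p.mean_velocity_mps['paretic']:.2f} m/s, "
      f"non-paretic {p.mean_velocity_mps['non_paretic']:.2f} m/s")
print(f"cadence      : {p.cadence_spm:.1f} steps/min")
print(f"step width   : {p.step_width_m:.2f} m")
print(f"ML / V sway  : {p.ml_sway_m:.3f} / {p.v_sway_m:.3f} m")
```

prints

```
window       : [5.50, 24.07] s (2.7 m path)
step length  : paretic 0.153 m, non-paretic 0.227 m
stance       : paretic 89.1 %, non-paretic 88.9 %
double supp. : 0.97 s
velocity     : paretic 0.12 m/s, non-paretic 0.18 m/s
cadence      : 45.2 steps/min
step width   : 0.16 m
ML / V sway  : 0.133 / 0.050 m
```

Reading: the subject needs 18.6 s to cross the 2.7 m path, taking many
short steps (cadence 45, step lengths 0.15/0.23 m) with the paretic (left)
side clearly shorter and slower; stance near 89 % of the cycle and almost
a second of double support per step indicate severe walking difficulty,
and the 13 cm mediolateral sway reflects the compensatory lateral
weight shifting. The recovered values match the generator's ground truth —
note that stance reads a few points above the nominal 86/85 % stance
fraction because the 2 cm/frame detector, by construction, latches stance
slightly early and releases it slightly late (see `docs/methods.md`).

The same pipeline is available from the shell:

```bash
gaitpath simulate --seed 7 --out walk.csv --truth-out truth.json
gaitpath analyze walk.csv --paretic-side left --out results.json --step-plot steps.svg
gaitpath compare reference_params.csv candidate_params.csv --out agreement.json
```

## Layout

```
src/gaitpath/
  io_skeleton.py   versioned skeleton CSV/JSON dialects, containers
  preprocess.py    cubic resampling + zero-phase Butterworth
  vgap.py          COM proxies, distance series, analysis window
  segmentation.py  ankle binarization, debouncing, event extraction
  parameters.py    the eight gait parameters, per-side assembly
  agreement.py     two-system statistics battery, TUG correlations
  synthetic.py     gait generator, closed-form ground truth, presets
  viz.py           radar charts and overhead step plots
  cli.py           `gaitpath analyze | simulate | compare | radar`
docs/methods.md    model, numerical conventions, generator details
tests/             unit + property + acceptance suites (brute-force oracles)
```
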