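# ventriq

Reduced-order left-ventricular mechanics with gradient-boosted tree
surrogates for pressure, volume, and regional wall stress.

Finite-element models of the beating heart take hours to days per
simulation, which rules them out for real-time uses such as device
design iteration or bedside monitoring.  A practical alternative is an
*emulator*: run the mechanistic model across a designed sweep of
material parameters once, then train a fast statistical model on the
results.  `ventriq` implements that workflow end to end for cardiac
mechanics researchers and surrogate-modeling practitioners — with the
expensive finite-element stage replaced by desk-scale reduced-order
simulators built on the same constitutive equations, so the entire
pipeline runs in minutes on one CPU.

## The models

**Passive myocardium** is a Holzapfel–Ogden-type orthotropic
hyperelastic material,

```
Ψ_dev = a/(2b) e^{b(I₁−3)} + Σ_{i=f,s} a_i/(2b_i) [e^{b_i(I₄ᵢ−1)²} − 1]
      + a_fs/(2b_fs) [e^{b_fs I₈fs²} − 1],       Ψ_vol = (1/D)[(J²−1)/2 − ln J]
```

with isochoric invariants of C = FᵀF along the fiber (f₀) and sheet (s₀)
directions, and tension-only fiber/sheet reinforcement.

**Active contraction** adds a Hill-type length- and calcium-dependent
fiber tension `T0 = Tmax · Ca₀²/(Ca₀² + ECa₅₀²) · Ct(t)` with a
raised-cosine twitch `Ct`, length-dependent calcium sensitivity
`ECa₅₀ = (Ca₀)max/√(e^{B(l−l₀)} − 1)`, sarcomere length
`l = l_R √(2E_ff + 1)`, and linear relaxation duration `t_r = m·l + b`.

**Truth models.** For pressure/volume, each ventricle is a thick-walled
incompressible sphere of this material coupled into a closed-loop 0-D
circulation (diode valves, three-element Windkessel afterloads, venous
compartments); each cardiac cycle is reported at 401 time points.  For
wall stress, a truncated prolate-spheroid shell is inflated to the
end-diastolic pressure by a global energy balance and fiber (S11),
cross-fiber (S22) and shear (S12) Cauchy stresses are evaluated at 576
endocardial element centroids with a ±60° transmural helix fiber field.

**Surrogate.** XGBoost regression (`gbtree`, squared-error objective),
tuned by exhaustive 3×3×3 grid search (learning rate × trees × depth)
with 3-fold cross-validation grouped by cycle/model so no cycle leaks
across folds, and scored by per-test-group R² and MAE (mean ± SD).

## Worked example

Simulate one cardiac cycle at mid-range active parameters and summarize
the LV trace:

```python
import dataclasses
import numpy as np
from ventriq import reduced_lv as rl
from ventriq.config import paper2019
from ventriq.surrogate import pv_summary

cfg = paper2019()
ap = dataclasses.replace(cfg.pv.active_base, l0=1.9, t0=0.16, Tmax=120.0)
lv = dataclasses.replace(cfg.lv_spec(), active=ap)
rv = dataclasses.replace(cfg.rv_spec(), active=ap)
trace, _ = rl.simulate_cycle(lv, rv, cfg.pv.circulation)
print(f"samples per cycle : {trace.n}")
summary = pv_summary(trace)
for qty, unit in (("P", "mmHg"), ("V", "ml")):
    s = summary[qty]
    print(f"{qty}: min {s['min']:7.1f} {unit}, max {s['max']:7.1f} {unit}, "
          f"t(max) {s['time_to_max']:.3f} s, max d{qty}/dt {s['max_derivative']:8.1f} {unit}/s")
print(f"stroke volume     : {trace.stroke_volume:.1f} ml")
print(f"stroke work       : {-np.trapezoid(trace.P, trace.V):.0f} mmHg*ml")
```

```
samples per cycle : 401
P: min    -3.5 mmHg, max   141.3 mmHg, t(max) 0.098 s, max dP/dt   7632.6 mmHg/s
V: min    48.1 ml, max   140.2 ml, t(max) 0.800 s, max dV/dt    390.3 ml/s
stroke volume     : 92.1 ml
stroke work       : 8881 mmHg*ml
```

The ventricle fills to 140 ml under a 15 mmHg preload, ejects 92 ml
against the arterial load with a 141 mmHg systolic peak, and the
trace lands on the fixed 401-point grid used by the surrogate datasets.
The enclosed pressure–volume loop area (stroke work, ≈8900 mmHg·ml
≈ 1.2 J) is positive, i.e. the chamber does net work on the blood.

Full experiments run from the command line:

```bash
ventriq run-pv     --out runs/pv     --seed 1   # 80 cycles, 77/3 split, P & V surrogates
ventriq run-stress --out runs/stress --seed 1   # 120 models, 100/20 split, S11/S22/S12
```

Each writes the train/test CSVs (with a units comment line and a JSON
sidecar recording seeds, ranges and unit mappings), the fitted models,
per-group score reports, gain-based feature-importance tables, and a
run manifest.  A typical `run-pv` report (seed 1):

```
P_LV: R2 0.949 +/- 0.021, MAE 2.456 +/- 0.247 (3 groups)
V_LV: R2 0.978 +/- 0.002, MAE 3.129 +/- 0.195 (3 groups)
```

## Layout

```
src/ventriq/constitutive.py   passive + active material law
src/ventriq/reduced_lv.py     PV simulator, ED stress generator, datasets
src/ventriq/doe.py            Latin hypercube + maximin design
src/ventriq/surrogate.py      XGBoost fit/grid-search/metrics/importance
src/ventriq/pipeline.py       experiment orchestration and artifacts
src/ventriq/cli.py            `ventriq` command line
docs/methods.md               model assumptions, calibration, limitations
```
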