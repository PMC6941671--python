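# Methods

## Scope and model structure

`ventriq` studies how well a gradient-boosted tree emulator can stand in
for a mechanistic simulator of left-ventricular (LV) mechanics.  The
pipeline has three stages:

1. a **material model** of passive and actively contracting myocardium
   evaluated at material points;
2. two **reduced-order truth models** built on that material law — a
   closed-loop two-ventricle pressure–volume (PV) simulator and an
   end-diastolic (ED) wall-stress generator — which produce the training
   and test data;
3. an **XGBoost surrogate** trained per output quantity with an
   exhaustive hyperparameter grid search under grouped cross-validation,
   evaluated by per-group R² and MAE.

## Constitutive model

Passive myocardium is a Holzapfel–Ogden-type orthotropic hyperelastic
solid (kPa):

```
psi_dev = a/(2b) exp[b(I1−3)]
        + Σ_{i=f,s} a_i/(2b_i) {exp[b_i (I4i−1)²] − 1}
        + a_fs/(2b_fs) {exp[b_fs I8fs²] − 1}
psi_vol = (1/D) [(J²−1)/2 − ln J]
```

The deviatoric part is evaluated on isochoric invariants
(`C̄ = J^{−2/3} C`) and the Cauchy stress uses a deviatoric projection,
so the reference state is exactly stress-free.  Fiber (`I4f`) and sheet
(`I4s`) terms engage only in tension (`I4 > 1`): fibers do not stiffen in
compression.  `D` is the volumetric penalty constant as printed
(0.2 MPa⁻¹ in the stress study); all generator kinematics are exactly
isochoric, so the volumetric term never contributes there.

Active fiber tension follows a Hill-type length- and calcium-dependent
twitch:

```
T0 = Tmax · Ca0² / (Ca0² + ECa50²) · Ct(t)
ECa50 = Ca0max / sqrt(exp[B(l − l0)] − 1),   l = lR sqrt(2 Eff + 1)
Ct = (1 − cos ω)/2,  ω = πt/t0 (upstroke), π(t−t0+tr)/tr (relaxation)
tr = m_relax · l + b_relax
```

`T0 = 0` for `l ≤ l0` (the published ECa50 expression is singular there;
`l0` is by definition the zero-tension length) and for `t ≥ t0 + tr`.
The total Cauchy stress adds `T0 f̂⊗f̂` along the deformed unit fiber
direction — the simplest objective embedding of a scalar fiber tension.

Closed-form stresses are verified against an independent oracle that
numerically differentiates the strain energy with respect to the
deformation gradient (relative tolerance 1e-5 on 100 random states), and
against numerical objectivity checks `σ(QF) = Qσ(F)Qᵀ`.

## Pressure–volume truth model

Each ventricle is a thick-walled incompressible sphere.  A wall layer at
reference radius `R0` moves to `r` with `r³ = ri³ + R0³ − Ri³`; the local
deformation gradient is `diag(λ⁻², λ, λ)` with `λ = r/R0` and fiber and
sheet directions tangential.  Cavity pressure follows from radial
equilibrium,

```
P = ∫_{ri}^{ro} (σ_ff + σ_ss − 2σ_rr)/r dr ,
```

by midpoint quadrature over 5 transmural layers.  The integrand is
invariant to the indeterminate incompressibility pressure.  An
energy-balance oracle (`P = dW/dV_cavity` for passive inflation, relative
tolerance 1e-3) checks the implementation through an independent route.

The two ventricles close into a 0-D circulation: diode valves, a
three-element Windkessel per outflow (characteristic impedance,
peripheral resistance, arterial compliance), and systemic/pulmonary
venous compartments, so right-ventricular function sets LV preload.  The
six-dimensional state (two volumes, four compartment pressures) is
advanced by fixed-step RK4 (numba-compiled; four sub-steps per output
interval, dt = 0.5 ms at the default 0.8 s cycle) through warm-up cycles
until the per-cycle volume drift of both chambers falls below 0.5% of
stroke volume (minimum 5, cap 120 cycles), then one cycle is recorded on
exactly 401 evenly spaced times.  Initial chamber volumes are set to the
passive filling equilibrium at the venous pressures, which keeps the
warm-up short.

### Calibration of the PV generator

The study conditions fix the sampled ranges (per ventricle: `l0`
1.5–2.8 µm, `t0` 0.075–0.25 s, `Tmax` 65–190 kPa), 80 cycles with a 77/3
split, and 401 samples per cycle.  The generator's free constants were
calibrated once, before surrogate training was finalized, to three
physiological requirements:

* **Every design point contracts.**  The sampled zero-tension length
  `l0` reaches 2.8 µm, so the reference length is set to `lR = 3.0 µm`,
  placing the whole `l0` range on the attainable sarcomere-length branch
  (ED lengths ≈ 3.1–3.3 µm at the default preload).  In this reduced
  model `l` is therefore a normalized activation variable rather than a
  literal sarcomere length; with a literal `lR ≈ 1.9 µm` more than half
  of the sampled designs would produce quiescent, non-pumping ventricles,
  unlike the source data in which every design converged with systolic
  function.
* **Venous-return-limited ejection.**  Wall volumes (70/35 ml LV/RV) and
  afterload (`Z_ao` = 0.01, `R_sys` = 0.4 mmHg·s/ml, `C_art` =
  10 ml/mmHg) put all designs in the Starling regime, where stroke
  volume is set primarily by preload.  This mirrors the published
  feature-importance pattern (activation lengths and time dominate;
  `Tmax`, `t0` contribute weakly) and keeps the parameter-to-trace map
  smooth enough for a tree ensemble trained on 77 cycles.
* **Informative ventricular interaction.**  Venous compliances
  (`C_sv` = 40, `C_pv` = 30 ml/mmHg) buffer end-diastolic volume enough
  to stabilize cycle levels while leaving RV function visible in the LV
  trace (a +20% perturbation of RV `l0` changes LV pressure by
  > 0.5 mmHg).

Absolute systolic pressures in this regime run higher (≈130 ± 30 mmHg
peak) than the published four-chamber traces; relative cycle-to-cycle
variability is comparable.  Pressure scale is not an evaluated quantity;
the surrogate scores are normalized per cycle.

## End-diastolic stress truth model

The LV endocardium is a truncated prolate spheroid (equatorial semi-axis
20 mm, long semi-axis 45 mm, base plane at 0.3·c above the equator,
apical cap excluded), gridded into 24 polar × 24 circumferential element
centroids (576 elements).  Inflation is a one-parameter incompressible
family: the short semi-axes scale by `1+κ` and the long by `1+0.4κ`; the
in-surface stretches follow from the surface metric and the radial
stretch from incompressibility.  The scalar κ solves the global energy
balance `dW/dκ = P_ED · dV_cav/dκ` (bracketed root finding, |ΔP| <
0.01 mmHg), with `W` integrated over a 576 × 3 surface-transmural
quadrature and a +60°→−60° linear transmural helix law.

Stresses are reported at the endocardial layer: the local deformation
(circumferential, longitudinal, radial frame) with the fiber at +60° in
the tangent plane, passive Cauchy stress from the material law, plus the
hydrostatic reaction pressure fixed by the endocardial traction
condition `σ_rr = −P_ED`.  That closure matters: the exactly isochoric
shell kinematics leaves the pressure field indeterminate, and anchoring
it to the applied load pins the stress level the way a full FE solve
does implicitly.  It is what keeps the fiber-stress population almost
entirely in the physiological 0–15 kPa band (≈99.8% at the printed
16.38 mmHg ED pressure across the 120-model design) and makes per-model
stress levels a mild function of the material constants.

The generator is axisymmetric: stresses vary with height (through the
meridional stretch) but not with circumferential position, so the θ
feature is uninformative here — unlike the image-based source anatomy
where position was the dominant feature family.  Radial position `r`
carries the same information instead.

## Design of experiments

Latin hypercube sampling stratifies each range into `n` equal bins with
one sample per bin (uniform within-bin jitter), then a maximin hill
climb (random within-column swaps, accepted only when the minimal
pairwise unit-cube distance strictly increases; 300 iterations by
default) improves space filling while preserving stratification exactly.
This replaces the unpublished surrogate-assisted DOE optimization of the
source workflow with the standard space-filling criterion.

## Surrogate and evaluation protocol

XGBoost regression trees (`gbtree`, squared-error objective — the modern
name of the legacy `reg:linear`), histogram tree method with 64 bins
(few smooth features; coarser quantization costs no measurable accuracy
and bounds the grid-search cost), single thread for bit reproducibility.
The grid is the printed 3×3×3 set (learning rate 0.01/0.05/0.1, trees
500/1000/1500, depth 7/15/20) with 3-fold cross-validation **grouped by
cycle or model id** — rows within a cycle are not independent, and
grouping prevents leakage.  Because full-batch boosting is sequential,
one 1500-tree ensemble per (rate, depth, fold) is trained and the
500/1000-tree entries are scored from its leading trees; this is exactly
the exhaustive search.  Ties break toward fewer trees, then shallower
trees, then smaller learning rate.

Evaluation follows the published convention: R² (Eq. form
`1 − SS_res/SS_tot`) and MAE per held-out cycle (PV) or per held-out
model (stress), then mean ± population (n-divisor) SD across groups.
Feature importance is total split gain normalized to shares.  Trace
summaries (min, max, time of maximum with earliest-tie rule, maximum
central-difference time derivative) are computed for reporting only; the
surrogate is never trained on derivatives.

## Problem sizes and determinism

The full experiments are desk-scale: 80 simulated cycles (≈20 s), the
two PV grid searches (≈5 min single-threaded), 120 ED inflation solves
(≈7 s) and the stress grid search (≈1 min).  Every stochastic stage
(DOE, maximin, split, training) has its own recorded seed, derived from
one master seed when given; identical configurations reproduce datasets
byte-for-byte.

## What passing tests do and do not show

The surrogate-quality bounds are replicated against the package's own
reduced-order simulator, not against the original finite-element data,
which are unavailable.  Passing therefore shows that the published
emulation protocol (DOE sizes, splits, grouped grid search, metrics)
attains the published accuracy on a mechanistically faithful but
geometrically reduced truth model of the same constitutive equations.
It does not validate the reduced model against imaging-based anatomy,
heterogeneous material fields, atria/pericardium, or the non-physiologic
aspects the original authors noted in their own FE traces.  Known
limitations: axisymmetric stress fields (θ uninformative); systolic
pressure scale above the published traces; activation length treated as
a calibration parameter; jagged tree-ensemble predictions are expected
behavior and deliberately left unsmoothed.
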