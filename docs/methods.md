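# Methods

## The model

Left-ventricular (LV) stroke work (SW) is classically the area inside
the pressure-volume (PV) loop. Pressure and volume are scalars, so the
PV loop carries no information about *how* the ventricle moved to
eject the blood. `lvloops` fractionates SW into the two global modes
of pumping using force-length (FL) loops:

- **Longitudinal**: the atrioventricular (AV) plane descends toward
  the apex by a displacement AVPD(t). The balancing force the blood
  exerts in that direction is F_long = P · A_epi,max, where A_epi,max
  is the largest epicardial short-axis cross-section at that instant.
  The epicardial (not endocardial) area is used because both the blood
  pool and the myocardium shorten longitudinally — the AV plane acts
  as a piston spanning the whole epicardial cross-section, and by
  conservation of wall volume the blood displaced per unit of plane
  travel is exactly A_epi · dL.
- **Radial**: the epicardial border moves inward by d_epi(t) =
  r_ED − r(t), measured per slice as the mean distance from the
  contour-point centroid. The radial force per slice is
  F_rad = P · A_endo with A_endo = endocardial circumference × slice
  thickness. One FL loop is integrated per slice (ventricles are not
  circular; slice areas differ) and the radial work is the sum of the
  slice-loop areas. The epicardial displacement is used because
  endocardial motion confounds tissue displacement with wall
  thickening from both pumping modes.

SW_long and SW_rad are the absolute shoelace areas of the closed
(displacement, force) trajectories over one beat, in joules after
converting mm → m, cm² → m², mmHg → Pa (133.322 Pa/mmHg). Their sum is
validated against the PV-loop area. The stroke volume is partitioned
the same way: SV_long = (maximal end-systolic AVPD) × (mean of the two
largest basal epicardial cross-sections at end diastole), SV_rad the
remainder; work per ejected volume is WEV = SW-component / SV-component
in mJ/mL, an energy-efficiency index per mode.

## Signals and grid

All per-frame measurements (volume by disc summation of endocardial
areas × slice spacing; mass = wall volume × 1.05 g/mL; per-slice
areas/radii; AVPD as the mean signed perpendicular distance of six
tracked basal insertion points to their view's end-diastolic AV-plane
line) are resampled to a common 100-point cycle grid by piecewise-
linear interpolation with periodic wraparound, then smoothed with a
circular three-point sliding mean. Linear interpolation avoids
overshoot on sparse cine grids; the circular boundary reflects the
periodicity of the cardiac cycle and conserves the cycle sum exactly.
End diastole (ED) / end systole (ES) are the grid points of maximum /
minimum volume, and both displacement signals are re-referenced to be
exactly zero at ED. Pressure is never smoothed.

**Basal slices.** Slices the AV plane crosses during systole have no
LV wall (hence no contours) in part of the cycle. By default
(`basal_slice_policy="zero_force"`) such a slice keeps its radial loop
with endocardial surface area — and therefore force — set to zero
while absent; this is the exact continuum accounting of the radial
work done by the basal band the AV plane sweeps. The alternative
(`"exclude"`) drops any slice not delineated in every frame, which
discards that band's work: on a phantom with 12 mm AVPD this loses
about AVPD/2L ≈ 8% of radial work, a bias the default policy avoids.

## Pressure

*Invasive route*: upstrokes are detected on a lightly smoothed dP/dt
with a refractory period; beat starts are the end-diastolic feet of
the upstrokes, refined by matched-filter alignment against a beat
template (threshold crossings alone jitter by several samples under
noise). Each beat is resampled onto its own normalized time, beats
are averaged pointwise after circular cross-correlation alignment,
and the average beat is circularly shifted so its diastolic minimum
(before the upstroke) sits at the geometry's ED grid point.

*Noninvasive route*: a time-varying elastance model
P(t) = E(t)·(V(t) − V0) with E(t) = E_min + α·E_N(t_N), where E_N is
the normalized double-Hill curve

    E_N(x) ∝ [(x/τ₁)^{n₁} / (1 + (x/τ₁)^{n₁})] · [1 / (1 + (x/τ₂)^{n₂})]

rescaled to [0, 1], with human-average defaults τ₁ = 0.269, n₁ = 1.32,
τ₂ = 0.452, n₂ = 21.9 on normalized cycle time starting at ED.
Calibration uses two anchors. P(ED) = EDP always (default EDP
5 mmHg when unmeasured; E_N(0) = 0 makes this fix E_min). For the
second anchor two modes exist:

- `anchor="es"` (default): E at the ES frame is set so P(ES) equals
  the target (default the systolic cuff pressure). Peak pressure may
  then exceed the target during ejection. This mode makes SW grow
  steeply (super-linearly) as V0 → ESV, the qualitative behaviour a
  V0 sensitivity analysis should exhibit, because E_max =
  target/(ESV − V0) diverges while ejection volumes stay above ESV.
- `anchor="peak"`: the cycle maximum of P equals the target, found by
  bisection. Under this mode SW *decreases* slowly with V0 (the cap
  suppresses the ejection-phase growth); it is kept for comparison.

V0 defaults to 0. The sensitivity sweep recomputes pressure and the
full decomposition for every integer V0 from 0 to 90% of ESV; the
percent longitudinal/radial split moves by well under half a
percentage point across the sweep (0.19 pp on the dilated phantom)
while absolute SW roughly doubles — so the *percent* split is robust
to the V0 = 0 approximation even where absolute work is not.

## The phantom

The synthetic ventricle is a wall-volume-conserving cylinder: fixed
apex, AV plane descending by avpd(t), epicardial radius shrinking by
d_epi(t), both following a smooth half-cosine rise over systole
(default systolic fraction 0.35) and return over diastole. The
endocardial radius solves π(r_epi² − r_endo²)·L = const exactly, so
mass conservation holds to 1e-10 on the dense internal truth grid
(≥ 2000 points, independent of the emitted frames). Contours are
80-point circles at fixed slice stations; a slice's contours exist in
a frame iff its centre lies apical to the AV plane. Optional seeded
radial Gaussian noise; identical seeds give byte-identical output.

Default dimensions (r_epi 30 mm, wall 10 mm, length 80 mm, AVPD
12 mm, epicardial excursion 2 mm, 30 frames) give EDV ≈ 100 mL,
SV ≈ 59 mL, EF ≈ 58% — a mid-size adult/large-swine ventricle. Named
presets provide a membrane-limit wall (0.3 mm) and a dilated
heart-failure-like ventricle (EDV ≈ 350 mL, EF ≈ 26%). Slices are
sub-millimetre by default so that disc-summation discretization (and
the ±h/2 boundary error at the moving AV plane) stays below the test
tolerances; clinical stacks use ~8 mm slices, where those
discretization terms are correspondingly larger.

Pressure is either a rectangular two-level waveform (eject level
while volume falls, fill level while it rises), which makes
SW = (P_eject − P_fill)·SV exactly, or a smooth sin² pulse. A
multi-beat recording generator (period jitter, additive noise)
exercises the invasive route.

What the phantom does *not* emulate: non-circular cross-sections,
trabeculated endocardium, twist (its volume effect is implicitly
inside the AVPD and epicardial displacements), regional dysfunction,
through-plane motion of the imaging slices, and segmentation error
beyond isotropic radial noise. Passing phantom tests therefore
demonstrates correctness of the computational chain and the
conservation properties of the model — not accuracy on real images.

## Energy-conservation behaviour and known limitations

For the cylinder, exact algebra gives

    SW_FL − SW_PV = −∮ P · 2πL·w · d(d_epi),    w = wall thickness,

so the FL total *under*-estimates PV stroke work by a term first-order
in w/r_epi times the radial work share. Consequences, all verified
numerically:

- Pure longitudinal motion (d_epi ≡ 0): the deficit vanishes; SW_long
  reproduces SW_PV to discretization accuracy at any wall thickness,
  and SW_rad = 0 exactly.
- Pure radial motion: SW_rad/SW_PV = mean(r_endo/r_epi) ≈ 1 − w/r_epi
  (0.99 at 0.3 mm wall, 0.93 at 2 mm, ~0.7 at 10 mm).
- Mixed motion, membrane-limit wall (0.3 mm): conservation within 1%.
- Mixed motion, physiological 10 mm wall: deviation ≈ −15…−19%
  (always negative), considerably larger than the few-percent bias
  reported on real ventricles. The cylinder concentrates *all*
  systolic wall thickening radially (10 → ~14 mm at ES), whereas real
  ventricles present a trabeculated endocardial surface (larger
  measured A_endo) and a mid-cavity bulge (larger maximal epicardial
  cross-section), both of which push the FL total back toward the PV
  value. The thick-wall deficit is thus a property of the idealized
  phantom geometry interacting with the method's
  endocardial-area × epicardial-displacement construction, and is the
  main caveat when reading absolute (not percent) work values.

## Numerical choices

- Shoelace loop areas equal the trapezoidal ∮F dL algebraically;
  orientation is normalized away (areas reported as absolute values).
- Degenerate loops (< 3 distinct vertices) yield zero area with a
  warning rather than an error.
- SV_long may exceed SV on inconsistent inputs; the package warns and
  reports a negative SV_rad instead of clamping, so the discrepancy
  stays visible. WEV values are NaN when their SV component is ≤ 0.
- ICC is the two-way random-effects, absolute-agreement,
  single-measure form (method agreement), computed from the ANOVA
  mean squares; labels poor/weak/moderate/strong/excellent at
  0.30/0.50/0.70/0.90. Bland-Altman differences are percent of the
  reference method by default (pair-mean basis selectable).
- All randomness is seeded; pipelines are deterministic for fixed
  inputs, configuration and seed.
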