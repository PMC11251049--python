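# Methods

## Scope and model

`vesselmech` characterizes thin-wall compliant vessel phantoms along the
same chain a bench study follows: uniaxial tensile testing → constitutive
description → inflation prediction → compliance/distensibility metrics,
with a synthetic-data layer standing in for the physical experiments.

The structural model is deliberately reduced-order. A vessel is a stack
of axial stations (z, inner radius a, wall thickness t), each treated as
an independent thick-walled ring under internal pressure and solved with
the closed-form Lamé field

    σ_r(r) = A − B/r²,  σ_θ(r) = A + B/r²,
    A = p a²/(b²−a²),   B = A b²,   b = a + t,

with axial stress σ_z = A for closed ends (the experiment seals the
distal outflows, so the wall carries the pressure end load) or
σ_z = ν(σ_r+σ_θ) for plane strain. Strains follow from isotropic linear
elasticity; radial displacement is u(r) = r ε_θ(r); enclosed volume is
the trapezoidal integral of π a_def(z)² along the axis.

Two fidelity gaps versus a full 3-D structural solve are inherent and
intentional: stations do not couple axially (slender-body approximation;
bending and shear transfer at the stenosis shoulders are neglected), and
the strain state that indexes the strain-dependent modulus is collapsed
to a single mid-wall value per ring, whereas a 3-D model evaluates it
pointwise. Consequently the solver predicts tube-scale compliance
faithfully but is not expected to reproduce patient-specific 3-D results
to the digit; it ranks geometries and materials, which is what the
characterization workflow needs.

## Constitutive description

**Constant modulus.** `E_const` is the OLS slope (free intercept) of the
stress–strain curve over strains ≤ 0.20, the physiological window of
arteries. The free intercept matches the spreadsheet-trendline
convention of bench practice; a through-origin variant is a flag.
Engineering stress/strain is assumed throughout — at the ≤ 20 % strains
that decide `E_const` the true-stress correction is second order, and
tensile records are conventionally reported in engineering form.

**Strain-dependent modulus.** `E(ε_m)` is tabulated as difference
quotients of the averaged curve on the schedule ε = 0, 0.002, …, 0.100,
0.15, …, 1.00 (50 fine + 18 coarse = 68 intervals). Nodes sit at
interval midpoints (the natural location of a secant-slope estimate);
evaluation is piecewise-linear with clamped extrapolation, so the table
behaves like a constant beyond its measured range instead of
extrapolating a trend. Averaging interpolates every specimen onto a
uniform 0.001-strain grid spanning the intersection of specimen ranges
and takes the pointwise mean; the per-point population SD is returned
alongside.

**Strain metric.** ε_m = γ/(√2(1+ν)) + |ε_vol|/(3(1−2ν)) with
ε_vol = tr(ε) and γ = √(2 dev(ε):dev(ε)). It is non-negative, zero only
at the zero tensor, and homogeneous of degree one — both properties are
enforced by tests. ε is interpreted as the small-strain tensor; the
package does not attempt a finite-strain reformulation, because the
constitutive model it feeds is linear elastic.

**Fixed point.** For table materials each ring solves the scalar
self-consistency condition E = E(ε_m(E)). Because all Lamé strains scale
as p/E at fixed geometry, ε_m(E) = k·p/E with a per-ring coefficient k
computed once, and the iteration E_{k+1} = table(k p / E_k) is cheap and
vectorized across stations. Convergence: relative modulus change
< 1e-8, cap 200 iterations, error on failure. Constant materials
converge on the first check. A property test cross-checks the fixed
point against independent 1-D root bracketing of E − table(k p/E).

## Pressure stepping

`direct` mode (default) solves each pressure on the reference geometry —
the textbook linear treatment. `incremental` mode ramps to the target in
50 equal load increments, updating each ring's reference radii and
thickness from the previous increment's deformed state; for table
materials the modulus of an increment is evaluated at the accumulated
mid-wall strain metric (explicit update, O(1/n) lag), because evaluating
at the increment's own near-zero strain would pin the modulus at E(0).

The two modes measure geometric nonlinearity: the gap in predicted
volume grows roughly quadratically with strain — ≈ 0.07 % at 1.5 %
mid-wall hoop strain, ≈ 0.5 % near 4 %, ≈ 0.8 % at 5 %, ≈ 7 % at 13 %.
At carotid-phantom working points (hoop strains of 5–15 % at systolic
pressure) incremental stepping is the more faithful choice; the
agreement tests therefore exercise the ≤ 3.5 %-strain regime where both
modes coincide within 0.5 %.

## Measurement-side metrics

Between diastole and systole (defaults 74/130 mmHg, a 56-mmHg clinical
pulse pressure): C = ΔV/Δp, C_V = C/V_d × 100, C_D = ΔD/(D_d Δp) × 100.
Endpoint volumes come from piecewise-linear interpolation of the
pressure–volume log and endpoint diameters from an OLS diameter–pressure
regression, because the 1-mm³ injection grid rarely lands exactly on the
endpoint pressures. Regression residuals beyond 3 residual SDs are
flagged but never dropped; a residual-SD floor of 1e-9 × max|D| prevents
machine-epsilon residuals on exact lines from being flagged. Standard
deviations are population SDs (divide by n) to match bench-report
convention here; `ddof=1` is a flag. Group comparisons route through
Shapiro–Wilk at α = 0.05 to Welch's t (normal) or Mann–Whitney
(non-normal), with one-sample/paired analogues (one-sample t / Wilcoxon
signed-rank); p-values are two-tailed and uncorrected. Non-monotone
pressure logs are sorted before interpolation and the report carries an
`isotonic-cleanup` flag.

Effective diameter of a (generally non-circular) lumen cross-section is
perimeter/π. STL surfaces are sliced by triangle–plane intersection;
segments are chained into loops by endpoint matching at 1e-6 mm, and
multi-loop slices (e.g. a plane cutting both daughter branches) report
each loop so the caller chooses the lumen of interest.

## Synthetic experiments

The generator reproduces the statistical structure the analysis assumes,
not any specific laboratory's data:

* **Tensile specimens** — a ground-truth law σ(ε) on a 0.001-strain grid
  plus i.i.d. Gaussian stress noise (default SD 0.005 MPa, 5 specimens).
  The 0.001 grid matches the averaging-grid convention and is coarse
  relative to real tensile logging (≈ 1e-6 strain per sample at
  1 mm/min on a 100-mm specimen), and it makes the analytic OLS slope SD
  of the averaged-curve fit ≈ 1 % of E0, so the 2 % recovery check is a
  ~2σ bound; recovery is asserted over a fixed seed panel.
  Presets: `pvah_like` (tangent modulus nearly flat, 0.33→0.30 MPa,
  ε_c = 0.15 — a hydrogel whose fit over 0–20 % lands near 0.31 MPa) and
  `silicone_like` (0.40→0.14 MPa, ε_c = 0.22 — pronounced softening over
  10–40 % strain). These are qualitative shapes, not measured curves.
* **Geometry** — a tube with an optional Gaussian lumen narrowing; the
  outer radius stays smooth so the wall thickens where the lumen narrows
  (plaque grows within the wall). Severity s puts the minimal radius at
  (1−s)·base. Stations every 1 mm; markers CCA/ICA/ECA plus ICAs at the
  most stenotic station.
* **Pressure–volume experiment** — 1-mm³ injections; after each, the
  equilibrium pressure inverts the monotone model P–V relation by
  bisection to 1e-6 mmHg; a constant per-step leak (optional) is
  subtracted from the contained volume and Gaussian read-out noise
  (default 0.5 mmHg) is added to the recorded pressure. Runs truncate
  with a warning at 160 mmHg. A leak biases the measured compliance
  upward, and the generator reproduces that ordering.
* **Diameter series** — model diameters at a marker site plus Gaussian
  noise (default 0.05 mm).

All generators are pure functions of (inputs, seed). Noise magnitudes
are stated assumptions — the bench protocol being emulated does not
quantify its noise — and are config fields, not constants. What passing
round-trip tests show is internal consistency of the pipeline under the
assumed noise model (Gaussian, homoscedastic, uncorrelated); they do not
certify behavior under real-world artifacts such as viscoelastic creep,
temperature drift, or meniscus errors in volume reading.

## Numerical choices

* 1 mmHg = 133.322387415 Pa; mm/mm³/MPa internally, mmHg at interfaces.
* Fixed point: relative tolerance 1e-8, 200-iteration cap, vectorized
  across stations with per-station convergence.
* P–V inversion: Brent bisection, xtol 1e-6 mmHg, bracket [0, p_max].
* Trapezoidal volume on the 1-mm station grid; exact for a uniform tube.
* Degenerate inputs fail loudly: non-monotone strain, disjoint specimen
  ranges, pulse-pressure window outside the measured range, zero-variance
  samples (test label `degenerate`), plane missing the mesh (empty,
  flagged), stenosis severity ≥ 0.95.

## Known limitations

* No axial coupling between stations and a single mid-wall ε_m per ring;
  patient-specific 3-D effects (bifurcation geometry, non-circular
  sections, bending) are outside the model.
* Linear elasticity only — no hyperelastic strain-energy fit, no
  viscoelasticity; strain-dependence enters solely through E(ε_m).
* Difference quotients amplify measurement noise by 1/Δε (≈ 500× on the
  0.2 % intervals); `modulus-table` is meant for averaged or low-noise
  curves, and the `synth` command therefore writes the ground-truth
  tangent-modulus table for simulation rather than quotients of noisy
  synthetic specimens.
* Branch topology is not represented; a bifurcation is handled as
  separate slice stacks whose volumes add.
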