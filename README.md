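# vesselmech

Mechanical characterization of thin-wall compliant vessel phantoms —
the soft silicone or polyvinyl-alcohol-hydrogel (PVA-H) vessel models used
on flow benches for cardiovascular research. The package covers the full
characterization chain for such models: extracting elastic moduli from
tensile tests, predicting quasi-static pressure–volume behavior of a
stenotic vessel, and computing the compliance and distensibility metrics
used to compare phantoms with real arteries. A synthetic-data generator
emulates the bench experiments so the whole pipeline is testable without
laboratory data.

## The model

**Material.** Wall material is linear elastic with Poisson ratio ν = 0.4
(nearly incompressible) and either a constant modulus `E_const` — the OLS
trendline slope of the stress–strain curve up to 20 % strain — or a
strain-dependent modulus `E(ε_m)` tabulated as piecewise difference
quotients of the averaged tensile curve on a 0.2 % / 5 % strain schedule
(68 nodes over 0–100 % strain). The scalar strain metric

    ε_m = γ / (√2 (1+ν)) + |ε_vol| / (3 (1−2ν)),
    ε_vol = tr(ε),  γ = √(2 dev(ε):dev(ε))

combines volumetric and shear strain so a single number indexes the
modulus table at any deformation state.

**Structure.** The vessel is a stack of axial slices, each an independent
thick-walled ring solved with the closed-form Lamé solution (closed-end
axial stress by default; plane strain available). Strain-dependent
stiffness is resolved by fixed-point iteration on E = E(ε_m(E)) at the
mid-wall radius. Enclosed volume is the trapezoidal integral of the
deformed lumen cross-section.

**Metrics.** Between diastolic and systolic pressures (defaults
P_d = 74, P_s = 130 mmHg):

    C   = (V_s − V_d) / (P_s − P_d)               [mm³/mmHg]
    C_V = C / V_d × 100                           [%/mmHg]   volumetric compliance
    C_D = (D_s − D_d) / (D_d (P_s − P_d)) × 100   [%/mmHg]   diameter distensibility

plus effective diameter D_eff = perimeter/π from STL cross-sections,
wall-thickness statistics over the P1–P8 × 10-slice measurement grid, and
normality-routed group comparisons (Shapiro–Wilk → Welch t / Mann–Whitney /
Wilcoxon).

## Worked example

Predict the compliance of a 50-mm vessel (lumen radius 3 mm, wall 1 mm)
with a 40 %-severity stenosis at mid-length, made of a 0.31-MPa material:

```python
from vesselmech import (
    MaterialSpec, gen_vessel_geometry,
    simulate_compliance_experiment, marker_distensibility,
)

geom = gen_vessel_geometry(length=50.0, base_radius=3.0, base_thickness=1.0,
                           stenosis=(25.0, 0.4, 4.0))
mat = MaterialSpec.constant(0.31, nu=0.4)

rep = simulate_compliance_experiment(geom, mat)
print(f"C   = {rep.C:.3f} mm^3/mmHg")
print(f"C_V = {rep.C_V:.3f} %/mmHg  (Pd={rep.Pd:.0f}, Ps={rep.Ps:.0f} mmHg)")
for site, cd in sorted(marker_distensibility(geom, mat).items()):
    print(f"C_D[{site:4s}] = {cd:.4f} %/mmHg")
```

```
C   = 3.815 mm^3/mmHg
C_V = 0.258 %/mmHg  (Pd=74, Ps=130 mmHg)
C_D[CCA ] = 0.1339 %/mmHg
C_D[ECA ] = 0.1339 %/mmHg
C_D[ICA ] = 0.1333 %/mmHg
C_D[ICAs] = 0.0735 %/mmHg
```

The vessel gains 3.8 mm³ per mmHg, i.e. 0.26 % of its diastolic volume
per mmHg — the order of magnitude of carotid-scale arteries and compliant
phantoms. Diameter distensibility is uniform along the healthy segment
(≈ 0.13 %/mmHg) and roughly halves at the stenotic marker `ICAs`, whose
narrowed lumen and thickened wall make it the stiffest station.

The same metrics can be computed from measurement-style data: feed a
syringe-pump pressure–volume log to `compliance_from_pv` and marker-site
diameter series to `distensibility_from_series` (3-SD outliers are
flagged but retained). `gen_pv_experiment` / `gen_diameter_series`
simulate those measurements, including 1-mm³ injection steps, pressure
read-out noise and an optional slow leak.

A CLI mirrors the library: `vesselmech tensile-fit | modulus-table |
simulate | compliance | distensibility | geometry | synth | report`
(see `vesselmech --help`).

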