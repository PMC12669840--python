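# billmech

Bill-shape morphometrics and stabbing biomechanics for hummingbird bills,
exercised end-to-end on parametric synthetic geometries.

Lekking hermit hummingbirds fight with their bills: males stab rivals with
the maxillary tip. Testing whether sexually dimorphic bills (straighter,
longer, sharper-tipped males vs. curvier females) are better stabbing
weapons requires two toolchains that rarely live in one place:

1. **3D geometric morphometrics** of the upper bill — three digitized contour
   curves (culmen + left/right tomia) resampled to 60 points each and merged
   into a 178-point landmark/semilandmark configuration; generalized
   Procrustes analysis (GPA) with sliding semilandmarks; extraction of the
   symmetric component of shape for bilaterally symmetric structures; PCA of
   shape space; and univariate descriptors — arc:chord curvature, arc length,
   outer surface area, a surface-area **sharpness ratio** 1 − A₁/A₂ (areas of
   the two distal millimeters), and the dorsal-view **included angle** of the
   tip.
2. **Comparative linear-static finite-element analysis** of stabbing — two-
   region (keratin shell over bone core) quadratic tetrahedral meshes, loads
   on the distal millimeter of the tip at two angles (horizontal = along the
   chord; parallel = along the bill-tip axis), von Mises stress summaries
   (98th-percentile peak and mesh-weighted arithmetic mean, MWAM), total
   strain energy, and eigenvalue buckling load factors, with size removed via
   force scaling at equal force:surface-area ratio,

   F_B = F_A · SA_B / SA_A,

   and strain-energy adjustment to the reference size,

   U′_B = U_B · (F_A/F_B)² · (V_B/V_A)^(1/3).

The package is aimed at morphologists and biomechanists who want a tested,
scriptable replica of this workflow. Since museum-specimen meshes and CT
scans are generally not redistributable, a first-class **synthetic-bill
generator** stands in for them: the culmen is a circular arc (the unique
planar curve with a prescribed arc:chord ratio), swept with a tapering
bilaterally symmetric cross-section, with known ground truth for every
specimen and a two-sex population model with realistic dimorphism and noise.
Everything downstream — landmarks, GPA, statistics (permutation Procrustes
ANOVA, exact Mann–Whitney U, Spearman), FEA — runs on these geometries and is
validated against closed forms and independent oracles.

## Worked example

```python
from billmech import BillParams, generate_surface, compute_metrics, scale_force

female = BillParams(arc_length=38.0, arc_chord_ratio=1.12, base_height=3.0,
                    base_width=4.0, taper_exponent=0.45)
male = BillParams(arc_length=42.0, arc_chord_ratio=1.01, base_height=3.3,
                  base_width=4.4, taper_exponent=0.6)
for name, params in [("female", female), ("male", male)]:
    m = compute_metrics(generate_surface(params, id=name))
    print(f"{name}: arc:chord={m.arc_chord_ratio:.3f}  arc={m.arc_length:.1f} mm  "
          f"sharpness={m.sharpness_ratio:.3f}  included angle={m.included_angle:.1f} deg  "
          f"outer SA={m.outer_surface_area:.1f} mm^2")
print(f"scaled load: {scale_force(200.0, 322.934, 327.791):.1f} mN")
```

prints

```
female: arc:chord=1.120  arc=38.0 mm  sharpness=0.460  included angle=57.3 deg  outer SA=181.8 mm^2
male: arc:chord=1.010  arc=42.0 mm  sharpness=0.494  included angle=34.9 deg  outer SA=205.2 mm^2
scaled load: 203.0 mN
```

The measured arc:chord and arc length recover each specimen's generating
parameters (the generator's contours are exact); the male bill is straighter,
longer, sharper by both metrics (higher sharpness ratio, smaller included
angle) and has the larger outer surface area. The last line is the
force:surface-area scaling rule applied to two models with 200 mN on the
reference: the target model receives 203 mN.

The full study — generate a 8 + 8 population, digitize landmarks, GPA +
symmetric component + PCA, metric tests, select the PC1-extreme female/male
pair, mesh them and run the comparative FE protocol at both angles:

```python
from billmech.pipeline import default_config, run_study
report = run_study(default_config(seed=1))
```

yields (seed 1):

```
PC1 variance: 98.4%  PC2: 0.8%
sex Procrustes ANOVA: R^2=0.93  p=0.001
extreme pair: {'reference': 'F08', 'target': 'M04'}
scaled load on target: 240 mN (reference 200 mN)
horizontal {'peak_vm_98': -30.1, 'mwam_vm': -74.1, 'strain_energy': -89.5, 'buckling_load_factor': -74.2}
parallel   {'peak_vm_98': 95.6, 'mwam_vm': -57.5, 'strain_energy': -78.7, 'buckling_load_factor': -66.7}
```

i.e. the sexes separate along PC1, sex explains most of the symmetric shape
variation, and under horizontal stabbing at equal force:surface-area the
straighter male bill stores far less strain energy (more efficient force
transmission) and carries a lower mean von Mises stress (lower breakage risk)
than the curved female bill. The percentage magnitudes are properties of the
synthetic family, not of any real specimen; the signs and orderings are the
scientific content. The same pipeline is scriptable from the shell:

```sh
billmech run-all --seed 1 --out study_out/
```

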