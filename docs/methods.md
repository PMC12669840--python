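# Methods

This note documents the models, conventions and parameter choices behind
`billmech`, in the order the pipeline uses them. Units are fixed internally
to mm / MPa / N (energies in mJ = N·mm); command-line force inputs are in mN
and converted.

## Synthetic bill geometry

**Centerline.** The culmen (dorsal midline of the upper bill) is modeled as a
planar circular arc — the unique planar curve with a prescribed arc:chord
ratio — lying in the sagittal (x–z) plane with its chord on the x axis, tip
at the origin and base at maximum x. The subtended angle θ solves
θ / (2 sin(θ/2)) = arc:chord by bracketed root-finding on (0, 2π); the
straight bill is the θ → 0 limit. Because the swept curve *is* the culmen,
the generator's arc length and arc:chord ratio are recovered exactly by the
downstream metrics (up to contour resampling error, well below 0.1%), which
is what makes end-to-end parameter-recovery tests meaningful.

**Cross-section.** At arc-length distance u from the tip the section is a
half-ellipse dorsal vault (half-width w(u), height h_d(u)) over a shallow
parabolic ventral face (depth 0.15 × the section height), hung below the
culmen point. The tomia — the lateral cutting edges — are the genuine slope
discontinuities where vault meets ventral face, so the three contour curves
(culmen, left/right tomium) are unambiguous and are emitted exactly on mesh
vertices. Sections shrink toward the tip as
g(u) = ((u + t₀)/(L + t₀))^τ with taper exponent τ and truncation
t₀ = 0.05 mm, which keeps the swept sections non-degenerate; the apex itself
is closed with a cone fan, and mirror symmetry about the sagittal plane is
exact to machine precision by construction.

**Choice of taper regime.** A single global power law couples tip sharpness
to the slenderness of the whole distal shaft. For a chordward (horizontal)
tip load the Euler-type bending-energy integrand scales near the apex as
u²/g(u)⁴ ~ u^(2−4τ): for τ ≥ 3/4 it diverges as t₀ → 0 and the total strain
energy is dominated by bending of an (unphysically) needle-like distal
shaft. Real bills are stout keratin-over-bone shafts whose sharpness is a
localized tip feature; their width profiles correspond to τ ≈ 0.45–0.65. The
default population therefore uses τ = 0.45 (females) and τ = 0.6 (males),
inside the arch-bending regime — numerically, the strain-energy ordering
between the two stabbing angles changes character at τ ≈ 0.55 almost
independently of curvature, so the female group (whose curved bills carry
the ordering claim) is kept below that boundary across its noise
distribution. Consequences of the single-exponent family are tested as
stated: sharpness ratio increases monotonically with τ (a cone, τ = 1, gives
exactly 2/3), and global metrics (arc, arc:chord, surface area) are
insensitive to t₀ at the 1% level while the sharpness ratio — a property of
the distal two millimeters — shifts by a few percent when t₀ is halved and
is checked with a correspondingly looser bound.

**Population model.** Two sexes, default n = 8 each, mirroring the dimorphism
pattern documented for large hermits: females curvier (arc:chord 1.12 vs
1.01), males longer (42 vs 38 mm), sharper-tipped (τ 0.6 vs 0.45, included
angle ≈ 35° vs 57°) and ~10% deeper/wider at the base (hence larger outer
surface area). Per-parameter Gaussian noise (sd: arc 1.2 mm, arc:chord 0.02,
τ 0.04, base dimensions ≈ 3%) is truncated to geometric validity by redraw;
contour points receive isotropic jitter of sd 0.05 mm, half the nominal
photogrammetry resolution, emulating digitization error. Each specimen draws
from an independent RNG substream keyed (seed, counter), so enlarging a
population never perturbs earlier specimens. What the generator does *not*
emulate: irregular real cross-sections, compound taper (stout shaft +
localized dagger), varying shell thickness, keratin anisotropy, or
maxilla–mandible interaction — so passing tests demonstrate correctness of
the machinery and reproduction of directional findings, not quantitative
claims about real birds.

**Volume meshing.** Cross-sections are meshed with a boundary ring, an
inward-offset ring at the shell–core interface and radial core layers
collapsing to a center node; consecutive stations are joined by prisms split
into face-compatible tetrahedra (quad-face diagonals keyed to the smallest
global node index), and the tip is closed with a cone fan. Interface nodes
are shared between shell and core elements, which *is* bonded contact.
Inward offsets use per-vertex edge-normal bisectors with the mitre
correction t/cos(φ/2) and are clamped by a ray-cast to the opposite boundary
(at 45% of the hit distance), so thin tip sections degrade gracefully to
all-shell rather than inverting. Shell thickness defaults to 0.15 mm
(uniform); the base cross-section (3–3.3 × 4–4.4 mm) and ~40 mm length are
plausible placeholders for a large hermit, not measured values.

## Landmark protocol

Three contours, stored tip-first, are resampled to n equally spaced points
in cumulative arc length (endpoints preserved exactly) and merged with the
shared tip kept once — 3n − 2 points, 178 at the default n = 60. The tip is
assigned to the culmen/midline set; the four curve endpoints (tip + three
proximal ends) are fixed landmarks, the remaining 174 slide. Left/right
tomium points are paired by within-curve index; culmen + tip form the
midline. Semilandmark tangents come from central differences of within-curve
neighbors. Specimens are aligned before digitization: chord (tip → proximal
culmen end) to +x, sagittal plane to x–z, tip at the origin, bird's left at
+y.

## Superimposition and shape space

GPA centers each configuration, scales it to unit centroid size, and
iterates rotation-to-consensus (proper rotations only, via SVD with the
det = +1 correction) with consensus re-estimation until the consensus moves
less than 1e−8 RMS (cap 100 inner iterations). Semilandmark sliding is
interleaved as an outer loop (cap 10 rounds): each semilandmark moves along
its tangent line by the projection of its residual to the consensus — the
Procrustes-distance-minimizing scalar — capped at half the local
inter-neighbor spacing to prevent fold-over, then is re-projected onto the
pre-slide polyline of its curve so points stay on the digitized contour.
The summed squared residual history is recorded and is non-increasing.
Because consensus orientation is otherwise arbitrary (it inherits the first
specimen's pose), the finished fit is rotated to the consensus principal
axes with axis signs fixed by third moments (skewness) — an axis with
near-zero skew, e.g. the left-right axis of a bilateral structure, takes its
sign from the det = +1 constraint. This makes the fit invariant to arbitrary
rigid motion and scaling of the inputs, which is asserted to 1e−8.

The symmetric component of each aligned configuration is the average of the
configuration with its reflected-and-relabeled copy after superimposition by
a proper rotation; the residual is the asymmetric component. PCA operates on
mean-centered flattened symmetric coordinates via SVD; components are
ordered by decreasing variance, percentages are reported over all nonzero
components (they sum to 100), and each component's sign is fixed so its
largest-magnitude loading is positive.

## Statistics

Procrustes ANOVA fits a linear model (factor via dummy coding, or a centered
covariate) to the flattened shape coordinates. R² = SS_effect/SS_total and F
uses the standard degrees of freedom. The p-value randomizes rows of the
response under the intercept-only reduced model — for a single predictor this
equals residual randomization — with the observed statistic included in the
reference set (p ≥ 1/(n_perm + 1); default n_perm = 999, seed mandatory,
bit-reproducible). Since SS_total is permutation-invariant, F is a monotone
function of SS_effect and the comparison runs on SS_effect in vectorized
batches. Mann–Whitney U is exact (full enumeration) when n·m ≤ 400 with no
ties and a tie-corrected normal approximation otherwise; the degenerate
all-tied case returns p = 1. Spearman's correlation is the Pearson
correlation of mid-ranks with a t-approximation p-value. Two-sided
alternatives throughout; no multiple-testing correction is applied.

## Bill metrics

Arc and chord are the cumulative polyline length and endpoint distance of
the culmen. "Distal millimeters" for the sharpness ratio are slabs along the
aligned x axis; triangles straddling slab planes are clipped exactly
(Sutherland–Hodgman polygon splitting) because the distal slab spans few
triangles and vertex binning would bias A₁. The ratio uses the full outer
(non-base) surface of each slab. The included angle is measured on the
dorsal (x–y) silhouette: 2·atan(half-width/0.5) at 0.5 mm from the tip, with
the half-width taken from the mesh cross-section at that plane. The
morphometric outer surface area sums the dorsal (tomium-to-tomium) face
selection; the comparative-FE scaling rule instead uses the area of the
entire closed volume-mesh boundary — both are computed and labeled
distinctly.

## Finite elements

Isotropic linear elasticity on 4- or 10-node tetrahedra (quadratic default;
linear available for fast checks, with documented accuracy loss from
locking). Midside nodes sit at edge midpoints, so the geometric map is
affine and one Jacobian per element suffices; TET10 uses the 4-point Gauss
rule, exact for the quadratic integrand. Default materials: shell 1700 MPa,
core 7300 MPa, Poisson 0.4 for both. The base cut plane is fully clamped;
the total tip force is shared over all nodes within 1 mm of the tip along x —
equally by default, with an area-weighted option (tip summaries are somewhat
sensitive to the distribution, so both are exposed). Horizontal loads point
along +x (the chord, into the bill); parallel loads along the centerline
tangent at the tip, proximally. Stresses are recovered once per element at
the centroid; the peak is the 98th percentile over unweighted element von
Mises values with linear order-statistic interpolation (discarding the top
2% as likely numerical singularities) and MWAM is the element-volume-weighted
mean. Strain energy is ½uᵀf, asserted equal to ½uᵀKu to 1e−8. Buckling
solves (K + λK_g)φ = 0 with the geometric stiffness assembled from centroid
stresses of the static pre-solution; the reduced problem −K_g x = νKx is
solved by shift-free Lanczos with the already-factorized K as the inner
solve, and λ = 1/ν_max for the largest positive ν (none ⇒ no compressive
instability under that load direction). Solver validation: cantilever tip
deflection within 5% of FL³/3EI at L/h = 20 and fixed-free Euler column load
within 10% of π²EI/4L² (both land near 0.2% at the test meshes of ~3,700
degrees of freedom).

## Comparative protocol

Unscaled analyses apply the empirical puncture forces (200 mN reference /
female, 125 mN target / male). Scaled analyses apply
F_B = F_A·SA_B/SA_A (equal force:surface-area; with the published areas
322.934 and 327.791 mm² and F_A = 200 mN this gives 203 mN) and adjust the
target's strain energy by U′_B = U_B (F_A/F_B)² (V_B/V_A)^(1/3) before
percentage differences 100·(B−A)/A are reported per metric. The volume
exponent 1/3 is the unique choice under which two geometrically similar
models, loaded per the force:surface-area rule, obtain identical adjusted
strain energies (U ∝ F²/length for linear elasticity); it is exposed as a
parameter. Forces are logged at integer mN; full precision is kept
internally. The reference model is configurable (default: the female of the
PC1-extreme pair; the choice is arbitrary in a comparative analysis).

## Pipeline problem sizes and determinism

The default study runs 8 + 8 specimens at surface resolution n_u = 80 rings
of 24 points, landmarks n = 60 (178 points), 999 ANOVA permutations, and
meshes only the two PC1-extreme specimens for FEA (24 stations, two radial
core layers: ≈ 6,300 quadratic tets, ≈ 30,000 degrees of freedom per model;
one factorization per model is reused across load angles and the buckling
solve). Statistical type-I calibration uses 1,000 null populations at
reduced contour resolution (10 points per curve, GPA without sliding, 199
permutations) — sizes chosen so the whole suite exercises every stage at
meaningful fidelity while staying fast enough to run routinely. Every
stochastic stage is keyed to explicit seeds; rerunning a study with the same
config reproduces the report bit-for-bit, and the config digest excludes
only the output path.

## Known limitations

- The synthetic family is smooth and single-exponent; it cannot represent a
  localized dagger on a stout shaft, so tip-local metrics (sharpness ratio,
  included angle) and FE percentage magnitudes should be read as properties
  of the family, not of real specimens.
- Sliding uses first-order tangent lines with polyline re-projection;
  equivalence with curve-reprojection implementations holds at the level of
  invariants, not coordinates.
- The buckling analysis is the linearized eigenvalue formulation; no
  post-buckling, no contact, no impact dynamics.
- Homogeneous isotropic materials by design (isolating shape effects);
  graded or anisotropic keratin is out of scope.
- The 98th-percentile peak stress operates on unweighted element values;
  volume-weighted percentiles are a defensible alternative convention.
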