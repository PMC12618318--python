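# Methods

## Scope and conventions

The toolkit implements the preprocessing layer of a head–neck finite-element
model build: mesh conversion and quality control, constitutive-law
evaluation, geometric verification and validation statistics. It does not
time-step a solver; solver-facing artifacts (LS-DYNA keyword decks) carry
element-formulation hints (ELFORM −2 for brain bricks, ELFORM 1 with IHQ 6
hourglass control for CSF) only as comment metadata, never parsed.

Internal units are millimetres, milliseconds and MPa (the common explicit-FE
convention); densities are kept in kg/m³ and Prony relaxation times in
seconds, matching how their literature sources quote them. Node ids are
1-based in every file dialect and 0-based contiguous internally, with the
original ids retained.

## Tet-to-hex conversion

Each positively oriented tetrahedron (V₀V₁V₂V₃) is split into four
hexahedra using its 6 edge midpoints, 4 face centroids and the element
centroid. The brick grown at vertex a, with the other vertices taken in an
even permutation (b, c, d), is

    (V_a, M_ab, F_abc, M_ac | M_ad, F_abd, C, F_acd)

in the standard bottom-quad/top-quad node ordering. Because (b, c, d) is an
even permutation of the positively oriented tet, the corner Jacobian at V_a
is positive by construction, and the four bricks partition the tetrahedron
exactly (volume conservation to round-off is a test invariant). The "face
point" is the triangle centroid — the unique choice for which the three
quadrilaterals tile the face and the equilateral face yields the
120°/90°/60°/90° quad angles.

Inserted nodes are deduplicated by canonical keys (sorted node-id tuples
for edges and faces), so two tetrahedra sharing a face produce hexahedra
sharing identical node ids. Output ordering is deterministic: hexes in tet
order with vertex-0..3 sub-order, inserted ids by first canonical-key
encounter. The output node array is laid out vertices | edge midpoints |
face centroids | element centroids, which makes the counting identity
N = V + E + F + T directly visible.

Degenerate tetrahedra (|volume| < 1e-12 mm³, below coordinate round-trip
precision) abort the conversion with the element named; duplicate
coordinates in the input (non-conformal meshes) are warned about but kept.

### Angle-constraint enforcement

Distorted input triangles produce quad corners above the 140° bound (a
right-isosceles face already yields 143.1°). The enforcement pass treats
this as a small optimisation problem: minimise

    E = Σ_corners max(0, θ − θ_target)²,   θ_target = bound − 5°

over the positions of the inserted nodes, by damped gradient descent with
analytic angle gradients. Each iteration accumulates per-node gradients
(averaged over contributing corners), takes a step of `relaxation × h²`
(h = local mean incident edge length) capped at 0.2 h, and accepts it only
if E decreases, otherwise halves the step (up to four times) — so the pass
cannot make the mesh worse, and it terminates early once every angle is
within the bound. The 5° margin places the stationary state clear of the
flag threshold.

Original tet vertices never move. With `preserve_boundary` on (default),
boundary nodes are restricted to movements that leave the boundary geometry
exactly invariant: nodes whose incident boundary quads are coplanar slide in
that plane, nodes on the crease between two planes slide along the crease
line, and nodes at corners of three or more planes are pinned. On faceted
(e.g. lattice) boundaries this permits full angle repair at zero shape
error; on smoothly curved boundaries most boundary nodes sit on slightly
non-coplanar patches and are pinned, which is the conservative choice.

A plain Laplacian relaxation (every inserted node toward the average of its
hex neighbours) was evaluated first and rejected: on the lattice-sphere
fixture its fixed point has worse corner angles (≈148°) than the raw
construction (≈145°), because the uniform-weight average is not an angle
optimiser. The penalty descent reaches ≤137° on the same fixture in under
ten iterations with zero flagged elements.

Elements still violating the bound after the iteration budget are flagged
and reported — mirroring the practical workflow in which a small residue of
elements is repaired manually — and the volume drift of the pass is recorded
(≤1% is a test invariant on the sphere fixture; in practice it is ~1e-10
because the boundary cannot move).

## Quality metrics

Commercial preprocessors do not publish their metric formulas, so standard
textbook definitions are used and stated: scaled Jacobian as the minimum
over element corners of the determinant of the unit edge triple (tet values
additionally scaled by √2 so the regular tetrahedron scores 1); aspect ratio
as longest/shortest edge; skewness as the maximum deviation of face-corner
angles from the ideal (60° triangles, 90° quads); warping as the angle
between the two triangle normals across a quad's diagonals (worse diagonal,
worst face); maximum angle as the largest face-corner angle measured in 3D
(hex faces need not be planar). "Jacobian" thresholds (0.4 hex, 0.8 tet) are
interpreted as scaled-Jacobian bounds since they are unit-free. "Average
mesh size" is the mean ± SD of all element edge lengths, which reproduces
millimetre-scale values comparable to published mesh tables. Degenerate
elements report a capped aspect-ratio sentinel (1e6) and zero Jacobian
rather than raising.

## Constitutive models

The registry stores the published parameter set for each tissue verbatim,
in the unit quoted (MPa for scalp/CSF/disk moduli, kPa for brain shear
moduli, GPa for bulk moduli and stiff elastic solids), with a YAML
round-trip. Specific decisions:

* **Scalp β = 0.00003** is printed without a unit; the decay constant's time
  basis is an explicit field (default 1/ms) surfaced in every curve export
  rather than a silent guess.
* **Brain Prony series** are normalized (G∞ + ΣGᵢ = 1 within 2%, enforced at
  construction); the registry self-checks that μ₀·G∞ matches the printed
  long-term modulus μ∞ within 3% for both white and gray matter.
* **Disk Prony coefficients** (1.70, 1.20, 2.00; sum > 1) are stored and
  evaluated exactly as printed, G(t) = Σ G_k e^(−t/τ_k) with no long-term
  term, since their normalization is not stated.
* **Volumetric term** W_H(J) = K/2 (J−1)² for polynomial materials, with K
  from the standard near-incompressibility relation K = 2μ(1+ν)/(3(1−2ν)),
  μ = 2(C₁₀+C₀₁), at the printed ν = 0.499.
* **CSF C₁₀ = 0.0112** is taken as MPa, consistent with the other rows.
* **Hill muscle shapes.** The active force–length and force–velocity curves
  are cited to the Hill-model literature without printed formulas; defaults
  are a Gaussian force–length exp(−((L/L_rest−1)/w)²) with w = 0.5 and the
  classic Hill hyperbola (shape 0.25, eccentric plateau 1.4), both
  overridable by callables. K_sh = 3 and L_max = 1.5 are likewise
  documented assumptions. Derived quantities follow the stated rules:
  L_rest = volume/PCSA, v_max = 10 L_rest per second, F_max = 0.3 MPa × PCSA.
* **Erosion** uses the maximum principal Green–Lagrange strain (the standard
  failure-strain measure in explicit-FE element deletion) against the 60%
  scalp threshold; batch mode returns eroded/surviving id lists.

Uniaxial Cauchy stress σ = λ ∂W/∂λ is evaluated analytically under
isochoric uniaxial stretch (F = diag(λ, λ^−½, λ^−½)) via the invariant chain
rule; tests cross-check it against central differences to 1e-5.

## Morphometry

Vertebral measures operate on six mid-sagittal landmarks supplied as data
(CSV); landmark picking is interactive in practice, so an automatic picker
is out of scope. Height and depth are means of the stated corner distances.
The dimensionless disk height follows the angle-corrected construction:
the two facing endplate lines define a bisector direction; the disk height
is the endplate-midpoint gap projected perpendicular to the bisector,
normalized by the mean of the two vertebral depths — invariant to rigid
motion and uniform scale, negative (and flagged) for interpenetrating
bodies.

PCA re-orientation sorts covariance eigenvectors by descending eigenvalue,
resolves signs against caller-supplied anatomical reference directions (or
a deterministic largest-component rule), and enforces det = +1. Clouds whose
neighbouring eigenvalues are within 5% of the leading one have no stable
axis order and are rejected as degenerate rather than silently ordered.

Surface thickness and ray queries use exact point-to-triangle distances and
Möller–Trumbore ray casting implemented vectorised in-package. Enclosed
volume is the divergence-theorem sum over an oriented closed triangulation,
reported in cm³; open surfaces raise with their boundary-edge count.

The neck flexion angle projects both the foramen-magnum-to-C7 line and the
vertical into the mid-sagittal plane and returns the signed angle (flexion
positive by the right-hand rule about the sagittal normal; the sign
convention is the package's, as sources report magnitudes). Curve comparison
linearly resamples the second series onto the first's sample times over the
overlap (≥3 samples required) for Pearson r; peaks are maxima of absolute
value with their times, and the average absolute value is reported because
oscillating displacement curves average to zero.

## Synthetic fixtures

Volume fixtures are cubic lattices, each cell cut into six tetrahedra
around its main diagonal (Kuhn template), which guarantees conformity,
positive orientation and bit-reproducibility with no external mesher. The
staircase boundary and right-angled tetrahedra are deliberately harsher than
a production tetrahedral mesh: lattice faces are right-isosceles, so the
raw conversion starts above the angle bound and genuinely exercises the
enforcement pass. What these fixtures do **not** emulate: smooth anatomical
surfaces, graded element sizes, and segmentation noise — conclusions about
those must come from real meshes. The sphere fixture used in the acceptance
checks is radius 40 mm at 2 mm cells (~200k tets → ~800k hexes), chosen as
the largest size that keeps the full pipeline in a few CPU-minutes while
being well past the regime where per-element effects average out.

The parametric vertebra realises all four requested body side lengths
exactly (posterior edge vertical, inferior edge horizontal, the
anterior-superior corner from a closed-form quadratic), so every
morphometric measure has a machine-precision ground truth; its point cloud
has cleanly ordered principal variances (body+spinous span > height >
lateral width) for pose-recovery tests. Time-series fixtures are seeded
damped oscillations A e^(−dt) sin(2πft) with optional Gaussian noise;
strain-field fixtures assign deterministic per-element tensors (uniform,
radial, or Gaussian hotspot).

## Numerical choices and limitations

* Angle computations clip cosines into [−1, 1]; degenerate corners (zero
  edge) report 0° rather than NaN, and degenerate elements report sentinel
  metrics with flags.
* The enforcement pass optimises a fixed quadratic penalty; it does not
  guarantee the global optimum and can stall at a stationary point, in
  which case residual violators are flagged (the honest outcome) rather
  than deleted.
* Hex volumes use centroid-fan decomposition (24 tets per element), exact
  for planar faces and a consistent convention for mildly warped ones.
* File I/O supports the node/element subset of each dialect: legacy ASCII
  VTK unstructured grids, ASCII/binary STL triangles, Abaqus-style .inp
  NODE/ELEMENT sections, LS-DYNA keyword NODE/ELEMENT_SOLID/ELEMENT_SHELL
  cards. Material, contact and load cards are out of scope.
* Anisotropic brain tissue (axonal fiber orientation), fluid–structure
  interaction for CSF, and solver-side behaviours (hourglass energy, tied
  contacts) are explicitly out of scope.
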