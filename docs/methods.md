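# Methods

This note records the models implemented in `lvfiber`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
data generator does and does not emulate.

## Idealized geometry

The synthetic left ventricle is a truncated prolate ellipsoidal shell:
endocardial and epicardial ellipsoids share the long (z) axis, apex at
z = −c, flat basal plane at z = h.  This shape was chosen because its
myocardial volume has a closed form, `π a b (h − h³/(3c²) + 2c/3)`
differenced between the two surfaces, which serves as an oracle for the
discrete tetrahedral volume.  The default study geometry — endo semi-axes
(25, 25, 60) mm, epi (33, 33, 68) mm, truncation 15 mm — gives an ~83 mm
long-axis extent (porcine scale) that accommodates a stack of 8–10
contiguous 8 mm short-axis slices, and an 8 mm wall.

The mesh is a structured hexahedral grid in (transmural, longitudinal,
circumferential) parameter space, subdivided by the Kuhn 6-tet scheme.
Kuhn subdivision keeps face diagonals consistent between neighbors
(including across the periodic seam), so the mesh is conforming and
watertight by construction; the apex cap uses collapsed (wedge)
hexahedra whose degenerate tets are dropped.  Boundary triangles are
classified into `endo` / `epi` / `base` by node membership; the
`apex_region` holds all nodes within the 2 mm diameter transmural
cylinder around the long axis.

Cavity volume partitions the endocardial surface against the basal-plane
center and sums signed tetra volumes; an open boundary off the basal
plane is rejected with the offending edges listed.

## Ventricular coordinates

Linear (P1) tetrahedral finite elements assemble the Laplace stiffness
matrix; Dirichlet conditions are imposed by row/column elimination and
the reduced system is solved with a sparse direct factorization (the
meshes used here stay well below the size where an iterative solver would
pay off).

* `t`: endo = 0, epi = 1.
* `l`: base = 1, apex cylinder = 0.
* `c`: two half-domain problems split at the plane through the long axis
  and the anterior direction (+x).  Anterior seam nodes get 0, posterior
  nodes 0.5; the y<0 half is mirrored to (1 − u) mod 1.  Tets lying
  entirely inside the apex cylinder are omitted (zero-flux insulation);
  inside the cylinder the coordinate is the cylindrical angle about the
  long axis.  On a surface of revolution the exact solution is the
  azimuthal angle / 2π, which the tests use as a brute-force oracle
  (agreement within 0.02 away from the apex at the default resolution;
  the residual is discretization error in the low-quality apex wedges and
  shrinks under refinement).

Frames re-orthogonalize the volume-weighted nodal gradients in the order
e_t → e_l → e_c = e_l × e_t; the transmural gradient is kept unrotated
because it is the most reliable direction on a thin wall.  The apex axis
is a genuine singular point of the longitudinal field (symmetric
neighbors cancel its nodal gradient), so frames there default to copying
the nearest non-degenerate node; `degenerate="raise"` restores the strict
behavior.  The circumferential gradient handles the periodic seam by
unwrapping nodal values within each element.

Streamline normalization traces the unit gradient field with fixed-step
RK4 (step = 0.25 × mean edge length) forward and backward from each node,
bisects the boundary crossing of the final partial step, and reports
arc-length fraction.  Normalization is **per streamline** (each node's
value is divided by its own streamline's total length) rather than by a
global maximum: per-streamline normalization is invariant to local wall
thickness, which is the property the coordinates exist to provide.  Nodes
whose streamline exhausts the step budget fall back to the raw Laplace
value and are logged.

## Diffusion model and tensor fit

The forward model is monoexponential: `S = S0 exp(−b gᵀ D g)` per
encoding volume.  The emulated acquisition uses 3/3/12 directions at
b = 100/200/450 s/mm², eight averages, 2 mm in-plane voxels, 8 mm slices.
Because the protocol has no b = 0 volume, `ln S0` is co-estimated as a
seventh unknown of the log-linear pseudo-inverse fit rather than
designating one shell as reference.  Noisy estimates are clamped to the
SPD cone with an eigenvalue floor of 1e−9 × trace before the matrix
logarithm, so the log-Euclidean machinery never sees a non-positive
eigenvalue.  Rician noise is simulated as the magnitude of a complex
signal with independent Gaussian channels (σ = S0/SNR); Gaussian and
noise-free variants exist for oracle tests.

The fiber direction is the leading eigenvector with its sign fixed to a
positive circumferential component; exact ties fall back to the
longitudinal, then transmural component.  Voxels whose two leading
eigenvalues coincide within 1e−12 × trace are flagged.

## Angle conventions

Helix and transverse angles use the standard projection definitions,
signed by the longitudinal and transmural half-spaces respectively, in
(−90°, 90°] with ±90° mapped to +90°.  E2A is reported as an unsigned
magnitude in [0°, 90°]: the angle between the sheet's projection onto the
cross-myocyte plane (spanned by the cross-myocyte direction
cm = e_t × f̂_p, with f̂_p the fiber's c–l-plane projection, and e_t) and
cm.

Sheet construction places s in the cross-myocyte plane at the target
angle, rotated toward +e_t (this fixes the branch; the magnitude
convention makes the two branches equivalent for reporting), and adds the
unique out-of-plane component along f̂_p that makes s exactly orthogonal
to the fiber.  Because that component is invisible to the E2A projection,
the recomputed angle equals the target exactly for every fiber that is
not purely transmural — including fibers with a transmural component,
where a project-then-orthogonalize construction would drift.

Synthetic truth fibers are built angle-exactly as
f ∝ e_c + tan(α) e_l + tan(β) e_t, which reproduces both generating
profiles α(t), β(t) identically (composing the two frame rotations does
not when both angles are nonzero).  The rule-based evaluator uses the
same construction, so an RBM refit on its own output is exact.

## The four reconstruction methods

All methods operate in (t, c, l) coordinate space with periodic wrapping
of circumferential differences; coordinate-space proximity is what the
shape-adapted transformation implies.  Physical-space distances are not
used.

**HFC.** Tensors are rotated into their sample's local frame, their
matrix logarithms averaged with the kernel weights, and the mean rotated
back at the target's frame.  The printed normalizer 2π·det H is retained
for fidelity although it cancels; the operative definition is the
exponent with the H⁻² metric and no ½ factor.  Targets whose weights all
underflow fall back to the nearest datum (logged).  Kernel optimization
searches diagonal H = diag(h_t, h_c, h_l) over a log-spaced grid with
coordinate descent, scoring by mean leave-one-slice-out fiber error; the
full 3 × 3 least-squares calibration of the original method is not
reproduced.

**PGD.** Basis building runs a greedy rank-one enrichment per heart and
projection: alternating least squares over the three 1-D coefficient
vectors on hat-function bases (N_F = 14, N_G = 24 periodic, N_H = 10),
initialized with constant functions, converged at relative misfit change
< 1e−8 or 200 sweeps.  The full tensor-product discretization of those
grids would carry 14·24·10 = 3360 coefficients; the separated form needs
(14+24+10)·6 = 288.  F and G factors are normalized to unit norm with a
dominant-entry sign convention so that across-heart statistics are
well-posed; scale rides on H.  Across hearts each 1-D factor is
mean-centered and compressed by SVD, truncated at six modes or at the
numerical rank (variation below 1e−9 of the stack norm is noise, e.g.
for identical training hearts).  Fitting solves all modes jointly per
coordinate direction (a linear solve in the mean+SVD weights of all
modes), cycling directions; each projection is fitted independently.
Joint ALS converges slowly but surely on in-span data (exact recovery
needs a few thousand sweeps; the 200-sweep default is accurate to ~1e−5
relative, plenty below measurement noise).  Underdetermined direction
solves are ridge-stabilized and logged.

**POD.** Snapshots are the flattened (c, l) slices of every transmural
level and training heart, one SVD per projection; the basis keeps eight
modes.  The gappy fit reduces the grid to the nearest grid point of each
datum, transfers the scattered values by tri-linear scattering (each
datum distributes value and weight to its 8 surrounding cell corners;
corner values are weight-normalized and restricted to the retained set),
then solves the masked basis per transmural level by least squares
(Tikhonov λ = 1e−8 × trace when rank-deficient, logged).  Transmural
levels with no data interpolate their weights linearly from observed
neighbors.  Evaluation interpolates weights linearly in t and the basis
bilinearly in (c, l), periodic in c.

**RBM.** Ordinary least squares of helix and transverse samples in the
(1 − t, t) basis; four parameters total; NaN (degenerate) angle samples
are dropped.

The leave-one-slice-out protocol excludes the mid-ventricular slice
(median of the per-slice median longitudinal coordinates, ties toward the
apex), refits the method on the rest, and scores per-voxel acute line
angles against the held-out eigenvectors; degenerate voxels are excluded
and counted.  Percentiles use linear interpolation between order
statistics; error aggregation is unweighted.

## Synthetic data: what it does and does not emulate

The generator reproduces the acquisition geometry (slice count,
thickness, spacing, in-plane grid), the encoding scheme, Rician
magnitude noise with averaging, a transmurally rotating helix field with
configurable endo/epi angles, and spatially correlated angular
heterogeneity (white nodal noise smoothed with a Gaussian kernel at a
5 mm correlation length, rescaled to the requested σ and recentered to
zero mean — a fixture for controllable local structure, not a
physiological model).  Voxel samples interpolate coordinates and frames
barycentrically; voxel tensors are built from the interpolated fiber
direction by default so the voxel's first eigenvector remains faithful
to the underlying rule on coarse meshes (log-Euclidean averaging of
nodal tensors is available, and is what the through-slab
thickness-averaging option uses).  Point sampling at the voxel center is
the default; slab averaging is opt-in because no partial-volume model is
asserted.

Not emulated: myocardial deformation and motion artifacts, registration
error between slices, susceptibility/eddy distortions, intravoxel fiber
dispersion, the right ventricle, and real population anatomy in the
PGD/POD training hearts (they are rule-based fields with smooth
low-frequency perturbations on the common grid).  Passing tests therefore
demonstrate correctness of the algorithms under the stated forward model,
not in-vivo performance.

The training population for the low-rank bases defaults to eight hearts
(helix endo/epi spread 8°, transverse spread 3°, smooth perturbation 4°)
— population-scale variability in the physiological range.  Default
diffusion eigenvalues are (1.5, 0.8, 0.5)·10⁻³ mm²/s.

## Constitutive laws

The passive model is the orthotropic Holzapfel–Ogden energy on isochoric
invariants with the printed porcine-calibrated parameters
(a_iso = 0.0943 kPa, b_iso = 5.874, a_f = 0.311 kPa, b_f = 11.271,
a_s = 0.0431 kPa, b_s = 9.772, a_fs = 0.0254 kPa, b_fs = 2.405), a linear
scale A, and the volumetric penalty (1/D)((J²−1)/2 − ln J) with D = 0.1.
The fiber and sheet exponential terms are gated to tension (I4 > 1), the
standard convention for this family.  The isotropic term is implemented
without a "−1" offset, as printed; a constant energy offset does not
affect stress.  The Cauchy stress is the analytic derivative with the
deviatoric projection of the isochoric split, verified against central
finite differences of the total energy to 1e−6 relative.

The active model is the time-varying elastance with length-dependent
calcium sensitivity: sarcomere length l = l_r √(2E_ff + 1), relaxation
time t_r = m·l + b (l in μm, t_r in ms — the unit reading consistent with
m = 300, b = −0.38 producing a few-hundred-ms relaxation), peak calcium
Ca0 = Ca0_max = 4.35 μmol/L, B = 4750 mm⁻¹ converted internally to
4.75 μm⁻¹ (the only reading that keeps the exponent dimensionless), and
l0 = 0.75 μm, l_r = 1.835 μm.  Below l0 the tension is switched off; the
switch is implemented as a linear ramp over [l0, l0 + δ] with δ = 0.01 μm
(configurable) because no functional form is prescribed for it.  T_max
and t0 are personalization targets with no canonical value; their
defaults (0.1 MPa, 150 ms) are physiologically typical placeholders.
Units are explicit: passive quantities in kPa, T_max in MPa as is
conventional; `active_stress_tensor` expects a tension already converted
to the passive unit.

The stress assembly adds T·f⊗f in the fiber direction and n·T·s⊗s in the
sheet direction (n ∈ [0, 1], default 0.5 mid-range); no FEM assembly,
boundary conditions, or parameter personalization loop is in scope.

## Numerical choices and limitations

* Sparse direct solves (SuperLU via scipy) for all Laplace systems.
* Point location uses a centroid KD-tree with batched barycentric checks
  over the nearest 40 candidates and accepts 1e−6 boundary overshoot.
* Tolerances: frames orthonormal to 1e−8; SPD clamping floor
  1e−9 × trace; log/exp round trip to 1e−10; ALS stopping 1e−8 relative
  misfit change.
* Problem sizes: tests run on meshes of ~3–8 k nodes (edge length
  3–3.5 mm) and reduced PGD/POD grids (16 × 30 × 16); the full
  20 × 200 × 120 common grid is supported and used by the CLI defaults.
* Known limitations: coordinates degrade in the apex wedge elements
  (frames fall back to nearest-neighbor on the axis); the half-domain
  circumferential solve assumes the anterior plane intersects the mesh
  (axisymmetric or near-axisymmetric geometry); PGD mode correspondence
  across hearts relies on the greedy ordering being stable, which holds
  for the smooth synthetic population but is not guaranteed for
  arbitrary inputs.
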