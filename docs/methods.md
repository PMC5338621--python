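# Methods

## Model and discretization

The electric potential in the head Ω obeys the quasistatic Poisson equation
∇·(σ∇u) = ∇·j_p with isotropic, piecewise-constant conductivity σ per
tissue compartment. The complete electrode model (CEM) imposes, for each
electrode contact surface e_ℓ on ∂Ω: no current through the skin outside
the electrodes, zero net current through each electrode, and a potential
jump across the skin–electrode interface proportional to the normal current
density and the effective contact impedance Z̃_ℓ = Z_ℓ A_ℓ (Z_ℓ the average
contact impedance in Ohm, A_ℓ the contact area in m²; Z̃ then carries
Ohm·m²). Under this parameterization the electrode voltage is the area mean
of the potential over the patch.

Discretization uses P1 nodal elements on tetrahedra. The weak form yields
the symmetric block system [[A, −B], [−Bᵀ, C]][z; v] = [−Gx; 0] with

- A = stiffness + Σ_ℓ (1/(Z_ℓ A_ℓ)) × patch mass (exact closed-form surface
  integrals: triangle mass matrix area·(1+δ_ij)/12),
- b_iℓ = (1/(Z_ℓ A_ℓ)) ∫_{e_ℓ} ψ_i dS, c_ℓℓ = 1/Z_ℓ,
- G the source divergence matrix (below).

The impedance factor 1/(Z_ℓ A_ℓ) multiplies the electrode boundary mass in
A; this is required for consistency with the weak form and with
c_ℓℓ = 1/Z_ℓ (the second block row then states that the net electrode
current vanishes, which the tests verify to solver precision).

Grounding fixes the potential at one deterministic boundary node chosen
maximally distant from all electrode centers and not under any patch. The
row *and* column of that node are replaced by the unit vector: because the
right-hand side, the B-row and the G-row at a scalp node far from sources
and electrodes are all zero, this is algebraically identical to the
one-sided ground row but preserves the symmetry of A. The same ground node
is used for CEM and PEM so that model comparisons are not contaminated by
the reference choice; the average-reference matrix R (columns of every lead
field sum to zero) removes any residual dependence.

The point electrode model (PEM) drops the boundary terms (pure grounded
stiffness) and evaluates the potential per electrode at a single point. The
default samples the nearest scalp node (B′ is a 0/1 selection matrix); a
barycentric mode interpolates on the containing boundary triangle and is
used by the point-electrode limit experiment, where CEM patches shrink to
single triangles and the PEM must be evaluated at the matched patch points
for the comparison to isolate the electrode-model difference.

Sign conventions: the forward right-hand side is −Gx. The PEM lead field is
therefore −R B′ᵀ A′⁻¹ G; the corresponding CEM expression
R(BᵀA⁻¹B − C)⁻¹BᵀA⁻¹G needs no extra sign. Both are checked against the
analytic sphere solution, which pins the global sign.

### Lead-field routes

Three equivalent computations are provided and cross-checked entrywise:

- `schur` (default): sparse LU of A; X = A⁻¹B; solve the L×L Schur system
  (BᵀX − C).
- `block`: sparse LU of the condensed matrix A − BC⁻¹Bᵀ; v = −C⁻¹BᵀK⁻¹Gx.
- `transfer`: the transfer-matrix equation AHᵀ = B solved per electrode by
  Jacobi-preconditioned conjugate gradients (A is SPD after symmetric
  grounding; default rtol 1e-10, iteration cap 10√N + 100).

Agreement is ~1e-12 relative on the validation head; the suite asserts
1e-8.

## Sources

Each interior face F of the brain compartment shared by two brain tetrahedra
defines a synthetic dipole: position at the midpoint of the two opposite
vertices P_i, P_j, unit moment q = (r_Pj − r_Pi)/d, d = ‖r_Pj − r_Pi‖. The
face-based (lowest Raviart–Thomas) basis function scaled so that ∫w dV = q
has piecewise-constant divergence ±4/(dV) on the two tets, giving a G
column with exactly two entries: +1/d at row P_i and −1/d at row P_j. The
right-hand side −Gx then injects current +x/d at the positive pole P_j — a
two-monopole dipole pointing P_i→P_j. An independent quadrature oracle in
the tests integrates ψ(∇·w) and w directly from the geometric definition
and confirms both the column and the moment.

Dipoles whose opposite vertices touch the brain-compartment boundary are
excluded (default one node layer) because conductivity jumps at the
interface produce outlier potentials. On the structured mesh, distinct
faces can share the same opposite-node pair and hence represent the *same*
dipole; such duplicates are removed (they would silently defeat the
leave-one-out exclusion used in the inverse experiments).

Eccentricity of a dipole is its distance from the head center divided by
the largest admissible dipole radius, so 0.98 means "as superficial as the
source space allows". The mean inter-dipole spacing — the resolution scale
used as a localization bound — is (V/M)^(1/3) with V the convex-hull volume
of the dipole cloud; mean nearest-neighbor distance is not used because
face midpoints on structured meshes can lie far closer than the actual
resolution.

## Inverse estimation

Minimum current estimation minimizes ‖Lx − y‖₂² + γ‖x‖₁ via the IAS
iteration: x₀ = 1, then n_iter = 50 reweighted least-squares steps with
weights D = diag|x|. Three linear-algebra routes of the identical update
are implemented: the stacked least-squares problem as printed, its normal
equations, and the dual (Woodbury) form x = DLᵀ(LDLᵀ + γI)⁻¹y. The dual
form is the default for M ≫ L (cost O(ML²) per step instead of O(M³)); the
routes agree to ~1e-11 and are cross-checked in the tests. |x_k| is floored
at 1e-12 of max|x| inside D to keep the reweighting defined at zeros. γ
defaults to the hierarchical-Bayes value ν²√2/θ₀ = 1.4142e-6 (ν = 0.001,
θ₀ = 1; the hyperprior shape β = 1.5 is carried for provenance but does not
enter the iteration). The objective f(x_i|y) is recorded per iteration; IAS
is not guaranteed monotone, so only f(final) ≤ f(x₀) is asserted.

Electrode data are normalized to unit 2-norm before inversion. The study
this design follows does not state its data units, and every reported
inverse measure (PD, AD, ND) is invariant to the data scale; unit
normalization makes γ = 1.4e-6 a meaningfully small regularization relative
to the data in all experiments.

The single-dipole summary is the |x|-weighted average of dipole positions
and unit moments; the averaged moment is deliberately *not* renormalized
(the angular difference is scale-invariant; exported moments are non-unit).

### Known behaviour of the estimator

With the generating dipole excluded from the dictionary (inverse-crime
avoidance), the minimum-ℓ1 representation of a superficial source is often
*not* the cluster of nearest dipoles: columns with larger gain (more radial
moments, slightly more superficial positions) are cheaper per unit data,
and the diffuse small-weight tail of the estimate pulls the weighted
centroid deeper. On the structured synthetic head this produces median
matched-model localization errors around the inter-dipole spacing with a
tail of several mm, and model-mismatched (CEM data, PEM inverse)
localization errors of ~10–16 mm at desk scale — larger in absolute terms
than on a fine unstructured mesh, with the same qualitative signature
(errors grow toward the surface; estimates land systematically deep). This
is a property of the estimator, not of the solvers: all update routes
agree, and extending the iteration count does not move mass back toward the
excluded source.

## Synthetic head and electrode cap

A deterministic cube grid is split into six Kuhn tetrahedra per cell and
mapped to the ball; a piecewise-linear radial warp places the four
compartment interfaces (brain/CSF/skull/scalp outer radii 37/42/47/52 mm —
a ~10.4 cm head) exactly on grid shells, so no tetrahedron straddles an
interface and labelling by centroid radius is exact. The default target
edge length 5 mm gives 48 000 tets / 9 261 nodes (mesh volume within 0.4%
of the ball, electrode patch areas within ~6% of the nominal disc on
average); a finer 3.5 mm profile (132k tets) is used where the deep
eccentricity bands must hold 100 dipoles. No randomness enters the
generator; the seed argument is recorded for provenance only.

Conductivities (S/m): scalp 0.33, skull 0.04, fontanel/suture 0.3, CSF
1.79, brain 0.33 (model I); model II closes the skull (fontanel = 0.04);
model III raises skull conductivity to 0.1. Fontanels are conical sectors
of the skull shell: one large anterior opening at the vertex (angular
radius 0.35 rad) and two smaller lateral ones (0.15 rad).

The cap is a deterministic Fibonacci spiral of 74 centers over the upper
65% of the sphere area, patches = boundary triangles whose centroid lies
within 5 mm of the center (10-mm diameter electrodes); patches are
validated disjoint. Electrode 5 is nominated "C6-like" and the vertex-most
electrode "Fz-like"; the fixed 10-nAm test sources are the admissible
dipole under the C6-like electrode (source A) and the admissible dipole on
the Fz/fontanel axis under the anterior opening (source B), in both cases
preferring the most radial moment among candidates within 3 mm of the
geometric optimum (grid-constrained moments are otherwise arbitrary, and a
tangential source would not peak at the overhead electrode).

## Numerical choices

- Direct sparse LU for all default solves; residuals checked against rtol
  1e-10 of the right-hand side.
- Surface and volume integrals of P1 quantities use exact closed forms; the
  test oracles use independent quadrature.
- The analytic dipole-in-insulated-sphere potential is summed as a Legendre
  series with explicit P_n and P_n′ recurrences, truncated when the term
  bound falls below 1e-12; the n = 1 term reproduces the classical
  center-dipole formula, which the tests pin.
- Impedance sweep: 14 log-uniform values in [0.1, 12000] Ohm. Eccentricity
  design: levels {0.2, 0.4, 0.6, 0.8, 0.98}, 100 sources per level, band
  half-width 0.02.
- Desk-scale problem sizes: default head 48k tets; validation head
  (edge 6.5 mm) 35k tets; point-electrode limit levels at edges
  9.5/6.5/4.5 mm.

## What the synthetic data do and do not show

The generator reproduces the *design* of the neonatal experiments —
four-shell geometry, fontanel openings, 74 large electrodes on a small
head, impedance sweep, eccentricity-stratified sources — but not the real
anatomy: no gyrification, no true fontanel shapes, no 10–20 montage
coordinates, structured rather than unstructured tetrahedra, and grid-
constrained dipole orientations. Passing tests therefore establish the
correctness of the discrete operators, the conservation identities, the
model limits and the qualitative electrode/skull-model effects (shunting
grows with impedance, CEM–PEM differences grow toward the surface and
flatten above ~100 Ohm); the absolute RDM/MAG/PD/AD/ND levels on real
neonatal anatomy are outside what this geometry can reproduce.

## Limitations

- Isotropic conductivity only; no anisotropy, no adaptive refinement.
- The cube-to-ball map concentrates mild element distortion along the grid
  diagonals; at the default resolution this is visible as a few-percent
  scatter in per-electrode patch areas.
- The IAS estimator inherits the depth/gain bias of minimum current
  estimation; see "Known behaviour" above.
- The CEM→PEM limit experiment requires the barycentric PEM evaluation at
  matched points; with snap-to-node sampling the node-offset discretization
  error (several %) dominates the electrode-model difference.
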