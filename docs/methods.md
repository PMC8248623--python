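# Methods

This note documents the models implemented in `tfmsm`, the defaults and
their rationale, the numerical choices, and what the synthetic validation
does and does not show. All conventions: x = column index, y = row index,
y increases downward; arrays are `[row, col]`; lengths in µm unless noted;
traction in Pa; sheet stress in N/m under a unit-thickness convention.

## Deformation measurement (PIV)

The substrate displacement between the tensed and relaxed bead image is
measured by cross-correlation of interrogation windows laid on a regular
grid with step `window_size − overlap`. Each window pair is zero-meaned
and correlated over all integer shifts (FFT correlation); the correlation
is divided by the per-lag overlap area, which removes the triangular
taper of the full correlation that otherwise biases the sub-pixel fit
toward zero, and the peak search is restricted to displacements of at
most half a window, where enough pixels overlap for the estimate to be
meaningful. The integer peak is refined independently in x and y by a
three-point Gaussian fit (log-parabola; plain parabola when a neighbor is
non-positive; ties at the peak resolve to the smaller index via the
argmax convention). Vector quality is scored by the ratio of the highest
correlation peak to the second-highest peak outside a 2 px Chebyshev
neighborhood of the first; vectors below the threshold (default 1.03) are
replaced by the mean of valid neighbors within a radius of 2 *deformation
grid points* (an image-pixel radius would contain no neighbors at typical
window spacing), growing the radius only if an invalid cluster exceeds
it. Defaults: 50 px windows, 25 px overlap.

Global stage drift is estimated before PIV by upsampled phase correlation
of the whole images (1/100 px), the tensed image is shifted back by the
Fourier-shift theorem, and both images are cropped to the common field of
view.

## Substrate mechanics and FTTC

For a linearly elastic substrate the surface displacement is
`u = K ⊛ t`. In Fourier space the half-space (Boussinesq) tensor
diagonalizes in the longitudinal/transverse basis of the wavevector k:

    K_par  = 2(1+ν)(1−ν)/(E k),      K_perp = 2(1+ν)/(E k)

equivalent to the componentwise form
`K = 2(1+ν)/(E k³) [[(1−ν)k²+ν k_y², −ν k_x k_y], [−ν k_x k_y, (1−ν)k²+ν k_x²]]`.
For a substrate layer of thickness h bonded to a rigid support each
eigencomponent is multiplied by a correction derived from the bonded-layer
elasticity problem (antiplane for the transverse part, plane strain for
the longitudinal part; derived symbolically and verified against the
half-space limit):

    γ_perp(s) = tanh(s)
    γ_par(s)  = ((3−4ν) sinh s cosh s + s) / ((3−4ν) cosh²s + (1−2ν)² + s²)

with `s = k h`. Both go to 1 as `s → ∞` and to 0 as `s → 0`; for `s > 25`
they are evaluated as 1 to avoid `cosh` overflow (the error is < 1e-21).

The forward map multiplies the traction transform by K; the inverse
(FTTC) solves the 2×2 system per wavevector exactly. The zero mode is
nulled in both directions: the displacement of a balanced traction field
is defined only up to a rigid translation, and nulling the zero mode of
the traction enforces global force balance (the residual mean after
cropping/smoothing is subtracted so the net traction is exactly zero).

Instead of explicit regularization the reconstructed traction components
are smoothed with an isotropic Gaussian, σ given in µm (default 3 µm,
converted to grid units). σ = 0 disables smoothing, in which case the
inverse is the exact algebraic inverse of the forward map **on a common
periodic domain** (`pad_factor=1`); this is the configuration the
round-trip tests use. With the default `pad_factor=2` both maps zero-pad
to twice the linear size before the FFT and crop afterwards, which
suppresses wrap-around of the aperiodic kernel for isolated fields at the
cost of exact invertibility near the field border (zero-padding the
cropped displacement is not the inverse of the padded forward map; the
artifacts are confined to the border because the inverse kernel is
quasi-local).

## Monolayer stress (FEM)

Force balance in the cell sheet couples the traction the cells exert on
the substrate to the divergence of the 2D sheet stress. The sheet is
discretized with one bilinear quadrilateral element per masked pixel
(nodes on pixel corners; interior holes are filled with a warning;
disconnected masks are rejected because the rigid-body constraints assume
one body). Element stiffness uses 2×2 Gauss quadrature; for square
elements it is independent of the edge length, so a single 8×8 matrix is
assembled everywhere.

Each pixel contributes a nodal load `f = −t a²` shared equally by its
four corner nodes. Before solving, the net force is removed by
subtracting the mean force vector from every node, and the net torque
about the grid's center of mass is removed by rotating every force vector
by the closed-form angle `tan α = −T₀/D₀` with `T₀ = Σ r×f`,
`D₀ = Σ r·f` — the exact solution of the stated rotate-until-torque-free
procedure, so no iterative search is needed. α is recorded on the solved
system (typically ≪ 5°).

The stiffness matrix has exactly the three rigid-body null modes; the
system is closed by whole-system conditions `Σdx = 0`, `Σdy = 0`,
`Σ(dx·r_y − dy·r_x) = 0` (r from the center of mass). Because the
balanced load is orthogonal to the null modes, the constrained solution
is computed exactly by eliminating three anchoring DOFs, factorizing the
reduced sparse matrix (SuperLU, MMD ordering — the dense constraint rows
would otherwise destroy sparsity and cost ~40× more), and then shifting
by the rigid-body combination that zeroes the three constraints; this is
algebraically identical to the least-squares/KKT solution of the stacked
system. The classical pin-two-nodes scheme is available as
`scheme="pinned"` and agrees with the default on stresses to ~1e-12
relative (stress is invariant under rigid motion).

Strains are evaluated from the shape-function derivatives at each element
center and assigned to the element's pixel; stress follows from the
plane-stress law with tensor shear strain,
`(σ11, σ22, σ12) = E/(1−ν²) [[1, ν, 0], [ν, 1, 0], [0, 0, 1−ν]] (ε11, ε22, ε12)`.
Sheet constants default to E = 1 Pa, ν = 0.5: the load vector carries the
physics, E cancels exactly from the traction→stress map (verified to LU
round-off) and ν moves the mean normal stress by < 3% between 0.3 and
0.5. With forces in N and coordinates in m the output stress is the 2D
sheet stress in N/m directly.

The analysis region should cover all cell-generated tractions: because
the reconstructed traction is blurred, part of the edge bands falls
outside the cell outline, and a patch-matched grid misses it. Masks are
expanded by Euclidean distance (`expand_mask`), and `expansion_scan`
reports mean normal stress (averaged over the *original* patch outline,
so it is comparable against the input magnitude) and contractility as a
function of the margin.

## Scalar metrics

* Strain energy `U = ½ Σ u·t a²` over a mask, in J.
* Force epicenter: least-squares intersection of the lines of action,
  minimizing `Σ|t_i × (r_e − r_i)|²` (2×2 normal equations via an
  eigendecomposition). Directions in which the system is rank deficient —
  e.g. two exactly opposing forces constrain the epicenter only to their
  common line — are completed with the force-weighted centroid; a
  deficient *and* inconsistent system (parallel lines of action with no
  common point) is an error. Contractility is `Σ F_i·û_i` with `û_i` the
  unit vector from pixel i toward the epicenter; centripetal fields give
  positive values.
* Stress scalars from the per-pixel principal stresses σ1 ≥ σ2:
  max normal σ1, max shear (σ1−σ2)/2, mean normal (σ1+σ2)/2, each
  averaged over the cell mask; CV = std/mean of the per-pixel mean
  normal stress.
* Line tension: per polyline segment, `T = σ(midpoint)·n` with σ
  bilinearly interpolated and n the unit segment normal. Averages are
  length-weighted; the normal component keeps its sign (tension vs
  compression) while the shear is averaged as a magnitude — consistent
  with typical colony data where the average magnitude barely exceeds the
  average normal component. Reversing a polyline flips the normal
  convention but no reported quantity. Segments leaving the valid stress
  region are skipped with a warning.

## Synthetic reference experiment

The validation chain models a square cell patch of width L = 150 µm
(default) carrying uniform biaxial tension σ0 (σxx = σyy = σ0, σxy = 0)
in a 400 × 400 µm field at 1 µm/px. The traction field follows from force
balance by central differences — inward bands along the patch edges, half
of each band's mass on the first pixel outside the outline, each edge
integrating to σ0 per unit length — and the deformation field from the
forward Fourier map with the finite-thickness kernel (h = 100 µm).
σ0 is a nominal unit scale (stored as 1 N/m); every recovery metric is a
ratio in which it cancels. The default substrate (E = 500 kPa, ν = 0.49)
is deliberately stiff so that the nominal stress produces few-pixel bead
displacements — the regime PIV handles — and is irrelevant to the
recovery metrics because all maps are linear in 1/E.

Bead images are rendered as Gaussian spots (σ = 1.2 px, 0.06 beads/px²,
dense seeding as in TFM practice) at uniform random positions; the tensed
image displaces each spot by the bilinearly interpolated deformation at
its position. All randomness derives from the spec seed. Not modeled:
camera/readout noise, photobleaching, 3D bead positions, out-of-plane
displacements. Passing PIV tests therefore demonstrate correctness of the
correlation machinery, not robustness to detector noise.

### What the chain measures

Running the recovered (blurred) traction through the FEM and averaging
the mean normal stress over the patch outline gives, under the defaults:

* patch-matched grid (margin 0): ≈ 48% recovery — the central-difference
  band places half of the edge traction outside the outline, and a
  grid that excludes it cannot transmit that force;
* the margin scan rises steeply and unimodally to ≈ 93% at an 8 µm
  margin (≈ 0.5 px band offset + ~2.5× the 3 µm smoothing σ), then
  declines slowly (≈ 0.3%/µm) as the expanded grid adds elastic material
  around the patch that shares the load;
* at a 5 µm margin the recovery is ≈ 90%;
* the optimal-margin recovery grows with patch width (edge effects scale
  with perimeter/area), from ≈ 66% at 20 µm to ≈ 93% at 150 µm;
  margin-expanded grids dominate patch-matched grids at every width;
* contractility (over a 12 µm-expanded area) is recovered to ≈ 0.2%
  (smoothing preserves the total centripetal force), and the epicenter
  exactly; the input contractility of the analytic square field equals
  `4 L σ0 asinh(1)` under the epicenter-projected definition;
* the CV of the mean normal stress over the patch is ≈ 0.08 for the
  recovered field (0 for the input): the residual heterogeneity is the
  stress ramp in the few-µm edge zone of the patch.

These numbers are computed, not asserted, by `scripts/acceptance.py` and
the validation tests; they move with the smoothing σ (a smaller σ shifts
the optimum margin left and raises small-patch recovery roughly in
proportion) — σ = 3 µm is kept as the standard choice for noisy real
data.

## Known limitations

* 2D only: z-tractions and z-displacements are ignored; valid for nearly
  incompressible substrates and flat colonies.
* FTTC assumes a laterally homogeneous, linearly elastic substrate.
* The Gaussian low-pass limits spatial resolution by design; no L1/L2 or
  Bayesian regularization is provided.
* The FEM strain field has no physical meaning (cell and substrate
  strains are not coupled); only the stress is interpretable.
* Cell segmentation and counting are out of scope; masks and boundary
  polylines are user inputs (label image + CSV).
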