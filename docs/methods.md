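# Methods

## The registration model

`divcurlreg` estimates a dense displacement field u aligning a moving image
M to a fixed image F by minimising

    D(F, M, u)  +  Σ_m α_m ‖∇^{σ_m} div u‖²  +  Σ_n β_n ‖∇^{κ_n} curl u‖²

where D is an image-similarity functional (the local correlation
coefficient by default) and the regulariser places *independent* penalties
of arbitrary derivative order on the divergence and the curl of u.  Setting
σ = κ = 0 penalises the amplitudes of local volume change and rotation;
σ = κ = 1 penalises their roughness without penalising the quantities
themselves.  Because compressibility and rotation are controlled by
separate weights, prior physical knowledge (an incompressible organ, an
irrotational expansion) maps directly onto the parameters.

## Helmholtz variables and the solenoidal constraint

The optimisation is carried out in the div-curl variables
f¹ = div u, (f², f³, f⁴) = curl u rather than in Cartesian components.
u is recovered from f by solving three Poisson equations

    Δu¹ = ∂x f¹ + ∂z f³ − ∂y f⁴,   Δu² = ∂y f¹ + ∂x f⁴ − ∂z f²,
    Δu³ = ∂z f¹ + ∂y f² − ∂x f³,

with homogeneous Dirichlet boundary conditions.  The forward and inverse
maps are mutual inverses only where the curl channels are themselves a
curl, i.e. on the constraint manifold

    C = ∂x f² + ∂y f³ + ∂z f⁴ = 0 ,

which is enforced with an augmented Lagrangian: a quadratic penalty θ/2‖C‖²
plus a multiplier field λ updated by λ ← λ + θC each iteration.

Each iteration performs: u = inverse_map(f); similarity value and gradient
at u; chain-rule pullback of the gradient to f-space; per-channel outlier
pruning; automatic time step; one semi-implicit update per channel; the
multiplier update.  The regulariser operator is diagonal in a DCT-II basis
with eigenvalues Λ^ρ = (6 − Σ_m 2cos((j_m−1)π/n_m))^ρ — the ρ-th power of
the reflected-boundary 7-point negative Laplacian — so the implicit solve
costs the same for any derivative order, which is what makes the
arbitrary-order regulariser practical.

## Numerical design choices

**Stencils.**  All public derivative operators use second-order central
differences with replicated-edge boundary handling.  Central first
differences compose to the stride-2 ("wide") Laplacian, whereas the
spectral Poisson solver (type-I sine transform) inverts the compact 7-point
operator; the base reconstruction therefore carries an O(h²) consistency
error (~1.4e-2 relative at 32³ for a smooth interior bump).  A staggered
forward/backward difference pair would remove this error algebraically, but
it changes the constraint-flow generator from the wide Laplacian (spectral
radius 3) to the compact one (radius 12), and the penalty coupling
t·θ = 0.4 used here is explicit-Euler stable only up to radius 5 — the
staggered variant diverges.  The adopted resolution keeps central stencils
and adds **one defect-correction sweep** to the inverse map,
u = 2A(f) − A(G(A(f))) with A the base solve and G the forward map, which
squares the error operator: round-trip error 3.6e-2 / 1.4e-3 / 1.7e-4 at
16³/32³/64³, i.e. fourth-order in practice.

**Adjoint-exact gradient pullback.**  The pullback is the exact transpose
of the defect-corrected linear map f ↦ u, assembled from the self-adjoint
Poisson solve and the exact transposed replicated-edge stencils.  A
directional-derivative oracle verifies it to ~1e-12.  A structural
consequence: the curl-channel block of the pulled-back gradient is itself a
discrete curl, hence exactly solenoidal away from the boundary.

**Time step and penalty weight.**  t = 0.02 / max_x ‖(δD/δf¹..⁴)(x)‖₂,
recomputed every iteration, so the max-norm of t·gradient equals 0.02
exactly; θ = 0.4/t couples the penalty to the step.  With the wide
Laplacian's spectral radius 3, the explicit constraint flow has per-step
amplification |1 − 0.4μ| ≤ 1, stable.

**Multiplier low-pass.**  The multiplier acts on the solution only through
∇λ; residual components near the grid's resolution limit lie in the
near-null space of that coupling, so a plain first-order multiplier update
integrates them without effect and λ grows without bound (measured: max|λ|
≈ 42 after 300 iterations, with the residual an order of magnitude *worse*
than penalty-only).  The update is therefore followed by a Gaussian
low-pass of λ (SD 2 voxels, `OptimizerConfig.lam_smooth_sd`), restricting
the controller to resolvable scales; λ then stays O(1) and the residual
plateaus ~26x lower.  Alternatives measured and rejected: updating every
K-th iteration, under-relaxation, hard spectral projection.

**Gradient conventions.**  Metric *values* are per-voxel means (scale-free
across pyramid levels); metric *gradients* are functional-derivative
densities (no 1/N factor).  The density scale is what makes the automatic
step, the regulariser weights α, β ∈ [0.1, 10], and the Euler-Lagrange
balance mutually consistent; with mean-scaled gradients the automatic step
becomes so large that the implicit denominators suppress every nonzero
frequency and the registration stalls.

**LCC.**  D = −⟨c/√(v_F·v_W + ε)⟩ with Gaussian-window (SD w, default 2
voxels) local covariance c and variances v.  The window filter uses
half-sample reflection, which makes it exactly self-adjoint and
constant-preserving, so the full analytic gradient is exact including
boundaries.  ε is the configured value (default 1e-6) times the product of
the two global variances, making D exactly invariant to affine intensity
maps of either image.  The default *truncated* gradient keeps only the
pointwise terms multiplying the warped-image gradient — the classic cheap
LCC force; the full variant back-propagates through the window convolutions
and is used by the finite-difference oracle.  Warping is trilinear with
replicated edges, and similarity gradients chain through the *exact*
Jacobian of the trilinear interpolant at the sample points (not a
finite-difference gradient of the warped image) — required for the
gradient oracle to hold at 1e-3 on non-smooth images.

**Outlier pruning.**  Each pulled-back channel gradient is clamped to
mean ± 3 SD (computed over the grid), with out-of-band values mapped to the
most extreme in-band datum; the automatic step is computed from the pruned
gradients, which allows much larger steps when isolated spikes occur.

**Pyramid.**  Levels are descending powers of two, as many as keep every
dimension ≥ 16; images are pre-smoothed with SD (s−1)/2 before linear
downsampling by s (no smoothing at s = 1).  The div-curl channels and λ
transfer to the next level by linear resampling without value rescaling —
divergence and curl are voxel-per-voxel derivative quantities, invariant
under uniform rescaling of both displacement and coordinates.  λ is
carried (not reset) across levels.  The stopping rule is a fixed iteration
budget per level (default 150), optionally with a relative-change early
stop.

## Synthetic scenes and what they do (not) show

The generators produce: blob images (sums of random axis-aligned Gaussians,
intensities in [0,1], mild noise) as stand-ins for anatomical contrast;
radial fields u = g(r)·r̂ with g(r) = peak·(r/r₀)·exp((1−(r/r₀)²)/2)
(irrotational by construction; invertible while peak < radius/2);
solenoidal fields curl(A) of smoothed random interior potentials
(divergence-free to round-off away from the boundary); and cubic B-spline
interpolations of random control-point displacements (knot spacing 8
voxels) emulating deformations generated by displacing randomly selected
control points.  The fixed image is always the moving image warped by the
truth field, so the exact answer is known everywhere.  These scenes have
piecewise-smooth contrast and exactly known, noise-free truth; they do not
reproduce CT/MR noise statistics, sliding interfaces, absent
correspondences, or intensity non-stationarity, so passing tests establish
the correctness and the physics-control behaviour of the optimiser, not
clinical-grade accuracy.

Experiment problem sizes (64×64×32 single-level for the constraint study —
the same grid the original convergence analysis used — 64³ two-level for
recovery, 48³ sweeps for the physics controls, 100–300 iterations) are
chosen so each driver completes in a few minutes on one CPU.

## Known limitations

* The constraint-contrast ratio between the unconstrained and
  augmented-Lagrangian runs is ~4-5 here, not orders of magnitude: with an
  adjoint-exact pullback the similarity force is already nearly solenoidal,
  so the unconstrained run accumulates very little residual to begin with.
  The qualitative structure (monotone growth without the constraint, a
  bounded plateau with it) is reproduced.
* Fractional derivative orders are not supported (integer 0..4).
* Single-modality similarity only (LCC, SSD); no mutual information.
* No spatially varying regularisation weights and no L1/discontinuity-
  preserving variants; sliding motion violates the smoothness model.
* The Dirichlet boundary condition of the reconstruction assumes
  displacements vanish at the image boundary; fields with large boundary
  motion are reconstructed with a boundary-layer error.
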