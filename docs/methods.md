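# Methods

This note records the model, the numerical choices, and the design
decisions behind `glioextent`, in enough detail to reproduce every
operator bit-for-bit.

## Model

The forward tumor model is the fully anisotropic
advection–diffusion–reaction equation for the tumor volume fraction
u(x, t) ∈ [0, 1]:

    ∂u/∂t = ∇·(D(x)∇u) + ∇·((∇·D(x)) u) + ρ u (1 − u),   ∇u = 0 on ∂Ω,

with a cell-wise symmetric positive definite diffusion tensor D(x)
(units length²/time) and logistic growth rate ρ (1/time).  The myopic
drift term ∇·((∇·D)u) appears whenever D is spatially variable; for
homogeneous fields it vanishes identically.

The stationalized problem replaces the front's lateral motion with the
closed-form penalty derived from the Fisher-KPP co-moving limit
solution U(x̃) = (1 + e^{x̃/√6})⁻² at speed ṽ = 5/√6:

    p(u) = |v| √(2/3) (1 − √u) u,

which equals −|v| U′(x̃(u)) on the invertible range.  The stationary
solution is pinned at u = θ (default 0.16, the imaging visibility
threshold) on the discrete border of the visible region and satisfies
zero-Neumann outer boundaries.  The identity is exact only for the
fully equilibrated 1D homogeneous front; everywhere else it is an
approximation whose quality the metrics module measures.

Dimensional runs use the penalty verbatim with the user's |v| (the
dimensional fixture uses the literature-style values α = 5·10⁻¹²,
ρ = 10⁻⁶ s⁻¹, v = 2.04·10⁻⁶ m/s).  Strict re-dimensionalization of the
1D derivation would insert an extra √(ρ/D) factor into the penalty;
the verbatim form is retained deliberately, because the method's whole
premise is that only the *relative* strength of diffusion, growth and
penalty matters, and the penalty magnitude is the user's estimate of
the front speed in whatever unit system the run uses.  The
inconsistency is confined to how a user interprets v for dimensional
runs and does not affect nondimensional validation.

Effective reaction ρu(1−u) − p(u) with ρ = 1, v = 5/√6: zeros at
u ∈ {0, 4/9, 1}; penalizing for u < 4/9, growing above.  Because
θ = 0.16 < 4/9, small-amplitude initial guesses converge to the
outward-moving branch (OMS); guesses near 1 select the inward branch
(IMS), which is irrelevant clinically but verified to exist.

## Discretization

* Structured axis-aligned grids, uniform spacing per axis; nodes carry
  the solution, cells (the dual grid) carry tensors and drift vectors.
  Node (i₀,…) sits at (i₀h₀,…); flat indices are C-order (last axis
  fastest); cells are half-open boxes owned by their lower corner, and
  a point on a shared face belongs to the lower-index cell.
* Q1 (multilinear) finite elements with 2-point Gauss quadrature per
  axis — exact for the multilinear mass/stiffness integrands with
  cell-constant tensors.  The stiffness operator applies
  −∫∇φᵢ·D∇φⱼ (symmetric negative semidefinite), the drift term is
  integrated by parts once (consistent with zero total flux through
  the outer boundary), and the consistent mass matrix is used both for
  the time derivative and for the reaction (group finite-element
  treatment: ∫f(u)φᵢ ≈ Σⱼ Mᵢⱼ f(uⱼ), giving the sparse Jacobian
  M·diag(f′(u))).
* Matrix divergence b = ∇·D is precomputed per cell by first-order
  finite differences of neighboring cell tensors (central in the
  interior, one-sided at the boundary).  Row-wise convention
  bⱼ = Σᵢ ∂ᵢDᵢⱼ; for symmetric tensors the column convention
  coincides.
* Internal Dirichlet constraints are identity rows: constrained rows
  of the residual become uᵢ − θ and of the Jacobian become eᵢ.  After
  convergence pinned entries are assigned θ exactly.  The discrete
  constraint set is the one-node-thick shell (nodes ≥ θ with a < θ
  face neighbor); optionally the full visible interior is pinned
  (`fill_interior=True`), which changes nothing outside the visible
  region.

## Solvers

* Forward: implicit Euler (unconditionally stable), reaction fully
  implicit, each step solved by damped Newton with backtracking line
  search.  Default per-step strategy is a frozen Jacobian (assembled
  and LU-factorized once at the step's initial iterate, reused for the
  within-step iterations); if that stalls the step is retried with
  full Newton.  Tolerances: absolute residual 1e−10, relative
  reduction 1e−8, max 50 iterations, up to 20 step halvings.  Default
  dt = 0.1 (nondimensional).
* Positivity guard: wherever an iterate leaves [0, 1] the model's
  reaction is replaced node-wise by n(ω) = −ρω (ω < 0) or ρ(1 − ω)
  (ω > 1); the derivative used in the Jacobian is −ρ there.  The
  penalty derivative at u → 0⁺ uses the one-sided limit
  d/du[(1 − √u)u] → 1 so the Jacobian stays finite.
* Stationary: damped Newton from the branch-selecting guess.  The
  outward default starts at 1e−3 on free nodes outside the visible
  region and at 1.0 on nodes the segmentation marks visible — the
  segmentation states that the density exceeds θ there, and without
  that information a uniformly small guess converges to the spurious
  low branch *inside* the constraint (the tumor bulk would be
  estimated as ≈ 0).  Outside the constraint both guesses give the
  same branch.
* Pseudo-transient fallback: on coarse 3D grids the pinned "staircase"
  shell can leave plain Newton without a usable basin of attraction.
  The stationary solver then integrates the constrained stationalized
  dynamics in pseudo-time (backward Euler, adaptive step: grow ×1.4 on
  success up to 50, shrink ×0.25 on failure or residual growth) and
  periodically attempts a Newton polish.
* Linear solves: sparse direct (SuperLU) by default — deterministic,
  so identical scenarios re-run to hash-identical artifacts — with an
  ILU-preconditioned BiCGSTAB alternative.

## Synthetic data

The scenario generators emulate the study conditions the validation
experiments need:

* 1D homogeneous: [0, 200] with 1000 elements, ρ = D = 1, ṽ = 5/√6,
  Gaussian initial condition (amplitude 1, sd 1 length unit ≡ 5 cells
  at this resolution, centered), dt = 0.1, pinning at t̃ = 20.  The sd
  is specified in physical units so refinement studies keep the same
  continuum problem.
* Randomly perturbed isotropic fields D_β = 𝟙_d δ^{1/d},
  δ ~ unif(1−β, 1+β), one independent draw per cell from a
  counter-based Philox generator keyed by the seed (C-order cell
  order), so det D equals the draw cell-wise and the field-mean
  determinant is ≈ 1 for every realisation.
* 2D "butterfly": 200×200 domain, isotropic tensors scaled by
  1 + 0.9 sin(3πx₁/L_x) — three vertical bands, fast–slow–fast — with
  the Gaussian seed at (50, 50) in the left fast band; 100×100 cells,
  t̃ = 20.
* 3D synthetic: 44³ domain with 20³ cells, diagonal tensors with
  eigenvalues (1+a, 1, 1/(1+a)), a(z) banded sinusoidally — unit
  determinant, fractional anisotropy up to ≈ 0.4 in bands; Gaussian
  sd 1.5, pinning at t̃ = 4.5, dt = 0.75.  This stands in for external
  DTI volumes in the automated suites; the external scenario (NIfTI
  tensor volume, α-scaled) is wired but requires a user-supplied file.

What the generators do *not* emulate: real DTI noise and non-SPD
voxels (only an opt-in eigenvalue-clamping repair is provided), tissue
segmentation error in ∂Ω_i, anatomical boundaries, or tumor models
with chemotaxis terms.  Passing tests therefore demonstrate the
correctness and internal consistency of the stationalization machinery
under controlled conditions, not clinical accuracy.

## Known numerical behavior and limitations

* Front speed: the implicit-Euler pulled front travels slightly fast —
  the effective linear growth per step is −ln(1−dtσ)/dt > σ — so at
  dt = 0.1 the measured u = 0.5 crossing speed over t̃ ∈ [10, 20] is
  ≈ 2.09 (theory 2, which also carries the transient −(3/2)ln t/t
  correction); halving dt and h moves it to ≈ 1.98.
* Because the forward *reference* front runs a few percent fast, the
  stationary estimate's small level sets sit slightly inside the
  forward tail at desk-scale dt (mild apparent underestimation at the
  1e−2 level in the 2D band test); the signed error field still shows
  both over- and underestimation, and the symmetric difference shrinks
  under refinement.
* 3D interior branch: at coarse resolutions where the visible region
  spans only ~1.5 front widths, the high-amplitude interior solution
  of the shell-pinned problem is below its critical size and
  collapses; the 3D scenario therefore pins the full visible interior,
  which solves the identical problem on the clinically read-out
  outside.
* The characteristic distance's spherical normalization assumes a
  ball-like reference region; the exact marching-squares/cubes surface
  mode is preferred for strongly non-spherical regions (both are
  computed in the pipeline).
* Gradient clouds in strongly random media (β = 0.8) scatter by up to
  ~2× around the analytic curve cell-by-cell (the local front steepens
  as 1/√D); the bin-averaged cloud still tracks the curve, which is
  the property the method relies on.
* Region measure: cells are weighted by the fraction of their corner
  nodes above the threshold — a sub-cell estimate exact to one cell
  layer; the 1D characteristic distance uses the two-endpoint
  normalization |A⊕B|/2 directly since a volume-equivalent radius is
  ill-posed there.
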