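# glioextent

Estimating the invisible extent of glioblastoma invasion from a single
imaging time point, by *stationalizing* reaction–diffusion tumor-growth
models.

## The problem

Glioblastoma multiforme infiltrates tissue far beyond the margin visible
on MRI/DTI: imaging only detects the tumor above a volume-fraction
threshold of about θ ≈ 0.16, while malignant cells have been cultured
centimeters outside the visible border.  Forward growth models of the
form

    ∂u/∂t = ∇·(D(x)∇u) + ∇·((∇·D(x)) u) + ρ u (1 − u)

(with a per-voxel symmetric positive definite diffusion tensor **D**
derived from DTI and logistic growth rate ρ) can describe this
infiltration, but they need an initial condition and a per-patient
parametrization that clinical data cannot supply: at diagnosis there is
exactly one scan, and treatment starts immediately.

## The method

In the homogeneous 1D limit the model reduces to the Fisher-KPP
equation, whose travelling front at the special dimensionless speed
ṽ = 5/√6 has the closed form

    U(x̃) = (1 + exp(x̃/√6))⁻²,

invertible on (0, 1).  Expressing the front's gradient as a function of
its amplitude turns the co-moving advection term ṽ·∇u into an
amplitude-only penalty

    p(u) = |ṽ| √(2/3) (1 − √u) u,

so the equilibrated front solves a *stationary* boundary-value problem:

    0 = ∇·(D∇u_s) + ∇·((∇·D) u_s) + ρ u_s (1 − u_s) − p(u_s),
    u_s = θ on ∂Ω_i (the visible tumor border),  ∇u_s = 0 on ∂Ω.

The segmented tumor border from a single scan pins the solution
(an internal Dirichlet constraint); solving outward yields the full
density profile — including the invisible tail — without knowing the
carciogenesis time or location.  The effective reaction
ρu(1−u) − p(u) penalizes amplitudes below 4/9 and grows above it, so
small-amplitude initial guesses select the clinically relevant
outward-moving branch of the constrained problem.

The package provides the closed-form machinery, Q1 finite-element
operators on structured grids, implicit-Euler forward solvers and
Newton stationary solvers, synthetic diffusion-tensor generators
(randomly perturbed isotropic fields, banded 2D/3D fields, scaled DTI
volumes), and the level-set metrics used to validate the approximation
(symmetric difference, characteristic level-set distance
L_B = |A⊕B|/|∂A|, gradient clouds, Péclet screening τ = |b|L/|D|).

## Worked example

Reconstruct a 1D front from its visible part only:

```python
import glioextent as ge
from glioextent.scenarios import gaussian_ic

grid = ge.build_grid((200.0,), (1000,))          # [0, 200], h = 0.2
field = ge.homogeneous_field(grid, 1.0)          # D = 1 (nondimensional)

# "ground truth": forward growth from a small Gaussian to t = 20
traj, _ = ge.solve_forward(
    grid, field, ge.ModelParams(rho=1.0), gaussian_ic(grid, 1.0, 1.0),
    ge.TimeControls(t_end=20.0, dt=0.1),
)
u_true = traj[-1][1]

# keep only what imaging would show (u >= 0.16) and re-estimate the rest
cons = ge.extract_constraints(u_true, theta=0.16)
u_est, report = ge.solve_stationary(grid, field, ge.ModelParams(), cons)

outside = u_true.values < 0.16
print("pinned nodes:", len(cons))
print("Newton iterations:", report.iterations)
print("max error outside visible region:",
      float(abs(u_est.values - u_true.values)[outside].max()))
A = ge.threshold_region(u_true, 1e-2)
B = ge.threshold_region(u_est, 1e-2)
print("characteristic distance at the 1e-2 level:",
      ge.characteristic_distance(A, B))
```

Output:

```
pinned nodes: 2
Newton iterations: 6
max error outside visible region: 0.006128720236430074
characteristic distance at the 1e-2 level: 0.2
```

The stationary estimate reproduces the hidden tail of the forward
solution to 0.006 in amplitude, and the 1% level set — a proxy for a
treatment margin — is off by 0.2 length units, a small fraction of the
~10-unit front width.

The same pipeline runs from the command line:

```bash
glioextent fixtures --kind 2d-butterfly --out configs/
glioextent estimate --config configs/2d-butterfly.yaml --out runs/butterfly
```

which writes the forward/stationary/error fields (VTK + HDF5), a
level-set sweep (CSV) and a reproducible run record (JSON).

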