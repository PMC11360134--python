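# Methods

## Model

Charge equilibration (Qeq) assigns atomic partial charges **Q** = {q_i} by
minimizing

    E_Qeq(Q) = E_elec(Q) + Σ_i ( E_i + χ_i q_i + ½ J_i q_i² )

subject to Σ_i q_i = Q_tot.  The per-element parameters are the
electronegativity χ_i (hartree/e), the hardness J_i (hartree/e², J_i > 0),
a Gaussian width σ_i (bohr) and an energy offset E_i (hartree).  The
electrostatic energy is that of the smooth density

    ρ(r) = Σ_i q_i ρ_i(r),
    ρ_i(r) = (2π σ_i²)^(−3/2) exp(−|r − r_i|² / (2 σ_i²)),

each ρ_i normalized to one, summed over all periodic images of a cell with
lattice matrix **h** (rows h₁, h₂, h₃, det **h** > 0).  σ is the *standard
deviation* of the Gaussian; parts of the Qeq literature use an
exp(−r²/σ²) convention, so widths from other codes may need rescaling.
Everything is in Hartree atomic units (e = 1, 4πε₀ = 1), which makes the
reciprocal Coulomb kernel 4π/|G|².

Because E_elec = ½ Qᵀ**A**Q with a symmetric positive-definite Coulomb
matrix **A**, E_Qeq is a strictly convex quadratic and the constrained
minimum is unique.  Stationarity is the bordered (KKT) linear system
(**A** + diag(J)) Q + χ + λ·1 = 0 with 1ᵀQ = Q_tot; the scalar λ is the
electronegativity level every atom equalizes to.

## Matrix-free particle-mesh solver

**A** is dense and its N² elements are never formed.  One product **A**·Q
is evaluated as

1. *spread*: rasterize ρ(Q) on a regular fractional-coordinate grid.  Each
   Gaussian is evaluated only within r_cut = σ_i √(−2 ln ε_trunc) of (an
   image of) the atom (ε_trunc = 1e−10 by default, so r_cut ≈ 6.8 σ_i);
2. *solve*: Ṽ(G) = 4π ρ̃(G)/|G|² by forward/inverse FFT, with Ṽ(0) = 0;
3. *probe*: (A·Q)_i = ∫ V ρ_i d³r by midpoint quadrature (weight Ω/N_grid)
   over the atom's local support.

This makes each product O(N_grid log N_grid + N_at) — quasi-linear, since
the grid grows with the cell volume.  The spread/probe supports are built
once per geometry and cached; for orthorhombic cells the Gaussian
factorizes per axis, so per-atom work reduces to three short 1-D weight
vectors, slice-wise accumulation and BLAS contractions, with periodic
images folded exactly axis by axis.  General triclinic cells use dense
per-atom support blocks with explicit minimum-image displacement vectors.

Supports wider than half the smallest cell height simply sum every
contributing image (exact); pass `multi_image=False` to get a refusing
guard instead.  The operator assembled this way is exactly symmetric
positive semi-definite by construction (quadrature-weighted SᵀKS form), so
conjugate gradients apply without caveats.

The constraint manifold is a hyperplane, so CG runs on projected vectors:
P g = g − mean(g)·1.  Every iterate then satisfies the charge constraint
to rounding error.  Convergence is declared on the max-norm of the
*projected* residual (the raw residual tends to −λ·1 and cannot vanish);
λ is recovered at the end as −mean(χ + M·Q).  The default initial guess is
the uniform feasible vector q_i = Q_tot/N; a warm start (e.g. the previous
MD step's charges) can be supplied and demonstrably cuts iterations.  An
optional Jacobi preconditioner uses the analytic diagonal
M_ii = 1/(σ_i√π) + J_i inside the projected subspace; it is off by default
(plain CG converges in a few tens of iterations even for extreme parameter
spreads).

### Choice of G = 0

The G = 0 Fourier coefficient of the potential is dropped.  For charged
cells this is the uniform neutralizing-background (jellium) convention;
energies of charged cells are defined only up to it.  The dense Ewald
reference applies the matching constant −(2π/Ω)(β² − σ_i² − σ_j²) so both
routes answer the same question.

## Energies, forces, stress

*Plancherel identity.*  E_elec is evaluated as the reciprocal series
(1/2Ω) Σ_{G≠0} 4π|ρ̃(G)|²/|G|².  On the discrete grid this equals the
real-space quadrature ½ Σ ρV·(Ω/N) identically (both are the same finite
quadratic form), and the test suite enforces agreement to 1e−12 relative.
Every series term is nonnegative, so E_elec ≥ 0 for any density.

*Forces.*  At fixed charges, F_i = −q_i ∫ V ∂ρ_i/∂r_i d³r with the
analytic Gaussian gradient ∂ρ_i/∂r_i = (d/σ_i²) ρ_i evaluated on the same
support and quadrature as the energy — so the computed force is the exact
derivative of the *discrete* energy up to the truncation threshold, and
Newton's third law holds to quadrature error.

*Stress.*  Under a homogeneous deformation r′ = (1+ε)r the reciprocal
vectors co-transform as G′ = (1+ε)^{−T}G, leaving phases invariant.  Three
pieces of the reciprocal series carry strain dependence: the 1/Ω
prefactor, the kernel (d(1/|G′|²)/dε_μν = 2 G_μ G_ν/|G|⁴), and the density
coefficients, whose derivative is the transform of δ_μν ρ plus the six
real-space fields ∂ρ/∂ε_μν = −Σ_i q_i (d_μ d_ν/σ_i²) ρ_i(d) (summed over
images like the density itself; six FFTs because the tensor is symmetric).
The macroscopic stress is σ_μν = (1/Ω) ∂E/∂ε_μν.

*Total derivatives for downstream energies.*  When an energy E(Q, R, h)
consumes the equilibrated charges without being minimized over them (the
fourth-generation MLP situation), the implicit dependence Q(R, h) is
handled by one adjoint solve

    M λ + μ·1 = −∂E/∂Q,   Σ_i λ_i = 0,

with the same matrix-free operator and projected CG.  The chain-rule
terms then become λᵀ(∂χ/∂R) — supplied by the owner of the χ model
through a contraction hook — and the Coulomb coupling λᵀ(∂A/∂R)Q, which
collapses to per-atom support integrals

    λ_i ∫ V^Q ∂ρ_i/∂r_i + q_i ∫ V^λ ∂ρ_i/∂r_i

with ρ^λ = Σ λ_i ρ_i and its potential V^λ.  The strain analogue couples
(ρ^λ, ρ^Q) and their strain-derivative fields in reciprocal space.  A
total-derivative evaluation therefore costs O(1) Poisson solves
independent of N (asserted by a test).  When E *is* E_Qeq, the envelope
property of the constrained minimum makes λ = 0 and the code takes the
variational shortcut.  Hardness is treated as strictly element-specific;
position-dependent hardness is out of scope.  ∂χ/∂R is never computed
here — χ models live outside and interact only via the hook
`hook(weights) -> Σ_j w_j ∂χ_j/∂r_i`.

## Dense Ewald reference

The oracle builds the full Gaussian-pair Coulomb matrix by Ewald
summation: a β-screened reciprocal series over 0 < |G| ≤ G_max (β chosen
by the classic √π (N/Ω²)^(1/6) work-balance heuristic, translated to a
width and floored at √2·σ_max), a short-ranged real-space lattice sum of
[erfc(r/√2β) − erfc(r/√2Γ)]/r with Γ² = σ_i² + σ_j², the analytic r→0
limit for the self terms (yielding A_ii = 1/(σ_i√π) plus image
contributions), and the background constant above.  Cutoffs are derived
from a target accuracy of 1e−12 and validated; the result is independent
of β to ~1e−14 (a tested identity).  The bordered system is then
factorized directly (guarded to ≤ 5000 atoms — this module is
intentionally the slow, high-accuracy reference).

## Synthetic fixtures

`random_test_system` generates the heterogeneous robustness benchmark:
800 atoms of 60 elements placed uniformly at random with minimum-image
pair distance ≥ 0.4 bohr, hardnesses ~ U[0.4, 1.4], electronegativities
and initial charges standard normal (initial charges rigidly shifted onto
the constraint).  Conditions the benchmark definition leaves open are
fixed as package conventions: cubic 20-bohr cell, σ ~ U[0.5, 1.0] bohr,
neutral cell — all configurable `FixtureSpec` fields.  The generator
emulates parameter heterogeneity and hard close contacts, *not* realistic
chemistry: passing tests show solver/derivative correctness and
robustness, not the physical fidelity of any parameterization.
`toy_chi_model` is a smooth pairwise χ(R) with a cosine cutoff standing in
for a learned electronegativity model; its hook is validated against
finite differences.

## Numerical choices and verification

- **Grid.** Default plane spacing ≤ min(σ_i)/3 per axis, rounded to
  2^a·3^b·5^c FFT sizes.  At three points per σ the aliasing/quadrature
  error of the sampled Gaussians is far below the 1e−10 truncation
  threshold, which then dominates the (tiny) discrepancy between mesh and
  Ewald routes.  Spacing is the single accuracy knob; no reciprocal-space
  damping beyond the grid's natural Nyquist limit.
- **Tolerances.** Solver default 1e−8 on the projected-residual max-norm;
  validation runs use 1e−9 to 1e−11.  Finite-difference oracles use
  central differences with steps of 1e−5 bohr (forces/strain) and 1e−6
  (charge-space and dense-matrix probes).
- **Degenerate inputs.** Non-positive hardness/width are rejected at
  construction; a non-positive-definite operator (pᵀMp ≤ 0, signalling
  broken parameters) aborts CG with a diagnostic; non-convergence raises
  an error carrying the best iterate and the residual history.
- **Determinism.** No hidden global randomness: every fixture takes a
  seed and reproduces bit-identically; CG has no randomized restarts.
- **Verification strategy.** Every analytic result has an independent
  route exercised in the tests: mesh density vs. brute-force image sums;
  mesh operator vs. dense Ewald matrix; energies vs. the closed-form
  Gaussian pair integral (isolated limit) and the Ewald oracle; every
  derivative vs. central finite differences of the *composed* energy with
  charges re-equilibrated at each perturbed geometry; adjoint terms vs.
  dense double sums.
- **Problem sizes.** The validation suite uses the full 800-atom
  benchmark for convergence, 4–100-atom systems (20 of them) for oracle
  equivalence, 6–12-atom systems for finite-difference work, and a
  200 vs. 1600 atom pair at matched density, matched parameter table and
  fixed CG iteration count for the cost-scaling property (the matched
  table keeps the mesh resolution per unit length identical, so the two
  measurements differ only in size).

## Known limitations

- Energies of charged cells depend on the jellium convention; comparing
  them across different cell volumes requires care.
- No smooth-PME B-spline interpolation: accuracy is bought with grid
  resolution, which is wasteful for very small σ (points ∝ σ_min^−3).
- The direct-evaluation supports assume σ varies by at most an order of
  magnitude; extremely wide σ in tiny cells degenerate to all-image sums
  that defeat the truncation.
- No MPI/GPU parallelism, no multilevel CG, no subsystem charge
  constraints, and no trajectory driver; single structures only.
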