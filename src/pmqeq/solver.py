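"""Matrix-free charge equilibration by constraint-projected conjugate gradients.

The Qeq energy is a convex quadratic in the charges,

    E_Qeq(Q) = 1/2 Q^T M Q + chi^T Q + sum_i E_i,   M = A + diag(J),

minimized on the hyperplane sum_i q_i = Q_tot.  The Coulomb matrix A never
materializes: A.Q is evaluated by spreading the density of Q on the mesh,
solving Poisson's equation with FFTs, and probing the potential back on each
atom's local support ((A.Q)_i = integral V[rho(Q)] rho_i), at quasi-linear
cost per product.

Because the constraint manifold is a hyperplane, any step along a projected
direction preserves the constraint exactly, so plain conjugate gradients on
the projected system converge like unconstrained CG on a positive-definite
operator.  Projection is P g = g - mean(g) 1; the scalar Lagrange multiplier
is recovered at the solution from the unprojected gradient, which there is
constant: chi + M Q = -lambda 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (AtomicSystem, ConvergenceError, PmqeqError, QeqParameters,
                   QeqResult, ResolvedParams, resolve_parameters)
from .mesh import Mesh, MeshField, SupportTable, DEFAULT_EPS_TRUNC
from .poisson import electrostatic_energy, solve_poisson

__all__ = [
    "SolverSettings",
    "QeqOperator",
    "project_constrained",
    "apply_A",
    "apply_M",
    "qeq_gradient",
    "solve_qeq",
]


@dataclass
class SolverSettings:
    """Iterative-solver knobs.

    tolerance : float
        Convergence threshold on the max-norm of the *projected* residual
        (hartree/e).  The raw gradient cannot vanish when the multiplier is
        nonzero, so the projected one is the meaningful metric.
    max_iterations : int
    initial_guess : array or None
        Warm-start charges; default is the uniform feasible guess
        q_i = Q_tot/N (e.g. pass the previous MD step's charges).
    preconditioner : "none" | "diagonal"
        Optional Jacobi preconditioning with the analytic diagonal
        M_ii = 1/(sigma_i sqrt(pi)) + J_i, applied inside the projected
        subspace.  Off by default.
    """

    tolerance: float = 1e-8
    max_iterations: int = 300
    initial_guess: np.ndarray | None = None
    preconditioner: str = "none"

    def __post_init__(self):
        if not self.tolerance > 0.0:
            raise ValueError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.preconditioner not in ("none", "diagonal"):
            raise ValueError(f"unknown preconditioner {self.preconditioner!r}")


def project_constrained(g: np.ndarray) -> np.ndarray:
    """Project a gradient onto the constraint hyperplane sum(dq) = 0:
    returns g - mean(g); the output sums to zero and the map is idempotent."""
    g = np.asarray(g, dtype=float)
    return g - g.mean()


class QeqOperator:
    """Matrix-free A and M products bound to one geometry.

    Builds the per-atom support table once; every product then costs one
    spread, one FFT Poisson solve and one probe pass.
    """

    def __init__(self, system: AtomicSystem, resolved: ResolvedParams,
                 mesh: Mesh | None = None,
                 eps_trunc: float = DEFAULT_EPS_TRUNC,
                 multi_image: bool = True):
        self.system = system
        self.resolved = resolved
        if mesh is None:
            mesh = Mesh.for_system(system, resolved.sigma)
        self.mesh = mesh
        self.table = SupportTable(system, resolved.sigma, mesh,
                                  eps_trunc=eps_trunc, multi_image=multi_image)
        self.last_density: MeshField | None = None
        self.last_potential: MeshField | None = None

    def density(self, Q: np.ndarray) -> MeshField:
        return self.table.spread(Q)

    def potential(self, Q: np.ndarray) -> MeshField:
        rho = self.density(Q)
        self.last_density = rho
        self.last_potential = solve_poisson(rho)
        return self.last_potential

    def apply_A(self, Q: np.ndarray) -> np.ndarray:
        """(A.Q)_i = integral V[rho(Q)](r) rho_i(r) d^3r."""
        return self.table.probe_all(self.potential(Q))

    def apply_M(self, Q: np.ndarray) -> np.ndarray:
        """M.Q = A.Q + J q, componentwise."""
        return self.apply_A(Q) + self.resolved.hardness * np.asarray(Q, float)

    def gradient(self, Q: np.ndarray) -> np.ndarray:
        """dE_Qeq/dq_i = chi_i + J_i q_i + (A.Q)_i."""
        return self.resolved.chi + self.apply_M(Q)

    def energy_elec(self, Q: np.ndarray) -> float:
        return electrostatic_energy(self.density(Q))

    def energy_qeq(self, Q: np.ndarray) -> float:
        r = self.resolved
        return (self.energy_elec(Q) + float(r.energy_offset.sum())
                + float(r.chi @ Q) + 0.5 * float(r.hardness @ Q ** 2))

    def precondition_diagonal(self) -> np.ndarray:
        """Analytic diagonal M_ii = 1/(sigma_i sqrt(pi)) + J_i (no A needed)."""
        return 1.0 / (self.resolved.sigma * np.sqrt(np.pi)) + self.resolved.hardness


def apply_A(system: AtomicSystem, sigma, Q, mesh: Mesh | None = None,
            eps_trunc: float = DEFAULT_EPS_TRUNC) -> np.ndarray:
    """One-shot matrix-free A.Q (see :meth:`QeqOperator.apply_A`)."""
    sigma = np.broadcast_to(np.asarray(sigma, float), (system.n_atoms,))
    resolved = ResolvedParams(chi=np.zeros(system.n_atoms),
                              hardness=np.ones(system.n_atoms),
                              sigma=sigma.copy(),
                              energy_offset=np.zeros(system.n_atoms))
    return QeqOperator(system, resolved, mesh, eps_trunc).apply_A(np.asarray(Q, float))


def apply_M(system: AtomicSystem, params: QeqParameters, Q,
            mesh: Mesh | None = None) -> np.ndarray:
    """One-shot matrix-free M.Q = (A + diag(J)).Q."""
    op = QeqOperator(system, resolve_parameters(system, params), mesh)
    return op.apply_M(np.asarray(Q, float))


def qeq_gradient(system: AtomicSystem, params: QeqParameters, Q,
                 mesh: Mesh | None = None) -> np.ndarray:
    """Per-atom derivative of E_Qeq at charges Q: chi + J q + A.Q."""
    op = QeqOperator(system, resolve_parameters(system, params), mesh)
    return op.gradient(np.asarray(Q, float))


def projected_cg(apply_M, b: np.ndarray, x0: np.ndarray, tolerance: float,
                 max_iterations: int, precondition: np.ndarray | None = None,
                 quadratic_track=None):
    """Conjugate gradients for M x = b restricted to x0 + {sum = 0}.

    Every residual and search direction is projected with
    :func:`project_constrained`, so all iterates keep sum(x) = sum(x0)
    exactly.  Terminates on max|P(b - M x)| <= tolerance.  Returns
    (x, iterations, residual_history, constraint_history, value_history).
    """
    x = x0.astype(float).copy()
    target_sum = x.sum()
    r = project_constrained(b - apply_M(x))
    z = project_constrained(r * precondition) if precondition is not None else r
    p = z.copy()
    rz = float(r @ z)
    res_hist = [float(np.abs(r).max())]
    con_hist = [abs(float(x.sum()) - target_sum)]
    val_hist = []
    if quadratic_track is not None:
        val_hist.append(quadratic_track(x))
    it = 0
    while res_hist[-1] > tolerance and it < max_iterations:
        Mp = apply_M(p)
        pMp = float(p @ Mp)
        if pMp <= 0.0:
            raise PmqeqError(
                "operator not positive definite on the constraint plane "
                f"(p^T M p = {pMp:.3e}); check hardness/width parameters"
            )
        alpha = rz / pMp
        x += alpha * p
        r = r - alpha * project_constrained(Mp)
        if precondition is not None:
            z = project_constrained(r * precondition)
        else:
            z = r
        rz_new = float(r @ z)
        p = z + (rz_new / rz) * p
        rz = rz_new
        it += 1
        res_hist.append(float(np.abs(r).max()))
        con_hist.append(abs(float(x.sum()) - target_sum))
        if quadratic_track is not None:
            val_hist.append(quadratic_track(x))
    return x, it, res_hist, con_hist, val_hist


def solve_qeq(system: AtomicSystem, params: QeqParameters,
              settings: SolverSettings | None = None,
              mesh: Mesh | None = None,
              eps_trunc: float = DEFAULT_EPS_TRUNC,
              operator: QeqOperator | None = None) -> QeqResult:
    """Charge equilibration: minimize E_Qeq under sum q_i = Q_tot.

    Runs projected CG on M Q = -chi starting from a feasible guess (uniform
    charges by default, or ``settings.initial_guess``).  Raises
    :class:`pmqeq.core.ConvergenceError` with the best iterate and residual
    history if the tolerance is not reached within ``max_iterations``.
    """
    settings = settings or SolverSettings()
    if operator is None:
        operator = QeqOperator(system, resolve_parameters(system, params),
                               mesh, eps_trunc=eps_trunc)
    n = system.n_atoms
    if settings.initial_guess is not None:
        x0 = np.asarray(settings.initial_guess, dtype=float).copy()
        if x0.shape != (n,):
            raise ValueError("initial guess must have one charge per atom")
        # land exactly on the constraint before iterating
        x0 += (system.total_charge - x0.sum()) / n
    else:
        x0 = np.full(n, system.total_charge / n)

    res = operator.resolved
    precond = None
    if settings.preconditioner == "diagonal":
        precond = 1.0 / operator.precondition_diagonal()

    offsets = float(res.energy_offset.sum())

    def energy_of(x):
        # E_Qeq from the same matrix-free products the solver uses; one extra
        # apply per recorded value, used only for the diagnostic history
        return (0.5 * float(x @ operator.apply_M(x)) + float(res.chi @ x)
                + offsets)

    track = energy_of if n <= 256 else None  # history is a small-system aid
    q, iters, res_hist, con_hist, e_hist = projected_cg(
        operator.apply_M, -res.chi, x0, settings.tolerance,
        settings.max_iterations, precond, quadratic_track=track)

    if res_hist[-1] > settings.tolerance:
        raise ConvergenceError(
            f"projected CG did not reach {settings.tolerance:.1e} within "
            f"{settings.max_iterations} iterations "
            f"(residual {res_hist[-1]:.3e})",
            best_charges=q, residual_history=res_hist)

    grad = res.chi + operator.apply_M(q)
    e_elec = operator.energy_elec(q)
    e_qeq = (e_elec + offsets + float(res.chi @ q)
             + 0.5 * float(res.hardness @ q ** 2))
    return QeqResult(
        charges=q,
        energy_elec=e_elec,
        energy_qeq=e_qeq,
        lagrange_multiplier=-float(grad.mean()),
        iterations=iters,
        residual_maxnorm=res_hist[-1],
        converged=True,
        residual_history=res_hist,
        energy_history=e_hist,
        constraint_history=con_hist,
    )
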