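"""Forces, macroscopic stress, and adjoint (lambda) total derivatives.

Two regimes are covered:

* The energy being differentiated *is* E_Qeq.  Charge equilibration is a
  constrained minimization, so by the envelope property the implicit
  dependence of the charges on geometry drops out and the total force is
  just the explicit one: the Hellmann-Feynman-like electrostatic force

      F_i = -q_i integral V(r) (d rho_i / d r_i) d^3r

  (evaluated on the atom's local support with the analytic Gaussian
  gradient) plus, if the electronegativities depend on positions, the
  contraction of Q with d chi/d R.  No adjoint solve is needed.

* A downstream energy E(Q, R, h) consumes the equilibrated charges without
  being minimized over them (the fourth-generation MLP situation).  Then
  one extra projected-CG solve for the adjoint charges,

      M lambda + mu 1 = -dE/dQ,   sum_i lambda_i = 0,

  converts the implicit dependence into two explicit terms: lambda^T
  (d chi/d R) and the lambda-Q Coulomb coupling lambda^T (dA/dR) Q.  The
  latter double sum is never formed; with the auxiliary densities
  rho^Q = sum q_i rho_i and rho^lambda = sum lambda_i rho_i and their
  potentials V^Q, V^lambda it collapses to per-atom support integrals

      [lambda^T (dA/dr_i) Q] = lambda_i integral V^Q d rho_i/d r_i
                             + q_i integral V^lambda d rho_i/d r_i,

  and its strain derivative to reciprocal-space expressions coupling the
  two densities and their six strain-derivative fields.  The whole
  total-derivative evaluation therefore costs O(1) Poisson solves
  regardless of the atom count.

Position-dependent electronegativity models live outside this package
(e.g. atomic neural networks); they enter only through a contraction hook
``dchi_hook(weights) -> (N, 3)`` returning sum_j w_j d chi_j / d r_i.
Hardness is treated as a strictly element-specific constant.
"""

from __future__ import annotations

import numpy as np

from .core import (AtomicSystem, DerivativeBundle, PmqeqError, QeqParameters,
                   QeqResult, resolve_parameters)
from .mesh import Mesh, MeshField, SupportTable, DEFAULT_EPS_TRUNC
from .poisson import (reciprocal_stress, solve_poisson, strain_coupling_matrix)
from .solver import QeqOperator, SolverSettings, project_constrained, projected_cg

__all__ = [
    "electrostatic_forces",
    "qeq_forces",
    "solve_lambda",
    "total_forces",
    "total_stress",
    "qeq_stress",
    "derivative_bundle",
]


def _operator(system, params, mesh, eps_trunc, operator):
    if operator is not None:
        return operator
    return QeqOperator(system, resolve_parameters(system, params), mesh,
                       eps_trunc=eps_trunc)


def electrostatic_forces(system: AtomicSystem, params: QeqParameters, Q,
                         mesh: Mesh | None = None,
                         eps_trunc: float = DEFAULT_EPS_TRUNC,
                         operator: QeqOperator | None = None) -> np.ndarray:
    """F_i = -q_i integral V(r) d rho_i/d r_i d^3r at fixed charges Q.

    Newton's third law (sum of forces = 0) holds up to quadrature/truncation
    error because the same discrete density and supports define the energy.
    """
    op = _operator(system, params, mesh, eps_trunc, operator)
    Q = np.asarray(Q, dtype=float)
    V = solve_poisson(op.density(Q))
    return -Q[:, None] * op.table.probe_gradient_all(V)


def qeq_forces(system: AtomicSystem, params: QeqParameters, result: QeqResult,
               dchi_hook=None, mesh: Mesh | None = None,
               eps_trunc: float = DEFAULT_EPS_TRUNC,
               operator: QeqOperator | None = None) -> np.ndarray:
    """Total forces when the energy is E_Qeq itself (variational shortcut).

    ``dchi_hook(weights)`` supplies sum_j w_j d chi_j/d r_i for
    position-dependent electronegativities; it is contracted with the
    converged charges.  With element-constant chi the result equals
    :func:`electrostatic_forces` exactly.
    """
    if not result.converged:
        raise PmqeqError("qeq_forces requires a converged QeqResult")
    forces = electrostatic_forces(system, params, result.charges, mesh,
                                  eps_trunc, operator)
    if dchi_hook is not None:
        forces = forces - dchi_hook(result.charges)
    return forces


def solve_lambda(system: AtomicSystem, params: QeqParameters, dE_dQ,
                 settings: SolverSettings | None = None,
                 mesh: Mesh | None = None,
                 eps_trunc: float = DEFAULT_EPS_TRUNC,
                 operator: QeqOperator | None = None) -> np.ndarray:
    """Adjoint charges: M lambda = -P dE/dQ with sum_i lambda_i = 0.

    Uses the same matrix-free operator and projected CG as the charge
    solve; lambda is linear in dE/dQ and vanishes for a constant dE/dQ.
    """
    settings = settings or SolverSettings()
    op = _operator(system, params, mesh, eps_trunc, operator)
    dE_dQ = np.asarray(dE_dQ, dtype=float)
    if dE_dQ.shape != (system.n_atoms,):
        raise ValueError("dE_dQ must have one entry per atom")
    b = -project_constrained(dE_dQ)
    if float(np.abs(b).max()) <= settings.tolerance:
        return np.zeros(system.n_atoms)
    x0 = np.zeros(system.n_atoms)
    precond = None
    if settings.preconditioner == "diagonal":
        precond = 1.0 / op.precondition_diagonal()
    lam, _, res_hist, _, _ = projected_cg(
        op.apply_M, b, x0, settings.tolerance, settings.max_iterations,
        precond)
    if res_hist[-1] > settings.tolerance:
        from .core import ConvergenceError
        raise ConvergenceError(
            f"adjoint CG did not reach {settings.tolerance:.1e} "
            f"(residual {res_hist[-1]:.3e})",
            best_charges=lam, residual_history=res_hist)
    return lam


def _coupling_forces(table: SupportTable, Q, lam, V_Q: MeshField,
                     V_lam: MeshField) -> np.ndarray:
    """Gradient contribution lambda^T (dA/dr_i) Q for every atom i."""
    grad = np.empty((len(Q), 3))
    for i in range(len(Q)):
        grad[i] = (lam[i] * table.probe_gradient(V_Q, i)
                   + Q[i] * table.probe_gradient(V_lam, i))
    return grad


def total_forces(system: AtomicSystem, params: QeqParameters, Q, lam,
                 explicit_force_part=None, dchi_hook=None,
                 mesh: Mesh | None = None,
                 eps_trunc: float = DEFAULT_EPS_TRUNC,
                 operator: QeqOperator | None = None) -> np.ndarray:
    """Total forces for a downstream energy E(Q(R, h), R, h).

    Assembles

        F_i = -dE/dr_i = F_i^elec(Q) + explicit_force_part_i
              - [lambda^T d chi/d r_i] - [lambda^T (dA/dr_i) Q]

    where the electrostatic term is the explicit derivative of E_elec(Q)
    (assumed part of E), ``explicit_force_part`` is -dE/dR of every *other*
    explicit position dependence of E at fixed charges, and the two bracket
    terms carry the implicit charge response through the adjoint lambda.
    In the variational limit (E = E_Qeq, lambda = 0) this reduces to
    :func:`qeq_forces`.
    """
    op = _operator(system, params, mesh, eps_trunc, operator)
    Q = np.asarray(Q, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if Q.shape != lam.shape or Q.shape != (system.n_atoms,):
        raise ValueError("Q and lambda must each have one entry per atom")
    V_Q = solve_poisson(op.density(Q))
    forces = -Q[:, None] * op.table.probe_gradient_all(V_Q)
    if np.any(lam != 0.0):
        V_lam = solve_poisson(op.density(lam))
        forces -= _coupling_forces(op.table, Q, lam, V_Q, V_lam)
        if dchi_hook is not None:
            forces = forces - dchi_hook(lam)
    if explicit_force_part is not None:
        forces = forces + np.asarray(explicit_force_part, dtype=float)
    return forces


def total_stress(system: AtomicSystem, params: QeqParameters, Q, lam,
                 explicit_stress_part=None,
                 mesh: Mesh | None = None,
                 eps_trunc: float = DEFAULT_EPS_TRUNC,
                 operator: QeqOperator | None = None) -> np.ndarray:
    """Macroscopic stress sigma_munu = (1/Omega) dE/d eps_munu (symmetric).

    Sums the strain derivative of E_elec(Q) (reciprocal-space expression
    including the kernel's own strain dependence and the six
    strain-derivative densities), the lambda-Q coupling strain term, and
    any caller-supplied explicit strain derivative of the remaining energy
    terms (``explicit_stress_part``, in hartree, i.e. dE/d eps before the
    volume division).
    """
    op = _operator(system, params, mesh, eps_trunc, operator)
    Q = np.asarray(Q, dtype=float)
    lam = np.asarray(lam, dtype=float)
    rho_Q = op.density(Q)
    strain_Q = op.table.spread_strain(Q)
    dE = reciprocal_stress(rho_Q, strain_Q)
    if np.any(lam != 0.0):
        rho_lam = op.density(lam)
        strain_lam = op.table.spread_strain(lam)
        dE = dE + strain_coupling_matrix(rho_lam, strain_lam, rho_Q, strain_Q)
    if explicit_stress_part is not None:
        dE = dE + np.asarray(explicit_stress_part, dtype=float)
    return dE / system.volume


def qeq_stress(system: AtomicSystem, params: QeqParameters,
               result: QeqResult, mesh: Mesh | None = None,
               eps_trunc: float = DEFAULT_EPS_TRUNC,
               operator: QeqOperator | None = None) -> np.ndarray:
    """Macroscopic stress when the energy is E_Qeq with element-constant
    chi: the envelope property makes it the explicit electrostatic strain
    derivative per unit volume (lambda = 0)."""
    if not result.converged:
        raise PmqeqError("qeq_stress requires a converged QeqResult")
    return total_stress(system, params, result.charges,
                        np.zeros(system.n_atoms), mesh=mesh,
                        eps_trunc=eps_trunc, operator=operator)


def derivative_bundle(system: AtomicSystem, params: QeqParameters,
                      result: QeqResult, mesh: Mesh | None = None,
                      operator: QeqOperator | None = None) -> DerivativeBundle:
    """Forces and stress for E = E_Qeq (constant chi), packed for output."""
    op = _operator(system, params, mesh, DEFAULT_EPS_TRUNC, operator)
    forces = qeq_forces(system, params, result, operator=op)
    stress = qeq_stress(system, params, result, operator=op)
    return DerivativeBundle(forces=forces, stress=stress,
                            lambda_charges=np.zeros(system.n_atoms))
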