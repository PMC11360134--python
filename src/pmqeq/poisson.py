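"""Reciprocal-space Poisson solver, electrostatic energies and stress.

Poisson's equation for a periodic charge density is diagonal in Fourier
space: V~(G) = 4 pi rho~(G) / |G|^2 for G != 0.  The G = 0 coefficient is
set to zero, which for cells with nonzero total charge corresponds to a
uniform neutralizing background (jellium); energies of charged cells are
defined only up to this convention.

With the physical Fourier coefficients rho~(G) = integral_cell rho e^{-iG.r}
(see :class:`pmqeq.mesh.MeshField`), Plancherel's theorem turns the
electrostatic energy into a reciprocal series over the discrete G lattice,

    E_elec = 1/2 integral rho V = 1/(2 Omega) sum_{G != 0} 4 pi |rho~(G)|^2 / |G|^2,

which equals the real-space midpoint quadrature of rho*V/2 identically (both
are the same finite quadratic form of the grid values), so the identity
holds to rounding error on every density.

Strain derivatives are evaluated in reciprocal space as well.  Under a
homogeneous deformation r' = (1+eps) r the reciprocal vectors co-transform
as G' = (1+eps)^{-T} G, so phases G.r are invariant and three pieces carry
strain dependence: the 1/Omega prefactor, the kernel 4 pi/|G'|^2, and the
density coefficients themselves, whose derivative is the Fourier transform
of delta_munu rho + d rho/d eps_munu (the volume-measure term plus the six
real-space strain fields from :meth:`pmqeq.mesh.SupportTable.spread_strain`).
"""

from __future__ import annotations

import numpy as np
import scipy.fft as _fft

from .core import MeshError
from .mesh import Mesh, MeshField, STRAIN_COMPONENTS

__all__ = [
    "solve_poisson",
    "electrostatic_energy",
    "cross_energy",
    "reciprocal_stress",
    "strain_coupling_matrix",
]

#: number of Poisson solves performed (diagnostic for the O(1)-solve property)
POISSON_SOLVE_COUNT = [0]


def _require_same_mesh(a: MeshField, b: MeshField):
    if not a.mesh.compatible_with(b.mesh):
        raise MeshError("fields live on different meshes")


def solve_poisson(rho: MeshField) -> MeshField:
    """Electrostatic potential of a periodic density, jellium convention.

    Returns V with V~(G) = 4 pi rho~(G)/|G|^2 (G != 0) and V~(0) = 0,
    transformed back to the real-space grid.
    """
    POISSON_SOLVE_COUNT[0] += 1
    mesh = rho.mesh
    v_hat_half = mesh.coulomb_kernel_half * _fft.rfftn(rho.values)
    return MeshField(mesh, _fft.irfftn(v_hat_half, s=mesh.dims))


def electrostatic_energy(rho: MeshField) -> float:
    """E_elec = 1/(2 Omega) sum_{G != 0} 4 pi |rho~(G)|^2/|G|^2  (hartree).

    Nonnegative for every density (each series term is >= 0).
    """
    mesh = rho.mesh
    hat = rho.hat
    return float((mesh.coulomb_kernel * (hat.real ** 2 + hat.imag ** 2)).sum()
                 / (2.0 * mesh.volume))


def cross_energy(rho_a: MeshField, V_b: MeshField) -> float:
    """Reciprocal-series evaluation of integral rho_a(r) V_b(r) d^3r.

    Symmetric under exchanging the roles of the two underlying densities:
    cross(rho_a, V[rho_b]) = cross(rho_b, V[rho_a]).
    """
    _require_same_mesh(rho_a, V_b)
    mesh = rho_a.mesh
    return float((rho_a.hat.conj() * V_b.hat).real.sum() / mesh.volume)


def _pair_stress(hat_a, strain_hats_a, hat_b, strain_hats_b, mesh: Mesh):
    """d/d eps_munu of (1/Omega) sum_{G!=0} (4 pi/G^2) Re[a~* b~]  (3x3)."""
    kernel = mesh.coulomb_kernel
    inv_g2 = mesh.inv_g_squared
    g = mesh.g_vectors
    omega = mesh.volume
    cross_ab = (hat_a.conj() * hat_b).real
    base = float((kernel * cross_ab).sum() / omega)
    out = np.zeros((3, 3))
    for (mu, nu), fa, fb in zip(STRAIN_COMPONENTS, strain_hats_a, strain_hats_b):
        # kernel strain: d(1/|G'|^2)/d eps_munu = +2 G_mu G_nu / |G|^4
        term = 2.0 * float(
            (kernel * inv_g2 * g[mu] * g[nu] * cross_ab).sum() / omega)
        # density strain: volume-measure part handled analytically via `base`
        term += float((kernel * (fa.conj() * hat_b
                                 + hat_a.conj() * fb).real).sum() / omega)
        out[mu, nu] = out[nu, mu] = term
    # -delta_munu from 1/Omega plus +2 delta_munu from the measure factor of
    # the two density coefficients
    out[np.diag_indices(3)] += base
    return out


def reciprocal_stress(rho: MeshField, strain_rho) -> np.ndarray:
    """Strain derivative d E_elec / d eps_munu of the reciprocal-series
    energy (symmetric 3x3, hartree; *not* divided by the cell volume).

    ``strain_rho`` are the six fields d rho/d eps_munu in the
    (xx, yy, zz, xy, xz, yz) ordering of
    :data:`pmqeq.mesh.STRAIN_COMPONENTS`.
    """
    if len(strain_rho) != 6:
        raise ValueError("expected six strain-derivative fields")
    for f in strain_rho:
        _require_same_mesh(rho, f)
    hats = [f.hat for f in strain_rho]
    return 0.5 * _pair_stress(rho.hat, hats, rho.hat, hats, rho.mesh)


def strain_coupling_matrix(rho_a: MeshField, strain_rho_a,
                           rho_b: MeshField, strain_rho_b) -> np.ndarray:
    """Strain derivative of the Coulomb coupling integral rho_a V[rho_b]
    between two densities (symmetric 3x3, hartree).

    This is the quasi-linear replacement for the lambda-Q double sum over
    d A_ij / d eps: with rho_a = sum lambda_i rho_i and
    rho_b = sum q_i rho_i it equals lambda^T (dA/d eps) Q.
    """
    _require_same_mesh(rho_a, rho_b)
    if len(strain_rho_a) != 6 or len(strain_rho_b) != 6:
        raise ValueError("expected six strain-derivative fields per density")
    return _pair_stress(rho_a.hat, [f.hat for f in strain_rho_a],
                        rho_b.hat, [f.hat for f in strain_rho_b], rho_a.mesh)
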