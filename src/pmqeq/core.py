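"""Domain types and unit conventions shared by all modules.

Everything in this package works in Hartree atomic units: lengths in bohr,
energies in hartree, charges in units of the elementary charge e, with
e = 1 and 4*pi*eps0 = 1.  The reciprocal-space Coulomb kernel is therefore
4*pi/|G|^2 and no unit conversion happens anywhere inside the library; the
only conversion lives in :mod:`pmqeq.io`, where file input declared in
angstrom is scaled by :data:`BOHR_PER_ANGSTROM` on read.

Gaussian density convention
---------------------------
Each atom carries a normalized spherical Gaussian charge density

    rho_i(r) = (2*pi*sigma_i**2)**(-3/2) * exp(-|r - r_i|**2 / (2*sigma_i**2))

so that ``integral rho_i d^3r = 1`` and ``sigma_i`` is the standard deviation
of the distribution.  Note that parts of the charge-equilibration literature
use an ``exp(-r**2/sigma**2)`` convention instead; parameters taken from
elsewhere may need their widths rescaled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "BOHR_PER_ANGSTROM",
    "AtomicSystem",
    "ElementParams",
    "QeqParameters",
    "QeqResult",
    "DerivativeBundle",
    "ResolvedParams",
    "PmqeqError",
    "ParameterResolutionError",
    "MeshError",
    "ConvergenceError",
    "resolve_parameters",
]

#: CODATA conversion factor applied to file input declared in angstrom.
BOHR_PER_ANGSTROM = 1.8897261254578281


class PmqeqError(Exception):
    """Base class for all errors raised by this package."""


class ParameterResolutionError(PmqeqError, KeyError):
    """A species in the system has no entry in the parameter table."""


class MeshError(PmqeqError):
    """Grid/field mismatch or an unrepresentable support request."""


class ConvergenceError(PmqeqError):
    """Iterative solver failed; carries the best iterate and history."""

    def __init__(self, message, best_charges=None, residual_history=None):
        super().__init__(message)
        self.best_charges = best_charges
        self.residual_history = residual_history


@dataclass
class AtomicSystem:
    """Periodic atomic structure.

    Parameters
    ----------
    lattice : (3, 3) array
        Lattice matrix **h** in bohr; *rows* are the lattice vectors
        h1, h2, h3.  Cartesian positions relate to fractional ones via
        ``r = s @ lattice``.
    species : sequence of str
        Per-atom element labels.
    positions : (N, 3) array
        Cartesian coordinates in bohr.  Positions are stored unwrapped;
        wrapping into the cell happens only where an algorithm needs
        fractional coordinates.
    total_charge : float
        Total charge Q_tot of the cell in units of e.
    """

    lattice: np.ndarray
    species: Sequence[str]
    positions: np.ndarray
    total_charge: float = 0.0

    def __post_init__(self):
        self.lattice = np.asarray(self.lattice, dtype=float).reshape(3, 3)
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.species = list(self.species)
        if self.positions.shape != (len(self.species), 3):
            raise ValueError(
                f"positions shape {self.positions.shape} does not match "
                f"{len(self.species)} species"
            )
        if len(self.species) < 1:
            raise ValueError("a system needs at least one atom")
        if self.volume <= 0.0:
            raise ValueError("lattice vectors must be right-handed: det(h) > 0")

    @property
    def n_atoms(self) -> int:
        return len(self.species)

    @property
    def volume(self) -> float:
        """Cell volume Omega = det(h) in bohr^3."""
        return float(np.linalg.det(self.lattice))

    @property
    def reciprocal_lattice(self) -> np.ndarray:
        """Rows are the reciprocal vectors b_i with b_i . h_j = 2 pi delta_ij."""
        return 2.0 * np.pi * np.linalg.inv(self.lattice).T

    @property
    def cell_heights(self) -> np.ndarray:
        """Perpendicular distance between lattice planes along each axis."""
        inv = np.linalg.inv(self.lattice)  # columns are duals of the rows of h
        return 1.0 / np.linalg.norm(inv.T, axis=1)

    def fractional_positions(self, wrap: bool = False) -> np.ndarray:
        frac = self.positions @ np.linalg.inv(self.lattice)
        return frac - np.floor(frac) if wrap else frac

    def minimum_image_displacements(self) -> np.ndarray:
        """(N, N, 3) Cartesian displacements r_i - r_j, minimum image."""
        frac = self.fractional_positions()
        d = frac[:, None, :] - frac[None, :, :]
        d -= np.round(d)
        return d @ self.lattice

    def with_positions(self, positions: np.ndarray) -> "AtomicSystem":
        return AtomicSystem(self.lattice.copy(), list(self.species),
                            np.asarray(positions, dtype=float).copy(),
                            self.total_charge)

    def strained(self, strain: np.ndarray) -> "AtomicSystem":
        """Homogeneously deformed copy: r' = (1 + eps) r, h' = h (1 + eps)^T.

        ``strain`` is the (not necessarily symmetric) 3x3 deformation matrix
        eps; fractional coordinates are preserved.
        """
        strain = np.asarray(strain, dtype=float).reshape(3, 3)
        deform = np.eye(3) + strain
        # rows of h transform like position vectors: h_i' = deform @ h_i
        return AtomicSystem(self.lattice @ deform.T, list(self.species),
                            self.positions @ deform.T, self.total_charge)


@dataclass(frozen=True)
class ElementParams:
    """Per-element Qeq parameters (hartree/e, hartree/e^2, bohr, hartree)."""

    chi: float
    hardness: float
    sigma: float
    energy_offset: float = 0.0

    def __post_init__(self):
        if not self.hardness > 0.0:
            raise ValueError(f"hardness must be positive, got {self.hardness}")
        if not self.sigma > 0.0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")


@dataclass
class QeqParameters:
    """Element-resolved Qeq parameter table with optional per-atom chi override.

    ``chi_override``, when given, replaces the element electronegativities
    atom by atom (the hook for environment-dependent chi models, e.g. from a
    fourth-generation machine-learning potential).
    """

    elements: Mapping[str, ElementParams]
    chi_override: np.ndarray | None = None

    def __post_init__(self):
        self.elements = dict(self.elements)
        if self.chi_override is not None:
            self.chi_override = np.asarray(self.chi_override, dtype=float)


@dataclass
class ResolvedParams:
    """Per-atom parameter vectors in atom order (see resolve_parameters)."""

    chi: np.ndarray
    hardness: np.ndarray
    sigma: np.ndarray
    energy_offset: np.ndarray


def resolve_parameters(system: AtomicSystem, params: QeqParameters) -> ResolvedParams:
    """Expand the element table into per-atom (chi, J, sigma, E) vectors.

    A per-atom ``chi_override`` on ``params`` takes precedence over the
    element electronegativities.  Raises
    :class:`ParameterResolutionError` naming any species missing from the
    table.
    """
    missing = sorted({s for s in system.species if s not in params.elements})
    if missing:
        raise ParameterResolutionError(
            f"no Qeq parameters for species: {', '.join(missing)}"
        )
    per = [params.elements[s] for s in system.species]
    chi = np.array([p.chi for p in per])
    if params.chi_override is not None:
        if params.chi_override.shape != (system.n_atoms,):
            raise ValueError(
                f"chi_override has shape {params.chi_override.shape}, "
                f"expected ({system.n_atoms},)"
            )
        chi = params.chi_override.astype(float).copy()
    return ResolvedParams(
        chi=chi,
        hardness=np.array([p.hardness for p in per]),
        sigma=np.array([p.sigma for p in per]),
        energy_offset=np.array([p.energy_offset for p in per]),
    )


@dataclass
class QeqResult:
    """Converged charges plus energies and solver diagnostics.

    Attributes
    ----------
    charges : (N,) array
        Equilibrated charges (e); sums to Q_tot to machine precision.
    energy_elec : float
        Electrostatic energy E_elec = 1/2 Q^T A Q (hartree).
    energy_qeq : float
        E_Qeq = E_elec + sum_i (E_i + chi_i q_i + 1/2 J_i q_i^2) (hartree).
    lagrange_multiplier : float
        Scalar multiplier of the total-charge constraint (hartree/e).
    iterations : int
        Conjugate-gradient iterations performed (0 for the direct solver).
    residual_maxnorm : float
        Max-norm of the projected residual at termination (hartree/e).
    residual_history, energy_history, constraint_history : lists
        Per-iteration diagnostics (projected-residual max-norm, E_Qeq, and
        |sum q - Q_tot|).
    """

    charges: np.ndarray
    energy_elec: float
    energy_qeq: float
    lagrange_multiplier: float
    iterations: int
    residual_maxnorm: float
    converged: bool = True
    residual_history: list = field(default_factory=list)
    energy_history: list = field(default_factory=list)
    constraint_history: list = field(default_factory=list)


@dataclass
class DerivativeBundle:
    """Forces (hartree/bohr), macroscopic stress (hartree/bohr^3, symmetric),
    and the adjoint lambda charges (e, summing to zero)."""

    forces: np.ndarray
    stress: np.ndarray | None = None
    lambda_charges: np.ndarray | None = None
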