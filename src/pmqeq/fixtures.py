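"""Deterministic generators for test systems and toy models.

Everything a test or validation run needs is generated here from a seed:

* the 800-atom, 60-element random stress-test system (uniform random
  positions with a 0.4-bohr minimum pair distance, hardnesses uniform in
  [0.4, 1.4], electronegativities and initial charges standard normal) that
  probes solver robustness under extreme parameter heterogeneity;
* a conventional 8-atom rocksalt cell for symmetry and stress checks;
* a smooth toy position-dependent electronegativity model standing in for a
  learned chi(R) (e.g. an atomic neural network), closing the loop for
  total-derivative tests.

The stress-test conditions the literature leaves open are fixed here as
package conventions: a cubic 20-bohr cell, Gaussian widths uniform in
[0.5, 1.0] bohr, and a neutral cell; all are configurable fields of
:class:`FixtureSpec`.  One seeded NumPy generator per fixture call; the same
seed reproduces the fixture bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import AtomicSystem, ElementParams, PmqeqError, QeqParameters

__all__ = [
    "FixtureSpec",
    "random_test_system",
    "rocksalt_fixture",
    "ToyChiParams",
    "toy_chi_model",
]


@dataclass
class FixtureSpec:
    """Recipe for a random periodic test system (all lengths in bohr)."""

    n_atoms: int = 800
    n_elements: int = 60
    min_distance: float = 0.4
    cell: np.ndarray = field(default_factory=lambda: 20.0 * np.eye(3))
    hardness_range: tuple = (0.4, 1.4)
    sigma_range: tuple = (0.5, 1.0)
    total_charge: float = 0.0
    seed: int = 0
    max_tries_per_atom: int = 2000

    def __post_init__(self):
        self.cell = np.asarray(self.cell, dtype=float).reshape(3, 3)
        if self.min_distance <= 0.0:
            raise ValueError("min_distance must be positive")
        for lo, hi in (self.hardness_range, self.sigma_range):
            if not (0.0 < lo <= hi):
                raise ValueError("parameter ranges must be positive")


def _min_image_dist2(frac_new, frac_old, lattice):
    d = frac_new[None, :] - frac_old
    d -= np.round(d)
    cart = d @ lattice
    return (cart ** 2).sum(axis=1)


def random_test_system(spec: FixtureSpec | None = None):
    """Random periodic system with element-wise random Qeq parameters.

    Returns ``(system, parameters, initial_charges)``.  Positions are
    uniform in the cell subject to the minimum-image pair distance floor
    (rejection sampling); elements are assigned round-robin; initial
    charges are standard normal, rigidly shifted onto the total-charge
    constraint.  Raises :class:`pmqeq.core.PmqeqError` if placement fails
    repeatedly (cell too small for the requested packing).
    """
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(spec.seed)
    lattice = spec.cell
    d2min = spec.min_distance ** 2

    frac = np.empty((spec.n_atoms, 3))
    placed = 0
    while placed < spec.n_atoms:
        for attempt in range(spec.max_tries_per_atom):
            cand = rng.random(3)
            if placed == 0 or np.all(
                    _min_image_dist2(cand, frac[:placed], lattice) >= d2min):
                frac[placed] = cand
                placed += 1
                break
        else:
            raise PmqeqError(
                f"could not place atom {placed + 1}/{spec.n_atoms} at "
                f"min distance {spec.min_distance}; use a larger cell"
            )

    labels = [f"El{k}" for k in range(spec.n_elements)]
    species = [labels[i % spec.n_elements] for i in range(spec.n_atoms)]

    hardness = rng.uniform(*spec.hardness_range, size=spec.n_elements)
    sigma = rng.uniform(*spec.sigma_range, size=spec.n_elements)
    chi = rng.standard_normal(spec.n_elements)
    elements = {
        labels[k]: ElementParams(chi=float(chi[k]), hardness=float(hardness[k]),
                                 sigma=float(sigma[k]))
        for k in range(spec.n_elements)
    }

    q0 = rng.standard_normal(spec.n_atoms)
    q0 += (spec.total_charge - q0.sum()) / spec.n_atoms

    system = AtomicSystem(lattice.copy(), species, frac @ lattice,
                          total_charge=spec.total_charge)
    return system, QeqParameters(elements), q0


def rocksalt_fixture(a: float = 10.6, sigma_cation: float = 1.0,
                     sigma_anion: float = 1.2, chi_split: float = 0.4,
                     hardness: float = 0.8,
                     cation: str = "Na", anion: str = "Cl"):
    """Conventional 8-atom rocksalt cell with two species of opposite
    electronegativity (+-chi_split); used for symmetry and stress tests."""
    if a <= 0.0:
        raise ValueError("lattice constant must be positive")
    cation_frac = np.array([[0.0, 0.0, 0.0], [0.0, 0.5, 0.5],
                            [0.5, 0.0, 0.5], [0.5, 0.5, 0.0]])
    anion_frac = cation_frac + 0.5 - np.floor(cation_frac + 0.5)
    frac = np.vstack([cation_frac, anion_frac])
    species = [cation] * 4 + [anion] * 4
    system = AtomicSystem(a * np.eye(3), species, frac * a, total_charge=0.0)
    params = QeqParameters({
        cation: ElementParams(chi=-chi_split, hardness=hardness,
                              sigma=sigma_cation),
        anion: ElementParams(chi=+chi_split, hardness=hardness,
                             sigma=sigma_anion),
    })
    return system, params


@dataclass
class ToyChiParams:
    """Parameters of the toy environment-dependent electronegativity
    chi_i = c_i + a * sum_j exp(-r_ij^2 / w) * f_cut(r_ij)  over periodic
    images within the cutoff, with the smooth cosine cutoff
    f_cut(r) = (1 + cos(pi r / r_cut)) / 2."""

    amplitude: float = 0.1
    width: float = 4.0
    r_cut: float = 4.0
    base: float = 0.0


def _pair_shifts(lattice: np.ndarray, r_cut: float) -> np.ndarray:
    inv = np.linalg.inv(lattice)
    heights = 1.0 / np.linalg.norm(inv.T, axis=1)
    nmax = np.ceil(r_cut / heights).astype(int)
    grids = np.meshgrid(*(np.arange(-n, n + 1) for n in nmax), indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=1) @ lattice


def toy_chi_model(system: AtomicSystem, model_params: ToyChiParams | None = None):
    """Smooth toy chi(R) plus its adjoint contraction hook.

    Returns ``(chi, hook)`` where ``chi`` is the per-atom electronegativity
    vector at the current geometry and ``hook(weights)`` evaluates
    sum_j w_j d chi_j / d r_i as an (N, 3) array -- the contraction an
    external chi model must supply to the adjoint force assembly.

    Requires r_cut < half the smallest cell height (single-image pair sum
    with a fixed shift list keeps chi smooth under small strains).
    """
    p = model_params or ToyChiParams()
    half = 0.5 * float(np.min(system.cell_heights))
    if not p.r_cut < half:
        raise PmqeqError(
            f"toy chi cutoff {p.r_cut} must be below half the smallest cell "
            f"height {half:.3f}"
        )
    shifts = _pair_shifts(system.lattice, p.r_cut)
    n = system.n_atoms

    def _pair_terms(positions):
        """Yields (i, j, d_vec, r) for every in-range ordered pair/image."""
        for i in range(n):
            d0 = positions[i][None, :] - positions  # (N, 3)
            for s in shifts:
                d = d0 + s
                r = np.sqrt((d ** 2).sum(axis=1))
                mask = (r < p.r_cut) & (r > 1e-12)
                yield i, np.nonzero(mask)[0], d[mask], r[mask]

    def chi_of(positions):
        chi = np.full(n, p.base)
        for i, _, _, r in _pair_terms(positions):
            chi[i] += p.amplitude * float(
                (np.exp(-r ** 2 / p.width)
                 * 0.5 * (1.0 + np.cos(np.pi * r / p.r_cut))).sum())
        return chi

    def hook(weights, positions=None):
        """sum_j w_j d chi_j / d r_i, shape (N, 3)."""
        w = np.asarray(weights, dtype=float)
        pos = system.positions if positions is None else positions
        out = np.zeros((n, 3))
        for i, js, d, r in _pair_terms(pos):
            # chi_i term: phi(|r_i - r_j - L|); d phi/d r_i = phi'(r) d/r
            g = np.exp(-r ** 2 / p.width)
            fc = 0.5 * (1.0 + np.cos(np.pi * r / p.r_cut))
            dfc = -0.5 * np.pi / p.r_cut * np.sin(np.pi * r / p.r_cut)
            dphi = p.amplitude * (-2.0 * r / p.width * g * fc + g * dfc)
            contrib = (dphi / r)[:, None] * d  # d chi_i/d r_i pair pieces
            out[i] += w[i] * contrib.sum(axis=0)
            # same pair seen from atom j: d chi_i/d r_j = -contrib
            np.add.at(out, js, -w[i] * contrib)
        return out

    return chi_of(system.positions), hook
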