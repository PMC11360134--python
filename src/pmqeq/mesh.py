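"""Periodic mesh, Gaussian charge spreading, and local-support probing.

This module rasterizes the superposition of atom-centered periodic Gaussian
densities

    rho(r) = sum_i q_i sum_{images L} rho_i(r - r_i - L)

onto a regular fractional-coordinate grid of the cell in quasi-linear time:
each normalized Gaussian decays exponentially, so only mesh points within a
truncation radius ``r_cut = sigma * sqrt(-2 ln eps_trunc)`` of (an image of)
the atom contribute.  The same local supports are reused to probe a potential
field against ``rho_i`` (the matrix-free A.Q product), against the analytic
Gaussian gradient (forces), and against the strain derivative of the periodic
density (stress).

Two evaluation paths exist behind one interface:

* orthorhombic cells aligned with the grid: the Gaussian factorizes per axis,
  so per-atom work is three short 1-D weight vectors plus one outer-product
  accumulation/contraction.  Periodic image sums fold exactly onto the grid
  axis by axis, so arbitrarily large supports (multi-image) cost nothing
  extra.
* general triclinic cells: a dense per-atom support block with explicit
  minimum-image displacement vectors.

Quadrature is the midpoint rule with weight Omega/(n1*n2*n3); for Gaussians
resolved by >= 3 points per sigma it converges superalgebraically and its
error is far below the truncation threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _field

import numpy as np
import scipy.fft as _fft

from .core import AtomicSystem, MeshError

__all__ = [
    "Mesh",
    "MeshField",
    "SupportTable",
    "next_smooth_size",
    "build_density",
    "build_strain_derivative_densities",
    "probe_potential_on_support",
]

#: symmetric strain-component ordering used for the 6 strain-derivative fields
STRAIN_COMPONENTS = ((0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2))

DEFAULT_EPS_TRUNC = 1e-10


def next_smooth_size(n: int) -> int:
    """Smallest FFT-friendly integer >= n with only factors 2, 3 and 5."""
    n = max(int(n), 1)
    while True:
        m = n
        for p in (2, 3, 5):
            while m % p == 0:
                m //= p
        if m == 1:
            return n
        n += 1


class Mesh:
    """Regular periodic grid over the cell spanned by ``lattice`` (rows)."""

    def __init__(self, lattice: np.ndarray, dims):
        self.lattice = np.asarray(lattice, dtype=float).reshape(3, 3)
        self.dims = tuple(int(d) for d in dims)
        if any(d < 4 for d in self.dims):
            raise MeshError(f"mesh needs >= 4 points per axis, got {self.dims}")
        self.volume = float(np.linalg.det(self.lattice))
        if self.volume <= 0.0:
            raise MeshError("lattice must satisfy det(h) > 0")
        self.n_points = int(np.prod(self.dims))
        self._g = None
        self._kernel_half = None

    @classmethod
    def from_spacing(cls, lattice: np.ndarray, spacing: float) -> "Mesh":
        """Grid whose plane spacing along every axis is <= ``spacing`` (bohr),
        rounded up to FFT-friendly (2^a 3^b 5^c) sizes."""
        lattice = np.asarray(lattice, dtype=float).reshape(3, 3)
        inv = np.linalg.inv(lattice)
        heights = 1.0 / np.linalg.norm(inv.T, axis=1)
        dims = [next_smooth_size(max(4, int(np.ceil(h / spacing))))
                for h in heights]
        return cls(lattice, dims)

    @classmethod
    def for_system(cls, system: AtomicSystem, sigma, spacing: float | None = None,
                   points_per_sigma: float = 3.0) -> "Mesh":
        """Default mesh: spacing <= min(sigma)/points_per_sigma per axis."""
        if spacing is None:
            spacing = float(np.min(sigma)) / points_per_sigma
        return cls.from_spacing(system.lattice, spacing)

    # ---- reciprocal-space tables (lazy) ------------------------------------

    @property
    def _g_tables(self):
        if self._g is None:
            b = 2.0 * np.pi * np.linalg.inv(self.lattice).T  # rows b1,b2,b3
            freqs = [_fft.fftfreq(n, d=1.0 / n) for n in self.dims]
            k1 = freqs[0][:, None, None]
            k2 = freqs[1][None, :, None]
            k3 = freqs[2][None, None, :]
            g = [k1 * b[0, c] + k2 * b[1, c] + k3 * b[2, c] for c in range(3)]
            g2 = g[0] ** 2 + g[1] ** 2 + g[2] ** 2
            kernel = np.zeros_like(g2)
            nz = g2 > 0.0
            kernel[nz] = 4.0 * np.pi / g2[nz]
            inv_g2 = np.zeros_like(g2)
            inv_g2[nz] = 1.0 / g2[nz]
            self._g = (g, g2, kernel, inv_g2)
        return self._g

    @property
    def g_vectors(self):
        """Three arrays with the Cartesian components of G on the FFT grid."""
        return self._g_tables[0]

    @property
    def g_squared(self):
        return self._g_tables[1]

    @property
    def coulomb_kernel(self):
        """4 pi / |G|^2 with the G = 0 entry set to zero (jellium convention)."""
        return self._g_tables[2]

    @property
    def inv_g_squared(self):
        return self._g_tables[3]

    @property
    def coulomb_kernel_half(self):
        """4 pi/|G|^2 on the rfftn half-spectrum grid (hot Poisson path)."""
        if self._kernel_half is None:
            b = 2.0 * np.pi * np.linalg.inv(self.lattice).T
            n1, n2, n3 = self.dims
            k1 = _fft.fftfreq(n1, d=1.0 / n1)[:, None, None]
            k2 = _fft.fftfreq(n2, d=1.0 / n2)[None, :, None]
            k3 = _fft.rfftfreq(n3, d=1.0 / n3)[None, None, :]
            g2 = sum((k1 * b[0, c] + k2 * b[1, c] + k3 * b[2, c]) ** 2
                     for c in range(3))
            kern = np.zeros_like(g2)
            nz = g2 > 0.0
            kern[nz] = 4.0 * np.pi / g2[nz]
            self._kernel_half = kern
        return self._kernel_half

    def compatible_with(self, other: "Mesh") -> bool:
        return self.dims == other.dims and np.allclose(self.lattice, other.lattice)


@dataclass
class MeshField:
    """Real scalar field on the mesh with lazily cached Fourier coefficients.

    ``hat`` holds the physical Fourier coefficients of the periodic field,

        f~(G_k) = (Omega / N) * sum_g f(r_g) exp(-i G_k . r_g)

    indexed like ``numpy.fft.fftn`` output; conjugate symmetry of a real
    field is inherited from the real-valued ``values``.
    """

    mesh: Mesh
    values: np.ndarray
    _hat: np.ndarray | None = _field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.mesh.dims:
            raise MeshError(
                f"field shape {self.values.shape} != mesh dims {self.mesh.dims}"
            )

    @property
    def hat(self) -> np.ndarray:
        if self._hat is None:
            scale = self.mesh.volume / self.mesh.n_points
            self._hat = _fft.fftn(self.values) * scale
        return self._hat

    def integral(self) -> float:
        """Midpoint-quadrature cell integral, weight Omega/N."""
        return float(self.values.sum() * self.mesh.volume / self.mesh.n_points)


# ---------------------------------------------------------------------------
# per-atom local supports


def _axis_window(s_frac: float, half_width_frac: float, n: int):
    """Integer grid indices j with j/n within the window around s_frac."""
    lo = int(np.ceil((s_frac - half_width_frac) * n))
    hi = int(np.floor((s_frac + half_width_frac) * n))
    return np.arange(lo, hi + 1)


class _SeparableSupport:
    """Per-atom axis-factorized Gaussian support (orthorhombic cells).

    Along each axis the support is at most two contiguous index segments
    (the window possibly wrapping the boundary); when the window spans the
    whole axis the periodic images are folded exactly onto the n grid
    points first (valid per axis because the image sum of a separable
    product factorizes).  Accumulation and contraction then run on plain
    slices, which keeps the inner loops at memcpy/BLAS speed.
    """

    __slots__ = ("segs", "w", "dw", "d2w", "pref", "sigma")

    def __init__(self, frac, lengths, dims, sigma, r_cut):
        self.sigma = sigma
        self.pref = (2.0 * np.pi * sigma * sigma) ** -1.5
        self.segs, self.w, self.dw, self.d2w = [], [], [], []
        for a in range(3):
            L, n = lengths[a], dims[a]
            j = _axis_window(frac[a], r_cut / L, n)
            d = (j / n - frac[a]) * L
            w = np.exp(-d * d / (2.0 * sigma * sigma))
            w_arrs = (w, d * w, d * d * w)
            if len(j) >= n:
                # support wraps the whole axis: fold images onto the grid
                m = j % n
                w_arrs = tuple(np.bincount(m, weights=x, minlength=n)
                               for x in w_arrs)
                segs = [(slice(0, n), slice(0, n))]
            else:
                m = j % n
                cut = np.nonzero(np.diff(m) < 0)[0]
                if len(cut) == 0:
                    segs = [(slice(m[0], m[-1] + 1), slice(0, len(m)))]
                else:
                    c = int(cut[0]) + 1
                    segs = [(slice(m[0], n), slice(0, c)),
                            (slice(0, m[-1] + 1), slice(c, len(m)))]
            self.segs.append(segs)
            self.w.append(w_arrs[0])
            self.dw.append(w_arrs[1])
            self.d2w.append(w_arrs[2])

    def _axis_weights(self, mu_power):
        # mu_power[a] in {0,1,2}: moment of the displacement along axis a
        table = (self.w, self.dw, self.d2w)
        return [table[mu_power[a]][a] for a in range(3)]

    def add_to(self, grid, scale, mu_power=(0, 0, 0)):
        wx, wy, wz = self._axis_weights(mu_power)
        for gx, lx in self.segs[0]:
            for gy, ly in self.segs[1]:
                wyz = np.outer(wy[ly], wz)
                for gz, lz in self.segs[2]:
                    grid[gx, gy, gz] += (scale * self.pref) * np.multiply.outer(
                        wx[lx], wyz[:, lz])

    def contract(self, grid, mu_power=(0, 0, 0)) -> float:
        wx, wy, wz = self._axis_weights(mu_power)
        total = 0.0
        for gx, lx in self.segs[0]:
            for gy, ly in self.segs[1]:
                wyz = np.outer(wy[ly], wz)
                for gz, lz in self.segs[2]:
                    sub = grid[gx, gy, gz]
                    total += float(
                        np.tensordot(sub, wyz[:, lz], axes=([1, 2], [0, 1]))
                        @ wx[lx])
        return self.pref * total


class _BlockSupport:
    """Per-atom dense support block with explicit displacement vectors
    (general triclinic cells)."""

    __slots__ = ("idx", "flat", "w", "d", "pref", "sigma", "unique")

    def __init__(self, frac, lattice, dims, sigma, r_cut):
        self.sigma = sigma
        self.pref = (2.0 * np.pi * sigma * sigma) ** -1.5
        inv = np.linalg.inv(lattice)
        half = r_cut * np.linalg.norm(inv, axis=0)  # fractional half-widths
        axes = [_axis_window(frac[a], half[a], dims[a]) for a in range(3)]
        ds = [axes[a] / dims[a] - frac[a] for a in range(3)]
        # Cartesian displacements d = ds @ h, built per axis by broadcasting
        d = np.empty((3,) + tuple(len(a) for a in axes))
        for c in range(3):
            d[c] = (ds[0][:, None, None] * lattice[0, c]
                    + ds[1][None, :, None] * lattice[1, c]
                    + ds[2][None, None, :] * lattice[2, c])
        r2 = d[0] ** 2 + d[1] ** 2 + d[2] ** 2
        self.w = np.exp(-r2 / (2.0 * sigma * sigma))
        self.d = d
        self.idx = [axes[a] % dims[a] for a in range(3)]
        self.unique = all(len(np.unique(i)) == len(i) for i in self.idx)
        if not self.unique:
            n2, n3 = dims[1], dims[2]
            self.flat = ((self.idx[0][:, None, None] * n2
                          + self.idx[1][None, :, None]) * n3
                         + self.idx[2][None, None, :]).ravel()
        else:
            self.flat = None

    def _moment(self, mu_power):
        w = self.w
        for a in range(3):
            for _ in range(mu_power[a]):
                w = w * self.d[a]
        return w

    def add_to(self, grid, scale, mu_power=(0, 0, 0)):
        block = (scale * self.pref) * self._moment(mu_power)
        if self.unique:
            grid[np.ix_(*self.idx)] += block
        else:
            np.add.at(grid.ravel(), self.flat, block.ravel())

    def contract(self, grid, mu_power=(0, 0, 0)) -> float:
        block = grid[np.ix_(*self.idx)]
        return self.pref * float((block * self._moment(mu_power)).sum())


def _is_orthorhombic(lattice: np.ndarray) -> bool:
    return np.allclose(lattice, np.diag(np.diag(lattice)), atol=0.0)


class SupportTable:
    """All per-atom local supports for one (system, sigma, mesh) geometry.

    Building the table is the only place Gaussians are evaluated; the
    charge-equilibration CG loop then reuses it for every spread and probe,
    so per-iteration work is pure accumulation/contraction.

    Parameters
    ----------
    eps_trunc : float
        Relative truncation threshold; r_cut_i = sigma_i * sqrt(-2 ln eps).
    multi_image : bool
        Allow supports reaching beyond half the smallest cell height (all
        contributing periodic images are then summed exactly).  When False,
        such a request raises :class:`MeshError`.
    """

    def __init__(self, system: AtomicSystem, sigma, mesh: Mesh,
                 eps_trunc: float = DEFAULT_EPS_TRUNC, multi_image: bool = True):
        sigma = np.broadcast_to(np.asarray(sigma, dtype=float), (system.n_atoms,))
        if np.any(sigma <= 0.0):
            raise ValueError("all Gaussian widths must be positive")
        if not (0.0 < eps_trunc < 1.0):
            raise ValueError("eps_trunc must lie in (0, 1)")
        if not np.allclose(system.lattice, mesh.lattice):
            raise MeshError("mesh was built for a different lattice")
        self.system = system
        self.sigma = sigma
        self.mesh = mesh
        self.eps_trunc = eps_trunc
        r_cut = sigma * np.sqrt(-2.0 * np.log(eps_trunc))
        min_half_height = 0.5 * float(np.min(system.cell_heights))
        if not multi_image and np.any(r_cut > min_half_height):
            raise MeshError(
                f"truncation radius {r_cut.max():.3f} bohr exceeds half the "
                f"smallest cell height {min_half_height:.3f} bohr; enable "
                "multi_image to sum all contributing periodic images"
            )
        frac = system.fractional_positions(wrap=True)
        lattice, dims = mesh.lattice, mesh.dims
        if _is_orthorhombic(lattice):
            lengths = np.diag(lattice)
            self.supports = [
                _SeparableSupport(frac[i], lengths, dims, sigma[i], r_cut[i])
                for i in range(system.n_atoms)
            ]
        else:
            self.supports = [
                _BlockSupport(frac[i], lattice, dims, sigma[i], r_cut[i])
                for i in range(system.n_atoms)
            ]

    @property
    def quad_weight(self) -> float:
        return self.mesh.volume / self.mesh.n_points

    def _check_field(self, V: MeshField):
        if not self.mesh.compatible_with(V.mesh):
            raise MeshError("field lives on a different mesh than the supports")

    # ---- spreading ---------------------------------------------------------

    def spread(self, charges) -> MeshField:
        """Rasterize rho(r) = sum_i q_i rho_i^periodic(r)."""
        charges = np.broadcast_to(np.asarray(charges, float), (len(self.supports),))
        grid = np.zeros(self.mesh.dims)
        for q, sup in zip(charges, self.supports):
            if q != 0.0:
                sup.add_to(grid, q)
        return MeshField(self.mesh, grid)

    def spread_strain(self, charges) -> list[MeshField]:
        """The six fields d rho / d eps_munu at fixed fractional coordinates.

        A homogeneous deformation r' = (1+eps) r stretches every
        minimum-image displacement d -> (1+eps) d, hence
        d rho_i / d eps_munu = -(d_mu d_nu / sigma_i^2) rho_i(d), summed over
        atoms and periodic images exactly like the density itself.
        """
        charges = np.broadcast_to(np.asarray(charges, float), (len(self.supports),))
        grids = [np.zeros(self.mesh.dims) for _ in STRAIN_COMPONENTS]
        for q, sup in zip(charges, self.supports):
            if q == 0.0:
                continue
            scale = -q / (sup.sigma * sup.sigma)
            for grid, (mu, nu) in zip(grids, STRAIN_COMPONENTS):
                power = [0, 0, 0]
                power[mu] += 1
                power[nu] += 1
                sup.add_to(grid, scale, tuple(power))
        return [MeshField(self.mesh, g) for g in grids]

    # ---- probing -----------------------------------------------------------

    def probe(self, V: MeshField, i: int) -> float:
        """Midpoint quadrature of integral V(r) rho_i(r) d^3r over the
        atom's local support (all periodic images)."""
        self._check_field(V)
        return self.quad_weight * self.supports[i].contract(V.values)

    def probe_all(self, V: MeshField) -> np.ndarray:
        self._check_field(V)
        w = self.quad_weight
        return np.array([w * s.contract(V.values) for s in self.supports])

    def probe_gradient(self, V: MeshField, i: int) -> np.ndarray:
        """integral V(r) d rho_i / d r_i d^3r  (a 3-vector).

        With the Gaussian convention used here,
        d rho_i / d r_i = (d / sigma_i^2) rho_i(d), d = r - r_i - image.
        """
        self._check_field(V)
        sup = self.supports[i]
        scale = self.quad_weight / (sup.sigma * sup.sigma)
        out = np.empty(3)
        for c in range(3):
            power = [0, 0, 0]
            power[c] = 1
            out[c] = scale * sup.contract(V.values, tuple(power))
        return out

    def probe_gradient_all(self, V: MeshField) -> np.ndarray:
        self._check_field(V)
        return np.array([self.probe_gradient(V, i)
                         for i in range(len(self.supports))])


# ---------------------------------------------------------------------------
# functional wrappers (one-shot convenience API)


def build_density(system: AtomicSystem, sigma, charges, mesh: Mesh | None = None,
                  eps_trunc: float = DEFAULT_EPS_TRUNC, multi_image: bool = True,
                  table: SupportTable | None = None) -> MeshField:
    """Periodic superposition density of Gaussian atomic charges on the mesh.

    The midpoint-quadrature cell integral of the result equals sum_i q_i up
    to the truncation threshold.
    """
    if table is None:
        if mesh is None:
            mesh = Mesh.for_system(system, sigma)
        table = SupportTable(system, sigma, mesh, eps_trunc, multi_image)
    return table.spread(charges)


def build_strain_derivative_densities(system: AtomicSystem, sigma, charges,
                                      mesh: Mesh | None = None,
                                      eps_trunc: float = DEFAULT_EPS_TRUNC,
                                      multi_image: bool = True,
                                      table: SupportTable | None = None):
    """Six fields d rho / d eps_munu, munu in (xx, yy, zz, xy, xz, yz)."""
    if table is None:
        if mesh is None:
            mesh = Mesh.for_system(system, sigma)
        table = SupportTable(system, sigma, mesh, eps_trunc, multi_image)
    return table.spread_strain(charges)


def probe_potential_on_support(V: MeshField, system: AtomicSystem, sigma,
                               which_atom: int,
                               eps_trunc: float = DEFAULT_EPS_TRUNC,
                               table: SupportTable | None = None) -> float:
    """integral V(r) rho_i(r) d^3r for one atom, on its local support."""
    if table is None:
        table = SupportTable(system, sigma, V.mesh, eps_trunc)
    return table.probe(V, which_atom)
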