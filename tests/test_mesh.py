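import numpy as np
import pytest

import pmqeq as pq
from pmqeq.mesh import STRAIN_COMPONENTS


def gaussian_sum_brute_force(system, sigma, Q, mesh, n_images=1):
    """Per-gridpoint sum over all atoms and a block of periodic images."""
    frac = np.stack(np.meshgrid(*[np.arange(n) / n for n in mesh.dims],
                                indexing="ij"), axis=-1)
    rg = frac @ mesh.lattice
    out = np.zeros(mesh.dims)
    shifts = range(-n_images, n_images + 1)
    for i in range(system.n_atoms):
        pref = (2 * np.pi * sigma[i] ** 2) ** -1.5
        for mx in shifts:
            for my in shifts:
                for mz in shifts:
                    img = system.positions[i] + np.array([mx, my, mz]) @ mesh.lattice
                    d2 = ((rg - img) ** 2).sum(-1)
                    out += Q[i] * pref * np.exp(-d2 / (2 * sigma[i] ** 2))
    return out


@pytest.fixture(scope="module")
def triclinic_five():
    lat = np.array([[8.0, 0.0, 0.0], [1.5, 7.5, 0.0], [-1.0, 0.8, 8.5]])
    rng = np.random.default_rng(0)
    pos = rng.random((5, 3)) @ lat
    system = pq.AtomicSystem(lat, ["A"] * 5, pos)
    sigma = np.full(5, 0.6)
    Q = rng.standard_normal(5)
    mesh = pq.Mesh(lat, (20, 18, 24))
    return system, sigma, Q, mesh


def test_zero_charges_give_zero_fields(small_random):
    system, _, res, mesh, _ = small_random
    table = pq.SupportTable(system, res.sigma, mesh)
    assert not np.any(table.spread(np.zeros(system.n_atoms)).values)
    for f in table.spread_strain(np.zeros(system.n_atoms)):
        assert not np.any(f.values)


def test_single_gaussian_integrates_to_its_charge():
    system = pq.AtomicSystem(20 * np.eye(3), ["X"], [[3.0, 4.0, 5.0]])
    mesh = pq.Mesh(system.lattice, (64, 64, 64))
    rho = pq.build_density(system, 1.0, [1.0], mesh=mesh)
    assert abs(rho.integral() - 1.0) < 1e-8


def test_cell_integral_equals_total_charge(small_random):
    system, _, res, mesh, q0 = small_random
    rho = pq.build_density(system, res.sigma, q0, mesh=mesh)
    assert abs(rho.integral() - q0.sum()) < 10 * 1e-10 * np.abs(q0).sum()


def test_density_matches_brute_force_image_sum(triclinic_five):
    system, sigma, Q, mesh = triclinic_five
    rho = pq.build_density(system, sigma, Q, mesh=mesh, eps_trunc=1e-14)
    brute = gaussian_sum_brute_force(system, sigma, Q, mesh)
    assert np.abs(rho.values - brute).max() < 1e-12


def test_density_is_linear_in_charges(small_random):
    system, _, res, mesh, _ = small_random
    table = pq.SupportTable(system, res.sigma, mesh)
    rng = np.random.default_rng(9)
    q1, q2 = rng.standard_normal((2, system.n_atoms))
    combined = table.spread(2.0 * q1 - 0.5 * q2).values
    separate = 2.0 * table.spread(q1).values - 0.5 * table.spread(q2).values
    assert np.abs(combined - separate).max() < 1e-13


def test_integer_grid_translation_permutes_values_exactly():
    """With dyadic positions and cell (so the shifted coordinates round
    identically) an integer-grid-vector translation is an exact
    permutation of the field values."""
    L, n = 16.0, 64
    system = pq.AtomicSystem(L * np.eye(3), ["A", "B"],
                             [[3.25, 5.5, 7.75], [9.0, 2.25, 4.5]])
    sigma = np.array([1.0, 0.75])
    Q = np.array([0.8, -0.3])
    mesh = pq.Mesh(system.lattice, (n, n, n))
    rho = pq.build_density(system, sigma, Q, mesh=mesh)
    shift_idx = (4, 8, 12)
    shift = np.array(shift_idx) / n * L  # exact dyadic Cartesian shift
    moved = system.with_positions(system.positions + shift)
    rho2 = pq.build_density(moved, sigma, Q, mesh=mesh)
    np.testing.assert_array_equal(
        rho2.values, np.roll(rho.values, shift_idx, axis=(0, 1, 2)))


def test_probe_of_constant_potential_returns_the_constant(small_random):
    system, _, res, mesh, _ = small_random
    table = pq.SupportTable(system, res.sigma, mesh)
    V = pq.MeshField(mesh, np.full(mesh.dims, 2.5))
    for i in range(0, system.n_atoms, 4):
        assert abs(table.probe(V, i) - 2.5) < 1e-8


def test_probe_matches_periodic_pair_interaction():
    """Probing the potential of one Gaussian with another reproduces the
    Ewald-summed pair interaction for the same periodic geometry."""
    L, si, sj, d = 14.0, 1.0, 0.8, 4.0
    system = pq.AtomicSystem(L * np.eye(3), ["A", "B"],
                             [[3.0, 3.0, 3.0], [3.0 + d, 3.0, 3.0]])
    mesh = pq.Mesh(system.lattice, (60, 60, 60))
    table = pq.SupportTable(system, [si, sj], mesh)
    V = pq.solve_poisson(table.spread([0.0, 1.0]))
    got = table.probe(V, 0)
    want = pq.ewald_pair_interaction([d, 0.0, 0.0], si, sj, system.lattice)
    assert abs(got - want) < 1e-8


def test_probe_approaches_isolated_gaussian_pair_integral():
    """In a growing cell the probe converges (like 1/L) to the closed-form
    isolated integral erf(d / sqrt(2 (si^2 + sj^2))) / d."""
    from scipy.special import erf
    si, sj, d = 1.0, 0.8, 4.0
    want = erf(d / np.sqrt(2 * (si ** 2 + sj ** 2))) / d
    devs = []
    for L, n in ((16.0, 64), (32.0, 128)):
        system = pq.AtomicSystem(L * np.eye(3), ["A", "B"],
                                 [[4.0, 4.0, 4.0], [4.0 + d, 4.0, 4.0]])
        mesh = pq.Mesh(system.lattice, (n, n, n))
        table = pq.SupportTable(system, [si, sj], mesh)
        V = pq.solve_poisson(table.spread([0.0, 1.0]))
        devs.append(abs(table.probe(V, 0) - want))
    assert devs[1] < 0.6 * devs[0]  # periodic correction decays ~ 1/L
    assert devs[1] < 0.1


def test_probe_invariant_under_full_grid_vector_translation(small_random):
    system, _, res, mesh, q0 = small_random
    table = pq.SupportTable(system, res.sigma, mesh)
    V = pq.solve_poisson(table.spread(q0))
    moved = system.with_positions(system.positions + system.lattice[0])
    table2 = pq.SupportTable(moved, res.sigma, mesh)
    for i in (0, 5, 11):
        assert abs(table.probe(V, i) - table2.probe(V, i)) < 1e-14


def test_strain_fields_match_finite_difference_of_density(triclinic_five):
    """(rho_strained - rho)/eps at fixed fractional grid coordinates equals
    sum_munu eps_munu d rho/d eps_munu."""
    system, sigma, Q, mesh = triclinic_five
    table = pq.SupportTable(system, sigma, mesh, eps_trunc=1e-14)
    fields = table.spread_strain(Q)
    rng = np.random.default_rng(4)
    eps_sym = rng.standard_normal((3, 3))
    eps_sym = 0.5 * (eps_sym + eps_sym.T)
    h = 1e-5
    predicted = np.zeros(mesh.dims)
    for f, (mu, nu) in zip(fields, STRAIN_COMPONENTS):
        w = 2.0 if mu != nu else 1.0  # field is the symmetric derivative
        predicted += w * eps_sym[mu, nu] * f.values
    def density_at(scale):
        s = system.strained(scale * eps_sym)
        m = pq.Mesh(s.lattice, mesh.dims)
        return pq.build_density(s, sigma, Q, mesh=m, eps_trunc=1e-14).values
    fd = (density_at(h) - density_at(-h)) / (2 * h)
    assert np.abs(fd - predicted).max() < 1e-6 * np.abs(predicted).max()


def test_strain_fields_vanish_off_diagonal_for_centered_atom():
    system = pq.AtomicSystem(12 * np.eye(3), ["X"], [[6.0, 6.0, 6.0]])
    mesh = pq.Mesh(system.lattice, (48, 48, 48))
    fields = pq.build_strain_derivative_densities(system, 1.0, [1.0], mesh=mesh)
    for f, (mu, nu) in zip(fields, STRAIN_COMPONENTS):
        if mu != nu:
            # odd in d_mu and d_nu around the atom: grid sum cancels
            assert abs(f.values.sum()) < 1e-12


def test_grid_refinement_improves_probe_accuracy():
    L, si, sj, d = 14.0, 1.0, 0.8, 4.0
    system = pq.AtomicSystem(L * np.eye(3), ["A", "B"],
                             [[3.0, 3.0, 3.0], [3.0 + d, 3.0, 3.0]])
    want = pq.ewald_pair_interaction([d, 0.0, 0.0], si, sj, system.lattice)
    errs = []
    for n in (10, 20):  # ~0.7 and ~1.4 points per sigma: underresolved
        mesh = pq.Mesh(system.lattice, (n, n, n))
        table = pq.SupportTable(system, [si, sj], mesh)
        V = pq.solve_poisson(table.spread([0.0, 1.0]))
        errs.append(abs(table.probe(V, 0) - want))
    assert errs[1] < errs[0]


def test_multi_image_refusal_and_grid_mismatch_errors():
    system = pq.AtomicSystem(6.0 * np.eye(3), ["X"], [[1.0, 1.0, 1.0]])
    mesh = pq.Mesh(system.lattice, (24, 24, 24))
    with pytest.raises(pq.MeshError, match="multi_image"):
        pq.SupportTable(system, 1.0, mesh, multi_image=False)
    table = pq.SupportTable(system, 1.0, mesh)  # allowed by default
    other = pq.Mesh(system.lattice, (20, 20, 20))
    V = pq.MeshField(other, np.zeros(other.dims))
    with pytest.raises(pq.MeshError):
        table.probe(V, 0)


def test_smooth_fft_sizes():
    assert pq.next_smooth_size(97) == 100
    assert pq.next_smooth_size(120) == 120
    assert pq.next_smooth_size(1) == 1
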