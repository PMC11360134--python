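import numpy as np
import pytest

import pmqeq as pq
import pmqeq.poisson as poisson

from conftest import fd_force_oracle, fd_strain_oracle


def test_single_centered_atom_feels_no_force():
    system = pq.AtomicSystem(12 * np.eye(3), ["X"], [[6.0, 6.0, 6.0]])
    params = pq.QeqParameters({"X": pq.ElementParams(0.0, 0.8, 1.0)})
    F = pq.electrostatic_forces(system, params, [1.0])
    assert np.abs(F).max() < 1e-10


def test_opposite_dimer_forces_are_antisymmetric_along_bond():
    system = pq.AtomicSystem(14 * np.eye(3), ["X", "X"],
                             [[5.0, 7.0, 7.0], [9.0, 7.0, 7.0]])
    params = pq.QeqParameters({"X": pq.ElementParams(0.0, 0.8, 1.0)})
    F = pq.electrostatic_forces(system, params, [1.0, -1.0])
    np.testing.assert_allclose(F[0], -F[1], atol=1e-10)
    assert np.abs(F[0][1:]).max() < 1e-10  # along the bond only
    assert F[0][0] > 0.0  # opposite charges attract (partner sits at +x)


def test_electrostatic_forces_match_finite_differences(tiny_fd_system):
    system, params, res, mesh = tiny_fd_system
    rng = np.random.default_rng(1)
    Q = rng.standard_normal(system.n_atoms)
    Q -= Q.mean()
    F = pq.electrostatic_forces(system, params, Q, mesh=mesh)
    assert np.abs(F.sum(axis=0)).max() < 1e-8  # Newton's third law

    def energy(s):
        m = pq.Mesh(s.lattice, mesh.dims)
        return pq.electrostatic_energy(pq.build_density(s, res.sigma, Q, mesh=m))

    fd = fd_force_oracle(energy, system)
    assert np.abs(F - fd).max() < 1e-6


def test_qeq_forces_reduce_to_electrostatic_for_constant_chi(tiny_fd_system):
    system, params, _, mesh = tiny_fd_system
    r = pq.solve_qeq(system, params, pq.SolverSettings(tolerance=1e-10),
                     mesh=mesh)
    F1 = pq.qeq_forces(system, params, r, mesh=mesh)
    F2 = pq.electrostatic_forces(system, params, r.charges, mesh=mesh)
    np.testing.assert_array_equal(F1, F2)


def test_qeq_forces_with_position_dependent_chi(tiny_fd_system):
    """Variational shortcut against finite differences of E_Qeq with the toy
    chi(R) model, charges re-equilibrated at every displaced geometry."""
    system, params, res, mesh = tiny_fd_system
    toy = pq.ToyChiParams(amplitude=0.15, width=3.0, r_cut=4.0, base=0.1)

    def solve(s):
        chi, hook = pq.toy_chi_model(s, toy)
        p = pq.QeqParameters(params.elements, chi_override=chi)
        r = pq.solve_qeq(s, p, pq.SolverSettings(tolerance=1e-9),
                         mesh=pq.Mesh(s.lattice, mesh.dims))
        return p, r, hook

    p, r, hook = solve(system)
    F = pq.qeq_forces(system, p, r, dchi_hook=hook, mesh=mesh)
    fd = fd_force_oracle(lambda s: solve(s)[1].energy_qeq, system)
    assert np.abs(F - fd).max() < 1e-6


def test_lambda_solve_properties(tiny_fd_system):
    system, params, _, mesh = tiny_fd_system
    n = system.n_atoms
    # constant right-hand side projects to zero
    lam0 = pq.solve_lambda(system, params, np.full(n, 3.1), mesh=mesh)
    assert not np.any(lam0)
    rng = np.random.default_rng(3)
    dE = rng.standard_normal(n)
    st = pq.SolverSettings(tolerance=1e-11)
    lam = pq.solve_lambda(system, params, dE, st, mesh=mesh)
    assert abs(lam.sum()) < 1e-12
    # matches the dense bordered solve
    assert np.abs(lam - pq.dense_lambda_solve(system, params, dE)).max() < 1e-8
    # linear in the right-hand side
    lam2 = pq.solve_lambda(system, params, 2.0 * dE, st, mesh=mesh)
    np.testing.assert_allclose(lam2, 2.0 * lam, atol=1e-9)


def test_coupling_term_matches_dense_double_sum(tiny_fd_system):
    """The quasi-linear lambda-Q mixed term equals the brute-force
    lambda^T (dA/dr_i) Q from dense Ewald matrices."""
    from pmqeq.adjoint import _coupling_forces
    system, params, res, mesh = tiny_fd_system
    rng = np.random.default_rng(6)
    Q = rng.standard_normal(system.n_atoms)
    lam = pq.project_constrained(rng.standard_normal(system.n_atoms))
    op = pq.QeqOperator(system, res, mesh)
    V_Q = pq.solve_poisson(op.density(Q))
    V_l = pq.solve_poisson(op.density(lam))
    mixed = _coupling_forces(op.table, Q, lam, V_Q, V_l)
    h = 1e-6
    for i in (0, 3):
        fd = np.zeros(3)
        for c in range(3):
            pos = system.positions.copy()
            pos[i, c] += h
            Ap = pq.coulomb_matrix(system.with_positions(pos), res.sigma)
            pos[i, c] -= 2 * h
            Am = pq.coulomb_matrix(system.with_positions(pos), res.sigma)
            fd[c] = lam @ ((Ap - Am) / (2 * h)) @ Q
        assert np.abs(mixed[i] - fd).max() < 1e-6


def _toy_downstream(system, params, mesh, with_chi_model=True):
    """Fourth-generation-style energy: E_Qeq plus a quadratic charge term,
    optionally with the position-dependent toy chi."""
    res = pq.resolve_parameters(system, params)
    rng = np.random.default_rng(2)
    k_extra = 0.3 + 0.1 * rng.random(system.n_atoms)
    c_extra = 0.2 * rng.standard_normal(system.n_atoms)
    toy = pq.ToyChiParams(amplitude=0.15, width=3.0, r_cut=4.0, base=0.1)
    st = pq.SolverSettings(tolerance=1e-9)

    def solve(s):
        if with_chi_model:
            chi, hook = pq.toy_chi_model(s, toy)
            p = pq.QeqParameters(params.elements, chi_override=chi)
        else:
            chi, hook, p = res.chi, None, params
        r = pq.solve_qeq(s, p, st, mesh=pq.Mesh(s.lattice, mesh.dims))
        return p, r, chi, hook

    def total_energy(s):
        _, r, _, _ = solve(s)
        q = r.charges
        return r.energy_qeq + 0.5 * float(k_extra @ q ** 2) + float(c_extra @ q)

    p, r, chi, hook = solve(system)
    Q = r.charges
    dE_dQ = (chi + res.hardness * Q
             + pq.apply_A(system, res.sigma, Q, mesh=mesh)
             + k_extra * Q + c_extra)
    lam = pq.solve_lambda(system, p, dE_dQ, pq.SolverSettings(tolerance=1e-11),
                          mesh=mesh)
    return p, Q, lam, hook, total_energy


def test_total_forces_reduce_to_qeq_forces_in_variational_limit(tiny_fd_system):
    system, params, _, mesh = tiny_fd_system
    r = pq.solve_qeq(system, params, pq.SolverSettings(tolerance=1e-10),
                     mesh=mesh)
    # for E = E_Qeq the projected gradient vanishes, so lambda = 0
    res = pq.resolve_parameters(system, params)
    dE_dQ = res.chi + res.hardness * r.charges + pq.apply_A(
        system, res.sigma, r.charges, mesh=mesh)
    lam = pq.solve_lambda(system, params, dE_dQ, mesh=mesh)
    assert not np.any(lam)
    F_tot = pq.total_forces(system, params, r.charges, lam, mesh=mesh)
    F_qeq = pq.qeq_forces(system, params, r, mesh=mesh)
    np.testing.assert_allclose(F_tot, F_qeq, atol=1e-12)


def test_total_forces_match_composed_finite_differences(tiny_fd_system):
    system, params, _, mesh = tiny_fd_system
    p, Q, lam, hook, total_energy = _toy_downstream(system, params, mesh)
    F = pq.total_forces(system, p, Q, lam, explicit_force_part=-hook(Q),
                        dchi_hook=hook, mesh=mesh)
    fd = fd_force_oracle(total_energy, system)
    assert np.abs(F - fd).max() < 1e-6


def test_total_stress_matches_composed_finite_differences(tiny_fd_system):
    system, params, _, mesh = tiny_fd_system
    p, Q, lam, _, total_energy = _toy_downstream(system, params, mesh,
                                                 with_chi_model=False)
    assert np.abs(lam).max() > 1e-6  # the adjoint path is actually exercised
    S = pq.total_stress(system, p, Q, lam, mesh=mesh)
    fd = fd_strain_oracle(total_energy, system) / system.volume
    assert np.abs(S - fd).max() < 1e-7
    np.testing.assert_allclose(S, S.T, atol=1e-14)


def test_qeq_stress_matches_reequilibrated_finite_differences():
    system, params = pq.rocksalt_fixture()
    res = pq.resolve_parameters(system, params)
    mesh = pq.Mesh.for_system(system, res.sigma)
    r = pq.solve_qeq(system, params, pq.SolverSettings(tolerance=1e-10),
                     mesh=mesh)
    S = pq.qeq_stress(system, params, r, mesh=mesh)

    def energy(s):
        return pq.solve_qeq(s, params, pq.SolverSettings(tolerance=1e-9),
                            mesh=pq.Mesh(s.lattice, mesh.dims)).energy_qeq

    fd = fd_strain_oracle(energy, system) / system.volume
    assert np.abs(S - fd).max() < 1e-7
    # cubic symmetry: equal diagonal, vanishing off-diagonal entries
    assert np.abs(S - np.diag(np.diag(S))).max() < 1e-12
    assert np.abs(np.diag(S) - S[0, 0]).max() < 1e-12


def test_zero_charges_give_zero_stress(tiny_fd_system):
    system, params, _, mesh = tiny_fd_system
    z = np.zeros(system.n_atoms)
    assert not np.any(pq.total_stress(system, params, z, z, mesh=mesh))


def test_forces_invariant_under_lattice_translation(tiny_fd_system):
    system, params, _, mesh = tiny_fd_system
    rng = np.random.default_rng(8)
    Q = rng.standard_normal(system.n_atoms)
    F1 = pq.electrostatic_forces(system, params, Q, mesh=mesh)
    moved = system.with_positions(system.positions + system.lattice.sum(axis=0))
    F2 = pq.electrostatic_forces(moved, params, Q, mesh=mesh)
    np.testing.assert_allclose(F1, F2, atol=1e-12)


def test_total_derivative_uses_constant_number_of_poisson_solves():
    """The adjoint assembly needs O(1) Poisson solves independent of N."""
    counts = []
    for n, edge in ((8, 9.0), (27, 13.0)):
        spec = pq.FixtureSpec(n_atoms=n, n_elements=3, min_distance=2.0,
                              cell=edge * np.eye(3), sigma_range=(0.8, 1.1),
                              seed=n)
        system, params, _ = pq.random_test_system(spec)
        rng = np.random.default_rng(n)
        Q = rng.standard_normal(n)
        lam = pq.project_constrained(rng.standard_normal(n))
        before = poisson.POISSON_SOLVE_COUNT[0]
        pq.total_forces(system, params, Q, lam)
        pq.total_stress(system, params, Q, lam)
        counts.append(poisson.POISSON_SOLVE_COUNT[0] - before)
    assert counts[0] == counts[1]
    assert counts[0] <= 6
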