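import numpy as np
import pytest

import pmqeq as pq


@pytest.fixture(scope="session")
def small_random():
    """12-atom random neutral system with its resolved parameters and mesh."""
    spec = pq.FixtureSpec(n_atoms=12, n_elements=4, min_distance=1.8,
                          cell=11.0 * np.eye(3), sigma_range=(0.7, 1.1),
                          seed=3)
    system, params, q0 = pq.random_test_system(spec)
    resolved = pq.resolve_parameters(system, params)
    mesh = pq.Mesh.for_system(system, resolved.sigma)
    return system, params, resolved, mesh, q0


@pytest.fixture(scope="session")
def tiny_fd_system():
    """6-atom well-separated system used for finite-difference oracles."""
    spec = pq.FixtureSpec(n_atoms=6, n_elements=3, min_distance=2.2,
                          cell=9.0 * np.eye(3), sigma_range=(0.8, 1.1),
                          seed=11)
    system, params, _ = pq.random_test_system(spec)
    resolved = pq.resolve_parameters(system, params)
    mesh = pq.Mesh.for_system(system, resolved.sigma)
    return system, params, resolved, mesh


def fd_force_oracle(energy_of_system, system, step=1e-5):
    """Central finite differences -dE/dr as an (N, 3) array."""
    out = np.empty((system.n_atoms, 3))
    for i in range(system.n_atoms):
        for c in range(3):
            pos = system.positions.copy()
            pos[i, c] += step
            ep = energy_of_system(system.with_positions(pos))
            pos[i, c] -= 2 * step
            em = energy_of_system(system.with_positions(pos))
            out[i, c] = -(ep - em) / (2 * step)
    return out


def fd_strain_oracle(energy_of_system, system, step=1e-5):
    """Central finite differences dE/d eps_munu under symmetric strains,
    returned as the symmetric 3x3 full-matrix derivative (the off-diagonal
    perturbation moves both eps_munu and eps_numu, so the difference
    quotient is halved there)."""
    out = np.zeros((3, 3))
    for mu, nu in pq.mesh.STRAIN_COMPONENTS:
        eps = np.zeros((3, 3))
        eps[mu, nu] = eps[nu, mu] = step
        de = (energy_of_system(system.strained(eps))
              - energy_of_system(system.strained(-eps))) / (2 * step)
        if mu != nu:
            de *= 0.5
        out[mu, nu] = out[nu, mu] = de
    return out
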