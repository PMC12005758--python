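"""Body forces, contact detection and contact laws."""

import numpy as np
import pytest

from magassembly.magnet import magnet_with_gap
from magassembly.mechanics import (
    WALL,
    contact_damping_blocks,
    detect_contacts,
    effective_stiffness,
    gravity_buoyancy,
    hertz_forces,
    magnetic_force,
    stokes_drag_coefficient,
)
from magassembly.params import SimulationParameters, WellGeometry
from magassembly.synthetic import SpheroidPopulation, sample_population


def brute_force_contacts(pop, well):
    """O(n^2) all-pairs oracle for contact detection."""
    out = set()
    x, r = pop.positions, pop.radii
    n = pop.n
    for i in range(n):
        for j in range(i + 1, n):
            if r[i] + r[j] - np.linalg.norm(x[i] - x[j]) >= 0:
                out.add((j, i) if i > j else (i, j))
        if r[i] - (x[i, 2] - well.floor_z) >= 0:
            out.add((i, "floor"))
        if r[i] - (well.radius - np.hypot(x[i, 0], x[i, 1])) >= 0:
            out.add((i, "lateral"))
    return out


def pop_of(positions, radii, counts=None):
    return SpheroidPopulation(np.asarray(positions, float), np.asarray(radii, float),
                              counts)


class TestBodyForces:
    def test_gravity_arithmetic(self, params):
        pop = pop_of([[0, 0, 1e-3]], [100e-6])
        F = gravity_buoyancy(pop, params)[0]
        expect = -4 / 3 * np.pi * (1e-4) ** 3 * 14.0 * 9.807
        assert F[2] == pytest.approx(expect, rel=1e-12)
        assert F[0] == 0 and F[1] == 0

    def test_gravity_neutral_buoyancy(self):
        p = SimulationParameters(rho_s=1000.0)
        pop = pop_of([[0, 0, 1e-3]], [100e-6])
        assert np.all(gravity_buoyancy(pop, p) == 0)

    def test_gravity_cubic_scaling(self, params):
        pop = pop_of([[0, 0, 1e-3], [0, 0, 2e-3]], [100e-6, 200e-6])
        F = gravity_buoyancy(pop, params)
        assert F[1, 2] == pytest.approx(8 * F[0, 2], rel=1e-12)

    def test_stokes_coefficient(self, params):
        pop = pop_of([[0, 0, 0], [0, 0, 1]], [100e-6, 200e-6])
        g = stokes_drag_coefficient(pop, params)
        assert g[0] == pytest.approx(6 * np.pi * 1.2e-3 * 1e-4, rel=1e-12)
        assert g[1] == pytest.approx(2 * g[0], rel=1e-12)

    def test_magnetic_force_zero_counts_and_linearity(self, magnet, np_spec, params):
        mag = magnet_with_gap(magnet, 1e-3)
        pop = pop_of(
            [[1e-3, 0, 1e-3], [1e-3, 0, 1e-3]], [1e-4, 1e-4], counts=[0.0, 2e10]
        )
        F = magnetic_force(pop, mag, np_spec, params)
        assert np.all(F[0] == 0)
        pop2 = pop_of([[1e-3, 0, 1e-3]], [1e-4], counts=[4e10])
        F2 = magnetic_force(pop2, mag, np_spec, params)
        assert np.allclose(F2[0], 2 * F[1], rtol=1e-12)

    def test_magnetic_force_pulls_toward_magnet(self, magnet, np_spec, params):
        mag = magnet_with_gap(magnet, 1e-3)
        pop = pop_of([[2e-3, 1e-3, 1.5e-3]], [1e-4], counts=[1e10])
        F = magnetic_force(pop, mag, np_spec, params)[0]
        assert F[2] < 0  # downward
        assert F[0] < 0 and F[1] < 0  # toward the axis


class TestContactDetection:
    def test_gap_means_no_pair(self, well):
        pop = pop_of([[0, 0, 1e-3], [0, 0, 1.3e-3]], [1e-4, 1e-4])
        pairs = [c for c in detect_contacts(pop, well) if c.j != WALL]
        assert pairs == []

    def test_hand_computed_overlap(self):
        well = WellGeometry(radius=10.0, height=10.0)
        pop = pop_of([[0, 0, 5.0], [1.5, 0, 5.0]], [1.0, 1.0])
        pairs = [c for c in detect_contacts(pop, well) if c.j != WALL]
        assert len(pairs) == 1
        c = pairs[0]
        assert c.delta == pytest.approx(0.5)
        sign = 1.0 if c.i == 0 else -1.0
        assert np.allclose(c.normal, [-sign, 0, 0])
        assert c.r_eff == pytest.approx(0.5)
        assert c.S == pytest.approx(np.pi * 0.5 * 0.5)

    def test_floor_boundary_contact(self, well):
        pop = pop_of([[0, 0, 1e-4]], [1e-4])
        walls = [c for c in detect_contacts(pop, well) if c.j == WALL]
        assert len(walls) == 1
        assert walls[0].delta == pytest.approx(0.0, abs=1e-18)
        assert np.allclose(walls[0].normal, [0, 0, 1])

    def test_lateral_wall_normal_points_inward(self, well):
        pop = pop_of([[well.radius - 5e-5, 0, 1e-3]], [1e-4])
        walls = [c for c in detect_contacts(pop, well) if c.j == WALL]
        assert len(walls) == 1
        assert np.allclose(walls[0].normal, [-1, 0, 0])

    def test_matches_brute_force_on_random_populations(self, well):
        for seed in (0, 1, 2):
            pop = sample_population(150, 150e-6, 0.2, well, seed=seed)
            # push some spheroids together and to the walls to force contacts
            pop.positions[::3, 2] = pop.radii[::3] * 0.9
            pop.positions[::7] *= 0.2
            got = set()
            for c in detect_contacts(pop, well):
                if c.j == WALL:
                    kind = "floor" if c.normal[2] != 0 else "lateral"
                    got.add((c.i, kind))
                else:
                    got.add((min(c.i, c.j), max(c.i, c.j)))
            assert got == brute_force_contacts(pop, well)


class TestHertz:
    def test_zero_overlap_zero_force(self, params, well):
        pop = pop_of([[0, 0, 1e-4]], [1e-4])
        contacts = detect_contacts(pop, well)
        F = hertz_forces(contacts, params, pop.n)
        assert np.all(F == 0)
        assert contacts[0].S == 0

    def test_closed_form_value(self, params):
        """Equal 100 um spheres, 1 um overlap, E = 120 Pa, nu = 0.5."""
        well = WellGeometry(radius=1.0, height=1.0)
        d = 2e-4 - 1e-6
        pop = pop_of([[0, 0, 0.5], [d, 0, 0.5]], [1e-4, 1e-4])
        contacts = [c for c in detect_contacts(pop, well) if c.j != WALL]
        F = hertz_forces(contacts, params, 2)
        E_star = 1.0 / (2 * (1 - 0.25) / 120.0)
        expect = 4 / 3 * E_star * np.sqrt(0.5e-4) * (1e-6) ** 1.5
        assert np.linalg.norm(F[0]) == pytest.approx(expect, rel=1e-9)
        # Newton's third law
        assert np.allclose(F[0], -F[1])

    def test_delta_three_halves_scaling(self, params):
        well = WellGeometry(radius=1.0, height=1.0)
        forces = []
        for delta in (1e-6, 4e-6):
            d = 2e-4 - delta
            pop = pop_of([[0, 0, 0.5], [d, 0, 0.5]], [1e-4, 1e-4])
            contacts = [c for c in detect_contacts(pop, well) if c.j != WALL]
            forces.append(np.linalg.norm(hertz_forces(contacts, params, 2)[0]))
        assert forces[1] == pytest.approx(8 * forces[0], rel=1e-9)

    def test_internal_forces_sum_to_zero(self, params, well):
        pop = sample_population(80, 150e-6, 0.1, well, seed=4)
        pop.positions *= 0.3  # force overlaps
        pop.positions[:, 2] = np.abs(pop.positions[:, 2]) + 2e-4
        contacts = [c for c in detect_contacts(pop, well) if c.j != WALL]
        F = hertz_forces(contacts, params, pop.n)
        assert np.linalg.norm(F.sum(axis=0)) < 1e-18


class TestContactDamping:
    def test_block_eigenvalues(self, params):
        well = WellGeometry(radius=1.0, height=1.0)
        pop = pop_of([[0, 0, 0.5], [1.9e-4, 0, 0.5]], [1e-4, 1e-4])
        contacts = [c for c in detect_contacts(pop, well) if c.j != WALL]
        p = SimulationParameters(c_n=0.9, c_t=0.3)
        B = contact_damping_blocks(contacts, p)[0]
        S = contacts[0].S
        eig = np.sort(np.linalg.eigvalsh(B))
        assert np.allclose(eig, [0.3 * S, 0.3 * S, 0.9 * S], rtol=1e-12)
        assert np.allclose(B, B.T)

    def test_isotropic_when_cn_equals_ct(self, params, well):
        pop = pop_of([[0, 0, 0.5e-4]], [1e-4])
        contacts = detect_contacts(pop, well)
        B = contact_damping_blocks(contacts, params)[0]
        S = contacts[0].S
        assert np.allclose(B, 0.6 * S * np.eye(3), rtol=1e-12)


def test_effective_stiffness_values():
    assert effective_stiffness(120.0, 120.0) == pytest.approx(80.0)
    assert effective_stiffness(120.0, 1000.0) == pytest.approx(
        1 / (0.75 / 120 + 0.75 / 1000)
    )
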