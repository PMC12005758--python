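"""Mobility system assembly, CG solve and time integration."""

import numpy as np
import pytest

from magassembly.integrator import (
    DEFAULT_SUBSTEP_FRAC,
    MobilitySystem,
    _body_forces,
    assemble_system,
    run,
    solve_velocities,
    step,
)
from magassembly.magnet import magnet_with_gap
from magassembly.mechanics import detect_contacts
from magassembly.params import (
    ConfigBundle,
    MagnetSpec,
    NanoparticleSpec,
    SimulationParameters,
    WellGeometry,
)
from magassembly.synthetic import SpheroidPopulation, allocate_nanoparticles, sample_population
from tests.conftest import make_bundle


def crowded_population(n, well, seed):
    """Random population compressed to guarantee many contacts."""
    pop = sample_population(n, 150e-6, 0.1, well, seed=seed)
    pop.positions[:, :2] *= 0.25
    pop.positions[:, 2] = (pop.positions[:, 2] - well.floor_z) * 0.25 + 1e-4
    return pop


class TestAssembly:
    def test_isolated_spheroid_closed_form(self, params, well, np_spec):
        pop = SpheroidPopulation(np.array([[0.0, 0.0, 1e-3]]), np.array([1e-4]))
        contacts = detect_contacts(pop, well)
        forces = _body_forces(pop, params, None, np_spec, contacts, None)
        system = assemble_system(pop, forces, contacts, params)
        gamma = 6 * np.pi * params.eta_m * 1e-4
        assert np.allclose(system.C.toarray(), gamma * np.eye(3))
        v = solve_velocities(system)
        assert np.allclose(v[0], forces.total[0] / gamma, rtol=1e-10)

    def test_symmetric_positive_definite(self, params, well, np_spec):
        for seed in (0, 1, 2):
            pop = crowded_population(100, well, seed)
            contacts = detect_contacts(pop, well)
            forces = _body_forces(pop, params, None, np_spec, contacts, None)
            C = assemble_system(pop, forces, contacts, params).C.toarray()
            assert np.abs(C - C.T).max() == 0.0
            # dense factorization oracle: Cholesky succeeds iff SPD
            np.linalg.cholesky(C)

    def test_offdiagonal_block_is_negated_damping(self, params):
        well = WellGeometry(radius=1.0, height=1.0)
        pop = SpheroidPopulation(
            np.array([[0, 0, 0.5], [1.8e-4, 0, 0.5]]), np.array([1e-4, 1e-4])
        )
        contacts = [c for c in detect_contacts(pop, well) if c.j != -1]
        from magassembly.mechanics import contact_damping_blocks

        forces = _body_forces(pop, params, None, NanoparticleSpec(), contacts, None)
        C = assemble_system(pop, forces, contacts, params).C.toarray()
        B = contact_damping_blocks(contacts, params)[0]
        assert np.allclose(C[0:3, 3:6], -B)
        assert np.allclose(C[3:6, 0:3], -B)


class TestSolve:
    def test_zero_force_zero_velocity(self, params, well, np_spec):
        pop = crowded_population(30, well, 3)
        contacts = detect_contacts(pop, well)
        forces = _body_forces(pop, params, None, np_spec, contacts, None)
        system = assemble_system(pop, forces, contacts, params)
        system.F[:] = 0.0
        assert np.all(solve_velocities(system) == 0.0)

    def test_cg_matches_dense_solve(self, params, well, np_spec, rng):
        pop = crowded_population(30, well, 5)
        contacts = detect_contacts(pop, well)
        forces = _body_forces(pop, params, None, np_spec, contacts, None)
        forces.F_mag = rng.normal(scale=1e-9, size=(30, 3))  # randomize RHS
        system = assemble_system(pop, forces, contacts, params)
        v = solve_velocities(system, tol=1e-12)
        v_dense = np.linalg.solve(system.C.toarray(), system.F).reshape(-1, 3)
        assert np.linalg.norm(v - v_dense) / np.linalg.norm(v_dense) < 1e-8


class TestStep:
    def test_null_dynamics(self, well, np_spec):
        p = SimulationParameters(rho_s=1000.0, dt=1e-3, I_out=1e-3)
        pop = SpheroidPopulation(np.array([[0.0, 0.0, 1e-3]]), np.array([1e-4]))
        out = step(pop, p, None, np_spec, well)
        assert np.array_equal(out.positions, pop.positions)
        assert np.all(out.velocities == 0)

    def test_terminal_sedimentation_velocity(self, well, np_spec):
        """Free fall far from walls balances Stokes drag against net
        gravity: v = 2 (rho_s - rho_m) g r^2 / (9 eta)."""
        p = SimulationParameters(dt=1e-3, I_out=1e-3)
        for r in (60e-6, 100e-6, 140e-6):
            pop = SpheroidPopulation(np.array([[0.0, 0.0, 2e-3]]), np.array([r]))
            out = step(pop, p, None, np_spec, well)
            v_expect = -2 * (p.rho_s - p.rho_m) * p.g * r**2 / (9 * p.eta_m)
            assert abs(out.velocities[0, 2] - v_expect) / abs(v_expect) < 1e-6
            assert np.allclose(out.velocities[0, :2], 0.0)

    def test_lambda_zero_matches_manual_explicit_update(self, well, np_spec):
        p = SimulationParameters(dt=1e-3, I_out=1e-3, lam=0.0)
        pop = crowded_population(20, well, 7)
        pop = allocate_nanoparticles(pop, p, np_spec, seed=1)
        contacts = detect_contacts(pop, well)
        forces = _body_forces(pop, p, None, np_spec, contacts, None)
        system = assemble_system(pop, forces, contacts, p)
        v = solve_velocities(system, tol=1e-12)
        out = step(pop, p, None, np_spec, well, substep_frac=None, cg_tol=1e-12)
        assert np.allclose(out.positions, pop.positions + p.dt * v, rtol=1e-9)

    def test_semi_implicit_operator_assembly(self, params, well, np_spec):
        """The lam > 0 operator is C plus lam*dt times the Hertz stiffness
        gradient projected on the contact normal, on-diagonal positive and
        off-diagonal negative (keeping the system SPD)."""
        from magassembly.mechanics import (
            contact_damping_blocks,
            hertz_stiffness_gradient,
        )

        pop = crowded_population(12, well, 9)
        contacts = detect_contacts(pop, well)
        forces = _body_forces(pop, params, None, np_spec, contacts, None)
        lam_dt = 0.37 * params.dt
        C0 = assemble_system(pop, forces, contacts, params).C.toarray()
        C1 = assemble_system(pop, forces, contacts, params, lam_dt=lam_dt).C.toarray()
        expect = np.zeros_like(C0)
        for c in contacts:
            K = lam_dt * hertz_stiffness_gradient(c, params) * np.outer(c.normal, c.normal)
            expect[3 * c.i : 3 * c.i + 3, 3 * c.i : 3 * c.i + 3] += K
            if c.j != -1:
                expect[3 * c.j : 3 * c.j + 3, 3 * c.j : 3 * c.j + 3] += K
                expect[3 * c.i : 3 * c.i + 3, 3 * c.j : 3 * c.j + 3] -= K
                expect[3 * c.j : 3 * c.j + 3, 3 * c.i : 3 * c.i + 3] -= K
        assert np.allclose(C1 - C0, expect, rtol=1e-12, atol=1e-20)
        np.linalg.cholesky(C1)  # still SPD

    def test_semi_implicit_step_is_stable(self, well, np_spec):
        pop = crowded_population(15, well, 9)
        p0 = SimulationParameters(dt=1e-4, I_out=1e-4, lam=0.0)
        p1 = SimulationParameters(dt=1e-4, I_out=1e-4, lam=1.0)
        d0 = step(pop, p0, None, np_spec, well).positions - pop.positions
        d1 = step(pop, p1, None, np_spec, well).positions - pop.positions
        assert np.all(np.isfinite(d1))
        # the implicit term only damps the contact response
        assert np.abs(d1).max() <= np.abs(d0).max() * 1.5


class TestRun:
    def test_snapshot_cadence(self, np_spec):
        bundle = make_bundle(dt=1e-3, I_out=1e-2, t_end=0.06, rho_s=1000.0)
        traj = run(bundle, n=2, engine="numpy", field_on=False)
        # floor(t_end / I_out) + 1 snapshots including t = 0
        assert len(traj) == 7
        assert np.allclose(traj.times, np.arange(7) * 1e-2)

    def test_determinism_same_seed(self):
        bundle = make_bundle(dt=2e-4, I_out=5e-3, t_end=0.02, seed=21)
        a = run(bundle, n=25, engine="numba")
        b = run(bundle, n=25, engine="numba")
        assert np.array_equal(a[-1].positions, b[-1].positions)
        assert np.array_equal(a[-1].np_counts, b[-1].np_counts)

    def test_gravity_only_sediments_to_floor(self):
        """With the field off every spheroid settles onto the well floor."""
        bundle = make_bundle(dt=5e-3, I_out=0.5, t_end=10.0)
        bundle.well.height = 1.5e-3
        traj = run(bundle, n=10, engine="numba", field_on=False)
        final = traj[-1]
        # resting height = radius above the floor (contact overlap ~ 0)
        assert np.all(final.positions[:, 2] < final.radii * 1.05)
        assert np.all(final.positions[:, 2] > final.radii * 0.5)

    def test_timestep_halving_convergence(self):
        """Halving dt changes final positions by < 1% of the displacement
        scale on a 50-spheroid magnet-on reference run."""
        finals = {}
        for dt in (2e-4, 1e-4):
            bundle = make_bundle(dt=dt, I_out=0.1, t_end=0.4, seed=13)
            traj = run(bundle, n=50, engine="numba")
            finals[dt] = traj[-1].positions
        start = run(make_bundle(dt=2e-4, I_out=0.1, t_end=0.0, seed=13), n=50,
                    engine="numba")[0].positions
        disp = np.linalg.norm(finals[2e-4] - start, axis=1).max()
        diff = np.linalg.norm(finals[2e-4] - finals[1e-4], axis=1).max()
        assert diff < 0.01 * disp


class TestEngineEquivalence:
    def test_production_engine_matches_naive_reference(self, np_spec):
        """The compiled engine reproduces a naive reference integrator
        (all-pairs contacts, dense direct solve, same substep guard) to
        1e-6 relative over 1000 steps."""
        bundle = make_bundle(dt=5e-5, I_out=0.025, t_end=0.05, seed=17)
        params, np_spec_, magnet, well = bundle
        pop = sample_population(40, well=well, seed=17)
        pop = allocate_nanoparticles(pop, params, np_spec_, seed=18)

        traj = run(bundle, pop=pop.copy(), engine="numba", cg_tol=1e-12)
        traj_np = run(bundle, pop=pop.copy(), engine="numpy", cg_tol=1e-12)

        # naive reference: dense solve, no spatial structures
        from magassembly.integrator import _build_field_table
        from magassembly.magnet import calibrate_gap

        mag = magnet_with_gap(magnet, calibrate_gap(magnet))
        table = _build_field_table(mag, well, params)
        x = pop.positions.copy()
        v = np.zeros_like(x)
        r_min = pop.radii.min()
        state = pop.copy()
        for _ in range(1000):
            t_rem = params.dt
            while t_rem > 0:
                state.positions = x
                contacts = detect_contacts(state, well)
                forces = _body_forces(state, params, mag, np_spec_, contacts, table)
                C = assemble_system(state, forces, contacts, params).C.toarray()
                v = np.linalg.solve(C, forces.total.ravel()).reshape(-1, 3)
                dt_eff = t_rem
                vmax = np.linalg.norm(v, axis=1).max()
                if vmax * dt_eff > DEFAULT_SUBSTEP_FRAC * r_min:
                    dt_eff = DEFAULT_SUBSTEP_FRAC * r_min / vmax
                x = x + dt_eff * v
                t_rem -= dt_eff

        scale = np.abs(x).max()
        for got in (traj[-1].positions, traj_np[-1].positions):
            assert np.abs(got - x).max() / scale < 1e-6
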