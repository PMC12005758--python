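"""Overdamped equations of motion: assembly, solve, and time stepping.

Because inertia is negligible at these scales, drag balances the applied
forces at every instant and the velocities solve a sparse symmetric
positive-definite linear system

    C v = F,

where the 3x3 diagonal blocks of C carry the Stokes drag 6 pi eta r_i I
plus the damping tensors of every contact touching spheroid i, and the
off-diagonal blocks are the negated damping tensor of the pair (so C is
symmetric and, with eta > 0, strictly positive definite).  The right-hand
side stacks the magnetic, gravitational and Hertz forces.  The system is
solved with a Jacobi-preconditioned conjugate-gradient method, warm
started from the previous velocities.

Positions advance semi-implicitly:

    (C - lam * dt * K) v_new = F,     x_new = x + dt v_new (+ sqrt(2 D) dW)

with K the position-gradient of the Hertz pair forces and lam in [0, 1]
the degree of implicitness (0 by default, making the explicit branch the
production path).  The optional thermal term uses diffusivity D (default
0: thermal forces are negligible for spheroids larger than ~100 um).

A displacement guard sub-steps adaptively whenever a single step would
move any spheroid farther than ``substep_frac`` times the smallest
radius, which keeps stiff late-stage contact piles stable.
"""

from __future__ import annotations

import logging
import math
import time as _time
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import mechanics
from .magnet import FieldTable, calibrate_gap, magnet_with_gap
from .mechanics import (
    WALL,
    ForceDecomposition,
    contact_damping_blocks,
    detect_contacts,
    gravity_buoyancy,
    hertz_forces,
    hertz_stiffness_gradient,
    magnetic_force,
    stokes_drag_coefficient,
)
from .params import ConfigBundle
from .synthetic import (
    DEFAULT_RADIUS_CV,
    DEFAULT_RADIUS_MEAN,
    SpheroidPopulation,
    allocate_nanoparticles,
    sample_population,
)
from .trajectory import Snapshot, Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "MobilitySystem",
    "SolverError",
    "assemble_system",
    "solve_velocities",
    "step",
    "run",
]

DEFAULT_CG_TOL = 1e-10
DEFAULT_SUBSTEP_FRAC = 0.1


class SolverError(RuntimeError):
    """Conjugate-gradient failure with diagnostics."""


@dataclass
class MobilitySystem:
    """Sparse mobility system C v = F for one state."""

    C: sp.csr_matrix
    F: np.ndarray
    n: int


def assemble_system(
    pop: SpheroidPopulation,
    forces: ForceDecomposition,
    contacts: list,
    params,
    lam_dt: float = 0.0,
) -> MobilitySystem:
    """Build the sparse 3n x 3n mobility matrix and force vector.

    ``lam_dt = lam * dt`` adds the semi-implicit Hertz-gradient term
    (lam = 0 leaves plain C).
    """
    n = pop.n
    gamma = stokes_drag_coefficient(pop, params)
    rows, cols, vals = [], [], []
    idx = np.arange(3 * n)
    rows.append(idx)
    cols.append(idx)
    vals.append(np.repeat(gamma, 3))

    eye = np.eye(3)
    blocks = contact_damping_blocks(contacts, params)
    for c, B in zip(contacts, blocks):
        if lam_dt != 0.0:
            B = B + lam_dt * hertz_stiffness_gradient(c, params) * np.outer(
                c.normal, c.normal
            )
        bi = 3 * c.i
        r3 = np.repeat(np.arange(3), 3)
        c3 = np.tile(np.arange(3), 3)
        rows.append(bi + r3)
        cols.append(bi + c3)
        vals.append(B.ravel())
        if c.j != WALL:
            bj = 3 * c.j
            rows.append(bj + r3)
            cols.append(bj + c3)
            vals.append(B.ravel())
            rows.append(bi + r3)
            cols.append(bj + c3)
            vals.append(-B.ravel())
            rows.append(bj + r3)
            cols.append(bi + c3)
            vals.append(-B.ravel())
    C = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(3 * n, 3 * n),
    ).tocsr()
    return MobilitySystem(C=C, F=forces.total.ravel().copy(), n=n)


def solve_velocities(
    system: MobilitySystem,
    tol: float = DEFAULT_CG_TOL,
    x0: np.ndarray | None = None,
    maxiter: int = 2000,
) -> np.ndarray:
    """Solve C v = F by preconditioned conjugate gradients, (n, 3).

    The relative residual ||Cv - F|| / ||F|| is guaranteed <= tol.
    """
    F = system.F
    normF = np.linalg.norm(F)
    if normF == 0.0:
        return np.zeros((system.n, 3))
    diag = system.C.diagonal()
    M = sp.diags(1.0 / diag)
    v, info = spla.cg(
        system.C, F, x0=None if x0 is None else x0.ravel(),
        rtol=tol, atol=0.0, maxiter=maxiter, M=M,
    )
    res = np.linalg.norm(system.C @ v - F) / normF
    if info != 0 or res > tol * 10:
        raise SolverError(
            f"CG failed: info={info}, relative residual {res:.3e} (tol {tol:.1e})"
        )
    return v.reshape(system.n, 3)


def _body_forces(pop, params, magnet, np_spec, contacts, field_table):
    F_mag = (
        magnetic_force(pop, magnet, np_spec, params, field_table=field_table)
        if magnet is not None
        else np.zeros((pop.n, 3))
    )
    return ForceDecomposition(
        F_mag=F_mag,
        F_grav=gravity_buoyancy(pop, params),
        F_hertz=hertz_forces(contacts, params, pop.n),
        gamma=stokes_drag_coefficient(pop, params),
    )


def step(
    state: SpheroidPopulation,
    params,
    magnet,
    np_spec,
    well,
    rng: np.random.Generator | None = None,
    field_table: FieldTable | None = None,
    substep_frac: float | None = DEFAULT_SUBSTEP_FRAC,
    cg_tol: float = DEFAULT_CG_TOL,
) -> SpheroidPopulation:
    """Advance the state by one timestep ``params.dt`` (pure-numpy path).

    Radii and nanoparticle counts are unchanged; positions and velocities
    are updated.  ``magnet=None`` switches the magnetic force off.
    """
    out = state.copy()
    n = out.n
    if n == 0:
        return out
    max_disp = math.inf if substep_frac is None else substep_frac * float(out.radii.min())
    t_rem = params.dt
    v_prev = out.velocities
    while t_rem > 0.0:
        contacts = detect_contacts(out, well)
        forces = _body_forces(out, params, magnet, np_spec, contacts, field_table)
        dt_eff = t_rem
        lam_dt = params.lam * dt_eff
        system = assemble_system(out, forces, contacts, params, lam_dt=lam_dt)
        v = solve_velocities(system, tol=cg_tol, x0=v_prev)
        vmax = float(np.max(np.linalg.norm(v, axis=1))) if n else 0.0
        if vmax * dt_eff > max_disp:
            dt_eff = max_disp / vmax
        out.positions = out.positions + dt_eff * v
        if params.D > 0.0:
            if rng is None:
                rng = np.random.default_rng(params.seed)
            out.positions = out.positions + math.sqrt(
                2.0 * params.D * dt_eff
            ) * rng.standard_normal((n, 3))
        v_prev = v
        t_rem -= dt_eff
    out.velocities = v_prev
    return out


def _build_field_table(magnet, well, params):
    top_z = magnet.top_face_center[2]
    z_min = max(well.floor_z - 0.3e-3, top_z + 1e-5)
    z_max = well.floor_z + well.height + 1e-3
    rho_max = well.radius * 1.25
    return FieldTable.from_magnet(
        magnet, params.mu0, rho_max=rho_max, z_min=z_min, z_max=z_max
    )


def run(
    bundle: ConfigBundle,
    pop: SpheroidPopulation | None = None,
    n: int | None = None,
    radius_mean: float = DEFAULT_RADIUS_MEAN,
    radius_cv: float = DEFAULT_RADIUS_CV,
    engine: str = "auto",
    gap: float | str | None = "calibrated",
    target_floor_B: float = 0.4,
    field_on: bool = True,
    substep_frac: float | None = DEFAULT_SUBSTEP_FRAC,
    cg_tol: float = DEFAULT_CG_TOL,
) -> Trajectory:
    """Simulate the bioassembly from t = 0 to ``t_end``, snapshotting every
    output interval (the t = 0 state included).

    If no population is given, one is sampled inside the well with
    ``params.seed`` and nanoparticle counts are allocated with
    ``params.seed + 1``.  ``gap="calibrated"`` positions the magnet so the
    peak floor field equals ``target_floor_B`` (0.4 T); a float places the
    top face that far below the floor; ``None`` uses the magnet as
    configured.  ``engine`` is "numba" (compiled production path),
    "numpy" (transparent reference path) or "auto".
    """
    params, np_spec, magnet, well = bundle
    if pop is None:
        from .synthetic import DEFAULT_N

        pop = sample_population(
            n if n is not None else DEFAULT_N,
            radius_mean, radius_cv, well, seed=params.seed,
        )
        pop = allocate_nanoparticles(pop, params, np_spec, seed=params.seed + 1)

    if not field_on:
        magnet = None
    elif gap == "calibrated":
        magnet = magnet_with_gap(magnet, calibrate_gap(magnet, target_B=target_floor_B))
    elif gap is not None:
        magnet = magnet_with_gap(magnet, float(gap))

    field_table = _build_field_table(magnet, well, params) if magnet is not None else None

    if engine == "auto":
        engine = "numpy" if params.D > 0.0 else "numba"
    if engine == "numba" and params.D > 0.0:
        raise ValueError("the compiled engine does not implement thermal diffusion")

    dt = params.dt
    steps_per_out = max(1, int(round(params.I_out / dt)))
    n_out = int(math.floor(params.t_end / params.I_out + 1e-9))

    state = pop.copy()
    traj = Trajectory([])
    traj.append(_make_snapshot(0.0, state, params, magnet, np_spec, well, field_table))

    if engine == "numba":
        from .engine import advance

        t_wall = _time.perf_counter()
        for k in range(1, n_out + 1):
            advance(
                state, params, magnet, np_spec, well, field_table,
                n_steps=steps_per_out, substep_frac=substep_frac, cg_tol=cg_tol,
            )
            t = k * params.I_out
            traj.append(_make_snapshot(t, state, params, magnet, np_spec, well, field_table))
            logger.info("t=%.3f s (%d/%d), wall %.1f s", t, k, n_out,
                        _time.perf_counter() - t_wall)
    elif engine == "numpy":
        rng = np.random.default_rng(params.seed + 2)
        for k in range(1, n_out + 1):
            for _ in range(steps_per_out):
                state = step(
                    state, params, magnet, np_spec, well,
                    rng=rng, field_table=field_table,
                    substep_frac=substep_frac, cg_tol=cg_tol,
                )
            t = k * params.I_out
            traj.append(_make_snapshot(t, state, params, magnet, np_spec, well, field_table))
    else:
        raise ValueError(f"unknown engine '{engine}'")
    return traj


def _make_snapshot(t, state, params, magnet, np_spec, well, field_table) -> Snapshot:
    contacts = detect_contacts(state, well)
    forces = _body_forces(state, params, magnet, np_spec, contacts, field_table)
    return Snapshot(
        time=t,
        positions=state.positions.copy(),
        velocities=state.velocities.copy(),
        radii=state.radii.copy(),
        np_counts=state.np_counts.copy(),
        F_mag=forces.F_mag,
        F_grav=forces.F_grav,
        F_hertz=forces.F_hertz,
    )
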