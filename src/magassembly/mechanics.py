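"""Body forces and contact interactions between spheroids and the well.

Forces on each spheroid:

* magnetic:   F_m,i = N_NP,i * F_single_NP(x_i)  (nanoparticle-count scaling)
* gravity less buoyancy:  F_g,i = -(4/3) pi r_i^3 (rho_s - rho_m) g e_z
* Stokes drag:  F_d,i = -6 pi eta_m r_i v_i  (enters the mobility matrix)
* Hertz repulsion between overlapping elastic spheres and with the well
  (analytic cylinder: floor plane + lateral wall), with contact area
  S = pi delta r_eff and velocity-proportional contact damping
  F_c = -S [c_t I + (c_n - c_t) n n^T] v_rel.

The effective Hertz stiffness combines the two bodies' moduli as
1/E* = (1 - nu^2)/E_a + (1 - nu^2)/E_b with nu = 0.5 for both the
spheroid and the well material (standard DEM convention; the wall is
treated as a flat body of infinite radius so r_eff = r_i there).

Rotational degrees of freedom are ignored, and the tabulated
spheroid-well adhesion energy density (1e-20 N m^-1) is numerically
negligible at these scales, so no adhesion force is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .magnet import FieldTable, cylinder_B, magnetization_factor
from .params import (
    MagnetSpec,
    NanoparticleSpec,
    SimulationParameters,
    WellGeometry,
)
from .synthetic import SpheroidPopulation

__all__ = [
    "WALL",
    "ContactPair",
    "ForceDecomposition",
    "effective_stiffness",
    "magnetic_force",
    "gravity_buoyancy",
    "stokes_drag_coefficient",
    "detect_contacts",
    "hertz_forces",
    "contact_damping_blocks",
]

#: sentinel index for spheroid-well contacts
WALL = -1

_POISSON = 0.5


@dataclass
class ContactPair:
    """One overlapping pair: spheroid ``i`` against spheroid ``j`` or the
    well (``j == WALL``).  ``normal`` points from j toward i."""

    i: int
    j: int
    delta: float
    normal: np.ndarray
    r_eff: float

    @property
    def S(self) -> float:
        """Hertz contact area S = pi delta r_eff [m^2]."""
        return np.pi * self.delta * self.r_eff


@dataclass
class ForceDecomposition:
    """Per-spheroid body forces [N] and Stokes drag coefficients [N s m^-1]."""

    F_mag: np.ndarray
    F_grav: np.ndarray
    F_hertz: np.ndarray
    gamma: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.F_mag + self.F_grav + self.F_hertz


def effective_stiffness(E_a: float, E_b: float, nu: float = _POISSON) -> float:
    """Hertz effective modulus E* of two bodies in contact [Pa]."""
    return 1.0 / ((1.0 - nu**2) / E_a + (1.0 - nu**2) / E_b)


def _np_forces_direct(positions, magnet, np_spec, mu0, h=1e-6):
    """Single-NP force at many points by central differences of |H|^2.

    Uses the current-free identity (H.grad)H = (1/2) grad |H|^2 so only
    six field evaluations are needed for any number of points.
    """
    pts = np.atleast_2d(positions)
    G = np.empty_like(pts)
    for j in range(3):
        dp = np.zeros(3)
        dp[j] = h
        Hp = cylinder_B(pts + dp, magnet) / mu0
        Hm = cylinder_B(pts - dp, magnet) / mu0
        G[:, j] = (0.5 * np.sum(Hp**2, axis=1) - 0.5 * np.sum(Hm**2, axis=1)) / (2 * h)
    H = np.linalg.norm(cylinder_B(pts, magnet), axis=1) / mu0
    f = magnetization_factor(H, np_spec)
    return mu0 * np_spec.V_NP * f[:, None] * G


def magnetic_force(
    pop: SpheroidPopulation,
    magnet: MagnetSpec,
    np_spec: NanoparticleSpec,
    params: SimulationParameters,
    field_table: FieldTable | None = None,
) -> np.ndarray:
    """Magnetic force on every spheroid, (n, 3) [N].

    F_m,i = N_NP,i times the single-nanoparticle force at the spheroid
    center.  Uses the precomputed field table when provided, otherwise
    evaluates the cylinder field directly.
    """
    if field_table is not None:
        f_np = field_table.np_force(pop.positions, np_spec)
    else:
        f_np = _np_forces_direct(pop.positions, magnet, np_spec, params.mu0)
    return pop.np_counts[:, None] * f_np


def gravity_buoyancy(pop: SpheroidPopulation, params: SimulationParameters) -> np.ndarray:
    """Net gravity minus buoyancy, (n, 3) [N], along -z."""
    mag = 4.0 / 3.0 * np.pi * pop.radii**3 * (params.rho_s - params.rho_m) * params.g
    out = np.zeros((pop.n, 3))
    out[:, 2] = -mag
    return out


def stokes_drag_coefficient(pop: SpheroidPopulation, params: SimulationParameters) -> np.ndarray:
    """Per-spheroid Stokes coefficients gamma_i = 6 pi eta_m r_i [N s m^-1]."""
    return 6.0 * np.pi * params.eta_m * pop.radii


def detect_contacts(pop: SpheroidPopulation, well: WellGeometry) -> list[ContactPair]:
    """All contact pairs with overlap delta >= 0.

    Sphere-sphere candidates come from a KD-tree neighbor query (cost
    near-linear in n); sphere-wall contacts are tested against the
    analytic cylinder floor and lateral wall.
    """
    pairs: list[ContactPair] = []
    n = pop.n
    if n == 0:
        return pairs
    x = pop.positions
    r = pop.radii
    if n > 1:
        tree = cKDTree(x)
        cand = tree.query_pairs(r=2.0 * float(r.max()), output_type="ndarray")
        if cand.size:
            i = cand[:, 0]
            j = cand[:, 1]
            dvec = x[i] - x[j]
            dist = np.linalg.norm(dvec, axis=1)
            delta = r[i] + r[j] - dist
            keep = delta >= 0.0
            for ii, jj, dd, vec, dn in zip(
                i[keep], j[keep], delta[keep], dvec[keep], dist[keep]
            ):
                normal = vec / dn if dn > 0 else np.array([0.0, 0.0, 1.0])
                r_eff = r[ii] * r[jj] / (r[ii] + r[jj])
                pairs.append(ContactPair(int(ii), int(jj), float(dd), normal, float(r_eff)))

    # floor: outward wall normal +z
    delta_f = r - (x[:, 2] - well.floor_z)
    for ii in np.flatnonzero(delta_f >= 0.0):
        pairs.append(
            ContactPair(int(ii), WALL, float(delta_f[ii]), np.array([0.0, 0.0, 1.0]), float(r[ii]))
        )
    # lateral wall: outward normal points inward (-rho_hat)
    rho = np.hypot(x[:, 0], x[:, 1])
    delta_w = r - (well.radius - rho)
    for ii in np.flatnonzero(delta_w >= 0.0):
        if rho[ii] > 0:
            nrm = np.array([-x[ii, 0] / rho[ii], -x[ii, 1] / rho[ii], 0.0])
        else:  # center of the well cannot touch the lateral wall unless r > R
            nrm = np.array([1.0, 0.0, 0.0])
        pairs.append(ContactPair(int(ii), WALL, float(delta_w[ii]), nrm, float(r[ii])))
    return pairs


def hertz_forces(
    contacts: list[ContactPair],
    params: SimulationParameters,
    n: int,
) -> np.ndarray:
    """Summed Hertz repulsion per spheroid, (n, 3) [N].

    F_H = (4/3) E* sqrt(r_eff) delta^(3/2) along the contact normal,
    applied equal-and-opposite to both members of a spheroid pair.
    """
    out = np.zeros((n, 3))
    Ess = effective_stiffness(params.E_spheroid, params.E_spheroid)
    Esw = effective_stiffness(params.E_spheroid, params.E_well)
    for c in contacts:
        if c.delta < 0:
            raise ValueError("negative overlap in contact list")
        E = Esw if c.j == WALL else Ess
        f = 4.0 / 3.0 * E * np.sqrt(c.r_eff) * c.delta**1.5
        out[c.i] += f * c.normal
        if c.j != WALL:
            out[c.j] -= f * c.normal
    return out


def hertz_stiffness_gradient(contact: ContactPair, params: SimulationParameters) -> float:
    """d|F_H|/d(delta) [N m^-1] for the semi-implicit operator."""
    E = (
        effective_stiffness(params.E_spheroid, params.E_well)
        if contact.j == WALL
        else effective_stiffness(params.E_spheroid, params.E_spheroid)
    )
    return 2.0 * E * np.sqrt(contact.r_eff * max(contact.delta, 0.0))


def contact_damping_blocks(
    contacts: list[ContactPair], params: SimulationParameters
) -> list[np.ndarray]:
    """3x3 damping tensor per contact: B = S [c_t I + (c_n - c_t) n n^T].

    The contact drag force is F_c = -B v_rel; B is symmetric PSD for
    non-negative damping coefficients, with eigenvalues
    {S c_n, S c_t, S c_t}.
    """
    blocks = []
    eye = np.eye(3)
    for c in contacts:
        nn = np.outer(c.normal, c.normal)
        blocks.append(c.S * (params.c_t * eye + (params.c_n - params.c_t) * nn))
    return blocks
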