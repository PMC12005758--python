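"""Field of a uniformly axially magnetized cylindrical permanent magnet.

The exterior flux density is evaluated with the closed-form solution of
Derby & Olbert (Am. J. Phys. 78, 2010) in terms of Bulirsch's generalized
complete elliptic integral ``cel``, which is implemented here (vectorized)
because scipy exposes no three-parameter complete elliptic integral.

The magnetophoretic force on a single superparamagnetic nanoparticle is

    F = mu0 * V_NP * f(|H|) * (H . grad) H

with the piecewise magnetization factor

    f(H) = 3                for |H| <  M_NP / 3   (linear, unsaturated)
    f(H) = M_NP / |H|       for |H| >= M_NP / 3   (saturated)

so that the particle's effective magnetization f(H)*H never exceeds the
material saturation magnetization M_NP.  In the current-free exterior
(H . grad) H == (1/2) grad |H|^2, which is what the precomputed field
table stores; the direct evaluator uses central finite differences of H
(step ``FD_STEP`` = 1e-6 m) and the identity is asserted in the tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .params import MagnetSpec, NanoparticleSpec, SimulationParameters

__all__ = [
    "FieldSample",
    "cel",
    "cylinder_B",
    "cylinder_field",
    "magnetization_factor",
    "single_np_force",
    "calibrate_gap",
    "magnet_with_gap",
    "FieldTable",
    "FD_STEP",
]

#: central-difference step for field gradients [m]
FD_STEP = 1e-6

_CEL_TOL = 1e-8


class InsideMagnetError(ValueError):
    """Evaluation point lies inside the magnet body."""


def cel(kc, p, c, s):
    """Bulirsch's generalized complete elliptic integral cel(kc, p, c, s).

    Vectorized over ``kc``; requires p > 0 (the only case the cylinder
    field needs).  Converges quadratically (AGM-type recurrence).
    """
    kc = np.atleast_1d(np.asarray(kc, dtype=float))
    p = np.broadcast_to(np.asarray(p, dtype=float), kc.shape).copy()
    c = np.broadcast_to(np.asarray(c, dtype=float), kc.shape).copy()
    s = np.broadcast_to(np.asarray(s, dtype=float), kc.shape).copy()
    if np.any(kc == 0.0):
        raise ValueError("cel undefined for kc = 0")
    if np.any(p <= 0.0):
        raise ValueError("cel implemented for p > 0 only")

    qc = np.abs(kc)
    a = c.copy()
    b = s.copy()
    e = qc.copy()
    em = np.ones_like(qc)
    pp = np.sqrt(p)
    b = b / pp

    done = np.zeros(qc.shape, dtype=bool)
    for _ in range(80):
        act = ~done
        f = a[act]
        a[act] = a[act] + b[act] / pp[act]
        g = e[act] / pp[act]
        b[act] = 2.0 * (b[act] + f * g)
        pp[act] = g + pp[act]
        g_old = em[act].copy()
        em[act] = qc[act] + em[act]
        conv = np.abs(g_old - qc[act]) <= g_old * _CEL_TOL
        idx = np.flatnonzero(act)
        done[idx[conv]] = True
        cont = idx[~conv]
        if cont.size == 0:
            break
        qc[cont] = 2.0 * np.sqrt(e[cont])
        e[cont] = qc[cont] * em[cont]
    return (np.pi / 2.0) * (b + a * em) / (em * (em + pp))


def _frame(magnet: MagnetSpec):
    """Orthonormal basis (u, v, axis) and the magnet center position."""
    ax = magnet.axis
    trial = np.array([1.0, 0.0, 0.0])
    if abs(ax[0]) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    u = np.cross(ax, trial)
    u /= np.linalg.norm(u)
    v = np.cross(ax, u)
    center = magnet.top_face_center - 0.5 * magnet.height * ax
    return u, v, center


def cylinder_B(points: np.ndarray, magnet: MagnetSpec) -> np.ndarray:
    """Flux density B [T] of the magnet at exterior points, shape (n, 3).

    Raises :class:`InsideMagnetError` if any point is strictly inside the
    magnet volume.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    _, _, center = _frame(magnet)
    rel = pts - center
    ax = magnet.axis
    z = rel @ ax
    rho_vec = rel - z[:, None] * ax
    rho = np.linalg.norm(rho_vec, axis=1)

    a = magnet.radius
    b_half = magnet.height / 2.0
    inside = (np.abs(z) < b_half) & (rho < a)
    if np.any(inside):
        raise InsideMagnetError("field requested inside the magnet body")

    # nudge off the rho = a cylinder where the elliptic parametrization
    # degenerates (gamma -> 0); the field itself is regular there
    near = np.abs(rho - a) < 1e-9 * a
    rho = np.where(near, np.where(rho >= a, a * (1 + 1e-9), a * (1 - 1e-9)), rho)

    zp = z + b_half
    zm = z - b_half
    sp = np.sqrt(zp**2 + (rho + a) ** 2)
    sm = np.sqrt(zm**2 + (rho + a) ** 2)
    alpha_p = a / sp
    alpha_m = a / sm
    beta_p = zp / sp
    beta_m = zm / sm
    gamma = (a - rho) / (a + rho)
    kp = np.sqrt((zp**2 + (a - rho) ** 2) / (zp**2 + (a + rho) ** 2))
    km = np.sqrt((zm**2 + (a - rho) ** 2) / (zm**2 + (a + rho) ** 2))

    B0 = magnet.Br / np.pi
    Brho = B0 * (alpha_p * cel(kp, 1.0, 1.0, -1.0) - alpha_m * cel(km, 1.0, 1.0, -1.0))
    g2 = gamma**2
    Bz = (
        B0
        * a
        / (a + rho)
        * (beta_p * cel(kp, g2, 1.0, gamma) - beta_m * cel(km, g2, 1.0, gamma))
    )

    with np.errstate(invalid="ignore", divide="ignore"):
        rho_hat = np.where(rho[:, None] > 0, rho_vec / np.maximum(rho, 1e-300)[:, None], 0.0)
    B = Brho[:, None] * rho_hat + Bz[:, None] * ax
    return B if np.asarray(points).ndim == 2 else B[0]


@dataclass
class FieldSample:
    """Field strength H [A m^-1], advective gradient (H.grad)H [A^2 m^-3],
    and flux density B [T] at one point."""

    H: np.ndarray
    gradH_H: np.ndarray
    B: np.ndarray


def _H_at(points, magnet, mu0):
    return cylinder_B(np.atleast_2d(points), magnet) / mu0


def cylinder_field(
    point: np.ndarray,
    magnet: MagnetSpec,
    mu0: float = 1.256e-6,
    h: float = FD_STEP,
) -> FieldSample:
    """H, (H.grad)H and B at one exterior point.

    The Jacobian of H is taken by central finite differences with step
    ``h`` along each axis (documented default 1e-6 m, far below every
    geometric scale of the problem).
    """
    p = np.asarray(point, dtype=float).reshape(3)
    B = cylinder_B(p[None, :], magnet)[0]
    H = B / mu0
    J = np.empty((3, 3))  # J[i, j] = dH_i / dx_j
    for j in range(3):
        dp = np.zeros(3)
        dp[j] = h
        Hp = _H_at(p + dp, magnet, mu0)[0]
        Hm = _H_at(p - dp, magnet, mu0)[0]
        J[:, j] = (Hp - Hm) / (2.0 * h)
    return FieldSample(H=H, gradH_H=J @ H, B=B)


def magnetization_factor(H_mag, np_spec: NanoparticleSpec):
    """Dimensionless factor f(|H|) of the piecewise magnetization model.

    Linear branch f = 3 below M_NP/3, saturated branch f = M_NP/|H| above;
    continuous at the branch point.  Accepts scalars or arrays; negative
    field magnitudes are a domain error.
    """
    H = np.asarray(H_mag, dtype=float)
    if np.any(H < 0):
        raise ValueError("field magnitude must be >= 0")
    M = np_spec.M_NP
    with np.errstate(divide="ignore"):
        f = np.where(H < M / 3.0, 3.0, M / np.maximum(H, 1e-300))
    return float(f) if np.isscalar(H_mag) else f


def single_np_force(
    point: np.ndarray,
    magnet: MagnetSpec,
    np_spec: NanoparticleSpec,
    params: SimulationParameters,
) -> np.ndarray:
    """Magnetic force [N] on one nanoparticle at ``point``."""
    sample = cylinder_field(point, magnet, mu0=params.mu0)
    f = magnetization_factor(float(np.linalg.norm(sample.H)), np_spec)
    return params.mu0 * np_spec.V_NP * f * sample.gradH_H


def _on_axis_B(z_above_top: float, magnet: MagnetSpec) -> float:
    """Closed-form |B| on the axis, z measured up from the top face."""
    a = magnet.radius
    L = magnet.height
    z = z_above_top
    return (
        magnet.Br
        / 2.0
        * ((z + L) / math.hypot(z + L, a) - z / math.hypot(z, a))
    )


def calibrate_gap(
    magnet: MagnetSpec,
    target_B: float = 0.4,
    bracket: tuple[float, float] = (1e-5, 20e-3),
) -> float:
    """Magnet-to-well-floor gap [m] at which the on-axis floor field
    equals ``target_B`` (the reported 0.4 T maximum at the well bottom).
    """
    f = lambda g: _on_axis_B(g, magnet) - target_B
    lo, hi = bracket
    if f(lo) < 0:
        raise ValueError(
            f"target {target_B} T exceeds the face field {_on_axis_B(lo, magnet):.3f} T"
        )
    return float(brentq(f, lo, hi, xtol=1e-9))


def magnet_with_gap(magnet: MagnetSpec, gap: float) -> MagnetSpec:
    """Copy of ``magnet`` placed coaxially below the well floor by ``gap``."""
    return MagnetSpec(
        diameter=magnet.diameter,
        height=magnet.height,
        Br=magnet.Br,
        top_face_center=np.array([0.0, 0.0, -gap]),
        axis=np.array([0.0, 0.0, 1.0]),
    )


class FieldTable:
    """Axisymmetric lookup table of |H| and (1/2) grad |H|^2.

    Built once per run on an (rho, z) grid; the integrator interpolates
    bilinearly.  Valid only for magnets aligned with +z.  The stored
    gradient is the exterior identity (H.grad)H = (1/2) grad |H|^2 taken
    by second-order differences of |H|^2 on the grid.
    """

    def __init__(self, rho, z, Hmag, Grho, Gz, mu0):
        self.rho = rho
        self.z = z
        self.Hmag = Hmag
        self.Grho = Grho
        self.Gz = Gz
        self.mu0 = mu0

    @classmethod
    def from_magnet(
        cls,
        magnet: MagnetSpec,
        mu0: float,
        rho_max: float,
        z_min: float,
        z_max: float,
        n_rho: int = 768,
        n_z: int = 512,
    ) -> "FieldTable":
        if abs(magnet.axis[2] - 1.0) > 1e-12 or np.any(np.abs(magnet.axis[:2]) > 1e-12):
            raise ValueError("FieldTable requires a +z-aligned magnet")
        top_z = magnet.top_face_center[2]
        if z_min <= top_z:
            raise ValueError("table z range must lie above the magnet top face")
        rho = np.linspace(0.0, rho_max, n_rho)
        z = np.linspace(z_min, z_max, n_z)
        R, Z = np.meshgrid(rho, z, indexing="ij")
        pts = np.column_stack(
            [R.ravel() + magnet.top_face_center[0], np.full(R.size, magnet.top_face_center[1]), Z.ravel()]
        )
        B = cylinder_B(pts, magnet)
        H = np.linalg.norm(B, axis=1).reshape(R.shape) / mu0
        U = 0.5 * H**2
        Grho, Gz = np.gradient(U, rho, z)
        return cls(rho, z, H, Grho, Gz, mu0)

    def _interp(self, table, rho, z):
        # uniform-grid bilinear lookup; operation order matches the
        # compiled engine bit-for-bit so the two paths stay interchangeable
        nr, nz = len(self.rho), len(self.z)
        drho = self.rho[1] - self.rho[0]
        dzz = self.z[1] - self.z[0]
        rr = np.clip((rho - self.rho[0]) / drho, 0.0, nr - 1.000001)
        zz = np.clip((z - self.z[0]) / dzz, 0.0, nz - 1.000001)
        ir = rr.astype(np.int64)
        iz = zz.astype(np.int64)
        tr = rr - ir
        tz = zz - iz
        w00 = (1 - tr) * (1 - tz)
        w10 = tr * (1 - tz)
        w01 = (1 - tr) * tz
        w11 = tr * tz
        return (
            table[ir, iz] * w00
            + table[ir + 1, iz] * w10
            + table[ir, iz + 1] * w01
            + table[ir + 1, iz + 1] * w11
        )

    def np_force(self, positions: np.ndarray, np_spec: NanoparticleSpec) -> np.ndarray:
        """Single-nanoparticle magnetic force [N] at each position, (n, 3)."""
        pts = np.atleast_2d(positions)
        x0, y0 = 0.0, 0.0
        dx = pts[:, 0] - x0
        dy = pts[:, 1] - y0
        rho = np.hypot(dx, dy)
        H = self._interp(self.Hmag, rho, pts[:, 2])
        Grho = self._interp(self.Grho, rho, pts[:, 2])
        Gz = self._interp(self.Gz, rho, pts[:, 2])
        f = magnetization_factor(H, np_spec)
        pref = self.mu0 * np_spec.V_NP * f
        with np.errstate(invalid="ignore"):
            ux = np.where(rho > 0, dx / np.maximum(rho, 1e-300), 0.0)
            uy = np.where(rho > 0, dy / np.maximum(rho, 1e-300), 0.0)
        out = np.empty_like(pts)
        out[:, 0] = pref * Grho * ux
        out[:, 1] = pref * Grho * uy
        out[:, 2] = pref * Gz
        return out
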