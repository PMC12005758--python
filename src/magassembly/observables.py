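"""Simulation readouts: coverage kinetics, assembly time, rate and stress
profiles.

Coverage is the area of the union of the spheroids' equatorial disks
projected onto the well floor, clipped to a circular region of interest
(default: the 5 mm magnet footprint, the implant's own size) and divided
by the ROI area.  Assembly time is the first time coverage reaches a
threshold fraction (default 95%) of its final plateau value; an
exponential time constant fitted to the same series is reported alongside
for comparison, since either convention can be found in kinetics plots.

Stress profiles divide each spheroid's body force (magnetic + gravity by
default; contact forces are excluded from the headline profiles but
remain exportable from trajectories) by its cross-section pi r_i^2.  The
radial component is projected on the outward cylindrical unit vector, so
compression toward the magnet axis is negative; the vertical component is
simply F_z / (pi r^2), negative downward.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.optimize import curve_fit

from .trajectory import Trajectory

__all__ = [
    "KineticsSeries",
    "StressProfile",
    "area_coverage",
    "coverage_series",
    "assembly_time",
    "AssemblyTimeResult",
    "exponential_time_constant",
    "rate_profile",
    "stress_profiles",
    "DEFAULT_ROI_RADIUS",
]

#: magnet footprint radius [m]: default coverage region of interest
DEFAULT_ROI_RADIUS = 2.5e-3


@dataclass
class KineticsSeries:
    """Coverage fraction versus time."""

    times: np.ndarray
    coverage: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.coverage = np.asarray(self.coverage, dtype=float)
        if self.times.size != self.coverage.size:
            raise ValueError("times and coverage disagree in length")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any((self.coverage < 0) | (self.coverage > 1)):
            raise ValueError("coverage must lie in [0, 1]")


@dataclass
class StressProfile:
    """Binned mean radial / vertical stress [N m^-2] versus distance from
    the magnet axis [m]."""

    bin_centers: np.ndarray
    radial_stress: np.ndarray
    vertical_stress: np.ndarray
    counts: np.ndarray


def area_coverage(
    state,
    roi_radius: float = DEFAULT_ROI_RADIUS,
    pixel: float | None = None,
) -> float:
    """Fraction of the ROI disk covered by projected spheroid disks.

    Computed by rasterization; ``pixel`` defaults to one tenth of the
    smallest spheroid radius.
    """
    if roi_radius <= 0:
        raise ValueError("roi_radius must be > 0")
    x = np.atleast_2d(state.positions)
    r = np.asarray(state.radii, dtype=float)
    if r.size == 0:
        return 0.0
    if pixel is None:
        pixel = float(r.min()) / 10.0
    npx = max(int(np.ceil(2 * roi_radius / pixel)), 4)
    edges = np.linspace(-roi_radius, roi_radius, npx + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    covered = np.zeros((npx, npx), dtype=bool)
    for xi, yi, ri in zip(x[:, 0], x[:, 1], r):
        lo_x = np.searchsorted(centers, xi - ri)
        hi_x = np.searchsorted(centers, xi + ri)
        lo_y = np.searchsorted(centers, yi - ri)
        hi_y = np.searchsorted(centers, yi + ri)
        if lo_x >= npx or hi_x == 0 or lo_y >= npx or hi_y == 0:
            continue
        cx = centers[lo_x:hi_x]
        cy = centers[lo_y:hi_y]
        if cx.size == 0 or cy.size == 0:
            continue
        mask = (cx[:, None] - xi) ** 2 + (cy[None, :] - yi) ** 2 <= ri**2
        covered[lo_x:hi_x, lo_y:hi_y] |= mask
    roi = (centers[:, None] ** 2 + centers[None, :] ** 2) <= roi_radius**2
    n_roi = int(roi.sum())
    if n_roi == 0:
        return 0.0
    return float((covered & roi).sum() / n_roi)


def coverage_series(
    traj: Trajectory,
    roi_radius: float = DEFAULT_ROI_RADIUS,
    pixel: float | None = None,
) -> KineticsSeries:
    """Coverage kinetics over all trajectory snapshots."""
    times = traj.times
    cov = np.array([area_coverage(s, roi_radius, pixel) for s in traj.snapshots])
    return KineticsSeries(times=times, coverage=cov)


class AssemblyTimeResult(NamedTuple):
    time: float
    plateau: float
    reached: bool


def assembly_time(series: KineticsSeries, threshold: float = 0.95) -> AssemblyTimeResult:
    """First time coverage reaches ``threshold`` times its final plateau.

    Linear interpolation between samples; a constant series assembles at
    t = 0.  ``reached`` is False only if the series never attains the
    target (then the end time is returned).
    """
    if series.times.size == 0:
        raise ValueError("empty kinetics series")
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    plateau = float(series.coverage[-1])
    target = threshold * plateau
    cov = series.coverage
    t = series.times
    if cov[0] >= target:
        return AssemblyTimeResult(float(t[0]) if t[0] > 0 else 0.0, plateau, True)
    above = np.flatnonzero(cov >= target)
    if above.size == 0:
        return AssemblyTimeResult(float(t[-1]), plateau, False)
    k = above[0]
    # linear interpolation on the crossing segment
    t_cross = t[k - 1] + (target - cov[k - 1]) / (cov[k] - cov[k - 1]) * (t[k] - t[k - 1])
    return AssemblyTimeResult(float(t_cross), plateau, True)


def exponential_time_constant(series: KineticsSeries) -> float:
    """Time constant tau of a saturating-exponential fit
    A(t) = A_inf (1 - exp(-t/tau)) to the coverage series."""
    t = series.times
    cov = series.coverage
    a0 = max(cov[-1], 1e-12)
    tau0 = max(t[-1] / 5.0, 1e-6)

    def model(t, a, tau):
        return a * (1.0 - np.exp(-t / tau))

    popt, _ = curve_fit(model, t, cov, p0=[a0, tau0], maxfev=10000)
    return float(popt[1])


def rate_profile(
    traj: Trajectory,
    n_bins: int = 10,
    r_max: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Radius-normalized speed [s^-1] binned by distance from the magnet
    axis.

    For every snapshot interval and spheroid, the displacement rate
    divided by the spheroid radius is assigned to the bin of its radial
    distance at the interval start; bin means are returned as
    (bin_centers, mean_rate, counts).
    """
    if len(traj) < 2:
        raise ValueError("rate profile needs at least two snapshots")
    rho_all, val_all = [], []
    for a, b in zip(traj.snapshots[:-1], traj.snapshots[1:]):
        dt = b.time - a.time
        disp = np.linalg.norm(b.positions - a.positions, axis=1)
        rho = np.hypot(a.positions[:, 0], a.positions[:, 1])
        rho_all.append(rho)
        val_all.append(disp / dt / a.radii)
    rho_all = np.concatenate(rho_all)
    val_all = np.concatenate(val_all)
    if r_max is None:
        r_max = float(rho_all.max()) or 1.0
    edges = np.linspace(0.0, r_max, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    idx = np.clip(np.digitize(rho_all, edges) - 1, 0, n_bins - 1)
    means = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = idx == b
        counts[b] = sel.sum()
        if counts[b]:
            means[b] = val_all[sel].mean()
    return centers, means, counts


def stress_profiles(
    snapshot,
    n_bins: int = 10,
    include_gravity: bool = True,
    r_max: float | None = DEFAULT_ROI_RADIUS,
) -> StressProfile:
    """Radial and vertical body-force stress binned by axial distance.

    ``snapshot`` must carry the per-spheroid force decomposition (as run
    snapshots do).  Stress convention: negative = compressive (toward the
    magnet axis, or downward).  The default binning domain is the magnet
    footprint (the extent of the assembled construct); ``r_max=None``
    extends it to the farthest spheroid.
    """
    F = snapshot.F_mag.copy()
    if include_gravity:
        F = F + snapshot.F_grav
    x = snapshot.positions
    r = snapshot.radii
    rho = np.hypot(x[:, 0], x[:, 1])
    area = np.pi * r**2
    with np.errstate(invalid="ignore"):
        ux = np.where(rho > 0, x[:, 0] / np.maximum(rho, 1e-300), 0.0)
        uy = np.where(rho > 0, x[:, 1] / np.maximum(rho, 1e-300), 0.0)
    sigma_rad = (F[:, 0] * ux + F[:, 1] * uy) / area
    sigma_vert = F[:, 2] / area
    if r_max is None:
        r_max = float(rho.max()) if rho.size and rho.max() > 0 else 1.0
    edges = np.linspace(0.0, r_max, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    idx = np.clip(np.digitize(rho, edges) - 1, 0, n_bins - 1)
    s_rad = np.zeros(n_bins)
    s_vert = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = idx == b
        counts[b] = sel.sum()
        if counts[b]:
            s_rad[b] = sigma_rad[sel].mean()
            s_vert[b] = sigma_vert[sel].mean()
    return StressProfile(
        bin_centers=centers, radial_stress=s_rad, vertical_stress=s_vert, counts=counts
    )
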