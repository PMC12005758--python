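"""Synthetic inputs with the stochastic structure the pipeline assumes.

Generates (a) spheroid populations randomly placed in a cylindrical well
with a unimodal (lognormal) radius distribution, (b) per-spheroid
nanoparticle counts obtained by area-weighted allocation of the total
added nanoparticle number with normal sampling (standard deviation equal
to half of the mean), (c) superparamagnetic (Langevin-shaped) hysteresis
curves with flat controls, and (d) oriented-stripe grayscale images for
the fiber-directionality analysis.

Every generator is bit-reproducible under a fixed seed.

Default population: 1200 microtissues of mean radius 100 um (CV 0.1),
from ~300,000 cells per well at ~250 cells per microtissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fequant import HysteresisCurve
from .params import NanoparticleSpec, SimulationParameters, WellGeometry

__all__ = [
    "SpheroidPopulation",
    "sample_population",
    "total_np_count",
    "allocate_nanoparticles",
    "synth_hysteresis",
    "synth_fiber_image",
    "DEFAULT_N",
    "DEFAULT_RADIUS_MEAN",
    "DEFAULT_RADIUS_CV",
]

DEFAULT_N = 1200
DEFAULT_RADIUS_MEAN = 100e-6
DEFAULT_RADIUS_CV = 0.1


@dataclass
class SpheroidPopulation:
    """Positions [m], radii [m], velocities [m s^-1] and nanoparticle
    counts of the spheroids in the well (the evolving system state)."""

    positions: np.ndarray
    radii: np.ndarray
    np_counts: np.ndarray = None
    velocities: np.ndarray = None

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float)).reshape(-1, 3)
        self.radii = np.asarray(self.radii, dtype=float).reshape(-1)
        if self.positions.shape[0] != self.radii.shape[0]:
            raise ValueError("positions and radii disagree in length")
        if np.any(self.radii <= 0):
            raise ValueError("all radii must be > 0")
        if self.np_counts is None:
            self.np_counts = np.zeros(self.n)
        self.np_counts = np.asarray(self.np_counts, dtype=float).reshape(-1)
        if np.any(self.np_counts < 0):
            raise ValueError("np_counts must be >= 0")
        if self.velocities is None:
            self.velocities = np.zeros_like(self.positions)
        self.velocities = np.asarray(self.velocities, dtype=float).reshape(-1, 3)

    @property
    def n(self) -> int:
        return self.radii.shape[0]

    def copy(self) -> "SpheroidPopulation":
        return SpheroidPopulation(
            self.positions.copy(),
            self.radii.copy(),
            self.np_counts.copy(),
            self.velocities.copy(),
        )


#: alias used when the population is viewed as the evolving dynamic state
SpheroidState = SpheroidPopulation


def sample_population(
    n: int,
    radius_mean: float = DEFAULT_RADIUS_MEAN,
    radius_cv: float = DEFAULT_RADIUS_CV,
    well: WellGeometry | None = None,
    seed: int = 0,
    overlap_tol: float = 0.0,
    max_tries: int = 200,
) -> SpheroidPopulation:
    """Random spheroid population inside the cylindrical well.

    Radii are lognormal with the requested arithmetic mean and coefficient
    of variation; positions are uniform in the well with rejection of
    pairwise overlaps exceeding ``overlap_tol`` (in meters of overlap
    depth).  Spheroids are fully contained in the well at init.

    Raises ``RuntimeError`` when the requested packing is infeasible
    (solid volume fraction > 0.5) or rejection fails after bounded tries.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if radius_mean <= 0:
        raise ValueError("radius_mean must be > 0")
    if not 0 <= radius_cv < 1:
        raise ValueError("radius_cv must be in [0, 1)")
    well = well or WellGeometry()
    rng = np.random.default_rng(seed)

    if n == 0:
        return SpheroidPopulation(np.zeros((0, 3)), np.zeros(0))

    if radius_cv == 0:
        radii = np.full(n, radius_mean)
    else:
        sigma2 = np.log1p(radius_cv**2)
        mu = np.log(radius_mean) - sigma2 / 2.0
        radii = rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)

    vol_frac = np.sum(4.0 / 3.0 * np.pi * radii**3) / (
        np.pi * well.radius**2 * well.height
    )
    if vol_frac > 0.5:
        raise RuntimeError(
            f"packing infeasible: requested solid fraction {vol_frac:.2f} > 0.5"
        )

    # place largest first to ease the rejection sampling
    order = np.argsort(radii)[::-1]
    radii_sorted = radii[order]
    pos = np.empty((n, 3))
    placed = 0
    for i in range(n):
        r = radii_sorted[i]
        ok = False
        for _ in range(max_tries):
            rho = (well.radius - r) * np.sqrt(rng.random())
            theta = 2.0 * np.pi * rng.random()
            zlo = well.floor_z + r
            zhi = well.floor_z + well.height - r
            if zhi <= zlo:
                raise RuntimeError("well too shallow for the sampled radii")
            cand = np.array(
                [rho * np.cos(theta), rho * np.sin(theta), rng.uniform(zlo, zhi)]
            )
            if placed == 0:
                ok = True
                break
            d = np.linalg.norm(pos[:placed] - cand, axis=1)
            overlap = (radii_sorted[:placed] + r) - d
            if np.max(overlap) <= overlap_tol:
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"could not place spheroid {i} without overlap after {max_tries} tries"
            )
        pos[placed] = cand
        placed += 1

    # undo the size ordering so the draw is exchangeable with the radii draw
    inv = np.empty(n, dtype=int)
    inv[order] = np.arange(n)
    return SpheroidPopulation(pos[inv], radii_sorted[inv])


def total_np_count(params: SimulationParameters, np_spec: NanoparticleSpec) -> float:
    """Total number of added nanoparticles N_NPtot = m_NPtot / (V_NP rho_NP).

    Real-valued; rounding is deferred to the per-spheroid allocation.
    """
    if params.m_NPtot <= 0:
        raise ValueError("m_NPtot must be > 0")
    return params.m_NPtot / (np_spec.V_NP * np_spec.rho_NP)


def allocate_nanoparticles(
    pop: SpheroidPopulation,
    params: SimulationParameters,
    np_spec: NanoparticleSpec,
    seed: int = 0,
) -> SpheroidPopulation:
    """Assign per-spheroid nanoparticle counts by surface-area weighting.

    Mean count mu_i = alpha * N_NPtot * A_i / A_tot with A_i = 4 pi r_i^2;
    the realized count is Normal(mu_i, mu_i/2) truncated at zero and
    rounded to an integer.  Returns a new population; the input is not
    modified.
    """
    if pop.n == 0:
        raise ValueError("population is empty")
    if not 0.0 <= params.alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    rng = np.random.default_rng(seed)
    areas = 4.0 * np.pi * pop.radii**2
    mu = params.alpha * total_np_count(params, np_spec) * areas / areas.sum()
    counts = rng.normal(loc=mu, scale=mu / 2.0)
    counts = np.round(np.maximum(counts, 0.0))
    out = pop.copy()
    out.np_counts = counts
    return out


def _langevin(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-6
    safe = np.where(small, 1.0, x)
    out = 1.0 / np.tanh(safe) - 1.0 / safe
    return np.where(small, x / 3.0, out)


def synth_hysteresis(
    fe_mass: float,
    reference_Msat: float = 60.0,
    field_grid: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    H_scale: float = 0.05,
    sample_mass: float = 1e-3,
    label: str = "",
) -> HysteresisCurve:
    """Langevin-shaped superparamagnetic hysteresis curve.

    moment [emu] = fe_mass [g] * reference_Msat [emu/g] * L(field/H_scale)
    plus Gaussian noise of ``noise_sd`` emu.  ``fe_mass = 0`` gives the
    flat (noise-only) control signature; the noiseless curve is exactly
    odd in the field.  ``H_scale`` (default 0.05 T) is a fixture shape
    parameter, not a measured quantity.
    """
    if fe_mass < 0:
        raise ValueError("fe_mass must be >= 0")
    if field_grid is None:
        field_grid = np.linspace(-7.0, 7.0, 201)
    field_grid = np.asarray(field_grid, dtype=float)
    if field_grid.size == 0:
        raise ValueError("field grid is empty")
    rng = np.random.default_rng(seed)
    moment = fe_mass * reference_Msat * _langevin(field_grid / H_scale)
    if noise_sd > 0:
        moment = moment + rng.normal(0.0, noise_sd, size=field_grid.shape)
    return HysteresisCurve(
        field=field_grid, moment=moment, sample_mass=sample_mass, label=label
    )


def synth_fiber_image(
    size: int = 256,
    angle: float = 45.0,
    wavelength: float = 12.0,
    contrast: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Grayscale stripe texture oriented at ``angle`` degrees.

    The fiber (stripe) direction is measured counterclockwise from the +x
    (column) axis with y pointing up (i.e. against the row index), in
    [0, 180).  Intensity is a sinusoid across the stripes plus Gaussian
    noise; ``contrast = 0`` gives a pure-noise isotropic image.
    """
    if not 0 <= angle < 180:
        raise ValueError("angle must be in [0, 180)")
    if size < 8:
        raise ValueError("size must be >= 8")
    rng = np.random.default_rng(seed)
    rows, cols = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    x = cols.astype(float)
    y = -rows.astype(float)  # y up
    th = np.deg2rad(angle)
    s = -x * np.sin(th) + y * np.cos(th)  # coordinate across the stripes
    img = 0.5 + 0.5 * contrast * np.sin(2.0 * np.pi * s / wavelength)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return img
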