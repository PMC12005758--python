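"""Model parameters, physical specifications and configuration I/O.

All quantities are SI internally.  CGS magnetic units (emu, emu g^-1) and
tesla appear only at I/O boundaries and are converted on the way in:
1 emu = 1e-3 A m^2, 1 emu g^-1 = 1 A m^2 kg^-1, B[T] = mu0 * H[A m^-1]
in the non-magnetic medium (relative permeability of water = 1).

The default parameter set reproduces the published model-parameter table of
the magnetic bioassembly model exactly (timestep 5e-5 s, medium viscosity
1.2e-3 Pa s, spheroid density 1014 kg m^-3, well stiffness 1000 Pa, spheroid
modulus 120 Pa, contact damping 0.6 Pa s m^-1, simulation time 60 s, output
interval 1 s, implicitness 0, nanoparticle absorption factor 0.75, total
added nanoparticle mass 10 ug for the "30 ug Fe mL^-1" incubation condition
and 20 ug for the "60 ug" condition).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "SimulationParameters",
    "NanoparticleSpec",
    "MagnetSpec",
    "WellGeometry",
    "ConfigBundle",
    "ConfigError",
    "ValidationError",
    "load_config",
    "dump_config",
    "MNP_MASS_BY_CONDITION",
]

#: Total MNP mass added (kg) keyed by the incubation-concentration label
#: used to name the two loading conditions (ug Fe per mL of medium).
MNP_MASS_BY_CONDITION = {"30": 10e-9, "60": 20e-9}


class ConfigError(ValueError):
    """Malformed configuration file."""


class ValidationError(ValueError):
    """A parameter violates its physical invariant."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass
class SimulationParameters:
    """Scalar model parameters (Table-style defaults, SI units)."""

    dt: float = 5e-5                 # timestep [s]
    mu0: float = 1.256e-6            # vacuum permeability [N A^-2]
    mu_r: float = 1.0                # relative permeability of water [-]
    g: float = 9.807                 # gravitational acceleration [m s^-2]
    eta_m: float = 1.2e-3            # medium viscosity [Pa s]
    rho_m: float = 1000.0            # medium density [kg m^-3]
    rho_s: float = 1014.0            # spheroid density [kg m^-3]
    E_well: float = 1000.0           # well stiffness [Pa]
    sigma_adh: float = 1e-20         # spheroid-well adhesion energy density [N m^-1]
    c_t: float = 0.6                 # tangential contact damping [Pa s m^-1]
    c_n: float = 0.6                 # normal contact damping [Pa s m^-1]
    E_spheroid: float = 120.0        # spheroid elastic modulus [Pa]
    t_end: float = 60.0              # simulation time [s]
    m_NPtot: float = 10e-9           # total MNP mass added [kg] (10 ug)
    I_out: float = 1.0               # output interval [s]
    lam: float = 0.0                 # degree of implicitness [-], in [0, 1]
    alpha: float = 0.75              # MNP absorption factor [-], in [0, 1]
    D: float = 0.0                   # thermal diffusivity [m^2 s^-1]
    seed: int = 0                    # RNG seed

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        _require(self.dt > 0, f"dt must be > 0, got {self.dt}")
        _require(self.eta_m > 0, f"eta_m must be > 0, got {self.eta_m}")
        _require(self.rho_m > 0, f"rho_m must be > 0, got {self.rho_m}")
        _require(self.rho_s > 0, f"rho_s must be > 0, got {self.rho_s}")
        _require(self.mu0 > 0, f"mu0 must be > 0, got {self.mu0}")
        _require(self.E_well > 0, f"E_well must be > 0, got {self.E_well}")
        _require(self.E_spheroid > 0, f"E_spheroid must be > 0, got {self.E_spheroid}")
        _require(self.c_t >= 0, f"c_t must be >= 0, got {self.c_t}")
        _require(self.c_n >= 0, f"c_n must be >= 0, got {self.c_n}")
        _require(0.0 <= self.alpha <= 1.0, f"alpha must be in [0, 1], got {self.alpha}")
        _require(0.0 <= self.lam <= 1.0, f"lam must be in [0, 1], got {self.lam}")
        _require(self.t_end >= 0, f"t_end must be >= 0, got {self.t_end}")
        _require(self.m_NPtot > 0, f"m_NPtot must be > 0, got {self.m_NPtot}")
        _require(self.I_out >= self.dt, f"I_out must be >= dt, got {self.I_out} < {self.dt}")
        _require(self.D >= 0, f"D must be >= 0, got {self.D}")


@dataclass
class NanoparticleSpec:
    """Superparamagnetic Fe3O4 nanoparticle specification.

    ``M_sat_mass`` is the mass saturation magnetization in emu g^-1
    (60 emu g^-1 for the citrate-coated ~6 nm magnetite particles); the
    volumetric magnetization used by the force law is
    ``M_NP = M_sat_mass * rho_NP`` in A m^-1 (1 emu g^-1 == 1 A m^2 kg^-1).
    """

    r_NP: float = 3e-9               # nanoparticle radius [m] (6 nm diameter)
    M_sat_mass: float = 60.0         # saturation magnetization [emu g^-1]
    rho_NP: float = 5180.0           # magnetite density [kg m^-3]

    def __post_init__(self) -> None:
        _require(self.r_NP > 0, f"r_NP must be > 0, got {self.r_NP}")
        _require(self.M_sat_mass > 0, f"M_sat_mass must be > 0, got {self.M_sat_mass}")
        _require(self.rho_NP > 0, f"rho_NP must be > 0, got {self.rho_NP}")

    @property
    def V_NP(self) -> float:
        """Nanoparticle volume [m^3]."""
        return 4.0 / 3.0 * math.pi * self.r_NP**3

    @property
    def M_NP(self) -> float:
        """Volumetric saturation magnetization [A m^-1]."""
        return self.M_sat_mass * self.rho_NP


@dataclass
class MagnetSpec:
    """Cylindrical NdFeB permanent magnet, axially magnetized along +z.

    ``top_face_center`` places the center of the top (pole) face in the
    well coordinate frame (origin at the well-floor center); it sits below
    the floor by the plate-gap distance.
    """

    diameter: float = 5e-3           # [m]
    height: float = 5e-3             # [m]
    Br: float = 1.48                 # remanence [T] (14800 Gauss)
    top_face_center: np.ndarray = field(
        default_factory=lambda: np.zeros(3)
    )
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        _require(self.diameter > 0, f"diameter must be > 0, got {self.diameter}")
        _require(self.height > 0, f"height must be > 0, got {self.height}")
        _require(self.Br > 0, f"Br must be > 0, got {self.Br}")
        self.top_face_center = np.asarray(self.top_face_center, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        nrm = float(np.linalg.norm(self.axis))
        _require(nrm > 0, "axis must be a nonzero vector")
        self.axis = self.axis / nrm

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def volume(self) -> float:
        return math.pi * self.radius**2 * self.height


@dataclass
class WellGeometry:
    """Analytic cylindrical well, coaxial with the magnet by default.

    The interior is {rho < radius, floor_z <= z <= floor_z + height}.
    The fill ``height`` bounds initial spheroid placement; there is no
    ceiling contact.
    """

    radius: float = 8e-3             # [m] (24-well plate)
    height: float = 3e-3             # [m] media fill height
    floor_z: float = 0.0             # [m]

    def __post_init__(self) -> None:
        _require(self.radius > 0, f"radius must be > 0, got {self.radius}")
        _require(self.height > 0, f"height must be > 0, got {self.height}")


@dataclass
class ConfigBundle:
    params: SimulationParameters
    np_spec: NanoparticleSpec
    magnet: MagnetSpec
    well: WellGeometry

    def __iter__(self):
        return iter((self.params, self.np_spec, self.magnet, self.well))


_SECTIONS = {
    "simulation": SimulationParameters,
    "nanoparticle": NanoparticleSpec,
    "magnet": MagnetSpec,
    "well": WellGeometry,
}
_ARRAY_FIELDS = {"top_face_center", "axis"}


def load_config(path: str | Path) -> ConfigBundle:
    """Read a YAML key-value configuration.

    Missing keys take their documented defaults; present keys override.
    Sections are ``simulation``, ``nanoparticle``, ``magnet``, ``well``.

    Raises
    ------
    ConfigError
        If the file does not parse as a mapping of mappings.
    ValidationError
        If any resulting field violates its invariant (the message names
        the offending field).
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse configuration {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"configuration root must be a mapping, got {type(raw).__name__}")

    built = {}
    for section, cls in _SECTIONS.items():
        entries = raw.get(section, {})
        if entries is None:
            entries = {}
        if not isinstance(entries, dict):
            raise ConfigError(f"section '{section}' must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(entries) - known
        if unknown:
            raise ConfigError(
                f"unknown key(s) in section '{section}': {sorted(unknown)}"
            )
        kwargs = {
            k: (np.asarray(v, dtype=float) if k in _ARRAY_FIELDS else v)
            for k, v in entries.items()
        }
        built[section] = cls(**kwargs)
    return ConfigBundle(
        params=built["simulation"],
        np_spec=built["nanoparticle"],
        magnet=built["magnet"],
        well=built["well"],
    )


def dump_config(bundle: ConfigBundle, path: str | Path) -> None:
    """Serialize a configuration bundle back to YAML (round-trip safe)."""
    out = {}
    for section, obj in zip(
        _SECTIONS, (bundle.params, bundle.np_spec, bundle.magnet, bundle.well)
    ):
        d = dataclasses.asdict(obj)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = [float(x) for x in v]
        out[section] = d
    Path(path).write_text(yaml.safe_dump(out, sort_keys=False))
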