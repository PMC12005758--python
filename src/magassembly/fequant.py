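"""Fe3O4 mass accounting from SQUID hysteresis curves.

A sample's superparamagnetic moment is read off at the saturation field
(+-7 T sweep limit), background-corrected by subtracting the matched
control tissue, and converted to micrograms of Fe3O4 with the specific
saturation magnetization of a reference nanoparticle powder of known dry
mass (emu per gram).  Percent reduction between two timepoints is plain
mass arithmetic reported as an integer percentage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "HysteresisCurve",
    "saturation_moment",
    "fe_content",
    "percent_reduction",
    "read_curve",
]


@dataclass
class HysteresisCurve:
    """(applied field [T], magnetic moment [emu]) pairs for one dried sample."""

    field: np.ndarray
    moment: np.ndarray
    sample_mass: float = 1.0     # dry mass [g]
    label: str = ""

    def __post_init__(self) -> None:
        self.field = np.asarray(self.field, dtype=float)
        self.moment = np.asarray(self.moment, dtype=float)
        if self.field.shape != self.moment.shape or self.field.size < 3:
            raise ValueError("field and moment must be equal-length with >= 3 points")
        if self.field.min() >= 0 or self.field.max() <= 0:
            raise ValueError("field grid must span negative and positive values")
        if self.sample_mass <= 0:
            raise ValueError("sample_mass must be > 0")

    def interp_moment(self, at_field: np.ndarray) -> np.ndarray:
        order = np.argsort(self.field)
        return np.interp(at_field, self.field[order], self.moment[order])


def read_curve(path, sample_mass: float = 1.0, label: str = "") -> HysteresisCurve:
    """Load a two-column CSV (field_T, moment_emu)."""
    df = pd.read_csv(path)
    cols = list(df.columns)
    if not {"field_T", "moment_emu"} <= set(cols):
        raise ValueError(f"expected columns field_T, moment_emu, got {cols}")
    return HysteresisCurve(
        field=df["field_T"].to_numpy(),
        moment=df["moment_emu"].to_numpy(),
        sample_mass=sample_mass,
        label=label,
    )


def saturation_moment(curve: HysteresisCurve, at_field: float = 7.0) -> float:
    """Moment magnitude [emu] at saturation.

    Mean of |m| linearly interpolated at +at_field and -at_field, so the
    result is insensitive to the branch sign convention of the sweep.
    """
    at = abs(at_field)
    if at > curve.field.max() or -at < curve.field.min():
        raise ValueError(
            f"saturation field {at} T outside measured range "
            f"[{curve.field.min()}, {curve.field.max()}] T"
        )
    mp, mm = curve.interp_moment(np.array([at, -at]))
    return 0.5 * (abs(mp) + abs(mm))


def fe_content(
    sample: HysteresisCurve,
    control: HysteresisCurve,
    reference_Msat: float = 60.0,
    at_field: float = 7.0,
) -> float:
    """Fe3O4 mass in the sample [ug].

    mass = (m_sat(sample) - m_sat(control)) / reference_Msat, with the
    reference specific moment in emu g^-1 from the calibration powder.
    If the curves are on different field grids the control is interpolated
    onto the sample grid before subtraction.  Negative results (control
    moment exceeding the sample's) are clipped to 0 with a warning.
    """
    if reference_Msat <= 0:
        raise ValueError("reference_Msat must be > 0")
    if sample.field.shape == control.field.shape and np.allclose(
        sample.field, control.field
    ):
        ctrl = control
    else:
        ctrl = HysteresisCurve(
            field=sample.field.copy(),
            moment=control.interp_moment(sample.field),
            sample_mass=control.sample_mass,
            label=control.label,
        )
    # subtract curves first so any shared baseline cancels exactly, then
    # read the signed (odd-component) saturation so a control exceeding
    # the sample is detected as a negative corrected moment
    corrected = HysteresisCurve(
        field=sample.field.copy(),
        moment=sample.moment - ctrl.moment,
        sample_mass=sample.sample_mass,
        label=sample.label,
    )
    at = abs(at_field)
    if at > corrected.field.max() or -at < corrected.field.min():
        raise ValueError(f"saturation field {at} T outside measured range")
    mp, mm = corrected.interp_moment(np.array([at, -at]))
    signed_sat = 0.5 * (mp - mm)
    mass_g = signed_sat / reference_Msat
    mass_ug = mass_g * 1e6
    if mass_ug < 0:
        warnings.warn("negative corrected moment; clipping Fe3O4 mass to 0")
        mass_ug = 0.0
    return mass_ug


def percent_reduction(mass_before: float, mass_after: float) -> int:
    """Integer percent reduction 100 * (1 - after/before)."""
    if mass_before <= 0:
        raise ValueError("mass_before must be > 0")
    if mass_after < 0:
        raise ValueError("mass_after must be >= 0")
    return int(round(100.0 * (1.0 - mass_after / mass_before)))
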