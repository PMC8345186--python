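"""Dose arithmetic between compound mass and compartment concentration.

The screening design uses three fixed compartments: the microinjection
bolus (4 nL), the whole embryo at 3 days post-fertilization (270 nL),
and a single bath well of E3 medium (200 µL).  External units follow the
reporting convention — nanograms for mass, micromolar for concentration —
with SI (grams, moles, liters) internally.  Molar mass is always a caller
input (selinexor, 443.31 g/mol, is the worked example throughout).

All conversions are exact closed forms:

    concentration [µM] = (mass [ng] x 1e-9 / M [g/mol]) / V [L] x 1e6
"""
from __future__ import annotations

from dataclasses import dataclass

#: Fixed compartment volumes, liters.
COMPARTMENT_VOLUMES_L: dict[str, float] = {
    "injection-bolus": 4e-9,  # 4 nL microinjection bolus
    "embryo": 270e-9,  # total embryo volume at 3 dpf
    "bath-well": 200e-6,  # one well of E3 medium
}

#: Molar mass of selinexor (KPT-330), g/mol — the example compound.
SELINEXOR_MOLAR_MASS = 443.31


def volume_liters(volume: float | str) -> float:
    """Resolve a compartment name or a volume in liters to liters."""
    if isinstance(volume, str):
        try:
            return COMPARTMENT_VOLUMES_L[volume]
        except KeyError:
            raise ValueError(
                f"unknown compartment {volume!r}; known: "
                f"{sorted(COMPARTMENT_VOLUMES_L)}"
            ) from None
    v = float(volume)
    if v <= 0:
        raise ValueError("volume must be positive")
    return v


def mass_to_concentration(
    mass_ng: float, molar_mass: float, volume: float | str
) -> float:
    """Concentration (µM) of ``mass_ng`` of compound in a compartment.

    ``volume`` is a compartment name ('injection-bolus', 'embryo',
    'bath-well') or a volume in liters.
    """
    if mass_ng <= 0 or molar_mass <= 0:
        raise ValueError("mass and molar mass must be positive")
    v = volume_liters(volume)
    moles = mass_ng * 1e-9 / molar_mass
    return moles / v * 1e6


def concentration_to_mass(
    conc_um: float, molar_mass: float, volume: float | str
) -> float:
    """Mass (ng) of compound at ``conc_um`` µM in a compartment; exact
    inverse of :func:`mass_to_concentration`."""
    if conc_um <= 0 or molar_mass <= 0:
        raise ValueError("concentration and molar mass must be positive")
    v = volume_liters(volume)
    moles = conc_um * 1e-6 * v
    return moles * molar_mass * 1e9


def injection_solution_concentration(
    mass_ng: float, molar_mass: float, bolus: float | str = "injection-bolus"
) -> float:
    """Concentration (µM) the injection solution must have so that one
    bolus (default 4 nL) delivers ``mass_ng`` of compound."""
    return mass_to_concentration(mass_ng, molar_mass, bolus)


@dataclass
class DoseSpec:
    """A dose tied to a compartment: give mass or concentration, get both.

    Exactly one of ``mass_ng`` / ``conc_um`` must be provided; the other
    is derived on construction.  ``compartment`` is a name from
    :data:`COMPARTMENT_VOLUMES_L` or a custom volume in liters.
    """

    molar_mass: float
    compartment: float | str = "embryo"
    mass_ng: float | None = None
    conc_um: float | None = None

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ValueError("molar mass must be positive")
        given = (self.mass_ng is not None) + (self.conc_um is not None)
        if given != 1:
            raise ValueError("provide exactly one of mass_ng or conc_um")
        self.volume_l = volume_liters(self.compartment)
        if self.mass_ng is not None:
            self.conc_um = mass_to_concentration(
                self.mass_ng, self.molar_mass, self.volume_l
            )
        else:
            assert self.conc_um is not None
            self.mass_ng = concentration_to_mass(
                self.conc_um, self.molar_mass, self.volume_l
            )
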