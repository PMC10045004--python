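"""Specific energy consumption and energy efficiency of a drying run.

With ``E`` the total electric energy in kWh, ``M_s`` the dry-solid mass
in kg, and ``X_i > X_f`` the initial and final dry-basis moisture
contents, the two customary metrics are

    SECe = 3600 E / (M_s (X_i - X_f))
    EE   = M_s (X_i - X_f) dh_v / (3600 E) * 100        [%]

with ``dh_v`` the evaporation enthalpy of water (2257 kJ/kg at 100 degC
by default).  ``3600 E`` with E in kWh is dimensionally kJ, so SECe
comes out in kJ per kg of evaporated water when dh_v is in kJ/kg; the
two metrics then satisfy the exact identity ``SECe * EE / 100 = dh_v``.
(The literature sometimes labels SECe "MJ/kg"; values here are returned
unscaled on the kJ-consistent basis that makes the identity hold.)
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "DELTA_HV_WATER",
    "EnergyInput",
    "EnergyResult",
    "specific_energy",
    "energy_efficiency",
    "energy_metrics",
]

#: Evaporation enthalpy of water at 100 degC, kJ/kg.
DELTA_HV_WATER = 2257.0


@dataclass(frozen=True)
class EnergyInput:
    """Inputs of the energy metrics; validated on construction."""

    energy_kwh: float
    dry_solid_kg: float
    x_initial: float
    x_final: float
    delta_hv: float = DELTA_HV_WATER

    def __post_init__(self):
        if self.energy_kwh < 0:
            raise ValueError("energy_kwh must be >= 0")
        if self.dry_solid_kg <= 0:
            raise ValueError("dry_solid_kg must be > 0")
        if not self.x_initial > self.x_final >= 0:
            raise ValueError("need x_initial > x_final >= 0")
        if self.delta_hv <= 0:
            raise ValueError("delta_hv must be > 0")

    @property
    def water_removed_kg(self) -> float:
        return self.dry_solid_kg * (self.x_initial - self.x_final)


@dataclass(frozen=True)
class EnergyResult:
    """SECe and EE with their algebraic consistency product."""

    sece: float
    ee_percent: float
    delta_hv: float

    @property
    def identity_product(self) -> float:
        """``SECe * EE / 100``; equals ``delta_hv`` exactly."""
        return self.sece * self.ee_percent / 100.0


def specific_energy(inp: EnergyInput) -> float:
    """``SECe = 3600 E / (M_s (X_i - X_f))``, energy per kg of water.

    Units: 3600 x kWh per kg water, i.e. kJ/kg water when delta_hv is
    taken in kJ/kg.
    """
    if inp.water_removed_kg == 0:
        raise ValueError("no water removed (X_i == X_f)")
    return 3600.0 * inp.energy_kwh / inp.water_removed_kg


def energy_efficiency(inp: EnergyInput) -> float:
    """``EE = M_s (X_i - X_f) dh_v / (3600 E) * 100`` in percent."""
    if inp.energy_kwh == 0:
        raise ValueError("zero energy input")
    return inp.water_removed_kg * inp.delta_hv / (3600.0 * inp.energy_kwh) * 100.0


def energy_metrics(inp: EnergyInput) -> EnergyResult:
    """Both metrics at once."""
    return EnergyResult(
        sece=specific_energy(inp),
        ee_percent=energy_efficiency(inp),
        delta_hv=inp.delta_hv,
    )
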