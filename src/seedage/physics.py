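"""Storage physics of high-pressure seed aging.

Dry seeds are aged inside steel tanks pressurised to 20 MPa with air
(elevated partial pressure of oxygen, EPPO) or nitrogen (EPPN).  Two small
pieces of physics define those storage environments: Dalton's law for the
oxygen partial pressure, and the Poynting effect — the increase of the
effective water activity (a_w) of a condensed phase under applied total
pressure — which raises the equilibrium relative humidity (ERH) experienced
by the seeds during pressurised storage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: Molar volume of liquid water, m^3/mol (~20-35 °C; weak T-dependence ignored).
WATER_MOLAR_VOLUME = 1.8066e-5
#: Universal gas constant, J/(mol K).
GAS_CONSTANT = 8.314
#: Ambient reference pressure, MPa.
AMBIENT_PRESSURE_MPA = 0.1
#: Mole fraction of O2 in dry air.
AIR_O2_MOLE_FRACTION = 0.21


def celsius_to_kelvin(temp_c: float) -> float:
    """Convert °C to kelvin."""
    return temp_c + 273.15


@dataclass(frozen=True)
class StorageCondition:
    """A seed-storage environment.

    Parameters
    ----------
    name
        Treatment label (e.g. ``"EPPO"``, ``"EPPN"``, ``"ambient"``).
    temperature_k
        Storage temperature in kelvin.
    total_pressure_mpa
        Total gas pressure in MPa.
    o2_mole_fraction
        Mole fraction of oxygen in the storage gas, in [0, 1].
    erh_percent
        Equilibrium relative humidity around the seeds, in [0, 100].
    """

    name: str
    temperature_k: float
    total_pressure_mpa: float
    o2_mole_fraction: float
    erh_percent: float

    def __post_init__(self) -> None:
        if self.total_pressure_mpa <= 0:
            raise ValueError("total pressure must be positive")
        if not 0.0 <= self.o2_mole_fraction <= 1.0:
            raise ValueError("O2 mole fraction must lie in [0, 1]")
        if not 0.0 <= self.erh_percent <= 100.0:
            raise ValueError("ERH must lie in [0, 100]%")
        if self.temperature_k <= 0:
            raise ValueError("temperature must be positive (kelvin)")

    @property
    def p_o2_mpa(self) -> float:
        """Oxygen partial pressure in MPa."""
        return partial_pressure(self.total_pressure_mpa, self.o2_mole_fraction)


def partial_pressure(total_pressure_mpa: float, mole_fraction: float) -> float:
    """Partial pressure of a gas component (Dalton's law).

    A 20 MPa air-filled tank carries an oxygen partial pressure of
    ``20 × 0.21 = 4.2`` MPa; at ambient pressure (0.1 MPa) the same fraction
    gives 0.021 MPa.
    """
    if total_pressure_mpa < 0:
        raise ValueError("total pressure must be non-negative")
    if not 0.0 <= mole_fraction <= 1.0:
        raise ValueError("mole fraction must lie in [0, 1]")
    return total_pressure_mpa * mole_fraction


def oxygen_enrichment(p_o2_treatment_mpa: float, p_o2_reference_mpa: float) -> float:
    """Ratio of treatment to reference oxygen partial pressure.

    EPPO at 4.2 MPa O2 versus the ambient 0.021 MPa gives a 200-fold
    oxygen enrichment.
    """
    if p_o2_reference_mpa <= 0:
        raise ValueError("reference partial pressure must be positive")
    return p_o2_treatment_mpa / p_o2_reference_mpa


def pressure_adjusted_aw(
    aw: float, pressure_mpa: float, temperature_k: float
) -> float:
    """Water activity under applied total pressure (Poynting correction).

    The effective water activity of a condensed phase rises with applied
    pressure as ``a_w · exp(V_w (P − P0) / (R T))`` with ``V_w`` the molar
    volume of liquid water and ``P0 = 0.1`` MPa the ambient reference state.
    At 20 MPa and 20 °C this lifts seeds equilibrated at a_w 0.40 to about
    0.46; the same correction applied to the 43.5% RH measured at 35 °C
    puts the ERH during pressurised storage at about 50%.

    The result is capped at 1 (saturation).
    """
    if not 0.0 < aw <= 1.0:
        raise ValueError("water activity must lie in (0, 1]")
    if pressure_mpa < AMBIENT_PRESSURE_MPA:
        raise ValueError("pressure below the ambient reference state (0.1 MPa)")
    if temperature_k <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    factor = math.exp(
        WATER_MOLAR_VOLUME
        * (pressure_mpa - AMBIENT_PRESSURE_MPA)
        * 1e6
        / (GAS_CONSTANT * temperature_k)
    )
    return min(aw * factor, 1.0)


def erh_from_aw(aw: float) -> float:
    """Equilibrium relative humidity (%) from water activity: ``a_w × 100``."""
    if not 0.0 <= aw <= 1.0:
        raise ValueError("water activity must lie in [0, 1]")
    return aw * 100.0
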