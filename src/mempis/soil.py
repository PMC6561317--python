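"""Soil-physics helpers: water-filled pore space and CO2 flux.

Small closed-form utilities used when preparing microcosm metadata:

* WFPS — the fraction of soil pore volume occupied by water, from the
  gravimetric water content (g water per g dry soil), bulk density Db and
  particle density Dp:  WFPS = gwc * Db / (1 - Db/Dp).
* CO2 flux from headspace concentration change via the ideal gas law:
  F = dC/dT * (V/M) * (P / (R*T)), reported in umol per g dry soil per
  second.
"""

from __future__ import annotations

__all__ = ["GAS_CONSTANT_CM3_KPA", "porosity", "wfps", "co2_flux"]

#: Universal gas constant in cm^3 kPa mol^-1 K^-1.
GAS_CONSTANT_CM3_KPA = 8.3e3

#: Typical bulk and (assumed) particle densities for a prairie mineral soil.
DEFAULT_BULK_DENSITY = 1.1  # g cm^-3
DEFAULT_PARTICLE_DENSITY = 2.65  # g cm^-3


def porosity(
    bulk_density: float = DEFAULT_BULK_DENSITY,
    particle_density: float = DEFAULT_PARTICLE_DENSITY,
) -> float:
    """Total soil porosity 1 - Db/Dp; requires 0 < Db < Dp."""
    if not 0 < bulk_density < particle_density:
        raise ValueError(
            f"need 0 < bulk density ({bulk_density}) < particle density "
            f"({particle_density})"
        )
    return 1.0 - bulk_density / particle_density


def wfps(
    gravimetric_water_content: float,
    bulk_density: float = DEFAULT_BULK_DENSITY,
    particle_density: float = DEFAULT_PARTICLE_DENSITY,
) -> float:
    """Water-filled pore space as a fraction (multiply by 100 for %WFPS)."""
    if gravimetric_water_content < 0:
        raise ValueError("gravimetric water content must be >= 0")
    return (
        gravimetric_water_content
        * bulk_density
        / porosity(bulk_density, particle_density)
    )


def co2_flux(
    dC_dT: float,
    volume_cm3: float,
    soil_mass_g: float,
    pressure_kPa: float = 101.325,
    temperature_K: float = 294.15,
    gas_constant: float = GAS_CONSTANT_CM3_KPA,
) -> float:
    """CO2 flux in umol g^-1 s^-1 from the headspace mole-fraction rate.

    dC_dT is the rate of change of the CO2 mole fraction (s^-1); V is the
    combined microcosm + chamber volume (cm^3); M the dry soil mass (g).
    """
    if volume_cm3 <= 0 or soil_mass_g <= 0 or temperature_K <= 0 or pressure_kPa <= 0:
        raise ValueError("V, M, T and P must all be positive")
    mol_per_g_s = dC_dT * (volume_cm3 / soil_mass_g) * (
        pressure_kPa / (gas_constant * temperature_K)
    )
    return mol_per_g_s * 1e6  # mol -> umol
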