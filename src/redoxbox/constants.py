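"""Physical constants and unit conversions shared across the model.

Internal units are mol and yr throughout; temperatures in K; gas partial
pressures in atm; seawater concentrations derived from fixed box volumes.
"""

TMOL = 1e12  # mol

# Earth geometry / atmosphere
EARTH_AREA = 5.10e14          # m^2
ATM_PRESSURE = 1.01325e5      # Pa, one atmosphere
GRAVITY = 9.81                # m s^-2

# Moles of a pure gas column exerting 1 atm partial pressure,
# N = P * A / (g * M).  Used to convert inventories <-> partial pressures.
MOL_PER_ATM_CO2 = ATM_PRESSURE * EARTH_AREA / (GRAVITY * 0.044)   # ~1.197e20
MOL_PER_ATM_O2 = ATM_PRESSURE * EARTH_AREA / (GRAVITY * 0.032)    # ~1.646e20
MOL_PER_ATM_CH4 = ATM_PRESSURE * EARTH_AREA / (GRAVITY * 0.016)   # ~3.293e20

# Ocean two-box geometry (surface 3% / deep 97% of the modern ocean volume)
OCEAN_VOLUME = 1.37e18        # m^3
SURF_FRACTION = 0.03
V_SURF = OCEAN_VOLUME * SURF_FRACTION        # m^3
V_DEEP = OCEAN_VOLUME * (1.0 - SURF_FRACTION)
L_SURF = V_SURF * 1e3         # litres
L_DEEP = V_DEEP * 1e3

# Modern reference atmosphere/ocean
PO2_STAR_ATM = 0.21           # atm, 1 PAL
PCO2_STAR_ATM = 2.8e-4        # atm, preindustrial reference
PCH4_STAR_ATM = 1.8e-6        # atm
SO4_STAR_MM = 28.0            # mM, modern seawater sulfate
CA_STAR_MM = 10.3             # mM, modern seawater calcium
T_STAR_K = 288.0              # K, modern global mean surface temperature
SOLAR_CONSTANT = 1361.0       # W m^-2

REDFIELD_C_P = 106.0          # molar C:P of marine organic matter


def po2_atm(o_as: float) -> float:
    """Partial pressure of O2 (atm) from the combined atmosphere-surface inventory.

    Dissolved O2 in the surface box is < 0.1% of the atmospheric inventory at
    all relevant states and is neglected in the partition.
    """
    return o_as / MOL_PER_ATM_O2


def po2_pal(o_as: float) -> float:
    return po2_atm(o_as) / PO2_STAR_ATM


def pch4_atm(m: float) -> float:
    return m / MOL_PER_ATM_CH4


def conc_mm(mol: float, litres: float) -> float:
    """Concentration in mmol/L (mM) of an inventory dissolved in `litres`."""
    return mol / litres * 1e3


def so4_surface_mm(s_s: float) -> float:
    return conc_mm(s_s, L_SURF)


def henry_co2(t_k: float) -> float:
    """Henry solubility of CO2 in seawater, mol L^-1 atm^-1, van 't Hoff form."""
    return 0.034 * pow(2.718281828459045, 2400.0 * (1.0 / t_k - 1.0 / 298.15))
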