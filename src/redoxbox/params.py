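"""Parameter containers: boundary conditions, rate-law constants, scenarios.

Every constant carries its units in the field comment.  Starred names (``*``)
are modern reference values to which the corresponding flux law normalises.
Validation is performed eagerly in ``__post_init__`` so that a mis-configured
scenario fails before any integration starts.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

from . import constants as cn


class ParameterError(ValueError):
    """A parameter violates its documented bounds."""


@dataclass
class SulfurParams:
    """Constants of the sulfur-cycle flux laws (degassing, weathering, burial)."""

    GYP_star: float = 150e18        # mol S, reference sedimentary gypsum
    PYR_star: float = 250e18        # mol S, reference sedimentary pyrite
    F_vgyp_star: float = 0.5e12     # mol S/yr, modern gypsum degassing
    F_vpyr_star: float = 0.3e12     # mol S/yr, modern pyrite degassing
    F_wgyp_star: float = 1.6e12     # mol S/yr, modern gypsum weathering
    F_wpyr_star: float = 1.3e12     # mol S/yr, modern pyrite weathering
    F_bgyp_star: float = 2.1e12     # mol S/yr = F_vgyp* + F_wgyp*
    # Modern pyrite burial closing the modern steady state, F_vpyr* + F_wpyr*.
    F_bpyr_star: float = 1.6e12     # mol S/yr
    k_pyrw: float = 0.017           # Monod half-saturation of oxidative weathering, pO2/pO2*
    c_pyrw: float = 1.017           # normalisation so F_wpyr = F_wpyr* at reference
    SO4_star_mM: float = cn.SO4_STAR_MM
    Ca_star_mM: float = cn.CA_STAR_MM
    pO2_floor_rel: float = 1e-10    # floor on pO2/pO2* in the pyrite-burial law

    def __post_init__(self) -> None:
        for name in ("GYP_star", "PYR_star", "F_vgyp_star", "F_vpyr_star",
                     "F_wgyp_star", "F_wpyr_star", "F_bgyp_star", "F_bpyr_star",
                     "k_pyrw", "c_pyrw", "SO4_star_mM", "Ca_star_mM"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"SulfurParams.{name} must be > 0")
        if abs(self.F_bgyp_star - (self.F_vgyp_star + self.F_wgyp_star)) > 1e-6 * self.F_bgyp_star:
            raise ParameterError(
                "F_bgyp_star must equal F_vgyp_star + F_wgyp_star (steady-state closure)")


@dataclass
class MSRParams:
    """Microbial sulfate reduction fractionation (Michaelis-Menten in [SO4])."""

    Delta_max: float = 40.0   # permil, saturation fractionation
    K_MSR: float = 0.2        # mM, sulfate half-saturation (= 200 uM)

    def __post_init__(self) -> None:
        if not (0.0 <= self.Delta_max <= 80.0):
            raise ParameterError("MSRParams.Delta_max must lie in [0, 80] permil")
        if self.K_MSR <= 0:
            raise ParameterError("MSRParams.K_MSR must be > 0")


@dataclass
class ClimateParams:
    """Zero-dimensional energy-balance parameterisation.

    OLR(T, pCO2, pCH4) = a + b (T - T*) - RF_CO2 - RF_CH4 with
    RF_CO2 = c1 ln(pCO2/pCO2*) + c2 ln^2(pCO2/pCO2*) and
    RF_CH4 = c_m ln(1 + pCH4/p_m0).  ``a`` closes the modern reference
    (288 K at preindustrial pCO2, modern CH4, full luminosity); ``b`` and
    ``c2`` are calibrated so a 0.7-atm CO2 atmosphere under 83% luminosity
    sits near 330 K (see ``climate.calibrate``).
    """

    albedo: float = 0.3
    solar_constant: float = cn.SOLAR_CONSTANT   # W m^-2
    T_ref: float = cn.T_STAR_K                  # K
    pco2_ref: float = cn.PCO2_STAR_ATM          # atm
    c1: float = 7.72          # W m^-2 per e-fold of CO2 (5.35/ln 2)
    c2: float = 0.304769      # W m^-2 per (e-fold)^2, high-CO2 enhancement
    b: float = 0.972927       # W m^-2 K^-1, OLR slope (5.5 K per CO2 doubling)
    c_m: float = 0.9          # W m^-2, CH4 forcing scale
    p_m0: float = 1e-6        # atm, CH4 forcing knee
    pch4_ref: float = cn.PCH4_STAR_ATM
    t_lo: float = 220.0       # K, root bracket
    t_hi: float = 420.0
    t_tol: float = 1e-6       # K

    @property
    def a(self) -> float:
        """Reference OLR closing the modern energy balance."""
        return (1.0 - self.albedo) * self.solar_constant / 4.0

    def __post_init__(self) -> None:
        if not (0.0 < self.albedo < 1.0):
            raise ParameterError("albedo must lie in (0, 1)")
        if self.b <= 0:
            raise ParameterError("OLR slope b must be > 0")


@dataclass
class CPOParams:
    """Constants of the reconstructed carbon-phosphorus-oxygen-methane core."""

    # Redox-dependent P burial
    k_anox: float = 200.0     # mol C/mol P buried under anoxia
    k_oxic: float = 60.0      # mol C/mol P buried under oxic conditions
    k1: float = 0.997527      # present-day oxic ocean fraction

    # Modern reference fluxes (mol/yr)
    F_pp_star: float = 400e12     # export production, C
    F_bo_star: float = 4.5e12     # marine organic C burial
    F_ws_star: float = 6.0e12     # silicate weathering (Ca-equivalent C units)
    F_wc_star: float = 12.0e12    # carbonate weathering
    F_voc_star: float = 1.25e12   # organic C degassing
    F_wo_star: float = 3.25e12    # oxidative weathering of organic C
    F_volc_star: float = 6.0e12   # CO2 degassing (carbonate metamorphism)

    # Reference reservoirs (mol)
    G_star: float = 1.25e21       # sedimentary organic carbon
    C_star: float = 5.0e21        # sedimentary carbonate
    P_deep_star: float = 2.92e15  # deep-ocean phosphate
    ALK_surf_star: float = 9.5e16 # surface alkalinity, mol eq

    # Weathering climate response
    co2_exponent: float = 0.3     # (pCO2/pCO2*)^0.3
    t_efold: float = 13.7         # K, Walker temperature e-fold
    k_wo: float = 0.017           # Monod half-saturation of organic oxidative weathering
    c_wo: float = 1.017           # normalisation at reference

    # Phosphorus / productivity
    p_uptake_rate: float = 0.5    # yr^-1, surface-P uptake by new production
    p_river_scale: float = 0.088  # Paleoproterozoic P delivery per unit silicate
                                  # weathering flux, relative to modern; sets the
                                  # pre-glacial net organic burial just below the
                                  # reductant sink (marginally subcritical low-O2 state)
    p_spike_exponent: float = 1.4 # super-linear P yield of transient weathering
                                  # pulses (finely ground post-glacial regolith)

    # Methane cycle
    phi_mg: float = 0.10          # fraction of anaerobic remineralisation to CH4
    k_ch4_ox: float = 0.1         # yr^-1, CH4 oxidation rate at high O2
    k_ch4_half: float = 1e-4      # pO2/pO2* half-saturation of CH4 oxidation
    k_esc: float = 2.8e-7         # yr^-1, diffusion-limited H-escape rate of CH4
    k_red_halfsat: float = 3.6e-7 # pO2/pO2* half-saturation of reductant oxidation

    # Initial Paleoproterozoic seawater calcium (Precambrian oceans were
    # calcium-rich relative to today)
    ca_init_mM: float = 20.6      # mM

    # Ocean circulation / deep respiration
    ventilation_yr: float = 1000.0  # deep-ocean ventilation timescale
    K_O2_deep: float = 0.01         # mol m^-3, half-saturation of aerobic deep respiration
    henry_o2: float = 1.3e-3        # mol L^-1 atm^-1, O2 solubility

    # Isotopes
    eps_org: float = 25.0         # permil, photosynthetic 13C fractionation
    d13c_mantle: float = -5.0     # permil, carbon added at the deglaciation reset

    # Optional fixed C/P burial ratio (low Corg/Preac sensitivity case); None = dynamic
    cp_sea_fixed: float | None = None

    def __post_init__(self) -> None:
        if not self.k_anox > self.k_oxic > 0:
            raise ParameterError("require k_anox > k_oxic > 0")
        if not (0.0 < self.k1 < 1.0):
            raise ParameterError("k1 must lie in (0, 1)")
        for name in ("F_pp_star", "F_bo_star", "F_ws_star", "F_wc_star",
                     "F_voc_star", "F_wo_star", "F_volc_star", "G_star",
                     "C_star", "P_deep_star", "ventilation_yr"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"CPOParams.{name} must be > 0")

    @property
    def cp_sea_star(self) -> float:
        """Modern C/P burial ratio (oxic fraction k1)."""
        from .carbon import cp_burial_ratio
        return cp_burial_ratio(1.0 - self.k1, self)

    @property
    def F_priv_star(self) -> float:
        """Modern riverine reactive-P input balancing modern P burial, mol P/yr."""
        return self.F_bo_star / self.cp_sea_star

    @property
    def circulation_m3yr(self) -> float:
        return cn.V_DEEP / self.ventilation_yr


@dataclass
class BoundaryConditions:
    """Boundary conditions of a simulation era.

    Defaults are the Paleoproterozoic low-O2 conditions: ~83% solar
    luminosity, ~12% continental weatherability, relative land area 0.48,
    and the low (post-GOE hydrothermal) reductant flux.
    """

    F_red: float = 0.075e12       # mol O2-equivalent/yr, interior reductant input
    luminosity_rel: float = 0.83  # fraction of the present solar constant
    weatherability: float = 0.1098 # fraction of present (calibrated, see methods)
    f_a: float = 0.48             # continental area relative to present
    sulfur: SulfurParams = field(default_factory=SulfurParams)
    cpo: CPOParams = field(default_factory=CPOParams)
    climate: ClimateParams = field(default_factory=ClimateParams)

    def __post_init__(self) -> None:
        if self.F_red < 0:
            raise ParameterError("F_red must be >= 0")
        if not (0.0 < self.f_a <= 1.0):
            raise ParameterError("f_a must lie in (0, 1]")
        if not (0.0 < self.luminosity_rel <= 1.2):
            raise ParameterError("luminosity_rel must lie in (0, 1.2]")
        if not (0.0 < self.weatherability <= 2.0):
            raise ParameterError("weatherability must lie in (0, 2]")

    def replace(self, **kw) -> "BoundaryConditions":
        return dataclasses.replace(self, **kw)


@dataclass
class SolverSettings:
    """Stiff-integrator settings and steady-state criteria."""

    rtol: float = 1e-8
    atol_scale: float = 1e-12     # absolute tolerance relative to reservoir scale
    max_step_yr: float = 1e7
    steady_tol: float = 1e-10     # yr^-1, max |dX/dt|/X at a declared fixed point
    n_output: int = 400           # points on the logarithmic output grid
    t_output_min: float = 1e2     # yr, first output time after the perturbation

    def __post_init__(self) -> None:
        if self.rtol <= 0 or self.atol_scale <= 0 or self.max_step_yr <= 0:
            raise ParameterError("solver tolerances must be > 0")


@dataclass
class Scenario:
    """A perturbation experiment: spin-up conditions plus the CO2 jump."""

    pCO2_init: float = 0.7        # atm, post-deglaciation CO2
    PYR_init: float = 400e18      # mol S, initial continental pyrite at spin-up
    msr: MSRParams = field(default_factory=MSRParams)
    bc: BoundaryConditions = field(default_factory=BoundaryConditions)
    t_end: float = 1e8            # yr
    solver: SolverSettings = field(default_factory=SolverSettings)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.pCO2_init <= 1.0):
            raise ParameterError("pCO2_init must lie in (0, 1] atm")
        if self.PYR_init <= 0:
            raise ParameterError("PYR_init must be > 0")
        if self.t_end <= 0:
            raise ParameterError("t_end must be > 0")
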