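"""Carbon, phosphorus, oxygen, and methane flux laws.

This is the predecessor-model core around which the sulfur cycle is built:
Walker-type silicate/carbonate weathering with a CO2-temperature feedback,
phosphorus-limited export production, COPSE-style organic burial and
redox-dependent C/P burial, a reduced methane cycle with photochemical
oxidation and diffusion-limited hydrogen escape, and the interior reductant
flux that separates permanent from temporary oxidation outcomes.
"""
from __future__ import annotations

import math
import warnings

from . import constants as cn
from .params import BoundaryConditions, CPOParams


def anoxic_fraction(pO2_rel: float, Fpp_rel: float,
                    params: CPOParams | None = None) -> float:
    """Anoxic fraction of the ocean, COPSE parameterisation.

    anox = max(1 - k1 * pO2_rel / Fpp_rel, 0), clipped to [0, 1].
    A vanishing productivity is treated as a fully anoxic ocean.
    """
    p = params or CPOParams()
    if pO2_rel < 0:
        raise ValueError("pO2_rel must be >= 0")
    if Fpp_rel <= 0:
        warnings.warn("anoxic_fraction: Fpp_rel <= 0, treating ocean as fully anoxic",
                      stacklevel=2)
        return 1.0
    return min(max(1.0 - p.k1 * pO2_rel / Fpp_rel, 0.0), 1.0)


def cp_burial_ratio(anox: float, params: CPOParams | None = None) -> float:
    """C/P burial ratio of marine organic matter as a function of ocean anoxia.

    CP_sea = k_anox k_oxic / ((1-anox) k_anox + anox k_oxic); ranges from
    k_oxic (fully oxic) to k_anox (fully anoxic), monotone increasing.
    """
    p = params or CPOParams()
    if not (0.0 <= anox <= 1.0):
        raise ValueError(f"anox must lie in [0, 1], got {anox}")
    if p.cp_sea_fixed is not None:
        return p.cp_sea_fixed
    return p.k_anox * p.k_oxic / ((1.0 - anox) * p.k_anox + anox * p.k_oxic)


def p_burial(F_bo: float, CP_sea: float) -> float:
    """Reactive-P burial flux (mol P/yr) from organic C burial and CP_sea."""
    if CP_sea <= 0:
        raise ValueError("CP_sea must be > 0")
    if F_bo < 0:
        raise ValueError("F_bo must be >= 0")
    return F_bo / CP_sea


def climate_weathering_factor(pco2_atm: float, t_k: float,
                              bc: BoundaryConditions) -> float:
    """Walker-type weathering response, normalised to 1 at the modern state.

    weatherability * f_a * (pCO2/pCO2*)^0.3 * exp((T - T*)/13.7 K)
    """
    p = bc.cpo
    return (bc.weatherability * bc.f_a
            * (max(pco2_atm, 1e-12) / cn.PCO2_STAR_ATM) ** p.co2_exponent
            * math.exp((t_k - cn.T_STAR_K) / p.t_efold))


def partition_co2(A: float, alk: float, t_k: float) -> float:
    """Atmospheric pCO2 (atm) from the combined atmosphere + surface-DIC pool.

    Surface DIC is approximated as dissolved CO2 (Henry's law) plus
    bicarbonate balancing the (constant) carbonate alkalinity; carbonate ion
    is negligible at the acidic, high-CO2 states simulated here.  The
    partition is then linear: A = ALK + pCO2 (N_atm + K_H(T) V_surf).
    """
    denom = cn.MOL_PER_ATM_CO2 + cn.henry_co2(t_k) * cn.L_SURF
    return max(A - alk, 1e-8 * cn.MOL_PER_ATM_CO2) / denom


def co2_pool_from_pressure(pco2_atm: float, alk: float, t_k: float) -> float:
    """Inverse of :func:`partition_co2`: total A for a target pCO2."""
    return alk + pco2_atm * (cn.MOL_PER_ATM_CO2 + cn.henry_co2(t_k) * cn.L_SURF)


def carbon_oxygen_fluxes(state, t_k: float, bc: BoundaryConditions) -> dict:
    """All C-P-O2-CH4 fluxes (mol/yr) for a given state and temperature.

    Returns a dict including the FluxSet entries this module owns plus the
    internal diagnostics (methanogenesis, deep respiration, anoxic fraction,
    CP_sea, riverine P) needed by the tendency assembly.  At the modern
    reference state every flux equals its starred reference value.
    """
    p = bc.cpo
    pco2 = partition_co2(state.A, state.ALK, t_k)
    po2_rel = cn.po2_pal(max(state.O_AS, 0.0))

    cf = climate_weathering_factor(pco2, t_k, bc)
    c_rel = max(state.C, 0.0) / p.C_star
    g_rel = max(state.G, 0.0) / p.G_star

    F_ws = p.F_ws_star * cf
    F_wc = p.F_wc_star * cf * c_rel
    F_volc = p.F_volc_star * c_rel
    F_voc = p.F_voc_star * g_rel
    F_wo = (p.F_wo_star * g_rel * bc.weatherability * bc.f_a * p.c_wo
            * po2_rel / (po2_rel + p.k_wo))
    F_bc = F_ws + F_wc   # instantaneous carbonate compensation (alkalinity balance)

    # phosphorus and productivity
    F_priv = (p.p_river_scale * p.F_priv_star
              * (F_ws / p.F_ws_star) ** p.p_spike_exponent)
    F_pp = cn.REDFIELD_C_P * p.p_uptake_rate * max(state.P_S, 0.0)
    fpp_rel = F_pp / p.F_pp_star
    F_bo = p.F_bo_star * fpp_rel * fpp_rel
    anox = anoxic_fraction(po2_rel, max(fpp_rel, 1e-12), p)
    cp_sea = cp_burial_ratio(anox, p)
    F_bo_P = F_bo / cp_sea

    # fate of exported organic matter
    o2_deep = max(state.O_D, 0.0) / cn.V_DEEP            # mol m^-3
    lam = o2_deep / (o2_deep + p.K_O2_deep)              # aerobic fraction
    R = max(F_pp - F_bo, 0.0)
    R_aer = lam * R                                      # deep-ocean O2 sink
    F_mg = 0.5 * p.phi_mg * (1.0 - lam) * R              # mol CH4/yr
    R_other = (1.0 - p.phi_mg) * (1.0 - lam) * R         # reoxidised in surface

    # methane sinks
    m = max(state.M, 0.0)
    F_oxi_CH4 = p.k_ch4_ox * (po2_rel / (po2_rel + p.k_ch4_half)) * m
    F_esc_CH4 = p.k_esc * m

    # interior reductants: fraction oxidised by O2, remainder escapes as H2
    f_ox = po2_rel / (po2_rel + p.k_red_halfsat)
    F_red_O = bc.F_red * f_ox

    # ocean circulation of O2 and P (positive into the surface box)
    q = p.circulation_m3yr
    o2_surf_sat = p.henry_o2 * cn.po2_atm(max(state.O_AS, 0.0)) * 1e3  # mol m^-3
    F_cir_O = q * (o2_deep - o2_surf_sat)
    F_cir_P = q * (max(state.P_D, 0.0) / cn.V_DEEP - max(state.P_S, 0.0) / cn.V_SURF)

    for name, val in (("F_ws", F_ws), ("F_wc", F_wc), ("F_pp", F_pp),
                      ("F_bo", F_bo), ("F_wo_O", F_wo)):
        if not math.isfinite(val) or val < 0:
            raise FloatingPointError(f"flux {name} is invalid: {val}")

    return {
        "pCO2_atm": pco2, "pO2_rel": po2_rel, "anox": anox, "CP_sea": cp_sea,
        "F_ws": F_ws, "F_wc": F_wc, "F_volc": F_volc, "F_voc": F_voc,
        "F_wo_O": F_wo, "F_bc": F_bc, "F_priv": F_priv, "F_pp": F_pp,
        "F_oph": F_pp, "F_bo": F_bo, "F_bo_P": F_bo_P,
        "F_dgS_O": R_other, "F_dgD_O": R_aer,
        "F_mg": F_mg, "F_oxi_CH4": F_oxi_CH4, "F_oxi_O": 2.0 * F_oxi_CH4,
        "F_esc": F_esc_CH4, "F_red": F_red_O,
        "F_cir_O": F_cir_O, "F_cir_P": F_cir_P,
    }
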