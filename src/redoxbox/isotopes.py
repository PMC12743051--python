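"""Isotope fractionation and mass-balance tendencies (delta34S and delta13C).

Sulfur isotope fractionation is attributed entirely to microbial sulfate
reduction (MSR): pyrite is buried at delta34S_sw - Delta_MSR, where
Delta_MSR follows a Michaelis-Menten dependence on the sulfate
concentration, Delta_MSR = Delta_max [SO4] / ([SO4] + K_MSR).  Gypsum
buries at seawater composition without fractionation.  Delta arithmetic is
linear (per-mil mixing), the standard box-model approximation; the error is
far below 0.1 permil for |delta| < 60 permil.
"""
from __future__ import annotations

from .params import MSRParams

#: reservoirs smaller than this (mol) have their delta derivative frozen
RESERVOIR_FLOOR = 1e12


def delta_msr(so4_mm: float, params: MSRParams | None = None) -> float:
    """Instantaneous MSR fractionation (permil) at sulfate concentration so4_mm."""
    p = params or MSRParams()
    if so4_mm < 0:
        raise ValueError("SO4 concentration must be >= 0")
    return p.Delta_max * so4_mm / (so4_mm + p.K_MSR)


def buried_pyrite_d34s(d34s_sw: float, so4_mm: float,
                       params: MSRParams | None = None) -> float:
    """delta34S of pyrite being buried: seawater minus Delta_MSR."""
    return d34s_sw - delta_msr(so4_mm, params)


def sulfur_isotope_tendencies(state, ledger, sfx: dict, delta: float) -> dict:
    """d/dt of d34S_sw, d34S_GYP, d34S_PYR (permil/yr).

    Seawater sulfate (one value for both ocean boxes) is driven by the
    isotopic contrast of its sources and by the offset removal via pyrite
    burial; each sediment reservoir relaxes toward the composition it is
    currently burying.  Mass-weighted total 34S is conserved exactly while
    all reservoirs are above the floor.
    """
    s_ocean = max(state.S_S, 0.0) + max(state.S_D, 0.0)
    d_sw = 0.0
    if s_ocean > RESERVOIR_FLOOR:
        d_sw = ((sfx["F_vgyp"] + sfx["F_wgyp"]) * (ledger.d34S_GYP - ledger.d34S_sw)
                + (sfx["F_vpyr"] + sfx["F_wpyr"]) * (ledger.d34S_PYR - ledger.d34S_sw)
                + sfx["F_bpyr"] * delta) / s_ocean
    d_gyp = 0.0
    if state.GYP > RESERVOIR_FLOOR:
        d_gyp = sfx["F_bgyp"] * (ledger.d34S_sw - ledger.d34S_GYP) / state.GYP
    d_pyr = 0.0
    if state.PYR > RESERVOIR_FLOOR:
        d_pyr = (sfx["F_bpyr"]
                 * ((ledger.d34S_sw - delta) - ledger.d34S_PYR) / state.PYR)
    return {"d34S_sw": d_sw, "d34S_GYP": d_gyp, "d34S_PYR": d_pyr}


def carbon_isotope_tendencies(state, ledger, cfx: dict, eps_org: float) -> dict:
    """d/dt of d13C_A, d13C_G, d13C_C (permil/yr).

    Organic burial fractionates by eps_org (buried at d13C_A - eps_org);
    carbonate buries at d13C_A; weathering and degassing return each
    sediment's own composition.  The small methane loop is treated as
    isotopically neutral.
    """
    d_a = 0.0
    if state.A > RESERVOIR_FLOOR:
        d_a = ((cfx["F_volc"] + cfx["F_wc"]) * (ledger.d13C_C - ledger.d13C_A)
               + (cfx["F_voc"] + cfx["F_wo_O"]) * (ledger.d13C_G - ledger.d13C_A)
               + cfx["F_bo"] * eps_org) / state.A
    d_g = 0.0
    if state.G > RESERVOIR_FLOOR:
        d_g = cfx["F_bo"] * ((ledger.d13C_A - eps_org) - ledger.d13C_G) / state.G
    d_c = 0.0
    if state.C > RESERVOIR_FLOOR:
        d_c = cfx["F_bc"] * (ledger.d13C_A - ledger.d13C_C) / state.C
    return {"d13C_A": d_a, "d13C_G": d_g, "d13C_C": d_c}


def total_34s_moment(state, ledger) -> float:
    """Mass-weighted sum of reservoir x delta34S (mol permil), a conserved quantity."""
    return ((state.S_S + state.S_D) * ledger.d34S_sw
            + state.GYP * ledger.d34S_GYP + state.PYR * ledger.d34S_PYR)
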