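"""Sulfur-cycle flux laws and sulfate/sediment mass-balance tendencies.

Sulfate enters the surface ocean by degassing and weathering of the two
crustal reservoirs (gypsum GYP and pyrite PYR) and leaves by gypsum and
pyrite burial; surface and deep boxes exchange by circulation.  Degassing
is proportional to reservoir size; gypsum weathering scales with carbonate
weathering; pyrite oxidative weathering follows a Monod law in atmospheric
pO2 (half-saturation 0.017 of present, saturating at the erosion-limited
maximum); gypsum burial is bilinear in [Ca2+] and [SO4 2-]; pyrite burial
is proportional to [SO4 2-] and organic burial and inversely proportional
to pO2, the COPSE shorthand for microbial sulfate reduction.
"""
from __future__ import annotations

import warnings

from .params import SulfurParams


def gypsum_degassing(GYP: float, p: SulfurParams | None = None) -> float:
    """Volcanic/metamorphic gypsum degassing, mol S/yr."""
    p = p or SulfurParams()
    return p.F_vgyp_star * max(GYP, 0.0) / p.GYP_star


def pyrite_degassing(PYR: float, p: SulfurParams | None = None) -> float:
    """Volcanic/metamorphic pyrite degassing, mol S/yr."""
    p = p or SulfurParams()
    return p.F_vpyr_star * max(PYR, 0.0) / p.PYR_star


def gypsum_weathering(GYP: float, F_wc_rel: float,
                      p: SulfurParams | None = None) -> float:
    """Gypsum weathering, proportional to the carbonate weathering flux."""
    p = p or SulfurParams()
    return p.F_wgyp_star * (max(GYP, 0.0) / p.GYP_star) * max(F_wc_rel, 0.0)


def pyrite_weathering(PYR: float, pO2_rel: float, f_a: float,
                      p: SulfurParams | None = None) -> float:
    """Oxidative pyrite weathering with a Monod pO2 dependence, mol S/yr."""
    p = p or SulfurParams()
    x = max(pO2_rel, 0.0)
    return (p.F_wpyr_star * f_a * p.c_pyrw * x / (x + p.k_pyrw)
            * max(PYR, 0.0) / p.PYR_star)


def gypsum_burial(Ca_rel: float, SO4_rel: float,
                  p: SulfurParams | None = None) -> float:
    """Gypsum (evaporite) burial, bilinear in calcium and sulfate."""
    p = p or SulfurParams()
    return p.F_bgyp_star * max(Ca_rel, 0.0) * max(SO4_rel, 0.0)


def pyrite_burial(SO4_rel: float, pO2_rel: float, Fbo_rel: float,
                  p: SulfurParams | None = None) -> float:
    """Pyrite burial via microbial sulfate reduction, mol S/yr.

    Proportional to sulfate and organic burial, inversely proportional to
    pO2; pO2_rel is floored (default 1e-10) to cap the anoxic amplification.
    """
    p = p or SulfurParams()
    if pO2_rel <= 0:
        warnings.warn("pyrite_burial: pO2_rel <= 0 clamped to floor", stacklevel=2)
    x = max(pO2_rel, p.pO2_floor_rel)
    return p.F_bpyr_star * max(SO4_rel, 0.0) * (1.0 / x) * max(Fbo_rel, 0.0)


def sulfur_fluxes(state, pO2_rel: float, F_wc_rel: float, Fbo_rel: float,
                  f_a: float, circulation_m3yr: float,
                  p: SulfurParams | None = None) -> dict:
    """All sulfur fluxes (mol S/yr) for a state; circulation positive into surface."""
    from . import constants as cn
    p = p or SulfurParams()
    so4_s = cn.so4_surface_mm(max(state.S_S, 0.0))
    so4_rel = so4_s / p.SO4_star_mM
    ca_rel = cn.conc_mm(max(state.Ca, 0.0), cn.L_SURF + cn.L_DEEP) / p.Ca_star_mM
    f_cir = circulation_m3yr * (max(state.S_D, 0.0) / cn.V_DEEP
                                - max(state.S_S, 0.0) / cn.V_SURF)
    return {
        "SO4_mM": so4_s,
        "F_vgyp": gypsum_degassing(state.GYP, p),
        "F_vpyr": pyrite_degassing(state.PYR, p),
        "F_wgyp": gypsum_weathering(state.GYP, F_wc_rel, p),
        "F_wpyr": pyrite_weathering(state.PYR, pO2_rel, f_a, p),
        "F_bgyp": gypsum_burial(ca_rel, so4_rel, p),
        "F_bpyr": pyrite_burial(so4_rel, pO2_rel, Fbo_rel, p),
        "F_cir_S": f_cir,
    }


def sulfur_tendencies(fluxes: dict) -> dict:
    """Mass-balance tendencies of S_S, S_D, GYP, PYR (mol S/yr).

    dS_S/dt = F_vgyp + F_vpyr + F_wgyp + F_wpyr - F_bgyp - F_bpyr + F_cir_S
    dS_D/dt = -F_cir_S
    dGYP/dt = F_bgyp - F_vgyp - F_wgyp
    dPYR/dt = F_bpyr - F_vpyr - F_wpyr

    The four tendencies sum to zero identically (total sulfur closure).
    """
    f = fluxes
    dss = (f["F_vgyp"] + f["F_vpyr"] + f["F_wgyp"] + f["F_wpyr"]
           - f["F_bgyp"] - f["F_bpyr"] + f["F_cir_S"])
    return {
        "S_S": dss,
        "S_D": -f["F_cir_S"],
        "GYP": f["F_bgyp"] - f["F_vgyp"] - f["F_wgyp"],
        "PYR": f["F_bpyr"] - f["F_vpyr"] - f["F_wpyr"],
    }
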