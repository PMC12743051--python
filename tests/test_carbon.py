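"""Redox-dependent P burial, anoxic fraction, and the weathering core."""
import dataclasses
import math

import numpy as np
import pytest

from redoxbox import BoundaryConditions, anoxic_fraction, cp_burial_ratio, p_burial
from redoxbox.carbon import (carbon_oxygen_fluxes, climate_weathering_factor,
                             co2_pool_from_pressure, partition_co2)
from redoxbox.params import CPOParams
from redoxbox import constants as cn
from redoxbox.state import ReservoirState


@pytest.mark.parametrize("po2_rel, fpp_rel, expected", [
    (1.0, 1.0, 1.0 - 0.997527),   # modern ocean: 0.247% anoxic
    (0.0, 1.0, 1.0),              # zero-oxygen limit
    (2.0, 1.0, 0.0),              # clipped at fully oxic
])
def test_anoxic_fraction(po2_rel, fpp_rel, expected):
    assert anoxic_fraction(po2_rel, fpp_rel) == pytest.approx(expected, abs=1e-12)


def test_anoxic_fraction_zero_productivity_warns():
    with pytest.warns(UserWarning):
        assert anoxic_fraction(0.5, 0.0) == 1.0


@pytest.mark.parametrize("anox, expected", [
    (0.0, 60.0),                  # oxic limit = k_oxic
    (1.0, 200.0),                 # anoxic limit = k_anox
    (0.5, 12000.0 / 130.0),       # harmonic mixture
])
def test_cp_burial_ratio(anox, expected):
    assert cp_burial_ratio(anox) == pytest.approx(expected, rel=1e-12)


def test_cp_burial_ratio_monotone():
    grid = np.linspace(0, 1, 50)
    vals = [cp_burial_ratio(a) for a in grid]
    assert np.all(np.diff(vals) > 0)


def test_cp_fixed_override():
    p = CPOParams(cp_sea_fixed=60.0)
    assert cp_burial_ratio(0.0, p) == cp_burial_ratio(1.0, p) == 60.0


@pytest.mark.parametrize("f_bo, cp, expected", [
    (60.0, 60.0, 1.0), (0.0, 123.0, 0.0), (200.0, 200.0, 1.0),
])
def test_p_burial(f_bo, cp, expected):
    assert p_burial(f_bo, cp) == expected


def test_p_burial_rejects_nonpositive_ratio():
    with pytest.raises(ValueError):
        p_burial(1.0, 0.0)


def _modern_state(bc):
    """A modern reference state: every flux should sit at its starred value."""
    p = bc.cpo
    alk = p.ALK_surf_star
    a = co2_pool_from_pressure(cn.PCO2_STAR_ATM, alk, cn.T_STAR_K)
    return ReservoirState(
        O_AS=cn.PO2_STAR_ATM * cn.MOL_PER_ATM_O2, O_D=0.25 * cn.V_DEEP,
        A=a, M=cn.PCH4_STAR_ATM * cn.MOL_PER_ATM_CH4,
        P_S=p.F_pp_star / (cn.REDFIELD_C_P * p.p_uptake_rate),
        P_D=p.P_deep_star,
        S_S=cn.SO4_STAR_MM * 1e-3 * cn.L_SURF, S_D=cn.SO4_STAR_MM * 1e-3 * cn.L_DEEP,
        Ca=cn.CA_STAR_MM * 1e-3 * (cn.L_SURF + cn.L_DEEP), ALK=alk,
        G=p.G_star, C=p.C_star, PYR=250e18, GYP=150e18)


def test_modern_reference_normalisation():
    """At the modern reference state the core fluxes equal their starred values."""
    bc = BoundaryConditions(weatherability=1.0, f_a=1.0, luminosity_rel=1.0)
    f = carbon_oxygen_fluxes(_modern_state(bc), cn.T_STAR_K, bc)
    p = bc.cpo
    assert f["F_ws"] == pytest.approx(p.F_ws_star, rel=1e-6)
    assert f["F_wc"] == pytest.approx(p.F_wc_star, rel=1e-6)
    assert f["F_pp"] == pytest.approx(p.F_pp_star, rel=1e-12)
    assert f["F_bo"] == pytest.approx(p.F_bo_star, rel=1e-12)
    assert f["F_volc"] == pytest.approx(p.F_volc_star, rel=1e-12)
    assert f["F_voc"] == pytest.approx(p.F_voc_star, rel=1e-12)
    assert f["F_wo_O"] == pytest.approx(p.F_wo_star, rel=1e-6)


def test_weathering_increases_with_temperature():
    bc = BoundaryConditions()
    lo = climate_weathering_factor(0.087, 300.0, bc)
    hi = climate_weathering_factor(0.087, 310.0, bc)
    assert hi > lo
    assert hi / lo == pytest.approx(math.exp(10.0 / 13.7), rel=1e-12)


def test_co2_partition_round_trip():
    alk = 9.5e16
    for pco2 in (1e-4, 0.087, 0.7):
        a = co2_pool_from_pressure(pco2, alk, 300.0)
        assert partition_co2(a, alk, 300.0) == pytest.approx(pco2, rel=1e-12)
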