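"""MSR fractionation and isotope mass balance."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from redoxbox import MSRParams, buried_pyrite_d34s, delta_msr
from redoxbox.isotopes import (carbon_isotope_tendencies, sulfur_isotope_tendencies,
                               total_34s_moment)
from redoxbox.state import IsotopeLedger, ReservoirState


@pytest.mark.parametrize("so4, dmax, k, expected", [
    (0.0, 40.0, 0.2, 0.0),            # no sulfate, no fractionation
    (0.2, 40.0, 0.2, 20.0),           # half-saturation
    (28.0, 40.0, 0.2, 40.0 * 28 / 28.2),  # modern ocean: ~39.7 permil
])
def test_delta_msr(so4, dmax, k, expected):
    assert delta_msr(so4, MSRParams(Delta_max=dmax, K_MSR=k)) == pytest.approx(
        expected, rel=1e-12)


@given(so4=st.floats(0, 100), k=st.floats(1e-3, 5.0), dmax=st.floats(0, 80))
@settings(max_examples=60, deadline=None)
def test_delta_msr_bounded_and_monotone(so4, k, dmax):
    p = MSRParams(Delta_max=dmax, K_MSR=k)
    d = delta_msr(so4, p)
    assert 0.0 <= d <= dmax
    assert delta_msr(so4 * 2 + 1e-6, p) >= d


def test_buried_pyrite_composition():
    p = MSRParams(Delta_max=40.0, K_MSR=0.2)
    assert buried_pyrite_d34s(5.0, 0.2, p) == pytest.approx(5.0 - 20.0)


def _state(s_s=1e18, s_d=3e19, gyp=10e18, pyr=400e18):
    return ReservoirState(O_AS=1e19, O_D=1e15, A=1e19, M=1e16, P_S=1e13,
                          P_D=3e15, S_S=s_s, S_D=s_d, Ca=1.4e19, ALK=9.5e16,
                          G=1.25e21, C=5e21, PYR=pyr, GYP=gyp)


def _fluxes(**kw):
    base = {k: 0.0 for k in ("F_vgyp", "F_vpyr", "F_wgyp", "F_wpyr",
                             "F_bgyp", "F_bpyr", "F_cir_S")}
    base.update(kw)
    return base


def test_zero_fluxes_zero_tendencies():
    led = IsotopeLedger(d34S_sw=5.0, d34S_GYP=10.0, d34S_PYR=-15.0)
    d = sulfur_isotope_tendencies(_state(), led, _fluxes(), delta=20.0)
    assert all(v == 0.0 for v in d.values())


def test_uniform_delta_no_fractionation_is_static():
    led = IsotopeLedger(d34S_sw=0.0, d34S_GYP=0.0, d34S_PYR=0.0)
    f = _fluxes(F_vgyp=1e11, F_vpyr=1e11, F_wgyp=2e11, F_wpyr=1e11,
                F_bgyp=2e11, F_bpyr=3e11)
    d = sulfur_isotope_tendencies(_state(), led, f, delta=0.0)
    assert all(abs(v) < 1e-30 for v in d.values())


@given(dsw=st.floats(-50, 50), dgyp=st.floats(-50, 50), dpyr=st.floats(-50, 50),
       delta=st.floats(0, 60),
       f=st.lists(st.floats(0, 5e12), min_size=6, max_size=6))
@settings(max_examples=80, deadline=None)
def test_total_34s_moment_conserved(dsw, dgyp, dpyr, delta, f):
    """The flux-weighted delta tendencies conserve mass-weighted total 34S."""
    state = _state()
    led = IsotopeLedger(d34S_sw=dsw, d34S_GYP=dgyp, d34S_PYR=dpyr)
    fx = dict(zip(["F_vgyp", "F_vpyr", "F_wgyp", "F_wpyr", "F_bgyp", "F_bpyr"], f))
    fx["F_cir_S"] = 0.0
    d = sulfur_isotope_tendencies(state, led, fx, delta)
    from redoxbox.sulfur import sulfur_tendencies
    dm = sulfur_tendencies(fx)
    # d/dt of sum(M_i * delta_i) = sum(M_i * ddelta_i + dM_i * delta_i)
    s_ocean = state.S_S + state.S_D
    rate = (s_ocean * d["d34S_sw"] + state.GYP * d["d34S_GYP"]
            + state.PYR * d["d34S_PYR"]
            + (dm["S_S"] + dm["S_D"]) * dsw + dm["GYP"] * dgyp
            + dm["PYR"] * dpyr)
    gross = sum(abs(v) for v in fx.values()) * 60 + 1.0
    assert abs(rate) < 1e-9 * gross


def test_carbon_isotope_zero_and_uniform_cases():
    state = _state()
    led = IsotopeLedger(d13C_A=0.0, d13C_G=0.0, d13C_C=0.0)
    zero = {k: 0.0 for k in ("F_volc", "F_wc", "F_voc", "F_wo_O", "F_bo", "F_bc")}
    d = carbon_isotope_tendencies(state, led, zero, eps_org=25.0)
    assert all(v == 0.0 for v in d.values())
    active = dict(zero, F_volc=6e12, F_wc=1.2e13, F_bo=4.5e12, F_bc=1.8e13)
    d = carbon_isotope_tendencies(state, led, active, eps_org=0.0)
    assert all(abs(v) < 1e-30 for v in d.values())


def test_small_reservoir_freezes_delta():
    state = _state(gyp=1e10)   # below the bookkeeping floor
    led = IsotopeLedger(d34S_sw=10.0, d34S_GYP=0.0, d34S_PYR=0.0)
    d = sulfur_isotope_tendencies(state, led, _fluxes(F_bgyp=1e11), delta=0.0)
    assert d["d34S_GYP"] == 0.0
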