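"""Ensemble sampling and rejection filtering."""
import numpy as np
import pytest
from scipy import stats

from redoxbox.montecarlo import (CONSERVATIVE_WINDOW, STRICT_WINDOW, MCSample,
                                 SpinupCache, results_frame, run_ensemble,
                                 sample_parameters, subsample)
from redoxbox.params import BoundaryConditions


def test_samples_reproducible_and_in_range():
    a = sample_parameters(500, seed=5)
    b = sample_parameters(500, seed=5)
    assert all(x.pCO2_init == y.pCO2_init and x.PYR_init == y.PYR_init
               for x, y in zip(a, b))
    for s in a:
        assert 0.08 <= s.pCO2_init <= 0.8
        assert 50e18 <= s.PYR_init <= 500e18
        assert 2e-2 <= s.K_MSR <= 2.0
        assert 10.0 <= s.Delta_max <= 60.0


def test_marginals_match_design_distributions():
    """KS tests at n = 1e4: uniform marginals, log-uniform K_MSR."""
    draws = sample_parameters(10000, seed=123)
    pco2 = np.array([s.pCO2_init for s in draws])
    kmsr = np.array([s.K_MSR for s in draws])
    dmax = np.array([s.Delta_max for s in draws])
    assert stats.kstest(pco2, stats.uniform(0.08, 0.72).cdf).pvalue > 0.01
    assert stats.kstest(dmax, stats.uniform(10, 50).cdf).pvalue > 0.01
    log_k = np.log(kmsr)
    assert stats.kstest(log_k, stats.uniform(np.log(0.02),
                                             np.log(2.0 / 0.02)).cdf).pvalue > 0.01
    # log-uniform median = geometric midpoint of the range
    assert np.median(kmsr) == pytest.approx(np.sqrt(0.02 * 2.0), rel=0.1)


@pytest.fixture(scope="module")
def small_ensemble(bc):
    cache = SpinupCache(bc, n_grid=8)
    samples = sample_parameters(24, seed=9)
    # plant the nominal-parameter sample and a guaranteed-reject sample
    samples[0] = MCSample(0, 0.7, 400e18, 0.2, 40.0)
    samples[1] = MCSample(1, 0.08, 400e18, 2.0, 10.0)
    return samples, run_ensemble(samples, bc, cache=cache)


def test_nominal_sample_is_accepted_strict(small_ensemble):
    _, results = small_ensemble
    assert results[0].accepted["strict"]
    assert STRICT_WINDOW[0] < results[0].summary.d34S_bpyr_min < STRICT_WINDOW[1]


def test_weak_fractionation_sample_is_rejected(small_ensemble):
    """Delta_max = 10 permil cannot produce a < -25 permil anomaly."""
    _, results = small_ensemble
    r = results[1]
    assert not r.accepted["strict"]
    assert r.summary.d34S_bpyr_min > -11.0


def test_acceptance_windows_nest(small_ensemble):
    _, results = small_ensemble
    for r in results:
        if r.accepted["strict"]:
            assert r.accepted["conservative"]


def test_results_ordered_by_index(small_ensemble):
    _, results = small_ensemble
    assert [r.sample.index for r in results] == list(range(len(results)))


def test_ensemble_is_deterministic(bc, small_ensemble):
    samples, results = small_ensemble
    cache = SpinupCache(bc, n_grid=8)
    again = run_ensemble(samples[:3], bc, cache=cache)
    for r1, r2 in zip(results[:3], again):
        assert r1.summary.d34S_bpyr_min == r2.summary.d34S_bpyr_min
        assert r1.summary.pO2_max == r2.summary.pO2_max


def test_subsample_statistics(small_ensemble):
    _, results = small_ensemble
    out = subsample(results, *CONSERVATIVE_WINDOW)
    stats_ = out["stats"]
    assert stats_["n_accepted"] == len(out["accepted"])
    strict = subsample(results, *STRICT_WINDOW)["stats"]
    assert strict["n_accepted"] <= stats_["n_accepted"]


def test_empty_subset_reports_none(small_ensemble):
    _, results = small_ensemble
    out = subsample(results, -20.0, -25.0)   # lo >= hi: empty by construction
    assert out["stats"]["n_accepted"] == 0
    assert out["stats"]["min_pCO2_init"] is None


def test_spinup_cache_interpolation_matches_direct(bc):
    """Grid interpolation reproduces a direct spin-up between nodes."""
    from redoxbox import spinup
    cache = SpinupCache(bc, n_grid=8)
    pyr = 230e18
    st_i, _ = cache.state_for(pyr)
    st_d, _ = spinup(bc, PYR_init=pyr, verify_yr=0.0)
    for f in ("O_AS", "A", "M", "P_D", "S_S", "PYR"):
        assert getattr(st_i, f) == pytest.approx(getattr(st_d, f), rel=2e-2)
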