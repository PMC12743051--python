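"""Monte Carlo ensemble: parameter sampling, batch runs, rejection filtering.

The sampled parameters and their ranges follow the uncertainty analysis
design: pCO2_init uniform on [0.08, 0.8] atm; initial crustal pyrite
uniform on [50, 500] x 1e18 mol; K_MSR log-uniform on [0.02, 2] mM;
Delta_max uniform on [10, 60] permil.  Each run is scored by the minimum
instantaneous buried-pyrite d34S over the 1e8-yr trajectory, and runs
reproducing the observed negative anomaly window are subsampled.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .driver import run_scenario_summary, spinup
from .params import BoundaryConditions, MSRParams, Scenario, SolverSettings
from .state import RunSummary

log = logging.getLogger(__name__)

#: sampling ranges of the ensemble design
PCO2_RANGE = (0.08, 0.8)          # atm, uniform
PYR_RANGE = (50e18, 500e18)       # mol, uniform
KMSR_RANGE = (2.0e-2, 2.0)        # mM, log-uniform
DMAX_RANGE = (10.0, 60.0)         # permil, uniform

#: acceptance windows on d34S_bpyr_min (permil)
STRICT_WINDOW = (-35.0, -25.0)
CONSERVATIVE_WINDOW = (-40.0, -20.0)


@dataclass
class MCSample:
    index: int
    pCO2_init: float     # atm
    PYR_init: float      # mol S
    K_MSR: float         # mM
    Delta_max: float     # permil
    rng_seed: int = 0


@dataclass
class MCResult:
    sample: MCSample
    summary: RunSummary
    accepted: dict = field(default_factory=dict)


def sample_parameters(n: int, seed: int) -> list[MCSample]:
    """Draw ``n`` parameter sets; reproducible for a given seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    pco2 = rng.uniform(*PCO2_RANGE, size=n)
    pyr = rng.uniform(*PYR_RANGE, size=n)
    kmsr = np.exp(rng.uniform(np.log(KMSR_RANGE[0]), np.log(KMSR_RANGE[1]), size=n))
    dmax = rng.uniform(*DMAX_RANGE, size=n)
    return [MCSample(i, float(pco2[i]), float(pyr[i]), float(kmsr[i]),
                     float(dmax[i]), rng_seed=seed) for i in range(n)]


class SpinupCache:
    """Steady states on a PYR_init grid, interpolated linearly per sample.

    Spin-up cost dominates the ensemble; the steady state varies smoothly
    (near-linearly) with the initial pyrite inventory, so a 20-point grid
    interpolation reproduces direct spin-ups to well below solver noise.
    """

    def __init__(self, bc: BoundaryConditions, n_grid: int = 20,
                 pyr_range: tuple[float, float] = PYR_RANGE,
                 solver: SolverSettings | None = None):
        self.bc = bc
        self.solver = solver or SolverSettings()
        self.grid = np.linspace(pyr_range[0], pyr_range[1], n_grid)
        states = []
        for pyr in self.grid:
            st, ld = spinup(bc, PYR_init=float(pyr), solver=self.solver,
                            verify_yr=0.0)
            states.append(np.concatenate([st.to_array(), ld.to_array()]))
        self._states = np.array(states)

    def state_for(self, pyr_init: float):
        from .state import IsotopeLedger, ReservoirState
        pyr = float(np.clip(pyr_init, self.grid[0], self.grid[-1]))
        y = np.array([np.interp(pyr, self.grid, self._states[:, j])
                      for j in range(self._states.shape[1])])
        return (ReservoirState.from_array(y[:14]), IsotopeLedger.from_array(y[14:]))


def run_ensemble(samples: list[MCSample], bc: BoundaryConditions | None = None,
                 t_end: float = 1e8, solver: SolverSettings | None = None,
                 cache: SpinupCache | None = None,
                 progress: bool = False) -> list[MCResult]:
    """One result per sample, ordered by sample index; failures are flagged.

    The ensemble boundary conditions default to the permanent-oxidation
    scenario (F_red = 0.075 Tmol O2-eq/yr).
    """
    bc = bc or BoundaryConditions()
    solver = solver or SolverSettings(rtol=1e-7, n_output=300)
    cache = cache or SpinupCache(bc, solver=solver)
    results = []
    for s in sorted(samples, key=lambda s: s.index):
        msr = MSRParams(Delta_max=s.Delta_max, K_MSR=s.K_MSR)
        sc = Scenario(pCO2_init=s.pCO2_init, PYR_init=s.PYR_init, msr=msr,
                      bc=bc, t_end=t_end, solver=solver, rng_seed=s.rng_seed)
        try:
            summary = run_scenario_summary(sc, spun=cache.state_for(s.PYR_init))
        except Exception as exc:   # a single bad draw must not kill the ensemble
            log.warning("ensemble run %d failed: %s", s.index, exc)
            summary = RunSummary(np.nan, np.nan, np.nan, np.nan, np.nan,
                                 np.nan, np.nan, np.nan, False,
                                 failed=True, failure_message=str(exc))
        accepted = {}
        for name, (lo, hi) in (("strict", STRICT_WINDOW),
                               ("conservative", CONSERVATIVE_WINDOW)):
            v = summary.d34S_bpyr_min
            accepted[name] = bool(not summary.failed and lo < v < hi)
        results.append(MCResult(s, summary, accepted))
        if progress and s.index % 100 == 0:
            log.info("ensemble progress: %d/%d", s.index + 1, len(samples))
    return results


def results_frame(results: list[MCResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "index": r.sample.index, "pCO2_init": r.sample.pCO2_init,
            "PYR_init": r.sample.PYR_init, "K_MSR": r.sample.K_MSR,
            "Delta_max": r.sample.Delta_max,
            "d34S_bpyr_min": r.summary.d34S_bpyr_min,
            "pO2_max": r.summary.pO2_max, "SO4_max": r.summary.SO4_max,
            "pO2_end": r.summary.pO2_end, "failed": r.summary.failed,
            "accepted_strict": r.accepted.get("strict", False),
            "accepted_conservative": r.accepted.get("conservative", False),
        })
    return pd.DataFrame(rows)


def subsample(results: list[MCResult], lo: float, hi: float) -> dict:
    """Accepted subset (lo < d34S_bpyr_min < hi) and its statistics.

    Statistics of an empty subset are reported as None, never as zero.
    """
    df = results_frame(results)
    ok = df[~df["failed"]]
    acc = ok[(ok["d34S_bpyr_min"] > lo) & (ok["d34S_bpyr_min"] < hi)]
    n = len(acc)
    stats = {
        "window": (lo, hi),
        "n_total": len(results),
        "n_accepted": n,
        "fraction_accepted": n / len(results) if results else None,
        "min_pCO2_init": float(acc["pCO2_init"].min()) if n else None,
        "fraction_pCO2_above_0.2": float((acc["pCO2_init"] > 0.2).mean()) if n else None,
        "pO2_max_range": (float(acc["pO2_max"].min()), float(acc["pO2_max"].max())) if n else None,
        "SO4_max_range": (float(acc["SO4_max"].min()), float(acc["SO4_max"].max())) if n else None,
    }
    return {"accepted": acc, "stats": stats}
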