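"""Model state, isotope ledger, flux container, and run diagnostics."""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np

from . import constants as cn

#: order of the prognostic variables in the ODE state vector
STATE_FIELDS = ("O_AS", "O_D", "A", "M", "P_S", "P_D", "S_S", "S_D",
                "Ca", "ALK", "G", "C", "PYR", "GYP")
ISOTOPE_FIELDS = ("d34S_sw", "d34S_GYP", "d34S_PYR", "d13C_A", "d13C_G", "d13C_C")
N_STATE = len(STATE_FIELDS) + len(ISOTOPE_FIELDS)


@dataclass
class ReservoirState:
    """Molar inventories of every atmosphere/ocean/sediment reservoir.

    O_AS and A are combined atmosphere + surface-ocean pools; their gaseous
    parts are recovered diagnostically via the gas-exchange partition.
    """

    O_AS: float   # mol O2, atmosphere + surface ocean
    O_D: float    # mol O2, deep ocean
    A: float      # mol C, atmospheric CO2 + surface DIC
    M: float      # mol CH4
    P_S: float    # mol P, surface ocean
    P_D: float    # mol P, deep ocean
    S_S: float    # mol S (SO4), surface ocean
    S_D: float    # mol S (SO4), deep ocean
    Ca: float     # mol Ca2+
    ALK: float    # mol eq alkalinity (surface)
    G: float      # mol C, sedimentary organic carbon
    C: float      # mol C, sedimentary carbonate
    PYR: float    # mol S, sedimentary pyrite
    GYP: float    # mol S, sedimentary gypsum

    def total_sulfur(self) -> float:
        return self.S_S + self.S_D + self.PYR + self.GYP

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in STATE_FIELDS], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "ReservoirState":
        return cls(**{f: float(v) for f, v in zip(STATE_FIELDS, arr)})


@dataclass
class IsotopeLedger:
    """Isotopic compositions (delta notation, permil) of the tracked pools.

    Seawater sulfate carries a single delta34S shared by both ocean boxes;
    all sulfur sources and sinks act on the surface box and circulation
    homogenises the ocean on timescales far shorter than the signals here.
    """

    d34S_sw: float = 0.0    # permil VCDT, oceanic sulfate
    d34S_GYP: float = 0.0   # permil, sedimentary gypsum
    d34S_PYR: float = 0.0   # permil, sedimentary pyrite
    d13C_A: float = 0.0     # permil VPDB, atmosphere + surface DIC
    d13C_G: float = -25.0   # permil, sedimentary organic carbon
    d13C_C: float = 0.0     # permil, sedimentary carbonate

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in ISOTOPE_FIELDS], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "IsotopeLedger":
        return cls(**{f: float(v) for f, v in zip(ISOTOPE_FIELDS, arr)})


#: every instantaneous flux, mol/yr (circulation terms are signed)
FLUX_FIELDS = (
    # sulfur cycle
    "F_vgyp", "F_vpyr", "F_wgyp", "F_wpyr", "F_bgyp", "F_bpyr", "F_cir_S",
    # oxygen cycle
    "F_oph", "F_dgS_O", "F_dgD_O", "F_voc", "F_wo_O", "F_oxi_O", "F_esc",
    "F_cir_O", "F_red",
    # carbon / phosphorus
    "F_wc", "F_ws", "F_bo", "F_bo_P", "F_pp", "F_bc", "F_volc",
)


@dataclass
class FluxSet:
    """Named snapshot of every instantaneous flux (mol/yr)."""
    F_vgyp: float = 0.0
    F_vpyr: float = 0.0
    F_wgyp: float = 0.0
    F_wpyr: float = 0.0
    F_bgyp: float = 0.0
    F_bpyr: float = 0.0
    F_cir_S: float = 0.0
    F_oph: float = 0.0
    F_dgS_O: float = 0.0
    F_dgD_O: float = 0.0
    F_voc: float = 0.0
    F_wo_O: float = 0.0
    F_oxi_O: float = 0.0
    F_esc: float = 0.0
    F_cir_O: float = 0.0
    F_red: float = 0.0
    F_wc: float = 0.0
    F_ws: float = 0.0
    F_bo: float = 0.0
    F_bo_P: float = 0.0
    F_pp: float = 0.0
    F_bc: float = 0.0
    F_volc: float = 0.0

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class RunSummary:
    """Event metrics extracted from a perturbation run."""

    d34S_bpyr_min: float          # permil, minimum instantaneous buried-pyrite d34S
    t_d34S_bpyr_min: float        # yr
    pO2_max: float                # PAL, overshoot maximum
    SO4_max: float                # mM, peak surface sulfate
    pO2_end: float                # PAL at t_end
    SO4_end: float                # mM at t_end
    d34S_sw_end: float            # permil at t_end
    pCO2_end: float               # atm at t_end
    permanent_oxidation: bool     # endpoint pO2 > 1e-6 PAL
    t_end: float = 0.0            # yr
    failed: bool = False
    failure_message: str = ""

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunSummary":
        return cls(**json.loads(Path(path).read_text()))


def validate_state(state: ReservoirState, total_sulfur: float | None = None,
                   rtol: float = 1e-6) -> list[str]:
    """Return a list of invariant violations (empty list = valid state).

    Checks non-negativity of every inventory and, when ``total_sulfur`` is
    given, conservation of S_S + S_D + PYR + GYP.
    """
    violations = []
    for f in STATE_FIELDS:
        v = getattr(state, f)
        if v < 0:
            violations.append(f"{f} negative")
        elif not np.isfinite(v):
            violations.append(f"{f} not finite")
    if total_sulfur is not None and total_sulfur > 0:
        s = state.total_sulfur()
        if abs(s - total_sulfur) > rtol * total_sulfur:
            violations.append(
                f"total sulfur {s:.6e} deviates from {total_sulfur:.6e}")
    return violations


def validate_ledger(ledger: IsotopeLedger) -> list[str]:
    """Sanity bounds on isotope values; |delta| >= 200 permil flags a blow-up."""
    violations = []
    for f in ISOTOPE_FIELDS:
        v = getattr(ledger, f)
        if not np.isfinite(v):
            violations.append(f"{f} not finite")
        elif abs(v) >= 200.0:
            violations.append(f"{f} out of sanity bound (|delta| >= 200)")
    return violations


def save_snapshot(path: str | Path, state: ReservoirState,
                  ledger: IsotopeLedger) -> None:
    """Serialize a state + ledger pair to JSON (bit-exact round trip)."""
    payload = {
        "state": {f: getattr(state, f).hex() if isinstance(getattr(state, f), float)
                  else getattr(state, f) for f in STATE_FIELDS},
        "ledger": {f: getattr(ledger, f).hex() for f in ISOTOPE_FIELDS},
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_snapshot(path: str | Path) -> tuple[ReservoirState, IsotopeLedger]:
    payload = json.loads(Path(path).read_text())
    state = ReservoirState(**{k: float.fromhex(v) for k, v in payload["state"].items()})
    ledger = IsotopeLedger(**{k: float.fromhex(v) for k, v in payload["ledger"].items()})
    return state, ledger
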