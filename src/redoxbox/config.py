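"""Configuration loading, validation, and canned scenario fixtures.

A run configuration is a YAML mapping with optional sections ``scenario``,
``boundary``, ``sulfur``, ``carbon_pox``, ``climate``, ``msr``, ``solver``
and ``output``.  Unknown keys are rejected (typo safety) and every value is
validated by the parameter dataclasses.  An empty file reproduces the
nominal permanent-oxidation scenario (pCO2_init = 0.7 atm, F_red = 0.075
Tmol O2-eq/yr).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .params import (BoundaryConditions, ClimateParams, CPOParams, MSRParams,
                     ParameterError, Scenario, SolverSettings, SulfurParams)


class ConfigError(ValueError):
    """Invalid configuration file (unknown key or out-of-range value)."""


_SECTION_TYPES = {
    "sulfur": SulfurParams,
    "carbon_pox": CPOParams,
    "climate": ClimateParams,
    "msr": MSRParams,
    "solver": SolverSettings,
}

_BOUNDARY_KEYS = ("F_red_Tmol", "luminosity_rel", "weatherability", "f_a")
_SCENARIO_KEYS = ("pCO2_init", "PYR_init_1e18_mol", "t_end_yr", "rng_seed")
_OUTPUT_KEYS = ("prefix", "log_level")


@dataclass
class RunConfig:
    """Validated configuration with provenance of defaulted values."""

    scenario: Scenario
    output_prefix: str = "redoxbox"
    log_level: str = "INFO"
    defaulted: list = field(default_factory=list)  # keys filled from defaults


def _build_section(cls, data: dict, name: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in section {name!r}; "
                          f"valid keys: {sorted(valid)}")
    try:
        return cls(**data)
    except (ParameterError, TypeError) as exc:
        raise ConfigError(f"invalid value in section {name!r}: {exc}") from exc


def load_config(path: str | Path | None = None,
                text: str | None = None) -> RunConfig:
    """Load and validate a YAML configuration.

    Either ``path`` or ``text`` must be given; an empty document yields the
    all-defaults nominal scenario.  Raises :class:`ConfigError` naming the
    offending key on any unknown or out-of-range entry.
    """
    if text is None:
        if path is None:
            raise ValueError("either path or text is required")
        text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ConfigError("top level of the config must be a mapping")
    known_sections = set(_SECTION_TYPES) | {"scenario", "boundary", "output"}
    unknown = set(raw) - known_sections
    if unknown:
        raise ConfigError(f"unknown section(s) {sorted(unknown)}; "
                          f"valid sections: {sorted(known_sections)}")

    defaulted = []
    parts = {}
    for name, cls in _SECTION_TYPES.items():
        data = raw.get(name, {}) or {}
        if not data:
            defaulted.append(name)
        parts[name] = _build_section(cls, data, name)

    bdata = dict(raw.get("boundary", {}) or {})
    unknown = set(bdata) - set(_BOUNDARY_KEYS)
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in section 'boundary'")
    bc_kwargs = {
        "sulfur": parts["sulfur"], "cpo": parts["carbon_pox"],
        "climate": parts["climate"],
    }
    if "F_red_Tmol" in bdata:
        bc_kwargs["F_red"] = float(bdata["F_red_Tmol"]) * 1e12
    for key in ("luminosity_rel", "weatherability", "f_a"):
        if key in bdata:
            bc_kwargs[key] = float(bdata[key])
    try:
        bc = BoundaryConditions(**bc_kwargs)
    except ParameterError as exc:
        raise ConfigError(f"invalid value in section 'boundary': {exc}") from exc

    sdata = dict(raw.get("scenario", {}) or {})
    unknown = set(sdata) - set(_SCENARIO_KEYS)
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in section 'scenario'")
    sc_kwargs = {"bc": bc, "msr": parts["msr"], "solver": parts["solver"]}
    if "pCO2_init" in sdata:
        sc_kwargs["pCO2_init"] = float(sdata["pCO2_init"])
    else:
        defaulted.append("scenario.pCO2_init")
    if "PYR_init_1e18_mol" in sdata:
        sc_kwargs["PYR_init"] = float(sdata["PYR_init_1e18_mol"]) * 1e18
    if "t_end_yr" in sdata:
        sc_kwargs["t_end"] = float(sdata["t_end_yr"])
    if "rng_seed" in sdata:
        sc_kwargs["rng_seed"] = int(sdata["rng_seed"])
    try:
        scenario = Scenario(**sc_kwargs)
    except ParameterError as exc:
        raise ConfigError(f"invalid value in section 'scenario': {exc}") from exc

    odata = dict(raw.get("output", {}) or {})
    unknown = set(odata) - set(_OUTPUT_KEYS)
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in section 'output'")
    return RunConfig(scenario=scenario,
                     output_prefix=str(odata.get("prefix", "redoxbox")),
                     log_level=str(odata.get("log_level", "INFO")),
                     defaulted=defaulted)


#: pCO2_init grid (atm) x F_red (Tmol O2-eq/yr) of the nominal experiment design
NOMINAL_PCO2_GRID = (0.1, 0.15, 0.2, 0.5, 0.7)
NOMINAL_FRED_TMOL = (0.075, 0.3)


def make_fixtures(kind: str, seed: int = 0) -> list[Scenario]:
    """Canned scenario sets for tests and quick experiments.

    ``nominal_grid``: the 5 x 2 design of pCO2_init and F_red values;
    ``mc_smoke``: 50 Monte Carlo draws from the ensemble distributions;
    ``degenerate``: null perturbation and edge-case scenarios.
    """
    if kind == "nominal_grid":
        out = []
        for fred in NOMINAL_FRED_TMOL:
            bc = BoundaryConditions(F_red=fred * 1e12)
            for pco2 in NOMINAL_PCO2_GRID:
                out.append(Scenario(pCO2_init=pco2, bc=bc, rng_seed=seed))
        return out
    if kind == "mc_smoke":
        from .montecarlo import sample_parameters
        bc = BoundaryConditions()
        return [Scenario(pCO2_init=s.pCO2_init, PYR_init=s.PYR_init,
                         msr=MSRParams(Delta_max=s.Delta_max, K_MSR=s.K_MSR),
                         bc=bc, rng_seed=seed)
                for s in sample_parameters(50, seed)]
    if kind == "degenerate":
        bc = BoundaryConditions()
        return [
            Scenario(pCO2_init=0.0873, bc=bc, rng_seed=seed),  # ~null perturbation
            Scenario(pCO2_init=0.1, PYR_init=50e18, bc=bc, rng_seed=seed),
            Scenario(pCO2_init=0.7, PYR_init=50e18, bc=bc,
                     msr=MSRParams(Delta_max=10.0, K_MSR=2.0), rng_seed=seed),
        ]
    raise ConfigError(f"unknown fixture kind {kind!r}; "
                      "choose from nominal_grid, mc_smoke, degenerate")
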