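"""Model parameter handling.

All kinetic constants are loaded from a flat JSON file in which every entry
carries an explicit unit string, e.g. ``{"r_c": {"value": 18.0, "units": "1/s"}}``.
Concentrations are micromolar (uM) and times are seconds throughout the
package; the unit strings in the file exist to make that convention explicit
and are validated on load.

The default file shipped with the package (``data/parameters.json``) holds the
kinetics of the glutamate-driven three-variable astrocyte model (G-ChI:
cytosolic Ca2+, IP3R gating variable h, cytosolic IP3) in its
frequency-modulation (FM) encoding regime, together with the nonlinear
gap-junction coupling and the Tsodyks-Markram equivalent-synapse constants.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, fields
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

__all__ = [
    "GChIParams",
    "GJCParams",
    "TMParams",
    "ParameterError",
    "load_parameters",
    "default_parameter_path",
]


class ParameterError(ValueError):
    """Raised when a parameter file is missing symbols or fails validation."""


# symbol -> expected unit string; doubles as the schema of required names
_SCHEMA = {
    # CICR / ER fluxes
    "r_c": "1/s",          # max IP3R channel permeability
    "r_l": "1/s",          # ER leak permeability
    "v_er": "uM/s",        # SERCA max uptake rate
    "k_er": "uM",          # SERCA Ca affinity
    "c_tot": "uM",         # total free Ca per unit cytosolic volume
    "rho_er": "1",         # ER-to-cytosol volume ratio
    # IP3R gating (Li-Rinzel constants)
    "d1": "uM",
    "d2": "uM",
    "d3": "uM",
    "d5": "uM",
    "o2": "1/(uM s)",      # Ca inactivation binding rate of IP3R
    # PLCbeta (mGluR-driven IP3 production)
    "o_beta": "uM/s",
    "k_r": "uM",           # glutamate affinity of mGluR
    "k_p": "uM",           # Ca-PKC-dependent inhibition scale
    "k_pi": "uM",          # Ca affinity of PKC
    "n_glu": "1",          # Hill exponent on glutamate
    # PLCdelta (Ca-driven IP3 production)
    "o_delta": "uM/s",
    "kappa_delta": "uM",   # IP3 inhibition of PLCdelta
    "k_delta": "uM",       # Ca affinity of PLCdelta
    # IP3 degradation
    "o_3k": "uM/s",
    "k_d": "uM",           # Ca affinity of IP3-3K (via CaMKII)
    "k_3": "uM",           # IP3 affinity of IP3-3K
    "omega_5p": "1/s",     # linear IP-5P degradation rate
    # Gap-junction IP3 exchange
    "f_gjc": "uM/s",       # coupling strength (saturating flux)
    "i_theta": "uM",       # threshold IP3 gradient
    "omega_i": "uM",       # sigmoid stiffness
    # Tsodyks-Markram equivalent synapse
    "u0": "1",             # basal release probability
    "omega_f": "1/s",      # facilitation decay rate
    "omega_d": "1/s",      # depression recovery rate
    "omega_c": "1/s",      # glutamate clearance rate
    "g_release": "uM",     # glutamate added per unit released fraction (rho_c * Y_T)
}


@dataclass(frozen=True)
class GChIParams:
    """Kinetics of one astrocyte (all concentrations uM, rates per second)."""

    r_c: float
    r_l: float
    v_er: float
    k_er: float
    c_tot: float
    rho_er: float
    d1: float
    d2: float
    d3: float
    d5: float
    o2: float
    o_beta: float
    k_r: float
    k_p: float
    k_pi: float
    n_glu: float
    o_delta: float
    kappa_delta: float
    k_delta: float
    o_3k: float
    k_d: float
    k_3: float
    omega_5p: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v) or v <= 0:
                raise ParameterError(f"GChI parameter {f.name} must be finite and > 0, got {v}")


@dataclass(frozen=True)
class GJCParams:
    """Nonlinear gap-junction IP3 exchange: saturating flux F, threshold
    gradient I_theta and sigmoid stiffness omega_I."""

    f_gjc: float
    i_theta: float
    omega_i: float

    def __post_init__(self) -> None:
        if self.f_gjc < 0:
            raise ParameterError("f_gjc must be >= 0")
        if self.omega_i <= 0:
            raise ParameterError("omega_i must be > 0")
        if self.i_theta < 0:
            raise ParameterError("i_theta must be >= 0")


@dataclass(frozen=True)
class TMParams:
    """Tsodyks-Markram equivalent synapse with exponential glutamate clearance."""

    u0: float
    omega_f: float
    omega_d: float
    omega_c: float
    g_release: float

    def __post_init__(self) -> None:
        if not 0 <= self.u0 <= 1:
            raise ParameterError("u0 must lie in [0, 1]")
        for name in ("omega_f", "omega_d", "omega_c", "g_release"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")


def default_parameter_path() -> Path:
    """Path of the parameter file shipped with the package."""
    return Path(str(resources.files("astrofilter").joinpath("data/parameters.json")))


def load_parameters(path: str | Path) -> tuple[GChIParams, GJCParams, TMParams]:
    """Load and validate a parameter file.

    The file must contain every symbol of the schema with the expected unit
    string.  There are deliberately no in-code defaults: simulations refuse to
    run without an explicit, auditable parameter file.
    """
    raw: Mapping[str, Any] = json.loads(Path(path).read_text())
    missing = sorted(set(_SCHEMA) - set(raw))
    if missing:
        raise ParameterError(f"parameter file {path} is missing symbols: {missing}")
    values: dict[str, float] = {}
    for name, expected_units in _SCHEMA.items():
        entry = raw[name]
        if not isinstance(entry, Mapping) or "value" not in entry or "units" not in entry:
            raise ParameterError(f"{name}: each entry needs 'value' and 'units'")
        if entry["units"] != expected_units:
            raise ParameterError(
                f"{name}: expected units {expected_units!r}, got {entry['units']!r}"
            )
        values[name] = float(entry["value"])

    gchi = GChIParams(**{f.name: values[f.name] for f in fields(GChIParams)})
    gjc = GJCParams(f_gjc=values["f_gjc"], i_theta=values["i_theta"], omega_i=values["omega_i"])
    tm = TMParams(
        u0=values["u0"],
        omega_f=values["omega_f"],
        omega_d=values["omega_d"],
        omega_c=values["omega_c"],
        g_release=values["g_release"],
    )
    return gchi, gjc, tm
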