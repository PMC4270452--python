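"""Single-astrocyte G-ChI right-hand side and gap-junction IP3 flux.

The G-ChI model describes one perfectly stirred astrocyte by three variables:
C, the cytosolic Ca2+ concentration (uM); h, the fraction of IP3 receptor
channels not yet inactivated by Ca2+; and I, the cytosolic IP3 concentration
(uM).  Ca2+ dynamics follow calcium-induced calcium release (CICR) from the
ER through IP3R channels (flux J_C), a passive ER leak (J_L) and SERCA
reuptake (J_P).  IP3 is produced by glutamate-activated PLCbeta (J_beta) and
Ca-activated PLCdelta (J_delta), and degraded by IP3-3K (J_3K, Ca-dependent)
and IP-5P (J_5P, linear).  Coupled astrocytes additionally exchange IP3
through gap-junction channels with a sigmoidal, gradient-thresholded flux.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .params import GChIParams, GJCParams

__all__ = ["AstrocyteState", "flux_terms", "gjc_flux", "rhs", "pack_state", "unpack_state"]

FLUX_NAMES = ("J_C", "J_L", "J_P", "J_beta", "J_delta", "J_3K", "J_5P")


@dataclass(frozen=True)
class AstrocyteState:
    """State of one astrocyte: Ca2+ (uM), IP3R availability h, IP3 (uM)."""

    C: float
    h: float
    I: float

    def __post_init__(self) -> None:
        if self.C < 0 or self.I < 0 or not 0 <= self.h <= 1:
            raise ValueError(f"invalid astrocyte state {self}")

    def as_array(self) -> np.ndarray:
        return np.array([self.C, self.h, self.I], dtype=float)


def _hill(x: np.ndarray | float, k: float, n: float = 1.0) -> np.ndarray | float:
    xn = x**n if n != 1.0 else x
    return xn / (xn + k**n)


def flux_terms(
    state: AstrocyteState | Mapping[str, np.ndarray],
    G: float | np.ndarray,
    params: GChIParams,
) -> dict[str, np.ndarray | float]:
    """Evaluate the seven fluxes of the model at a state (scalar or arrays).

    Sign conventions: J_C and J_L fill the cytosol with Ca2+, J_P empties it;
    J_beta and J_delta produce IP3, J_3K and J_5P degrade it.
    ``state`` may be an :class:`AstrocyteState` or a mapping with arrays under
    keys ``C``, ``h``, ``I`` for vectorised evaluation along a trajectory.
    """
    if isinstance(state, AstrocyteState):
        C, h, I = state.C, state.h, state.I
    else:
        C, h, I = state["C"], state["h"], state["I"]
    p = params

    # free ER Ca expressed per cytosolic volume: c_tot - (1 + rho_er) C
    er_drive = p.c_tot - (1.0 + p.rho_er) * C
    m_inf = _hill(I, p.d1)
    n_inf = _hill(C, p.d5)
    j_c = p.r_c * (m_inf * n_inf * h) ** 3 * er_drive
    j_l = p.r_l * er_drive
    j_p = p.v_er * _hill(C, p.k_er, 2.0)

    # glutamate affinity of PLCbeta is lowered by Ca-dependent (PKC) feedback
    k_gamma = p.k_r * (1.0 + (p.k_p / p.k_r) * _hill(C, p.k_pi))
    j_beta = p.o_beta * _hill(G, k_gamma, p.n_glu)
    j_delta = p.o_delta / (1.0 + I / p.kappa_delta) * _hill(C, p.k_delta, 2.0)
    j_3k = p.o_3k * _hill(C, p.k_d, 4.0) * _hill(I, p.k_3)
    j_5p = p.omega_5p * I

    out = dict(zip(FLUX_NAMES, (j_c, j_l, j_p, j_beta, j_delta, j_3k, j_5p)))
    for name, v in out.items():
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite flux {name} at C={C}, h={h}, I={I}, G={G}")
    return out


def h_kinetics(C, h, I, params: GChIParams):
    """dh/dt: Ca-dependent IP3R inactivation with IP3-dependent recovery."""
    q2 = params.d2 * (I + params.d1) / (I + params.d3)
    return params.o2 * (q2 * (1.0 - h) - C * h)


def gjc_flux(
    i_i: float | np.ndarray, i_j: float | np.ndarray, gjc: GJCParams
) -> float | np.ndarray:
    """IP3 flux into cell i from cell j (uM/s).

    Sigmoid of the absolute IP3 gradient, directed down-gradient:
    ~0 for gradients well below the threshold ``i_theta``, ~F/2 at the
    threshold, saturating at F for large gradients.  Exactly antisymmetric:
    gjc_flux(a, b) == -gjc_flux(b, a).

    The sigmoid tail value at zero gradient, tanh(-i_theta/omega_i), is
    subtracted so that the flux is exactly zero and continuous at delta = 0
    (the raw sign(delta)-gated sigmoid has a jump there that stalls adaptive
    ODE solvers once coupled cells synchronise).  For i_theta >= 3 omega_i
    the correction is below 0.5% of F everywhere.
    """
    delta = np.asarray(i_j, dtype=float) - np.asarray(i_i, dtype=float)
    tail = np.tanh(gjc.i_theta / gjc.omega_i)
    mag = 0.5 * gjc.f_gjc * (np.tanh((np.abs(delta) - gjc.i_theta) / gjc.omega_i) + tail)
    out = np.sign(delta) * mag
    return float(out) if out.ndim == 0 else out


def pack_state(C: np.ndarray, h: np.ndarray, I: np.ndarray) -> np.ndarray:
    return np.concatenate([C, h, I])


def unpack_state(y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = y.size // 3
    return y[:n], y[n : 2 * n], y[2 * n :]


def rhs(
    y: np.ndarray,
    g_inputs: np.ndarray,
    edges: np.ndarray,
    gchi: GChIParams,
    gjc: GJCParams,
) -> np.ndarray:
    """Network right-hand side over packed state ``y = [C..., h..., I...]``.

    ``g_inputs`` holds the per-cell extracellular glutamate concentration
    (zero for cells without a stimulated synapse, which encodes the a=0/1
    indicator), ``edges`` is an (m, 2) integer array of gap-junction pairs
    (each undirected pair listed once).
    """
    C, h, I = unpack_state(y)
    n = C.size
    if g_inputs.shape != (n,):
        raise ValueError("g_inputs size does not match state")
    fl = flux_terms({"C": C, "h": h, "I": I}, g_inputs, gchi)
    dC = fl["J_C"] + fl["J_L"] - fl["J_P"]
    dh = h_kinetics(C, h, I, gchi)
    dI = fl["J_beta"] + fl["J_delta"] - fl["J_3K"] - fl["J_5P"]
    if edges.size:
        ia, ja = edges[:, 0], edges[:, 1]
        j_pair = gjc_flux(I[ia], I[ja], gjc)  # flux into ia from ja
        dI = dI.copy()
        np.add.at(dI, ia, j_pair)
        np.add.at(dI, ja, -j_pair)
    return pack_state(dC, dh, dI)
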