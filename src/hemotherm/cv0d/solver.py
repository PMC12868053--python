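"""RK4 integration of the 0-D loop and element-pressure diagnostics."""
from __future__ import annotations

import numpy as np

from .. import _kernels as K
from ..errors import NumericsError, ValidationError
from .circuit import Circuit0DState, CircuitSystem

P_BLOWUP = 1.0e6  # Pa


def rk4_step(system: CircuitSystem, state: Circuit0DState, dt: float,
             Q_in: np.ndarray, P_root: float) -> Circuit0DState:
    """Advance the 0-D state by one RK4 step with fixed boundary values.

    ``Q_in`` holds the terminal-artery inflow of each peripheral
    circulation; ``P_root`` is the aortic-root pressure seen by the
    aortic valve."""
    if dt <= 0:
        raise ValidationError("dt must be > 0")
    new = state.copy()
    new.phase = K.rk4_0d_step(new.y, new.phase, dt, system.period, system.n_circ,
                              system.pc, system.pr, system.vc_par, system.vc_idx,
                              system.hp, system.rho_g_dh,
                              np.asarray(Q_in, dtype=float), float(P_root))
    if state.phase > new.phase:
        new.cycle = state.cycle + 1
    if not np.all(np.isfinite(new.y)):
        raise NumericsError("0-D state became non-finite")
    p = element_pressures(system, new)
    worst = max(abs(v) for v in p.values())
    if worst > P_BLOWUP:
        raise NumericsError(f"0-D pressure blow-up: |P| reached {worst:.3g} Pa")
    return new


def rhs(system: CircuitSystem, state: Circuit0DState,
        Q_in: np.ndarray, P_root: float) -> np.ndarray:
    """Raw time derivative of the state vector (for tests/diagnostics)."""
    dy = np.zeros_like(state.y)
    K.cv0d_rhs(state.y, dy, state.phase, system.n_circ, system.pc, system.pr,
               system.vc_par, system.vc_idx, system.hp, system.rho_g_dh,
               np.asarray(Q_in, dtype=float), float(P_root))
    return dy


def element_pressures(system: CircuitSystem, state: Circuit0DState) -> dict[str, float]:
    """Pressures [Pa] of the monitored lumped elements."""
    y = state.y
    hp = system.hp
    e_a = K.activation_atrium(state.phase, hp[12], hp[13], hp[14])
    e_v = K.activation_ventricle(state.phase, hp[15], hp[16], hp[17])
    out: dict[str, float] = {}
    for k, name in enumerate(("svc", "ivc", "avc")):
        out[name] = y[system.idx_V_vc(k)] / system.vc_par[k, 0]
    v = [y[system.idx_V_heart(k)] for k in range(6)]
    out["right_atrium"] = (hp[0] * e_a + hp[4]) * v[0]
    out["right_ventricle"] = (hp[1] * e_v + hp[5]) * v[1]
    out["pulmonary_artery"] = hp[30] * hp[32] * np.exp(min(v[2] / hp[32], 50.0))
    out["pulmonary_vein"] = hp[31] * hp[33] * np.exp(min(v[3] / hp[33], 50.0))
    out["left_atrium"] = (hp[2] * e_a + hp[6]) * v[4]
    out["left_ventricle"] = (hp[3] * e_v + hp[7]) * v[5]
    n = system.n_circ
    out["arteriole_nodes_max"] = float(np.max(y[:n] / system.pc[:, 1]))
    out["veins_min"] = float(np.min(y[9 * n:10 * n] / system.pc[:, 2]))
    return out
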