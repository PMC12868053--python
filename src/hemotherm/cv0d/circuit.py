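"""Assembly of the lumped-parameter closed loop into flat solver arrays.

Topology: every terminal artery drains into its four-route peripheral
circulation; collecting veins join the superior / inferior / abdominal
vena cava (inferior drains through the abdominal segment); the venae
cavae fill the right atrium; right ventricle -> pulmonary artery ->
pulmonary vein -> left atrium -> left ventricle -> aortic valve (the
1-D root).  State layout documented in ``_kernels``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .. import _kernels as K
from ..errors import CouplingError
from ..parameters.types import ROUTES, ParameterSet
from ..units import MMHG_TO_PA

VC_ORDER = ("superior", "inferior", "abdominal")
CHAMBER_ORDER = ("right_atrium", "right_ventricle", "left_atrium", "left_ventricle")
VALVE_ORDER = ("tricuspid", "pulmonary_valve", "mitral", "aortic")


@dataclass
class Circuit0DState:
    """Flat state vector plus cardiac phase/cycle bookkeeping."""

    y: np.ndarray
    phase: float = 0.5
    cycle: int = 0

    def copy(self) -> "Circuit0DState":
        return Circuit0DState(self.y.copy(), self.phase, self.cycle)


@dataclass
class CircuitSystem:
    """Packed parameter arrays for the 0-D kernels."""

    circ_ids: list[int]                      # terminal artery id per circulation
    pc: np.ndarray                           # (Np, 5): R_da, C_al, C_v, R_v, L_v
    pr: np.ndarray                           # (Np, 4, 8) per-route RLC
    vc_par: np.ndarray                       # (3, 3): C, R, L
    vc_idx: np.ndarray                       # (Np,) vena cava index per circulation
    hp: np.ndarray                           # heart/pulmonary parameter vector
    rho_g_dh: np.ndarray                     # (Np,) gravity head of the vein element
    period: float
    init_pressures: dict = field(default_factory=dict)

    @property
    def n_circ(self) -> int:
        return len(self.circ_ids)

    @property
    def n_state(self) -> int:
        return 23 * self.n_circ + K.N_EXTRA

    # -- index helpers -----------------------------------------------------
    def idx_V_al(self, i): return i
    def idx_V_cp(self, i, r): return self.n_circ + 4 * i + r
    def idx_V_vn(self, i, r): return 5 * self.n_circ + 4 * i + r
    def idx_V_v(self, i): return 9 * self.n_circ + i
    def idx_Q_al(self, i, r): return 10 * self.n_circ + 4 * i + r
    def idx_Q_cp(self, i, r): return 14 * self.n_circ + 4 * i + r
    def idx_Q_vn(self, i, r): return 18 * self.n_circ + 4 * i + r
    def idx_Q_v(self, i): return 22 * self.n_circ + i

    @property
    def o_vc(self): return 23 * self.n_circ

    def idx_V_vc(self, k): return self.o_vc + k
    def idx_Q_vc(self, k): return self.o_vc + 3 + k
    def idx_V_heart(self, k): return self.o_vc + 6 + k      # ra, rv, pa, pv, la, lv
    def idx_Q_heart(self, k): return self.o_vc + 12 + k     # tri, pulv, pul, pvla, mit, aov

    @property
    def idx_Q_aov(self): return self.o_vc + 17

    def route_flows(self, state: Circuit0DState) -> np.ndarray:
        """Arteriole-branch flows (Np, 4) [m3/s]."""
        o = 10 * self.n_circ
        return state.y[o:o + 4 * self.n_circ].reshape(self.n_circ, 4).copy()

    def total_volume(self, state: Circuit0DState) -> float:
        y = state.y
        n = self.n_circ
        return float(np.sum(y[:10 * n]) + np.sum(y[self.o_vc:self.o_vc + 3])
                     + np.sum(y[self.o_vc + 6:self.o_vc + 12]))


def build_circuit(params: ParameterSet, circ_order: list[int]) -> CircuitSystem:
    """Pack the ParameterSet circuits in the terminal order of the 1-D tree."""
    missing = [i for i in circ_order if i not in params.peripherals]
    if missing:
        raise CouplingError(f"no peripheral circulation for terminal arteries {missing}")
    n = len(circ_order)
    pc = np.zeros((n, 5))
    pr = np.zeros((n, 4, 8))
    vc_idx = np.zeros(n, dtype=np.int64)
    for i, aid in enumerate(circ_order):
        c = params.peripherals[aid]
        pc[i] = (c.R_da, c.C_al, c.C_v, c.R_v, c.L_v)
        for r, route in enumerate(ROUTES):
            pr[i, r] = (c.R_al[route], c.L_al[route], c.R_cp[route], c.L_cp[route],
                        c.C_cp[route], c.R_vn[route], c.L_vn[route], c.C_vn[route])
        vc_idx[i] = VC_ORDER.index(c.vena_cava)

    vc_par = np.array([[params.vena_cavae[k]["C"], params.vena_cavae[k]["R"],
                        params.vena_cavae[k]["L"]] for k in VC_ORDER])

    hp = np.zeros(40)
    for k, name in enumerate(CHAMBER_ORDER):
        ch = params.chambers[name]
        hp[k] = ch.E_A
        hp[4 + k] = ch.E_B
        hp[8 + k] = ch.S
    at = params.chambers["right_atrium"]
    vt = params.chambers["right_ventricle"]
    hp[12:15] = (at.T_cs, at.T_cp, at.T_rp)
    hp[15:18] = (vt.T_cs, vt.T_cp, vt.T_rp)
    for k, name in enumerate(VALVE_ORDER):
        v = params.valves[name]
        hp[18 + k] = v.R
        hp[22 + k] = v.B
        hp[26 + k] = v.L
    pa = params.pulmonary["pulmonary_artery"]
    pv = params.pulmonary["pulmonary_vein"]
    hp[30:32] = (pa.E0, pv.E0)
    hp[32:34] = (pa.Phi, pv.Phi)
    hp[34:36] = (pa.S, pv.S)
    hp[36] = params.pulmonary_links["pa_to_pv"]["R"]
    hp[37] = params.pulmonary_links["pa_to_pv"]["L"]
    hp[38] = params.pulmonary_links["pv_to_la"]["R"]
    hp[39] = params.pulmonary_links["pv_to_la"]["L"]

    return CircuitSystem(
        circ_ids=list(circ_order),
        pc=pc, pr=pr, vc_par=vc_par, vc_idx=vc_idx, hp=hp,
        rho_g_dh=np.zeros(n),
        period=params.heart_period,
        init_pressures=dict(params.circuit_defaults["reference_pressures_mmHg"]),
    )


def initial_state(system: CircuitSystem, phase: float = 0.5) -> Circuit0DState:
    """Volumes at the reference (diastolic-like) pressures, zero flows.

    Chambers start on their passive filling line; pulmonary compartments
    at their reference operating pressures."""
    p = {k: float(v) * MMHG_TO_PA for k, v in system.init_pressures.items()}
    n = system.n_circ
    y = np.zeros(system.n_state)
    for i in range(n):
        y[system.idx_V_al(i)] = system.pc[i, 1] * p["arteriole_node"]
        y[system.idx_V_v(i)] = system.pc[i, 2] * p["vein"]
        for r in range(4):
            y[system.idx_V_cp(i, r)] = system.pr[i, r, 4] * p["capillary"]
            y[system.idx_V_vn(i, r)] = system.pr[i, r, 7] * p["venule"]
    for k in range(3):
        y[system.idx_V_vc(k)] = system.vc_par[k, 0] * p["vena_cava"]
    hp = system.hp
    p_ch = np.array([4.0, 5.0, 8.0, 8.0]) * MMHG_TO_PA  # ra, rv, la, lv passive
    y[system.idx_V_heart(0)] = p_ch[0] / hp[4]
    y[system.idx_V_heart(1)] = p_ch[1] / hp[5]
    y[system.idx_V_heart(4)] = p_ch[2] / hp[6]
    y[system.idx_V_heart(5)] = p_ch[3] / hp[7]
    p_pul = np.array([15.0, 8.0]) * MMHG_TO_PA
    y[system.idx_V_heart(2)] = hp[32] * np.log(p_pul[0] / (hp[30] * hp[32]))
    y[system.idx_V_heart(3)] = hp[33] * np.log(p_pul[1] / (hp[31] * hp[33]))
    return Circuit0DState(y=y, phase=phase, cycle=0)
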