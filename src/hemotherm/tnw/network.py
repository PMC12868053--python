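"""The multi-segment thermal network and its implicit time stepper.

Nodes: tissue compartments (with heat capacity), artery/vein nodes per
segment, and superficial veins in the limbs.  Piston-flow segments
(neck, abdomen, upper/lower arms, thighs, legs) treat their artery and
vein as quasi-steady exchangers traversed by the through-flow;
head/hand/foot vessels and all superficial veins are perfectly mixed
pools.  The whole system is linear in the temperatures for given
flows, so the implicit step is a single dense solve and is
unconditionally stable for any dt.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ..errors import CouplingError, NumericsError, ValidationError
from ..parameters.types import ParameterSet
from .environment import EnvironmentSpec, respiration_losses, skin_latent_loss
from .exchange import counterflow_coeff, piston_coeff

PISTON_BASES = {"neck", "abdomen", "upper_arm", "lower_arm", "thigh", "leg"}
POOL_BASES = {"head", "hand", "foot"}
LIMB_BASES = {"upper_arm", "lower_arm", "hand", "thigh", "leg", "foot"}

#: segment whose artery node feeds each segment's artery ("left_heart" = aorta)
ARTERY_PARENT = {
    "neck": "left_heart", "head": "neck", "abdomen": "left_heart",
    "thigh_r": "abdomen", "leg_r": "thigh_r", "foot_r": "leg_r",
    "thigh_l": "abdomen", "leg_l": "thigh_l", "foot_l": "leg_l",
    "upper_arm_r": "left_heart", "lower_arm_r": "upper_arm_r", "hand_r": "lower_arm_r",
    "upper_arm_l": "left_heart", "lower_arm_l": "upper_arm_l", "hand_l": "lower_arm_l",
}

#: distal segments whose (deep) veins drain into each segment's vein
VEIN_DISTAL = {
    "neck": ["head"], "abdomen": ["thigh_r", "thigh_l"],
    "thigh_r": ["leg_r"], "leg_r": ["foot_r"],
    "thigh_l": ["leg_l"], "leg_l": ["foot_l"],
    "upper_arm_r": ["lower_arm_r"], "lower_arm_r": ["hand_r"],
    "upper_arm_l": ["lower_arm_l"], "lower_arm_l": ["hand_l"],
    "head": [], "hand_r": [], "hand_l": [], "foot_r": [], "foot_l": [],
}

#: superficial-vein chains (limbs only); arm chains end at the right heart,
#: leg chains join the abdominal deep vein
SV_DISTAL = {
    "upper_arm_r": "lower_arm_r", "lower_arm_r": "hand_r", "hand_r": None,
    "upper_arm_l": "lower_arm_l", "lower_arm_l": "hand_l", "hand_l": None,
    "thigh_r": "leg_r", "leg_r": "foot_r", "foot_r": None,
    "thigh_l": "leg_l", "leg_l": "foot_l", "foot_l": None,
}

#: segments whose deep vein (and upper-arm superficial vein) returns to the
#: right heart
RETURN_TO_HEART = ["neck", "abdomen", "upper_arm_r", "upper_arm_l"]

MASS_TOL = 1e-9


def _base(segment: str) -> str:
    return segment.rsplit("_", 1)[0] if segment.endswith(("_r", "_l")) else segment


@dataclass
class FlowRouting:
    """Per-edge blood flows of the thermal network [m3/s].

    ``comp_inflow`` holds the perfusion of every tissue compartment
    (negative values are clamped to zero).  Through-flows of artery,
    vein and superficial-vein nodes are derived from these by
    conservation; ``sv_fraction`` diverts that fraction of limb
    compartment outflow through the superficial vein.
    """

    comp_inflow: dict[tuple[str, str], float]
    sv_fraction: dict[str, float] = field(default_factory=dict)
    artery_flow: dict[str, float] = field(default_factory=dict)
    vein_flow: dict[str, float] = field(default_factory=dict)
    sv_flow: dict[str, float] = field(default_factory=dict)
    vein_comp_in: dict[str, float] = field(default_factory=dict)
    sv_comp_in: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.comp_inflow = {k: max(float(v), 0.0) for k, v in self.comp_inflow.items()}
        self._derive()

    def _seg_comp_total(self, seg: str) -> float:
        return sum(v for (s, _), v in self.comp_inflow.items() if s == seg)

    def _derive(self) -> None:
        def artery_subtree(seg: str) -> float:
            total = self._seg_comp_total(seg)
            for child, parent in ARTERY_PARENT.items():
                if parent == seg:
                    total += artery_subtree(child)
            return total

        for seg in ARTERY_PARENT:
            self.artery_flow[seg] = artery_subtree(seg)

        for seg in VEIN_DISTAL:
            f_sv = self.sv_fraction.get(seg, 0.0) if _base(seg) in LIMB_BASES else 0.0
            if not 0.0 <= f_sv < 1.0:
                raise ValidationError(f"superficial-vein fraction for {seg} must be in [0,1)")
            comp = self._seg_comp_total(seg)
            self.vein_comp_in[seg] = comp * (1.0 - f_sv)
            self.sv_comp_in[seg] = comp * f_sv

        def sv_chain(seg: str) -> float:
            total = self.sv_comp_in.get(seg, 0.0)
            distal = SV_DISTAL.get(seg)
            if distal is not None:
                total += sv_chain(distal)
            return total

        for seg in SV_DISTAL:
            self.sv_flow[seg] = sv_chain(seg)

        def vein_chain(seg: str) -> float:
            total = self.vein_comp_in[seg]
            for d in VEIN_DISTAL[seg]:
                total += vein_chain(d)
            if seg == "abdomen":
                total += self.sv_flow.get("thigh_r", 0.0) + self.sv_flow.get("thigh_l", 0.0)
            return total

        for seg in VEIN_DISTAL:
            self.vein_flow[seg] = vein_chain(seg)

    @property
    def cardiac_output(self) -> float:
        return sum(self.comp_inflow.values())

    def check_conservation(self) -> None:
        """At every vessel node, inflow must equal outflow (relative 1e-9)."""
        for seg in VEIN_DISTAL:
            inflow = self.vein_comp_in[seg] + sum(self.vein_flow[d] for d in VEIN_DISTAL[seg])
            if seg == "abdomen":
                inflow += self.sv_flow.get("thigh_r", 0.0) + self.sv_flow.get("thigh_l", 0.0)
            if abs(inflow - self.vein_flow[seg]) > MASS_TOL * max(inflow, 1e-12):
                raise ValidationError(f"vein node {seg}: inflow != outflow")
        returns = sum(self.vein_flow[s] for s in RETURN_TO_HEART)
        returns += self.sv_flow.get("upper_arm_r", 0.0) + self.sv_flow.get("upper_arm_l", 0.0)
        returns += self._seg_comp_total("chest")
        if abs(returns - self.cardiac_output) > 1e-6 * max(self.cardiac_output, 1e-12):
            raise ValidationError("venous return does not match cardiac output")


@dataclass
class ThermalState:
    """Temperatures [degC] of every node plus the simulation clock [s]."""

    temps: np.ndarray
    index: dict[tuple[str, str], int]
    time: float = 0.0

    def __getitem__(self, key: tuple[str, str]) -> float:
        return float(self.temps[self.index[key]])

    def copy(self) -> "ThermalState":
        return ThermalState(self.temps.copy(), self.index, self.time)

    def as_dict(self) -> dict[tuple[str, str], float]:
        return {k: float(self.temps[i]) for k, i in self.index.items()}


class ThermalNetwork:
    """Assembled thermal network for a given parameter set, environment
    and flow routing."""

    def __init__(self, params: ParameterSet, env: EnvironmentSpec, flows: FlowRouting):
        self.params = params
        self.env = env
        self.flows = flows
        flows.check_conservation()
        self.rho_c = params.blood.rho_c
        self.nodes = list(params.thermal_nodes.values())
        self.index = {n.key: i for i, n in enumerate(self.nodes)}
        self.n = len(self.nodes)
        self.total_metabolism = sum(n.basal_met for n in self.nodes)
        self.skin_areas = {seg: self.surface_area(seg) for seg in self._segments()}
        self._matrix_cache: tuple[np.ndarray, np.ndarray] | None = None

    # -- geometry ----------------------------------------------------------
    def _segments(self) -> list[str]:
        return self.params.segments

    def surface_area(self, segment: str) -> float:
        skin = self.params.thermal_nodes.get((segment, "skin"))
        if skin is None or skin.radius is None:
            return 0.0
        if skin.segment_length == 0.0:
            return 4.0 * math.pi * skin.radius**2
        return 2.0 * math.pi * skin.radius * skin.segment_length

    # -- exchange coefficients --------------------------------------------
    def _piston_coeffs(self, seg: str) -> tuple[float, float, float]:
        """(K_ar-core, K_ve-core, K_counterflow) [W/K] for a piston segment."""
        tc = self.params.conductances
        ar, ve, core = (seg, "artery"), (seg, "vein"), (seg, "core")
        q_ar = self.flows.artery_flow[seg]
        q_ve = self.flows.vein_flow[seg]
        k_ar = piston_coeff(q_ar, tc.get(ar, core), self.rho_c)
        k_ve = piston_coeff(q_ve, tc.get(ve, core), self.rho_c)
        if q_ar > 0 and q_ve > 0:
            k_cf = counterflow_coeff(q_ar, q_ve, tc.get(ar, ve), self.rho_c)
        else:
            k_cf = 0.0
        return k_ar, k_ve, k_cf

    def _vein_inlet_weights(self, seg: str) -> dict[tuple[str, str], float]:
        """Flow-weighted composition of the distal (inlet) venous blood."""
        entries: dict[tuple[str, str], float] = {}
        for d in VEIN_DISTAL[seg]:
            entries[(d, "vein")] = self.flows.vein_flow[d]
        if seg == "abdomen":
            for d in ("thigh_r", "thigh_l"):
                q = self.flows.sv_flow.get(d, 0.0)
                if q > 0:
                    entries[(d, "superficial_vein")] = q
        total = sum(entries.values())
        if total <= 0:
            return {}
        return {k: v / total for k, v in entries.items()}

    # -- matrix assembly ---------------------------------------------------
    def _advective_sources(self) -> dict[tuple[str, str], list[tuple[tuple[str, str], float]]]:
        """(node -> [(source node, flow m3/s), ...]) for every advection edge."""
        fl = self.flows
        src: dict[tuple[str, str], list[tuple[tuple[str, str], float]]] = {
            n.key: [] for n in self.nodes}

        co = fl.cardiac_output
        src[("chest", "lung")].append((("chest", "right_heart"), co))
        src[("chest", "left_heart")].append((("chest", "lung"), co))

        for (seg, node), q in fl.comp_inflow.items():
            if q <= 0:
                continue
            if seg == "chest":
                source = ("chest", "left_heart")
            else:
                source = (seg, "artery")
            src[(seg, node)].append((source, q))

        for seg in ARTERY_PARENT:
            parent = ARTERY_PARENT[seg]
            source = ("chest", "left_heart") if parent == "left_heart" else (parent, "artery")
            q = fl.artery_flow[seg]
            if q > 0:
                src[(seg, "artery")].append((source, q))

        for seg in VEIN_DISTAL:
            f_sv = fl.sv_comp_in.get(seg, 0.0)
            comp_total = fl.vein_comp_in[seg] + f_sv
            for (s, node), q in fl.comp_inflow.items():
                if s != seg or q <= 0:
                    continue
                share = q / comp_total if comp_total > 0 else 0.0
                q_deep = q * (fl.vein_comp_in[seg] / comp_total) if comp_total > 0 else 0.0
                q_sv = q - q_deep
                if q_deep > 0:
                    src[(seg, "vein")].append(((seg, node), q_deep))
                if q_sv > 0 and (seg, "superficial_vein") in src:
                    src[(seg, "superficial_vein")].append(((seg, node), q_sv))
            for d in VEIN_DISTAL[seg]:
                q = fl.vein_flow[d]
                if q > 0:
                    src[(seg, "vein")].append(((d, "vein"), q))
            if seg == "abdomen":
                for d in ("thigh_r", "thigh_l"):
                    q = fl.sv_flow.get(d, 0.0)
                    if q > 0:
                        src[(seg, "vein")].append(((d, "superficial_vein"), q))

        for prox, d in SV_DISTAL.items():
            if d is not None and fl.sv_flow.get(d, 0.0) > 0:
                src[(prox, "superficial_vein")].append(((d, "superficial_vein"),
                                                        fl.sv_flow[d]))

        rh = ("chest", "right_heart")
        for seg in RETURN_TO_HEART:
            q = fl.vein_flow[seg]
            if q > 0:
                src[rh].append(((seg, "vein"), q))
        for seg in ("upper_arm_r", "upper_arm_l"):
            q = fl.sv_flow.get(seg, 0.0)
            if q > 0:
                src[rh].append(((seg, "superficial_vein"), q))
        for (s, node), q in fl.comp_inflow.items():
            if s == "chest" and q > 0:
                src[rh].append((("chest", node), q))
        return src

    def assemble(self, T_prev: np.ndarray, dt: float) -> tuple[np.ndarray, np.ndarray]:
        """Dense linear system  M T_new = b  of the implicit step.

        Latent skin loss is evaluated at the previous skin temperature
        (the only non-linear term); everything else is implicit."""
        M, b_const, cap = self._assemble_static(dt)
        return M, b_const + cap / dt * T_prev - self._latent_vector(T_prev)

    def _latent_vector(self, T_prev: np.ndarray) -> np.ndarray:
        e = np.zeros(self.n)
        for seg in self._segments():
            key = (seg, "skin")
            if key in self.index:
                i = self.index[key]
                e[i] = skin_latent_loss(self.env, seg, self.skin_areas[seg], float(T_prev[i]))
        return e

    def _assemble_static(self, dt: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(matrix, constant rhs part, heat-capacity vector); the rhs part
        excludes heat storage and the lagged latent loss."""
        tcm = self.params.conductances
        rho_c = self.rho_c
        n = self.n
        M = np.zeros((n, n))
        b = np.zeros(n)
        cap_vec = np.zeros(n)
        idx = self.index
        c_res, e_res = respiration_losses(self.env, self.total_metabolism)
        sources = self._advective_sources()

        piston_segs = {seg for seg in ARTERY_PARENT if _base(seg) in PISTON_BASES}

        for node in self.nodes:
            i = idx[node.key]
            seg, name = node.key
            cap = node.heat_capacity if node.heat_capacity else 0.0
            cap_vec[i] = cap

            M[i, i] += cap / dt
            b[i] += node.basal_met

            # conduction (skip artery/vein-core conduction in piston segments:
            # replaced by the piston exchange terms)
            for other, tc in tcm.neighbours(node.key):
                if seg in piston_segs and {name, other[1]} & {"artery", "vein"} and \
                        "superficial_vein" not in (name, other[1]):
                    continue
                j = idx[other]
                M[i, i] += tc
                M[i, j] -= tc

            # advection into this node
            for source, q in sources[node.key]:
                k = rho_c * q
                j = idx[source]
                M[i, i] += k
                M[i, j] -= k

            # surface losses of skin nodes
            if name == "skin":
                h = self.env.surface_coefficient(seg)
                area = self.skin_areas[seg]
                M[i, i] += h * area
                b[i] += h * area * self.env.air_temperature
            if name == "lung":
                b[i] -= c_res + e_res

        # piston artery/vein rows get their exchange terms; the core rows the
        # antisymmetric counterparts
        for seg in piston_segs:
            k_ar, k_ve, k_cf = self._piston_coeffs(seg)
            i_ar = idx[(seg, "artery")]
            i_ve = idx[(seg, "vein")]
            i_core = idx[(seg, "core")]
            parent = ARTERY_PARENT[seg]
            i_prox = idx[("chest", "left_heart")] if parent == "left_heart" \
                else idx[(parent, "artery")]
            weights = self._vein_inlet_weights(seg)

            # artery: gains  k_ar (T_core - T_prox) + k_cf (T_mix - T_prox)
            M[i_ar, i_core] -= k_ar
            M[i_ar, i_prox] += k_ar + k_cf
            for key, w in weights.items():
                M[i_ar, idx[key]] -= k_cf * w
            # core: -k_ar (T_core - T_prox)
            M[i_core, i_core] += k_ar
            M[i_core, i_prox] -= k_ar

            # vein: gains  k_ve (T_core - T_mix) - k_cf (T_mix - T_prox)
            M[i_ve, i_core] -= k_ve
            M[i_ve, i_prox] -= k_cf
            for key, w in weights.items():
                M[i_ve, idx[key]] += (k_ve + k_cf) * w
            # core: -k_ve (T_core - T_mix)
            M[i_core, i_core] += k_ve
            for key, w in weights.items():
                M[i_core, idx[key]] -= k_ve * w

        # isolated-node guard for quasi-steady rows
        for node in self.nodes:
            i = idx[node.key]
            if (node.heat_capacity is None) and M[i, i] == 0.0:
                raise NumericsError(f"isolated quasi-steady node {node.key}: "
                                    "all flows and conductances are zero")
        return M, b, cap_vec

    # -- stepping ----------------------------------------------------------
    def initial_state(self, temperature: float = 36.5) -> ThermalState:
        return ThermalState(np.full(self.n, temperature), self.index)

    def step(self, state: ThermalState, dt: float = 10.0) -> ThermalState:
        """One implicit (backward) step; unconditionally stable for any dt.

        The system matrix depends only on flows, conductances and dt, so
        it is assembled and LU-factorised once and reused; only the
        right-hand side (heat stored + lagged latent loss) is rebuilt."""
        if dt <= 0:
            raise ValidationError("dt must be > 0")
        import scipy.linalg as sla
        if self._matrix_cache is None or self._matrix_cache[0] != dt:
            M, b_const, cap = self._assemble_static(dt)
            try:
                lu = sla.lu_factor(M)
            except Exception as exc:
                raise NumericsError(
                    f"thermal solve failed (condition number {np.linalg.cond(M):.3g})"
                ) from exc
            self._matrix_cache = (dt, lu, b_const, cap)
        _, lu, b_const, cap = self._matrix_cache
        b = b_const + cap / dt * state.temps - self._latent_vector(state.temps)
        temps = sla.lu_solve(lu, b)
        if not np.all(np.isfinite(temps)):
            raise NumericsError("thermal solve produced non-finite temperatures")
        return ThermalState(temps, self.index, state.time + dt)

    def run_to_steady(self, state: ThermalState | None = None, dt: float = 10.0,
                      horizon: float = 24.0 * 3600.0,
                      tol_K_per_s: float = 2e-6) -> tuple[ThermalState, bool]:
        """Advance until every node's |dT/dt| < tol (or the horizon)."""
        state = state or self.initial_state()
        steps = max(int(horizon / dt), 1)
        converged = False
        for _ in range(steps):
            new = self.step(state, dt)
            rate = np.max(np.abs(new.temps - state.temps)) / dt
            state = new
            if rate < tol_K_per_s:
                converged = True
                break
        return state, converged

    # -- diagnostics ---------------------------------------------------------
    def solve_vessel_temperatures(self, comp_temps: dict[tuple[str, str], float]
                                  ) -> dict[str, tuple[float, float]]:
        """Quasi-steady vessel temperatures for *fixed* compartment
        temperatures, solved segment-by-segment in topological order
        (arteries proximal to distal, veins distal to proximal)."""
        fl = self.flows
        rho_c = self.rho_c
        T: dict[tuple[str, str], float] = dict(comp_temps)

        def artery_order(seg_list):
            out, pending = [], list(seg_list)
            while pending:
                for seg in list(pending):
                    parent = ARTERY_PARENT[seg]
                    if parent == "left_heart" or (parent, "artery") in T or parent in out:
                        out.append(seg)
                        pending.remove(seg)
            return out

        # arteries proximal -> distal; vein inlet temps are not needed for
        # arteries until the counterflow term, which uses distal vein temps:
        # solve veins first where possible is circular, so iterate twice
        # (the linear coupling through k_cf is weak and converges fast).
        for _ in range(12):
            for seg in artery_order(list(ARTERY_PARENT)):
                parent = ARTERY_PARENT[seg]
                t_prox = T.get(("chest", "left_heart"), comp_temps.get(("chest", "left_heart"), 37.0)) \
                    if parent == "left_heart" else T[(parent, "artery")]
                if _base(seg) in PISTON_BASES:
                    k_ar, k_ve, k_cf = self._piston_coeffs(seg)
                    q_ar = fl.artery_flow[seg]
                    weights = self._vein_inlet_weights(seg)
                    t_mix = sum(w * T.get(k, t_prox) for k, w in weights.items()) if weights else t_prox
                    t_core = T[(seg, "core")]
                    gain = k_ar * (t_core - t_prox) + k_cf * (t_mix - t_prox)
                    T[(seg, "artery")] = t_prox + gain / (rho_c * q_ar) if q_ar > 0 else t_prox
                else:
                    T[(seg, "artery")] = self._pool_temperature(seg, "artery", T)
            for seg in reversed(artery_order(list(VEIN_DISTAL))):
                if _base(seg) in PISTON_BASES:
                    self._solve_piston_vein(seg, T)
                else:
                    T[(seg, "vein")] = self._pool_temperature(seg, "vein", T)
        return {seg: (T[(seg, "artery")], T[(seg, "vein")]) for seg in ARTERY_PARENT}

    def _pool_temperature(self, seg: str, vessel: str, T: dict) -> float:
        fl = self.flows
        tcm = self.params.conductances
        rho_c = self.rho_c
        num = 0.0
        den = 0.0
        if vessel == "artery":
            parent = ARTERY_PARENT[seg]
            t_src = T.get(("chest", "left_heart"), 37.0) if parent == "left_heart" \
                else T[(parent, "artery")]
            q = fl.artery_flow[seg]
            num += rho_c * q * t_src
            den += rho_c * q
            core = (seg, "core")
            tc = tcm.get((seg, "artery"), core)
            if tc > 0:
                num += tc * T[core]
                den += tc
        else:
            comp_total = self.flows.vein_comp_in.get(seg, 0.0)
            for (s, node), qc in fl.comp_inflow.items():
                if s == seg and qc > 0:
                    q_deep = qc * (1.0 - fl.sv_fraction.get(seg, 0.0))
                    num += rho_c * q_deep * T[(s, node)]
                    den += rho_c * q_deep
            core = (seg, "core")
            tc = tcm.get((seg, "vein"), core)
            if tc > 0:
                num += tc * T[core]
                den += tc
        if den == 0.0:
            raise NumericsError(f"isolated pool node ({seg}, {vessel})")
        return num / den

    def _solve_piston_vein(self, seg: str, T: dict) -> None:
        fl = self.flows
        rho_c = self.rho_c
        k_ar, k_ve, k_cf = self._piston_coeffs(seg)
        parent = ARTERY_PARENT[seg]
        t_prox = T.get(("chest", "left_heart"), 37.0) if parent == "left_heart" \
            else T[(parent, "artery")]
        weights = self._vein_inlet_weights(seg)
        t_mix = sum(w * T[k] for k, w in weights.items()) if weights else t_prox
        q_dist = sum(fl.vein_flow[d] for d in VEIN_DISTAL[seg])
        if seg == "abdomen":
            q_dist += fl.sv_flow.get("thigh_r", 0.0) + fl.sv_flow.get("thigh_l", 0.0)
        num = rho_c * q_dist * t_mix
        den = rho_c * q_dist
        for (s, node), qc in fl.comp_inflow.items():
            if s == seg and qc > 0:
                q_deep = qc * (fl.vein_comp_in[seg] / max(fl.vein_comp_in[seg]
                                                          + fl.sv_comp_in.get(seg, 0.0), 1e-30))
                num += rho_c * q_deep * T[(s, node)]
                den += rho_c * q_deep
        t_core = T[(seg, "core")]
        num += k_ve * (t_core - t_mix) + k_cf * (t_prox - t_mix)
        if den == 0.0:
            raise NumericsError(f"isolated vein node {seg}")
        T[(seg, "vein")] = num / den

    def energy_balance(self, state: ThermalState) -> dict[str, float]:
        """Metabolic input vs environmental losses [W] at the given state."""
        c_res, e_res = respiration_losses(self.env, self.total_metabolism)
        sensible = 0.0
        latent = 0.0
        for seg in self._segments():
            skin = (seg, "skin")
            if skin not in self.index:
                continue
            area = self.skin_areas[seg]
            t_sk = state[skin]
            sensible += self.env.surface_coefficient(seg) * area * (t_sk - self.env.air_temperature)
            latent += skin_latent_loss(self.env, seg, area, t_sk)
        total_loss = sensible + latent + c_res + e_res
        return {
            "metabolism": self.total_metabolism,
            "sensible": sensible,
            "skin_latent": latent,
            "respiration_sensible": c_res,
            "respiration_latent": e_res,
            "total_loss": total_loss,
            "closure": (self.total_metabolism - total_loss) / self.total_metabolism,
        }
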