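"""Construction of the four-route peripheral RLC circuits.

Each terminal artery of the 1-D tree drains through a peripheral
circulation: a distal arterial end (pure resistance), four parallel
routes (core, muscle, fat, skin) of arteriole -> capillary -> venule
chains, and a shared collecting vein, finally joining a vena cava.

The series split of the total viscous resistance R_T gives the arteriole
90 % of R_T; the remaining 10 % is distributed over the distal arterial
end, capillary, venule and vein in proportion to the classical
single-route ratios (17 : 21 : 6.5 : 1.5) renormalised among themselves.
Inertance scales with sqrt(R_T) and compliance with 1/R_T, the
proportionality constants being inherited from the single-route
reference circuit.  The decomposition into four routes makes each
route's resistances inversely proportional to its flow fraction, which
preserves the capillary and venule node pressures at the reference flow.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

from ..errors import ValidationError
from ..units import MMHG_TO_PA, ML_TO_M3
from .types import ROUTES, PeripheralCircuit

# lambda [mmHg-mL units] -> SI: L/sqrt(R) picks up  L_conv / sqrt(R_conv)
_LAMBDA_TO_SI = (MMHG_TO_PA / ML_TO_M3) / math.sqrt(MMHG_TO_PA / ML_TO_M3)


def series_resistance_split(split_cfg: dict) -> dict[str, float]:
    """Fractions of R_T carried by each series element of a single route."""
    share_al = float(split_cfg["arteriole_share"])
    if not 0.0 < share_al < 1.0:
        raise ValidationError("arteriole share must lie in (0, 1)")
    ratios = split_cfg["literature_ratios"]
    total = sum(float(v) for v in ratios.values())
    rest = 1.0 - share_al
    split = {name: rest * float(v) / total for name, v in ratios.items()}
    split["arteriole"] = share_al
    return split


def _scaling_si(scaling_cfg: dict) -> tuple[dict[str, float], dict[str, float]]:
    gamma = {k: float(v) for k, v in scaling_cfg["gamma_s"].items()}  # C*R_T [s], unit-invariant
    lam = {k: float(v) * _LAMBDA_TO_SI for k, v in scaling_cfg["lambda_mmHg"].items()}
    return gamma, lam


@dataclass(frozen=True)
class SingleRouteCircuit:
    """Reference single-route circuit for a given R_T (used by the audit)."""

    R_T: float
    R_da: float
    R_al: float
    L_al: float
    C_al: float
    R_cp: float
    L_cp: float
    C_cp: float
    R_vn: float
    L_vn: float
    C_vn: float
    R_v: float
    L_v: float
    C_v: float


def build_single_route(R_T: float, circuit_cfg: dict) -> SingleRouteCircuit:
    if R_T <= 0:
        raise ValidationError("total viscous resistance R_T must be > 0")
    split = series_resistance_split(circuit_cfg["resistance_split"])
    gamma, lam = _scaling_si(circuit_cfg["scaling_constants"])
    sq = math.sqrt(R_T)
    return SingleRouteCircuit(
        R_T=R_T,
        R_da=split["distal_arterial_end"] * R_T,
        R_al=split["arteriole"] * R_T,
        L_al=lam["arteriole"] * sq,
        C_al=gamma["arteriole"] / R_T,
        R_cp=split["capillary"] * R_T,
        L_cp=lam["capillary"] * sq,
        C_cp=gamma["capillary"] / R_T,
        R_vn=split["venule"] * R_T,
        L_vn=lam["venule"] * sq,
        C_vn=gamma["venule"] / R_T,
        R_v=split["vein"] * R_T,
        L_v=lam["vein"] * sq,
        C_v=gamma["vein"] / R_T,
    )


def build_peripheral_circuit(
    R_T: float,
    route_flow_fractions: dict[str, float],
    circuit_cfg: dict,
    skeleton: PeripheralCircuit | None = None,
) -> PeripheralCircuit:
    """Decompose a single-route circuit of total resistance ``R_T`` into four routes.

    ``route_flow_fractions`` maps core/muscle/fat/skin onto positive
    fractions summing to one.  Returns a :class:`PeripheralCircuit` with
    every element value populated; if ``skeleton`` is given its identity
    fields (artery id, mapping) are preserved.
    """
    if R_T <= 0:
        raise ValidationError("total viscous resistance R_T must be > 0")
    fractions = {r: float(route_flow_fractions[r]) for r in ROUTES}
    for r, f in fractions.items():
        if f <= 0:
            raise ValidationError(f"route flow fraction for {r!r} must be > 0")
    s = sum(fractions.values())
    if abs(s - 1.0) > 1e-9:
        raise ValidationError("route flow fractions must sum to 1")

    circ = skeleton or PeripheralCircuit(
        artery_id=-1, tnw_segment="", vena_cava="", R_T_route={}, routes={}
    )
    circ.R_T_route = {r: R_T / fractions[r] for r in ROUTES}
    derive_elements(circ, circuit_cfg)
    return circ


def derive_elements(circ: PeripheralCircuit, circuit_cfg: dict) -> None:
    """(Re-)derive every R, L, C of a circuit from its per-route R_T values.

    Called at construction and after each calibration update so the RLC
    scaling laws (L ~ sqrt(R_T), C ~ 1/R_T) and the 90/10 arteriole split
    are preserved exactly.
    """
    split = series_resistance_split(circuit_cfg["resistance_split"])
    gamma, lam = _scaling_si(circuit_cfg["scaling_constants"])
    R_T_agg = 1.0 / sum(1.0 / circ.R_T_route[r] for r in ROUTES)

    # shared elements follow the aggregate resistance
    circ.R_da = split["distal_arterial_end"] * R_T_agg
    circ.C_al = gamma["arteriole"] / R_T_agg
    circ.R_v = split["vein"] * R_T_agg
    circ.L_v = lam["vein"] * math.sqrt(R_T_agg)
    circ.C_v = gamma["vein"] / R_T_agg

    for r in ROUTES:
        R_T_r = circ.R_T_route[r]
        sq = math.sqrt(R_T_r)
        circ.R_al[r] = split["arteriole"] * R_T_r
        circ.L_al[r] = lam["arteriole"] * sq
        circ.R_cp[r] = split["capillary"] * R_T_r
        circ.L_cp[r] = lam["capillary"] * sq
        circ.C_cp[r] = gamma["capillary"] / R_T_r
        circ.R_vn[r] = split["venule"] * R_T_r
        circ.L_vn[r] = lam["venule"] * sq
        circ.C_vn[r] = gamma["venule"] / R_T_r


def dc_node_pressures(
    circ: PeripheralCircuit | SingleRouteCircuit, Q: float, P_out: float = 0.0
) -> dict[str, float]:
    """Steady (DC) node pressures at total inflow ``Q`` with outlet at ``P_out``.

    For the four-route circuit the flow divides among routes in inverse
    proportion to the route resistances; per-route capillary/venule node
    pressures are returned route-wise, plus the shared vein node and inlet.
    """
    if isinstance(circ, SingleRouteCircuit):
        p_vein = P_out + Q * circ.R_v
        p_vn = p_vein + Q * circ.R_vn
        p_cp = p_vn + Q * circ.R_cp
        p_al = p_cp + Q * circ.R_al
        p_in = p_al + Q * circ.R_da
        return {"inlet": p_in, "arteriole_node": p_al, "capillary": p_cp,
                "venule": p_vn, "vein": p_vein}

    g = {r: 1.0 / circ.R_T_route[r] for r in ROUTES}
    g_sum = sum(g.values())
    p_vein = P_out + Q * circ.R_v
    out: dict[str, float] = {"vein": p_vein}
    p_al_node = None
    for r in ROUTES:
        q_r = Q * g[r] / g_sum
        p_vn = p_vein + q_r * circ.R_vn[r]
        p_cp = p_vn + q_r * circ.R_cp[r]
        p_al = p_cp + q_r * circ.R_al[r]
        out[f"venule_{r}"] = p_vn
        out[f"capillary_{r}"] = p_cp
        p_al_node = p_al
    out["arteriole_node"] = p_al_node
    out["inlet"] = p_al_node + Q * circ.R_da
    return out
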