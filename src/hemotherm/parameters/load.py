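"""Loading and validation of the standard-person parameter set.

The packaged data files hold the printed anatomy/physiology tables:
thermal nodes (heat capacity, basal metabolism, simplified geometry),
the 77-artery tree (lengths, radii, wall properties, topology), the
baseline flow-rate targets, the terminal-to-thermal-network route map,
and the 0-D circuit / environment defaults.
"""
from __future__ import annotations

import copy
import math
from pathlib import Path

import pandas as pd
import yaml

from ..errors import LoadError, TopologyError, ValidationError
from ..units import (
    B_MMHG_S2_ML2_TO_SI,
    C_ML_MMHG_TO_SI,
    E_MMHG_ML_TO_SI,
    L_MMHG_S2_ML_TO_SI,
    MMHG_TO_PA,
    ML_MIN_TO_M3_S,
    R_MMHG_S_ML_TO_SI,
)
from .conductance import derive_conductances
from .peripheral import build_peripheral_circuit
from .types import (
    ROUTES,
    ArteryRecord,
    BloodProperties,
    HeartChamberParams,
    ParameterSet,
    PeripheralCircuit,
    PulmonaryParams,
    RouteSpec,
    ThermalNode,
    ValveParams,
)

DATA_DIR = Path(__file__).resolve().parent.parent / "data"

_FILES = {
    "thermal_nodes": "thermal_nodes.csv",
    "arteries": "arteries.csv",
    "flow_targets": "flow_targets.csv",
    "peripheral_map": "peripheral_map.csv",
    "circuit_defaults": "circuit_defaults.yaml",
    "environment_defaults": "environment_defaults.yaml",
}

_VENA_CAVA_BY_SEGMENT = {
    "head": "superior", "neck": "superior", "chest": "superior",
    "upper_arm": "superior", "lower_arm": "superior", "hand": "superior",
    "abdomen": "abdominal",
    "thigh": "inferior", "leg": "inferior", "foot": "inferior",
}


def _deep_update(base: dict, extra: dict) -> dict:
    for key, value in extra.items():
        if isinstance(value, dict) and isinstance(base.get(key), dict):
            _deep_update(base[key], value)
        else:
            base[key] = value
    return base


def _read(data_dir: Path, name: str) -> Path:
    path = data_dir / _FILES[name]
    if not path.exists():
        raise LoadError(f"missing parameter file: {path}")
    return path


def _expand_segments(row_segment: str, bilateral: int) -> list[str]:
    if bilateral:
        return [f"{row_segment}_r", f"{row_segment}_l"]
    return [row_segment]


def _load_thermal_nodes(path: Path) -> dict[tuple[str, str], ThermalNode]:
    df = pd.read_csv(path)
    nodes: dict[tuple[str, str], ThermalNode] = {}
    for _, row in df.iterrows():
        for seg in _expand_segments(row["segment"], int(row["bilateral"])):
            cap = None if pd.isna(row["heat_capacity_J_K"]) else float(row["heat_capacity_J_K"])
            node = ThermalNode(
                segment=seg,
                node=row["node"],
                kind=row["kind"],
                heat_capacity=cap,
                basal_met=float(row["basal_met_W"]),
                segment_length=float(row["segment_length_m"]),
                radius=None if pd.isna(row["radius_m"]) else float(row["radius_m"]),
                vessel_area=None if pd.isna(row["vessel_area_m2"]) else float(row["vessel_area_m2"]),
            )
            nodes[node.key] = node
    return nodes


def _load_arteries(path: Path) -> tuple[dict[int, ArteryRecord], int]:
    df = pd.read_csv(path, keep_default_na=False)
    arteries: dict[int, ArteryRecord] = {}
    for _, row in df.iterrows():
        rec = ArteryRecord(
            id=int(row["id"]),
            name=row["name"],
            side=row["side"],
            length=float(row["length_m"]),
            r_prox=float(row["r_prox_m"]),
            r_dist=float(row["r_dist_m"]),
            h_rel=float(row["h_rel"]),
            youngs_modulus=float(row["E_Pa"]),
            parent=int(row["parent"]) or None,
        )
        if rec.id in arteries:
            raise TopologyError(f"duplicate artery id {rec.id}")
        arteries[rec.id] = rec

    roots = [a for a in arteries.values() if a.parent is None]
    if len(roots) != 1:
        raise TopologyError(f"expected exactly one root artery, found {len(roots)}")
    root = roots[0]
    for a in arteries.values():
        if a.parent is not None:
            if a.parent not in arteries:
                raise TopologyError(f"artery {a.id} references unknown parent {a.parent}")
            arteries[a.parent].daughters.append(a.id)

    # connectivity / acyclicity check by traversal from the root
    seen: set[int] = set()
    stack = [root.id]
    while stack:
        i = stack.pop()
        if i in seen:
            raise TopologyError(f"cycle detected at artery {i}")
        seen.add(i)
        stack.extend(arteries[i].daughters)
    if len(seen) != len(arteries):
        orphans = sorted(set(arteries) - seen)
        raise TopologyError(f"orphan arteries not reachable from the root: {orphans}")
    return arteries, root.id


def _chamber(name: str, cfg: dict, timing: dict) -> HeartChamberParams:
    kind = cfg["kind"]
    t = timing[kind]
    return HeartChamberParams(
        name=name,
        kind=kind,
        E_A=float(cfg["E_A_mmHg_ml"]) * E_MMHG_ML_TO_SI,
        E_B=float(cfg["E_B_mmHg_ml"]) * E_MMHG_ML_TO_SI,
        S=float(cfg["S_mmHg_s_ml"]) * R_MMHG_S_ML_TO_SI,
        T_cs=float(t["T_cs"]), T_cp=float(t["T_cp"]), T_rp=float(t["T_rp"]),
    )


def load_standard_person(data_dir: str | Path | None = None, overrides: dict | None = None) -> ParameterSet:
    """Load the packaged standard-person description.

    ``overrides`` is a nested mapping merged over the raw configuration
    before construction; recognised top-level keys are ``heart_rate``
    plus the sections of the two YAML defaults files (e.g.
    ``{"blood": {"density_kg_m3": 1060.0}}``).
    """
    data_dir = Path(data_dir) if data_dir is not None else DATA_DIR
    circuit_cfg = yaml.safe_load(_read(data_dir, "circuit_defaults").read_text())
    env_cfg = yaml.safe_load(_read(data_dir, "environment_defaults").read_text())
    overrides = copy.deepcopy(overrides) if overrides else {}
    if "heart_rate" in overrides:
        circuit_cfg["heart_rate_bpm"] = overrides.pop("heart_rate")
    env_keys = set(env_cfg)
    _deep_update(circuit_cfg, {k: v for k, v in overrides.items() if k not in env_keys})
    _deep_update(env_cfg, {k: v for k, v in overrides.items() if k in env_keys})

    b = circuit_cfg["blood"]
    blood = BloodProperties(
        density=float(b["density_kg_m3"]),
        specific_heat=float(b["specific_heat_J_kgK"]),
        kinematic_viscosity=float(b["kinematic_viscosity_m2_s"]),
        boundary_layer=float(b["boundary_layer_m"]),
    )

    thermal_nodes = _load_thermal_nodes(_read(data_dir, "thermal_nodes"))
    arteries, root_id = _load_arteries(_read(data_dir, "arteries"))
    if blood.boundary_layer >= min(a.r_dist for a in arteries.values()):
        raise ValidationError("friction boundary layer must be below the smallest artery radius")

    targets = pd.read_csv(_read(data_dir, "flow_targets"))
    pmap = pd.read_csv(_read(data_dir, "peripheral_map"))

    group_target = dict(zip(targets["group"], targets["target_ml_min"]))
    missing = set(pmap["group"]) - set(group_target)
    if missing:
        raise ValidationError(f"peripheral map references unknown target groups: {sorted(missing)}")

    pressures = circuit_cfg["reference_pressures_mmHg"]
    dp_ref = float(pressures["perfusion_drop"]) * MMHG_TO_PA

    peripherals: dict[int, PeripheralCircuit] = {}
    terminal_ids = {a.id for a in arteries.values() if a.is_terminal}
    for artery_id, rows in pmap.groupby("artery_id"):
        artery_id = int(artery_id)
        if artery_id not in terminal_ids:
            raise TopologyError(f"peripheral map attaches to non-terminal artery {artery_id}")
        routes: dict[str, RouteSpec] = {}
        q_route: dict[str, float] = {}
        for _, row in rows.iterrows():
            r = row["route"]
            routes[r] = RouteSpec(group=row["group"], weight=float(row["weight"]),
                                  tnw_node=row["tnw_node"])
            q_route[r] = float(row["weight"]) * group_target[row["group"]] * ML_MIN_TO_M3_S
            if q_route[r] <= 0:
                raise ValidationError(f"non-positive seed flow for artery {artery_id} route {r}")
        if set(routes) != set(ROUTES):
            raise ValidationError(f"artery {artery_id}: peripheral map must define all four routes")
        seg = rows.iloc[0]["tnw_segment"]
        base = seg.rsplit("_", 1)[0] if seg.endswith(("_r", "_l")) else seg
        q_tot = sum(q_route.values())
        skeleton = PeripheralCircuit(
            artery_id=artery_id,
            tnw_segment=seg,
            vena_cava=_VENA_CAVA_BY_SEGMENT[base],
            R_T_route={},
            routes=routes,
        )
        peripherals[artery_id] = build_peripheral_circuit(
            dp_ref / q_tot, {r: q_route[r] / q_tot for r in ROUTES}, circuit_cfg, skeleton
        )
    unmapped = terminal_ids - set(peripherals)
    if unmapped:
        raise TopologyError(f"terminal arteries without a peripheral circulation: {sorted(unmapped)}")

    heart_cfg = circuit_cfg["heart"]
    chambers = {name: _chamber(name, cfg, heart_cfg["timing_fractions"])
                for name, cfg in heart_cfg["chambers"].items()}
    valves = {
        name: ValveParams(
            name=name,
            R=float(cfg["R_mmHg_s_ml"]) * R_MMHG_S_ML_TO_SI,
            B=float(cfg["B_mmHg_s2_ml2"]) * B_MMHG_S2_ML2_TO_SI,
            L=float(cfg["L_mmHg_s2_ml"]) * L_MMHG_S2_ML_TO_SI,
        )
        for name, cfg in heart_cfg["valves"].items()
    }
    pul_cfg = circuit_cfg["pulmonary"]
    pulmonary = {
        name: PulmonaryParams(
            name=name,
            E0=float(cfg["E0_mmHg_ml"]) * E_MMHG_ML_TO_SI,
            Phi=float(cfg["Phi_ml"]) * 1e-6,
            S=float(cfg["S_mmHg_s_ml"]) * R_MMHG_S_ML_TO_SI,
        )
        for name, cfg in pul_cfg["compartments"].items()
    }
    pulmonary_links = {
        name: {"R": float(cfg["R_mmHg_s_ml"]) * R_MMHG_S_ML_TO_SI,
               "L": float(cfg["L_mmHg_s2_ml"]) * L_MMHG_S2_ML_TO_SI}
        for name, cfg in pul_cfg["links"].items()
    }
    vena_cavae = {
        name: {"C": float(cfg["C_ml_mmHg"]) * C_ML_MMHG_TO_SI,
               "R": float(cfg["R_mmHg_s_ml"]) * R_MMHG_S_ML_TO_SI,
               "L": float(cfg["L_mmHg_s2_ml"]) * L_MMHG_S2_ML_TO_SI}
        for name, cfg in circuit_cfg["vena_cavae"].items()
    }

    conductances = derive_conductances(
        thermal_nodes,
        env_cfg["tissue_conductivity_W_mK"],
        env_cfg["vessel_films"],
    )

    hr = float(circuit_cfg["heart_rate_bpm"])
    if hr <= 0 or not math.isfinite(hr):
        raise ValidationError("heart rate must be a positive finite value")

    return ParameterSet(
        blood=blood,
        thermal_nodes=thermal_nodes,
        conductances=conductances,
        arteries=arteries,
        root_id=root_id,
        chambers=chambers,
        valves=valves,
        pulmonary=pulmonary,
        pulmonary_links=pulmonary_links,
        vena_cavae=vena_cavae,
        peripherals=peripherals,
        heart_rate=hr,
        poisson_ratio=float(circuit_cfg["wall"]["poisson_ratio"]),
        env_defaults=env_cfg,
        circuit_defaults=circuit_cfg,
        flow_targets=targets,
    )
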