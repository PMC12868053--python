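"""Thermal conductances from the simplified concentric geometry.

Each body segment is a set of concentric layers (sphere for the head,
cylinders elsewhere).  Radial conduction between adjacent layers is the
series combination of the half-shell of each layer, evaluated from the
layer's mid-radius to the interface.  Vessel-tissue composites combine
the in-vessel convective film and the intervening tissue conduction in
series over the printed vessel surface areas.  Head artery and vein
conductances are zero (their vessels cannot be meaningfully simplified).
"""
from __future__ import annotations

import math

from ..errors import GeometryError, ValidationError
from .types import ConductanceMatrix, ThermalNode

#: sentinel cap for a vanishing shell (r_out -> r_in)
CONDUCTANCE_CAP = 1.0e9


def cylindrical_shell_conductance(k: float, length: float, r_in: float, r_out: float) -> float:
    """Conductance 2 pi k l / ln(r_out/r_in) of a cylindrical shell [W/K]."""
    if r_out < r_in or r_in <= 0:
        raise GeometryError(f"cylindrical shell requires 0 < r_in <= r_out, got {r_in}, {r_out}")
    log_ratio = math.log(r_out / r_in)
    if log_ratio < 2.0 * math.pi * k * length / CONDUCTANCE_CAP:
        return CONDUCTANCE_CAP
    return 2.0 * math.pi * k * length / log_ratio


def spherical_shell_conductance(k: float, r_in: float, r_out: float) -> float:
    """Conductance 4 pi k / (1/r_in - 1/r_out) of a spherical shell [W/K]."""
    if r_out < r_in or r_in <= 0:
        raise GeometryError(f"spherical shell requires 0 < r_in <= r_out, got {r_in}, {r_out}")
    gap = 1.0 / r_in - 1.0 / r_out
    if gap < 4.0 * math.pi * k / CONDUCTANCE_CAP:
        return CONDUCTANCE_CAP
    return 4.0 * math.pi * k / gap


def series_conductance(*values: float) -> float:
    inv = 0.0
    for g in values:
        if g <= 0:
            return 0.0
        inv += 1.0 / g
    return 1.0 / inv


def _conductivity(name: str, table: dict[str, float]) -> float:
    k = table.get(name, table.get("core"))
    if k is None or k <= 0:
        raise ValidationError(f"no positive conductivity for tissue {name!r}")
    return float(k)


def derive_conductances(
    thermal_nodes: dict[tuple[str, str], ThermalNode],
    tissue_conductivities: dict[str, float],
    vessel_films: dict[str, float],
) -> ConductanceMatrix:
    """Build the full symmetric conductance matrix for the thermal network."""
    tc = ConductanceMatrix()
    segments: dict[str, list[ThermalNode]] = {}
    for node in thermal_nodes.values():
        segments.setdefault(node.segment, []).append(node)

    h_film = float(vessel_films["film_coeff_W_m2K"])
    g_tissue = float(vessel_films["tissue_coeff_W_m2K"])
    g_av = float(vessel_films["av_tissue_coeff_W_m2K"])
    g_sv = float(vessel_films["sv_skin_conductance_W_K"])

    for seg, nodes in segments.items():
        layers = sorted(
            (n for n in nodes if n.kind == "compartment" and n.radius is not None),
            key=lambda n: n.radius,
        )
        base = seg.rsplit("_", 1)[0] if seg.endswith(("_r", "_l")) else seg
        is_sphere = layers and layers[0].segment_length == 0.0

        # radial conduction between adjacent concentric layers
        r_in_prev = 0.0
        for inner, outer in zip(layers[:-1], layers[1:]):
            k_in = _conductivity(inner.node, tissue_conductivities)
            k_out = _conductivity(outer.node, tissue_conductivities)
            r_mid_in = 0.5 * (r_in_prev + inner.radius)
            r_mid_out = 0.5 * (inner.radius + outer.radius)
            if is_sphere:
                g_in = spherical_shell_conductance(k_in, max(r_mid_in, 1e-6), inner.radius)
                g_out = spherical_shell_conductance(k_out, inner.radius, r_mid_out)
            else:
                length = inner.segment_length
                g_in = cylindrical_shell_conductance(k_in, length, max(r_mid_in, 1e-6), inner.radius)
                g_out = cylindrical_shell_conductance(k_out, length, inner.radius, r_mid_out)
            tc.set(inner.key, outer.key, series_conductance(g_in, g_out))
            r_in_prev = inner.radius

        # vessel-tissue and arterio-venous composites
        ar = thermal_nodes.get((seg, "artery"))
        ve = thermal_nodes.get((seg, "vein"))
        sv = thermal_nodes.get((seg, "superficial_vein"))
        core = thermal_nodes.get((seg, "core")) or thermal_nodes.get((seg, "brain"))
        if ar is not None and ve is not None and base != "head":
            for vessel in (ar, ve):
                if vessel.vessel_area is None or vessel.vessel_area <= 0:
                    if h_film > 0:
                        raise ValidationError(
                            f"vessel {vessel.key} has no surface area but a film coefficient"
                        )
                    continue
                area = vessel.vessel_area
                tc.set(vessel.key, core.key,
                       series_conductance(h_film * area, g_tissue * area))
            a_min = min(ar.vessel_area, ve.vessel_area)
            tc.set(ar.key, ve.key,
                   series_conductance(h_film * a_min, g_av * a_min, h_film * a_min))
        if sv is not None:
            skin = thermal_nodes[(seg, "skin")]
            tc.set(sv.key, skin.key, g_sv)

    return tc
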