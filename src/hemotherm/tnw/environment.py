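"""Ambient environment, respiration and insensible skin losses.

With no autonomic model, skin evaporation is insensible diffusion only:
a fixed wettedness fraction of the maximal evaporative capacity set by
the skin-to-air vapour-pressure deficit.  Respiration losses follow the
classical thermophysiology formulations (sensible loss proportional to
metabolism times the inhaled-air temperature deficit; latent loss
proportional to metabolism times the vapour-pressure deficit).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

from ..errors import ValidationError


def saturation_vapour_pressure(T_celsius: float) -> float:
    """Saturation water-vapour pressure [kPa] (Tetens formula)."""
    return 0.6105 * math.exp(17.27 * T_celsius / (T_celsius + 237.3))


@dataclass
class EnvironmentSpec:
    """Ambient air state and per-segment surface exchange coefficients."""

    air_temperature: float                   # degC
    relative_humidity: float                 # percent
    surface_coefficients: dict[str, float]   # W/(m2 K), combined, per base segment
    respiration: dict = field(default_factory=dict)
    skin_evaporation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.relative_humidity <= 100.0:
            raise ValidationError("relative humidity must lie in [0, 100] %")
        for seg, h in self.surface_coefficients.items():
            if h <= 0:
                raise ValidationError(f"surface coefficient for {seg} must be > 0")

    @property
    def vapour_pressure(self) -> float:
        """Ambient water-vapour pressure [kPa]."""
        return self.relative_humidity / 100.0 * saturation_vapour_pressure(self.air_temperature)

    def surface_coefficient(self, segment: str) -> float:
        base = segment.rsplit("_", 1)[0] if segment.endswith(("_r", "_l")) else segment
        return float(self.surface_coefficients[base])

    def evaporative_coefficient(self, segment: str) -> float:
        """h_e = Lewis ratio x convective part of the combined coefficient
        [W/(m2 kPa)]."""
        lr = float(self.skin_evaporation["lewis_ratio_K_kPa"])
        h_r = float(self.skin_evaporation["radiative_coeff_W_m2K"])
        h_c = max(self.surface_coefficient(segment) - h_r, 0.1)
        return lr * h_c

    @classmethod
    def from_defaults(cls, env_cfg: dict, air_temperature: float | None = None,
                      relative_humidity: float | None = None) -> "EnvironmentSpec":
        amb = env_cfg["ambient"]
        return cls(
            air_temperature=float(amb["air_temperature_C"] if air_temperature is None
                                  else air_temperature),
            relative_humidity=float(amb["relative_humidity_pct"] if relative_humidity is None
                                    else relative_humidity),
            surface_coefficients=dict(env_cfg["surface_coefficients_W_m2K"]),
            respiration=dict(env_cfg["respiration"]),
            skin_evaporation=dict(env_cfg["skin_evaporation"]),
        )


def respiration_losses(env: EnvironmentSpec, total_metabolism: float) -> tuple[float, float]:
    """(C_res, E_res) [W]: sensible and latent respiratory losses, >= 0."""
    r = env.respiration
    c_res = float(r["c_res_W_per_W_K"]) * total_metabolism * (
        float(r["exhale_ref_C"]) - env.air_temperature)
    e_res = float(r["e_res_W_per_W_kPa"]) * total_metabolism * (
        float(r["vapour_ref_kPa"]) - env.vapour_pressure)
    return max(c_res, 0.0), max(e_res, 0.0)


def skin_latent_loss(env: EnvironmentSpec, segment: str, area: float,
                     T_skin: float) -> float:
    """Insensible diffusion loss E_sk [W] of one skin node, >= 0."""
    w = float(env.skin_evaporation["wettedness"])
    deficit = saturation_vapour_pressure(T_skin) - env.vapour_pressure
    return max(w * env.evaporative_coefficient(segment) * area * deficit, 0.0)


def respiration_and_skin_losses(skin_temps: dict[str, float],
                                skin_areas: dict[str, float],
                                env: EnvironmentSpec,
                                total_metabolism: float):
    """All latent/respiratory loss terms.

    Returns (C_res, E_res, {segment: E_sk}).  The lung node receives
    C_res + E_res; each skin node its own E_sk."""
    c_res, e_res = respiration_losses(env, total_metabolism)
    e_sk = {seg: skin_latent_loss(env, seg, skin_areas[seg], t)
            for seg, t in skin_temps.items()}
    return c_res, e_res, e_sk
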