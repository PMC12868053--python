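"""Blood-tissue heat-exchange operators.

Piston flow: blood traversing a segment's artery or vein equilibrates
exponentially with the surrounding tissue; the net gain of the tissue
from the passing blood is

    q = rho c Q (1 - exp(-TC/(rho c Q))) (T_tissue - T_inlet)

Counterflow: the adjacent artery and vein exchange like a counterflow
heat exchanger with NTU = TC/(rho c Q_ve); the balanced-flow limit
(Q_ve -> Q_ar) replaces the indeterminate general formula.
"""
from __future__ import annotations

import math

from ..errors import ValidationError

BALANCED_TOL = 1e-6


def piston_coeff(Q: float, TC: float, rho_c: float) -> float:
    """Effective exchange conductance rho c Q (1 - exp(-TC/(rho c Q))) [W/K].

    Continuity limits: 0 at Q = 0 (no carrier) and at TC = 0; -> rho c Q
    (perfect equilibration) as TC -> infinity."""
    if Q < 0 or TC < 0:
        raise ValidationError("piston exchange requires Q >= 0 and TC >= 0")
    if Q == 0.0 or TC == 0.0:
        return 0.0
    return rho_c * Q * (1.0 - math.exp(-TC / (rho_c * Q)))


def piston_vessel_gain(Q: float, TC: float, T_tissue: float, T_inlet: float,
                       rho_c: float) -> float:
    """Heat gained by the vessel blood from the tissue [W] (antisymmetric:
    the tissue receives the negative of this)."""
    return piston_coeff(Q, TC, rho_c) * (T_tissue - T_inlet)


def counterflow_coeff(Q_ar: float, Q_ve: float, TC_ar_ve: float, rho_c: float) -> float:
    """Effective arterio-venous exchange conductance [W/K].

    Never exceeds rho c min(Q_ar, Q_ve) (second-law bound of a
    counterflow exchanger)."""
    if Q_ar <= 0 or Q_ve <= 0:
        raise ValidationError("counterflow exchange requires positive flows")
    if TC_ar_ve < 0:
        raise ValidationError("TC_ar_ve must be >= 0")
    if TC_ar_ve == 0.0:
        return 0.0
    ntu = TC_ar_ve / (rho_c * Q_ve)
    ratio = Q_ve / Q_ar
    if abs(1.0 - ratio) < BALANCED_TOL:
        return rho_c * Q_ve * ntu / (1.0 + ntu)
    if ratio < 1.0:
        z = math.exp(-ntu * (1.0 - ratio))
        return rho_c * Q_ve * (1.0 - z) / (1.0 - ratio * z)
    # Q_ve > Q_ar: algebraically identical form that keeps the exponent
    # negative (multiply through by exp(-ntu (ratio - 1)))
    w = math.exp(-ntu * (ratio - 1.0))
    return rho_c * Q_ve * (w - 1.0) / (w - ratio)


def counterflow_exchange(Q_ar: float, Q_ve: float, TC_ar_ve: float,
                         T_ve_dist: float, T_ar_prox: float, rho_c: float) -> float:
    """Heat gained by the arterial blood from the venous blood [W]
    (antisymmetric pair)."""
    return counterflow_coeff(Q_ar, Q_ve, TC_ar_ve, rho_c) * (T_ve_dist - T_ar_prox)
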