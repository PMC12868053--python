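"""Heart chambers, valves and pulmonary compartments (element equations).

The chamber law is a time-varying elastance P = (E_A e(T) + E_B) V
+ S dV/dt with the piecewise-cosine activation e(T); atrial activation
wraps across the cycle boundary (atrial systole straddles end-diastole),
ventricular activation is zero outside its contraction/relaxation
window.  Valves obey P_up - P_dw = Q R + Q^2 B + L dQ/dt with a diode
contract (flow clamped at zero under an adverse gradient).
"""
from __future__ import annotations

import math

from .. import _kernels as K
from ..errors import NumericsError, ValidationError
from ..parameters.types import HeartChamberParams, PulmonaryParams


def activation(T: float, timing: HeartChamberParams, kind: str | None = None) -> float:
    """Normalized activation e in [0, 1] at cycle fraction ``T`` in (0, 1]."""
    if not 0.0 < T <= 1.0:
        raise ValidationError("cycle fraction T must lie in (0, 1]")
    kind = kind or timing.kind
    if kind == "atrium":
        return float(K.activation_atrium(T, timing.T_cs, timing.T_cp, timing.T_rp))
    if kind == "ventricle":
        return float(K.activation_ventricle(T, timing.T_cs, timing.T_cp, timing.T_rp))
    raise ValidationError(f"unknown chamber kind {kind!r}")


def chamber_pressure(V: float, e: float, params: HeartChamberParams,
                     dV_dt: float = 0.0) -> float:
    """Chamber pressure [Pa] from the elastance law."""
    if V <= 0:
        raise ValidationError("chamber volume must be > 0")
    return (params.E_A * e + params.E_B) * V + params.S * dV_dt


def valve_flow_rhs(P_up: float, P_dw: float, Q: float, R: float, B: float,
                   L: float) -> float:
    """dQ/dt of a valve; zero while the valve is closed under an adverse
    gradient (diode contract)."""
    if L <= 0:
        raise ValidationError("valve inertance L must be > 0")
    return float(K._valve_dq(P_up, P_dw, Q, R, B, L))


def pulmonary_pressure(V: float, params: PulmonaryParams, dV_dt: float = 0.0) -> float:
    """Exponential pulmonary state equation P = E0 Phi exp(V/Phi) + S dV/dt."""
    if V <= 0:
        raise ValidationError("pulmonary volume must be > 0")
    x = V / params.Phi
    if x > 50.0:
        raise NumericsError("pulmonary compartment overfilled (V/Phi > 50): unstable state")
    return params.E0 * params.Phi * math.exp(x) + params.S * dV_dt
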