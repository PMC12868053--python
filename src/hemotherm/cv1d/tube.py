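"""Elastic tube law closing the 1-D conservation equations.

P(A) = (E h / (r0 (1 - sigma^2))) (sqrt(A/A0) - 1) with h = h_rel * r0,
so the stiffness coefficient beta = E h_rel / (1 - sigma^2) is
independent of the local reference radius.
"""
from __future__ import annotations

import numpy as np

from ..errors import ValidationError


def stiffness(E: float, h_rel: float, sigma: float) -> float:
    """Tube-law coefficient beta [Pa]."""
    return E * h_rel / (1.0 - sigma**2)


def tube_law(A, A0, E: float, h_rel: float, sigma: float = 0.5):
    """Transmural pressure [Pa] relative to the reference state A0."""
    A = np.asarray(A, dtype=float)
    if np.any(A <= 0) or np.any(np.asarray(A0) <= 0):
        raise ValidationError("tube law requires positive areas (collapse not modelled)")
    return stiffness(E, h_rel, sigma) * (np.sqrt(A / np.asarray(A0)) - 1.0)


def tube_law_inverse(P, A0, E: float, h_rel: float, sigma: float = 0.5):
    """Area from transmural pressure (monotone inversion of the tube law)."""
    beta = stiffness(E, h_rel, sigma)
    root = 1.0 + np.asarray(P, dtype=float) / beta
    if np.any(root <= 0):
        raise ValidationError("pressure below collapse limit of the tube law")
    return np.asarray(A0) * root**2


def wave_speed(A, A0, E: float, h_rel: float, rho: float, sigma: float = 0.5):
    """Local nonlinear wave speed c(A) = sqrt(beta/(2 rho)) (A/A0)^(1/4)."""
    beta = stiffness(E, h_rel, sigma)
    return np.sqrt(beta / (2.0 * rho)) * (np.asarray(A) / np.asarray(A0)) ** 0.25
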