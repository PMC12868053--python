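"""Two-step Lax-Wendroff advance, junction coupling and boundaries.

These wrappers operate on :class:`ArterialSystem`/:class:`ArterialState1D`
and call the flat-array kernels.  The fused driver loop uses the same
kernels directly.
"""
from __future__ import annotations

import numpy as np

from .. import _kernels as K
from ..errors import CouplingError, NumericsError, ValidationError
from .grid import ArterialState1D, ArterialSystem


def cfl_limit(system: ArterialSystem, state: ArterialState1D) -> float:
    """Largest stable dt over the whole grid: min dx / (|u| + c)."""
    beta_nodes = np.repeat(system.betas, system.counts)
    dx_nodes = np.repeat(system.dxs, system.counts)
    c = np.sqrt(beta_nodes / (2.0 * system.blood.density)) * (state.A / system.A0) ** 0.25
    u = state.Q / state.A
    return float(np.min(dx_nodes / (np.abs(u) + c)))


def pressures(system: ArterialSystem, state: ArterialState1D) -> np.ndarray:
    """Nodal transmural pressures [Pa] via the tube law."""
    beta_nodes = np.repeat(system.betas, system.counts)
    return beta_nodes * (np.sqrt(state.A / system.A0) - 1.0)


def lax_wendroff_step(system: ArterialSystem, state: ArterialState1D, dt: float,
                      check_cfl: bool = True,
                      return_face_flux: bool = False):
    """Advance all interior nodes by one Richtmyer step (boundary nodes
    are closed separately by junctions/boundary conditions).

    With ``return_face_flux`` the half-step face mass fluxes are also
    returned (needed for the conservative boundary-node update)."""
    if dt <= 0:
        raise ValidationError("dt must be > 0")
    if np.any(state.A <= 0):
        raise NumericsError("negative cross-sectional area before step")
    if check_cfl:
        limit = cfl_limit(system, state)
        if dt > limit:
            raise NumericsError(
                f"CFL violation: dt={dt:g} exceeds stable limit {limit:g}"
            )
    new = state.copy()
    scratch_a = np.empty_like(state.A)
    scratch_q = np.empty_like(state.Q)
    max_cfl = K.lw_interior_step(
        new.A, new.Q, scratch_a, scratch_q, system.A0, system.dA0dx, system.H,
        system.starts, system.counts, system.dxs, system.betas,
        system.blood.density, system.friction_coeff, system.gravity, dt,
    )
    if check_cfl and max_cfl > 1.0:
        raise NumericsError(f"CFL violation during step (worst ratio {max_cfl:.3f})")
    if np.any(new.A[np.concatenate(
            [np.arange(s + 1, s + n - 1) for s, n in zip(system.starts, system.counts)])] <= 0):
        raise NumericsError("negative cross-sectional area after step")
    new.time = state.time + dt
    if return_face_flux:
        return new, scratch_q
    return new


def solve_junctions(system: ArterialSystem, old: ArterialState1D,
                    new: ArterialState1D, dt: float, tol: float = 1e-12) -> float:
    """Resolve all junctions in place on ``new``; returns worst residual."""
    return K.solve_junctions(
        new.A, new.Q, old.A, old.Q, system.A0,
        system.starts, system.counts, system.dxs, system.betas,
        system.jn_parent, system.jn_d1, system.jn_d2,
        system.blood.density, dt, tol,
    )


def junction_residual(system: ArterialSystem, state: ArterialState1D) -> tuple[float, float]:
    """(worst flow-conservation, worst pressure-jump) residual over junctions.

    Flow residual is relative to the parent flow scale, pressure jump is
    relative to the parent stiffness."""
    p = pressures(system, state)
    worst_q = 0.0
    worst_p = 0.0
    for k in range(len(system.jn_parent)):
        pa = system.jn_parent[k]
        pe = system.starts[pa] + system.counts[pa] - 1
        q_in = state.Q[pe]
        p_par = p[pe]
        q_out = 0.0
        for d in (system.jn_d1[k], system.jn_d2[k]):
            if d < 0:
                continue
            s = system.starts[d]
            q_out += state.Q[s]
            worst_p = max(worst_p, abs(p[s] - p_par) / system.betas[pa])
        worst_q = max(worst_q, abs(q_in - q_out) / (abs(q_in) + 1e-12))
    return worst_q, worst_p


def apply_boundaries(system: ArterialSystem, old: ArterialState1D, new: ArterialState1D,
                     dt: float, root_inflow: float,
                     terminal_pressures: np.ndarray) -> np.ndarray:
    """Close the root (prescribed inflow) and terminals (prescribed pressure).

    Returns the resulting terminal outflows, ordered like
    ``system.term_ends``."""
    if terminal_pressures is None or len(terminal_pressures) != len(system.term_ends):
        raise CouplingError("one terminal pressure per terminal artery is required")
    K.apply_root(new.A, new.Q, old.A, old.Q, system.A0, int(system.starts[0]),
                 float(system.dxs[0]), float(system.betas[0]),
                 system.blood.density, dt, float(root_inflow))
    q_out = np.empty(len(system.term_ends))
    K.apply_terminals(new.A, new.Q, old.A, old.Q, system.A0,
                      system.term_ends, system.term_art,
                      system.starts, system.counts, system.dxs, system.betas,
                      system.blood.density, dt,
                      np.asarray(terminal_pressures, dtype=float), q_out)
    return q_out


def advance(system: ArterialSystem, state: ArterialState1D, dt: float,
            root_inflow: float, terminal_pressures: np.ndarray,
            check_cfl: bool = True) -> tuple[ArterialState1D, np.ndarray]:
    """One full 1-D step: interior scheme + junctions + boundaries +
    conservative half-cell update of the boundary-node areas."""
    new, face_flux = lax_wendroff_step(system, state, dt, check_cfl=check_cfl,
                                       return_face_flux=True)
    solve_junctions(system, state, new, dt)
    q_out = apply_boundaries(system, state, new, dt, root_inflow, terminal_pressures)
    K.conservative_end_update(new.A, new.Q, state.A, face_flux,
                              system.starts, system.counts, system.dxs, dt)
    return new, q_out
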