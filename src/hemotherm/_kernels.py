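"""Numba kernels for the 1-D arterial solver and the 0-D closed loop.

Everything here is plain-array numerics: the object-level modules
(`cv1d`, `cv0d`, `driver`) pack their states into the flat arrays these
kernels consume.  All quantities are SI.

1-D scheme: two-step (Richtmyer) Lax-Wendroff on the area/flow form of
the cross-section-averaged conservation equations, with the elastic
tube law substituted into the momentum flux.  Friction, gravity and
reference-area taper act as sources.  Junctions and the root/terminal
boundaries are closed with Riemann invariants (u +- 4c for this tube
law) and Newton iteration.

0-D scheme: classical RK4 on the stacked volume/flow state of the
peripheral circulations, venae cavae, heart chambers and pulmonary
compartments, with valve flows clamped non-negative.
"""
from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# tube law helpers
# ---------------------------------------------------------------------------


@njit(cache=True)
def tube_pressure(A, A0, beta):
    """Transmural pressure of the elastic tube law."""
    return beta * (np.sqrt(A / A0) - 1.0)


@njit(cache=True)
def wave_speed(A, A0, beta, rho):
    """Local wave speed c = sqrt(beta/(2 rho)) (A/A0)^(1/4)."""
    return np.sqrt(beta / (2.0 * rho)) * (A / A0) ** 0.25


@njit(cache=True)
def _momentum_flux(A, Q, A0h, beta, rho):
    return Q * Q / A + beta * A * np.sqrt(A) / (3.0 * rho * np.sqrt(A0h))


@njit(cache=True)
def _friction(A, Q, fric):
    # 2 pi r nu / delta * (Q / A), with r = sqrt(A/pi)
    r = np.sqrt(A / np.pi)
    return fric * r * Q / A


@njit(cache=True)
def _geom_source(A, dA0dx, A0, beta, rho):
    # taper of the reference area acting as a momentum source
    return beta * A * np.sqrt(A) * dA0dx / (3.0 * rho * A0 * np.sqrt(A0))


@njit(cache=True)
def lw_interior_step(A, Q, Ah, Qh, A0, dA0dx, H, starts, counts, dxs, betas,
                     rho, fric, grav, dt):
    """Advance the interior nodes of every artery by one Richtmyer step.

    ``Ah``/``Qh`` are scratch buffers for the half-step states.  Boundary
    nodes (first/last of each artery) are left untouched.  Returns the
    worst CFL ratio (must stay <= 1) over the advanced grid.
    """
    max_cfl = 0.0
    for a in range(starts.shape[0]):
        s = starts[a]
        n = counts[a]
        dx = dxs[a]
        beta = betas[a]
        # half step: edge-centred states at j+1/2
        for j in range(s, s + n - 1):
            Am = 0.5 * (A[j] + A[j + 1])
            Qm = 0.5 * (Q[j] + Q[j + 1])
            A0h = 0.5 * (A0[j] + A0[j + 1])
            dA0h = 0.5 * (dA0dx[j] + dA0dx[j + 1])
            dHdx = (H[j + 1] - H[j]) / dx
            f_l = _momentum_flux(A[j], Q[j], A0[j], beta, rho)
            f_r = _momentum_flux(A[j + 1], Q[j + 1], A0[j + 1], beta, rho)
            src = (_geom_source(Am, dA0h, A0h, beta, rho)
                   - Am * grav * dHdx - _friction(Am, Qm, fric))
            Ah[j] = Am - 0.5 * dt / dx * (Q[j + 1] - Q[j])
            Qh[j] = Qm - 0.5 * dt / dx * (f_r - f_l) + 0.5 * dt * src
        # full step on interior nodes
        qprev = Qh[s]
        fprev = _momentum_flux(Ah[s], Qh[s], 0.5 * (A0[s] + A0[s + 1]), beta, rho)
        for j in range(s + 1, s + n - 1):
            A0h_r = 0.5 * (A0[j] + A0[j + 1])
            f_here = _momentum_flux(Ah[j], Qh[j], A0h_r, beta, rho)
            Amid = 0.5 * (Ah[j - 1] + Ah[j])
            Qmid = 0.5 * (Qh[j - 1] + Qh[j])
            dHdx = (H[j + 1] - H[j - 1]) / (2.0 * dx)
            src = (_geom_source(Amid, dA0dx[j], A0[j], beta, rho)
                   - Amid * grav * dHdx - _friction(Amid, Qmid, fric))
            A_new = A[j] - dt / dx * (Qh[j] - qprev)
            Q_new = Q[j] - dt / dx * (f_here - fprev) + dt * src
            qprev = Qh[j]
            fprev = f_here
            A[j] = A_new
            Q[j] = Q_new
        for j in range(s, s + n):
            c = wave_speed(A[j], A0[j], beta, rho)
            u = Q[j] / A[j]
            cfl = (abs(u) + c) * dt / dx
            if cfl > max_cfl:
                max_cfl = cfl
    return max_cfl


@njit(cache=True)
def _char_forward(A, Q, A0, beta, rho, dt, dx, j_end):
    """Forward Riemann invariant u + 4c at the foot of the outgoing
    characteristic reaching the distal end node ``j_end`` after dt."""
    u1 = Q[j_end] / A[j_end]
    c1 = wave_speed(A[j_end], A0[j_end], beta, rho)
    w1 = u1 + 4.0 * c1
    u0 = Q[j_end - 1] / A[j_end - 1]
    c0 = wave_speed(A[j_end - 1], A0[j_end - 1], beta, rho)
    w0 = u0 + 4.0 * c0
    xi = (u1 + c1) * dt / dx
    if xi < 0.0:
        xi = 0.0
    elif xi > 1.0:
        xi = 1.0
    return (1.0 - xi) * w1 + xi * w0


@njit(cache=True)
def _char_backward(A, Q, A0, beta, rho, dt, dx, j_start):
    """Backward Riemann invariant u - 4c at the foot of the outgoing
    characteristic reaching the proximal end node ``j_start`` after dt."""
    u1 = Q[j_start] / A[j_start]
    c1 = wave_speed(A[j_start], A0[j_start], beta, rho)
    w1 = u1 - 4.0 * c1
    u0 = Q[j_start + 1] / A[j_start + 1]
    c0 = wave_speed(A[j_start + 1], A0[j_start + 1], beta, rho)
    w0 = u0 - 4.0 * c0
    xi = (c1 - u1) * dt / dx
    if xi < 0.0:
        xi = 0.0
    elif xi > 1.0:
        xi = 1.0
    return (1.0 - xi) * w1 + xi * w0


@njit(cache=True)
def solve_junctions(A, Q, A_old, Q_old, A0, starts, counts, dxs, betas,
                    jn_parent, jn_d1, jn_d2, rho, dt, tol):
    """Resolve every junction: mass conservation + pressure continuity +
    one outgoing characteristic per connected artery end.

    Characteristics are extrapolated from the pre-step state
    (``A_old``/``Q_old``); the solved interface values are written into
    the end nodes of ``A``/``Q``.  Returns the worst damped-Newton
    residual (relative to the parent flow scale).
    """
    worst = 0.0
    for k in range(jn_parent.shape[0]):
        p = jn_parent[k]
        d1 = jn_d1[k]
        d2 = jn_d2[k]
        pe = starts[p] + counts[p] - 1
        s1 = starts[d1]
        two = d2 >= 0
        s2 = starts[d2] if two else s1

        bp = betas[p]
        b1 = betas[d1]
        b2 = betas[d2] if two else b1
        a0p = A0[pe]
        a01 = A0[s1]
        a02 = A0[s2] if two else a01

        w1 = _char_forward(A_old, Q_old, A0, bp, rho, dt, dxs[p], pe)
        v1 = _char_backward(A_old, Q_old, A0, b1, rho, dt, dxs[d1], s1)
        v2 = _char_backward(A_old, Q_old, A0, b2, rho, dt, dxs[d2], s2) if two else 0.0

        ap = A_old[pe]
        a1 = A_old[s1]
        a2 = A_old[s2] if two else a01
        q_scale = abs(Q_old[pe]) + 1e-8
        p_scale = bp

        for _ in range(50):
            cp = wave_speed(ap, a0p, bp, rho)
            c1 = wave_speed(a1, a01, b1, rho)
            up = w1 - 4.0 * cp
            u1 = v1 + 4.0 * c1
            Pp = tube_pressure(ap, a0p, bp)
            P1 = tube_pressure(a1, a01, b1)
            if two:
                c2 = wave_speed(a2, a02, b2, rho)
                u2 = v2 + 4.0 * c2
                P2 = tube_pressure(a2, a02, b2)
                f1 = ap * up - a1 * u1 - a2 * u2
                f2 = Pp - P1
                f3 = Pp - P2
                res = abs(f1) / q_scale + (abs(f2) + abs(f3)) / p_scale
            else:
                u2 = 0.0
                f1 = ap * up - a1 * u1
                f2 = Pp - P1
                f3 = 0.0
                res = abs(f1) / q_scale + abs(f2) / p_scale
            if res < tol:
                break
            # Jacobian entries
            dQp = up - cp            # d(ap*up)/d ap
            dQ1 = -(u1 + c1)         # d(-a1*u1)/d a1
            dPp = bp / (2.0 * np.sqrt(ap * a0p))
            dP1 = b1 / (2.0 * np.sqrt(a1 * a01))
            if two:
                c2 = wave_speed(a2, a02, b2, rho)
                dQ2 = -(u2 + c2)
                dP2 = b2 / (2.0 * np.sqrt(a2 * a02))
                # solve J d = -f with J = [[dQp, dQ1, dQ2],
                #                          [dPp, -dP1, 0 ],
                #                          [dPp, 0,  -dP2]]  (Cramer)
                det = dQp * (dP1 * dP2) + dQ1 * (dPp * dP2) + dQ2 * (dP1 * dPp)
                if det == 0.0:
                    break
                r1, r2, r3 = -f1, -f2, -f3
                da_p = (r1 * dP1 * dP2 + dQ1 * (r2 * dP2) + dQ2 * (dP1 * r3)) / det
                da_1 = (dQp * (r2 * (-dP2)) - r1 * (dPp * (-dP2))
                        + dQ2 * (dPp * r3 - r2 * dPp)) / det
                da_2 = (dQp * (-dP1 * r3) - dQ1 * (dPp * r3 - r2 * dPp)
                        + r1 * (dP1 * dPp)) / det
            else:
                det = dQp * (-dP1) - dQ1 * dPp
                if det == 0.0:
                    break
                da_p = (-f1 * (-dP1) - dQ1 * (-f2)) / det
                da_1 = (dQp * (-f2) - (-f1) * dPp) / det
                da_2 = 0.0
            # damped update keeping areas positive
            lam = 1.0
            for _h in range(30):
                ok = (ap + lam * da_p > 0.1 * a0p) and (a1 + lam * da_1 > 0.1 * a01)
                if two:
                    ok = ok and (a2 + lam * da_2 > 0.1 * a02)
                if ok:
                    break
                lam *= 0.5
            ap += lam * da_p
            a1 += lam * da_1
            if two:
                a2 += lam * da_2
        # write interface values
        cp = wave_speed(ap, a0p, bp, rho)
        up = w1 - 4.0 * cp
        A[pe] = ap
        Q[pe] = ap * up
        c1 = wave_speed(a1, a01, b1, rho)
        u1 = v1 + 4.0 * c1
        A[s1] = a1
        Q[s1] = a1 * u1
        if two:
            c2 = wave_speed(a2, a02, b2, rho)
            u2 = v2 + 4.0 * c2
            A[s2] = a2
            Q[s2] = a2 * u2
        if res > worst:
            worst = res
    return worst


@njit(cache=True)
def apply_root(A, Q, A_old, Q_old, A0, start, dx, beta, rho, dt, Q_root):
    """Prescribed-inflow root boundary closed with the backward characteristic."""
    j = start
    w2 = _char_backward(A_old, Q_old, A0, beta, rho, dt, dx, j)
    a = A_old[j]
    for _ in range(60):
        c = wave_speed(a, A0[j], beta, rho)
        f = Q_root / a - 4.0 * c - w2
        df = -Q_root / (a * a) - c / a
        step = f / df
        a_new = a - step
        if a_new <= 0.05 * A0[j]:
            a_new = 0.5 * (a + 0.05 * A0[j])
        if abs(a_new - a) < 1e-16 + 1e-12 * A0[j]:
            a = a_new
            break
        a = a_new
    A[j] = a
    Q[j] = Q_root


@njit(cache=True)
def apply_terminals(A, Q, A_old, Q_old, A0, term_ends, term_art, starts, counts,
                    dxs, betas, rho, dt, P_term, Q_out):
    """Prescribed-pressure terminal boundaries closed with the forward
    characteristic; fills ``Q_out`` with the resulting terminal flows."""
    for t in range(term_ends.shape[0]):
        j = term_ends[t]
        a_idx = term_art[t]
        beta = betas[a_idx]
        a = A0[j] * (1.0 + P_term[t] / beta) ** 2
        w1 = _char_forward(A_old, Q_old, A0, beta, rho, dt, dxs[a_idx], j)
        u = w1 - 4.0 * wave_speed(a, A0[j], beta, rho)
        A[j] = a
        Q[j] = a * u
        Q_out[t] = Q[j]


@njit(cache=True)
def conservative_end_update(A, Q, A_old, Qh, starts, counts, dxs, dt):
    """Half-cell conservative area update of every boundary node.

    The junction/boundary solves fix the boundary mass fluxes (nodal Q);
    the boundary-node areas are then advanced so that each artery's
    trapezoidal volume changes exactly by its boundary flow integrals,
    making the tree's blood volume bookkeeping exact.  ``Qh`` holds the
    half-step face fluxes from the interior scheme."""
    for a in range(starts.shape[0]):
        s = starts[a]
        e = s + counts[a] - 1
        dx2 = 0.5 * dxs[a]
        a_new = A_old[s] - dt / dx2 * (Qh[s] - Q[s])
        if a_new > 0.0:
            A[s] = a_new
        a_new = A_old[e] - dt / dx2 * (Q[e] - Qh[e - 1])
        if a_new > 0.0:
            A[e] = a_new


# ---------------------------------------------------------------------------
# heart activation (piecewise cosine)
# ---------------------------------------------------------------------------


@njit(cache=True)
def activation_atrium(T, t_cs, t_cp, t_rp):
    wrap = t_cs + t_cp + t_rp - 1.0
    if T <= wrap:
        return 0.5 * (1.0 + np.cos(np.pi * (T + 1.0 - (t_cs + t_cp)) / t_rp))
    if T <= t_cs:
        return 0.0
    if T <= t_cs + t_cp:
        return 0.5 * (1.0 - np.cos(np.pi * (T - t_cs) / t_cp))
    return 0.5 * (1.0 + np.cos(np.pi * (T - (t_cs + t_cp)) / t_rp))


@njit(cache=True)
def activation_ventricle(T, t_cs, t_cp, t_rp):
    if T <= t_cs:
        return 0.0
    if T <= t_cs + t_cp:
        return 0.5 * (1.0 - np.cos(np.pi * (T - t_cs) / t_cp))
    if T <= t_cs + t_cp + t_rp:
        return 0.5 * (1.0 + np.cos(np.pi * (T - (t_cs + t_cp)) / t_rp))
    return 0.0


@njit(cache=True)
def _valve_dq(p_up, p_dw, q, R, B, L):
    if q <= 0.0 and p_up <= p_dw:
        return 0.0
    return (p_up - p_dw - q * R - B * q * abs(q)) / L


# ---------------------------------------------------------------------------
# 0-D right-hand side and RK4
# ---------------------------------------------------------------------------
# State layout (Np peripheral circulations):
#   [0:Np]          V_al   shared arteriole node volumes
#   [Np:5Np]        V_cp   capillary volumes (i*4+r)
#   [5Np:9Np]       V_vn   venule volumes
#   [9Np:10Np]      V_v    collecting vein volumes
#   [10Np:14Np]     Q_al   arteriole branch flows
#   [14Np:18Np]     Q_cp   capillary flows
#   [18Np:22Np]     Q_vn   venule flows
#   [22Np:23Np]     Q_v    vein -> vena cava flows
#   [23Np:23Np+3]   V_vc   vena cava volumes (sup, inf, abd)
#   [+3:+6]         Q_vc   vena cava flows (svc->ra, ivc->avc, avc->ra)
#   [+6:+12]        V_ra, V_rv, V_pa, V_pv, V_la, V_lv
#   [+12:+18]       Q_tri, Q_pvv, Q_pul, Q_pvla, Q_mit, Q_aov
# Heart parameter vector hp:
#   [0:4] E_A (ra,rv,la,lv)  [4:8] E_B  [8:12] S
#   [12:15] atrium (T_cs,T_cp,T_rp)  [15:18] ventricle (T_cs,T_cp,T_rp)
#   [18:22] valve R (tri,pulv,mit,aov) [22:26] valve B [26:30] valve L
#   [30:32] pulm E0 (pa,pv) [32:34] pulm Phi [34:36] pulm S
#   [36] R pa->pv [37] L pa->pv [38] R pv->la [39] L pv->la

N_EXTRA = 18


@njit(cache=True)
def cv0d_rhs(y, dy, phase, Np, pc, pr, vc_par, vc_idx, hp, rho_g_dh, Q_in, P_root):
    """Time derivative of the 0-D state.  Returns the right-atrial pressure
    so callers can monitor it cheaply (any scalar would do)."""
    o_vcp = Np
    o_vvn = 5 * Np
    o_vv = 9 * Np
    o_qal = 10 * Np
    o_qcp = 14 * Np
    o_qvn = 18 * Np
    o_qv = 22 * Np
    o_vc = 23 * Np

    vc_in = np.zeros(3)

    # vena cava pressures
    p_vc = np.empty(3)
    for k in range(3):
        p_vc[k] = y[o_vc + k] / vc_par[k, 0]

    # heart/pulmonary pressures (need flows first)
    q_svc = y[o_vc + 3]
    q_ivc = y[o_vc + 4]
    q_avc = y[o_vc + 5]
    v_h = y[o_vc + 6:o_vc + 12]
    q_h = y[o_vc + 12:o_vc + 18]
    q_tri, q_pvv, q_pul, q_pvla, q_mit, q_aov = q_h[0], q_h[1], q_h[2], q_h[3], q_h[4], q_h[5]

    e_a = activation_atrium(phase, hp[12], hp[13], hp[14])
    e_v = activation_ventricle(phase, hp[15], hp[16], hp[17])

    dv_ra = q_svc + q_avc - q_tri
    dv_rv = q_tri - q_pvv
    dv_pa = q_pvv - q_pul
    dv_pv = q_pul - q_pvla
    dv_la = q_pvla - q_mit
    dv_lv = q_mit - q_aov

    p_ra = (hp[0] * e_a + hp[4]) * v_h[0] + hp[8] * dv_ra
    p_rv = (hp[1] * e_v + hp[5]) * v_h[1] + hp[9] * dv_rv
    p_la = (hp[2] * e_a + hp[6]) * v_h[4] + hp[10] * dv_la
    p_lv = (hp[3] * e_v + hp[7]) * v_h[5] + hp[11] * dv_lv

    x_pa = v_h[2] / hp[32]
    x_pv = v_h[3] / hp[33]
    if x_pa > 50.0:
        x_pa = 50.0
    if x_pv > 50.0:
        x_pv = 50.0
    p_pa = hp[30] * hp[32] * np.exp(x_pa) + hp[34] * dv_pa
    p_pv = hp[31] * hp[33] * np.exp(x_pv) + hp[35] * dv_pv

    # peripheral circulations
    for i in range(Np):
        p_al = y[i] / pc[i, 1]
        p_v = y[o_vv + i] / pc[i, 2]
        sum_qal = 0.0
        sum_qvn = 0.0
        for r in range(4):
            ir = i * 4 + r
            p_cp = y[o_vcp + ir] / pr[i, r, 4]
            p_vn = y[o_vvn + ir] / pr[i, r, 7]
            q_al = y[o_qal + ir]
            q_cp = y[o_qcp + ir]
            q_vn = y[o_qvn + ir]
            dy[o_vcp + ir] = q_al - q_cp
            dy[o_vvn + ir] = q_cp - q_vn
            dy[o_qal + ir] = (p_al - p_cp - pr[i, r, 0] * q_al) / pr[i, r, 1]
            dy[o_qcp + ir] = (p_cp - p_vn - pr[i, r, 2] * q_cp) / pr[i, r, 3]
            dy[o_qvn + ir] = (p_vn - p_v - pr[i, r, 5] * q_vn) / pr[i, r, 6]
            sum_qal += q_al
            sum_qvn += q_vn
        q_v = y[o_qv + i]
        dy[i] = Q_in[i] - sum_qal
        dy[o_vv + i] = sum_qvn - q_v
        k = vc_idx[i]
        dy[o_qv + i] = (p_v - p_vc[k] - pc[i, 3] * q_v - rho_g_dh[i]) / pc[i, 4]
        vc_in[k] += q_v

    # venae cavae: svc -> ra, ivc -> avc, avc -> ra
    dy[o_vc + 0] = vc_in[0] - q_svc
    dy[o_vc + 1] = vc_in[1] - q_ivc
    dy[o_vc + 2] = vc_in[2] + q_ivc - q_avc
    dy[o_vc + 3] = (p_vc[0] - p_ra - vc_par[0, 1] * q_svc) / vc_par[0, 2]
    dy[o_vc + 4] = (p_vc[1] - p_vc[2] - vc_par[1, 1] * q_ivc) / vc_par[1, 2]
    dy[o_vc + 5] = (p_vc[2] - p_ra - vc_par[2, 1] * q_avc) / vc_par[2, 2]

    dy[o_vc + 6] = dv_ra
    dy[o_vc + 7] = dv_rv
    dy[o_vc + 8] = dv_pa
    dy[o_vc + 9] = dv_pv
    dy[o_vc + 10] = dv_la
    dy[o_vc + 11] = dv_lv

    dy[o_vc + 12] = _valve_dq(p_ra, p_rv, q_tri, hp[18], hp[22], hp[26])
    dy[o_vc + 13] = _valve_dq(p_rv, p_pa, q_pvv, hp[19], hp[23], hp[27])
    dy[o_vc + 14] = (p_pa - p_pv - hp[36] * q_pul) / hp[37]
    dy[o_vc + 15] = (p_pv - p_la - hp[38] * q_pvla) / hp[39]
    dy[o_vc + 16] = _valve_dq(p_la, p_lv, q_mit, hp[20], hp[24], hp[28])
    dy[o_vc + 17] = _valve_dq(p_lv, P_root, q_aov, hp[21], hp[25], hp[29])
    return p_ra


@njit(cache=True)
def rk4_0d_step(y, phase, dt, period, Np, pc, pr, vc_par, vc_idx, hp,
                rho_g_dh, Q_in, P_root):
    """One RK4 step of the 0-D loop; boundary values held constant.

    Valve flows are clamped non-negative after the update (diode
    contract).  Returns the new cardiac phase in (0, 1]."""
    n = y.shape[0]
    k1 = np.empty(n)
    k2 = np.empty(n)
    k3 = np.empty(n)
    k4 = np.empty(n)
    yt = np.empty(n)

    ph2 = phase + 0.5 * dt / period
    ph3 = phase + dt / period
    if ph2 > 1.0:
        ph2 -= 1.0
    if ph3 > 1.0:
        ph3 -= 1.0

    cv0d_rhs(y, k1, phase, Np, pc, pr, vc_par, vc_idx, hp, rho_g_dh, Q_in, P_root)
    for j in range(n):
        yt[j] = y[j] + 0.5 * dt * k1[j]
    cv0d_rhs(yt, k2, ph2, Np, pc, pr, vc_par, vc_idx, hp, rho_g_dh, Q_in, P_root)
    for j in range(n):
        yt[j] = y[j] + 0.5 * dt * k2[j]
    cv0d_rhs(yt, k3, ph2, Np, pc, pr, vc_par, vc_idx, hp, rho_g_dh, Q_in, P_root)
    for j in range(n):
        yt[j] = y[j] + dt * k3[j]
    cv0d_rhs(yt, k4, ph3, Np, pc, pr, vc_par, vc_idx, hp, rho_g_dh, Q_in, P_root)
    for j in range(n):
        y[j] += dt / 6.0 * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])

    o = 23 * Np
    for j in (o + 12, o + 13, o + 16, o + 17):  # tri, pulmonary, mitral, aortic
        if y[j] < 0.0:
            y[j] = 0.0
    return ph3


@njit(cache=True)
def advance_coupled(A, Q, Ah, Qh, A_old, Q_old, A0, dA0dx, H,
                    starts, counts, dxs, betas,
                    jn_parent, jn_d1, jn_d2,
                    term_ends, term_art, term_circ, R_da,
                    y, phase, Np, pc, pr, vc_par, vc_idx, hp, rho_g_dh,
                    rho, fric, grav, dt, period, n_steps,
                    Q_term, P_term,
                    rec_nodes, rec_art, rec_buf, sum_qal, sum_qin, sum_aov, sum_dt):
    """Co-advance the 1-D tree and the 0-D loop over ``n_steps`` sub-steps.

    Exchange is lagged by one sub-step: the 0-D loop supplies terminal
    pressures (arteriole-node pressure plus the distal-arterial-end drop
    at the previous terminal flow) and the aortic-valve flow provides the
    1-D root inflow.  ``rec_nodes`` selects 1-D nodes whose pressure is
    recorded each sub-step into ``rec_buf``; ``sum_*`` accumulate flow
    integrals for cycle averaging.  Returns (phase, error_code) where
    error_code 0 = ok, 1 = CFL violation, 2 = non-finite/blow-up.
    """
    o_qal = 10 * Np
    o_aov = 23 * Np + 17
    root = starts[0]
    err = 0
    qin = np.zeros(Np)
    for step in range(n_steps):
        # 0-D -> 1-D boundary data
        P_root = tube_pressure(A[root], A0[root], betas[0])
        for t in range(term_ends.shape[0]):
            i = term_circ[t]
            P_term[t] = y[i] / pc[i, 1] + R_da[i] * Q_term[t]
        q_root_in = y[o_aov]

        # 1-D advance
        for j in range(A.shape[0]):
            A_old[j] = A[j]
            Q_old[j] = Q[j]
        cfl = lw_interior_step(A, Q, Ah, Qh, A0, dA0dx, H, starts, counts,
                               dxs, betas, rho, fric, grav, dt)
        if cfl > 1.0:
            err = 1
            break
        solve_junctions(A, Q, A_old, Q_old, A0, starts, counts, dxs, betas,
                        jn_parent, jn_d1, jn_d2, rho, dt, 1e-12)
        apply_root(A, Q, A_old, Q_old, A0, root, dxs[0], betas[0], rho, dt, q_root_in)
        apply_terminals(A, Q, A_old, Q_old, A0, term_ends, term_art, starts,
                        counts, dxs, betas, rho, dt, P_term, Q_term)
        conservative_end_update(A, Q, A_old, Qh, starts, counts, dxs, dt)

        # 0-D advance with the fresh terminal flows (negative terminal
        # outflow is allowed transiently; the peripheral volume breathes back)
        for i in range(Np):
            qin[i] = 0.0
        for t in range(term_ends.shape[0]):
            qin[term_circ[t]] += Q_term[t]
            sum_qin[term_circ[t]] += Q_term[t] * dt
        phase = rk4_0d_step(y, phase, dt, period, Np, pc, pr, vc_par, vc_idx,
                            hp, rho_g_dh, qin, P_root)

        # accumulate cycle integrals
        for i in range(Np):
            for r in range(4):
                sum_qal[i, r] += y[o_qal + i * 4 + r] * dt
        sum_aov[0] += y[o_aov] * dt
        sum_dt[0] += dt
        for m in range(rec_nodes.shape[0]):
            jn = rec_nodes[m]
            rec_buf[step, m] = tube_pressure(A[jn], A0[jn], betas[rec_art[m]])
        if not np.isfinite(y[o_aov]) or not np.isfinite(A[root]):
            err = 2
            break
        for i in range(Np):
            if abs(y[i] / pc[i, 1]) > 1.0e6:
                err = 2
                break
        if err != 0:
            break
    return phase, err
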