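"""Compiled inner loop of the 1-D solver.

One call advances the whole tree through one cardiac cycle.  The interior
of every segment is integrated with an explicit MacCormack
predictor–corrector of the 1-D mass/momentum equations

    dA/dt + dQ/dx = 0
    dQ/dt + d(Q^2/A)/dx + (A/rho) dP/dx = -2 (zeta_v + 2) pi mu Q / (rho A)

with the Langewouters law closing P(A) node by node.  Boundary nodes are
closed with linearized characteristic invariants (P +/- Z Q with
Z = rho c / A frozen at the local state, interpolated at the foot of the
characteristic): junctions enforce mass conservation and static pressure
continuity in closed form, terminals couple to an implicit-Euler
3-element Windkessel, and the root couples to the elastance ventricle
through the aortic valve's turbulence/inertance pressure-drop law.

All state lives in flat float64 arrays; the layout is produced by
``pulsatree.solver.discretize``.
"""

import numpy as np
from numba import njit

# heart parameter vector layout
HP_V0 = 0
HP_PVEN = 1
HP_RMIT = 2
HP_AMAX = 3
HP_LEFF = 4
HP_KVO = 5
HP_KVC = 6
HP_ZMIN = 7

# inflow modes
MODE_VALVE = 0
MODE_IDEAL_VALVE = 1
MODE_PRESCRIBED_Q = 2


@njit(cache=True)
def _p_of_a(a, am, p0, p1):
    x = a / am - 0.5
    if x > 0.499:
        x = 0.499
    elif x < -0.499:
        x = -0.499
    return p0 + p1 * np.tan(np.pi * x)


@njit(cache=True)
def _a_of_p(p, am, p0, p1):
    return am * (0.5 + np.arctan((p - p0) / p1) / np.pi)


@njit(cache=True)
def _wave_speed(a, am, p0, p1, rho):
    x = a / am - 0.5
    if x > 0.499:
        x = 0.499
    elif x < -0.499:
        x = -0.499
    th = np.tan(np.pi * x)
    ca = am / (np.pi * p1 * (1.0 + th * th))
    return np.sqrt(a / (rho * ca))


@njit(cache=True)
def run_cycle(A, Q, P, As, Qs, Ps,
              Am, P0n, P1n, gam, dAdt, Aprev,
              seg_start, seg_n, dx,
              jparent, jcoff, jchild,
              tseg, tR1, tR2, tC, tPout, tPc,
              mon_idx,
              E_arr, Qin_arr,
              hp, hs,
              inflow_mode, visco_on,
              dt, rho, fric_c,
              P_mon, Q_mon, A_mon, lv_out, vol_io):
    S = seg_start.shape[0]
    N = A.shape[0]
    nsteps = E_arr.shape[0]
    M = mon_idx.shape[0]

    lP = np.empty(S)
    lQ = np.empty(S)
    lA = np.empty(S)
    lc = np.empty(S)
    lP2 = np.empty(S)
    lQ2 = np.empty(S)
    rP = np.empty(S)
    rQ = np.empty(S)
    rA = np.empty(S)
    rc = np.empty(S)
    rP2 = np.empty(S)
    rQ2 = np.empty(S)

    max_cfl = 0.0
    max_seg = -1

    # scratch for the implicit wall-viscosity (diffusion) solve
    max_n = 0
    for s in range(S):
        if seg_n[s] > max_n:
            max_n = seg_n[s]
    td_a = np.empty(max_n)
    td_b = np.empty(max_n)
    td_c = np.empty(max_n)
    td_d = np.empty(max_n)

    for step in range(nsteps):
        # nodal elastic pressure
        for i in range(N):
            P[i] = _p_of_a(A[i], Am[i], P0n[i], P1n[i])

        # snapshot boundary-adjacent values; track CFL number at segment ends
        for s in range(S):
            i0 = seg_start[s]
            i1 = i0 + seg_n[s] - 1
            lP[s] = P[i0]
            lQ[s] = Q[i0]
            lA[s] = A[i0]
            lc[s] = _wave_speed(A[i0], Am[i0], P0n[i0], P1n[i0], rho)
            lP2[s] = P[i0 + 1]
            lQ2[s] = Q[i0 + 1]
            rP[s] = P[i1]
            rQ[s] = Q[i1]
            rA[s] = A[i1]
            rc[s] = _wave_speed(A[i1], Am[i1], P0n[i1], P1n[i1], rho)
            rP2[s] = P[i1 - 1]
            rQ2[s] = Q[i1 - 1]
            cl = (abs(lQ[s] / lA[s]) + lc[s]) * dt / dx[s]
            cr = (abs(rQ[s] / rA[s]) + rc[s]) * dt / dx[s]
            m = cl if cl > cr else cr
            if m > max_cfl:
                max_cfl = m
                max_seg = s

        if visco_on:
            for i in range(N):
                Aprev[i] = A[i]

        # MacCormack predictor (forward differences)
        for s in range(S):
            i0 = seg_start[s]
            i1 = i0 + seg_n[s] - 1
            r = dt / dx[s]
            for i in range(i0, i1):
                As[i] = A[i] - r * (Q[i + 1] - Q[i])
                f2a = Q[i + 1] * Q[i + 1] / A[i + 1]
                f2b = Q[i] * Q[i] / A[i]
                Qs[i] = (Q[i] - r * (f2a - f2b + (A[i] / rho) * (P[i + 1] - P[i]))
                         - dt * fric_c * Q[i] / A[i])
            for i in range(i0, i1):
                Ps[i] = _p_of_a(As[i], Am[i], P0n[i], P1n[i])

        # corrector (backward differences), interior nodes only
        for s in range(S):
            i0 = seg_start[s]
            i1 = i0 + seg_n[s] - 1
            r = dt / dx[s]
            for i in range(i0 + 1, i1):
                f2a = Qs[i] * Qs[i] / As[i]
                f2b = Qs[i - 1] * Qs[i - 1] / As[i - 1]
                a_new = 0.5 * (A[i] + As[i]) - 0.5 * r * (Qs[i] - Qs[i - 1])
                q_new = (0.5 * (Q[i] + Qs[i])
                         - 0.5 * r * (f2a - f2b + (As[i] / rho) * (Ps[i] - Ps[i - 1]))
                         - 0.5 * dt * fric_c * Qs[i] / As[i])
                A[i] = a_new
                Q[i] = q_new

        # junctions: mass + static pressure continuity with the outgoing
        # characteristic of every adjoining segment (linear in Q, P)
        for j in range(jparent.shape[0]):
            p = jparent[j]
            i1 = seg_start[p] + seg_n[p] - 1
            Zp = rho * rc[p] / rA[p]
            up = rQ[p] / rA[p]
            lam = (up + rc[p]) * dt / dx[p]
            if lam < 0.0:
                lam = 0.0
            elif lam > 1.0:
                lam = 1.0
            fp = (1.0 - lam) * (rP[p] + Zp * rQ[p]) + lam * (rP2[p] + Zp * rQ2[p])
            gsum = 1.0 / Zp
            bsum = fp / Zp
            for k in range(jcoff[j], jcoff[j + 1]):
                c = jchild[k]
                Zc = rho * lc[c] / lA[c]
                uc = lQ[c] / lA[c]
                lamc = (lc[c] - uc) * dt / dx[c]
                if lamc < 0.0:
                    lamc = 0.0
                elif lamc > 1.0:
                    lamc = 1.0
                bc = (1.0 - lamc) * (lP[c] - Zc * lQ[c]) + lamc * (lP2[c] - Zc * lQ2[c])
                gsum += 1.0 / Zc
                bsum += bc / Zc
            p_star = bsum / gsum
            Q[i1] = (fp - p_star) / Zp
            A[i1] = _a_of_p(p_star, Am[i1], P0n[i1], P1n[i1])
            for k in range(jcoff[j], jcoff[j + 1]):
                c = jchild[k]
                i0c = seg_start[c]
                Zc = rho * lc[c] / lA[c]
                uc = lQ[c] / lA[c]
                lamc = (lc[c] - uc) * dt / dx[c]
                if lamc < 0.0:
                    lamc = 0.0
                elif lamc > 1.0:
                    lamc = 1.0
                bc = (1.0 - lamc) * (lP[c] - Zc * lQ[c]) + lamc * (lP2[c] - Zc * lQ2[c])
                Q[i0c] = (p_star - bc) / Zc
                A[i0c] = _a_of_p(p_star, Am[i0c], P0n[i0c], P1n[i0c])

        # terminal Windkessels (implicit Euler on the stored pressure)
        for t in range(tseg.shape[0]):
            s = tseg[t]
            i1 = seg_start[s] + seg_n[s] - 1
            Z = rho * rc[s] / rA[s]
            u = rQ[s] / rA[s]
            lam = (u + rc[s]) * dt / dx[s]
            if lam < 0.0:
                lam = 0.0
            elif lam > 1.0:
                lam = 1.0
            f = (1.0 - lam) * (rP[s] + Z * rQ[s]) + lam * (rP2[s] + Z * rQ2[s])
            alpha = 1.0 / (1.0 + dt / (tR2[t] * tC[t]))
            rhs = f - alpha * tPc[t] - alpha * dt * tPout[t] / (tR2[t] * tC[t])
            q_b = rhs / (Z + tR1[t] + alpha * dt / tC[t])
            p_b = f - Z * q_b
            tPc[t] = alpha * (tPc[t] + dt * q_b / tC[t] + dt * tPout[t] / (tR2[t] * tC[t]))
            Q[i1] = q_b
            A[i1] = _a_of_p(p_b, Am[i1], P0n[i1], P1n[i1])
            vol_io[1] += q_b * dt

        # proximal boundary: ventricle + aortic valve (or prescribed flow)
        i0 = seg_start[0]
        Z = rho * lc[0] / lA[0]
        u = lQ[0] / lA[0]
        lam = (lc[0] - u) * dt / dx[0]
        if lam < 0.0:
            lam = 0.0
        elif lam > 1.0:
            lam = 1.0
        b = (1.0 - lam) * (lP[0] - Z * lQ[0]) + lam * (lP2[0] - Z * lQ2[0])

        V = hs[0]
        zeta = hs[1]
        q_av = hs[2]
        p_lv = 0.0
        q_mit = 0.0
        if inflow_mode == MODE_PRESCRIBED_Q:
            q_new = Qin_arr[step]
        else:
            E = E_arr[step]
            p_lv = E * (V - hp[HP_V0])
            if p_lv < 0.0:
                p_lv = 0.0
            q_mit = (hp[HP_PVEN] - p_lv) / hp[HP_RMIT]
            if q_mit < 0.0:
                q_mit = 0.0
            if inflow_mode == MODE_IDEAL_VALVE:
                q_new = (p_lv - b) / Z
                if q_new < 0.0:
                    q_new = 0.0
                zeta = 1.0 if q_new > 0.0 else 0.0
            else:
                if zeta > hp[HP_ZMIN]:
                    a_eff = hp[HP_AMAX] * zeta
                    b_v = rho / (2.0 * a_eff * a_eff)
                    l_v = rho * hp[HP_LEFF] / a_eff
                    q_new = ((l_v / dt * q_av + p_lv - b)
                             / (l_v / dt + b_v * abs(q_av) + Z))
                else:
                    q_new = 0.0
        p_root = b + Z * q_new
        if inflow_mode == MODE_VALVE:
            dp = p_lv - p_root
            rate = (1.0 - zeta) * hp[HP_KVO] * dp if dp > 0.0 else zeta * hp[HP_KVC] * dp
            zeta += dt * rate
            if zeta < 0.0:
                zeta = 0.0
            elif zeta > 1.0:
                zeta = 1.0
        if inflow_mode != MODE_PRESCRIBED_Q:
            V += dt * (q_mit - q_new)
        Q[i0] = q_new
        A[i0] = _a_of_p(p_root, Am[i0], P0n[i0], P1n[i0])
        vol_io[0] += q_new * dt
        hs[0] = V
        hs[1] = zeta
        hs[2] = q_new

        if visco_on:
            # Voigt wall viscosity: P_visc = Gamma dA/dt = -Gamma dQ/dx acts
            # as a diffusion of Q; integrate implicitly (Thomas solve per
            # segment, Dirichlet values at the characteristic-closed ends)
            for s in range(S):
                i0 = seg_start[s]
                n = seg_n[s]
                i1 = i0 + n - 1
                h2 = dx[s] * dx[s]
                for k in range(1, n - 1):
                    i = i0 + k
                    gl = 0.5 * (gam[i - 1] + gam[i])
                    gr = 0.5 * (gam[i] + gam[i + 1])
                    coef = dt * A[i] / (rho * h2)
                    td_a[k] = -coef * gl
                    td_c[k] = -coef * gr
                    td_b[k] = 1.0 + coef * (gl + gr)
                    td_d[k] = Q[i]
                td_b[0] = 1.0
                td_c[0] = 0.0
                td_d[0] = Q[i0]
                td_a[n - 1] = 0.0
                td_b[n - 1] = 1.0
                td_d[n - 1] = Q[i1]
                # forward elimination
                for k in range(1, n):
                    w = td_a[k] / td_b[k - 1]
                    td_b[k] = td_b[k] - w * td_c[k - 1]
                    td_d[k] = td_d[k] - w * td_d[k - 1]
                # back substitution
                Q[i1] = td_d[n - 1] / td_b[n - 1]
                for k in range(n - 2, -1, -1):
                    Q[i0 + k] = (td_d[k] - td_c[k] * Q[i0 + k + 1]) / td_b[k]
            for i in range(N):
                dAdt[i] = (A[i] - Aprev[i]) / dt

        for m in range(M):
            im = mon_idx[m]
            A_mon[step, m] = A[im]
            Q_mon[step, m] = Q[im]
            pm = _p_of_a(A[im], Am[im], P0n[im], P1n[im])
            if visco_on:
                pm += gam[im] * dAdt[im]
            P_mon[step, m] = pm
        lv_out[step, 0] = p_lv
        lv_out[step, 1] = q_new
        lv_out[step, 2] = q_mit
        lv_out[step, 3] = V

    return max_cfl, max_seg
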