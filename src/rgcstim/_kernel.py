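"""Numba time-stepping kernel for the branched cable equation.

Crank-Nicolson voltage update with staggered exact-exponential gate updates
and an O(N) Hines solve on the compartment tree (compartments are ordered so
parent[i] < i).  The extracellular potential enters as an equivalent current
through the axial branches, Ve sampled at compartment midpoints; a spatially
uniform Ve therefore produces exactly zero membrane response.

Everything here is deterministic and sequential, so repeated runs (and runs
distributed across worker processes) are bitwise identical.

Units: mV, ms, uS, nF, nA; conductance densities are converted by the caller.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# indices into the consts vector
(ENA, EK, EL, KD, HILL, CARES, CAOUT, CATAU, NERNST, RATESCALE,
 MSHIFT) = range(11)


@njit(cache=True)
def _exprel(u):
    if abs(u) < 1e-9:
        return 1.0 - 0.5 * u
    return u / np.expm1(u)


@njit(cache=True)
def gate_rates(v, m_shift):
    """(alpha, beta) per gate in order m, h, n, a, ha, c (1/ms)."""
    out = np.empty((6, 2))
    vm = v - m_shift
    out[0, 0] = 6.0 * _exprel(-0.1 * (vm + 30.0))
    out[0, 1] = 20.0 * np.exp(-(vm + 55.0) / 18.0)
    out[1, 0] = 0.4 * np.exp(-(v + 50.0) / 20.0)
    out[1, 1] = 6.0 / (1.0 + np.exp(-0.1 * (v + 20.0)))
    out[2, 0] = 0.2 * _exprel(-0.1 * (v + 40.0))
    out[2, 1] = 0.4 * np.exp(-(v + 50.0) / 80.0)
    out[3, 0] = 0.06 * _exprel(-0.1 * (v + 90.0))
    out[3, 1] = 0.1 * np.exp(-(v + 30.0) / 10.0)
    out[4, 0] = 0.04 * np.exp(-(v + 70.0) / 20.0)
    out[4, 1] = 0.6 / (1.0 + np.exp(-0.1 * (v + 40.0)))
    out[5, 0] = 3.0 * _exprel(-0.1 * (v + 13.0))
    out[5, 1] = 10.0 * np.exp(-(v + 38.0) / 18.0)
    return out


@njit(cache=True)
def simulate(parent, g_ax, c_nf, gbar, area_cm2, cafac, consts,
             v0, gates0, ca0,
             n_steps, dt,
             phi, stim_i,
             inj_comp, inj_na, inj_on, inj_off,
             rec_idx, snap_steps,
             dense, diagnostics):
    """Integrate the cell for n_steps of dt ms.

    parent:   (N,) tree parent per compartment, parent[0] == -1
    g_ax:     (N,) axial conductance to parent, uS (g_ax[0] unused)
    c_nf:     (N,) membrane capacitance, nF
    gbar:     (N, 6) max conductances gna gk ga gca gkca gl, uS
    cafac:    (N,) uA/cm^2 -> mM/ms conversion for the calcium shell
    phi:      (N,) extracellular transfer vector, mV per uA
    stim_i:   (n_steps + 1,) stimulus current (uA) at step boundaries
    inj_*:    rectangular intracellular injections (nA, step windows)
    rec_idx:  compartments recorded every step
    snap_steps: sorted step indices at which to snapshot whole-cell Vm
    dense:    solve the linear system densely instead of via the tree solver
    diagnostics: track the worst per-step charge-balance residual

    Returns (v_rec, snaps, first_cross, v, gates, ca, max_residual) where
    first_cross[i] is the step index of compartment i's first upward 0 mV
    crossing (-1 if none).
    """
    n = parent.shape[0]
    v = v0.copy()
    gates = gates0.copy()
    ca = ca0.copy()

    n_rec = rec_idx.shape[0]
    v_rec = np.empty((n_rec, n_steps + 1))
    for k in range(n_rec):
        v_rec[k, 0] = v[rec_idx[k]]
    snaps = np.empty((snap_steps.shape[0], n))
    snap_ptr = 0
    if snap_steps.shape[0] > 0 and snap_steps[0] == 0:
        snaps[0, :] = v
        snap_ptr = 1
    first_cross = np.full(n, -1, dtype=np.int64)

    diag = np.empty(n)
    rhs = np.empty(n)
    gtot = np.empty(n)
    btot = np.empty(n)
    ve_a = np.empty(n)
    ve_b = np.empty(n)
    src = np.empty(n)
    max_resid = 0.0

    ena = consts[ENA]
    ek = consts[EK]
    el = consts[EL]
    kd = consts[KD]
    hill = consts[HILL]
    ca_res = consts[CARES]
    ca_out = consts[CAOUT]
    tau = consts[CATAU]
    nernst = consts[NERNST]
    rscale = consts[RATESCALE]
    m_shift = consts[MSHIFT]

    for step in range(n_steps):
        t_mid = (step + 0.5) * dt
        # gates: exact exponential relaxation at V^n
        for i in range(n):
            r = gate_rates(v[i], m_shift)
            for g in range(6):
                a = r[g, 0] * rscale
                b = r[g, 1] * rscale
                inf = a / (a + b)
                gates[i, g] = inf + (gates[i, g] - inf) * np.exp(-dt * (a + b))

        # calcium pool: exact linear-ODE update driven by I_Ca at V^n
        for i in range(n):
            eca = nernst * np.log(ca_out / ca[i])
            c3 = gates[i, 5] ** 3
            ica_dens = gbar[i, 3] * c3 * (v[i] - eca) * 1e-3 / area_cm2[i]
            source = -ica_dens * cafac[i]
            target = ca_res + source * tau
            newca = target + (ca[i] - target) * np.exp(-dt / tau)
            ca[i] = newca if newca > ca_res else ca_res

        # linearized membrane: I_ion = gtot*V - btot (uS, uS*mV)
        for i in range(n):
            m3h = gates[i, 0] ** 3 * gates[i, 1]
            n4 = gates[i, 2] ** 4
            a3h = gates[i, 3] ** 3 * gates[i, 4]
            c3 = gates[i, 5] ** 3
            x = (ca[i] / kd) ** hill
            fkca = x / (1.0 + x)
            eca = nernst * np.log(ca_out / ca[i])
            g_na = gbar[i, 0] * m3h
            g_k = gbar[i, 1] * n4
            g_a = gbar[i, 2] * a3h
            g_ca = gbar[i, 3] * c3
            g_kca = gbar[i, 4] * fkca
            g_l = gbar[i, 5]
            gtot[i] = g_na + g_k + g_a + g_ca + g_kca + g_l
            btot[i] = (g_na * ena + (g_k + g_a + g_kca) * ek
                       + g_ca * eca + g_l * el)

        # extracellular potentials at both step boundaries
        ia = stim_i[step]
        ib = stim_i[step + 1]
        for i in range(n):
            ve_a[i] = phi[i] * ia
            ve_b[i] = phi[i] * ib

        # sources: axial Ve coupling (time-centered) + injections
        for i in range(n):
            src[i] = 0.0
        for i in range(1, n):
            p = parent[i]
            d_ve = 0.5 * ((ve_a[p] - ve_a[i]) + (ve_b[p] - ve_b[i]))
            src[i] += g_ax[i] * d_ve
            src[p] -= g_ax[i] * d_ve
        for k in range(inj_comp.shape[0]):
            if inj_on[k] <= t_mid < inj_off[k]:
                src[inj_comp[k]] += inj_na[k]

        # Crank-Nicolson system on the tree
        for i in range(n):
            diag[i] = c_nf[i] / dt + 0.5 * gtot[i]
            rhs[i] = (c_nf[i] / dt - 0.5 * gtot[i]) * v[i] + btot[i] + src[i]
        for i in range(1, n):
            p = parent[i]
            diag[i] += 0.5 * g_ax[i]
            diag[p] += 0.5 * g_ax[i]
            rhs[i] += 0.5 * g_ax[i] * (v[p] - v[i])
            rhs[p] += 0.5 * g_ax[i] * (v[i] - v[p])

        if dense:
            mat = np.zeros((n, n))
            for i in range(n):
                mat[i, i] = diag[i]
            for i in range(1, n):
                p = parent[i]
                mat[i, p] = -0.5 * g_ax[i]
                mat[p, i] = -0.5 * g_ax[i]
            v_new = np.linalg.solve(mat, rhs.copy())
        else:
            d2 = diag.copy()
            r2 = rhs.copy()
            for i in range(n - 1, 0, -1):
                p = parent[i]
                f = (-0.5 * g_ax[i]) / d2[i]
                d2[p] -= f * (-0.5 * g_ax[i])
                r2[p] -= f * r2[i]
            v_new = np.empty(n)
            v_new[0] = r2[0] / d2[0]
            for i in range(1, n):
                v_new[i] = (r2[i] + 0.5 * g_ax[i] * v_new[parent[i]]) / d2[i]

        if diagnostics:
            # residual of the CN balance per compartment, relative to the
            # largest single current term anywhere this step
            big = 0.0
            worst = 0.0
            for i in range(n):
                cap = c_nf[i] * (v_new[i] - v[i]) / dt
                ion = 0.5 * gtot[i] * (v_new[i] + v[i]) - btot[i]
                r_i = cap + ion - src[i]
                if abs(cap) > big:
                    big = abs(cap)
                if abs(ion) > big:
                    big = abs(ion)
                if abs(src[i]) > big:
                    big = abs(src[i])
                if parent[i] >= 0:
                    a_term = 0.5 * g_ax[i] * ((v_new[parent[i]] - v_new[i])
                                              + (v[parent[i]] - v[i]))
                    r_i -= a_term
                    if abs(a_term) > big:
                        big = abs(a_term)
                for j in range(1, n):
                    if parent[j] == i:
                        a_term = 0.5 * g_ax[j] * ((v_new[j] - v_new[i])
                                                  + (v[j] - v[i]))
                        r_i -= a_term
                        if abs(a_term) > big:
                            big = abs(a_term)
                if abs(r_i) > worst:
                    worst = abs(r_i)
            if big > 0.0 and worst / big > max_resid:
                max_resid = worst / big

        for i in range(n):
            if first_cross[i] < 0 and v[i] < 0.0 <= v_new[i]:
                first_cross[i] = step + 1
            v[i] = v_new[i]

        for k in range(n_rec):
            v_rec[k, step + 1] = v[rec_idx[k]]
        if snap_ptr < snap_steps.shape[0] and snap_steps[snap_ptr] == step + 1:
            snaps[snap_ptr, :] = v
            snap_ptr += 1

    return v_rec, snaps, first_cross, v, gates, ca, max_resid
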