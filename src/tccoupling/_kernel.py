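"""Low-level integration kernel for the branched cable equation.

Backward-Euler time stepping with a staggered gate update: gate variables
relax analytically toward their steady state at the previous voltage, then
the linearized membrane system is solved exactly on the tree in O(n) using
Hines elimination (children are eliminated into their parents, which is
possible because segments are stored parent-before-child).

Everything here operates on flat numpy arrays so the hot loop can be
compiled with numba; :mod:`tccoupling.simulator` builds the arrays.  When
numba is unavailable the same functions run as pure Python.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(fn):
            return fn

        return wrap


@njit(cache=True)
def hines_solve(parent, a_par, diag, rhs, v_out):
    """Exact solve of the symmetric tree system in place.

    Equation i:  diag[i]*V_i - a_par[i]*V_parent - sum_children a_par[c]*V_c
    = rhs[i].  ``diag`` and ``rhs`` are destroyed.
    """
    n = parent.shape[0]
    for i in range(n - 1, 0, -1):
        p = parent[i]
        f = a_par[i] / diag[i]
        diag[p] -= f * a_par[i]
        rhs[p] += f * rhs[i]
    v_out[0] = rhs[0] / diag[0]
    for i in range(1, n):
        v_out[i] = (rhs[i] + a_par[i] * v_out[parent[i]]) / diag[i]


@njit(cache=True)
def _gate_inf_tau(v, ca, vhalf, k, tmin, tamp, vtau, sigma, q, cadep, cahalf, cahill):
    if cadep:
        c = ca if ca > 1e-12 else 1e-12
        inf = 1.0 / (1.0 + (cahalf / c) ** cahill)
        tau = tmin / q
    else:
        inf = 1.0 / (1.0 + math.exp(-(v - vhalf) / k))
        u = (v - vtau) / sigma
        tau = (tmin + tamp / (math.exp(u) + math.exp(-u))) / q
    return inf, tau


@njit(cache=True)
def integrate(
    # topology / passive
    parent, a_par, cm_dt, gl, el,
    # channels (CSR over active segments)
    chan_ptr, chan_seg, chan_gbar, chan_erev, chan_isca, chan_caflux, chan_gptr,
    # gates
    gate_vhalf, gate_k, gate_tmin, gate_tamp, gate_vtau, gate_sigma,
    gate_q, gate_cadep, gate_cahalf, gate_cahill, gate_power, gate_off, gx,
    # calcium pool
    ca, ca_factor, ca_rest, ca_tau, nernst_coef, ca_out,
    # synapses
    syn_seg, syn_g, syn_e, syn_nmda, syn_eta, syn_gamma, fr, fd, A, B,
    # events (absolute step indices, sorted) and injections
    ev_step, ev_syn, ev_w, inj_seg, inj,
    # probes / recording
    probe_seg, stride, out,
    # state / loop control
    v, dt, step0, nsteps, theta,
):
    n = parent.shape[0]
    nc = chan_ptr.shape[0] - 1
    m = syn_seg.shape[0]
    K = ev_step.shape[0]
    ni = inj_seg.shape[0]
    npr = probe_seg.shape[0]

    diag = np.empty(n)
    rhs = np.empty(n)
    awork = np.empty(n)
    gadd = np.empty(n)
    geadd = np.empty(n)
    gca = np.empty(n)
    gcae = np.empty(n)
    vnew = np.empty(n)

    ev_i = 0
    while ev_i < K and ev_step[ev_i] < step0:
        ev_i += 1
    rec_i = 0
    # record initial sample at step0
    for p in range(npr):
        out[p, rec_i] = v[probe_seg[p]]
    rec_i += 1

    dexp_ca = math.exp(-dt / ca_tau)

    for istep in range(step0, step0 + nsteps):
        for i in range(n):
            gadd[i] = 0.0
            geadd[i] = 0.0
            gca[i] = 0.0
            gcae[i] = 0.0

        # synaptic events scheduled for this step
        while ev_i < K and ev_step[ev_i] == istep:
            s = ev_syn[ev_i]
            A[s] += ev_w[ev_i]
            B[s] += ev_w[ev_i]
            ev_i += 1

        # double-exponential state decay and conductance accumulation
        # (states are flushed to zero once negligible: avoids denormals)
        for s in range(m):
            if A[s] != 0.0:
                A[s] *= fr[s]
                if A[s] < 1e-12:
                    A[s] = 0.0
            if B[s] != 0.0:
                B[s] *= fd[s]
                if B[s] < 1e-12:
                    B[s] = 0.0
            g = syn_g[s] * (B[s] - A[s])
            if g != 0.0:
                if syn_nmda[s]:
                    g = g / (1.0 + syn_eta[s] * math.exp(-syn_gamma[s] * v[syn_seg[s]]))
                gadd[syn_seg[s]] += g
                geadd[syn_seg[s]] += g * syn_e[s]

        # gate relaxation at the previous voltage (staggered update)
        for c in range(nc):
            for g in range(chan_gptr[c], chan_gptr[c + 1]):
                off = gate_off[g]
                for j in range(chan_ptr[c], chan_ptr[c + 1]):
                    i = chan_seg[j]
                    inf, tau = _gate_inf_tau(
                        v[i], ca[i], gate_vhalf[g], gate_k[g], gate_tmin[g],
                        gate_tamp[g], gate_vtau[g], gate_sigma[g], gate_q[g],
                        gate_cadep[g], gate_cahalf[g], gate_cahill[g])
                    idx = off + j - chan_ptr[c]
                    gx[idx] = inf + (gx[idx] - inf) * math.exp(-dt / tau)

        # channel conductances
        for c in range(nc):
            for j in range(chan_ptr[c], chan_ptr[c + 1]):
                i = chan_seg[j]
                gprod = chan_gbar[j]
                if gprod == 0.0:
                    continue
                for g in range(chan_gptr[c], chan_gptr[c + 1]):
                    x = gx[gate_off[g] + j - chan_ptr[c]]
                    for _ in range(gate_power[g]):
                        gprod *= x
                if chan_isca[c]:
                    erev = nernst_coef * math.log(ca_out / ca[i])
                else:
                    erev = chan_erev[c]
                gadd[i] += gprod
                geadd[i] += gprod * erev
                if chan_caflux[c]:
                    gca[i] += gprod
                    gcae[i] += gprod * erev

        # assemble and solve (theta-method: 1 = backward Euler, 0.5 = CN)
        omt = 1.0 - theta
        for i in range(n):
            gtot = gl[i] + gadd[i]
            ge = gl[i] * el[i] + geadd[i]
            diag[i] = cm_dt[i] + theta * gtot
            rhs[i] = cm_dt[i] * v[i] + theta * ge + omt * (ge - gtot * v[i])
        for k in range(ni):
            rhs[inj_seg[k]] += inj[k, istep - step0]
        for i in range(1, n):
            diag[i] += theta * a_par[i]
            diag[parent[i]] += theta * a_par[i]
            if omt != 0.0:
                p = parent[i]
                ax = a_par[i] * (v[p] - v[i])
                rhs[i] += omt * ax
                rhs[p] -= omt * ax
        for i in range(n):
            awork[i] = theta * a_par[i]
        hines_solve(parent, awork, diag, rhs, vnew)

        blown = False
        for i in range(n):
            if not math.isfinite(vnew[i]):
                blown = True
            v[i] = vnew[i]
        if blown:
            return istep

        # submembrane calcium pool (exponential Euler with the new voltage)
        for i in range(n):
            if gca[i] != 0.0 or ca[i] != ca_rest:
                ica = gca[i] * v[i] - gcae[i]  # nA; inward is negative
                ca_inf = ca_rest - ica * ca_factor[i] * ca_tau
                ca[i] = ca_inf + (ca[i] - ca_inf) * dexp_ca

        if (istep + 1 - step0) % stride == 0 and rec_i < out.shape[1]:
            for p in range(npr):
                out[p, rec_i] = v[probe_seg[p]]
            rec_i += 1

    return -1
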