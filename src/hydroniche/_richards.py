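"""Compiled inner kernels of the Richards solver.

The solver spends essentially all of its time in the damped-Newton substep;
these numba kernels implement it over plain arrays.  The math mirrors the
documentation in :mod:`hydroniche.soilwater`: mixed-form mass residual,
geometric-mean internodal conductivity, smooth (soft-min) limitation of the
rain flux by the ponded-surface Darcy flux, supply-limited evaporation and
Feddes-reduced transpiration as sink terms, chord-slope storage
linearization, analytic dK/dh terms, Thomas tridiagonal solve, and a
backtracking line search on the residual norm.
"""

from __future__ import annotations

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_FAIL = 1


@njit(cache=True)
def _theta_cell(h, tr, thm, ts, al, en, em, hs, ss):
    if h < hs:
        return tr + (thm - tr) * (1.0 + abs(al * h) ** en) ** (-em)
    return ts + ss * (h - hs)


@njit(cache=True)
def _capacity_cell(h, tr, thm, al, en, em, hs, ss):
    if h < hs:
        ah = abs(al * h)
        c = (thm - tr) * al * en * em * ah ** (en - 1.0) * (1.0 + ah**en) ** (
            -em - 1.0
        )
        return c if c > 1e-12 else 1e-12
    return ss


@njit(cache=True)
def _K_cell(h, al, en, em, ks, el, hs):
    if h >= hs:
        return ks
    se = (1.0 + abs(al * h) ** en) ** (-em)
    if se < 1e-12:
        se = 1e-12
    u = se ** (1.0 / em)
    f = 1.0 - (1.0 - u) ** em
    return ks * se**el * f * f


@njit(cache=True)
def _Kprime_cell(h, al, en, em, ks, el, hs):
    if h >= hs:
        return 0.0
    se = (1.0 + abs(al * h) ** en) ** (-em)
    if se < 1e-12:
        se = 1e-12
    if se > 1.0 - 1e-9:
        se = 1.0 - 1e-9
    u = se ** (1.0 / em)
    f = 1.0 - (1.0 - u) ** em
    dk_dse = ks * (
        el * se ** (el - 1.0) * f * f
        + 2.0 * se**el * f * (1.0 - u) ** (em - 1.0) * se ** (1.0 / em - 1.0)
    )
    ah = abs(al * h)
    dse_dh = al * en * em * ah ** (en - 1.0) * (1.0 + ah**en) ** (-em - 1.0)
    out = dk_dse * dse_dh
    return out if out < 1e6 else 1e6


@njit(cache=True)
def _feddes_cell(h, f1, f2, f3, f4):
    if h >= f1 or h <= f4:
        return 0.0
    if h > f2:  # ramp down toward anaerobic limit
        return (f1 - h) / (f1 - f2)
    if h >= f3:
        return 1.0
    return (h - f4) / (f3 - f4)


@njit(cache=True)
def _residual(
    h, theta0, dt, rain, ep, tp, bdens, edens,
    tr, ts, thm, al, en, em, ks, el,
    hs, ss, h_dry, h_pond, ln_dry_ratio, h_wet,
    fp1, fp2, fp3, fp4, dz, free_drain,
    F, K, th, Kint, grad, sink_t, sink_e,
):
    """Fill residual and flux arrays; returns (res, qtop, qbot, g_top, evap)."""
    n = h.size
    for i in range(n):
        K[i] = _K_cell(h[i], al[i], en[i], em[i], ks[i], el[i], hs)
        th[i] = _theta_cell(h[i], tr[i], thm[i], ts[i], al[i], en[i], em[i], hs, ss)
    for i in range(n - 1):
        Kint[i] = np.sqrt(K[i] * K[i + 1])
        grad[i] = (h[i + 1] - h[i]) / dz

    k_surf = 0.5 * (ks[0] + K[0])
    imax = k_surf * (1.0 - 2.0 * (h[0] - h_pond) / dz)
    w = 1e-3 * k_surf
    if w < 1e-12:
        w = 1e-12
    d = (rain - imax) / w
    if d > 40.0:
        qtop = imax
        weight = 1.0
    elif d < -40.0:
        qtop = rain
        weight = 0.0
    else:
        weight = 1.0 / (1.0 + np.exp(-d))
        lo = rain if rain < imax else imax
        ad = d if d > 0 else -d
        qtop = lo - w * np.log1p(np.exp(-ad))
    g_top = weight * 2.0 * k_surf / dz
    qbot = K[n - 1] if free_drain else 0.0

    evap = 0.0
    for i in range(n):
        a = _feddes_cell(h[i], fp1, fp2, fp3, fp4)
        sink_t[i] = tp * bdens[i] * a
        if edens[i] > 0.0:
            hi = h[i]
            if hi >= h_wet:
                beta = 1.0
            elif hi <= h_dry:
                beta = 0.0
            else:
                beta = (np.log(-h_dry) - np.log(-hi)) / ln_dry_ratio
            sink_e[i] = ep * edens[i] * beta
            evap += sink_e[i] * dz
        else:
            sink_e[i] = 0.0

    res = 0.0
    for i in range(n):
        q_in = qtop if i == 0 else Kint[i - 1] * (1.0 - grad[i - 1])
        q_out = qbot if i == n - 1 else Kint[i] * (1.0 - grad[i])
        F[i] = (th[i] - theta0[i]) * dz / dt + (sink_t[i] + sink_e[i]) * dz - (
            q_in - q_out
        )
        af = F[i] if F[i] > 0 else -F[i]
        if af > res:
            res = af
    return res, qtop, qbot, g_top, evap


@njit(cache=True)
def _thomas(lower, diag, upper, rhs, x, cp, dp):
    n = diag.size
    cp[0] = upper[0] / diag[0]
    dp[0] = rhs[0] / diag[0]
    for i in range(1, n):
        m = diag[i] - lower[i] * cp[i - 1]
        if i < n - 1:
            cp[i] = upper[i] / m
        dp[i] = (rhs[i] - lower[i] * dp[i - 1]) / m
    x[n - 1] = dp[n - 1]
    for i in range(n - 2, -1, -1):
        x[i] = dp[i] - cp[i] * x[i + 1]


@njit(cache=True)
def substep(
    h_io, theta_io, dt, rain, ep, tp, bdens, edens,
    tr, ts, thm, al, en, em, ks, el,
    hs, ss, h_dry, h_pond, h_wet,
    fp1, fp2, fp3, fp4, dz, free_drain,
    tol_mass, max_iter,
    sink_out,
):
    """One implicit substep; mutates h_io/theta_io/sink_out on success.

    Returns (status, n_iter, qtop, qbot, runoff, evap).
    """
    n = h_io.size
    h0 = h_io.copy()
    theta0 = theta_io.copy()
    ln_dry_ratio = np.log(-h_dry) - np.log(-h_wet)

    F = np.empty(n)
    K = np.empty(n)
    th = np.empty(n)
    Kint = np.empty(n - 1)
    grad = np.empty(n - 1)
    sink_t = np.empty(n)
    sink_e = np.empty(n)
    F2 = np.empty(n)
    K2 = np.empty(n)
    th2 = np.empty(n)
    Kint2 = np.empty(n - 1)
    grad2 = np.empty(n - 1)
    sink_t2 = np.empty(n)
    sink_e2 = np.empty(n)
    lower = np.empty(n)
    diag = np.empty(n)
    upper = np.empty(n)
    delta = np.empty(n)
    h_try = np.empty(n)
    cp = np.empty(n)
    dp = np.empty(n)

    h = h0.copy()
    res, qtop, qbot, g_top, evap = _residual(
        h, theta0, dt, rain, ep, tp, bdens, edens,
        tr, ts, thm, al, en, em, ks, el,
        hs, ss, h_dry, h_pond, ln_dry_ratio, h_wet,
        fp1, fp2, fp3, fp4, dz, free_drain,
        F, K, th, Kint, grad, sink_t, sink_e,
    )

    for it in range(max_iter):
        if res * dt < tol_mass:
            runoff = rain - qtop
            if runoff < 0.0:
                runoff = 0.0
            for i in range(n):
                h_io[i] = h[i]
                theta_io[i] = th[i] - F[i] * dt / dz
                sink_out[i] = sink_t[i]
            return STATUS_OK, it, qtop, qbot, runoff, evap

        # Jacobian assembly
        for i in range(n):
            c = _capacity_cell(h[i], tr[i], thm[i], al[i], en[i], em[i], hs, ss)
            dh = h[i] - h0[i]
            adh = dh if dh > 0 else -dh
            if adh > 1e-4:
                chord = (th[i] - theta0[i]) / dh
                if chord > 1e-12:
                    c = chord
            # evaporation supply-limitation slope (stabilizing)
            g_sink = 0.0
            if edens[i] > 0.0 and h_dry < h[i] < h_wet:
                g_sink = -ep * edens[i] / (h[i] * ln_dry_ratio) * dz
            diag[i] = c * dz / dt + g_sink
            lower[i] = 0.0
            upper[i] = 0.0
        for i in range(n - 1):
            G = Kint[i] / dz
            kp_lo = _Kprime_cell(h[i], al[i], en[i], em[i], ks[i], el[i], hs)
            kp_hi = _Kprime_cell(h[i + 1], al[i + 1], en[i + 1], em[i + 1],
                                 ks[i + 1], el[i + 1], hs)
            klo = K[i] if K[i] > 1e-30 else 1e-30
            khi = K[i + 1] if K[i + 1] > 1e-30 else 1e-30
            omg = 1.0 - grad[i]
            half_lo = 0.5 * Kint[i] / klo * kp_lo * omg
            half_hi = 0.5 * Kint[i] / khi * kp_hi * omg
            diag[i] += G + half_lo
            diag[i + 1] += G - half_hi
            upper[i] = -G + half_hi
            lower[i + 1] = -G - half_lo
        diag[0] += g_top
        if free_drain:
            diag[n - 1] += _Kprime_cell(
                h[n - 1], al[n - 1], en[n - 1], em[n - 1], ks[n - 1], el[n - 1], hs
            )
        for i in range(n):
            if diag[i] < 1e-12:
                diag[i] = 1e-12
            F2[i] = -F[i]
        _thomas(lower, diag, upper, F2, delta, cp, dp)

        dmax = 0.0
        for i in range(n):
            ad = delta[i] if delta[i] > 0 else -delta[i]
            if ad > dmax:
                dmax = ad
        if dmax > 5.0e4:
            s = 5.0e4 / dmax
            for i in range(n):
                delta[i] *= s

        step = 1.0
        improved = False
        res2 = res
        qtop2 = qtop
        qbot2 = qbot
        g_top2 = g_top
        evap2 = evap
        while step > 1.0 / 2048.0:
            for i in range(n):
                v = h[i] + step * delta[i]
                if v < -1.0e7:
                    v = -1.0e7
                elif v > 50.0:
                    v = 50.0
                h_try[i] = v
            res2, qtop2, qbot2, g_top2, evap2 = _residual(
                h_try, theta0, dt, rain, ep, tp, bdens, edens,
                tr, ts, thm, al, en, em, ks, el,
                hs, ss, h_dry, h_pond, ln_dry_ratio, h_wet,
                fp1, fp2, fp3, fp4, dz, free_drain,
                F2, K2, th2, Kint2, grad2, sink_t2, sink_e2,
            )
            if res2 < res:
                improved = True
                break
            step *= 0.5
        if not improved:
            if res * dt < 10.0 * tol_mass:
                runoff = rain - qtop
                if runoff < 0.0:
                    runoff = 0.0
                for i in range(n):
                    h_io[i] = h[i]
                    theta_io[i] = th[i] - F[i] * dt / dz
                    sink_out[i] = sink_t[i]
                return STATUS_OK, it, qtop, qbot, runoff, evap
            return STATUS_FAIL, it, 0.0, 0.0, 0.0, 0.0
        for i in range(n):
            h[i] = h_try[i]
            F[i] = F2[i]
            K[i] = K2[i]
            th[i] = th2[i]
            sink_t[i] = sink_t2[i]
            sink_e[i] = sink_e2[i]
        for i in range(n - 1):
            Kint[i] = Kint2[i]
            grad[i] = grad2[i]
        res = res2
        qtop = qtop2
        qbot = qbot2
        g_top = g_top2
        evap = evap2
    return STATUS_FAIL, max_iter, 0.0, 0.0, 0.0, 0.0
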