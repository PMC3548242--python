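"""Numba kernels for the generative integrator and the Kalman passes.

The flows implemented here mirror the reference implementations in
:mod:`slowmodes.generative` (cross-checked by unit tests); they exist so
that dense stochastic simulation and the many extended-Kalman filter passes
required by finite-difference free-energy optimization run at compiled
speed.

State layout for the joint filter: ``z = [x_n (n), x_h (4 per region,
region-major)]`` with dimension ``d = 5 n``.  Hemodynamic parameter rows
are ``(kappa_s, kappa_f, tau0, alpha, E0, epsilon0)``; observation constant
rows are ``(V0, k1, k2, epsilon0)``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_NOPYTHON = {"cache": True, "fastmath": False}


@njit(**_NOPYTHON)
def hemo_flow(xh, xn, hp):
    """Balloon flow for one region. xh: (4,), xn scalar, hp: (6,)."""
    ks, kf, tau0, alpha, e0, _eps0 = hp[0], hp[1], hp[2], hp[3], hp[4], hp[5]
    s = xh[0]
    # saturate the log states at +/-5 so that explicit-integrator
    # intermediates cannot overflow the exponentials; the filter and the
    # simulator clamp the actual trajectory well inside this range
    lf = min(max(xh[1], -5.0), 5.0)
    lv = min(max(xh[2], -5.0), 5.0)
    lq = min(max(xh[3], -5.0), 5.0)
    f = np.exp(lf)
    extraction = 1.0 - (1.0 - e0) ** np.exp(-lf)
    out = np.empty(4)
    out[0] = xn - ks * s - kf * (f - 1.0)
    out[1] = s * np.exp(-lf)
    out[2] = (f - np.exp(lv / alpha)) * np.exp(-lv) / tau0
    out[3] = (np.exp(lf - lq) * extraction / e0 - np.exp((1.0 - alpha) * lv / alpha)) / tau0
    return out


@njit(**_NOPYTHON)
def full_flow(z, a, hp, u):
    """Joint neural + hemodynamic flow. z: (5n,), u: (n,) drive."""
    n = a.shape[0]
    dz = np.empty(z.shape[0])
    for i in range(n):
        acc = u[i]
        for j in range(n):
            acc += a[i, j] * z[j]
        dz[i] = acc
    for r in range(n):
        dh = hemo_flow(z[n + 4 * r : n + 4 * r + 4], z[r], hp[r])
        for j in range(4):
            dz[n + 4 * r + j] = dh[j]
    return dz


@njit(**_NOPYTHON)
def full_jac(z, a, hp):
    """Jacobian of :func:`full_flow` with respect to z."""
    n = a.shape[0]
    d = 5 * n
    jac = np.zeros((d, d))
    for i in range(n):
        for j in range(n):
            jac[i, j] = a[i, j]
    for r in range(n):
        ks, kf, tau0, alpha, e0 = hp[r, 0], hp[r, 1], hp[r, 2], hp[r, 3], hp[r, 4]
        o = n + 4 * r
        s, lf, lv, lq = z[o], z[o + 1], z[o + 2], z[o + 3]
        ef = np.exp(lf)
        b = 1.0 - e0
        u_ = np.exp(-lf)
        bu = b**u_
        extraction = 1.0 - bu
        # row s
        jac[o, r] = 1.0
        jac[o, o] = -ks
        jac[o, o + 1] = -kf * ef
        # row ln f
        jac[o + 1, o] = np.exp(-lf)
        jac[o + 1, o + 1] = -s * np.exp(-lf)
        # row ln v
        jac[o + 2, o + 1] = np.exp(lf - lv) / tau0
        jac[o + 2, o + 2] = (
            -np.exp(lf - lv) - (1.0 / alpha - 1.0) * np.exp(lv * (1.0 / alpha - 1.0))
        ) / tau0
        # row ln q
        jac[o + 3, o + 1] = (
            np.exp(lf - lq) * extraction + np.log(b) * bu * np.exp(-lq)
        ) / (e0 * tau0)
        jac[o + 3, o + 2] = -((1.0 - alpha) / alpha) * np.exp((1.0 - alpha) * lv / alpha) / tau0
        jac[o + 3, o + 3] = -np.exp(lf - lq) * extraction / (e0 * tau0)
    return jac


@njit(**_NOPYTHON)
def observe(z, oc):
    """BOLD observation per region. oc rows: (V0, k1, k2, eps0)."""
    n = oc.shape[0]
    y = np.empty(n)
    for r in range(n):
        v0, k1, k2, eps0 = oc[r, 0], oc[r, 1], oc[r, 2], oc[r, 3]
        lv = z[n + 4 * r + 2]
        lq = z[n + 4 * r + 3]
        y[r] = v0 * (
            k1 * (1.0 - np.exp(lq))
            + k2 * (1.0 - np.exp(lq - lv))
            + (1.0 - eps0) * (1.0 - np.exp(lv))
        )
    return y


@njit(**_NOPYTHON)
def observe_jac(z, oc):
    n = oc.shape[0]
    h = np.zeros((n, 5 * n))
    for r in range(n):
        v0, k1, k2, eps0 = oc[r, 0], oc[r, 1], oc[r, 2], oc[r, 3]
        lv = z[n + 4 * r + 2]
        lq = z[n + 4 * r + 3]
        h[r, n + 4 * r + 2] = v0 * (k2 * np.exp(lq - lv) - (1.0 - eps0) * np.exp(lv))
        h[r, n + 4 * r + 3] = v0 * (-k1 * np.exp(lq) - k2 * np.exp(lq - lv))
    return h


@njit(**_NOPYTHON)
def simulate_dense(a, hp, oc, u, noise, dt, steps_per_tr, n_scans):
    """Euler-Maruyama (neural) + RK4 (hemodynamic) dense integration.

    u, noise: (n_steps-1, n) arrays at resolution dt.  Returns
    (x_n, x_h_flat, y) with x_h_flat of shape (n_steps, 4n) and y sampled
    at scan indices.
    """
    n = a.shape[0]
    n_steps = u.shape[0] + 1
    xn = np.zeros((n_steps, n))
    xh = np.zeros((n_steps, n, 4))
    for t in range(n_steps - 1):
        for i in range(n):
            acc = u[t, i]
            for j in range(n):
                acc += a[i, j] * xn[t, j]
            xn[t + 1, i] = xn[t, i] + dt * acc + noise[t, i]
            if np.abs(xn[t + 1, i]) > 1e6:
                # caller translates this into a region-named error
                raise FloatingPointError("neural state diverged")
        for r in range(n):
            h0 = xh[t, r]
            for j in range(4):
                if np.abs(h0[j]) > 20.0:
                    # hemodynamic log-state left its physiological regime
                    raise FloatingPointError("hemodynamic state overflow")
            k1 = hemo_flow(h0, xn[t, r], hp[r])
            k2 = hemo_flow(h0 + 0.5 * dt * k1, xn[t, r], hp[r])
            k3 = hemo_flow(h0 + 0.5 * dt * k2, xn[t, r], hp[r])
            k4 = hemo_flow(h0 + dt * k3, xn[t, r], hp[r])
            xh[t + 1, r] = h0 + dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    y = np.empty((n_scans, n))
    for si in range(n_scans):
        t = si * steps_per_tr
        for r in range(n):
            v0, c1, c2, eps0 = oc[r, 0], oc[r, 1], oc[r, 2], oc[r, 3]
            lv = xh[t, r, 2]
            lq = xh[t, r, 3]
            y[si, r] = v0 * (
                c1 * (1.0 - np.exp(lq))
                + c2 * (1.0 - np.exp(lq - lv))
                + (1.0 - eps0) * (1.0 - np.exp(lv))
            )
    return xn, xh, y


@njit(**_NOPYTHON)
def expm_ss(b):
    """Matrix exponential by third-order Taylor with scaling and squaring.

    Accurate enough for propagating covariances through locally frozen
    Jacobians, and — unlike a plain truncated series — stable for stiff
    blocks (balloon rates grow like e^{|log state|}).
    """
    d = b.shape[0]
    norm = 0.0
    for i in range(d):
        row = 0.0
        for j in range(d):
            row += abs(b[i, j])
        if row > norm:
            norm = row
    k = 0
    while norm > 0.5 and k < 30:
        norm *= 0.5
        k += 1
    s = b / (2.0**k)
    eye = np.eye(d)
    out = eye + s + 0.5 * (s @ s) + (s @ s @ s) / 6.0
    for _ in range(k):
        out = out @ out
    return out


@njit(**_NOPYTHON)
def ekf_pass(y, mask, a, hp, oc, q_neural, r_var, n_sub, tr, m0, p0):
    """Extended Kalman filter over scans with locally linearized flow.

    y: (T, n) observations; mask: (T,) 1 = observed, 0 = missing.
    q_neural: state-noise variance per unit time on each neural state.
    r_var: measurement-noise variance per region per scan.

    Returns (loglik, mf, Pf, mp, Pp, Phi, innov, S) where Phi[t] is the
    composed linearized transition from scan t-1 to t (Phi[0] = I) and
    innov/S are the innovations and their covariances (identity S and zero
    innovation at masked scans).
    """
    t_n, n = y.shape
    d = 5 * n
    dt = tr / n_sub
    mf = np.zeros((t_n, d))
    pf = np.zeros((t_n, d, d))
    mp = np.zeros((t_n, d))
    pp = np.zeros((t_n, d, d))
    phi = np.zeros((t_n, d, d))
    innov = np.zeros((t_n, n))
    smat = np.zeros((t_n, n, n))
    eye = np.eye(d)

    q_sub = np.zeros((d, d))
    for i in range(n):
        q_sub[i, i] = q_neural * dt
    for i in range(n, d):
        q_sub[i, i] = 1e-10 * dt  # numerical floor on hemodynamic states

    m = m0.copy()
    p = p0.copy()
    loglik = 0.0
    zero_u = np.zeros(n)
    # physiological clamp: neural states and vasodilatory signal within
    # +/-10, log hemodynamic states within +/-3 (flow/volume ratios e^3)
    lim_n = 10.0
    lim_h = 3.0
    for t in range(t_n):
        if t > 0:
            phi_scan = eye.copy()
            for _ in range(n_sub):
                j = full_jac(m, a, hp)
                f_sub = expm_ss(dt * j)
                k1 = full_flow(m, a, hp, zero_u)
                k2 = full_flow(m + 0.5 * dt * k1, a, hp, zero_u)
                k3 = full_flow(m + 0.5 * dt * k2, a, hp, zero_u)
                k4 = full_flow(m + dt * k3, a, hp, zero_u)
                m = m + dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
                for i in range(n):
                    m[i] = min(max(m[i], -lim_n), lim_n)
                for r in range(n):
                    o = n + 4 * r
                    m[o] = min(max(m[o], -lim_n), lim_n)
                    for j in range(1, 4):
                        m[o + j] = min(max(m[o + j], -lim_h), lim_h)
                p = f_sub @ p @ f_sub.T + q_sub
                phi_scan = f_sub @ phi_scan
            p = 0.5 * (p + p.T)
            phi[t] = phi_scan
        else:
            phi[t] = eye
        mp[t] = m
        pp[t] = p
        if mask[t] == 1:
            h = observe_jac(m, oc)
            yhat = observe(m, oc)
            e_t = y[t] - yhat
            s_mat = h @ p @ h.T
            for i in range(n):
                s_mat[i, i] += r_var
            s_inv = np.linalg.inv(s_mat)
            k_gain = p @ h.T @ s_inv
            m = m + k_gain @ e_t
            for i in range(n):
                m[i] = min(max(m[i], -lim_n), lim_n)
            for r in range(n):
                o = n + 4 * r
                m[o] = min(max(m[o], -lim_n), lim_n)
                for j in range(1, 4):
                    m[o + j] = min(max(m[o + j], -lim_h), lim_h)
            ikh = eye - k_gain @ h
            p = ikh @ p @ ikh.T + r_var * (k_gain @ k_gain.T)
            p = 0.5 * (p + p.T)
            sign, logdet = np.linalg.slogdet(s_mat)
            loglik += -0.5 * (
                n * np.log(2.0 * np.pi) + logdet + e_t @ (s_inv @ e_t)
            )
            innov[t] = e_t
            smat[t] = s_mat
        else:
            smat[t] = np.eye(n)
        mf[t] = m
        pf[t] = p
    return loglik, mf, pf, mp, pp, phi, innov, smat


@njit(**_NOPYTHON)
def rts_pass(mf, pf, mp, pp, phi):
    """Rauch-Tung-Striebel smoother; returns (ms, Ps, C) with C[t] the
    lag-one smoothed cross-covariance Cov(z_{t+1}, z_t)."""
    t_n, d = mf.shape
    ms = np.zeros((t_n, d))
    ps = np.zeros((t_n, d, d))
    cs = np.zeros((t_n - 1, d, d)) if t_n > 1 else np.zeros((0, d, d))
    ms[t_n - 1] = mf[t_n - 1]
    ps[t_n - 1] = pf[t_n - 1]
    for t in range(t_n - 2, -1, -1):
        pp_inv = np.linalg.inv(pp[t + 1])
        g = pf[t] @ phi[t + 1].T @ pp_inv
        ms[t] = mf[t] + g @ (ms[t + 1] - mp[t + 1])
        ps[t] = pf[t] + g @ (ps[t + 1] - pp[t + 1]) @ g.T
        ps[t] = 0.5 * (ps[t] + ps[t].T)
        cs[t] = ps[t + 1] @ g.T
    return ms, ps, cs
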