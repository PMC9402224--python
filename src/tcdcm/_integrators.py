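"""Compiled fixed-step RK4 integrators for the neural and balloon stages.

Both kernels are batched over a leading parameter axis so that all the
perturbed parameter sets of a central-difference Jacobian integrate in a
single call.  The two stages are integrated sequentially on the same
microtime grid: the neural trajectory is stored at bin edges and the
balloon stage evaluates its RK4 half-steps on the linear interpolant of
that stored trajectory, so simulating the stages separately or jointly
gives identical output.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def neural_rk4(a_eff, b_low, b_high, c, u, dt):  # pragma: no cover - compiled
    """Batched RK4 for dx/dt = (A_eff + u1*Bl + u2*Bh) x + C u.

    a_eff, b_low, b_high : (B, R, R); c : (B, R, 2); u : (2, T) piecewise
    constant per bin.  Returns x : (B, T+1, R) at bin edges, x[:,0]=0.
    """
    nb, nr, _ = a_eff.shape
    nt = u.shape[1]
    x = np.zeros((nb, nt + 1, nr))
    m = np.empty((nb, nr, nr))
    drive = np.empty((nb, nr))
    k1 = np.empty(nr)
    k2 = np.empty(nr)
    k3 = np.empty(nr)
    k4 = np.empty(nr)
    xm = np.empty(nr)
    u0_prev = -1.0
    u1_prev = -1.0
    for t in range(nt):
        u0 = u[0, t]
        u1 = u[1, t]
        if u0 != u0_prev or u1 != u1_prev:
            # u is block-constant: rebuild the effective coupling only at
            # condition boundaries
            for b in range(nb):
                for i in range(nr):
                    drive[b, i] = c[b, i, 0] * u0 + c[b, i, 1] * u1
                    for j in range(nr):
                        m[b, i, j] = (
                            a_eff[b, i, j] + u0 * b_low[b, i, j] + u1 * b_high[b, i, j]
                        )
            u0_prev = u0
            u1_prev = u1
        for b in range(nb):
            for i in range(nr):
                acc = drive[b, i]
                for j in range(nr):
                    acc += m[b, i, j] * x[b, t, j]
                k1[i] = acc
            for i in range(nr):
                xm[i] = x[b, t, i] + 0.5 * dt * k1[i]
            for i in range(nr):
                acc = drive[b, i]
                for j in range(nr):
                    acc += m[b, i, j] * xm[j]
                k2[i] = acc
            for i in range(nr):
                xm[i] = x[b, t, i] + 0.5 * dt * k2[i]
            for i in range(nr):
                acc = drive[b, i]
                for j in range(nr):
                    acc += m[b, i, j] * xm[j]
                k3[i] = acc
            for i in range(nr):
                xm[i] = x[b, t, i] + dt * k3[i]
            for i in range(nr):
                acc = drive[b, i]
                for j in range(nr):
                    acc += m[b, i, j] * xm[j]
                k4[i] = acc
            for i in range(nr):
                x[b, t + 1, i] = x[b, t, i] + dt / 6.0 * (
                    k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i]
                )
    return x


@njit(cache=True, fastmath=True)
def balloon_rk4(x, x_mid, kappa, gamma, tau, alpha, e0, v0, epsilon, dt):  # pragma: no cover
    """Batched RK4 for the balloon-Windkessel stage driven by ``x``.

    x : (B, T+1, R) neural trajectory at bin edges; x_mid : (B, T, R) its
    half-step values (Hermite midpoints preserve 4th-order coupling);
    hemodynamic constants are per-region vectors of length R.  Returns
    (y, bad_bin): y (B, T+1, R) BOLD in percent-signal units, bad_bin =
    first bin where f, v or q left the positive domain (-1 when none did;
    y is invalid past that bin).
    """
    nb, nt1, nr = x.shape
    nt = nt1 - 1
    y = np.zeros((nb, nt1, nr))
    bad_bin = -1
    inv_alpha = 1.0 / alpha
    log_ome = np.log(1.0 - e0)
    s = np.zeros((nb, nr))
    f = np.ones((nb, nr))
    v = np.ones((nb, nr))
    q = np.ones((nb, nr))
    for t in range(nt):
        for b in range(nb):
            for r in range(nr):
                x0 = x[b, t, r]
                x1 = x[b, t + 1, r]
                xm = x_mid[b, t, r]
                sc = s[b, r]
                fc = f[b, r]
                vc = v[b, r]
                qc = q[b, r]
                ka = kappa[r]
                ga = gamma[r]
                it = 1.0 / tau[r]
                ia = inv_alpha[r]
                e0r = e0[r]
                lome = log_ome[r]
                ep = epsilon[r]

                # k1 at (x0, state)
                ds1 = ep * x0 - ka * sc - ga * (fc - 1.0)
                df1 = sc
                fv = np.exp(ia * np.log(vc))
                dv1 = it * (fc - fv)
                ef = 1.0 - np.exp(lome / fc)
                dq1 = it * (fc * ef / e0r - fv * qc / vc)

                # k2 at (xm, state + dt/2 k1)
                s2 = sc + 0.5 * dt * ds1
                f2 = fc + 0.5 * dt * df1
                v2 = vc + 0.5 * dt * dv1
                q2 = qc + 0.5 * dt * dq1
                if f2 <= 0.0 or v2 <= 0.0 or q2 <= 0.0:
                    return y, t
                ds2 = ep * xm - ka * s2 - ga * (f2 - 1.0)
                df2 = s2
                fv = np.exp(ia * np.log(v2))
                dv2 = it * (f2 - fv)
                ef = 1.0 - np.exp(lome / f2)
                dq2 = it * (f2 * ef / e0r - fv * q2 / v2)

                # k3 at (xm, state + dt/2 k2)
                s3 = sc + 0.5 * dt * ds2
                f3 = fc + 0.5 * dt * df2
                v3 = vc + 0.5 * dt * dv2
                q3 = qc + 0.5 * dt * dq2
                if f3 <= 0.0 or v3 <= 0.0 or q3 <= 0.0:
                    return y, t
                ds3 = ep * xm - ka * s3 - ga * (f3 - 1.0)
                df3 = s3
                fv = np.exp(ia * np.log(v3))
                dv3 = it * (f3 - fv)
                ef = 1.0 - np.exp(lome / f3)
                dq3 = it * (f3 * ef / e0r - fv * q3 / v3)

                # k4 at (x1, state + dt k3)
                s4 = sc + dt * ds3
                f4 = fc + dt * df3
                v4 = vc + dt * dv3
                q4 = qc + dt * dq3
                if f4 <= 0.0 or v4 <= 0.0 or q4 <= 0.0:
                    return y, t
                ds4 = ep * x1 - ka * s4 - ga * (f4 - 1.0)
                df4 = s4
                fv = np.exp(ia * np.log(v4))
                dv4 = it * (f4 - fv)
                ef = 1.0 - np.exp(lome / f4)
                dq4 = it * (f4 * ef / e0r - fv * q4 / v4)

                sn = sc + dt / 6.0 * (ds1 + 2.0 * ds2 + 2.0 * ds3 + ds4)
                fn = fc + dt / 6.0 * (df1 + 2.0 * df2 + 2.0 * df3 + df4)
                vn = vc + dt / 6.0 * (dv1 + 2.0 * dv2 + 2.0 * dv3 + dv4)
                qn = qc + dt / 6.0 * (dq1 + 2.0 * dq2 + 2.0 * dq3 + dq4)
                if fn <= 0.0 or vn <= 0.0 or qn <= 0.0:
                    return y, t
                s[b, r] = sn
                f[b, r] = fn
                v[b, r] = vn
                q[b, r] = qn
                k1c = 7.0 * e0r
                k2c = 2.0
                k3c = 2.0 * e0r - 0.2
                y[b, t + 1, r] = (
                    100.0
                    * v0[r]
                    * (k1c * (1.0 - qn) + k2c * (1.0 - qn / vn) + k3c * (1.0 - vn))
                )
    return y, bad_bin
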