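"""Numba kernels: adaptive rejection sampling and the Gibbs sweep for
logistic factor-model posteriors.

The full conditional of one factor coordinate given the data, the item
parameters and the remaining coordinates is

    log p(x) = sum_j [ y_j eta_j(x) - log(1 + exp(eta_j(x))) ]
               - (x - mu_c)^2 / (2 var_c) + const,

with eta_j(x) linear in x and (mu_c, var_c) the Gaussian prior conditional.
This is strictly log-concave (the prior term alone has curvature 1/var_c),
so each coordinate is drawn exactly by adaptive rejection sampling
(tangent upper hulls, chord lower hulls/squeezing).  On the rare numerical
failure of the hull construction the kernel falls back to slice sampling
with stepping-out, which leaves the same conditional invariant.
"""

import numpy as np
from numba import njit

_MAXP = 50          # max hull support points
_MAX_REJECT = 300   # ARS rejections before the slice-sampling fallback


@njit(cache=True)
def _log1pexp(u):
    if u > 35.0:
        return u + np.exp(-u)
    if u < -35.0:
        return np.exp(u)
    return np.log1p(np.exp(u))


@njit(cache=True)
def _h_and_grad(x, y_row, a_col, eta_row, xi_cur, mu, ivar):
    """Log conditional density (up to a constant) and its derivative."""
    h = -0.5 * ivar * (x - mu) * (x - mu)
    hp = -ivar * (x - mu)
    dx = x - xi_cur
    for j in range(y_row.shape[0]):
        a = a_col[j]
        if a == 0.0:
            continue
        eta = eta_row[j] + a * dx
        h += y_row[j] * eta - _log1pexp(eta)
        if eta > 35.0:
            p = 1.0
        elif eta < -35.0:
            p = np.exp(eta)
        else:
            p = 1.0 / (1.0 + np.exp(-eta))
        hp += a * (y_row[j] - p)
    return h, hp


@njit(cache=True)
def _slice_draw(y_row, a_col, eta_row, xi_cur, mu, ivar, x0, w):
    """Slice sampler with stepping-out and shrinkage (fallback kernel)."""
    h0, _ = _h_and_grad(x0, y_row, a_col, eta_row, xi_cur, mu, ivar)
    logy = h0 + np.log(np.random.random())
    u = np.random.random()
    lo = x0 - w * u
    hi = lo + w
    for _ in range(60):
        hl, _ = _h_and_grad(lo, y_row, a_col, eta_row, xi_cur, mu, ivar)
        if hl < logy:
            break
        lo -= w
    for _ in range(60):
        hr, _ = _h_and_grad(hi, y_row, a_col, eta_row, xi_cur, mu, ivar)
        if hr < logy:
            break
        hi += w
    for _ in range(200):
        x = lo + np.random.random() * (hi - lo)
        hx, _ = _h_and_grad(x, y_row, a_col, eta_row, xi_cur, mu, ivar)
        if hx >= logy:
            return x
        if x < x0:
            lo = x
        else:
            hi = x
    return x0


@njit(cache=True)
def _ars_draw(y_row, a_col, eta_row, xi_cur, mu, ivar, x_start):
    """One exact draw from the log-concave conditional by ARS."""
    sd = 1.0 / np.sqrt(ivar)

    # --- initial abscissae bracketing the mode (slopes + on left, - on right)
    step = sd
    xl = x_start - step
    ok = False
    for _ in range(80):
        hl, hpl = _h_and_grad(xl, y_row, a_col, eta_row, xi_cur, mu, ivar)
        if hpl > 0.0:
            ok = True
            break
        step *= 2.0
        xl = x_start - step
    if not ok:
        return _slice_draw(y_row, a_col, eta_row, xi_cur, mu, ivar, x_start, sd)
    step = sd
    xr = x_start + step
    ok = False
    for _ in range(80):
        hr, hpr = _h_and_grad(xr, y_row, a_col, eta_row, xi_cur, mu, ivar)
        if hpr < 0.0:
            ok = True
            break
        step *= 2.0
        xr = x_start + step
    if not ok:
        return _slice_draw(y_row, a_col, eta_row, xi_cur, mu, ivar, x_start, sd)

    xs = np.empty(_MAXP)
    hs = np.empty(_MAXP)
    hps = np.empty(_MAXP)
    xm = 0.5 * (xl + xr)
    hm, hpm = _h_and_grad(xm, y_row, a_col, eta_row, xi_cur, mu, ivar)
    xs[0], hs[0], hps[0] = xl, hl, hpl
    xs[1], hs[1], hps[1] = xm, hm, hpm
    xs[2], hs[2], hps[2] = xr, hr, hpr
    n = 3

    z = np.empty(_MAXP + 1)          # segment boundaries
    logmass = np.empty(_MAXP)

    for _ in range(_MAX_REJECT):
        # --- tangent intersections
        z[0] = -np.inf
        for i in range(n - 1):
            dhp = hps[i] - hps[i + 1]
            if dhp < 1e-12:
                z[i + 1] = 0.5 * (xs[i] + xs[i + 1])
            else:
                z[i + 1] = (hs[i + 1] - hs[i] - xs[i + 1] * hps[i + 1]
                            + xs[i] * hps[i]) / dhp
                if z[i + 1] < xs[i]:
                    z[i + 1] = xs[i]
                elif z[i + 1] > xs[i + 1]:
                    z[i + 1] = xs[i + 1]
        z[n] = np.inf

        # --- segment log-masses under the piecewise-exponential hull
        for i in range(n):
            hp = hps[i]
            zl = z[i]
            zr = z[i + 1]
            if i == 0:
                # zl = -inf, hp > 0
                logmass[i] = hs[i] + hp * (zr - xs[i]) - np.log(hp)
            elif i == n - 1:
                # zr = +inf, hp < 0
                logmass[i] = hs[i] + hp * (zl - xs[i]) - np.log(-hp)
            else:
                u1 = hp * (zl - xs[i])
                u2 = hp * (zr - xs[i])
                hi_u = u1 if u1 > u2 else u2
                lo_u = u2 if u1 > u2 else u1
                d = hi_u - lo_u
                if np.abs(hp) < 1e-12 or d < 1e-12:
                    logmass[i] = hs[i] + hi_u + np.log(zr - zl)
                else:
                    logmass[i] = (hs[i] + hi_u + np.log1p(-np.exp(-d))
                                  - np.log(np.abs(hp)))

        shift = logmass[0]
        for i in range(1, n):
            if logmass[i] > shift:
                shift = logmass[i]
        total = 0.0
        for i in range(n):
            total += np.exp(logmass[i] - shift)

        # --- sample a segment, then a point within it
        u = np.random.random() * total
        seg = n - 1
        acc = 0.0
        for i in range(n):
            acc += np.exp(logmass[i] - shift)
            if u <= acc:
                seg = i
                break
        hp = hps[seg]
        zl = z[seg]
        zr = z[seg + 1]
        v = np.random.random()
        if seg == 0:
            x = zr + np.log(v) / hp                     # hp > 0
        elif seg == n - 1:
            x = zl + np.log(1.0 - v) / hp               # hp < 0
        elif np.abs(hp) < 1e-12:
            x = zl + v * (zr - zl)
        elif hp > 0.0:
            x = zr + np.log(v + (1.0 - v) * np.exp(-hp * (zr - zl))) / hp
        else:
            x = zl + np.log(1.0 - v + v * np.exp(hp * (zr - zl))) / hp
        if not np.isfinite(x):
            continue

        u_env = hs[seg] + hp * (x - xs[seg])
        w = np.log(np.random.random())

        # --- squeeze with the chord lower hull
        if x >= xs[0] and x <= xs[n - 1]:
            k = 0
            for i in range(n - 1):
                if x <= xs[i + 1]:
                    k = i
                    break
            dx = xs[k + 1] - xs[k]
            if dx > 0.0:
                l_x = ((xs[k + 1] - x) * hs[k] + (x - xs[k]) * hs[k + 1]) / dx
                if w <= l_x - u_env:
                    return x

        hx, hpx = _h_and_grad(x, y_row, a_col, eta_row, xi_cur, mu, ivar)
        if w <= hx - u_env:
            return x

        # --- reject: refine the hull
        if n < _MAXP:
            pos = n
            for i in range(n):
                if x < xs[i]:
                    pos = i
                    break
            for i in range(n, pos, -1):
                xs[i] = xs[i - 1]
                hs[i] = hs[i - 1]
                hps[i] = hps[i - 1]
            xs[pos], hs[pos], hps[pos] = x, hx, hpx
            n += 1

    return _slice_draw(y_row, a_col, eta_row, xi_cur, mu, ivar, x_start, sd)


@njit(cache=True)
def _seed(seed):
    np.random.seed(seed)


@njit(cache=True)
def _gibbs_sweep(Y, A, eta, Xi, cond_w, cond_ivar, n_sweeps):
    """Full Gibbs scans over all persons and factor coordinates (in place).

    ``eta`` is the N x J linear-predictor cache d_j + a_j^T xi_i, kept in
    sync incrementally.  ``cond_w[k]`` are the Gaussian prior conditional
    regression weights (entry k zero) and ``cond_ivar[k]`` the conditional
    precision.  Persons are conditionally independent; the scan order is
    fixed for reproducibility.
    """
    N, J = Y.shape
    K = Xi.shape[1]
    for _s in range(n_sweeps):
        for i in range(N):
            for k in range(K):
                mu = 0.0
                for l in range(K):
                    mu += cond_w[k, l] * Xi[i, l]
                xi_old = Xi[i, k]
                x = _ars_draw(Y[i], A[:, k], eta[i], xi_old, mu,
                              cond_ivar[k], xi_old)
                Xi[i, k] = x
                d = x - xi_old
                if d != 0.0:
                    for j in range(J):
                        eta[i, j] += A[j, k] * d
    return Xi


@njit(cache=True)
def _gauss_draws(mu, ivar, n_draws, x0):
    """ARS draws from a pure Gaussian conditional (J = 0); kernel check."""
    y = np.empty(0)
    a = np.empty(0)
    eta = np.empty(0)
    out = np.empty(n_draws)
    x = x0
    for i in range(n_draws):
        x = _ars_draw(y, a, eta, x, mu, ivar, x)
        out[i] = x
    return out
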