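"""Compiled numerical kernels: RK4 Lotka-Volterra solving and damped
Gauss-Newton (Levenberg-Marquardt) curve fits used inside the genome scans.

Everything here is an internal fast path.  The public modules expose the
same computations with validated containers; genome scans and permutation
thresholds call these kernels so that tens of thousands of weighted curve
fits stay affordable on one CPU.

Parameter conventions (unconstrained optimizer space):
  Richards: u = (log A, log r, lam, log v), curve evaluated directly on the
            modeling scale of the phenotype matrix (log10 abundance by default).
  LV:       u = (log r_e, log K_e, alpha_es, log r_s, log K_s, alpha_se),
            dynamics solved on the raw abundance scale, compared on log10.
"""

import math

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# ODE solving
# ---------------------------------------------------------------------------


@njit(cache=True)
def _lv_deriv(ne, ns, re, ke, aes, rs, ks, ase):
    dne = re * ne * (1.0 - (ne + aes * ns) / ke)
    dns = rs * ns * (1.0 - (ns + ase * ne) / ks)
    return dne, dns


@njit(cache=True)
def lv_rk4_dense(theta, n0e, n0s, t0, t1, n_steps):
    """Fixed-step RK4 over [t0, t1]; returns (n_steps+1, 2) states.

    On overflow the remaining rows are NaN."""
    re, ke, aes, rs, ks, ase = theta[0], theta[1], theta[2], theta[3], theta[4], theta[5]
    out = np.empty((n_steps + 1, 2))
    h = (t1 - t0) / n_steps
    ne, ns = n0e, n0s
    out[0, 0] = ne
    out[0, 1] = ns
    lim = 1e6 * max(ke, ks)
    for i in range(n_steps):
        k1e, k1s = _lv_deriv(ne, ns, re, ke, aes, rs, ks, ase)
        k2e, k2s = _lv_deriv(ne + 0.5 * h * k1e, ns + 0.5 * h * k1s, re, ke, aes, rs, ks, ase)
        k3e, k3s = _lv_deriv(ne + 0.5 * h * k2e, ns + 0.5 * h * k2s, re, ke, aes, rs, ks, ase)
        k4e, k4s = _lv_deriv(ne + h * k3e, ns + h * k3s, re, ke, aes, rs, ks, ase)
        ne = ne + h / 6.0 * (k1e + 2.0 * k2e + 2.0 * k3e + k4e)
        ns = ns + h / 6.0 * (k1s + 2.0 * k2s + 2.0 * k3s + k4s)
        if not (math.isfinite(ne) and math.isfinite(ns)) or abs(ne) > lim or abs(ns) > lim:
            for j in range(i + 1, n_steps + 1):
                out[j, 0] = np.nan
                out[j, 1] = np.nan
            return out
        out[i + 1, 0] = ne
        out[i + 1, 1] = ns
    return out


@njit(cache=True)
def lv_rk4_obs(theta, n0e, n0s, t_obs, h_max):
    """RK4 landing exactly on each observation time; returns (T, 2).

    Integration starts from the inoculation state (n0e, n0s) at time 0, so
    a grid whose first time is 0 reports the initial state there."""
    re, ke, aes, rs, ks, ase = theta[0], theta[1], theta[2], theta[3], theta[4], theta[5]
    T = t_obs.shape[0]
    out = np.empty((T, 2))
    ne, ns = n0e, n0s
    lim = 1e6 * max(ke, ks)
    prev = 0.0
    for j in range(0, T):
        dt = t_obs[j] - prev
        prev = t_obs[j]
        if dt <= 0.0:
            out[j, 0] = ne
            out[j, 1] = ns
            continue
        nst = int(math.ceil(dt / h_max))
        if nst < 1:
            nst = 1
        h = dt / nst
        for _ in range(nst):
            k1e, k1s = _lv_deriv(ne, ns, re, ke, aes, rs, ks, ase)
            k2e, k2s = _lv_deriv(ne + 0.5 * h * k1e, ns + 0.5 * h * k1s, re, ke, aes, rs, ks, ase)
            k3e, k3s = _lv_deriv(ne + 0.5 * h * k2e, ns + 0.5 * h * k2s, re, ke, aes, rs, ks, ase)
            k4e, k4s = _lv_deriv(ne + h * k3e, ns + h * k3s, re, ke, aes, rs, ks, ase)
            ne = ne + h / 6.0 * (k1e + 2.0 * k2e + 2.0 * k3e + k4e)
            ns = ns + h / 6.0 * (k1s + 2.0 * k2s + 2.0 * k3s + k4s)
            if not (math.isfinite(ne) and math.isfinite(ns)) or abs(ne) > lim or abs(ns) > lim:
                for k in range(j, T):
                    out[k, 0] = np.nan
                    out[k, 1] = np.nan
                return out
        out[j, 0] = ne
        out[j, 1] = ns
    return out


# ---------------------------------------------------------------------------
# curve evaluation on the modeling scale
# ---------------------------------------------------------------------------


@njit(cache=True)
def richards_curve_u(u, t_obs):
    """Richards curve from unconstrained parameters (log A, log r, lam, log v)."""
    A = math.exp(min(max(u[0], -30.0), 30.0))
    r = math.exp(min(max(u[1], -30.0), 30.0))
    lam = u[2]
    v = math.exp(min(max(u[3], -5.0), 4.0))
    T = t_obs.shape[0]
    out = np.empty(T)
    slope = r / A * (1.0 + v) ** (1.0 + 1.0 / v)
    for i in range(T):
        e = slope * (lam - t_obs[i])
        if e > 60.0:
            e = 60.0
        elif e < -60.0:
            e = -60.0
        inner = 1.0 + v * math.exp(1.0 + v) * math.exp(e)
        out[i] = A * inner ** (-1.0 / v)
    return out


@njit(cache=True)
def lv_curve_u(u, t_obs, n0e, n0s, h_max, log_scale):
    """Stacked LV mean curve (2T,) from unconstrained parameters."""
    theta = np.empty(6)
    theta[0] = math.exp(min(max(u[0], -30.0), 30.0))
    theta[1] = math.exp(min(max(u[1], -30.0), 60.0))
    theta[2] = u[2]
    theta[3] = math.exp(min(max(u[3], -30.0), 30.0))
    theta[4] = math.exp(min(max(u[4], -30.0), 60.0))
    theta[5] = u[5]
    sol = lv_rk4_obs(theta, n0e, n0s, t_obs, h_max)
    T = t_obs.shape[0]
    out = np.empty(2 * T)
    for i in range(T):
        ne = sol[i, 0]
        ns = sol[i, 1]
        if not (math.isfinite(ne) and math.isfinite(ns)):
            for j in range(2 * T):
                out[j] = np.nan
            return out
        if log_scale:
            out[i] = math.log10(max(ne, 1e-12))
            out[T + i] = math.log10(max(ns, 1e-12))
        else:
            out[i] = ne
            out[T + i] = ns
    return out


# ---------------------------------------------------------------------------
# whitened distance and LM fits
# ---------------------------------------------------------------------------


@njit(cache=True)
def whiten_resid(Wc, y, mu):
    """w = Wc (y - mu); ||w||^2 = (y-mu)' Sigma^{-1} (y-mu) when Wc = L^{-1}.

    Wc is lower triangular (inverse Cholesky factor), so the upper half is
    skipped."""
    n = y.shape[0]
    w = np.empty(n)
    for i in range(n):
        acc = 0.0
        for j in range(i + 1):
            acc += Wc[i, j] * (y[j] - mu[j])
        w[i] = acc
    return w


@njit(cache=True)
def qdist(Wc, y, mu):
    w = whiten_resid(Wc, y, mu)
    acc = 0.0
    for i in range(w.shape[0]):
        acc += w[i] * w[i]
    return acc


@njit(cache=True)
def _lm_core_richards(ybar, t_obs, Wc, u0, max_iter):
    npar = 4
    u = u0.copy()
    mu = richards_curve_u(u, t_obs)
    f = whiten_resid(Wc, ybar, mu)
    cost = f @ f
    lam_damp = 1e-3
    for _ in range(max_iter):
        m = f.shape[0]
        J = np.empty((m, npar))
        for p in range(npar):
            du = 1e-6 * (1.0 + abs(u[p]))
            up = u.copy()
            up[p] += du
            fp = whiten_resid(Wc, ybar, richards_curve_u(up, t_obs))
            for i in range(m):
                J[i, p] = (fp[i] - f[i]) / du
        g = J.T @ f
        H = J.T @ J
        improved = False
        for _trial in range(12):
            Hd = H.copy()
            for p in range(npar):
                Hd[p, p] += lam_damp * (H[p, p] + 1e-12)
            step = np.linalg.solve(Hd, -g)
            u_new = u + step
            f_new = whiten_resid(Wc, ybar, richards_curve_u(u_new, t_obs))
            c_new = f_new @ f_new
            if math.isfinite(c_new) and c_new < cost:
                rel = (cost - c_new) / (cost + 1e-30)
                u = u_new
                f = f_new
                cost = c_new
                lam_damp = max(lam_damp * 0.3, 1e-12)
                improved = True
                if rel < 1e-8:
                    return u, cost
                break
            lam_damp *= 10.0
            if lam_damp > 1e10:
                break
        if not improved:
            break
    return u, cost


_PEN_W = 10.0  # sqrt of the quadratic box-penalty weight


@njit(cache=True)
def _lv_resid_pen(u, ybar, t_obs, Wc, n0e, n0s, h_max, log_scale, lo, hi):
    """Whitened residual extended by box-penalty terms; NaN row on blow-up.

    The penalty keeps the six LV parameters inside a biologically plausible
    box, cutting the (K -> inf, alpha -> inf) flat ridge on which partner-
    induced saturation mimics self-limitation."""
    twoT = ybar.shape[0]
    out = np.empty(twoT + 6)
    mu = lv_curve_u(u, t_obs, n0e, n0s, h_max, log_scale)
    if np.isnan(mu[0]) or np.isnan(mu[twoT - 1]):
        out[:] = np.nan
        return out
    f = whiten_resid(Wc, ybar, mu)
    for i in range(twoT):
        out[i] = f[i]
    for j in range(6):
        exc = 0.0
        if u[j] > hi[j]:
            exc = u[j] - hi[j]
        elif u[j] < lo[j]:
            exc = lo[j] - u[j]
        out[twoT + j] = _PEN_W * exc
    return out


@njit(cache=True)
def _lm_core_lv(ybar, t_obs, Wc, u0, n0e, n0s, h_max, log_scale, lo, hi, max_iter):
    npar = 6
    u = u0.copy()
    f = _lv_resid_pen(u, ybar, t_obs, Wc, n0e, n0s, h_max, log_scale, lo, hi)
    if np.any(np.isnan(f)):
        return u, np.inf
    cost = f @ f
    lam_damp = 1e-3
    for _ in range(max_iter):
        m = f.shape[0]
        J = np.empty((m, npar))
        ok = True
        for p in range(npar):
            du = 1e-6 * (1.0 + abs(u[p]))
            up = u.copy()
            up[p] += du
            fp = _lv_resid_pen(up, ybar, t_obs, Wc, n0e, n0s, h_max, log_scale, lo, hi)
            if np.any(np.isnan(fp)):
                ok = False
                break
            for i in range(m):
                J[i, p] = (fp[i] - f[i]) / du
        if not ok:
            break
        g = J.T @ f
        H = J.T @ J
        improved = False
        for _trial in range(12):
            Hd = H.copy()
            for p in range(npar):
                Hd[p, p] += lam_damp * (H[p, p] + 1e-12)
            step = np.linalg.solve(Hd, -g)
            u_new = u + step
            f_new = _lv_resid_pen(u_new, ybar, t_obs, Wc, n0e, n0s, h_max,
                                  log_scale, lo, hi)
            if np.any(np.isnan(f_new)):
                lam_damp *= 10.0
                continue
            c_new = f_new @ f_new
            if math.isfinite(c_new) and c_new < cost:
                rel = (cost - c_new) / (cost + 1e-30)
                u = u_new
                f = f_new
                cost = c_new
                lam_damp = max(lam_damp * 0.3, 1e-12)
                improved = True
                if rel < 1e-8:
                    return u, cost
                break
            lam_damp *= 10.0
            if lam_damp > 1e10:
                break
        if not improved:
            break
    return u, cost


@njit(cache=True)
def fit_richards_lm(ybar, t_obs, Wc, u0, max_iter=40):
    return _lm_core_richards(ybar, t_obs, Wc, u0, max_iter)


@njit(cache=True)
def default_lv_box(ybar, t_obs, log_scale):
    """(lo, hi) box in u space: r in [0.01, 10]/h, K within 1e-3..1e3 of the
    observed maximum abundance, |alpha| <= 5."""
    T = t_obs.shape[0]
    max_a = ybar[0]
    max_b = ybar[T]
    for i in range(T):
        if ybar[i] > max_a:
            max_a = ybar[i]
        if ybar[T + i] > max_b:
            max_b = ybar[T + i]
    if log_scale:
        log_ka = max_a * math.log(10.0)
        log_kb = max_b * math.log(10.0)
    else:
        log_ka = math.log(max(max_a, 1e-6))
        log_kb = math.log(max(max_b, 1e-6))
    span = math.log(1e3)
    lo = np.array([math.log(0.01), log_ka - span, -5.0,
                   math.log(0.01), log_kb - span, -5.0])
    hi = np.array([math.log(10.0), log_ka + span, 5.0,
                   math.log(10.0), log_kb + span, 5.0])
    return lo, hi


@njit(cache=True)
def fit_lv_lm(ybar, t_obs, Wc, u0, n0e, n0s, h_max=0.5, log_scale=True,
              max_iter=40):
    lo, hi = default_lv_box(ybar, t_obs, log_scale)
    return _lm_core_lv(ybar, t_obs, Wc, u0, n0e, n0s, h_max, log_scale, lo, hi, max_iter)


@njit(cache=True)
def fit_lv_alpha_lm(ybar, t_obs, Wc, u_base, n0e, n0s, h_max=0.25,
                    log_scale=True, max_iter=40):
    """Profile fit of the two interaction coefficients only.

    Growth parameters (r_e, K_e, r_s, K_s) stay at ``u_base``; only
    (alpha_es, alpha_se) are optimized.  This conditional estimator avoids
    the near-collinear (K, alpha) ridge of the free six-parameter fit and is
    used for interaction-coefficient reporting; scans and LRTs use the free
    fit."""
    u = u_base.copy()
    a = np.array([u_base[2], u_base[5]])
    twoT = ybar.shape[0]

    def resid(av):
        uu = u_base.copy()
        uu[2] = av[0]
        uu[5] = av[1]
        mu = lv_curve_u(uu, t_obs, n0e, n0s, h_max, log_scale)
        out = np.empty(twoT + 2)
        if np.isnan(mu[0]) or np.isnan(mu[twoT - 1]):
            out[:] = np.nan
            return out
        f = whiten_resid(Wc, ybar, mu)
        for i in range(twoT):
            out[i] = f[i]
        for j in range(2):
            exc = 0.0
            if av[j] > 5.0:
                exc = av[j] - 5.0
            elif av[j] < -5.0:
                exc = -5.0 - av[j]
            out[twoT + j] = _PEN_W * exc
        return out

    f = resid(a)
    if np.any(np.isnan(f)):
        return a, np.inf
    cost = f @ f
    lam_damp = 1e-3
    for _ in range(max_iter):
        m = f.shape[0]
        J = np.empty((m, 2))
        ok = True
        for p in range(2):
            da = 1e-6 * (1.0 + abs(a[p]))
            ap = a.copy()
            ap[p] += da
            fp = resid(ap)
            if np.any(np.isnan(fp)):
                ok = False
                break
            for i in range(m):
                J[i, p] = (fp[i] - f[i]) / da
        if not ok:
            break
        g = J.T @ f
        H = J.T @ J
        improved = False
        for _trial in range(12):
            Hd = H.copy()
            for p in range(2):
                Hd[p, p] += lam_damp * (H[p, p] + 1e-12)
            step = np.linalg.solve(Hd, -g)
            a_new = a + step
            f_new = resid(a_new)
            if np.any(np.isnan(f_new)):
                lam_damp *= 10.0
                continue
            c_new = f_new @ f_new
            if math.isfinite(c_new) and c_new < cost:
                rel = (cost - c_new) / (cost + 1e-30)
                a = a_new
                f = f_new
                cost = c_new
                lam_damp = max(lam_damp * 0.3, 1e-12)
                improved = True
                if rel < 1e-8:
                    return a, cost
                break
            lam_damp *= 10.0
            if lam_damp > 1e10:
                break
        if not improved:
            break
    return a, cost


# ---------------------------------------------------------------------------
# genome scans
# ---------------------------------------------------------------------------


@njit(cache=True)
def fm_scan_lrt(Y, G, t_obs, Wc, mu0, u0, max_iter=15):
    """Functional-mapping LRT per marker with the covariance profiled at H0.

    Y: (n, T) phenotype matrix on the modeling scale; G: (n, m) haploid
    genotype codes in {0, 1} with -1 for missing; Wc: whitener of the shared
    covariance; mu0: fitted shared mean curve; u0: its parameters (warm
    start for the per-genotype fits).

    Returns (lrt (m,), uhat (m, 2, 4)).  LRT = sum_g n_g [d(ybar_g, mu0) -
    d(ybar_g, muhat_g)], the exact 2(l1 - l0) for fixed covariance.
    Monomorphic markers keep NaN.
    """
    n, T = Y.shape
    m = G.shape[1]
    lrt = np.full(m, np.nan)
    uhat = np.full((m, 2, 4), np.nan)
    for mk in range(m):
        ybar = np.zeros((2, T))
        cnt = np.zeros(2)
        for i in range(n):
            g = G[i, mk]
            if g < 0:
                continue
            cnt[g] += 1.0
            for t in range(T):
                ybar[g, t] += Y[i, t]
        if cnt[0] < 1.0 or cnt[1] < 1.0:
            continue
        stat = 0.0
        for g in range(2):
            for t in range(T):
                ybar[g, t] /= cnt[g]
            d0 = qdist(Wc, ybar[g], mu0)
            ug, dg = _lm_core_richards(ybar[g], t_obs, Wc, u0, max_iter)
            if dg > d0:  # warm start guarantees dg <= d0 up to numerics
                dg = d0
                ug = u0.copy()
            stat += cnt[g] * (d0 - dg)
            uhat[mk, g, :] = ug
        lrt[mk] = stat
    return lrt, uhat


@njit(cache=True)
def cocom_scan_lrt(Y2, GA, GB, t_obs, Wc, mu0, u0, n0e, n0s, h_max=0.5,
                   log_scale=True, max_iter=12):
    """Systems-mapping LRT for every interspecific marker pair.

    Y2: (n, 2T) stacked [species A | species B] trajectories on the modeling
    scale for n strain pairs; GA/GB: (n, mA), (n, mB) genotype codes with -1
    missing; mu0/u0: shared-curve H0 fit (LV, 2T) used as warm start.

    Returns (lrt (mA, mB), uhat (mA, mB, 4, 6)).  Combos are indexed
    2*gA + gB in (AB=3? no:) order [a/b, a/B, A/b, A/B] -> index 2*gA+gB with
    allele code 1 = uppercase.  Empty combos contribute zero.
    """
    n, twoT = Y2.shape
    mA = GA.shape[1]
    mB = GB.shape[1]
    lrt = np.full((mA, mB), np.nan)
    uhat = np.full((mA, mB, 4, 6), np.nan)
    for ja in range(mA):
        for jb in range(mB):
            ybar = np.zeros((4, twoT))
            cnt = np.zeros(4)
            for i in range(n):
                ga = GA[i, ja]
                gb = GB[i, jb]
                if ga < 0 or gb < 0:
                    continue
                c = 2 * ga + gb
                cnt[c] += 1.0
                for t in range(twoT):
                    ybar[c, t] += Y2[i, t]
            informative = 0
            for c in range(4):
                if cnt[c] > 0.0:
                    informative += 1
            if informative < 2:
                continue
            stat = 0.0
            for c in range(4):
                if cnt[c] < 1.0:
                    continue
                for t in range(twoT):
                    ybar[c, t] /= cnt[c]
                d0 = qdist(Wc, ybar[c], mu0)
                lo, hi = default_lv_box(ybar[c], t_obs, log_scale)
                uc, dc = _lm_core_lv(ybar[c], t_obs, Wc, u0, n0e, n0s, h_max,
                                     log_scale, lo, hi, max_iter)
                if dc > d0:
                    dc = d0
                    uc = u0.copy()
                stat += cnt[c] * (d0 - dc)
                uhat[ja, jb, c, :] = uc
            lrt[ja, jb] = stat
    return lrt, uhat
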