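"""Numba kernels for the per-subject Laplace inner optimisation.

The inner problem — finding each subject's empirical-Bayes eta mode and the
curvature there — is a few-dimensional Newton iteration evaluated thousands
of times inside the outer parameter search.  These kernels mirror the
vectorised numpy implementation in :mod:`cipropk.estimation` (which remains
as a fallback and as the reference for equivalence tests) with explicit
per-subject loops.

All kernels are pure functions of their arguments; failures are signalled
through status codes rather than exceptions.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    NUMBA_AVAILABLE = True
except Exception:  # pragma: no cover
    NUMBA_AVAILABLE = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap

_LOG2PI = float(np.log(2.0 * np.pi))


@njit(cache=True)
def _conc_subject(lp, te, decay, rate, out):
    """Two-compartment superposition for one subject.

    ``lp`` is the log of (CL, Vc, Vp, Q); ``te``/``decay`` the precomputed
    infused/decay times per (observation, dose); ``rate`` the infusion rates.
    """
    cl = np.exp(lp[0])
    vc = np.exp(lp[1])
    vp = np.exp(lp[2])
    q = np.exp(lp[3])
    k10 = cl / vc
    k12 = q / vc
    k21 = q / vp
    s = k10 + k12 + k21
    disc2 = s * s - 4.0 * k10 * k21
    disc = np.sqrt(disc2) if disc2 > 0.0 else 0.0
    alpha = 0.5 * (s + disc)
    beta = k10 * k21 / alpha
    denom = alpha - beta
    if denom < 1e-300:
        denom = 1e-300
    beta_safe = beta if beta > 1e-300 else 1e-300
    a_amp = (alpha - k21) / (vc * denom * alpha)
    b_amp = (k21 - beta) / (vc * denom * beta_safe)
    mo, md = te.shape
    for j in range(mo):
        acc = 0.0
        for k in range(md):
            r = rate[k]
            if r > 0.0:
                acc += r * (
                    a_amp * (-np.expm1(-alpha * te[j, k])) * np.exp(-alpha * decay[j, k])
                    + b_amp * (-np.expm1(-beta * te[j, k])) * np.exp(-beta * decay[j, k])
                )
        out[j] = acc if acc > 0.0 else 0.0


@njit(cache=True)
def _g_subject(y, mask, f, v, eta, om_inv, logdet_om):
    """Joint -2 log density of one subject at the given eta."""
    mo = y.shape[0]
    d = eta.shape[0]
    g = 0.0
    for j in range(mo):
        if mask[j]:
            r = y[j] - f[j]
            g += np.log(2.0 * np.pi * v[j]) + r * r / v[j]
    quad = 0.0
    for a in range(d):
        for b in range(d):
            quad += eta[a] * om_inv[a, b] * eta[b]
    return g + quad + logdet_om + d * _LOG2PI


@njit(cache=True)
def _chol_d(H, L):
    """Cholesky of a small SPD matrix; returns 0 on success, 1 on failure."""
    d = H.shape[0]
    for i in range(d):
        for j in range(i + 1):
            acc = H[i, j]
            for k in range(j):
                acc -= L[i, k] * L[j, k]
            if i == j:
                if acc <= 0.0:
                    return 1
                L[i, i] = np.sqrt(acc)
            else:
                L[i, j] = acc / L[j, j]
    return 0


@njit(cache=True)
def _solve_chol(L, b, x):
    """Solve L L' x = b in place for small lower-triangular L."""
    d = L.shape[0]
    for i in range(d):
        acc = b[i]
        for k in range(i):
            acc -= L[i, k] * x[k]
        x[i] = acc / L[i, i]
    for i in range(d - 1, -1, -1):
        acc = x[i]
        for k in range(i + 1, d):
            acc -= L[k, i] * x[k]
        x[i] = acc / L[i, i]


@njit(cache=True)
def _fv_subject(lp_base, iiv_idx, eta, sp, sa, te, decay, rate, f, v):
    d = iiv_idx.shape[0]
    lp = lp_base.copy()
    for k in range(d):
        lp[iiv_idx[k]] += eta[k]
        if lp[iiv_idx[k]] > 60.0:
            lp[iiv_idx[k]] = 60.0
        elif lp[iiv_idx[k]] < -60.0:
            lp[iiv_idx[k]] = -60.0
    _conc_subject(lp, te, decay, rate, f)
    mo = f.shape[0]
    for j in range(mo):
        val = (sp * f[j]) ** 2 + sa * sa
        v[j] = val if val > 1e-10 else 1e-10


@njit(cache=True)
def laplace_kernel(y, mask, te, decay, rate, lp_base, iiv_idx, om_inv,
                   logdet_om, sp, sa, etas, max_iter, gain_tol, step_tol,
                   central, ofv, f_out, v_out, F_out, H_out):
    """Per-subject Newton to the eta mode plus the Laplace log-determinant.

    Mutates ``etas`` (modes), ``ofv`` (per-subject -2 log marginal
    likelihood), ``f_out``/``v_out`` (individual predictions and residual
    variances), ``F_out`` (d f/d eta at the mode, central differences) and
    ``H_out`` (Gauss-Newton curvature).  Returns 0 on success, or the index
    of the first subject whose curvature was not positive definite plus 1.
    """
    n, mo = y.shape
    d = iiv_idx.shape[0]
    delta = 1e-4

    f = np.empty(mo)
    v = np.empty(mo)
    ft = np.empty(mo)
    vt = np.empty(mo)
    fp = np.empty(mo)
    vp_ = np.empty(mo)
    fm = np.empty(mo)
    vm = np.empty(mo)
    F = np.empty((mo, d))
    grad = np.empty(d)
    H = np.empty((d, d))
    L = np.zeros((d, d))
    step = np.empty(d)
    eta = np.empty(d)
    trial = np.empty(d)

    for i in range(n):
        for k in range(d):
            eta[k] = etas[i, k]
        _fv_subject(lp_base[i], iiv_idx, eta, sp, sa, te[i], decay[i], rate[i], f, v)
        g = _g_subject(y[i], mask[i], f, v, eta, om_inv, logdet_om)

        for _ in range(max_iter):
            # FD Jacobian of f w.r.t. eta (forward while far, per `central`)
            for k in range(d):
                eta[k] += delta
                _fv_subject(lp_base[i], iiv_idx, eta, sp, sa, te[i], decay[i],
                            rate[i], fp, vp_)
                eta[k] -= delta
                if central:
                    eta[k] -= delta
                    _fv_subject(lp_base[i], iiv_idx, eta, sp, sa, te[i],
                                decay[i], rate[i], fm, vm)
                    eta[k] += delta
                    for j in range(mo):
                        F[j, k] = (fp[j] - fm[j]) / (2.0 * delta)
                else:
                    for j in range(mo):
                        F[j, k] = (fp[j] - f[j]) / delta
            # gradient and Gauss-Newton Hessian of g/2
            for a in range(d):
                acc = 0.0
                for b in range(d):
                    acc += om_inv[a, b] * eta[b]
                grad[a] = acc
                for b in range(d):
                    H[a, b] = om_inv[a, b]
            for j in range(mo):
                if mask[i, j]:
                    r = y[i, j] - f[j]
                    dvc = 2.0 * sp * sp * f[j]
                    w2 = 1.0 / v[j] - r * r / (v[j] * v[j])
                    for a in range(d):
                        grad[a] += -F[j, a] * r / v[j] \
                            + 0.5 * w2 * dvc * F[j, a]
                        for b in range(d):
                            H[a, b] += F[j, a] * F[j, b] / v[j] \
                                + 0.5 * (dvc * F[j, a]) * (dvc * F[j, b]) / (v[j] * v[j])
            if _chol_d(H, L) != 0:
                break
            _solve_chol(L, grad, step)
            nrm = 0.0
            for k in range(d):
                step[k] = -step[k]
                nrm += step[k] * step[k]
            nrm = np.sqrt(nrm)
            if nrm > 3.0:
                for k in range(d):
                    step[k] *= 3.0 / nrm
            lam = 1.0
            accepted = False
            gt = g
            for _ in range(12):
                for k in range(d):
                    trial[k] = eta[k] + lam * step[k]
                _fv_subject(lp_base[i], iiv_idx, trial, sp, sa, te[i],
                            decay[i], rate[i], ft, vt)
                gt = _g_subject(y[i], mask[i], ft, vt, trial, om_inv, logdet_om)
                if gt <= g + 1e-12:
                    accepted = True
                    break
                lam *= 0.5
            if not accepted:
                break
            gain = g - gt
            for k in range(d):
                eta[k] = trial[k]
            for j in range(mo):
                f[j] = ft[j]
                v[j] = vt[j]
            g = gt
            if gain < gain_tol and lam * nrm < step_tol:
                break

        # final central-difference curvature at the mode
        for k in range(d):
            eta[k] += delta
            _fv_subject(lp_base[i], iiv_idx, eta, sp, sa, te[i], decay[i],
                        rate[i], fp, vp_)
            eta[k] -= 2.0 * delta
            _fv_subject(lp_base[i], iiv_idx, eta, sp, sa, te[i], decay[i],
                        rate[i], fm, vm)
            eta[k] += delta
            for j in range(mo):
                F[j, k] = (fp[j] - fm[j]) / (2.0 * delta)
        for a in range(d):
            for b in range(d):
                H[a, b] = om_inv[a, b]
        for j in range(mo):
            if mask[i, j]:
                dvc = 2.0 * sp * sp * f[j]
                for a in range(d):
                    for b in range(d):
                        H[a, b] += F[j, a] * F[j, b] / v[j] \
                            + 0.5 * (dvc * F[j, a]) * (dvc * F[j, b]) / (v[j] * v[j])
        if _chol_d(H, L) != 0:
            return i + 1
        logdet = 0.0
        for k in range(d):
            logdet += 2.0 * np.log(L[k, k])
        ofv[i] = g - d * _LOG2PI + logdet
        for k in range(d):
            etas[i, k] = eta[k]
        for j in range(mo):
            f_out[i, j] = f[j]
            v_out[i, j] = v[j]
            for k in range(d):
                F_out[i, j, k] = F[j, k]
        for a in range(d):
            for b in range(d):
                H_out[i, a, b] = H[a, b]
    return 0
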