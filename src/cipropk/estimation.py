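"""Approximate marginal maximum likelihood for the nonlinear mixed-effects model.

The marginal likelihood of each subject's concentration vector integrates the
Gaussian residual model over the subject's log-normal random effects.  That
integral has no closed form for the two-compartment model, so it is
approximated with a Laplace-type expansion around the empirical-Bayes mode of
the random effects, with the residual variance evaluated at the individual
predictions (the "interaction" of FOCE-I).  The curvature term uses the
Gauss-Newton (expected-information) Hessian, which is positive definite by
construction.

Per subject ``i`` with observations ``y``, predictions ``f(eta)`` and
residual variance ``v(eta) = (sigma_prop * f)^2 + sigma_add^2``:

``-2 log L_i  ~=  g(eta*) - d*log(2*pi) + log det H(eta*)``

where ``g(eta) = sum_j [log(2*pi*v_j) + (y_j - f_j)^2 / v_j]
+ eta' Omega^-1 eta + log det(2*pi*Omega)`` is the joint -2 log density,
``eta*`` its minimiser, and ``H`` the Gauss-Newton Hessian of ``g/2``.  The
objective function value (OFV) is the sum over subjects; differences in OFV
between nested models are compared to chi-square quantiles.

With no random effects (``omega = 0``) the expression reduces to the exact
Gaussian -2 log likelihood (extended least squares), which serves as an
independent oracle in the tests.

Fixed effects are estimated on the log scale (positivity), omega through its
Cholesky factor (positive semi-definiteness).  The outer optimisation is
Nelder-Mead followed by an L-BFGS-B polish by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import _kernels
from .dataset import PackedCohort, PKDataset
from .population import PARAM_NAMES, CovariateEffect, PopulationModel

__all__ = [
    "FORWARD_DELTA_OFV",
    "BACKWARD_DELTA_OFV",
    "FitResult",
    "CovariateSearchResult",
    "ofv",
    "fit",
    "shrinkage",
    "lrt_decision",
    "covariate_search",
]

logger = logging.getLogger(__name__)

_LOG2PI = float(np.log(2.0 * np.pi))

#: forward-inclusion threshold: chi-square(1) 95% quantile, rounded to 2 dp
FORWARD_DELTA_OFV = 3.84
#: backward-elimination retention threshold: chi-square(1) 99.9% quantile
BACKWARD_DELTA_OFV = 10.83

_VAR_FLOOR = 1e-10


# ---------------------------------------------------------------------------
# inner (per-subject) Laplace machinery, vectorised over the whole cohort
# ---------------------------------------------------------------------------


class _LaplaceEngine:
    """Evaluates the FOCE-I objective for a packed cohort.

    The template model fixes the *structure* (which parameters carry etas,
    which covariate effects exist); parameter values are supplied per call.
    """

    def __init__(self, packed: PackedCohort, template: PopulationModel):
        self.packed = packed
        self.eta_cache: np.ndarray | None = None  # warm start across outer iterations
        self.iiv_params = template.iiv_params
        self.d = len(self.iiv_params)
        self.iiv_idx = [PARAM_NAMES.index(p) for p in self.iiv_params]
        self.effects = template.covariate_effects
        self.effect_idx = [PARAM_NAMES.index(e.parameter) for e in self.effects]
        self.effect_z = []
        for e in self.effects:
            if e.covariate not in packed.covariates.columns:
                raise ValueError(
                    f"dataset has no covariate column {e.covariate!r} needed "
                    f"by effect {e.label}"
                )
            values = packed.covariates[e.covariate].to_numpy(dtype=float)
            if np.any(~np.isfinite(values)):
                raise ValueError(f"covariate {e.covariate!r} has missing values")
            self.effect_z.append(np.asarray(e.z(values), dtype=float))
        self.mask = packed.obs_mask.astype(float)
        self.y = np.where(packed.obs_mask, packed.y, 0.0)
        # dose/observation geometry is constant across likelihood evaluations:
        # time since infusion start (clipped), infused time and decay time per
        # (subject, observation, dose) triple, and the infusion rates
        tp = np.maximum(
            packed.obs_time[:, :, None] - packed.dose_time[:, None, :], 0.0
        )
        safe_dur = np.where(packed.dose_dur > 0, packed.dose_dur, 1.0)
        self._te = np.minimum(tp, safe_dur[:, None, :])
        self._decay = tp - self._te
        self._rate = np.where(packed.dose_dur > 0,
                              packed.dose_amt / safe_dur, 0.0)
        self._n4 = np.zeros((packed.n, 4))
        self._iiv_idx_arr = np.array(self.iiv_idx, dtype=np.int64)

    # -- model evaluation ---------------------------------------------------

    def param_matrix(self, log_theta, coefs, etas):
        lp = self._n4 + log_theta
        for z, idx, c in zip(self.effect_z, self.effect_idx, coefs):
            lp[:, idx] += c * z
        if self.d:
            for k, idx in enumerate(self.iiv_idx):
                lp[:, idx] += etas[:, k]
        np.clip(lp, -60.0, 60.0, out=lp)
        return np.exp(lp)

    def predict(self, pm):
        """Vectorised two-compartment superposition on the precomputed design.

        Algebraically identical to :func:`cipropk.pk.infusion_concentration`
        (asserted in the tests) but reuses the constant dose/observation
        geometry for speed inside the likelihood loop.
        """
        cl, vc, vp, q = pm[:, 0], pm[:, 1], pm[:, 2], pm[:, 3]
        k10 = cl / vc
        k12 = q / vc
        k21 = q / vp
        s = k10 + k12 + k21
        disc = np.sqrt(np.maximum(s * s - 4.0 * k10 * k21, 0.0))
        alpha = 0.5 * (s + disc)
        beta = k10 * k21 / alpha
        denom = np.maximum(alpha - beta, 1e-300)
        a_amp = (alpha - k21) / (vc * denom * alpha)
        b_amp = (k21 - beta) / (vc * denom * np.maximum(beta, 1e-300))
        out = None
        for lam, amp in ((alpha, a_amp), (beta, b_amp)):
            lam_b = lam[:, None, None]
            term = (-np.expm1(-lam_b * self._te)) * np.exp(-lam_b * self._decay)
            part = np.einsum("nmd,nd->nm", term, self._rate) * amp[:, None]
            out = part if out is None else out + part
        return np.maximum(out, 0.0)

    # -- objective ----------------------------------------------------------

    def _f_v(self, log_theta, coefs, sp, sa, etas):
        f = self.predict(self.param_matrix(log_theta, coefs, etas))
        v = np.maximum((sp * f) ** 2 + sa * sa, _VAR_FLOOR)
        return f, v

    def _g(self, etas, f, v, om_inv, logdet_om):
        """Joint -2 log density per subject (the Laplace exponent)."""
        r = self.y - f
        g = np.sum(self.mask * (np.log(2.0 * np.pi * v) + r * r / v), axis=1)
        if self.d:
            quad = np.einsum("ni,ij,nj->n", etas, om_inv, etas)
            g = g + quad + logdet_om + self.d * _LOG2PI
        return g

    def laplace(self, log_theta, coefs, sp, sa, omega, eta0=None,
                max_iter=60, warm=False, fd_scheme="central",
                gain_tol=1e-9, step_tol=1e-7):
        """Per-subject OFV contributions and empirical-Bayes etas.

        Returns ``(etas, ofv_i, aux)`` where ``aux`` carries the individual
        predictions, residual variances, the Jacobian of ``f`` w.r.t. eta at
        the mode and the Gauss-Newton Hessian (for CWRES / shrinkage reuse).
        """
        n, d = self.packed.n, self.d
        mask = self.mask
        if d == 0:
            etas = np.zeros((n, 0))
            f, v = self._f_v(log_theta, coefs, sp, sa, etas)
            ofv_i = self._g(etas, f, v, None, 0.0)
            return etas, ofv_i, {"f": f, "v": v, "F": np.zeros((n,) + f.shape[1:] + (0,)),
                                 "H": np.zeros((n, 0, 0))}

        sign, logdet_om = np.linalg.slogdet(omega)
        if sign <= 0:
            raise np.linalg.LinAlgError("omega must be positive definite")
        om_inv = np.linalg.inv(omega)

        if eta0 is None and warm and self.eta_cache is not None \
                and self.eta_cache.shape == (n, d):
            eta0 = self.eta_cache
        etas = np.zeros((n, d)) if eta0 is None else np.array(eta0, dtype=float)

        if _kernels.NUMBA_AVAILABLE:
            lp_base = np.clip(self._n4 + log_theta, -60.0, 60.0)
            for z, idx, cf in zip(self.effect_z, self.effect_idx, coefs):
                lp_base[:, idx] += cf * z
            mo = self.packed.obs_mask.shape[1]
            ofv_i = np.zeros(n)
            f = np.zeros((n, mo))
            v = np.zeros((n, mo))
            F = np.zeros((n, mo, d))
            H = np.zeros((n, d, d))
            status = _kernels.laplace_kernel(
                self.y, self.packed.obs_mask, self._te, self._decay,
                self._rate, lp_base, self._iiv_idx_arr, om_inv, logdet_om,
                sp, sa, etas, max_iter, gain_tol, step_tol,
                fd_scheme == "central", ofv_i, f, v, F, H,
            )
            if status:
                raise np.linalg.LinAlgError(
                    "non-positive-definite Laplace curvature "
                    f"(subject index {status - 1})"
                )
            if warm:
                self.eta_cache = etas.copy()
            return etas, ofv_i, {"f": f, "v": v, "F": F, "H": H}

        f, v = self._f_v(log_theta, coefs, sp, sa, etas)
        g = self._g(etas, f, v, om_inv, logdet_om)
        delta_eta = 1e-4
        F = np.zeros(f.shape + (d,))
        grad = np.zeros((n, d))
        H = np.tile(om_inv, (n, 1, 1))

        last_gmax = [np.inf]

        def curvature(etas, f, v, scheme=None):
            """FD Jacobian of f w.r.t. eta, gradient and GN Hessian of g/2."""
            if scheme is None:
                scheme = fd_scheme if last_gmax[0] > 1e-3 else "central"
            for k in range(d):
                shift = np.zeros((n, d))
                shift[:, k] = delta_eta
                fp, _ = self._f_v(log_theta, coefs, sp, sa, etas + shift)
                if scheme == "central":
                    fm, _ = self._f_v(log_theta, coefs, sp, sa, etas - shift)
                    F[:, :, k] = (fp - fm) / (2.0 * delta_eta)
                else:
                    F[:, :, k] = (fp - f) / delta_eta
            r = self.y - f
            dv = 2.0 * sp * sp * f[:, :, None] * F
            w1 = mask * r / v
            w2 = mask * (1.0 / v - r * r / (v * v))
            grad[:] = (
                -np.einsum("nm,nmk->nk", w1, F)
                + 0.5 * np.einsum("nm,nmk->nk", w2, dv)
                + etas @ om_inv
            )
            H[:] = (
                np.einsum("nmk,nml,nm->nkl", F, F, mask / v)
                + 0.5 * np.einsum("nmk,nml,nm->nkl", dv, dv, mask / (v * v))
                + om_inv
            )
            return grad, H

        for _ in range(max_iter):
            # cheap forward differences far from the mode, central close to it
            grad, H = curvature(etas, f, v)
            gmax = float(np.max(np.abs(grad))) if n else 0.0
            last_gmax[0] = gmax
            if gmax < 1e-7:
                break
            step = -np.linalg.solve(H, grad[..., None])[..., 0]
            norm = np.linalg.norm(step, axis=1)
            scale = np.where(norm > 3.0, 3.0 / np.maximum(norm, 1e-300), 1.0)
            step = step * scale[:, None]
            lam = np.ones(n)
            for _ in range(12):
                trial = etas + lam[:, None] * step
                ft, vt = self._f_v(log_theta, coefs, sp, sa, trial)
                gt = self._g(trial, ft, vt, om_inv, logdet_om)
                worse = gt > g + 1e-12
                if not np.any(worse):
                    break
                lam[worse] *= 0.5
            improved = gt <= g + 1e-12
            if np.any(improved):
                etas[improved] = trial[improved]
                f[improved] = ft[improved]
                v[improved] = vt[improved]
            g_new = np.where(improved, gt, g)
            max_gain = float(np.max(g - g_new)) if n else 0.0
            applied = (
                float(np.max(np.abs(lam[:, None] * step)[improved]))
                if np.any(improved)
                else 0.0
            )
            g = g_new
            if max_gain < gain_tol and applied < step_tol:
                break

        # curvature at the converged mode for the log-det term
        grad, H = curvature(etas, f, v, scheme="central")
        sign_h, logdet_h = np.linalg.slogdet(H)
        if np.any(sign_h <= 0):
            raise np.linalg.LinAlgError("non-positive-definite Laplace curvature")
        ofv_i = g - d * _LOG2PI + logdet_h
        if warm:
            self.eta_cache = etas.copy()
        return etas, ofv_i, {"f": f, "v": v, "F": F.copy(), "H": H.copy()}


# ---------------------------------------------------------------------------
# parameter vector <-> model transform
# ---------------------------------------------------------------------------


class _ParamTransform:
    """Packs a PopulationModel into an unconstrained vector and back.

    thetas and residual SDs on log scale; omega through its Cholesky factor
    (log diagonal, free off-diagonal); covariate-effect coefficients raw
    (power exponent, or log multiplier for binary effects).
    """

    def __init__(self, template: PopulationModel, fix: Sequence[str] = ()):
        self.template = template
        self.d = template.d
        self.names: list[str] = []
        for p in PARAM_NAMES:
            self.names.append(p)
        self.chol_index: list[tuple[int, int]] = []
        for i in range(self.d):
            for j in range(i + 1):
                self.names.append(f"omega[{i},{j}]")
                self.chol_index.append((i, j))
        self.names.append("sigma_prop")
        self.names.append("sigma_add")
        for e in template.covariate_effects:
            self.names.append(f"beta:{e.label}")
        fix = set(fix)
        unknown = fix - set(self._fixable())
        if unknown:
            raise ValueError(f"unknown fix names {sorted(unknown)}")
        self.free = np.array([not self._is_fixed(nm, fix) for nm in self.names])
        self.x_full0 = self.to_vector(template)

    def _fixable(self):
        out = list(PARAM_NAMES) + ["omega", "sigma_prop", "sigma_add"]
        out += [f"beta:{e.label}" for e in self.template.covariate_effects]
        return out

    @staticmethod
    def _is_fixed(name: str, fix: set) -> bool:
        if name.startswith("omega["):
            return "omega" in fix
        return name in fix

    def to_vector(self, model: PopulationModel) -> np.ndarray:
        x = []
        for p in PARAM_NAMES:
            x.append(np.log(model.theta[p]))
        if self.d:
            om = np.asarray(model.omega, dtype=float)
            jitter = 0.0
            for _ in range(6):
                try:
                    L = np.linalg.cholesky(om + jitter * np.eye(self.d))
                    break
                except np.linalg.LinAlgError:
                    jitter = max(jitter * 10.0, 1e-10)
            else:
                raise np.linalg.LinAlgError("omega has no Cholesky factor")
            for (i, j) in self.chol_index:
                x.append(np.log(max(L[i, j], 1e-6)) if i == j else L[i, j])
        x.append(np.log(max(model.sigma_prop, 1e-6)))
        x.append(np.log(max(model.sigma_add, 1e-6)))
        for e in model.covariate_effects:
            x.append(e.coefficient)
        return np.array(x, dtype=float)

    def pieces(self, x_full: np.ndarray):
        """Split a full vector into (log_theta, coefs, sp, sa, omega)."""
        x_full = np.clip(x_full, -60.0, 60.0)  # overflow guard during search
        k = 0
        log_theta = x_full[k:k + 4]
        k += 4
        if self.d:
            L = np.zeros((self.d, self.d))
            for (i, j) in self.chol_index:
                L[i, j] = np.exp(x_full[k]) if i == j else x_full[k]
                k += 1
            omega = L @ L.T
        else:
            omega = np.zeros((0, 0))
        sp = float(np.exp(x_full[k])); k += 1
        sa = float(np.exp(x_full[k])); k += 1
        coefs = x_full[k:]
        return log_theta, coefs, sp, sa, omega

    def to_model(self, x_full: np.ndarray) -> PopulationModel:
        log_theta, coefs, sp, sa, omega = self.pieces(x_full)
        effects = tuple(
            e.with_coefficient(float(c))
            for e, c in zip(self.template.covariate_effects, coefs)
        )
        return PopulationModel(
            theta={p: float(np.exp(v)) for p, v in zip(PARAM_NAMES, log_theta)},
            iiv_params=self.template.iiv_params,
            omega=omega,
            sigma_prop=sp,
            sigma_add=sa,
            covariate_effects=effects,
        )

    def fold(self, x_free: np.ndarray) -> np.ndarray:
        x = self.x_full0.copy()
        x[self.free] = x_free
        return x

    @property
    def x_free0(self) -> np.ndarray:
        return self.x_full0[self.free]

    @property
    def free_names(self) -> list[str]:
        return [nm for nm, fr in zip(self.names, self.free) if fr]


# ---------------------------------------------------------------------------
# public results
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Estimates and diagnostics from one population fit."""

    model: PopulationModel
    ofv: float
    converged: bool
    message: str
    n_subjects: int
    n_obs: int
    etas: pd.DataFrame  # empirical-Bayes etas, index = subject id
    iwres: np.ndarray  # individual weighted residuals (flat, masked)
    shrinkage_eta: dict[str, float] = field(default_factory=dict)
    shrinkage_eps: float = float("nan")
    rse: dict[str, float] | None = None
    n_function_evals: int = 0

    def to_dict(self) -> dict:
        return {
            "model": self.model.to_dict(),
            "ofv": self.ofv,
            "converged": self.converged,
            "message": self.message,
            "n_subjects": self.n_subjects,
            "n_obs": self.n_obs,
            "rse_percent": self.rse,
            "shrinkage_eta_percent": self.shrinkage_eta,
            "shrinkage_eps_percent": self.shrinkage_eps,
            "iiv_cv_percent": self.model.iiv_cv_percent(),
            "etas": {str(k): list(map(float, v))
                     for k, v in self.etas.T.items()},
        }


@dataclass
class CovariateSearchResult:
    """Trace and outcome of forward-inclusion / backward-elimination."""

    trace: pd.DataFrame
    included: tuple[CovariateEffect, ...]
    final: FitResult


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def ofv(dataset: PKDataset, model: PopulationModel) -> float:
    """-2 x approximate marginal log likelihood of ``model`` on ``dataset``.

    Deterministic given inputs.  Raises with the offending subject id when
    the likelihood is not finite.
    """
    packed = dataset.pack()
    engine = _LaplaceEngine(packed, model)
    trans = _ParamTransform(model)
    log_theta, coefs, sp, sa, omega = trans.pieces(trans.to_vector(model))
    _, ofv_i, _ = engine.laplace(log_theta, coefs, sp, sa, omega)
    bad = ~np.isfinite(ofv_i)
    if np.any(bad):
        sid = packed.ids[np.argmax(bad)]
        raise ValueError(f"non-finite likelihood contribution for subject {sid}")
    return float(np.sum(ofv_i))


def _objective_factory(engine: _LaplaceEngine, trans: _ParamTransform):
    counter = {"n": 0}

    def objective(x_free: np.ndarray) -> float:
        counter["n"] += 1
        try:
            log_theta, coefs, sp, sa, omega = trans.pieces(trans.fold(x_free))
            # slightly relaxed inner tolerance during the outer search: the
            # objective stays a pure function of x (cold-started inner
            # optimisation), so finite-difference outer gradients remain
            # consistent; the reported OFV is recomputed at full precision
            _, ofv_i, _ = engine.laplace(log_theta, coefs, sp, sa, omega,
                                         fd_scheme="forward",
                                         gain_tol=3e-6, step_tol=1e-5)
            val = float(np.sum(ofv_i))
        except (np.linalg.LinAlgError, ValueError, FloatingPointError, OverflowError):
            return 1e10
        if not np.isfinite(val):
            return 1e10
        return val

    return objective, counter


def _fd_hessian(fun, x, rel_step=1e-3):
    """Central-difference Hessian of a scalar function."""
    k = len(x)
    h = rel_step * np.maximum(np.abs(x), 1.0)
    H = np.zeros((k, k))
    f0 = fun(x)
    for i in range(k):
        ei = np.zeros(k); ei[i] = h[i]
        fpp = fun(x + ei); fmm = fun(x - ei)
        H[i, i] = (fpp - 2.0 * f0 + fmm) / (h[i] ** 2)
    for i in range(k):
        for j in range(i):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            fpq = fun(x + ei + ej)
            fpm = fun(x + ei - ej)
            fmp = fun(x - ei + ej)
            fmm = fun(x - ei - ej)
            H[i, j] = H[j, i] = (fpq - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return H


def _reported_quantities(trans: _ParamTransform, x_full: np.ndarray) -> dict[str, float]:
    model = trans.to_model(x_full)
    out = {p: model.theta[p] for p in PARAM_NAMES}
    for p in model.iiv_params:
        out[f"IIV_{p}"] = 100.0 * np.sqrt(model.omega_var(p))
    out["sigma_prop"] = model.sigma_prop
    out["sigma_add"] = model.sigma_add
    for e in model.covariate_effects:
        out[f"beta:{e.label}"] = e.theta_cov
    return out


def _compute_rse(objective, trans, x_free):
    """RSE% per reported quantity via inverse observed information + delta method."""
    try:
        H = _fd_hessian(objective, x_free)
        cov_x = 2.0 * np.linalg.pinv(0.5 * (H + H.T))
    except np.linalg.LinAlgError:
        return None
    names = list(_reported_quantities(trans, trans.fold(x_free)))
    k = len(x_free)
    h = 1e-4 * np.maximum(np.abs(x_free), 1.0)
    grads = {nm: np.zeros(k) for nm in names}
    for i in range(k):
        ei = np.zeros(k); ei[i] = h[i]
        qp = _reported_quantities(trans, trans.fold(x_free + ei))
        qm = _reported_quantities(trans, trans.fold(x_free - ei))
        for nm in names:
            grads[nm][i] = (qp[nm] - qm[nm]) / (2.0 * h[i])
    q0 = _reported_quantities(trans, trans.fold(x_free))
    rse = {}
    for nm in names:
        var = float(grads[nm] @ cov_x @ grads[nm])
        if var < 0 or q0[nm] == 0:
            rse[nm] = float("nan")
        else:
            rse[nm] = 100.0 * np.sqrt(var) / abs(q0[nm])
    return rse


def fit(
    dataset: PKDataset,
    model_spec: PopulationModel,
    *,
    fix: Sequence[str] = (),
    method: str = "nm+bfgs",
    compute_rse: bool = True,
    nm_maxiter: int = 4000,
) -> FitResult:
    """Fit the population model to a dataset by FOCE-I-style Laplace ML.

    ``model_spec`` supplies both the model structure and the initial values.
    ``fix`` freezes parameters by name (``"CL"``, ``"Vc"``, ``"Vp"``, ``"Q"``,
    ``"omega"``, ``"sigma_prop"``, ``"sigma_add"``, ``"beta:<param>~<cov>"``).
    ``method`` is one of ``"nm+bfgs"`` (default: Nelder-Mead then a
    quasi-Newton polish), ``"bfgs"`` (polish only, for warm starts) or
    ``"nm"``.  Non-convergence is reported in the result, not raised.
    """
    if dataset.n_subjects < 2:
        raise ValueError("fit requires at least 2 subjects")
    packed = dataset.pack()
    engine = _LaplaceEngine(packed, model_spec)
    trans = _ParamTransform(model_spec, fix=fix)
    objective, counter = _objective_factory(engine, trans)

    x = trans.x_free0
    if len(x) == 0:
        raise ValueError("no free parameters to estimate")
    messages = []
    success = True
    if method not in ("nm+bfgs", "bfgs", "nm"):
        raise ValueError(f"unknown method {method!r}")
    if "nm" in method.split("+"):
        res = minimize(
            objective, x, method="Nelder-Mead",
            options={"maxiter": nm_maxiter, "maxfev": nm_maxiter,
                     "xatol": 1e-4, "fatol": 1e-6, "adaptive": True},
        )
        x = res.x
        messages.append(f"NM: {res.message}")
        success = bool(res.success)
    if "bfgs" in method.split("+"):
        res = minimize(
            objective, x, method="L-BFGS-B",
            options={"maxiter": 400, "ftol": 1e-10, "gtol": 1e-6, "eps": 3e-4},
        )
        x = res.x
        messages.append(f"LBFGSB: {res.message}")
        # an abnormal line-search exit means the search hit the numerical
        # noise floor of the objective; the iterate is still a minimiser
        success = bool(res.success) or "ABNORMAL" in str(res.message)

    x_full = trans.fold(x)
    log_theta, coefs, sp, sa, omega = trans.pieces(x_full)
    etas, ofv_i, aux = engine.laplace(log_theta, coefs, sp, sa, omega)
    total_ofv = float(np.sum(ofv_i))
    model_hat = trans.to_model(x_full)

    eta_frame = pd.DataFrame(
        etas, index=pd.Index(packed.ids, name="ID"), columns=list(model_hat.iiv_params)
    )
    mask = packed.obs_mask
    iwres = ((packed.y - aux["f"]) / np.sqrt(aux["v"]))[mask]
    shr_eta = {}
    for k, p in enumerate(model_hat.iiv_params):
        om_sd = np.sqrt(model_hat.omega[k, k])
        if om_sd < 1e-8:
            shr_eta[p] = float("nan")
        else:
            shr_eta[p] = 100.0 * (1.0 - np.std(etas[:, k], ddof=1) / om_sd)
    shr_eps = 100.0 * (1.0 - np.std(iwres, ddof=1)) if len(iwres) > 1 else float("nan")

    rse = None
    if compute_rse:
        rse = _compute_rse(objective, trans, x)

    return FitResult(
        model=model_hat,
        ofv=total_ofv,
        converged=success and np.isfinite(total_ofv),
        message="; ".join(messages),
        n_subjects=packed.n,
        n_obs=packed.n_obs,
        etas=eta_frame,
        iwres=iwres,
        shrinkage_eta=shr_eta,
        shrinkage_eps=float(shr_eps),
        rse=rse,
        n_function_evals=counter["n"],
    )


def shrinkage(fit_result: FitResult, model: PopulationModel | None = None):
    """Eta- and epsilon-shrinkage (%) from a converged fit.

    ``eta_shr = 100*(1 - SD(EBE etas)/omega)`` per random-effect dimension and
    ``eps_shr = 100*(1 - SD(IWRES))``.  Dimensions with ``omega = 0`` are
    reported as NaN (undefined).
    """
    model = model or fit_result.model
    etas = fit_result.etas
    out = {}
    for k, p in enumerate(model.iiv_params):
        om_sd = np.sqrt(model.omega[k, k])
        if om_sd < 1e-8 or p not in etas.columns:
            out[p] = float("nan")
        else:
            out[p] = 100.0 * (1.0 - np.std(etas[p].to_numpy(), ddof=1) / om_sd)
    iwres = fit_result.iwres
    eps = 100.0 * (1.0 - np.std(iwres, ddof=1)) if len(iwres) > 1 else float("nan")
    return out, float(eps)


def lrt_decision(delta_ofv: float, step: str) -> bool:
    """Likelihood-ratio decision for one covariate at 1 degree of freedom.

    Forward inclusion requires an OFV drop of at least 3.84 (p < 0.05);
    backward elimination retains only if removal raises the OFV by strictly
    more than 10.83 (p < 0.001).
    """
    if not np.isfinite(delta_ofv):
        raise ValueError("delta_ofv must be finite")
    if step == "forward":
        return bool(delta_ofv >= FORWARD_DELTA_OFV)
    if step == "backward":
        return bool(delta_ofv > BACKWARD_DELTA_OFV)
    raise ValueError(f"step must be 'forward' or 'backward', got {step!r}")


def covariate_search(
    dataset: PKDataset,
    base: PopulationModel,
    candidates: Sequence[CovariateEffect],
    *,
    method: str = "bfgs",
    base_fit: FitResult | None = None,
) -> CovariateSearchResult:
    """Stepwise covariate modelling: greedy forward inclusion, backward elimination.

    Each remaining candidate is added to the current model and refitted
    (warm-started from the current estimates); the best candidate is included
    when its OFV drop reaches 3.84.  After forward selection stalls, included
    effects are removed one at a time and only those whose removal raises the
    OFV by more than 10.83 are retained.  Candidates whose fit fails to
    converge are skipped with a warning.  Deterministic given the dataset and
    the candidate ordering (ties go to the earlier candidate).
    """
    rows = []
    if base_fit is None:
        base_fit = fit(dataset, base, method=method, compute_rse=False)
    current = base_fit
    included: list[CovariateEffect] = []
    step = 0
    remaining = list(candidates)

    while remaining:
        step += 1
        results = []
        for cand in remaining:
            spec = current.model.replace(
                covariate_effects=current.model.covariate_effects + (cand,)
            )
            try:
                r = fit(dataset, spec, method=method, compute_rse=False)
            except Exception as exc:  # noqa: BLE001 - candidate-level robustness
                logger.warning("forward fit failed for %s: %s", cand.label, exc)
                continue
            if not r.converged:
                logger.warning("forward fit for %s did not converge; skipped",
                               cand.label)
                continue
            delta = current.ofv - r.ofv
            results.append((delta, cand, r))
            rows.append({"step": step, "phase": "forward", "candidate": cand.label,
                         "ofv": r.ofv, "delta_ofv": delta, "action": "tested"})
        if not results:
            break
        best_delta, best_cand, best_fit_ = max(results, key=lambda t: t[0])
        if lrt_decision(best_delta, "forward"):
            included.append(best_cand)
            remaining.remove(best_cand)
            current = best_fit_
            rows.append({"step": step, "phase": "forward",
                         "candidate": best_cand.label, "ofv": current.ofv,
                         "delta_ofv": best_delta, "action": "included"})
        else:
            break

    while included:
        step += 1
        results = []
        for eff in included:
            effects = tuple(e for e in current.model.covariate_effects
                            if e.label != eff.label)
            spec = current.model.replace(covariate_effects=effects)
            try:
                r = fit(dataset, spec, method=method, compute_rse=False)
            except Exception as exc:  # noqa: BLE001
                logger.warning("backward fit failed for %s: %s", eff.label, exc)
                continue
            delta = r.ofv - current.ofv
            results.append((delta, eff, r))
            rows.append({"step": step, "phase": "backward", "candidate": eff.label,
                         "ofv": r.ofv, "delta_ofv": delta, "action": "tested"})
        if not results:
            break
        worst_delta, worst_eff, reduced = min(results, key=lambda t: t[0])
        if lrt_decision(worst_delta, "backward"):
            break  # weakest effect still highly significant: retain all
        included = [e for e in included if e.label != worst_eff.label]
        current = reduced
        rows.append({"step": step, "phase": "backward",
                     "candidate": worst_eff.label, "ofv": current.ofv,
                     "delta_ofv": worst_delta, "action": "removed"})

    trace = pd.DataFrame(
        rows, columns=["step", "phase", "candidate", "ofv", "delta_ofv", "action"]
    )
    return CovariateSearchResult(trace=trace, included=tuple(included), final=current)
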