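"""Two-compartment intravenous-infusion pharmacokinetics.

Deterministic disposition kinetics for a drug given as repeated zero-order
(constant-rate) infusions into the central compartment of a mammillary
two-compartment model.  Everything here is closed form: micro rate constants
and disposition exponents, concentration-time superposition over an arbitrary
dose history, the steady-state solution via the accumulation factor, and
steady-state exposure metrics with a free-fraction (plasma protein binding)
correction.

Parameterisation is the clearance form used throughout clinical
pharmacokinetics:

* ``CL``  elimination clearance from the central compartment (L/h)
* ``Vc``  central volume of distribution (L)
* ``Vp``  peripheral volume of distribution (L)
* ``Q``   inter-compartmental (distribution) clearance (L/h)

from which the micro constants are ``k10 = CL/Vc``, ``k12 = Q/Vc`` and
``k21 = Q/Vp``.  The disposition exponents ``alpha > beta`` are the negated
eigenvalues of the 2x2 rate matrix and satisfy ``alpha*beta = k10*k21`` and
``alpha + beta = k10 + k12 + k21``.

All times are in hours measured from the first dose, amounts in mg, volumes
in L and concentrations in mg/L.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PKParameters",
    "MicroConstants",
    "DosingRegimen",
    "ExposureMetrics",
    "micro_constants",
    "concentration",
    "steady_state_metrics",
    "infusion_concentration",
    "steady_state_concentration",
]

_LN2 = float(np.log(2.0))

#: default unbound (free) fraction of ciprofloxacin in plasma; the average
#: protein binding in critically ill adults is ~30%.
DEFAULT_UNBOUND_FRACTION = 0.7


@dataclass(frozen=True)
class PKParameters:
    """Structural two-compartment parameters of one individual.

    Attributes
    ----------
    cl : float
        Elimination clearance, L/h.
    vc : float
        Central volume of distribution, L.
    vp : float
        Peripheral volume of distribution, L.
    q : float
        Inter-compartmental clearance, L/h.

    All four must be strictly positive and finite.
    """

    cl: float
    vc: float
    vp: float
    q: float

    def __post_init__(self) -> None:
        for name in ("cl", "vc", "vp", "q"):
            value = float(getattr(self, name))
            if not np.isfinite(value) or value <= 0.0:
                raise ValueError(
                    f"PK parameter {name!r} must be strictly positive and "
                    f"finite, got {value!r}"
                )

    def as_array(self) -> np.ndarray:
        """Return ``[cl, vc, vp, q]`` as a float array."""
        return np.array([self.cl, self.vc, self.vp, self.q], dtype=float)


@dataclass(frozen=True)
class MicroConstants:
    """Micro rate constants and disposition exponents (all 1/h, half-lives h)."""

    k10: float
    k12: float
    k21: float
    alpha: float
    beta: float
    t_half_alpha: float
    t_half_beta: float


@dataclass(frozen=True)
class DosingRegimen:
    """A repeated intravenous infusion schedule.

    Attributes
    ----------
    dose : float
        Amount per administration, mg (``>= 0``).
    interval : float
        Dosing interval tau, h.
    infusion_duration : float
        Zero-order infusion duration, h; must satisfy
        ``0 < infusion_duration <= interval``.  Default 1.0 h.
    n_doses : int
        Number of administered doses for the superposition (non-steady-state)
        solution; doses are given at ``0, tau, 2*tau, ...``.
    steady_state : bool
        If True, :func:`concentration` returns the periodic steady-state
        profile (time is interpreted modulo the interval).
    """

    dose: float
    interval: float
    infusion_duration: float = 1.0
    n_doses: int = 1
    steady_state: bool = False

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError(f"dose must be non-negative, got {self.dose}")
        if self.interval <= 0:
            raise ValueError(f"interval must be positive, got {self.interval}")
        if not (0.0 < self.infusion_duration <= self.interval):
            raise ValueError(
                "infusion_duration must lie in (0, interval], got "
                f"{self.infusion_duration} with interval {self.interval}"
            )
        if self.n_doses < 1:
            raise ValueError(f"n_doses must be >= 1, got {self.n_doses}")

    @property
    def daily_dose(self) -> float:
        """Total dose per 24 h, mg."""
        return self.dose * 24.0 / self.interval


@dataclass(frozen=True)
class ExposureMetrics:
    """Free-drug steady-state exposure metrics.

    ``fauc24`` is the free area under the curve over 24 h (mg*h/L), ``fcmax``
    and ``fcmin`` the free peak (end of infusion) and trough (end of interval)
    concentrations (mg/L).
    """

    fauc24: float
    fcmax: float
    fcmin: float

    def __post_init__(self) -> None:
        if self.fcmin < -1e-12 or self.fcmax < self.fcmin - 1e-9:
            raise ValueError(
                f"exposure metrics must satisfy fcmax >= fcmin >= 0, got "
                f"fcmax={self.fcmax}, fcmin={self.fcmin}"
            )


def _disposition(cl, vc, vp, q):
    """Vectorised micro constants and exponents.

    ``beta`` is computed as ``k10*k21/alpha`` (product of roots over the large
    root), which is numerically stable when the roots are well separated.
    """
    k10 = cl / vc
    k12 = q / vc
    k21 = q / vp
    s = k10 + k12 + k21
    disc = np.sqrt(np.maximum(s * s - 4.0 * k10 * k21, 0.0))
    alpha = 0.5 * (s + disc)
    beta = k10 * k21 / alpha
    return k10, k12, k21, alpha, beta


def micro_constants(params: PKParameters) -> MicroConstants:
    """Micro rate constants, disposition exponents and half-lives.

    Satisfies ``alpha*beta == k10*k21`` and ``alpha + beta == k10 + k12 + k21``
    to floating-point accuracy.  ``t_half_beta`` is the terminal half-life.
    """
    k10, k12, k21, alpha, beta = _disposition(*params.as_array())
    t_half_alpha = _LN2 / alpha if alpha > 0 else np.inf
    t_half_beta = _LN2 / beta if beta > 0 else np.inf
    return MicroConstants(
        k10=float(k10),
        k12=float(k12),
        k21=float(k21),
        alpha=float(alpha),
        beta=float(beta),
        t_half_alpha=float(t_half_alpha),
        t_half_beta=float(t_half_beta),
    )


def _macro(cl, vc, vp, q):
    """Bolus macro coefficients A, B (per unit dose) and exponents."""
    k10, k12, k21, alpha, beta = _disposition(cl, vc, vp, q)
    denom = alpha - beta
    denom = np.where(np.abs(denom) < 1e-300, 1e-300, denom)
    a_coef = (alpha - k21) / (vc * denom)
    b_coef = (k21 - beta) / (vc * denom)
    return alpha, beta, a_coef, b_coef


def infusion_concentration(cl, vc, vp, q, dose_time, dose_amt, dose_dur, t):
    """Central concentration under superposition of infusion doses (batched).

    Parameters
    ----------
    cl, vc, vp, q : array_like, shape (n,)
        Per-individual structural parameters.
    dose_time, dose_amt, dose_dur : array_like, shape (n, n_dose)
        Dose event start times (h), amounts (mg) and infusion durations (h).
        Padding entries are encoded with ``dose_amt == 0`` (any duration > 0).
    t : array_like, shape (n, n_time)
        Evaluation times, h.

    Returns
    -------
    ndarray, shape (n, n_time)
        Total plasma concentration, mg/L.

    The per-dose solution uses a single expression valid both during and
    after the infusion: with ``tp`` the time since infusion start, ``te =
    min(tp, T)`` the infused time and rate ``R = amt/T``,

    ``C = sum_i R * (coef_i/lambda_i) * (1 - exp(-lambda_i te)) * exp(-lambda_i (tp-te))``.
    """
    cl, vc, vp, q = (np.asarray(x, dtype=float) for x in (cl, vc, vp, q))
    dose_time = np.asarray(dose_time, dtype=float)
    dose_amt = np.asarray(dose_amt, dtype=float)
    dose_dur = np.asarray(dose_dur, dtype=float)
    t = np.asarray(t, dtype=float)

    alpha, beta, a_coef, b_coef = _macro(cl, vc, vp, q)
    safe_dur = np.where(dose_dur > 0, dose_dur, 1.0)
    rate = np.where(dose_dur > 0, dose_amt / safe_dur, 0.0)

    tp = t[:, :, None] - dose_time[:, None, :]
    tp = np.maximum(tp, 0.0)
    te = np.minimum(tp, safe_dur[:, None, :])
    decay = tp - te

    out = np.zeros(t.shape, dtype=float)
    for lam, coef in ((alpha, a_coef), (beta, b_coef)):
        lam_safe = np.maximum(lam, 1e-300)
        lam_b = lam_safe[:, None, None]
        amp = (coef / lam_safe)[:, None, None]
        out += np.sum(
            rate[:, None, :]
            * amp
            * (-np.expm1(-lam_b * te))
            * np.exp(-lam_b * decay),
            axis=2,
        )
    return np.maximum(out, 0.0)


def steady_state_concentration(cl, vc, vp, q, dose, interval, dose_dur, t):
    """Periodic steady-state concentration within a dosing interval (batched).

    Parameters are as in :func:`infusion_concentration` but with a single
    repeated dose (scalar or (n,) ``dose``, ``interval``, ``dose_dur``) and
    ``t`` of shape (n, n_time) interpreted modulo the interval (time since the
    start of a steady-state infusion).  Uses the accumulation-factor closed
    form, exact for linear kinetics.
    """
    t = np.asarray(t, dtype=float)
    n = t.shape[0]
    cl, vc, vp, q, dose, interval, dose_dur = (
        np.broadcast_to(np.asarray(x, dtype=float), (n,)).astype(float)
        for x in (cl, vc, vp, q, dose, interval, dose_dur)
    )

    alpha, beta, a_coef, b_coef = _macro(cl, vc, vp, q)
    rate = (dose / dose_dur)[:, None]
    tau = interval[:, None]
    dur = dose_dur[:, None]

    tp = np.mod(t, tau)
    te = np.minimum(tp, dur)
    decay = tp - te

    out = np.zeros(t.shape, dtype=float)
    for lam, coef in ((alpha, a_coef), (beta, b_coef)):
        lam_safe = np.maximum(lam, 1e-300)
        lam_b = lam_safe[:, None]
        amp = (coef / lam_safe)[:, None]
        within = (-np.expm1(-lam_b * te)) * np.exp(-lam_b * decay)
        prior = (-np.expm1(-lam_b * dur)) * np.exp(
            -lam_b * (tau + tp - dur)
        ) / (-np.expm1(-lam_b * tau))
        out += rate * amp * (within + prior)
    return np.maximum(out, 0.0)


def concentration(params: PKParameters, regimen: DosingRegimen, t):
    """Total plasma concentration at time(s) ``t`` (h from first dose), mg/L.

    For a non-steady-state regimen this is the closed-form superposition of
    the ``n_doses`` administered infusions; with ``regimen.steady_state`` the
    periodic steady-state solution is returned and ``t`` is interpreted
    modulo the dosing interval.

    Raises
    ------
    ValueError
        If any requested time is negative.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    scalar = t_arr.ndim == 0
    tt = np.atleast_1d(t_arr)[None, :]
    if regimen.steady_state:
        out = steady_state_concentration(
            np.array([params.cl]),
            np.array([params.vc]),
            np.array([params.vp]),
            np.array([params.q]),
            np.array([regimen.dose]),
            np.array([regimen.interval]),
            np.array([regimen.infusion_duration]),
            tt,
        )
    else:
        dose_times = (np.arange(regimen.n_doses) * regimen.interval)[None, :]
        amts = np.full((1, regimen.n_doses), regimen.dose, dtype=float)
        durs = np.full((1, regimen.n_doses), regimen.infusion_duration, dtype=float)
        out = infusion_concentration(
            np.array([params.cl]),
            np.array([params.vc]),
            np.array([params.vp]),
            np.array([params.q]),
            dose_times,
            amts,
            durs,
            tt,
        )
    out = out[0]
    return float(out[0]) if scalar else out


def steady_state_metrics(
    params: PKParameters,
    regimen: DosingRegimen,
    fu: float = DEFAULT_UNBOUND_FRACTION,
) -> ExposureMetrics:
    """Free-drug steady-state exposure for a repeated-infusion regimen.

    For linear kinetics the steady-state AUC over one interval equals
    ``dose/CL``, hence ``fAUC24 = fu * (24/interval) * dose / CL``.  The free
    peak is the model concentration at the end of the steady-state infusion
    (the true maximum for an IV infusion) and the free trough the value at
    the end of the interval.

    Parameters
    ----------
    fu : float
        Unbound fraction in plasma, in (0, 1].  Default 0.7.
    """
    if not (0.0 < fu <= 1.0):
        raise ValueError(f"unbound fraction fu must be in (0, 1], got {fu}")
    fauc24 = fu * (24.0 / regimen.interval) * regimen.dose / params.cl
    ss = DosingRegimen(
        dose=regimen.dose,
        interval=regimen.interval,
        infusion_duration=regimen.infusion_duration,
        steady_state=True,
    )
    cmax = concentration(params, ss, regimen.infusion_duration)
    cmin = concentration(params, ss, regimen.interval)
    return ExposureMetrics(fauc24=fauc24, fcmax=fu * cmax, fcmin=fu * cmin)
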