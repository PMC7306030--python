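"""Population-level model: fixed effects, between-subject variability, covariates.

Maps population typical values ("theta"), multiplicative covariate effects and
log-normal individual random effects ("eta") to the structural
:class:`~cipropk.pk.PKParameters` of one subject, and defines the combined
proportional + additive residual-error model for observed concentrations.

The individual model for a parameter ``P`` is

``P_j = P_pop * prod_k m_k(cov_jk) * exp(eta_Pj)``,  ``eta ~ N(0, omega)``

with continuous covariate effects entering as powers of the covariate
normalised to the population median, ``m = (cov/cov_m)^theta_cov``, and
binary covariates as multipliers, ``m = theta_cov^cov`` (cov in {0, 1}).

Between-subject variability is reported as a coefficient of variation using
the common pharmacometric approximation ``CV% = 100*sqrt(omega^2)``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .pk import PKParameters

__all__ = [
    "PARAM_NAMES",
    "COVARIATE_COLUMNS",
    "CovariateEffect",
    "IndividualCovariates",
    "PopulationModel",
    "individual_params",
    "sample_individuals",
    "residual_observe",
    "cv_percent",
    "reference_model",
]

#: order of the structural parameters everywhere in this package
PARAM_NAMES = ("CL", "Vc", "Vp", "Q")

#: covariate column names used in datasets (NONMEM-style CSV)
COVARIATE_COLUMNS = ("AGE", "SEX", "WT", "BMI", "CREA", "EGFR", "ALB", "RRT")

_FIELD_TO_COLUMN = {
    "age": "AGE",
    "sex": "SEX",
    "weight": "WT",
    "bmi": "BMI",
    "serum_creatinine": "CREA",
    "egfr": "EGFR",
    "albumin": "ALB",
    "rrt": "RRT",
}


@dataclass(frozen=True)
class IndividualCovariates:
    """Per-subject covariates.

    Continuous covariates must be positive when present; ``sex`` (1 = male)
    and ``rrt`` (1 = renal replacement therapy) are binary flags.  Units:
    age years, weight kg, BMI kg/m^2, serum creatinine umol/L, eGFR
    mL/min/1.73m^2, albumin g/L.
    """

    age: float | None = None
    sex: float | None = None
    weight: float | None = None
    bmi: float | None = None
    serum_creatinine: float | None = None
    egfr: float | None = None
    albumin: float | None = None
    rrt: float | None = None

    def __post_init__(self) -> None:
        for name in ("age", "weight", "bmi", "serum_creatinine", "egfr", "albumin"):
            value = getattr(self, name)
            if value is not None and value <= 0:
                raise ValueError(f"covariate {name!r} must be positive, got {value}")
        for name in ("sex", "rrt"):
            value = getattr(self, name)
            if value is not None and value not in (0, 1, 0.0, 1.0):
                raise ValueError(f"covariate {name!r} must be binary, got {value}")

    def as_columns(self) -> dict[str, float | None]:
        """Covariates keyed by dataset column name (AGE, SEX, WT, ...)."""
        return {col: getattr(self, f) for f, col in _FIELD_TO_COLUMN.items()}

    @classmethod
    def from_columns(cls, row: Mapping[str, float]) -> "IndividualCovariates":
        kwargs = {}
        for f, col in _FIELD_TO_COLUMN.items():
            if col in row and row[col] is not None and not (
                isinstance(row[col], float) and np.isnan(row[col])
            ):
                kwargs[f] = float(row[col])
        return cls(**kwargs)


@dataclass(frozen=True)
class CovariateEffect:
    """A multiplicative covariate effect on one structural parameter.

    ``kind="power"``: multiplier ``(cov/cov_median)**theta_cov`` for a
    continuous covariate normalised to the population median.
    ``kind="binary"``: multiplier ``theta_cov**cov`` for a 0/1 covariate.

    ``theta_cov`` defaults to the null value (0 exponent, i.e. multiplier 1
    for power; the binary default multiplier is 1.0 when ``theta_cov`` is
    left at 0.0 it is interpreted as exponent form only for power effects, so
    pass ``theta_cov=1.0`` explicitly for a null binary effect).
    """

    parameter: str
    covariate: str
    kind: str = "power"
    theta_cov: float = 0.0
    cov_median: float | None = None

    def __post_init__(self) -> None:
        if self.parameter not in PARAM_NAMES:
            raise ValueError(f"unknown parameter {self.parameter!r}")
        if self.kind not in ("power", "binary"):
            raise ValueError(f"kind must be 'power' or 'binary', got {self.kind!r}")
        if self.kind == "power":
            if self.cov_median is None or self.cov_median <= 0:
                raise ValueError("power effects need a positive cov_median")
        if self.kind == "binary" and self.theta_cov <= 0:
            raise ValueError("binary multiplier theta_cov must be > 0")

    @property
    def label(self) -> str:
        return f"{self.parameter}~{self.covariate}"

    def z(self, value):
        """Linearised covariate predictor: the multiplier is exp(coefficient * z)."""
        value = np.asarray(value, dtype=float)
        if self.kind == "power":
            return np.log(value / self.cov_median)
        return value

    @property
    def coefficient(self) -> float:
        """Coefficient on the log-parameter scale (exponent, or log multiplier)."""
        if self.kind == "power":
            return float(self.theta_cov)
        return float(np.log(self.theta_cov))

    def with_coefficient(self, coef: float) -> "CovariateEffect":
        theta = coef if self.kind == "power" else float(np.exp(coef))
        return dataclasses.replace(self, theta_cov=theta)

    def multiplier(self, value) -> np.ndarray:
        """Multiplicative factor applied to the typical parameter value."""
        return np.exp(self.coefficient * self.z(value))


def _covariate_value(cov, name: str):
    """Look up a covariate by column name or dataclass field name."""
    if cov is None:
        raise ValueError(f"covariate {name!r} required but no covariates given")
    if isinstance(cov, IndividualCovariates):
        mapping = cov.as_columns()
        mapping.update({f: getattr(cov, f) for f in _FIELD_TO_COLUMN})
    else:
        mapping = dict(cov)
    if name not in mapping or mapping[name] is None:
        raise ValueError(f"covariate {name!r} missing for this subject")
    return mapping[name]


@dataclass
class PopulationModel:
    """Fixed effects, IIV covariance, residual error and covariate effects.

    Attributes
    ----------
    theta : dict
        Typical values for ``CL`` (L/h), ``Vc`` (L), ``Vp`` (L), ``Q`` (L/h).
    iiv_params : tuple of str
        Structural parameters carrying a log-normal random effect, in omega
        order (e.g. ``("CL", "Vc")``).
    omega : ndarray
        Symmetric positive semi-definite covariance of the etas (log scale).
    sigma_prop : float
        Proportional residual SD (fraction).
    sigma_add : float
        Additive residual SD (mg/L).
    covariate_effects : tuple of CovariateEffect
        Multiplicative, composable covariate effects.
    """

    theta: dict[str, float]
    iiv_params: tuple[str, ...] = ("CL", "Vc")
    omega: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))
    sigma_prop: float = 0.0
    sigma_add: float = 0.0
    covariate_effects: tuple[CovariateEffect, ...] = ()

    def __post_init__(self) -> None:
        self.theta = {k: float(v) for k, v in self.theta.items()}
        missing = set(PARAM_NAMES) - set(self.theta)
        if missing:
            raise ValueError(f"theta missing entries for {sorted(missing)}")
        for name in PARAM_NAMES:
            if self.theta[name] <= 0:
                raise ValueError(f"theta[{name!r}] must be positive")
        self.iiv_params = tuple(self.iiv_params)
        for p in self.iiv_params:
            if p not in PARAM_NAMES:
                raise ValueError(f"unknown IIV parameter {p!r}")
        om = np.asarray(self.omega, dtype=float)
        d = len(self.iiv_params)
        if om.shape != (d, d):
            raise ValueError(f"omega must be {d}x{d}, got {om.shape}")
        if not np.allclose(om, om.T, atol=1e-10):
            raise ValueError("omega must be symmetric")
        om = 0.5 * (om + om.T)
        if d and np.min(np.linalg.eigvalsh(om)) < -1e-10:
            raise ValueError("omega must be positive semi-definite")
        self.omega = om
        if self.sigma_prop < 0 or self.sigma_add < 0:
            raise ValueError("residual SDs must be non-negative")
        self.covariate_effects = tuple(self.covariate_effects)

    # ---- structure helpers -------------------------------------------------

    @property
    def d(self) -> int:
        """Number of random-effect dimensions."""
        return len(self.iiv_params)

    def omega_var(self, param: str) -> float:
        """IIV variance (log scale) for a structural parameter (0 if none)."""
        if param not in self.iiv_params:
            return 0.0
        i = self.iiv_params.index(param)
        return float(self.omega[i, i])

    def iiv_cv_percent(self) -> dict[str, float]:
        """CV% per IIV parameter, ``100*sqrt(omega^2)``."""
        return {p: cv_percent(self.omega_var(p)) for p in self.iiv_params}

    def replace(self, **kwargs) -> "PopulationModel":
        return dataclasses.replace(self, **kwargs)

    # ---- individual mapping ------------------------------------------------

    def individual_params(self, cov=None, eta=None) -> PKParameters:
        """Structural parameters of one subject; see :func:`individual_params`."""
        return individual_params(self, cov, eta)

    # ---- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "theta": dict(self.theta),
            "units": {"CL": "L/h", "Vc": "L", "Vp": "L", "Q": "L/h"},
            "iiv_params": list(self.iiv_params),
            "omega": np.asarray(self.omega).tolist(),
            "sigma_prop": float(self.sigma_prop),
            "sigma_add": float(self.sigma_add),
            "sigma_add_units": "mg/L",
            "covariate_effects": [
                {
                    "parameter": e.parameter,
                    "covariate": e.covariate,
                    "kind": e.kind,
                    "theta_cov": e.theta_cov,
                    "cov_median": e.cov_median,
                }
                for e in self.covariate_effects
            ],
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "PopulationModel":
        effects = tuple(
            CovariateEffect(
                parameter=e["parameter"],
                covariate=e["covariate"],
                kind=e.get("kind", "power"),
                theta_cov=e.get("theta_cov", 0.0),
                cov_median=e.get("cov_median"),
            )
            for e in data.get("covariate_effects", ())
        )
        return cls(
            theta=dict(data["theta"]),
            iiv_params=tuple(data.get("iiv_params", ())),
            omega=np.asarray(data.get("omega", np.zeros((0, 0))), dtype=float),
            sigma_prop=float(data.get("sigma_prop", 0.0)),
            sigma_add=float(data.get("sigma_add", 0.0)),
            covariate_effects=effects,
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "PopulationModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def individual_params(pop: PopulationModel, cov=None, eta=None) -> PKParameters:
    """Map population parameters + covariates + random effects to one subject.

    ``eta`` must have length ``pop.d`` (``None`` means all zero).  Each
    structural parameter is ``theta * prod(covariate multipliers) * exp(eta)``;
    parameters without a random effect use ``exp(0)``.
    """
    if eta is None:
        eta = np.zeros(pop.d)
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (pop.d,):
        raise ValueError(
            f"eta must have shape ({pop.d},) matching iiv_params, got {eta.shape}"
        )
    logp = {p: np.log(pop.theta[p]) for p in PARAM_NAMES}
    for eff in pop.covariate_effects:
        value = _covariate_value(cov, eff.covariate)
        logp[eff.parameter] += eff.coefficient * float(eff.z(value))
    for k, p in enumerate(pop.iiv_params):
        logp[p] += eta[k]
    return PKParameters(
        cl=float(np.exp(logp["CL"])),
        vc=float(np.exp(logp["Vc"])),
        vp=float(np.exp(logp["Vp"])),
        q=float(np.exp(logp["Q"])),
    )


def sample_individuals(
    pop: PopulationModel,
    n: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    covariates=None,
):
    """Draw ``n`` virtual individuals from the population model.

    Returns ``(etas, params)`` with ``etas`` of shape (n, d) drawn from
    ``N(0, omega)`` and ``params`` of shape (n, 4) in :data:`PARAM_NAMES`
    order.  Reproducible for a fixed ``seed``.

    ``covariates`` (a DataFrame with one row per individual) is required when
    the model carries covariate effects.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    d = pop.d
    if d:
        if np.min(np.linalg.eigvalsh(pop.omega)) < -1e-10:
            raise ValueError("omega must be positive semi-definite")
        etas = rng.multivariate_normal(np.zeros(d), pop.omega, size=n)
    else:
        etas = np.zeros((n, 0))
    logp = np.tile(np.log([pop.theta[p] for p in PARAM_NAMES]), (n, 1))
    for eff in pop.covariate_effects:
        if covariates is None or eff.covariate not in covariates:
            raise ValueError(
                f"model has covariate effect on {eff.covariate!r}; pass a "
                "covariates table with that column"
            )
        z = eff.z(np.asarray(covariates[eff.covariate], dtype=float))
        logp[:, PARAM_NAMES.index(eff.parameter)] += eff.coefficient * z
    for k, p in enumerate(pop.iiv_params):
        logp[:, PARAM_NAMES.index(p)] += etas[:, k]
    return etas, np.exp(logp)


def residual_observe(
    pred,
    eps_prop=None,
    eps_add=None,
    *,
    sigma_prop: float = 0.0,
    sigma_add: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
):
    """Apply the combined proportional + additive residual-error model.

    ``y = pred * (1 + eps_prop) + eps_add``.  Pass ``eps_prop``/``eps_add``
    explicitly for the deterministic form; leave them ``None`` to draw from
    ``N(0, sigma^2)`` (zero when the corresponding SD is zero).
    """
    pred = np.asarray(pred, dtype=float)
    if np.any(pred < 0):
        raise ValueError("predicted concentrations must be non-negative")
    if rng is None:
        rng = np.random.default_rng(seed)
    if eps_prop is None:
        eps_prop = rng.normal(0.0, sigma_prop, size=pred.shape) if sigma_prop else 0.0
    if eps_add is None:
        eps_add = rng.normal(0.0, sigma_add, size=pred.shape) if sigma_add else 0.0
    out = pred * (1.0 + np.asarray(eps_prop)) + np.asarray(eps_add)
    return float(out) if out.ndim == 0 else out


def cv_percent(omega_sq) -> float:
    """Between-subject variability as CV%, ``100*sqrt(omega^2)``."""
    omega_sq = np.asarray(omega_sq, dtype=float)
    if np.any(omega_sq < 0):
        raise ValueError("variance must be non-negative")
    out = 100.0 * np.sqrt(omega_sq)
    return float(out) if out.ndim == 0 else out


def reference_model(
    cl_vc_corr: float = 0.5,
    include_q_iiv: bool = False,
    q_cv: float = 0.30,
) -> PopulationModel:
    """Published final population estimates for IV ciprofloxacin in adult ICU patients.

    Two-compartment disposition with typical values CL 25.4 L/h, Vc 91.1 L,
    Vp 164 L, Q 91.9 L/h; log-normal between-subject variability on CL
    (67.8 CV%) and Vc (51.0 CV%) with a full covariance block, and a combined
    proportional (15.3%) + additive (0.143 mg/L) residual error.  No covariate
    effects were retained in the final model.

    Parameters
    ----------
    cl_vc_corr : float
        Correlation of the CL and Vc random effects.  The source analysis
        estimated a covariance but did not report its value; 0.5 is a
        typical positive correlation and is configurable.
    include_q_iiv : bool
        Also place a diagonal random effect on Q (the model-building path
        included one, the reported final table did not).
    q_cv : float
        CV (fraction) for the optional Q random effect.
    """
    om_cl, om_vc = 0.678, 0.510
    cov = cl_vc_corr * om_cl * om_vc
    if include_q_iiv:
        omega = np.array(
            [
                [om_cl**2, cov, 0.0],
                [cov, om_vc**2, 0.0],
                [0.0, 0.0, q_cv**2],
            ]
        )
        iiv = ("CL", "Vc", "Q")
    else:
        omega = np.array([[om_cl**2, cov], [cov, om_vc**2]])
        iiv = ("CL", "Vc")
    return PopulationModel(
        theta={"CL": 25.4, "Vc": 91.1, "Vp": 164.0, "Q": 91.9},
        iiv_params=iiv,
        omega=omega,
        sigma_prop=0.153,
        sigma_add=0.143,
    )
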