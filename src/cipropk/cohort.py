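"""Synthetic ICU-cohort generator.

Emulates the sparse prospective sampling design of a two-centre ICU study of
intravenous ciprofloxacin so the estimation, evaluation and PTA machinery can
be exercised end to end without patient data: 42 subjects split 3/25/14
across 400 mg q24h/q12h/q8h, short infusions, and five samples within one
day-2 dosing interval (pre-dose trough, a peak drawn 15-30 min after the end
of infusion, 1 h and 3 h post-infusion, and the next trough).

Covariates are drawn from log-normal marginals matched to the published
cohort medians and IQRs (BMI uses the published min-max range); sex and
renal-replacement-therapy flags use the published frequencies.  Observations
receive combined proportional + additive residual error and are censored
below the assay quantification limit of 0.04 mg/L (M1: dropped with a count).

The generator returns both the observable dataset and a hidden truth record
(per-subject etas and structural parameters) for recovery testing.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import PKDataset
from .pk import infusion_concentration
from .population import (
    COVARIATE_COLUMNS,
    PARAM_NAMES,
    CovariateEffect,
    PopulationModel,
    reference_model,
)

__all__ = ["StudyDesign", "generate_cohort", "covariate_effect_scenario"]

logger = logging.getLogger(__name__)

# median and (lower, upper) dispersion anchor per continuous covariate.
# All are median (IQR) except BMI, whose published spread reads as a
# min-max range and is treated as one (fitted as a wide log-normal).
_CONTINUOUS_MARGINALS = {
    "AGE": (65.5, 56.0, 71.0, "iqr"),
    "WT": (80.0, 64.0, 90.0, "iqr"),
    "BMI": (26.0, 17.8, 46.3, "range"),
    "CREA": (90.0, 70.0, 153.0, "iqr"),
    "EGFR": (58.5, 32.0, 101.0, "iqr"),
    "ALB": (25.0, 22.0, 29.0, "iqr"),
}

_P_MALE = 25.0 / 42.0
_P_RRT = 10.0 / 42.0

#: standard-normal quantiles spanned by an IQR and by a min-max range
_Z_IQR = 0.6744897501960817
_Z_RANGE = 1.96


def covariate_median(name: str) -> float:
    """Population median used to normalise continuous covariate effects."""
    return _CONTINUOUS_MARGINALS[name][0]


@dataclass(frozen=True)
class StudyDesign:
    """The emulated sparse-sampling study design.

    ``group_sizes`` and ``group_regimens`` describe the dose groups
    (default: 400 mg q24h / q12h / q8h in 3 / 25 / 14 subjects).  Sampling
    happens within the day-2 dosing interval starting at ``sampling_start``
    hours after the first dose, with the peak drawn uniformly
    ``peak_window`` hours after the end of the infusion and further samples
    at ``post_infusion_offsets``.  ``missingness`` is the per-sample
    probability of a missed draw; ``lloq`` the assay quantification limit.
    """

    group_sizes: tuple[int, ...] = (3, 25, 14)
    group_regimens: tuple[tuple[float, float], ...] = (
        (400.0, 24.0),
        (400.0, 12.0),
        (400.0, 8.0),
    )  # (dose mg, interval h) per group
    infusion_duration: float = 0.5
    sampling_start: float = 24.0
    peak_window: tuple[float, float] = (0.25, 0.5)
    post_infusion_offsets: tuple[float, ...] = (1.0, 3.0)
    missingness: float = 0.0
    lloq: float = 0.04
    egfr_group_medians: tuple[float, ...] | None = None  # confounded-design option

    def __post_init__(self) -> None:
        if len(self.group_sizes) != len(self.group_regimens):
            raise ValueError("group_sizes and group_regimens must align")
        if any(s < 0 for s in self.group_sizes):
            raise ValueError("group sizes must be non-negative")
        if sum(self.group_sizes) == 0:
            raise ValueError("design must contain at least one subject")
        if not (0.0 <= self.missingness < 1.0):
            raise ValueError("missingness must be in [0, 1)")
        for dose, interval in self.group_regimens:
            if dose < 0 or interval <= 0:
                raise ValueError("invalid regimen in design")
            if not (0.0 < self.infusion_duration <= interval):
                raise ValueError("infusion duration must fit inside each interval")
        lo, hi = self.peak_window
        if not (0.0 <= lo <= hi):
            raise ValueError("invalid peak window")
        if self.egfr_group_medians is not None and len(
            self.egfr_group_medians
        ) != len(self.group_sizes):
            raise ValueError("egfr_group_medians must have one entry per group")

    @property
    def n_subjects(self) -> int:
        return int(sum(self.group_sizes))


def _lognormal_params(median, lo, hi, kind):
    mu = np.log(median)
    z = _Z_IQR if kind == "iqr" else _Z_RANGE
    sigma = (np.log(hi) - np.log(lo)) / (2.0 * z)
    return mu, sigma


def _draw_covariates(design: StudyDesign, groups, rng) -> pd.DataFrame:
    n = len(groups)
    out = {}
    for name, (med, lo, hi, kind) in _CONTINUOUS_MARGINALS.items():
        mu, sigma = _lognormal_params(med, lo, hi, kind)
        out[name] = np.exp(rng.normal(mu, sigma, size=n))
    if design.egfr_group_medians is not None:
        # dose-by-renal-function confounding: shift each group's eGFR to its
        # own median while keeping the overall log-scale spread
        _, sigma = _lognormal_params(*_CONTINUOUS_MARGINALS["EGFR"])
        medians = np.asarray(design.egfr_group_medians, dtype=float)
        out["EGFR"] = np.exp(
            np.log(medians[groups]) + rng.normal(0.0, sigma, size=n)
        )
    out["SEX"] = (rng.random(n) < _P_MALE).astype(float)
    out["RRT"] = (rng.random(n) < _P_RRT).astype(float)
    return pd.DataFrame(out)[list(COVARIATE_COLUMNS)]


def generate_cohort(
    design: StudyDesign | None = None,
    truth: PopulationModel | None = None,
    seed: int | None = None,
):
    """Simulate one cohort under the study design and a known truth model.

    Returns ``(dataset, truth_record)``: the observable
    :class:`~cipropk.dataset.PKDataset` (dose history through day 2 plus the
    five-sample observation template, with residual error and BLQ censoring
    applied) and a per-subject DataFrame of the hidden etas and structural
    parameters.  The number of censored/missing samples is recorded in
    ``truth_record.attrs``.

    Fully reproducible for a fixed ``seed``.
    """
    design = design or StudyDesign()
    truth = truth if truth is not None else reference_model()
    rng = np.random.default_rng(seed)

    groups = np.concatenate(
        [np.full(sz, g, dtype=int) for g, sz in enumerate(design.group_sizes)]
    )
    n = len(groups)
    covs = _draw_covariates(design, groups, rng)

    d = truth.d
    etas = (
        rng.multivariate_normal(np.zeros(d), truth.omega, size=n)
        if d
        else np.zeros((n, 0))
    )

    records = []
    truth_rows = []
    n_blq = 0
    n_missing = 0
    dur = design.infusion_duration
    start = design.sampling_start
    for i in range(n):
        dose, interval = design.group_regimens[groups[i]]
        cov_row = covs.iloc[i]
        params = truth.individual_params(cov_row.to_dict(), etas[i])

        dose_times = np.arange(0.0, start + 1e-9, interval)
        end_inf = start + dur
        peak = end_inf + rng.uniform(*design.peak_window)
        obs_times = np.array(
            [start, peak]
            + [end_inf + off for off in design.post_infusion_offsets]
            + [start + interval]
        )
        obs_times = np.sort(obs_times)

        p = params.as_array()
        pred = infusion_concentration(
            p[:1], p[1:2], p[2:3], p[3:4],
            dose_times[None, :],
            np.full((1, len(dose_times)), dose),
            np.full((1, len(dose_times)), dur),
            obs_times[None, :],
        )[0]
        eps_p = rng.normal(0.0, truth.sigma_prop, size=pred.shape)
        eps_a = rng.normal(0.0, truth.sigma_add, size=pred.shape)
        y = pred * (1.0 + eps_p) + eps_a

        sid = i + 1
        cov_vals = {c: float(cov_row[c]) for c in COVARIATE_COLUMNS}
        for td in dose_times:
            records.append(
                {"ID": sid, "TIME": td, "EVID": 1, "AMT": dose, "DUR": dur,
                 "DV": np.nan, "MDV": 1, **cov_vals}
            )
        for t_obs, value in zip(obs_times, y):
            if design.missingness and rng.random() < design.missingness:
                n_missing += 1
                continue
            if value < design.lloq:
                n_blq += 1
                continue
            records.append(
                {"ID": sid, "TIME": t_obs, "EVID": 0, "AMT": 0.0, "DUR": 0.0,
                 "DV": value, "MDV": 0, **cov_vals}
            )
        truth_rows.append(
            {"ID": sid, "group": groups[i], "dose": dose, "interval": interval,
             **{f"eta_{pname}": etas[i, k]
                for k, pname in enumerate(truth.iiv_params)},
             **dict(zip(("CL", "Vc", "Vp", "Q"), p))}
        )

    frame = pd.DataFrame(records).sort_values(
        ["ID", "TIME", "EVID"], kind="stable"
    ).reset_index(drop=True)
    # DUR must be positive on dose rows only; observation rows carry 0 but the
    # dataset validator only inspects DUR on EVID == 1 rows
    frame.loc[frame["EVID"] == 0, "DUR"] = 0.0
    dataset = PKDataset(frame)
    if n_blq:
        logger.info("generator censored %d observations below LLOQ", n_blq)
    truth_record = pd.DataFrame(truth_rows)
    truth_record.attrs["n_blq_dropped"] = n_blq
    truth_record.attrs["n_missing"] = n_missing
    return dataset, truth_record


def covariate_effect_scenario(
    design: StudyDesign | None = None,
    effect: CovariateEffect | None = None,
    n_subjects: int | None = None,
    truth: PopulationModel | None = None,
    seed: int | None = None,
):
    """A cohort whose truth includes a specified covariate effect.

    Used for selection power / type-I-error studies of the covariate search:
    ``effect.theta_cov = 0`` (power kind) reproduces the null scenario.  When
    ``n_subjects`` is given, the default 3/25/14 group split is rescaled to
    that total by largest-remainder apportionment.

    Returns ``(dataset, truth_record)`` as :func:`generate_cohort`.
    """
    design = design or StudyDesign()
    truth = truth if truth is not None else reference_model()
    if effect is not None:
        truth = truth.replace(
            covariate_effects=truth.covariate_effects + (effect,)
        )
    if n_subjects is not None:
        base = np.asarray(design.group_sizes, dtype=float)
        quota = n_subjects * base / base.sum()
        sizes = np.floor(quota).astype(int)
        rema = quota - sizes
        for k in np.argsort(-rema)[: n_subjects - sizes.sum()]:
            sizes[k] += 1
        design = dataclasses.replace(design, group_sizes=tuple(int(s) for s in sizes))
    return generate_cohort(design, truth, seed)
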