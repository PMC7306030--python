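"""Longitudinal PK event records: NONMEM-style CSV reading, writing, packing.

A dataset is one row per event: dose events (``EVID == 1``) carry ``AMT``
(mg) and ``DUR`` (infusion duration, h); observation events (``EVID == 0``)
carry ``DV`` (total plasma concentration, mg/L) with ``MDV == 0``.  Subject
covariates are replicated on every row under the columns in
:data:`~cipropk.population.COVARIATE_COLUMNS`.

``pack`` converts the record list into rectangular per-subject arrays
(padded with masked entries) so the estimation and simulation machinery can
evaluate the whole cohort with vectorised closed-form kinetics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .population import COVARIATE_COLUMNS

__all__ = ["REQUIRED_COLUMNS", "PKDataset", "PackedCohort"]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("ID", "TIME", "EVID", "AMT", "DUR", "DV", "MDV")

#: assay lower limit of quantification, mg/L
DEFAULT_LLOQ = 0.04


@dataclass
class PackedCohort:
    """Rectangular per-subject arrays for vectorised cohort computations."""

    ids: np.ndarray  # (n,) subject identifiers
    obs_time: np.ndarray  # (n, mo)
    obs_mask: np.ndarray  # (n, mo) bool
    y: np.ndarray  # (n, mo) observed concentrations (0 where masked)
    obs_row: np.ndarray  # (n, mo) row index into the observations frame, -1 pad
    tad: np.ndarray  # (n, mo) time after most recent prior dose
    dose_time: np.ndarray  # (n, md)
    dose_amt: np.ndarray  # (n, md) 0 where padded
    dose_dur: np.ndarray  # (n, md) 1 where padded
    covariates: pd.DataFrame  # indexed by subject id

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_obs(self) -> int:
        return int(self.obs_mask.sum())


class PKDataset:
    """A cohort of dose and observation records with per-subject covariates.

    Invariants checked at construction: times non-negative and non-decreasing
    within subject, every subject has at least one dose and one quantified
    observation, quantified concentrations are positive.
    """

    def __init__(self, frame: pd.DataFrame, validate: bool = True):
        frame = frame.copy().reset_index(drop=True)
        missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"dataset missing required columns {missing}")
        cov_cols = [c for c in COVARIATE_COLUMNS if c in frame.columns]
        extra = [
            c for c in frame.columns if c not in REQUIRED_COLUMNS + tuple(cov_cols)
        ]
        frame = frame[list(REQUIRED_COLUMNS) + cov_cols + extra]
        # canonical dtypes so text round-trips compare equal
        for col in ("ID", "EVID", "MDV"):
            frame[col] = frame[col].astype(np.int64)
        for col in frame.columns:
            if col not in ("ID", "EVID", "MDV") and pd.api.types.is_numeric_dtype(
                frame[col]
            ):
                frame[col] = frame[col].astype(np.float64)
        self.frame = frame
        self.covariate_columns = cov_cols
        if validate:
            self._validate()

    def _validate(self) -> None:
        f = self.frame
        if np.any(f["TIME"].to_numpy() < 0):
            raise ValueError("TIME must be non-negative")
        if not set(np.unique(f["EVID"])) <= {0, 1}:
            raise ValueError("EVID must be 0 (observation) or 1 (dose)")
        for sid, grp in f.groupby("ID", sort=False):
            t = grp["TIME"].to_numpy(dtype=float)
            if np.any(np.diff(t) < -1e-9):
                raise ValueError(f"subject {sid}: times must be non-decreasing")
            doses = grp[grp["EVID"] == 1]
            obs = grp[(grp["EVID"] == 0) & (grp["MDV"] == 0)]
            if len(doses) == 0:
                raise ValueError(f"subject {sid}: needs at least one dose record")
            if len(obs) == 0:
                raise ValueError(f"subject {sid}: needs at least one observation")
            if np.any(doses["AMT"].to_numpy(dtype=float) < 0):
                raise ValueError(f"subject {sid}: dose AMT must be non-negative")
            if np.any(doses["DUR"].to_numpy(dtype=float) <= 0):
                raise ValueError(f"subject {sid}: infusion DUR must be positive")
            dv = obs["DV"].to_numpy(dtype=float)
            if np.any(~np.isfinite(dv)) or np.any(dv <= 0):
                raise ValueError(
                    f"subject {sid}: quantified concentrations must be positive"
                )

    # ---- accessors ---------------------------------------------------------

    @property
    def subject_ids(self) -> np.ndarray:
        return self.frame["ID"].unique()

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def observations(self) -> pd.DataFrame:
        f = self.frame
        return f[(f["EVID"] == 0) & (f["MDV"] == 0)]

    def doses(self) -> pd.DataFrame:
        return self.frame[self.frame["EVID"] == 1]

    @property
    def n_observations(self) -> int:
        return len(self.observations())

    def covariates(self) -> pd.DataFrame:
        """One row per subject (first record), indexed by ID."""
        first = self.frame.groupby("ID", sort=False).first()
        return first[self.covariate_columns]

    def dose_interval(self) -> pd.Series:
        """Modal inter-dose interval per subject (h); NaN for single doses."""
        out = {}
        for sid, grp in self.doses().groupby("ID", sort=False):
            t = np.sort(grp["TIME"].to_numpy(dtype=float))
            out[sid] = float(np.median(np.diff(t))) if len(t) > 1 else np.nan
        return pd.Series(out, name="interval")

    # ---- transformations ---------------------------------------------------

    def drop_blq(self, lloq: float = DEFAULT_LLOQ) -> tuple["PKDataset", int]:
        """Discard observations below the quantification limit (M1 handling).

        Returns the filtered dataset and the number of records dropped.
        """
        f = self.frame
        blq = (f["EVID"] == 0) & (f["MDV"] == 0) & (f["DV"] < lloq)
        n = int(blq.sum())
        if n:
            logger.warning("dropping %d observations below LLOQ %.3g mg/L", n, lloq)
        return PKDataset(f[~blq], validate=True), n

    def resample_subjects(self, ids) -> "PKDataset":
        """Bootstrap helper: new dataset from subjects ``ids`` (with repeats).

        Subjects are relabelled ``1..len(ids)`` so repeated draws remain
        distinct individuals.
        """
        parts = []
        for new_id, sid in enumerate(ids, start=1):
            block = self.frame[self.frame["ID"] == sid].copy()
            block["ID"] = new_id
            parts.append(block)
        return PKDataset(pd.concat(parts, ignore_index=True), validate=False)

    # ---- IO ----------------------------------------------------------------

    def write_csv(self, path) -> None:
        # %.17g guarantees exact float64 round-trip through text
        self.frame.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def read_csv(cls, path, drop_blq: bool = False, lloq: float = DEFAULT_LLOQ):
        """Read a NONMEM-style CSV; optionally discard BLQ observations."""
        frame = pd.read_csv(path, float_precision="round_trip")
        ds = cls(frame)
        if drop_blq:
            ds, _ = ds.drop_blq(lloq)
        return ds

    def equals(self, other: "PKDataset") -> bool:
        return self.frame.equals(other.frame)

    # ---- packing -----------------------------------------------------------

    def pack(self) -> PackedCohort:
        obs = self.observations()
        doses = self.doses()
        ids = self.subject_ids
        n = len(ids)
        obs_groups = {sid: g for sid, g in obs.groupby("ID", sort=False)}
        dose_groups = {sid: g for sid, g in doses.groupby("ID", sort=False)}
        mo = max(len(g) for g in obs_groups.values())
        md = max(len(g) for g in dose_groups.values())

        obs_time = np.zeros((n, mo))
        obs_mask = np.zeros((n, mo), dtype=bool)
        y = np.zeros((n, mo))
        obs_row = np.full((n, mo), -1, dtype=int)
        tad = np.zeros((n, mo))
        dose_time = np.zeros((n, md))
        dose_amt = np.zeros((n, md))
        dose_dur = np.ones((n, md))

        obs_positions = {row: k for k, row in enumerate(obs.index)}
        for i, sid in enumerate(ids):
            og = obs_groups[sid]
            dg = dose_groups[sid]
            no, nd = len(og), len(dg)
            t_obs = og["TIME"].to_numpy(dtype=float)
            obs_time[i, :no] = t_obs
            obs_mask[i, :no] = True
            y[i, :no] = og["DV"].to_numpy(dtype=float)
            obs_row[i, :no] = [obs_positions[r] for r in og.index]
            t_dose = dg["TIME"].to_numpy(dtype=float)
            dose_time[i, :nd] = t_dose
            dose_amt[i, :nd] = dg["AMT"].to_numpy(dtype=float)
            dose_dur[i, :nd] = dg["DUR"].to_numpy(dtype=float)
            # time after the most recent dose given strictly before the sample
            for j, t in enumerate(t_obs):
                prior = t_dose[t_dose < t - 1e-12]
                tad[i, j] = t - prior.max() if len(prior) else t
        return PackedCohort(
            ids=np.asarray(ids),
            obs_time=obs_time,
            obs_mask=obs_mask,
            y=y,
            obs_row=obs_row,
            tad=tad,
            dose_time=dose_time,
            dose_amt=dose_amt,
            dose_dur=dose_dur,
            covariates=self.covariates(),
        )
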