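"""Model qualification: nonparametric bootstrap, VPC, NPDE and residual diagnostics.

All procedures simulate or resample under the fitted model and are
bit-for-bit reproducible at a fixed seed and replicate count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import solve_triangular

from .dataset import PKDataset
from .estimation import FitResult, _LaplaceEngine, fit
from .population import PARAM_NAMES, PopulationModel

__all__ = [
    "BootstrapResult",
    "VPCResult",
    "NPDEResult",
    "bootstrap",
    "vpc",
    "npde",
    "gof",
    "plot_vpc",
    "plot_gof",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


@dataclass
class BootstrapResult:
    """Resampled estimates with percentile confidence intervals."""

    estimates: pd.DataFrame  # one row per successful resample
    median: pd.Series
    ci: pd.DataFrame  # rows "2.5%", "97.5%"
    n_success: int
    n_fail: int
    flagged: bool  # True when more than half of the refits failed


def _scalar_estimates(model: PopulationModel) -> dict[str, float]:
    out = {p: model.theta[p] for p in PARAM_NAMES}
    for p in model.iiv_params:
        out[f"IIV_{p}"] = 100.0 * np.sqrt(model.omega_var(p))
    out["sigma_prop"] = model.sigma_prop
    out["sigma_add"] = model.sigma_add
    for e in model.covariate_effects:
        out[f"beta:{e.label}"] = e.theta_cov
    return out


def bootstrap(
    dataset: PKDataset,
    model_spec: PopulationModel,
    n_resamples: int = 1000,
    seed: int | None = None,
    *,
    stratify_by_interval: bool = False,
    method: str = "bfgs",
) -> BootstrapResult:
    """Nonparametric bootstrap: resample subjects with replacement and refit.

    ``model_spec`` provides structure and the warm-start values (typically
    the point estimates of the original fit).  Refits use a quasi-Newton
    polish by default.  Failed or non-converged refits are counted and
    excluded; the result is flagged when more than half fail.

    With ``stratify_by_interval`` resampling is done within dosing-interval
    groups, preserving the dose-group sizes of the design.
    """
    if dataset.n_subjects < 2:
        raise ValueError("bootstrap requires at least 2 subjects")
    rng = np.random.default_rng(seed)
    ids = dataset.subject_ids
    groups = None
    if stratify_by_interval:
        interval = dataset.dose_interval()
        groups = [ids[np.isin(ids, interval[interval == val].index)]
                  for val in sorted(interval.dropna().unique())]
        leftover = ids[np.isin(ids, interval[interval.isna()].index)]
        if len(leftover):
            groups.append(leftover)
    rows = []
    n_fail = 0
    for _ in range(n_resamples):
        if groups is None:
            draw = rng.choice(ids, size=len(ids), replace=True)
        else:
            draw = np.concatenate(
                [rng.choice(g, size=len(g), replace=True) for g in groups]
            )
        resampled = dataset.resample_subjects(draw)
        try:
            r = fit(resampled, model_spec, method=method, compute_rse=False)
        except Exception as exc:  # noqa: BLE001 - count, don't crash
            logger.warning("bootstrap refit raised: %s", exc)
            n_fail += 1
            continue
        if not r.converged or not np.isfinite(r.ofv):
            n_fail += 1
            continue
        rows.append(_scalar_estimates(r.model))
    estimates = pd.DataFrame(rows)
    n_success = len(estimates)
    flagged = n_fail > n_success
    if flagged:
        logger.warning("bootstrap: %d/%d refits failed", n_fail, n_resamples)
    if n_success:
        median = estimates.median()
        ci = estimates.quantile([0.025, 0.975])
        ci.index = ["2.5%", "97.5%"]
    else:
        median = pd.Series(dtype=float)
        ci = pd.DataFrame()
    return BootstrapResult(
        estimates=estimates, median=median, ci=ci,
        n_success=n_success, n_fail=n_fail, flagged=flagged,
    )


# ---------------------------------------------------------------------------
# simulation helper shared by VPC and NPDE
# ---------------------------------------------------------------------------


def _simulate_replicates(packed, model: PopulationModel, n_sim: int,
                         rng: np.random.Generator, chunk: int = 200):
    """Simulate observation vectors under the model with the original design.

    Yields arrays of shape (n_rep_chunk, n_subjects, mo); masked positions are
    zero.  Randomness: fresh etas per subject per replicate plus combined
    residual error.
    """
    engine = _LaplaceEngine(packed, model)
    log_theta = np.log([model.theta[p] for p in PARAM_NAMES])
    coefs = np.array([e.coefficient for e in model.covariate_effects])
    sp, sa, omega = model.sigma_prop, model.sigma_add, model.omega
    n, mo = packed.obs_mask.shape
    d = model.d
    done = 0
    while done < n_sim:
        m = min(chunk, n_sim - done)
        if d:
            etas = rng.multivariate_normal(np.zeros(d), omega, size=(m, n))
        else:
            etas = np.zeros((m, n, 0))
        sims = np.empty((m, n, mo))
        for r in range(m):
            f = engine.predict(engine.param_matrix(log_theta, coefs, etas[r]))
            eps_p = rng.standard_normal((n, mo)) * sp
            eps_a = rng.standard_normal((n, mo)) * sa
            sims[r] = f * (1.0 + eps_p) + eps_a
        sims *= packed.obs_mask
        yield sims
        done += m


# ---------------------------------------------------------------------------
# VPC
# ---------------------------------------------------------------------------


@dataclass
class VPCResult:
    """Binned observed percentiles with simulated confidence bands."""

    bin_edges: np.ndarray  # on the time-after-dose axis
    table: pd.DataFrame  # per bin: n, observed med/p5/p95, CI bounds per percentile
    n_sim: int


_PCTS = {"p5": 5.0, "median": 50.0, "p95": 95.0}


def vpc(
    dataset: PKDataset,
    model: PopulationModel,
    n_sim: int = 1000,
    seed: int | None = None,
    bins=None,
) -> VPCResult:
    """Visual predictive check on the time-after-dose axis.

    Simulates ``n_sim`` replicates of the dataset under ``model`` with the
    original dosing/sampling design, then per time bin compares the observed
    median/5th/95th percentiles with the simulated 95% confidence interval of
    each percentile.

    Default bins follow the sparse sampling template: a peak bin just after
    the end of infusion, two mid-interval bins and a trough bin, with the
    median infusion duration anchoring the edges.  Pass explicit ``bins``
    (edges, h) to override.  Empty bins are dropped with a warning.
    """
    packed = dataset.pack()
    rng = np.random.default_rng(seed)
    tad = packed.tad[packed.obs_mask]
    y = packed.y[packed.obs_mask]
    if bins is None:
        dur = float(np.median(packed.dose_dur[packed.dose_amt > 0]))
        bins = np.array([0.0, dur + 0.75, dur + 2.0, dur + 6.0, np.inf])
    bins = np.asarray(bins, dtype=float)
    idx = np.digitize(tad, bins) - 1
    n_bins = len(bins) - 1

    keep = []
    for b in range(n_bins):
        if np.sum(idx == b) == 0:
            logger.warning("VPC: bin %d is empty and was dropped", b)
        else:
            keep.append(b)

    sim_pct = {k: [] for k in _PCTS}
    for sims in _simulate_replicates(packed, model, n_sim, rng):
        flat = sims[:, packed.obs_mask]  # (m, n_obs)
        for name, pct in _PCTS.items():
            reps = np.stack(
                [np.percentile(flat[:, idx == b], pct, axis=1) for b in keep],
                axis=1,
            )  # (m, n_keep)
            sim_pct[name].append(reps)

    rows = []
    for j, b in enumerate(keep):
        sel = idx == b
        row = {
            "bin": b,
            "tad_lo": bins[b],
            "tad_hi": bins[b + 1],
            "n": int(sel.sum()),
            "obs_p5": float(np.percentile(y[sel], 5)),
            "obs_median": float(np.percentile(y[sel], 50)),
            "obs_p95": float(np.percentile(y[sel], 95)),
        }
        for name in _PCTS:
            reps = np.concatenate([c[:, j] for c in sim_pct[name]])
            row[f"sim_{name}_lo"] = float(np.percentile(reps, 2.5))
            row[f"sim_{name}_mid"] = float(np.percentile(reps, 50))
            row[f"sim_{name}_hi"] = float(np.percentile(reps, 97.5))
        rows.append(row)
    table = pd.DataFrame(rows)
    for name in _PCTS:  # percentile ordering within each bin
        assert (table[f"sim_{name}_lo"] <= table[f"sim_{name}_hi"]).all()
    return VPCResult(bin_edges=bins, table=table, n_sim=n_sim)


# ---------------------------------------------------------------------------
# NPDE
# ---------------------------------------------------------------------------


@dataclass
class NPDEResult:
    """Normalised prediction distribution errors and their null diagnostics."""

    table: pd.DataFrame  # ID, TIME, DV, npde
    mean: float
    variance: float
    normality_stat: float
    normality_pvalue: float
    n_sim: int


def npde(
    dataset: PKDataset,
    model: PopulationModel,
    n_sim: int = 1000,
    seed: int | None = None,
) -> NPDEResult:
    """Normalised prediction distribution errors.

    Per subject, ``n_sim`` replicate observation vectors are simulated under
    the model.  Observed and simulated vectors are mean-centred and
    decorrelated with the inverse Cholesky factor of the empirical simulated
    covariance; each decorrelated observation's percentile among its
    decorrelated simulated counterparts is mapped through the inverse
    standard-normal CDF.  Percentiles are clipped to
    ``(1/(2 n_sim), 1 - 1/(2 n_sim))``.  Under the true model the NPDE are
    approximately iid N(0, 1).

    A singular simulated covariance is ridge-regularised with a warning.
    """
    if n_sim < 100:
        raise ValueError("npde requires n_sim >= 100")
    packed = dataset.pack()
    rng = np.random.default_rng(seed)
    sims = np.concatenate(
        list(_simulate_replicates(packed, model, n_sim, rng)), axis=0
    )  # (n_sim, n, mo)

    obs = dataset.observations()
    npde_flat = np.empty(packed.n_obs)
    lo = 1.0 / (2.0 * n_sim)
    out_rows = np.empty(packed.n_obs, dtype=int)
    pos = 0
    for i in range(packed.n):
        m = packed.obs_mask[i]
        k = int(m.sum())
        yi = packed.y[i, m]
        si = sims[:, i, m]  # (n_sim, k)
        mu = si.mean(axis=0)
        cov = np.cov(si, rowvar=False)
        cov = np.atleast_2d(cov)
        ridge = 0.0
        for _ in range(8):
            try:
                L = np.linalg.cholesky(cov + ridge * np.eye(k))
                break
            except np.linalg.LinAlgError:
                ridge = max(ridge * 10.0, 1e-8 * float(np.mean(np.diag(cov))))
                logger.warning(
                    "npde: singular simulated covariance for subject %s, "
                    "ridge %.2e", packed.ids[i], ridge,
                )
        y_dec = solve_triangular(L, yi - mu, lower=True)
        s_dec = solve_triangular(L, (si - mu).T, lower=True)  # (k, n_sim)
        # midpoint tie handling: an observation exactly at the simulated
        # median maps to percentile 0.5 and hence NPDE 0
        pct = ((s_dec < y_dec[:, None]).sum(axis=1)
               + 0.5 * (s_dec == y_dec[:, None]).sum(axis=1)) / n_sim
        pct = np.clip(pct, lo, 1.0 - lo)
        npde_flat[pos:pos + k] = stats.norm.ppf(pct)
        out_rows[pos:pos + k] = packed.obs_row[i, m]
        pos += k

    order = np.argsort(out_rows)
    values = npde_flat[order]
    table = obs[["ID", "TIME", "DV"]].reset_index(drop=True).copy()
    table["npde"] = values
    stat, pval = stats.normaltest(values)
    return NPDEResult(
        table=table,
        mean=float(values.mean()),
        variance=float(values.var(ddof=1)),
        normality_stat=float(stat),
        normality_pvalue=float(pval),
        n_sim=n_sim,
    )


# ---------------------------------------------------------------------------
# goodness of fit
# ---------------------------------------------------------------------------


def gof(fit_result: FitResult, dataset: PKDataset,
        model: PopulationModel | None = None) -> pd.DataFrame:
    """Residual table: PRED, IPRED, IWRES and CWRES per observation.

    PRED is the population prediction (eta = 0), IPRED the prediction at the
    empirical-Bayes etas, and CWRES the conditional weighted residual from a
    first-order linearisation of the individual model around the eta mode:
    ``CWRES = L^-1 (y - (f(eta*) - G eta*))`` with
    ``L L' = G Omega G' + diag(v)`` and ``G = df/deta`` at the mode.
    """
    model = model or fit_result.model
    packed = dataset.pack()
    engine = _LaplaceEngine(packed, model)
    log_theta = np.log([model.theta[p] for p in PARAM_NAMES])
    coefs = np.array([e.coefficient for e in model.covariate_effects])
    sp, sa, omega = model.sigma_prop, model.sigma_add, model.omega

    etas = fit_result.etas.reindex(packed.ids).to_numpy()
    if model.d == 0:
        etas = np.zeros((packed.n, 0))
    pred = engine.predict(engine.param_matrix(log_theta, coefs,
                                              np.zeros_like(etas)))
    f_ind, v_ind = engine._f_v(log_theta, coefs, sp, sa, etas)

    d = model.d
    G = np.zeros(f_ind.shape + (d,))
    delta = 1e-4
    for k in range(d):
        shift = np.zeros_like(etas)
        shift[:, k] = delta
        fp, _ = engine._f_v(log_theta, coefs, sp, sa, etas + shift)
        fm, _ = engine._f_v(log_theta, coefs, sp, sa, etas - shift)
        G[:, :, k] = (fp - fm) / (2.0 * delta)

    obs = dataset.observations()
    n_rows = len(obs)
    cols = {name: np.empty(n_rows) for name in
            ("PRED", "IPRED", "IWRES", "CWRES", "TAD")}
    for i in range(packed.n):
        m = packed.obs_mask[i]
        rows = packed.obs_row[i, m]
        yi = packed.y[i, m]
        fi = f_ind[i, m]
        vi = v_ind[i, m]
        Gi = G[i, m]
        if d:
            cov_i = Gi @ omega @ Gi.T + np.diag(vi)
            L = np.linalg.cholesky(cov_i)
            centred = yi - (fi - Gi @ etas[i])
            cwres = solve_triangular(L, centred, lower=True)
        else:
            cwres = (yi - fi) / np.sqrt(vi)
        cols["PRED"][rows] = pred[i, m]
        cols["IPRED"][rows] = fi
        cols["IWRES"][rows] = (yi - fi) / np.sqrt(vi)
        cols["CWRES"][rows] = cwres
        cols["TAD"][rows] = packed.tad[i, m]

    out = obs[["ID", "TIME", "DV"]].reset_index(drop=True).copy()
    for name in ("TAD", "PRED", "IPRED", "IWRES", "CWRES"):
        out[name] = cols[name]
    return out


# ---------------------------------------------------------------------------
# plotting (matplotlib, optional use)
# ---------------------------------------------------------------------------


def plot_vpc(result: VPCResult, path=None, ax=None):
    """Percentile-band VPC panel (observed lines over simulated ribbons)."""
    import matplotlib
    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 5))
    t = result.table
    x = 0.5 * (t["tad_lo"] + np.minimum(t["tad_hi"], t["tad_lo"] * 0 + 30))
    for name, color in (("p5", "tab:blue"), ("median", "tab:red"),
                        ("p95", "tab:blue")):
        ax.fill_between(x, t[f"sim_{name}_lo"], t[f"sim_{name}_hi"],
                        alpha=0.25, color=color)
        ax.plot(x, t[f"obs_{name}"], "-o", color=color, label=f"observed {name}")
    ax.set_xlabel("time after dose (h)")
    ax.set_ylabel("concentration (mg/L)")
    ax.legend(fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_gof(table: pd.DataFrame, path=None):
    """2x2 goodness-of-fit panel: OBS vs PRED/IPRED, CWRES vs TAD/PRED."""
    import matplotlib
    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(9, 8))
    lim = [0, max(table["DV"].max(), table["PRED"].max(), table["IPRED"].max())]
    for ax, col in zip(axes[0], ("PRED", "IPRED")):
        ax.plot(table[col], table["DV"], "o", ms=3, alpha=0.6)
        ax.plot(lim, lim, "k-", lw=1)
        ax.set_xlabel(col)
        ax.set_ylabel("OBS (mg/L)")
    for ax, col in zip(axes[1], ("TAD", "PRED")):
        ax.plot(table[col], table["CWRES"], "o", ms=3, alpha=0.6)
        ax.axhline(0.0, color="k", lw=1)
        ax.set_xlabel(col)
        ax.set_ylabel("CWRES")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
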