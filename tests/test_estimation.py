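"""FOCE-I objective and fit against exact and quadrature oracles."""

import numpy as np
import pandas as pd
import pytest

import cipropk as c
from cipropk.dataset import PKDataset
from cipropk.pk import infusion_concentration


def _design_frame(n_subj, obs_times, y_per_subject, dose=400.0, tau=12.0,
                  dur=0.5, n_dose=3):
    rows = []
    for i in range(n_subj):
        for k in range(n_dose):
            rows.append({"ID": i + 1, "TIME": k * tau, "EVID": 1, "AMT": dose,
                         "DUR": dur, "DV": np.nan, "MDV": 1})
        for t, v in zip(obs_times, y_per_subject[i]):
            rows.append({"ID": i + 1, "TIME": t, "EVID": 0, "AMT": 0.0,
                         "DUR": 0.0, "DV": v, "MDV": 0})
    frame = pd.DataFrame(rows).sort_values(["ID", "TIME", "EVID"])
    return PKDataset(frame.reset_index(drop=True))


def _predict(model, eta, obs_times, dose=400.0, tau=12.0, dur=0.5, n_dose=3):
    p = model.individual_params(None, eta).as_array()
    dt = np.arange(n_dose) * tau
    return infusion_concentration(
        p[:1], p[1:2], p[2:3], p[3:4], dt[None, :],
        np.full((1, n_dose), dose), np.full((1, n_dose), dur),
        np.asarray(obs_times, dtype=float)[None, :],
    )[0]


@pytest.fixture(scope="module")
def tiny_dataset(ref_model):
    """Two subjects with known etas, moderate noise."""
    rng = np.random.default_rng(42)
    obs_times = [24.0, 25.0, 25.5, 27.5, 36.0]
    etas = np.array([[0.3, -0.2], [-0.5, 0.4]])
    y = []
    for eta in etas:
        f = _predict(ref_model, eta, obs_times)
        y.append(f * (1 + rng.normal(0, 0.153, f.shape))
                 + rng.normal(0, 0.143, f.shape))
    return _design_frame(2, obs_times, np.abs(y))


def test_ofv_equals_exact_gaussian_deviance_without_random_effects(tiny_dataset,
                                                                   ref_model):
    """With omega = 0 the Laplace OFV is the exact -2 log likelihood."""
    sa = 0.5
    m0 = ref_model.replace(iiv_params=(), omega=np.zeros((0, 0)),
                           sigma_prop=0.0, sigma_add=sa)
    val = c.ofv(tiny_dataset, m0)
    obs = tiny_dataset.observations()
    resid = []
    for sid, grp in obs.groupby("ID"):
        f = _predict(m0, np.zeros(0), grp["TIME"].to_numpy())
        resid.append(grp["DV"].to_numpy() - f)
    r = np.concatenate(resid)
    exact = float(np.sum(np.log(2 * np.pi * sa**2) + r**2 / sa**2))
    assert val == pytest.approx(exact, rel=1e-9)


def test_ofv_matches_gauss_hermite_quadrature(tiny_dataset, ref_model):
    """Laplace-with-interaction OFV vs dense 2-D quadrature of the true
    marginal likelihood (independent numerical oracle)."""
    val = c.ofv(tiny_dataset, ref_model)

    # 80-point tensor Gauss-Hermite with covariance rotation
    nodes, weights = np.polynomial.hermite_e.hermegauss(80)
    L = np.linalg.cholesky(ref_model.omega)
    obs = tiny_dataset.observations()
    total = 0.0
    for sid, grp in obs.groupby("ID"):
        t = grp["TIME"].to_numpy()
        y = grp["DV"].to_numpy()
        lik = 0.0
        for a, wa in zip(nodes, weights):
            for b, wb in zip(nodes, weights):
                eta = L @ np.array([a, b])
                f = _predict(ref_model, eta, t)
                v = (ref_model.sigma_prop * f) ** 2 + ref_model.sigma_add**2
                ll = -0.5 * np.sum(np.log(2 * np.pi * v) + (y - f) ** 2 / v)
                lik += wa * wb * np.exp(ll)
        total += -2.0 * (np.log(lik) - np.log(2 * np.pi))
    assert val == pytest.approx(total, abs=0.5)


def test_ofv_additive_over_subjects(tiny_dataset, ref_model):
    """Duplicating every subject doubles the OFV."""
    base = c.ofv(tiny_dataset, ref_model)
    f = tiny_dataset.frame
    dup = pd.concat([f, f.assign(ID=f["ID"] + 10)], ignore_index=True)
    assert c.ofv(PKDataset(dup), ref_model) == pytest.approx(2 * base, rel=1e-9)


def test_ofv_invariant_to_subject_relabelling(tiny_dataset, ref_model):
    base = c.ofv(tiny_dataset, ref_model)
    f = tiny_dataset.frame.copy()
    f["ID"] = f["ID"].map({1: 7, 2: 3})
    shuffled = pd.concat(
        [f[f["ID"] == 3], f[f["ID"] == 7]], ignore_index=True
    )
    assert c.ofv(PKDataset(shuffled), ref_model) == pytest.approx(base, rel=1e-12)


def test_near_noiseless_recovery_within_one_percent(ref_model):
    """Rich sampling, no IIV, tiny additive noise: thetas recovered to 1%."""
    rng = np.random.default_rng(9)
    obs_times = [24.1, 24.6, 24.8, 25.0, 25.5, 26.5, 28.0, 30.0, 33.0, 36.0]
    truth = ref_model.replace(iiv_params=(), omega=np.zeros((0, 0)),
                              sigma_prop=0.0, sigma_add=1e-3)
    y = []
    for _ in range(3):
        f = _predict(truth, np.zeros(0), obs_times)
        y.append(f + rng.normal(0, 1e-3, f.shape))
    ds = _design_frame(3, obs_times, y)
    res = c.fit(ds, truth, fix=("sigma_prop", "sigma_add"), compute_rse=False)
    for p in ("CL", "Vc", "Vp", "Q"):
        assert res.model.theta[p] == pytest.approx(ref_model.theta[p], rel=0.01), p


def test_refit_is_a_fixed_point(small_cohort, small_fit):
    """Restarting the optimiser at the estimates moves the OFV by < 0.01."""
    dataset, _ = small_cohort
    again = c.fit(dataset, small_fit.model, method="bfgs", compute_rse=False)
    assert abs(again.ofv - small_fit.ofv) < 0.01


def test_perturbing_estimates_does_not_decrease_ofv(small_cohort, small_fit):
    dataset, _ = small_cohort
    for p, factor in (("CL", 1.15), ("Vc", 0.85)):
        worse = small_fit.model.replace(
            theta={**small_fit.model.theta,
                   p: small_fit.model.theta[p] * factor}
        )
        assert c.ofv(dataset, worse) >= small_fit.ofv - 1e-6


def test_shrinkage_definitions():
    """Total shrinkage when all EBEs collapse to zero; none when SD = omega."""
    etas = pd.DataFrame({"CL": np.zeros(8), "Vc": np.zeros(8)})
    model = c.reference_model()
    fr = c.FitResult(
        model=model, ofv=0.0, converged=True, message="", n_subjects=8,
        n_obs=40, etas=etas, iwres=np.ones(40),
    )
    shr, _ = c.shrinkage(fr)
    assert shr["CL"] == pytest.approx(100.0)
    spread = np.zeros(9)
    spread[:4], spread[5:] = 0.678, -0.678  # SD exactly omega_CL
    scale = 0.678 / np.std(spread, ddof=1)
    etas2 = pd.DataFrame({"CL": spread * scale, "Vc": np.zeros(9)})
    fr2 = c.FitResult(
        model=model, ofv=0.0, converged=True, message="", n_subjects=9,
        n_obs=45, etas=etas2, iwres=np.ones(45),
    )
    shr2, _ = c.shrinkage(fr2)
    assert shr2["CL"] == pytest.approx(0.0, abs=1e-9)


def test_clearance_shrinkage_small_for_rich_design(small_fit):
    """The sparse-but-informative template keeps CL shrinkage well below 20%."""
    assert small_fit.shrinkage_eta["CL"] < 20.0


def test_lrt_decision_thresholds():
    assert c.lrt_decision(3.84, "forward")
    assert not c.lrt_decision(3.83, "forward")
    assert not c.lrt_decision(10.83, "backward")  # strict inequality
    assert c.lrt_decision(10.84, "backward")
    assert not c.lrt_decision(0.0, "forward")
    assert not c.lrt_decision(0.0, "backward")
    with pytest.raises(ValueError):
        c.lrt_decision(float("nan"), "forward")
    with pytest.raises(ValueError):
        c.lrt_decision(1.0, "sideways")


def test_fit_requires_subjects_and_reports_metadata(small_cohort, small_fit):
    dataset, _ = small_cohort
    assert small_fit.n_subjects == dataset.n_subjects
    assert small_fit.n_obs == dataset.n_observations
    assert set(small_fit.etas.columns) == {"CL", "Vc"}
    single = PKDataset(dataset.frame[dataset.frame["ID"] == 1])
    with pytest.raises(ValueError):
        c.fit(single, c.reference_model())
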