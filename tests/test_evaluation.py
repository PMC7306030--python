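"""Bootstrap, VPC, NPDE and goodness-of-fit diagnostics."""

import numpy as np
import pandas as pd
import pytest

import cipropk as c


def test_bootstrap_reproducible_and_consistent(small_cohort, small_fit):
    dataset, _ = small_cohort
    one = c.bootstrap(dataset, small_fit.model, n_resamples=1, seed=4)
    two = c.bootstrap(dataset, small_fit.model, n_resamples=1, seed=4)
    assert one.estimates.equals(two.estimates)

    res = c.bootstrap(dataset, small_fit.model, n_resamples=20, seed=4)
    assert res.n_success + res.n_fail == 20
    assert not res.flagged
    # bootstrap median close to the point estimate (consistency)
    assert res.median["CL"] == pytest.approx(small_fit.model.theta["CL"], rel=0.15)
    assert (res.ci.loc["2.5%"] <= res.median).all()
    assert (res.median <= res.ci.loc["97.5%"]).all()


def test_bootstrap_of_identical_clones_degenerates(ref_model):
    """Every resample of a cohort of identical subjects is the same dataset,
    so the resampled estimates collapse onto a single point."""
    design = c.StudyDesign(group_sizes=(0, 1, 0))
    ds_one, _ = c.generate_cohort(design, c.reference_model(), seed=6)
    clones = ds_one.resample_subjects([1, 1, 1, 1])
    res = c.bootstrap(clones, ref_model, n_resamples=3, seed=0)
    assert res.n_success == 3
    spread = res.estimates.max() - res.estimates.min()
    assert float(spread.abs().max()) == pytest.approx(0.0, abs=1e-8)


def test_vpc_reproducible_and_ordered(small_cohort, ref_model):
    dataset, _ = small_cohort
    a = c.vpc(dataset, ref_model, n_sim=100, seed=9)
    b = c.vpc(dataset, ref_model, n_sim=100, seed=9)
    assert a.table.equals(b.table)
    t = a.table
    assert (t["obs_p5"] <= t["obs_median"]).all()
    assert (t["obs_median"] <= t["obs_p95"]).all()
    assert (t["sim_median_lo"] <= t["sim_median_hi"]).all()


def test_vpc_degenerate_noiseless_model():
    """A noise-free model reproducing constant observations yields zero-width
    simulated bands containing the observations."""
    truth = c.reference_model().replace(
        omega=np.zeros((2, 2)), sigma_prop=0.0, sigma_add=0.0
    )
    design = c.StudyDesign(group_sizes=(0, 4, 0))
    dataset, _ = c.generate_cohort(design, truth, seed=2)
    res = c.vpc(dataset, truth, n_sim=50, seed=1)
    t = res.table
    np.testing.assert_allclose(t["sim_median_lo"], t["sim_median_hi"], rtol=1e-12)
    np.testing.assert_allclose(t["obs_median"], t["sim_median_mid"], rtol=1e-9)


def test_npde_reproducible_and_near_null_under_truth(small_cohort, ref_model):
    dataset, _ = small_cohort
    a = c.npde(dataset, ref_model, n_sim=300, seed=5)
    b = c.npde(dataset, ref_model, n_sim=300, seed=5)
    assert a.table.equals(b.table)
    assert np.isfinite(a.table["npde"]).all()
    assert abs(a.mean) < 1.0  # generating model: roughly centred


def test_npde_zero_for_observation_at_simulated_median():
    """Noise-free observations evaluated under an additive-error model sit at
    the median of their simulated distribution, so NPDE ~ 0 (within the
    Monte-Carlo resolution of the empirical percentile)."""
    noiseless = c.reference_model().replace(
        omega=np.zeros((2, 2)), sigma_prop=0.0, sigma_add=0.0
    )
    design = c.StudyDesign(group_sizes=(0, 2, 0))
    dataset, _ = c.generate_cohort(design, noiseless, seed=3)
    model = noiseless.replace(sigma_add=0.1)
    res = c.npde(dataset, model, n_sim=1000, seed=8)
    np.testing.assert_allclose(res.table["npde"], 0.0, atol=0.15)


def test_npde_detects_gross_misspecification(small_cohort, ref_model):
    """Clearance 10x the truth shifts predictions far below the data."""
    dataset, _ = small_cohort
    wrong = ref_model.replace(theta={**ref_model.theta, "CL": 254.0})
    res = c.npde(dataset, wrong, n_sim=300, seed=5)
    assert abs(res.mean) > 1.0


def test_npde_requires_enough_replicates(small_cohort, ref_model):
    dataset, _ = small_cohort
    with pytest.raises(ValueError):
        c.npde(dataset, ref_model, n_sim=50, seed=1)


def test_gof_noiseless_residuals_vanish():
    truth = c.reference_model().replace(
        omega=np.zeros((2, 2)), sigma_prop=0.0, sigma_add=0.01
    )
    design = c.StudyDesign(group_sizes=(0, 3, 0))
    dataset, _ = c.generate_cohort(
        design, truth.replace(sigma_add=0.0), seed=4
    )
    etas = pd.DataFrame(
        np.zeros((3, 2)), index=pd.Index([1, 2, 3], name="ID"),
        columns=["CL", "Vc"],
    )
    fr = c.FitResult(
        model=truth, ofv=0.0, converged=True, message="", n_subjects=3,
        n_obs=dataset.n_observations, etas=etas, iwres=np.zeros(1),
    )
    table = c.gof(fr, dataset)
    np.testing.assert_allclose(table["CWRES"], 0.0, atol=1e-6)
    np.testing.assert_allclose(table["IWRES"], 0.0, atol=1e-6)
    # all etas zero: individual and population predictions coincide
    np.testing.assert_allclose(table["IPRED"], table["PRED"], rtol=1e-12)
    np.testing.assert_allclose(table["IPRED"], table["DV"], rtol=1e-9)


def test_gof_cwres_centred_under_truth(small_cohort, ref_model, small_fit):
    dataset, _ = small_cohort
    table = c.gof(small_fit, dataset)
    n = len(table)
    assert abs(table["CWRES"].mean()) < 3.0 / np.sqrt(n)
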