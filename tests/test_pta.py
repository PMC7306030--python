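"""Monte Carlo target attainment against the closed-form log-normal oracle."""

import numpy as np
import pytest
from scipy import stats

import cipropk as c
from cipropk.pta import FAUC_TARGET, FCMAX_TARGET


@pytest.fixture(scope="module")
def q12_regimen():
    return c.DosingRegimen(dose=400.0, interval=12.0, infusion_duration=1.0)


def test_closed_form_values(ref_model, q12_regimen):
    """Hand-evaluated points of Phi(log(fu*D24/(100*MIC)/CL_pop)/omega_CL)."""
    p = c.pta_closed_form(ref_model, q12_regimen, 0.5)
    expect = stats.norm.cdf(np.log((0.7 * 800 / 50) / 25.4) / 0.678)
    assert p == pytest.approx(expect, rel=1e-12)
    assert p == pytest.approx(0.114, abs=0.005)

    reg1200 = c.DosingRegimen(dose=400.0, interval=8.0, infusion_duration=1.0)
    p2 = c.pta_closed_form(ref_model, reg1200, 0.25)
    assert p2 == pytest.approx(stats.norm.cdf(np.log(33.6 / 25.4) / 0.678), rel=1e-12)
    assert p2 == pytest.approx(0.66, abs=0.01)


def test_closed_form_degenerate_and_breakpoint(ref_model, q12_regimen):
    det = ref_model.replace(omega=np.zeros((2, 2)))
    # breakpoint MIC: fu*D24/(100*MIC) = CL_pop  =>  MIC = 0.7*800/(100*25.4)
    mic_star = 0.7 * 800.0 / (100.0 * 25.4)
    assert c.pta_closed_form(det, q12_regimen, mic_star * 0.99) == 1.0
    assert c.pta_closed_form(det, q12_regimen, mic_star * 1.01) == 0.0
    assert c.pta_closed_form(ref_model, q12_regimen, mic_star) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        c.pta_closed_form(ref_model, q12_regimen, 0.5, target=FCMAX_TARGET)


def test_simulated_pta_matches_closed_form(ref_model, q12_regimen):
    """Monte Carlo PTA within 2 SE of the analytic value across the grid."""
    res = c.simulate_pta(ref_model, q12_regimen, n=5000, seed=17)
    exact = c.pta_closed_form(ref_model, q12_regimen, res.mic)
    se = np.sqrt(np.maximum(exact * (1 - exact), 1e-12) / res.n_virtual)
    assert np.all(np.abs(res.pta - exact) <= 2.0 * se + 1e-12)


def test_pta_invariants(ref_model, q12_regimen):
    res = c.simulate_pta(ref_model, q12_regimen, n=2000, seed=3)
    assert np.all(np.diff(res.pta) <= 0)  # non-increasing in MIC
    assert np.all((res.pta >= 0) & (res.pta <= 1))
    # nested bands
    assert np.all(res.ci99[0] <= res.ci95[0] + 1e-12)
    assert np.all(res.ci95[1] <= res.ci99[1] + 1e-12)
    again = c.simulate_pta(ref_model, q12_regimen, n=2000, seed=3)
    np.testing.assert_array_equal(res.pta, again.pta)
    # higher daily dose dominates
    q8 = c.DosingRegimen(dose=400.0, interval=8.0, infusion_duration=1.0)
    res8 = c.simulate_pta(ref_model, q8, n=2000, seed=3)
    assert np.all(res8.pta >= res.pta - 0.02)


def test_pta_degenerate_step_and_limits(ref_model, q12_regimen):
    det = ref_model.replace(omega=np.zeros((2, 2)))
    res = c.simulate_pta(det, q12_regimen, n=500, seed=1)
    assert set(np.unique(res.pta)) <= {0.0, 1.0}
    wide = c.simulate_pta(ref_model, q12_regimen,
                          mic_grid=(1e-6, 1e4), n=2000, seed=2)
    assert wide.pta[0] == pytest.approx(1.0, abs=1e-3)
    assert wide.pta[-1] == pytest.approx(0.0, abs=1e-3)


def test_fcmax_pta_uses_profile_maximum(ref_model, q12_regimen):
    """The fCmax metric equals the brute-force fine-grid maximum of the
    steady-state profile times fu, per virtual subject."""
    res = c.simulate_pta(ref_model, q12_regimen, target=FCMAX_TARGET,
                         n=400, seed=11)
    _, params = c.sample_individuals(ref_model, 400, seed=11)
    tgrid = np.linspace(0.0, 12.0, 1201)
    for row in params[:5]:
        p = c.PKParameters(*row)
        reg = c.DosingRegimen(dose=400.0, interval=12.0, infusion_duration=1.0,
                              steady_state=True)
        brute = 0.7 * np.max(c.concentration(p, reg, tgrid))
        m = c.steady_state_metrics(p, q12_regimen)
        assert m.fcmax == pytest.approx(brute, rel=1e-4)
    assert np.all(np.diff(res.pta) <= 0)


def test_observed_attainment_fractions():
    """26/42 and 34/42 attainment reproduce the published 61.9% and 81.0%."""
    fauc = [120.0] * 26 + [20.0] * 16  # vs threshold 100*MIC with MIC 0.25-ish
    frac, n = c.observed_attainment(fauc, mic=1.0, target=FAUC_TARGET)
    assert n == 26
    assert 100 * frac == pytest.approx(61.9, abs=0.05)
    cmax = [10.0] * 34 + [1.0] * 8
    frac2, n2 = c.observed_attainment(cmax, mic=1.0, target=FCMAX_TARGET)
    assert n2 == 34
    assert 100 * frac2 == pytest.approx(81.0, abs=0.05)
    # inclusive comparison at the exact threshold
    frac3, n3 = c.observed_attainment([100.0, 100.0], mic=1.0, target=FAUC_TARGET)
    assert frac3 == 1.0
    with pytest.raises(ValueError):
        c.observed_attainment([], mic=1.0)


def test_typical_attainment_curve(ref_model):
    """The typical-value curve attains the fAUC target at 1200 mg/day only
    for MICs below ~0.31 mg/L (fu*1200/(100*CL))."""
    reg = c.DosingRegimen(dose=400.0, interval=8.0, infusion_duration=1.0)
    table = c.typical_attainment(ref_model, reg)
    mic_star = 0.7 * 1200.0 / (100.0 * 25.4)
    for _, row in table.iterrows():
        assert row["attained"] == (row["MIC"] <= mic_star)
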