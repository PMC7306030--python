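"""Closed-form two-compartment infusion kinetics against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad, solve_ivp

import cipropk as c
from tests.conftest import random_params

# -- micro constants ---------------------------------------------------------


def test_micro_constants_match_rate_matrix_eigenvalues(typical_params):
    """alpha/beta are the negated eigenvalues of the 2x2 disposition matrix."""
    mc = c.micro_constants(typical_params)
    A = np.array(
        [[-(mc.k10 + mc.k12), mc.k21], [mc.k12, -mc.k21]]
    )
    lams = np.sort(-np.linalg.eigvals(A).real)  # [beta, alpha]
    assert mc.beta == pytest.approx(lams[0], rel=1e-10)
    assert mc.alpha == pytest.approx(lams[1], rel=1e-10)
    # frozen values for the published typical parameters
    assert mc.k10 == pytest.approx(0.2788, abs=5e-5)
    assert mc.k21 == pytest.approx(0.5604, abs=5e-5)
    assert mc.beta == pytest.approx(0.0888, abs=5e-5)
    assert mc.t_half_beta == pytest.approx(7.80, abs=5e-3)


@given(
    cl=st.floats(1.0, 80.0),
    vc=st.floats(5.0, 300.0),
    vp=st.floats(5.0, 500.0),
    q=st.floats(0.5, 300.0),
)
@settings(max_examples=50, deadline=None, derandomize=True)
def test_micro_constant_identities(cl, vc, vp, q):
    """alpha*beta = k10*k21 and alpha+beta = k10+k12+k21 for any valid params."""
    mc = c.micro_constants(c.PKParameters(cl, vc, vp, q))
    assert mc.alpha > mc.beta > 0
    assert mc.alpha * mc.beta == pytest.approx(mc.k10 * mc.k21, rel=1e-10)
    assert mc.alpha + mc.beta == pytest.approx(mc.k10 + mc.k12 + mc.k21, rel=1e-10)


def test_one_compartment_limit_as_q_vanishes():
    """With negligible inter-compartmental clearance the profile collapses to
    the one-compartment infusion solution with rate constant k10 = CL/Vc."""
    cl, vc = 25.4, 91.1
    p = c.PKParameters(cl, vc, 164.0, 1e-7)
    mc = c.micro_constants(p)
    k10 = cl / vc
    assert mc.alpha == pytest.approx(k10, rel=1e-6)
    reg = c.DosingRegimen(dose=400.0, interval=12.0, infusion_duration=1.0)
    t = np.array([0.5, 1.0, 2.0, 6.0, 12.0])
    rate = 400.0
    te = np.minimum(t, 1.0)
    one_cpt = rate / (k10 * vc) * (1 - np.exp(-k10 * te)) * np.exp(
        -k10 * (t - te)
    )
    np.testing.assert_allclose(c.concentration(p, reg, t), one_cpt, rtol=1e-4)


def test_invalid_parameters_rejected():
    with pytest.raises(ValueError):
        c.PKParameters(-1.0, 91.1, 164.0, 91.9)
    with pytest.raises(ValueError):
        c.PKParameters(25.4, 0.0, 164.0, 91.9)
    with pytest.raises(ValueError):
        c.DosingRegimen(dose=400, interval=8.0, infusion_duration=9.0)
    with pytest.raises(ValueError):
        c.DosingRegimen(dose=-1, interval=8.0)


# -- concentration profile ---------------------------------------------------


def _ode_concentration(params, regimen, times):
    """Numerical oracle: stiff ODE integration of the two-compartment system."""
    mc = c.micro_constants(params)
    rate = regimen.dose / regimen.infusion_duration

    def rhs(t, a):
        k = int(t // regimen.interval)
        infusing = (
            k < regimen.n_doses
            and (t - k * regimen.interval) <= regimen.infusion_duration
        )
        inp = rate if infusing else 0.0
        return [
            inp - (mc.k10 + mc.k12) * a[0] + mc.k21 * a[1],
            mc.k12 * a[0] - mc.k21 * a[1],
        ]

    switch = []
    for k in range(regimen.n_doses):
        switch += [k * regimen.interval, k * regimen.interval + regimen.infusion_duration]
    sol = solve_ivp(
        rhs, (0.0, float(np.max(times))), [0.0, 0.0], t_eval=times,
        rtol=1e-10, atol=1e-12, max_step=0.05, method="LSODA",
    )
    return sol.y[0] / params.vc


def test_closed_form_matches_ode_integration():
    """Closed form vs numerical ODE oracle to 1e-6 relative on random draws."""
    rng = np.random.default_rng(123)
    for _ in range(4):
        p = random_params(rng)
        reg = c.DosingRegimen(dose=400.0, interval=12.0,
                              infusion_duration=float(rng.uniform(0.5, 1.0)),
                              n_doses=3)
        t = np.linspace(0.25, 35.0, 40)
        closed = c.concentration(p, reg, t)
        ode = _ode_concentration(p, reg, t)
        np.testing.assert_allclose(closed, ode, rtol=1e-6)


def test_zero_dose_and_washout(typical_params):
    reg0 = c.DosingRegimen(dose=0.0, interval=12.0, infusion_duration=1.0)
    assert c.concentration(typical_params, reg0, 5.0) == 0.0
    reg = c.DosingRegimen(dose=400.0, interval=12.0, infusion_duration=1.0)
    assert c.concentration(typical_params, reg, 2000.0) < 1e-12
    with pytest.raises(ValueError):
        c.concentration(typical_params, reg, -1.0)


def test_superposition_of_shifted_single_doses(typical_params):
    """n-dose profile equals the sum of n time-shifted single-dose profiles."""
    t = np.linspace(0.0, 60.0, 121)
    single = c.DosingRegimen(dose=400.0, interval=12.0, infusion_duration=0.75)
    for n in (2, 3, 5):
        multi = c.DosingRegimen(dose=400.0, interval=12.0,
                                infusion_duration=0.75, n_doses=n)
        total = np.zeros_like(t)
        for k in range(n):
            shifted = np.clip(t - k * 12.0, 0.0, None)
            total += np.where(t >= k * 12.0,
                              c.concentration(typical_params, single, shifted), 0.0)
        np.testing.assert_allclose(
            c.concentration(typical_params, multi, t), total, rtol=1e-10, atol=1e-12
        )


def test_auc_conservation_single_dose():
    """Numerically integrated AUC(0-inf) equals dose/CL within 0.1%."""
    rng = np.random.default_rng(5)
    p = random_params(rng)
    reg = c.DosingRegimen(dose=400.0, interval=24.0, infusion_duration=1.0)
    auc, _ = quad(lambda t: c.concentration(p, reg, t), 0.0, 3000.0, limit=500)
    assert auc == pytest.approx(400.0 / p.cl, rel=1e-3)


def test_steady_state_periodicity_and_accumulation(typical_params):
    """Accumulation closed form equals brute-force superposition after many
    doses, and is periodic over the interval."""
    reg_ss = c.DosingRegimen(dose=400.0, interval=12.0, infusion_duration=1.0,
                             steady_state=True)
    t = np.linspace(0.0, 12.0, 25)
    ss = c.concentration(typical_params, reg_ss, t)
    # ~29 terminal half-lives of dosing
    n = 20
    reg_n = c.DosingRegimen(dose=400.0, interval=12.0, infusion_duration=1.0,
                            n_doses=n)
    brute = c.concentration(typical_params, reg_n, (n - 1) * 12.0 + t)
    np.testing.assert_allclose(ss, brute, rtol=1e-6)
    np.testing.assert_allclose(
        ss, c.concentration(typical_params, reg_ss, t + 12.0), rtol=1e-12
    )


# -- steady-state exposure metrics ------------------------------------------


def test_fauc_identity_and_fu_scaling(typical_params):
    """fAUC24 = fu * daily dose / CL for linear kinetics."""
    reg = c.DosingRegimen(dose=400.0, interval=12.0, infusion_duration=1.0)
    m = c.steady_state_metrics(typical_params, reg)
    assert m.fauc24 == pytest.approx(0.7 * 800.0 / 25.4, rel=1e-12)
    assert m.fauc24 == pytest.approx(22.05, abs=5e-3)
    m_unbound = c.steady_state_metrics(typical_params, reg, fu=1.0)
    assert m_unbound.fauc24 / m.fauc24 == pytest.approx(1.0 / 0.7, rel=1e-12)
    with pytest.raises(ValueError):
        c.steady_state_metrics(typical_params, reg, fu=1.5)
    with pytest.raises(ValueError):
        c.steady_state_metrics(typical_params, reg, fu=0.0)


def test_metrics_linear_in_dose(typical_params):
    reg1 = c.DosingRegimen(dose=400.0, interval=8.0, infusion_duration=0.5)
    reg2 = c.DosingRegimen(dose=800.0, interval=8.0, infusion_duration=0.5)
    m1 = c.steady_state_metrics(typical_params, reg1)
    m2 = c.steady_state_metrics(typical_params, reg2)
    assert m2.fauc24 == pytest.approx(2 * m1.fauc24, rel=1e-10)
    assert m2.fcmax == pytest.approx(2 * m1.fcmax, rel=1e-10)
    assert m2.fcmin == pytest.approx(2 * m1.fcmin, rel=1e-10)


def test_fcmax_is_profile_maximum(typical_params):
    """End-of-infusion value is the maximum of the steady-state profile."""
    reg = c.DosingRegimen(dose=400.0, interval=12.0, infusion_duration=0.5,
                          steady_state=True)
    fine = c.concentration(typical_params, reg, np.linspace(0.0, 12.0, 4801))
    m = c.steady_state_metrics(
        typical_params,
        c.DosingRegimen(dose=400.0, interval=12.0, infusion_duration=0.5),
    )
    assert m.fcmax == pytest.approx(0.7 * fine.max(), rel=1e-5)
    assert m.fcmin == pytest.approx(0.7 * fine[-1], rel=1e-10)
    assert m.fcmax >= m.fcmin >= 0.0
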