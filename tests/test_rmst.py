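import numpy as np
import pytest
from scipy import integrate

from conftest import mirrored
from rerandsurv import (ScenarioSpec, drmst_test, ipcw_adjusted_drmst, rmst,
                        simulate_trial, simulate_trials)

# Exact values for the (1e, 2c, 3e, 4c) arm at tau = 4, by hand integration
# of the product-limit curve: mu = 23/8, var = 93/256.
MU4 = 2.875
VAR4 = 0.36328125


def test_rmst_hand_integrated_fixture(four_subject_arm):
    est = rmst(four_subject_arm["time"], four_subject_arm["event"], tau=4.0)
    np.testing.assert_allclose(est.mu, MU4, rtol=1e-12)
    np.testing.assert_allclose(est.var, VAR4, rtol=1e-12)
    assert est.computable and not est.extended


def test_rmst_equals_restricted_mean_without_censoring(rng):
    y = rng.exponential(5.0, size=200)
    est = rmst(y, np.ones(200, dtype=int), tau=8.0)
    np.testing.assert_allclose(est.mu, np.minimum(y, 8.0).mean(), rtol=1e-12)


def test_rmst_flat_curve_when_no_events():
    est = rmst(np.array([9.0, 11.0]), np.array([0, 0]), tau=6.0)
    assert est.mu == 6.0 and est.var == 0.0 and not est.computable


def test_rmst_invariant_to_position_of_late_censoring(four_subject_arm):
    """Moving a censoring time around beyond the last event and beyond tau
    cannot change the restricted mean or its variance."""
    t, e = four_subject_arm["time"], four_subject_arm["event"]
    a = rmst(np.concatenate([t, [5.0]]), np.concatenate([e, [0]]), tau=4.0)
    b = rmst(np.concatenate([t, [12.0]]), np.concatenate([e, [0]]), tau=4.0)
    np.testing.assert_allclose(a.mu, b.mu, rtol=1e-12)
    np.testing.assert_allclose(a.var, b.var, rtol=1e-12)


def test_rmst_method2_extends_horizontally():
    # longest time censored before tau: curve held constant to tau
    est = rmst(np.array([1.0, 3.0]), np.array([1, 0]), tau=10.0)
    assert est.extended
    np.testing.assert_allclose(est.mu, 1.0 + 0.5 * 9.0, rtol=1e-12)


def test_drmst_zero_on_mirrored_data(six_subject_trial):
    res = drmst_test(mirrored(six_subject_trial), tau=4.0)
    assert res.z == pytest.approx(0.0, abs=1e-12)
    assert res.p == pytest.approx(0.5, abs=1e-12)


def test_drmst_sign_and_arm_swap(six_subject_trial):
    res = drmst_test(six_subject_trial, tau=4.0)
    swap = drmst_test(six_subject_trial.with_arm(1 - six_subject_trial.arm),
                      tau=4.0)
    np.testing.assert_allclose(res.z, -swap.z, rtol=1e-12)


def test_drmst_composed_from_arm_estimates(six_subject_trial):
    tr = six_subject_trial
    r1 = rmst(tr.time[tr.arm == 1], tr.event[tr.arm == 1], tau=4.0)
    r0 = rmst(tr.time[tr.arm == 0], tr.event[tr.arm == 0], tau=4.0)
    res = drmst_test(tr, tau=4.0)
    np.testing.assert_allclose(
        res.z, (r1.mu - r0.mu) / np.sqrt(r1.var + r0.var), rtol=1e-12)


def test_drmst_not_computable_without_events():
    from rerandsurv import TrialData
    tr = TrialData(z=np.zeros((4, 3), dtype=int), arm=np.array([1, 1, 0, 0]),
                   time=np.array([21.0, 22.0, 23.0, 24.0]),
                   event=np.zeros(4, dtype=int))
    res = drmst_test(tr, tau=30.0)
    assert not res.computable


def test_ipcw_reduces_to_mean_difference_without_censoring(rng):
    """All weights are one without censoring; with no covariates the arm
    coefficient is exactly the difference in restricted means."""
    from rerandsurv import TrialData
    n = 120
    arm = (rng.random(n) < 0.5).astype(int)
    y = rng.exponential(4.0 + 2.0 * arm)
    tr = TrialData(z=np.zeros((n, 3), dtype=int), arm=arm, time=y,
                   event=np.ones(n, dtype=int))
    tau = 6.0
    fit, res = ipcw_adjusted_drmst(tr, tau=tau, covariates=False)
    x = np.minimum(y, tau)
    np.testing.assert_allclose(fit.params[1],
                               x[arm == 1].mean() - x[arm == 0].mean(),
                               rtol=1e-10)
    assert np.allclose(fit.weights[fit.weights > 0], 1.0)


def test_ipcw_zero_on_mirrored_data(six_subject_trial):
    fit, res = ipcw_adjusted_drmst(mirrored(six_subject_trial), tau=4.0)
    assert res.z == pytest.approx(0.0, abs=1e-10)


def test_ipcw_consistent_for_true_restricted_mean_difference(rng):
    """Large-n check against the closed-form piecewise-exponential dRMST
    (numerical integration of the true survivor functions)."""
    spec = ScenarioSpec("slowdelay", lambda0=0.10, epsilon=5.0, hr1=1.0,
                        hr2=0.40, cov_hr=1.0)
    tau = 30.0

    def s1(t):
        r1, r2 = 0.10, 0.04
        return np.where(t < 5.0, np.exp(-r1 * t),
                        np.exp(-r1 * 5.0 - r2 * (t - 5.0)))

    def s0(t):
        return np.exp(-0.10 * t)

    true_diff = integrate.quad(lambda t: s1(t) - s0(t), 0, tau, limit=200)[0]
    tr = simulate_trial(spec, 20_000, rng)
    fit, res = ipcw_adjusted_drmst(tr, tau=tau)
    assert res.computable
    assert abs(fit.params[1] - true_diff) < 0.25
    # and the unadjusted test estimates the same quantity
    from rerandsurv.rmst_tests import rmst as rmst_fn
    r1 = rmst_fn(tr.time[tr.arm == 1], tr.event[tr.arm == 1], tau)
    r0 = rmst_fn(tr.time[tr.arm == 0], tr.event[tr.arm == 0], tau)
    assert abs((r1.mu - r0.mu) - true_diff) < 0.25


def test_adjusted_and_unadjusted_agree_without_censoring_or_covariates(rng):
    """Same estimand, different variance estimators: Z's agree in sign and
    roughly in magnitude on a sizeable uncensored trial."""
    from rerandsurv import TrialData
    n = 400
    arm = (rng.random(n) < 0.5).astype(int)
    y = rng.exponential(6.0 + 3.0 * arm)
    tr = TrialData(z=np.zeros((n, 3), dtype=int), arm=arm, time=y,
                   event=np.ones(n, dtype=int))
    plain = drmst_test(tr, tau=10.0)
    fit, adj = ipcw_adjusted_drmst(tr, tau=10.0, covariates=False)
    assert np.sign(plain.z) == np.sign(adj.z)
    assert abs(plain.z - adj.z) / abs(plain.z) < 0.10
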