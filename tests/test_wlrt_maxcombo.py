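import numpy as np
import pytest
from scipy import stats

from conftest import mirrored
from rerandsurv import (DEFAULT_WEIGHTS, get_scenario, logrank, maxcombo,
                        simulate_trial, simulate_trials, wlrt,
                        wlrt_covariance)
from rerandsurv.wlrt_maxcombo import (WeightSpec, _mvn_cdf_equal,
                                      maxcombo_z_batch, wlrt_batch)

# Exact values for the six-subject fixture, from risk-set enumeration with
# rational arithmetic: U00 = -17/30, V00 = 1091/900, U01 = -2/5,
# V01 = 181/900, Cov(U00, U01) = 361/900.
Z00 = 0.5146791156801717
Z01 = 0.8919529754965997
V00 = 1091 / 900
V01 = 181 / 900
COV01 = 361 / 900
CORR01 = COV01 / np.sqrt(V00 * V01)


def test_logrank_on_hand_enumerated_fixture(six_subject_trial):
    res = wlrt(six_subject_trial, (0, 0))
    assert res.computable
    np.testing.assert_allclose(res.u, -17 / 30, rtol=1e-12)
    np.testing.assert_allclose(res.v, V00, rtol=1e-12)
    np.testing.assert_allclose(res.z, Z00, rtol=1e-12)


def test_late_weighted_statistic_on_fixture(six_subject_trial):
    res = wlrt(six_subject_trial, (0, 1))
    np.testing.assert_allclose(res.u, -2 / 5, rtol=1e-12)
    np.testing.assert_allclose(res.v, V01, rtol=1e-12)
    np.testing.assert_allclose(res.z, Z01, rtol=1e-12)


def test_covariance_term_by_term_oracle(six_subject_trial):
    cov, corr = wlrt_covariance(six_subject_trial, [(0, 0), (0, 1)])
    np.testing.assert_allclose(cov[0, 0], V00, rtol=1e-12)
    np.testing.assert_allclose(cov[1, 1], V01, rtol=1e-12)
    np.testing.assert_allclose(cov[0, 1], COV01, rtol=1e-12)
    np.testing.assert_allclose(corr[0, 1], CORR01, rtol=1e-12)


def test_duplicate_weights_are_perfectly_correlated(six_subject_trial):
    _, corr = wlrt_covariance(six_subject_trial, [(0, 0), (0, 0)])
    np.testing.assert_allclose(corr, np.ones((2, 2)), rtol=1e-12)


def test_mirrored_data_has_zero_score(six_subject_trial):
    res = logrank(mirrored(six_subject_trial))
    assert res.u == pytest.approx(0.0, abs=1e-12)
    assert res.z == pytest.approx(0.0, abs=1e-12)


def test_arm_swap_negates_z(six_subject_trial):
    swapped = six_subject_trial.with_arm(1 - six_subject_trial.arm)
    for w in DEFAULT_WEIGHTS:
        a = wlrt(six_subject_trial, w)
        b = wlrt(swapped, w)
        np.testing.assert_allclose(a.z, -b.z, rtol=1e-12)


def test_single_allinclusive_stratum_equals_unstratified(rng):
    tr = simulate_trial(get_scenario("delayed"), 80, rng)
    plain = wlrt(tr, (1, 1))
    strat = wlrt(tr, (1, 1), strata=np.zeros(tr.n, dtype=int))
    assert plain.u == strat.u and plain.v == strat.v and plain.z == strat.z


def test_logrank_matches_lifelines(rng):
    lifelines = pytest.importorskip("lifelines")
    from lifelines.statistics import logrank_test
    tr = simulate_trial(get_scenario("PH"), 120, rng)
    res = logrank(tr)
    ll = logrank_test(tr.time[tr.arm == 1], tr.time[tr.arm == 0],
                      tr.event[tr.arm == 1], tr.event[tr.arm == 0])
    np.testing.assert_allclose(res.z ** 2, ll.test_statistic, rtol=1e-10)


def test_weight_spec_validation():
    with pytest.raises(ValueError):
        WeightSpec(-1, 0)


def test_batch_matches_per_column_evaluation(rng):
    tr = simulate_trial(get_scenario("crossing"), 60, rng)
    arm_matrix = (rng.random((60, 8)) < 0.5).astype(int)
    z, _, _ = wlrt_batch(tr, arm_matrix, DEFAULT_WEIGHTS, strata="factors")
    for m in range(8):
        trm = tr.with_arm(arm_matrix[:, m])
        for k, w in enumerate(DEFAULT_WEIGHTS):
            single = wlrt(trm, w, strata="factors")
            if single.computable:
                np.testing.assert_allclose(z[k, m], single.z, rtol=1e-10)
            else:
                assert np.isnan(z[k, m])
    zmax = maxcombo_z_batch(tr, arm_matrix, DEFAULT_WEIGHTS, "factors")
    np.testing.assert_allclose(zmax, np.nanmax(z, axis=0), rtol=1e-12)


def test_maxcombo_single_weight_reduces_to_normal_tail(six_subject_trial):
    mc = maxcombo(six_subject_trial, weights=[(0, 0)])
    np.testing.assert_allclose(mc.p, stats.norm.sf(Z00), atol=2e-4)


def test_maxcombo_p_decreasing_in_zmax():
    corr = np.eye(4) * 0.2 + 0.8
    ps = [1 - _mvn_cdf_equal(z, corr) for z in (0.5, 1.0, 1.5, 2.0)]
    assert all(a > b for a, b in zip(ps, ps[1:]))


def test_mvn_tail_matches_monte_carlo(six_subject_trial):
    mc = maxcombo(six_subject_trial)
    rng = np.random.default_rng(123)
    draws = rng.multivariate_normal(np.zeros(4), mc.correlation,
                                    size=1_000_000)
    p_mc = 1.0 - (draws <= mc.z_max).all(axis=1).mean()
    se = np.sqrt(p_mc * (1 - p_mc) / 1_000_000)
    assert abs(mc.p - p_mc) < 3 * se


def test_logrank_z_is_standard_normal_under_simple_randomised_null(rng):
    """With simple 1:1 assignment, exchangeable exponential outcomes and no
    covariate effect, the log-rank Z should be N(0,1)."""
    from rerandsurv import ScenarioSpec, TrialData
    n, reps = 300, 1200
    zs = np.empty(reps)
    for r in range(reps):
        arm = (rng.random(n) < 0.5).astype(int)
        y = rng.exponential(10.0, size=n)
        c = rng.uniform(20, 40, size=n)
        tr = TrialData(z=np.zeros((n, 3), dtype=int), arm=arm,
                       time=np.minimum(y, c), event=(y <= c).astype(int))
        zs[r] = logrank(tr).z
    assert stats.kstest(zs, "norm").pvalue > 0.001
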