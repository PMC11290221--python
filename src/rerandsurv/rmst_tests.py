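"""Restricted mean survival time (RMST) tests.

The RMST up to horizon tau is mu(tau) = integral_0^tau S(t) dt, the mean
survival time over the first tau months; the difference dRMST =
mu_exp - mu_con is interpretable without proportional hazards.  When the
longest observed time in an arm is censored before tau, the Kaplan-Meier
curve is extended horizontally to tau before integrating (Horiguchi's
"Method 2"), applied to observed data and re-randomised replicates alike.
The test is non-computable only when no events occur in either arm by tau
(both variances vanish, so no standard error exists).

The covariate-adjusted variant regresses the tau-restricted time
min(T, tau) on (1, arm, z1, z2, z3) by inverse-probability-of-censoring
weighted (IPCW) least squares: subjects known to survive their restricted
time (event by tau, or followed beyond tau) get weight 1/G_arm(X-), where
G_arm is the per-arm reverse Kaplan-Meier censoring-survivor curve, and
the treatment coefficient is tested with a sandwich (robust) variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
import statsmodels.api as sm

from .datagen import TrialData
from .km_core import km
from .results import TestResult

DEFAULT_TAU = 30.0


@dataclass(frozen=True)
class RMSTEstimate:
    """Area under the KM curve on [0, tau] with its large-sample variance.

    ``extended`` flags that the curve was held constant beyond the last
    observed time to reach tau.  ``n_events`` = 0 means the curve never
    drops: mu = tau with zero variance (flagged non-computable on its own,
    though the two-arm test may still be).
    """

    tau: float
    mu: float
    var: float
    n_events: int
    extended: bool

    @property
    def computable(self) -> bool:
        return self.n_events > 0


def rmst(time, event, tau: float = DEFAULT_TAU) -> RMSTEstimate:
    """RMST of one arm: KM area on [0, tau], horizontally extended.

    Variance: sum over event times t_j <= tau of
    A_j^2 d_j / (n_j (n_j - d_j)) with A_j = integral_{t_j}^{tau} S(t) dt;
    terms with n_j = d_j (curve hits zero) are dropped.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    curve = km(time, event)
    extended = bool(len(time)) and float(time.max()) < tau
    if len(curve.time) == 0:
        return RMSTEstimate(tau, tau, 0.0, 0, extended)
    tj = curve.time[curve.time <= tau]
    J = len(tj)
    surv = curve.surv[:J]
    # segment boundaries: 0, t_1, ..., t_J, tau ; S is 1 before t_1
    knots = np.concatenate(([0.0], tj, [tau]))
    heights = np.concatenate(([1.0], surv))
    widths = np.diff(knots)
    mu = float(np.sum(heights * widths))
    # A_j = integral from t_j to tau = cumulative segment areas from the right
    seg = heights[1:] * widths[1:]                    # area on [t_j, t_{j+1})
    a = np.cumsum(seg[::-1])[::-1]
    d = curve.n_events[:J].astype(float)
    n = curve.n_at_risk[:J].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = a ** 2 * d / (n * (n - d))
    var = float(np.sum(np.where(n > d, terms, 0.0)))
    return RMSTEstimate(tau, mu, var, int(d.sum()), extended)


def drmst_test(trial: TrialData, tau: float = DEFAULT_TAU) -> TestResult:
    """Unadjusted dRMST Z test: Z = (mu_exp - mu_con)/sqrt(v_exp + v_con).

    Oriented so positive Z favours the experimental arm; one-sided upper
    normal tail.  Non-computable when no events occur in either arm.
    """
    exp_mask = np.asarray(trial.arm) == 1
    r1 = rmst(trial.time[exp_mask], trial.event[exp_mask], tau)
    r0 = rmst(trial.time[~exp_mask], trial.event[~exp_mask], tau)
    vtot = r1.var + r0.var
    if vtot <= 0:
        return TestResult.not_computable(
            "drmst", "no events in either arm by tau: SE not estimable")
    z = (r1.mu - r0.mu) / np.sqrt(vtot)
    return TestResult(method="drmst", z=float(z), p=float(stats.norm.sf(z)))


@dataclass
class IPCWFit:
    """IPCW least-squares fit of the tau-restricted time.

    ``params`` ordered (intercept, arm, z1, z2, z3, ...); ``cov`` is the
    sandwich variance; ``z_treatment`` tests the arm coefficient.
    """

    params: np.ndarray
    cov: np.ndarray
    names: list
    z_treatment: float
    weights: np.ndarray


def ipcw_adjusted_drmst(trial: TrialData, tau: float = DEFAULT_TAU,
                        covariates: bool = True):
    """Covariate-adjusted dRMST via IPCW linear regression.

    Returns ``(IPCWFit | None, TestResult)``.  Weights are
    delta_i(tau) / G_arm(X_i-) with X_i = min(T_i, tau) and delta_i(tau)
    indicating the restricted time is fully observed.  Sandwich variance;
    Z = beta_arm / SE, positive favouring experimental.
    """
    time = np.asarray(trial.time, dtype=float)
    event = np.asarray(trial.event)
    arm = np.asarray(trial.arm)
    if not ((event[arm == 1] == 1).any() or (event[arm == 0] == 1).any()):
        return None, TestResult.not_computable(
            "drmst_adj", "no events in either arm")
    x_restricted = np.minimum(time, tau)
    delta = ((event == 1) & (time <= tau)) | (time > tau)
    w = np.zeros(len(time))
    for a in (0, 1):
        m = arm == a
        g = km(time[m], event[m], reverse=True)
        gx = g.eval_left(x_restricted[m])
        need = delta[m]
        if (gx[need] <= 0).any():
            return None, TestResult.not_computable(
                "drmst_adj", "censoring survivor estimate is zero at a "
                             "weighted time")
        wm = np.zeros(m.sum())
        wm[need] = 1.0 / gx[need]
        w[m] = wm
    cols = [np.ones(len(time)), arm.astype(float)]
    names = ["intercept", "arm"]
    if covariates:
        for k in range(trial.z.shape[1]):
            cols.append(trial.z[:, k].astype(float))
            names.append(f"z{k + 1}")
    design = np.column_stack(cols)
    keep = w > 0
    if keep.sum() <= design.shape[1]:
        return None, TestResult.not_computable(
            "drmst_adj", "too few fully observed restricted times")
    fit = sm.WLS(x_restricted[keep], design[keep], weights=w[keep]) \
            .fit(cov_type="HC0")
    beta = np.asarray(fit.params)
    cov = np.asarray(fit.cov_params())
    se = np.sqrt(cov[1, 1])
    if not np.isfinite(se) or se <= 0:
        return None, TestResult.not_computable("drmst_adj", "degenerate SE")
    z = beta[1] / se
    res = TestResult(method="drmst_adj", z=float(z), p=float(stats.norm.sf(z)))
    return IPCWFit(beta, cov, names, float(z), w), res
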