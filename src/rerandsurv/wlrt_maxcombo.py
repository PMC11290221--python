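"""Fleming-Harrington weighted log-rank tests and the MaxCombo test.

The G^{rho,gamma} weighted log-rank statistic over pooled distinct event
times t_j uses weights w_j = S(t_j-)^rho (1 - S(t_j-))^gamma from the
left-continuous pooled Kaplan-Meier curve:

    U = sum_j w_j (d_1j - n_1j d_j / n_j)
    V = sum_j w_j^2 n_1j n_0j d_j (n_j - d_j) / (n_j^2 (n_j - 1))

with the j-term dropped when n_j = 1.  The oriented statistic is
Z = -U / sqrt(V): fewer experimental-arm events than expected gives
Z > 0, so large positive Z supports experimental-arm superiority.
(rho, gamma) = (0,0) is the standard log-rank; (1,0) stresses early,
(0,1) late and (1,1) mid-study differences.

Stratified versions sum U and V over strata (by default the full
z1 x z2 x z3 cross-classification), each stratum using its own risk table
and its own within-stratum pooled Kaplan-Meier for the weights.

The MaxCombo statistic is the maximum of the oriented component Z's; its
asymptotic one-sided p-value is 1 - P(N(0, R) <= z_max * 1) with R the
estimated correlation matrix of the components, integrated numerically.

Batch evaluation
----------------
For fixed outcomes and covariates, U is *linear* in the assignment vector
(d_1j and n_1j are inner products of per-time indicator rows with the arm
vector), and V needs only the per-time experimental at-risk counts.  The
re-randomisation engine exploits this: all M regenerated statistics are a
handful of matrix products against the (n x M) assignment matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datagen import TrialData
from .km_core import risk_table, km
from .results import MaxComboResult

#: MaxCombo component weights used throughout the study.
DEFAULT_WEIGHTS = ((0, 0), (1, 0), (1, 1), (0, 1))


@dataclass(frozen=True)
class WeightSpec:
    """Fleming-Harrington exponents (rho for S, fh_gamma for 1-S)."""

    rho: float
    fh_gamma: float

    def __post_init__(self):
        if self.rho < 0 or self.fh_gamma < 0:
            raise ValueError("FH exponents must be non-negative")


def _as_weights(weights) -> list[WeightSpec]:
    return [w if isinstance(w, WeightSpec) else WeightSpec(*w) for w in weights]


class _StratumTerms:
    """Arm-independent per-stratum quantities for batch WLRT evaluation.

    For stratum members (index array ``idx``) and distinct event times j:
    ``atrisk``/``ev`` are (J, m) indicator matrices, ``w`` the (K, J) FH
    weight rows, ``vconst`` = d(n-d)/(n^2(n-1)) (0 where n = 1) and
    ``coef_u`` the (K, m) per-patient coefficients with
    U_k = coef_u[k] . arm[idx] for any assignment vector.
    """

    def __init__(self, time, event, idx, wspecs):
        self.idx = idx
        t, e = time[idx], event[idx]
        rt = risk_table(t, e, np.zeros_like(e))
        self.J = len(rt)
        if self.J == 0:
            return
        curve = km(t, e)
        sprev = curve.surv_prev
        self.w = np.vstack([
            sprev ** ws.rho * (1.0 - sprev) ** ws.fh_gamma for ws in wspecs
        ])                                               # (K, J)
        self.d, self.n = rt.d.astype(float), rt.n.astype(float)
        self.atrisk = (t[None, :] >= rt.time[:, None]).astype(float)   # (J, m)
        self.ev = ((e == 1)[None, :]
                   & (t[None, :] == rt.time[:, None])).astype(float)    # (J, m)
        with np.errstate(divide="ignore", invalid="ignore"):
            vc = self.d * (self.n - self.d) / (self.n ** 2 * (self.n - 1.0))
        self.vconst = np.where(self.n > 1, vc, 0.0)
        centred = self.ev - (self.d / self.n)[:, None] * self.atrisk
        self.coef_u = self.w @ centred                               # (K, m)

    def accumulate(self, arm_matrix, u_acc, v_acc, vterms=None):
        """Add this stratum's U, V contributions for each assignment column.

        ``arm_matrix`` is (n, M); ``u_acc``/``v_acc`` are (K, M) running
        sums.  When ``vterms`` is a list, the per-time variance terms for
        the (single-column) observed assignment are appended for
        covariance computation.
        """
        if self.J == 0:
            return
        a = arm_matrix[self.idx, :]                       # (m, M)
        u_acc += self.coef_u @ a
        n1 = self.atrisk @ a                              # (J, M)
        vt = self.vconst[:, None] * n1 * (self.n[:, None] - n1)
        v_acc += (self.w ** 2) @ vt
        if vterms is not None:
            vterms.append((self.w, vt[:, 0]))


def _prepare(trial: TrialData, weights, strata):
    """Build per-stratum terms.  ``strata=None`` pools everything;
    ``strata='factors'`` uses the z1 x z2 x z3 cross-classification; an
    array of labels defines custom strata."""
    wspecs = _as_weights(weights)
    time = np.asarray(trial.time, dtype=float)
    event = np.asarray(trial.event)
    if strata is None:
        groups = [np.arange(trial.n)]
    else:
        labels = trial.stratum_ids() if isinstance(strata, str) and strata == "factors" \
            else np.asarray(strata)
        groups = [np.flatnonzero(labels == g) for g in np.unique(labels)]
    terms = [_StratumTerms(time, event, idx, wspecs) for idx in groups]
    return wspecs, [t for t in terms if t.J > 0]


def wlrt_batch(trial: TrialData, arm_matrix: np.ndarray,
               weights=DEFAULT_WEIGHTS, strata=None):
    """Oriented Z for every weight (rows) and assignment column.

    Returns ``(z, u, v)`` each of shape (K, M); entries with V <= 0 are
    NaN in ``z`` (non-computable).
    """
    wspecs, terms = _prepare(trial, weights, strata)
    arm_matrix = np.asarray(arm_matrix, dtype=float)
    if arm_matrix.ndim == 1:
        arm_matrix = arm_matrix[:, None]
    K, M = len(wspecs), arm_matrix.shape[1]
    u = np.zeros((K, M))
    v = np.zeros((K, M))
    for t in terms:
        t.accumulate(arm_matrix, u, v)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(v > 0, -u / np.sqrt(v), np.nan)
    return z, u, v


@dataclass(frozen=True)
class WLRTResult:
    """Score U, variance V and oriented Z for one FH weight."""

    method: str
    u: float
    v: float
    z: float
    p: float
    computable: bool = True
    detail: str = ""

    def reject(self, alpha: float = 0.025) -> bool:
        return bool(self.computable and self.p <= alpha)


def wlrt(trial: TrialData, weight=(0, 0), strata=None) -> WLRTResult:
    """One Fleming-Harrington weighted log-rank test (one-sided).

    ``weight=(0,0)`` is the standard log-rank; ``strata='factors'`` gives
    the stratified version over the z1 x z2 x z3 cells.
    """
    z, u, v = wlrt_batch(trial, trial.arm, [weight], strata)
    ws = _as_weights([weight])[0]
    label = f"wlrt({ws.rho:g},{ws.fh_gamma:g})" + ("_strat" if strata is not None else "")
    if not np.isfinite(z[0, 0]):
        return WLRTResult(label, float(u[0, 0]), float(v[0, 0]),
                          float("nan"), float("nan"), computable=False,
                          detail="zero variance (no usable events)")
    zval = float(z[0, 0])
    return WLRTResult(label, float(u[0, 0]), float(v[0, 0]),
                      zval, float(stats.norm.sf(zval)))


def logrank(trial: TrialData, strata=None) -> WLRTResult:
    """Standard (or stratified) log-rank test: FH weight (0, 0)."""
    return wlrt(trial, (0, 0), strata)


def wlrt_covariance(trial: TrialData, weights=DEFAULT_WEIGHTS, strata=None):
    """Covariance and correlation of the component scores U_k.

    Cov(U_k, U_l) = sum_j w_kj w_lj V_j with the per-time hypergeometric
    variance terms V_j, summed over strata; the diagonal reproduces each
    component's V.
    """
    wspecs, terms = _prepare(trial, weights, strata)
    K = len(wspecs)
    arm = np.asarray(trial.arm, dtype=float)[:, None]
    cov = np.zeros((K, K))
    u = np.zeros((K, 1))
    v = np.zeros((K, 1))
    vterms = []
    for t in terms:
        t.accumulate(arm, u, v, vterms)
    for w, vt in vterms:
        cov += (w * vt[None, :]) @ w.T
    sd = np.sqrt(np.diag(cov))
    if (sd <= 0).any():
        return cov, None
    corr = cov / np.outer(sd, sd)
    np.fill_diagonal(corr, 1.0)
    return cov, corr


class _SobolCache:
    """Scrambled Sobol point sets shared by every MVN integration call.

    The points are fixed at import (deterministic scrambling seeds), so
    p-values are reproducible; 8 independent scramblings give a spread
    from which the integration error is estimated.
    """

    def __init__(self, dim: int = 3, n_batches: int = 4):
        self.n_batches = n_batches
        self._sets = {}
        self.dim = dim

    def get(self, log2_n: int) -> np.ndarray:
        key = log2_n
        if key not in self._sets:
            from scipy.stats import qmc
            batches = [
                qmc.Sobol(d=self.dim, scramble=True, seed=1000 + b)
                .random_base2(log2_n)
                for b in range(self.n_batches)
            ]
            self._sets[key] = np.stack(batches)      # (B, N, dim)
        return self._sets[key]


_SOBOL = _SobolCache()
_MVN_TOL = 2e-5


def _mvn_cdf_equal(b: float, corr: np.ndarray, tol: float = _MVN_TOL) -> float:
    """P(Z_1 <= b, ..., Z_K <= b) for Z ~ N(0, corr).

    Genz sequential-conditioning transform integrated by scrambled-Sobol
    quasi-Monte-Carlo; the point count escalates until the spread of the
    independent scramblings is below ``tol`` (capped at 2^15 points per
    batch, where the verified absolute error is below 1e-6).
    """
    from scipy.special import ndtr, ndtri
    K = corr.shape[0]
    evals = np.linalg.eigvalsh(corr)
    if evals.min() < 1e-9:   # numerically singular (e.g. duplicated weights)
        corr = (corr + 1e-8 * np.eye(K)) / (1.0 + 1e-8)
    L = np.linalg.cholesky(corr)
    tiny = 1e-15
    for log2_n in (13, 15):
        pts = _SOBOL.get(log2_n)                     # (B, N, K-1)
        f = np.full(pts.shape[:2], ndtr(b / L[0, 0]))
        y = np.empty(pts.shape[:2] + (K - 1,))
        e_prev = f.copy()
        for k in range(1, K):
            y[..., k - 1] = ndtri(np.clip(pts[..., k - 1] * e_prev,
                                          tiny, 1 - tiny))
            num = b - np.einsum("j,bnj->bn", L[k, :k], y[..., :k])
            e_prev = ndtr(num / L[k, k])
            f *= e_prev
        batch_means = f.mean(axis=1)
        err = batch_means.std(ddof=1) / np.sqrt(len(batch_means))
        if err < tol:
            break
    return float(batch_means.mean())


def _mvn_max_sf(z_max: float, corr: np.ndarray) -> float:
    """P(max_k Z_k >= z_max) for Z ~ N(0, corr), by numerical integration."""
    cdf = _mvn_cdf_equal(z_max, corr)
    return float(min(max(1.0 - cdf, 0.0), 1.0))


def maxcombo(trial: TrialData, weights=DEFAULT_WEIGHTS,
             strata=None) -> MaxComboResult:
    """MaxCombo test: maximum of the oriented component Z's with an
    asymptotic multivariate-normal one-sided p-value."""
    wspecs = _as_weights(weights)
    z, u, v = wlrt_batch(trial, trial.arm, wspecs, strata)
    zc = z[:, 0]
    label_weights = tuple((w.rho, w.fh_gamma) for w in wspecs)
    if not np.isfinite(zc).all():
        return MaxComboResult(label_weights, zc, np.eye(len(wspecs)),
                              float("nan"), float("nan"),
                              computable=False,
                              detail="a component has zero variance")
    _, corr = wlrt_covariance(trial, wspecs, strata)
    if corr is None:
        return MaxComboResult(label_weights, zc, np.eye(len(wspecs)),
                              float("nan"), float("nan"),
                              computable=False,
                              detail="zero-variance component in covariance")
    z_max = float(zc.max())
    p = _mvn_max_sf(z_max, corr)
    return MaxComboResult(label_weights, zc, corr, z_max, p, p_source="mvn")


def maxcombo_z_batch(trial: TrialData, arm_matrix: np.ndarray,
                     weights=DEFAULT_WEIGHTS, strata=None) -> np.ndarray:
    """MaxCombo statistic z_max for each assignment column (NaN where any
    component is non-computable) — the re-randomisation fast path."""
    z, _, _ = wlrt_batch(trial, arm_matrix, weights, strata)
    return np.where(np.isfinite(z).all(axis=0), z.max(axis=0), np.nan)
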