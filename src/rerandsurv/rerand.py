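"""Re-randomisation (randomisation-based) tests.

The null distribution of any oriented statistic S is approximated by
regenerating the minimisation assignment sequence M times with outcomes,
covariates and entry order held fixed, recomputing S on each regenerated
dataset, and reporting

    p = sum_m I(S_m >= S_obs) / D

over the D computable replicates (no +1 continuity correction, so p = 0
is attainable; regenerated sequences may repeat and are not deduplicated).

Weighted log-rank family statistics (log-rank, individual FH weights,
MaxCombo, and their stratified versions) are evaluated for all M
assignment columns at once through the linear-algebra fast path in
:mod:`rerandsurv.wlrt_maxcombo`; Cox- and RMST-based statistics fall back
to a per-replicate loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import cox_tests, rmst_tests, wlrt_maxcombo
from .datagen import TrialData
from .randomisation import regenerate_assignments_batch
from .results import RerandResult

DEFAULT_M = 1000


@dataclass(frozen=True)
class RerandConfig:
    """Re-randomisation settings: replication count, master seed, statistic."""

    statistic: str
    m: int = DEFAULT_M
    seed: int = 0
    prob_preferred: float = 0.7

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("M must be >= 1")


def _stat_drmst(trial):
    return rmst_tests.drmst_test(trial)


def _stat_drmst_adj(trial):
    return rmst_tests.ipcw_adjusted_drmst(trial)[1]


def _stat_cox(trial):
    return cox_tests.cox_wald(trial, adjust=False)[1]


def _stat_cox_adj(trial):
    return cox_tests.cox_wald(trial, adjust=True)[1]


#: statistics with a vectorised assignment-matrix path: label -> (weights, strata)
_WLRT_FAMILY = {
    "lrt": ([(0, 0)], None),
    "lrt_strat": ([(0, 0)], "factors"),
    "wlrt_1_0": ([(1, 0)], None),
    "wlrt_1_1": ([(1, 1)], None),
    "wlrt_0_1": ([(0, 1)], None),
    "maxcombo": (wlrt_maxcombo.DEFAULT_WEIGHTS, None),
    "maxcombo_strat": (wlrt_maxcombo.DEFAULT_WEIGHTS, "factors"),
}

#: statistics needing a per-replicate refit
_GENERIC = {
    "cox": _stat_cox,
    "cox_adj": _stat_cox_adj,
    "drmst": _stat_drmst,
    "drmst_adj": _stat_drmst_adj,
}

STATISTICS = tuple(_WLRT_FAMILY) + tuple(_GENERIC)


def _wlrt_family_values(trial, arm_matrix, label):
    weights, strata = _WLRT_FAMILY[label]
    z = wlrt_maxcombo.maxcombo_z_batch(trial, arm_matrix, weights, strata)
    return z


def rerand_statistics(trial: TrialData, label: str,
                      arm_matrix: np.ndarray) -> np.ndarray:
    """Oriented statistic evaluated at each assignment column (NaN where a
    replicate is non-computable)."""
    if label in _WLRT_FAMILY:
        return _wlrt_family_values(trial, arm_matrix, label)
    if label not in _GENERIC:
        raise KeyError(f"unknown statistic {label!r}; known: {STATISTICS}")
    fn = _GENERIC[label]
    out = np.empty(arm_matrix.shape[1])
    for m in range(arm_matrix.shape[1]):
        res = fn(trial.with_arm(arm_matrix[:, m]))
        out[m] = res.z if res.computable else np.nan
    return out


def rerand_test(trial: TrialData, statistic: str, m: int = DEFAULT_M,
                rng: np.random.Generator | int | None = None,
                prob_preferred: float = 0.7,
                arm_matrix: np.ndarray | None = None) -> RerandResult:
    """Re-randomisation test of the named oriented statistic.

    Parameters
    ----------
    statistic : one of :data:`STATISTICS`.
    m : number of regenerated assignment sequences.
    rng : Generator or master seed; identical seeds give bit-identical
        results.
    arm_matrix : optional pre-drawn (n, M) assignment matrix, letting
        several statistics share one reference set.
    """
    rng = np.random.default_rng(rng)
    obs = rerand_statistics(trial, statistic, np.asarray(trial.arm)[:, None])[0]
    method = f"rerand_{statistic}"
    if not np.isfinite(obs):
        return RerandResult(method, float("nan"), np.empty(0), float("nan"),
                            computable=False,
                            detail="statistic not computable on observed data")
    if arm_matrix is None:
        arm_matrix = regenerate_assignments_batch(
            trial.z, prob_preferred, m, rng)
    s = rerand_statistics(trial, statistic, arm_matrix)
    ok = np.isfinite(s)
    n_bad = int((~ok).sum())
    if ok.sum() == 0:
        return RerandResult(method, float(obs), s, float("nan"),
                            n_noncomputable=n_bad, computable=False,
                            detail="all replicates non-computable")
    p = float((s[ok] >= obs).mean())
    return RerandResult(method, float(obs), s, p, n_noncomputable=n_bad)


def run_config(trial: TrialData, config: RerandConfig) -> RerandResult:
    """Convenience wrapper driving :func:`rerand_test` from a config."""
    return rerand_test(trial, config.statistic, m=config.m,
                       rng=np.random.default_rng(config.seed),
                       prob_preferred=config.prob_preferred)
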