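"""Simulation harness: scenario x sample-size x method rejection rates.

Each grid cell simulates ``reps`` trials under one scenario and sample
size, applies every requested method to the *same* trials (paired
comparison), and reports the empirical one-sided rejection rate at
``alpha`` with its Monte-Carlo standard error.  dRMST-family methods
exclude replicates in which no events occur in either arm; exclusion
counts are reported so the accounting is auditable.  Re-randomisation
methods share one regenerated assignment matrix per trial.

Method labels combine a flavour (``asymp_`` or ``rerand_``) with a
statistic: ``lrt``, ``maxcombo``, ``cox``, ``drmst``, their adjusted
versions ``lrt_strat``, ``maxcombo_strat``, ``cox_adj``, ``drmst_adj``,
the individual FH weights ``wlrt_1_0``/``wlrt_1_1``/``wlrt_0_1``, and
restricted-mean horizons ``drmst_tau20``/``drmst_tau25``.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from . import cox_tests, rmst_tests, wlrt_maxcombo
from .datagen import PROFILES, ScenarioSpec, get_scenario, simulate_trials
from .randomisation import regenerate_assignments_batch
from .rerand import STATISTICS as RERAND_STATISTICS
from .rerand import rerand_test


def mc_se(p_hat: float, n_reps: int) -> float:
    """Monte-Carlo standard error of a rejection proportion, in percent."""
    if not 0.0 <= p_hat <= 1.0:
        raise ValueError("p_hat must be a proportion")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    return 100.0 * float(np.sqrt(p_hat * (1.0 - p_hat) / n_reps))


def _asymp_lrt(trial):
    return wlrt_maxcombo.logrank(trial)


def _asymp_lrt_strat(trial):
    return wlrt_maxcombo.logrank(trial, "factors")


def _asymp_maxcombo(trial):
    return wlrt_maxcombo.maxcombo(trial)


def _asymp_maxcombo_strat(trial):
    return wlrt_maxcombo.maxcombo(trial, strata="factors")


_ASYMP = {
    "asymp_lrt": _asymp_lrt,
    "asymp_lrt_strat": _asymp_lrt_strat,
    "asymp_maxcombo": _asymp_maxcombo,
    "asymp_maxcombo_strat": _asymp_maxcombo_strat,
    "asymp_wlrt_1_0": lambda tr: wlrt_maxcombo.wlrt(tr, (1, 0)),
    "asymp_wlrt_1_1": lambda tr: wlrt_maxcombo.wlrt(tr, (1, 1)),
    "asymp_wlrt_0_1": lambda tr: wlrt_maxcombo.wlrt(tr, (0, 1)),
    "asymp_cox": lambda tr: cox_tests.cox_wald(tr, adjust=False)[1],
    "asymp_cox_adj": lambda tr: cox_tests.cox_wald(tr, adjust=True)[1],
    "asymp_drmst": lambda tr: rmst_tests.drmst_test(tr),
    "asymp_drmst_tau20": lambda tr: rmst_tests.drmst_test(tr, tau=20.0),
    "asymp_drmst_tau25": lambda tr: rmst_tests.drmst_test(tr, tau=25.0),
    "asymp_drmst_adj": lambda tr: rmst_tests.ipcw_adjusted_drmst(tr)[1],
}

METHODS = tuple(_ASYMP) + tuple(f"rerand_{s}" for s in RERAND_STATISTICS)


@dataclass
class SimulationResult:
    """One grid cell: empirical rejection rate of one method."""

    scenario: str
    n: int
    method: str
    reps: int
    completed: int
    excluded: int
    rejections: int
    rate_pct: float
    mc_se_pct: float


def _validate_methods(methods):
    unknown = [m for m in methods if m not in METHODS]
    if unknown:
        raise KeyError(f"unknown method labels {unknown}; known: {sorted(METHODS)}")


def _cell_rng(seed: int, scenario: str, n: int) -> np.random.Generator:
    tag = zlib.crc32(scenario.encode()) % (2 ** 31)
    return np.random.default_rng([int(seed), tag, int(n)])


def _apply_method(method: str, trial, arm_matrix, rerand_m: int) -> float:
    """One-sided p-value of ``method`` on ``trial`` (NaN = non-computable)."""
    if method in _ASYMP:
        res = _ASYMP[method](trial)
        return res.p if res.computable else np.nan
    stat = method.removeprefix("rerand_")
    res = rerand_test(trial, stat, m=rerand_m, arm_matrix=arm_matrix)
    return res.p if res.computable else np.nan


def run_grid(scenarios, ns=(50, 100, 500), methods=("asymp_lrt",),
             reps: int = 200, rerand_m: int = 500, alpha: float = 0.025,
             seed: int = 0, prob_preferred: float = 0.7,
             out_dir=None, progress: bool = False) -> pd.DataFrame:
    """Empirical rejection rates over a scenario x n x method grid.

    Returns a tidy DataFrame with one row per cell; when ``out_dir`` is
    given, also writes ``results.csv``, the per-replicate p-values
    (``pvalues.csv.gz``) and a JSON run manifest.
    """
    scenario_list = [get_scenario(s) if isinstance(s, str) else s
                     for s in scenarios]
    methods = list(methods)
    _validate_methods(methods)
    if reps < 1:
        raise ValueError("reps must be >= 1")
    need_rerand = [m for m in methods if m.startswith("rerand_")]
    rows, audit = [], []
    for spec in scenario_list:
        for n in ns:
            rng = _cell_rng(seed, spec.name, n)
            trials = simulate_trials(spec, n, reps, rng,
                                     prob_preferred=prob_preferred)
            pvals = {m: np.full(reps, np.nan) for m in methods}
            for t_idx, trial in enumerate(trials):
                arm_matrix = None
                if need_rerand:
                    arm_matrix = regenerate_assignments_batch(
                        trial.z, prob_preferred, rerand_m, rng)
                for m in methods:
                    pvals[m][t_idx] = _apply_method(m, trial, arm_matrix,
                                                    rerand_m)
            if progress:   # pragma: no cover - cosmetic
                print(f"[{spec.name} n={n}] {reps} replicates done")
            for m in methods:
                p = pvals[m]
                ok = np.isfinite(p)
                completed = int(ok.sum())
                rejections = int((p[ok] <= alpha).sum())
                rate = 100.0 * rejections / completed if completed else np.nan
                rows.append(SimulationResult(
                    scenario=spec.name, n=int(n), method=m, reps=reps,
                    completed=completed, excluded=reps - completed,
                    rejections=rejections, rate_pct=rate,
                    mc_se_pct=mc_se(rejections / completed, completed)
                    if completed else np.nan))
                for t_idx in range(reps):
                    audit.append((spec.name, int(n), m, t_idx, p[t_idx]))
    table = pd.DataFrame([asdict(r) for r in rows])
    if out_dir is not None:
        _persist(table, audit, out_dir, dict(
            scenarios=[s.name for s in scenario_list], ns=list(map(int, ns)),
            methods=methods, reps=int(reps), rerand_m=int(rerand_m),
            alpha=float(alpha), seed=int(seed),
            prob_preferred=float(prob_preferred)))
    return table


def _persist(table, audit, out_dir, config):
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "results.csv", index=False)
    pd.DataFrame(audit, columns=["scenario", "n", "method", "replicate", "p"]) \
        .to_csv(out / "pvalues.csv.gz", index=False)
    manifest = {
        "config": config,
        "config_hash": f"{zlib.crc32(json.dumps(config, sort_keys=True).encode()):08x}",
        "versions": {"rerandsurv": _pkg_version, "numpy": np.__version__,
                     "pandas": pd.__version__},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def pivot_rates(table: pd.DataFrame) -> pd.DataFrame:
    """Reshape a tidy grid result into a methods x n table of rates (%),
    the layout the study's type-I-error tables use."""
    return table.pivot_table(index="method", columns="n", values="rate_pct")


def profile(name: str) -> dict:
    """Replication profile (``smoke``, ``desk`` or ``paper``)."""
    try:
        return dict(PROFILES[name])
    except KeyError:
        raise KeyError(f"unknown profile {name!r}; known: {sorted(PROFILES)}") \
            from None
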