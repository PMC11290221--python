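"""Result containers shared across test modules.

Every hypothesis test in this package reports an *oriented* Z statistic:
large positive values support superiority of the experimental arm
(arm code 1), and the one-sided p-value is the upper normal tail.
Statistics that cannot be evaluated on a given dataset (e.g. a restricted
mean difference with no events anywhere) are returned as non-computable
flagged values rather than raised exceptions, so simulation harnesses can
implement explicit exclusion accounting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class TestResult:
    """Oriented one-sided test outcome.

    Attributes
    ----------
    method : str
        Label of the test that produced this result.
    z : float
        Oriented Z statistic (positive favours the experimental arm);
        ``nan`` when not computable.
    p : float
        One-sided p-value (upper normal tail for asymptotic tests);
        ``nan`` when not computable.
    computable : bool
        False when the statistic could not be evaluated; ``z`` and ``p``
        are then ``nan`` and ``detail`` says why.
    detail : str
        Optional diagnostic message.
    """

    method: str
    z: float
    p: float
    computable: bool = True
    detail: str = ""

    @classmethod
    def not_computable(cls, method: str, detail: str = "") -> "TestResult":
        return cls(method=method, z=float("nan"), p=float("nan"),
                   computable=False, detail=detail)

    def reject(self, alpha: float = 0.025) -> bool:
        """One-sided rejection at level ``alpha`` (False when not computable)."""
        return bool(self.computable and self.p <= alpha)


@dataclass
class MaxComboResult:
    """MaxCombo test outcome.

    ``z_components`` are the oriented weighted log-rank Z statistics, one
    per weight; ``correlation`` is their estimated null correlation matrix;
    ``z_max`` the maximum component; ``p`` the one-sided p-value obtained
    either by multivariate-normal integration (``p_source='mvn'``) or by
    re-randomisation (``p_source='rerand'``).
    """

    weights: tuple
    z_components: np.ndarray
    correlation: np.ndarray
    z_max: float
    p: float
    p_source: str = "mvn"
    computable: bool = True
    detail: str = ""

    def as_test_result(self, method: str) -> TestResult:
        if not self.computable:
            return TestResult.not_computable(method, self.detail)
        return TestResult(method=method, z=self.z_max, p=self.p)


@dataclass
class RerandResult:
    """Re-randomisation test outcome.

    ``s_obs`` is the statistic on the observed assignment, ``s_rerand`` the
    M regenerated statistics (``nan`` where a replicate was not computable)
    and ``p`` the Monte-Carlo p-value  sum(S_m >= S_obs) / D  over the D
    computable replicates.  No +1 continuity correction is applied, so
    p = 0 is attainable.
    """

    method: str
    s_obs: float
    s_rerand: np.ndarray
    p: float
    n_noncomputable: int = 0
    computable: bool = True
    detail: str = ""

    def as_test_result(self) -> TestResult:
        if not self.computable:
            return TestResult.not_computable(self.method, self.detail)
        return TestResult(method=self.method, z=self.s_obs, p=self.p)
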