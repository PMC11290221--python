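"""Counting-process primitives: risk tables and Kaplan-Meier curves.

These feed every test in the package: distinct-event-time risk tables for
(weighted) log-rank statistics, the product-limit estimator for
Fleming-Harrington weights and restricted means, and the reverse
Kaplan-Meier censoring-survivor estimate for inverse-probability-of-
censoring weights.  At tied observed times, events are taken to precede
censorings (ties have probability zero under the continuous generator but
occur in user data).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class RiskTable:
    """Per distinct event time t_1 < ... < t_J: at-risk and event counts.

    ``n``/``d`` are totals, ``n1``/``d1`` the experimental-arm counts.
    """

    time: np.ndarray
    n: np.ndarray
    n1: np.ndarray
    d: np.ndarray
    d1: np.ndarray

    @property
    def n0(self) -> np.ndarray:
        return self.n - self.n1

    @property
    def d0(self) -> np.ndarray:
        return self.d - self.d1

    def __len__(self) -> int:
        return len(self.time)


def risk_table(time, event, arm, mask=None) -> RiskTable:
    """Pooled distinct-event-time risk table; optional boolean subset mask.

    The at-risk set at t_j counts subjects with T >= t_j; censored times
    enter risk sets only.  Zero events yield an empty table.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    arm = np.asarray(arm)
    if mask is not None:
        time, event, arm = time[mask], event[mask], arm[mask]
    ev = event == 1
    if not ev.any():
        empty = np.empty(0)
        return RiskTable(empty, empty.astype(int), empty.astype(int),
                         empty.astype(int), empty.astype(int))
    tj, inv = np.unique(time[ev], return_inverse=True)
    d = np.bincount(inv, minlength=len(tj))
    d1 = np.bincount(inv, weights=arm[ev], minlength=len(tj)).astype(np.int64)
    tsorted = np.sort(time)
    n = len(time) - np.searchsorted(tsorted, tj, side="left")
    t1sorted = np.sort(time[arm == 1])
    n1 = len(t1sorted) - np.searchsorted(t1sorted, tj, side="left")
    return RiskTable(tj, n.astype(np.int64), n1.astype(np.int64),
                     d.astype(np.int64), d1)


@dataclass
class KMEstimate:
    """Product-limit survivor curve evaluated at its jump times.

    ``surv`` is S(t_j) just after the jump; ``surv_prev`` the left limit
    S(t_j-), the quantity Fleming-Harrington weights are built from.  The
    curve is a right-continuous step function, equal to 1 before the first
    event and held constant after the last observed time.
    """

    time: np.ndarray        # distinct event times
    surv: np.ndarray        # S(t_j)
    surv_prev: np.ndarray   # S(t_j-)
    n_at_risk: np.ndarray
    n_events: np.ndarray
    t_max: float            # largest observed time (any status)
    last_is_event: bool

    def eval(self, t) -> np.ndarray:
        """S(t), right-continuous."""
        idx = np.searchsorted(self.time, np.asarray(t, dtype=float), side="right")
        return np.concatenate(([1.0], self.surv))[idx]

    def eval_left(self, t) -> np.ndarray:
        """S(t-), the left limit."""
        idx = np.searchsorted(self.time, np.asarray(t, dtype=float), side="left")
        return np.concatenate(([1.0], self.surv))[idx]


def km(time, event, reverse: bool = False) -> KMEstimate:
    """Kaplan-Meier estimate; ``reverse=True`` estimates the censoring
    survivor function G by swapping the roles of events and censorings."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if reverse:
        event = 1 - event
    rt = risk_table(time, event, np.zeros_like(event))
    if len(rt) == 0:
        return KMEstimate(rt.time, rt.time, rt.time,
                          rt.n, rt.d, float(time.max()) if len(time) else 0.0,
                          False)
    frac = 1.0 - rt.d / rt.n
    surv = np.cumprod(frac)
    surv_prev = np.concatenate(([1.0], surv[:-1]))
    t_max = float(time.max())
    last_is_event = bool((event[time == time.max()] == 1).any())
    return KMEstimate(rt.time, surv, surv_prev, rt.n, rt.d, t_max, last_is_event)
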