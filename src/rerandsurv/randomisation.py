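"""Pocock-Simon minimisation for two-arm trials.

Each incoming patient is assigned to the arm that minimises the summed
marginal imbalance over the binary stratification factors, with a fixed
preference probability (0.7 throughout the simulation study); exact ties —
including the first patient — are a fair coin.  The imbalance for a
candidate arm is evaluated *after* hypothetically adding the patient to
that arm, using the "range" metric (absolute count difference at the
patient's own factor levels, equal factor weights).

RNG contract
------------
Every assignment consumes exactly one uniform deviate: the patient goes to
the experimental arm when ``u < q`` with ``q = prob_preferred`` if the
experimental arm is preferred, ``1 - prob_preferred`` if the control arm
is preferred, and ``0.5`` on a tie.  The vectorised batch generator draws
the same stream in the same order at batch size 1, so scalar and batch
paths are bit-compatible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EXPERIMENTAL = 1
CONTROL = 0


@dataclass
class MinimisationState:
    """Running per-factor, per-level, per-arm assignment counts.

    ``counts[f, l, a]`` is the number of previously assigned patients with
    level ``l`` of factor ``f`` in arm ``a`` (0 = control, 1 = experimental).
    """

    n_factors: int = 3
    prob_preferred: float = 0.7
    counts: np.ndarray | None = None
    n_assigned: int = 0

    def __post_init__(self) -> None:
        if not 0.5 < self.prob_preferred <= 1.0:
            raise ValueError("prob_preferred must be in (0.5, 1].")
        if self.counts is None:
            self.counts = np.zeros((self.n_factors, 2, 2), dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (self.n_factors, 2, 2):
            raise ValueError("counts must have shape (n_factors, 2, 2).")


def assign_next(state: MinimisationState, covariates, rng: np.random.Generator) -> int:
    """Assign the next patient and update ``state`` in place.

    Parameters
    ----------
    covariates : sequence of int
        One observed binary level per stratification factor.

    Returns
    -------
    int
        1 for the experimental arm, 0 for control.
    """
    z = np.asarray(covariates, dtype=np.int64)
    if z.shape != (state.n_factors,):
        raise ValueError(
            f"expected {state.n_factors} factor levels, got shape {z.shape}"
        )
    if not np.isin(z, (0, 1)).all():
        raise ValueError("factor levels must be binary (0/1).")
    fr = np.arange(state.n_factors)
    c = state.counts[fr, z, :]                      # (F, 2): [control, experimental]
    diff = c[:, EXPERIMENTAL] - c[:, CONTROL]
    imb_exp = np.abs(diff + 1).sum()                # add patient to experimental
    imb_con = np.abs(diff - 1).sum()                # add patient to control
    if imb_exp < imb_con:
        q = state.prob_preferred
    elif imb_exp > imb_con:
        q = 1.0 - state.prob_preferred
    else:
        q = 0.5
    arm = int(rng.random() < q)
    state.counts[fr, z, arm] += 1
    state.n_assigned += 1
    return arm


def regenerate_assignments(covariates, prob_preferred: float,
                           rng: np.random.Generator) -> np.ndarray:
    """One fresh minimisation assignment sequence for an entry-ordered cohort.

    ``covariates`` is an (n, F) binary array in entry order.  Outcomes play
    no role: this is exactly the randomisation procedure re-run, which is
    what the re-randomisation engine needs.
    """
    z = np.atleast_2d(np.asarray(covariates, dtype=np.int64))
    state = MinimisationState(n_factors=z.shape[1], prob_preferred=prob_preferred)
    return np.array([assign_next(state, zi, rng) for zi in z], dtype=np.int8)


def regenerate_assignments_batch(covariates, prob_preferred: float, n_draws: int,
                                 rng: np.random.Generator) -> np.ndarray:
    """``n_draws`` i.i.d. minimisation sequences for one fixed cohort.

    Returns an (n, n_draws) int8 array; column ``m`` is one regenerated
    assignment vector.  All draws share the covariate table and entry
    order, as in a re-randomisation test.
    """
    z = np.asarray(covariates, dtype=np.int64)
    n, nf = z.shape
    zb = np.broadcast_to(z, (n_draws, n, nf))
    return _assign_sequential_batch(zb, prob_preferred, rng).T.astype(np.int8)


def _assign_sequential_batch(covariates: np.ndarray, prob_preferred: float,
                             rng: np.random.Generator) -> np.ndarray:
    """Run R independent minimisation sequences in lock-step.

    ``covariates`` has shape (R, n, F); returns (R, n) assignments.  Step i
    draws one uniform per replicate, matching the scalar path's stream.
    """
    nrep, n, nf = covariates.shape
    counts = np.zeros((nrep, nf, 2, 2), dtype=np.int64)
    arms = np.empty((nrep, n), dtype=np.int8)
    rr = np.arange(nrep)[:, None]
    fr = np.arange(nf)[None, :]
    for i in range(n):
        zi = covariates[:, i, :]                          # (R, F)
        c = counts[rr, fr, zi, :]                         # (R, F, 2)
        diff = c[..., EXPERIMENTAL] - c[..., CONTROL]
        imb_exp = np.abs(diff + 1).sum(axis=1)
        imb_con = np.abs(diff - 1).sum(axis=1)
        q = np.where(imb_exp < imb_con, prob_preferred,
                     np.where(imb_exp > imb_con, 1.0 - prob_preferred, 0.5))
        arm = (rng.random(nrep) < q).astype(np.int64)
        counts[np.arange(nrep)[:, None], fr, zi, arm[:, None]] += 1
        arms[:, i] = arm
    return arms
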