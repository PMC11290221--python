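"""Reading and validating user-supplied trial data.

Expected layout: a delimited text file (comma-separated by default, header
required, UTF-8) with observed time, event indicator and arm columns, and
optionally the three binary stratification factors and an entry-order
column.  Times are in months by design, though nothing downstream depends
on the unit.  Re-randomisation tests additionally require covariates and
entry order — without them the minimisation reference set is undefined —
and the CLI refuses them when either is missing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datagen import TrialData


class TrialValidationError(ValueError):
    """Raised when a user data file fails validation; the message lists
    the offending rows."""


DEFAULT_COLUMNS = dict(time="time", event="event", arm="arm",
                       covariates=("z1", "z2", "z3"),
                       entry_order="entry_order")


def _bad_rows(mask: np.ndarray, limit: int = 10) -> str:
    rows = np.flatnonzero(mask) + 1   # 1-based, excluding header
    shown = ", ".join(map(str, rows[:limit]))
    more = "" if len(rows) <= limit else f" (+{len(rows) - limit} more)"
    return shown + more


def read_trial(path, time_col="time", event_col="event", arm_col="arm",
               covariate_cols=("z1", "z2", "z3"), entry_order_col=None,
               sep=",") -> TrialData:
    """Read and validate a trial table into :class:`TrialData`.

    Entry order defaults to file order.  Missing covariate columns are
    filled with zeros (asymptotic unadjusted tests only need time, event
    and arm); validation errors name the offending data rows.
    """
    df = pd.read_csv(path, sep=sep)
    for col in (time_col, event_col, arm_col):
        if col not in df.columns:
            raise TrialValidationError(f"required column {col!r} not found; "
                                       f"file has {list(df.columns)}")
    if entry_order_col is not None:
        if entry_order_col not in df.columns:
            raise TrialValidationError(f"entry-order column {entry_order_col!r} "
                                       "not found")
        df = df.sort_values(entry_order_col, kind="stable")
    time = pd.to_numeric(df[time_col], errors="coerce").to_numpy(dtype=float)
    bad = ~np.isfinite(time) | (time <= 0)
    if bad.any():
        raise TrialValidationError(
            f"non-positive or non-numeric times in rows: {_bad_rows(bad)}")
    event = df[event_col].to_numpy()
    bad = ~np.isin(event, (0, 1))
    if bad.any():
        raise TrialValidationError(
            f"event indicator outside {{0,1}} in rows: {_bad_rows(bad)}")
    arm_raw = df[arm_col].to_numpy()
    levels = pd.unique(arm_raw)
    if len(levels) != 2:
        raise TrialValidationError(
            f"arm column must have exactly 2 levels, found {list(levels)}")
    if set(levels) == {0, 1}:
        arm = arm_raw.astype(int)
    else:   # map the lexicographically larger label to the experimental arm
        order = sorted(levels, key=str)
        arm = (arm_raw == order[1]).astype(int)
    have_cov = covariate_cols is not None and \
        all(c in df.columns for c in covariate_cols)
    if have_cov:
        z = df[list(covariate_cols)].to_numpy()
        bad = ~np.isin(z, (0, 1)).all(axis=1)
        if bad.any():
            raise TrialValidationError(
                f"non-binary covariates in rows: {_bad_rows(bad)}")
    else:
        z = np.zeros((len(df), 3), dtype=np.int8)
    return TrialData(z=z, arm=arm, time=time, event=event.astype(np.int8))


def write_trial(trial: TrialData, path, sep=",") -> None:
    """Write a trial in the canonical column layout (inverse of
    :func:`read_trial` on validated data)."""
    trial.to_frame().to_csv(path, sep=sep, index=False)


def has_rerand_inputs(df_or_trial, covariate_cols=("z1", "z2", "z3")) -> bool:
    """True when the data carry what a re-randomisation test needs
    (covariates; entry order is the row order by construction)."""
    if isinstance(df_or_trial, TrialData):
        return True
    return all(c in df_or_trial.columns for c in covariate_cols)
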