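"""Trial generation under a piecewise-exponential hazard with minimisation.

The data-generating model is a two-arm trial with three binary prognostic
factors z1, z2 ~ Bernoulli(2/3), z3 ~ Bernoulli(1/3), treatment assigned
sequentially by Pocock-Simon minimisation (preference probability 0.7),
event times from

    lambda_i(t) = lambda0 * hr(t)^arm * cov_hr^(z1+z2+z3),
    hr(t) = hr1 for t < epsilon, hr2 for t >= epsilon,

and independent administrative censoring C ~ Uniform[20, 40] months
(patients accrued uniformly over 20 months and followed at least 20).
The observed time is T = min(Y, C) with event indicator I(Y <= C).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .randomisation import _assign_sequential_batch

TRIAL_COLUMNS = ["entry_order", "z1", "z2", "z3", "arm", "time", "event"]


def _config() -> dict:
    with resources.files("rerandsurv.data").joinpath("scenarios.yaml").open() as fh:
        return yaml.safe_load(fh)


_CFG = _config()
COVARIATE_PREVALENCE = tuple(_CFG["covariate_prevalence"])
CENSORING_WINDOW = tuple(_CFG["censoring_window"])
PROFILES = dict(_CFG["profiles"])


@dataclass(frozen=True)
class ScenarioSpec:
    """One row of the scenario catalogue.

    ``hr1``/``hr2`` are the treatment hazard ratios before/after the change
    point ``epsilon`` (months); ``cov_hr`` the common per-factor covariate
    hazard ratio; ``n`` an optional default total sample size.
    """

    name: str
    lambda0: float
    epsilon: float
    hr1: float
    hr2: float
    cov_hr: float
    n: int | None = None

    def __post_init__(self):
        if min(self.lambda0, self.hr1, self.hr2, self.cov_hr) <= 0:
            raise ValueError("hazards and hazard ratios must be positive")
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")
        if self.n is not None and self.n < 2:
            raise ValueError("n must be at least 2")


@dataclass
class TrialData:
    """One trial in entry order: covariates, assignment, observed outcome."""

    z: np.ndarray        # (n, 3) binary prognostic factors
    arm: np.ndarray      # (n,) 1 = experimental, 0 = control
    time: np.ndarray     # (n,) observed months, > 0
    event: np.ndarray    # (n,) 1 = event, 0 = censored

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=np.int8)
        self.arm = np.asarray(self.arm, dtype=np.int8)
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=np.int8)
        n = len(self.time)
        if self.z.shape != (n, 3) or self.arm.shape != (n,) or self.event.shape != (n,):
            raise ValueError("inconsistent array lengths in TrialData")

    @property
    def n(self) -> int:
        return len(self.time)

    @property
    def entry_order(self) -> np.ndarray:
        return np.arange(1, self.n + 1)

    def stratum_ids(self) -> np.ndarray:
        """Cross-classification label of (z1, z2, z3): 0..7."""
        return (self.z @ np.array([4, 2, 1])).astype(np.int64)

    def with_arm(self, arm: np.ndarray) -> "TrialData":
        """Copy with a replacement assignment vector (for re-randomisation)."""
        return replace(self, arm=np.asarray(arm, dtype=np.int8))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "entry_order": self.entry_order,
            "z1": self.z[:, 0], "z2": self.z[:, 1], "z3": self.z[:, 2],
            "arm": self.arm, "time": self.time, "event": self.event,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TrialData":
        df = df.sort_values("entry_order") if "entry_order" in df else df
        return cls(
            z=df[["z1", "z2", "z3"]].to_numpy(),
            arm=df["arm"].to_numpy(),
            time=df["time"].to_numpy(),
            event=df["event"].to_numpy(),
        )


def scenario_catalogue() -> dict[str, ScenarioSpec]:
    """The seven study scenarios, keyed by name."""
    return {name: ScenarioSpec(name=name, **row)
            for name, row in _CFG["scenarios"].items()}


def get_scenario(name: str) -> ScenarioSpec:
    cat = scenario_catalogue()
    try:
        return cat[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; known: {sorted(cat)}") from None


def draw_event_times(spec: ScenarioSpec, arm, z_total,
                     rng: np.random.Generator) -> np.ndarray:
    """Inverse-CDF piecewise-exponential event times (months), vectorised.

    ``z_total`` is z1+z2+z3 per patient.  With pre/post change-point rates
    r1, r2 and E ~ Exp(1):  Y = E/r1 if E < r1*epsilon, else
    epsilon + (E - r1*epsilon)/r2.  Control-arm times are plain
    exponentials since the treatment hazard ratio applies only to arm 1.
    """
    arm = np.asarray(arm)
    covf = spec.cov_hr ** np.asarray(z_total, dtype=float)
    r1 = spec.lambda0 * np.where(arm == 1, spec.hr1, 1.0) * covf
    r2 = spec.lambda0 * np.where(arm == 1, spec.hr2, 1.0) * covf
    e = rng.exponential(size=arm.shape)
    cut = r1 * spec.epsilon
    return np.where(e < cut, e / r1, spec.epsilon + (e - cut) / r2)


def draw_event_time(spec: ScenarioSpec, arm: int, z1: int, z2: int, z3: int,
                    rng: np.random.Generator) -> float:
    return float(draw_event_times(spec, np.array([arm]),
                                  np.array([z1 + z2 + z3]), rng)[0])


def simulate_trials(spec: ScenarioSpec, n: int, reps: int,
                    rng: np.random.Generator,
                    prob_preferred: float = 0.7) -> list[TrialData]:
    """``reps`` independent trials of total size ``n``, batch-vectorised.

    All replicates advance in lock-step through the minimisation sequence,
    so the cost is O(n) vector operations regardless of ``reps``.
    """
    prev = np.asarray(COVARIATE_PREVALENCE)
    z = (rng.random((reps, n, 3)) < prev).astype(np.int8)
    arms = _assign_sequential_batch(z.astype(np.int64), prob_preferred, rng)
    y = draw_event_times(spec, arms, z.sum(axis=2), rng)
    lo, hi = CENSORING_WINDOW
    c = rng.uniform(lo, hi, size=(reps, n))
    time = np.minimum(y, c)
    event = (y <= c).astype(np.int8)
    return [TrialData(z=z[r], arm=arms[r], time=time[r], event=event[r])
            for r in range(reps)]


def simulate_trial(spec: ScenarioSpec, n: int, rng: np.random.Generator,
                   prob_preferred: float = 0.7) -> TrialData:
    """A single simulated trial (batch generator at replication 1)."""
    return simulate_trials(spec, n, 1, rng, prob_preferred)[0]
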