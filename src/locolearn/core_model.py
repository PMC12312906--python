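"""Dual-context state-space forward model of trial-by-trial foot clearance.

The learner maintains one state per obstacle-height context (LOW / HIGH),
interpreted as the estimated success-range threshold in meters.  Each trial
produces a motor output (estimated foot clearance), a dead-zone error
relative to the success range, and an interference-weighted state update.

Two readings of the motor-output equation are supported:

* ``DOT`` (default) — the literal inner product of the state vector with the
  context vector, so with interference ``q > 0`` the output blends both
  states.
* ``SELECT`` — the output is the state component matching the current
  obstacle height; the context vector only routes the *update*.

All quantities are in meters unless stated otherwise.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "HeightClass",
    "Group",
    "Phase",
    "OutputVariant",
    "ObstacleSpec",
    "LearnerState",
    "ParticipantParams",
    "TrialRecord",
    "TrialResult",
    "DEFAULT_OBSTACLES",
    "compute_error",
    "context_vector",
    "motor_output",
    "state_update",
    "simulate_sequence",
    "simulate_fc_est",
    "simulate_fc_est_batch",
]


class HeightClass(enum.Enum):
    LOW = "LOW"
    HIGH = "HIGH"


class Group(enum.Enum):
    CONTROL = "CONTROL"
    PD = "PD"


class Phase(enum.Enum):
    BASELINE = "BASELINE"
    ACQUISITION = "ACQUISITION"
    NO_FEEDBACK = "NO_FEEDBACK"
    RETENTION = "RETENTION"


class OutputVariant(enum.Enum):
    DOT = "DOT"
    SELECT = "SELECT"


@dataclass(frozen=True)
class ObstacleSpec:
    """One obstacle height class with its rewarded clearance interval."""

    height_class: HeightClass
    physical_height: float
    h_lower: float
    h_upper: float

    def __post_init__(self) -> None:
        if not (self.h_lower < self.h_upper):
            raise ValueError(
                f"h_lower must be < h_upper, got [{self.h_lower}, {self.h_upper}]"
            )
        if self.physical_height <= 0:
            raise ValueError("physical_height must be positive")
        if self.h_lower < 0:
            raise ValueError("success-range thresholds are clearances and must be >= 0")


#: Default obstacle definitions: LOW 0.05 m tall, rewarded clearance
#: 0.05–0.09 m above its top; HIGH 0.18 m tall, rewarded 0.01–0.05 m.
DEFAULT_OBSTACLES: dict[HeightClass, ObstacleSpec] = {
    HeightClass.LOW: ObstacleSpec(HeightClass.LOW, 0.05, 0.05, 0.09),
    HeightClass.HIGH: ObstacleSpec(HeightClass.HIGH, 0.18, 0.01, 0.05),
}


@dataclass(frozen=True)
class LearnerState:
    """Per-context threshold estimates at a given trial."""

    x_low: float
    x_high: float
    trial_index: int = 1

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x_low) and math.isfinite(self.x_high)):
            raise ValueError("state components must be finite")
        if self.trial_index < 1:
            raise ValueError("trial_index must be >= 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.x_low, self.x_high])


@dataclass(frozen=True)
class ParticipantParams:
    """Participant-level model parameters.

    B is the learning rate (fraction of the error corrected next trial),
    q the interference routed to the other context, tau the observation
    noise scale, k the baseline scaling factor for initial states.
    """

    B: float
    q: float
    tau: float
    k: float
    x1_low: float
    x1_high: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.B <= 1.0:
            raise ValueError(f"B must lie in [0, 1], got {self.B}")
        if not 0.0 <= self.q <= 1.0:
            raise ValueError(f"q must lie in [0, 1], got {self.q}")
        if not self.tau > 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if self.k < 0:
            raise ValueError(f"k must be non-negative, got {self.k}")

    def initial_state(self) -> LearnerState:
        return LearnerState(self.x1_low, self.x1_high, trial_index=1)


@dataclass(frozen=True)
class TrialRecord:
    """One observed obstacle crossing."""

    participant_id: str
    group: Group
    phase: Phase
    bout: int
    obstacle_index: int
    height_class: HeightClass
    fc_observed: float | None = None

    def __post_init__(self) -> None:
        if self.fc_observed is not None:
            if math.isnan(self.fc_observed):
                object.__setattr__(self, "fc_observed", None)
            elif self.fc_observed < 0:
                raise ValueError("fc_observed must be >= 0 (or missing)")


@dataclass(frozen=True)
class TrialResult:
    """Forward-simulation output for a single trial."""

    fc_est: float
    fc_observed: float
    error: float
    state: LearnerState


def compute_error(fc_est: float, spec: ObstacleSpec) -> float:
    """Dead-zone error of an estimated clearance against the success range.

    Zero inside the closed interval [h_lower, h_upper]; otherwise the signed
    distance from the violated threshold to ``fc_est``.  Negative values mean
    the clearance should be reduced on the next same-context trial.
    """
    if not math.isfinite(fc_est):
        raise ValueError(f"fc_est must be finite, got {fc_est}")
    if fc_est > spec.h_upper:
        return spec.h_upper - fc_est
    if fc_est < spec.h_lower:
        return spec.h_lower - fc_est
    return 0.0


def context_vector(height_class: HeightClass, q: float) -> tuple[float, float]:
    """Context weights (w_low, w_high) routing an update across the two states."""
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"q must lie in [0, 1], got {q}")
    if height_class is HeightClass.LOW:
        return (1.0, q)
    if height_class is HeightClass.HIGH:
        return (q, 1.0)
    raise ValueError(f"unknown height class: {height_class!r}")


def motor_output(
    state: LearnerState,
    height_class: HeightClass,
    q: float,
    variant: OutputVariant = OutputVariant.DOT,
) -> float:
    """Estimated foot clearance produced from the current state."""
    if variant is OutputVariant.DOT:
        w_low, w_high = context_vector(height_class, q)
        return state.x_low * w_low + state.x_high * w_high
    if variant is OutputVariant.SELECT:
        # Selection reading: output the state matching the current context.
        if height_class is HeightClass.LOW:
            return state.x_low
        if height_class is HeightClass.HIGH:
            return state.x_high
        raise ValueError(f"unknown height class: {height_class!r}")
    raise ValueError(f"unknown output variant: {variant!r}")


def state_update(
    state: LearnerState,
    error: float,
    height_class: HeightClass,
    params: ParticipantParams,
) -> LearnerState:
    """Apply the interference-weighted error correction: x' = x + B·e·c."""
    w_low, w_high = context_vector(height_class, params.q)
    return LearnerState(
        x_low=state.x_low + params.B * error * w_low,
        x_high=state.x_high + params.B * error * w_high,
        trial_index=state.trial_index + 1,
    )


def simulate_sequence(
    params: ParticipantParams,
    schedule: Sequence[ObstacleSpec],
    noise: str = "none",
    nu: float = 5.0,
    seed: int | np.random.Generator | None = None,
    variant: OutputVariant = OutputVariant.DOT,
) -> list[TrialResult]:
    """Run the forward model over an obstacle schedule.

    Parameters
    ----------
    noise
        ``"none"`` (fc_observed = fc_est) or ``"student_t"`` (fc_observed =
        fc_est + tau·t(nu)).  The error driving the state update is always
        computed from the noiseless motor output fc_est.
    seed
        Integer seed or a ``numpy.random.Generator``; required determinism
        only matters when noise is enabled.
    """
    schedule = list(schedule)
    if not schedule:
        raise ValueError("schedule must be non-empty")
    if noise not in ("none", "student_t"):
        raise ValueError(f"unknown noise model: {noise!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    state = params.initial_state()
    results: list[TrialResult] = []
    for spec in schedule:
        fc_est = motor_output(state, spec.height_class, params.q, variant)
        err = compute_error(fc_est, spec)
        if noise == "student_t":
            fc_obs = fc_est + params.tau * rng.standard_t(nu)
        else:
            fc_obs = fc_est
        next_state = state_update(state, err, spec.height_class, params)
        results.append(TrialResult(fc_est=fc_est, fc_observed=fc_obs, error=err, state=state))
        state = next_state
    return results


def _height_codes(schedule: Sequence[ObstacleSpec]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    codes = np.array(
        [0 if s.height_class is HeightClass.LOW else 1 for s in schedule], dtype=np.int64
    )
    lo = np.array([s.h_lower for s in schedule])
    hi = np.array([s.h_upper for s in schedule])
    return codes, lo, hi


def simulate_fc_est(
    params: ParticipantParams,
    schedule: Sequence[ObstacleSpec],
    variant: OutputVariant = OutputVariant.DOT,
) -> np.ndarray:
    """Noiseless fc_est trajectory as a numpy array (thin wrapper)."""
    codes, lo, hi = _height_codes(schedule)
    out = simulate_fc_est_batch(
        np.array([params.B]),
        np.array([params.q]),
        np.array([params.x1_low]),
        np.array([params.x1_high]),
        codes,
        lo,
        hi,
        variant=variant,
    )
    return out[0]


def simulate_fc_est_batch(
    B: np.ndarray,
    q: np.ndarray,
    x1_low: np.ndarray,
    x1_high: np.ndarray,
    height_codes: np.ndarray,
    h_lower: np.ndarray,
    h_upper: np.ndarray,
    variant: OutputVariant = OutputVariant.DOT,
) -> np.ndarray:
    """Vectorized noiseless forward simulation over a batch of parameter draws.

    Iterates over trials (the recursion is sequential) but evaluates all
    parameter draws simultaneously.  Returns fc_est of shape (n_draws,
    n_trials).  ``height_codes`` uses 0 for LOW, 1 for HIGH.
    """
    B = np.asarray(B, dtype=float)
    q = np.asarray(q, dtype=float)
    n_draws = B.shape[0]
    n_trials = len(height_codes)
    x_low = np.asarray(x1_low, dtype=float).copy()
    x_high = np.asarray(x1_high, dtype=float).copy()
    select = variant is OutputVariant.SELECT
    fc = np.empty((n_draws, n_trials))
    for n in range(n_trials):
        if height_codes[n] == 0:
            w_low, w_high = np.ones(n_draws), q
            fc_est = x_low if select else x_low + q * x_high
        else:
            w_low, w_high = q, np.ones(n_draws)
            fc_est = x_high if select else q * x_low + x_high
        err = np.where(
            fc_est > h_upper[n],
            h_upper[n] - fc_est,
            np.where(fc_est < h_lower[n], h_lower[n] - fc_est, 0.0),
        )
        fc[:, n] = fc_est
        step = B * err
        x_low = x_low + step * w_low
        x_high = x_high + step * w_high
    return fc
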