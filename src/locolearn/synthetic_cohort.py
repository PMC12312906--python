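"""Synthetic study cohorts with known ground-truth parameters.

Emulates the study design — two groups (controls and PD), two obstacle
heights with distinct success ranges, per-height baseline bouts, 192
acquisition obstacles in six 32-obstacle bouts (the fifth without
performance feedback), and Day-2 retention trials — so that every
downstream stage (fitting, testing, metrics) can be exercised without
human data.

Baseline foot-clearance levels are not reported by the study; the defaults
here (LOW 0.15 ± 0.04 m, HIGH 0.10 ± 0.04 m above the obstacle top) are
stand-ins chosen to start learners above their success ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_model import (
    DEFAULT_OBSTACLES,
    Group,
    HeightClass,
    ObstacleSpec,
    OutputVariant,
    ParticipantParams,
    Phase,
    simulate_sequence,
    state_update,
)

__all__ = [
    "PopulationParams",
    "CohortDesign",
    "CohortData",
    "sigmoid",
    "logit",
    "draw_participants",
    "generate_schedule",
    "generate_cohort",
    "default_populations",
]


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def logit(p):
    p = np.asarray(p, dtype=float)
    return np.log(p / (1.0 - p))


@dataclass(frozen=True)
class PopulationParams:
    """Group-level generating hyper-parameters.

    Participant learning rates are sigmoid(Normal(theta_B, sigma_B)) and
    interference values sigmoid(Normal(theta_q, sigma_q)); nu is the shared
    Student-t degrees of freedom of the observation noise.
    """

    theta_B: float
    sigma_B: float
    theta_q: float
    sigma_q: float
    nu: float = 5.0
    group: Group = Group.CONTROL

    def __post_init__(self) -> None:
        if self.sigma_B <= 0 or self.sigma_q <= 0:
            raise ValueError("sigma_B and sigma_q must be positive")
        if self.nu <= 0:
            raise ValueError("nu must be positive")


def default_populations(
    b_control: float = 0.08,
    b_pd: float = 0.14,
    q_control: float = 0.36,
    q_pd: float = 0.45,
    sigma_B: float = 0.5,
    sigma_q: float = 0.8,
    nu: float = 5.0,
) -> tuple[PopulationParams, PopulationParams]:
    """Generating populations centered on the reported group medians."""
    ctrl = PopulationParams(
        theta_B=float(logit(b_control)), sigma_B=sigma_B,
        theta_q=float(logit(q_control)), sigma_q=sigma_q,
        nu=nu, group=Group.CONTROL,
    )
    pd_ = PopulationParams(
        theta_B=float(logit(b_pd)), sigma_B=sigma_B,
        theta_q=float(logit(q_pd)), sigma_q=sigma_q,
        nu=nu, group=Group.PD,
    )
    return ctrl, pd_


@dataclass(frozen=True)
class CohortDesign:
    """Structural description of a synthetic study."""

    n_control: int = 20
    n_pd: int = 15
    n_baseline_per_height: int = 32
    n_acquisition: int = 192
    bout_size: int = 32
    no_feedback_bout: int = 5
    n_retention_per_height: int = 16
    baseline_fc_mean: dict[HeightClass, float] = field(
        default_factory=lambda: {HeightClass.LOW: 0.15, HeightClass.HIGH: 0.10}
    )
    baseline_fc_sd: dict[HeightClass, float] = field(
        default_factory=lambda: {HeightClass.LOW: 0.04, HeightClass.HIGH: 0.04}
    )
    tau_mean: float = 0.023          # observation SD ~0.03 m at nu = 5
    tau_log_sd: float = 0.25
    k_value: float = 1.0
    forgetting_factor: float = 1.0   # 1.0 carries the final state to Day 2
    max_run: int = 4
    output_variant: OutputVariant = OutputVariant.SELECT
    obstacles: dict[HeightClass, ObstacleSpec] = field(
        default_factory=lambda: dict(DEFAULT_OBSTACLES)
    )

    def __post_init__(self) -> None:
        n_bouts = self.n_acquisition // self.bout_size
        if n_bouts * self.bout_size != self.n_acquisition:
            raise ValueError("n_acquisition must be a multiple of bout_size")
        if self.bout_size % 2 != 0:
            raise ValueError("bout_size must be even (balanced LOW/HIGH per bout)")
        if not (1 <= self.no_feedback_bout <= n_bouts):
            raise ValueError("no_feedback_bout out of range")
        if not (0.0 <= self.forgetting_factor <= 1.0):
            raise ValueError("forgetting_factor must lie in [0, 1]")

    @property
    def n_bouts(self) -> int:
        return self.n_acquisition // self.bout_size


@dataclass
class CohortData:
    """A generated cohort: trial table plus ground-truth parameter tables."""

    trials: pd.DataFrame
    truth: pd.DataFrame
    populations: pd.DataFrame
    seed: int


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def draw_participants(
    pop: PopulationParams,
    n: int,
    seed,
    design: CohortDesign | None = None,
) -> list[ParticipantParams]:
    """Draw participant-level parameters from a generating population."""
    if n < 1:
        raise ValueError("n must be >= 1")
    design = design or CohortDesign()
    rng = _rng(seed)
    B = sigmoid(rng.normal(pop.theta_B, pop.sigma_B, size=n))
    q = sigmoid(rng.normal(pop.theta_q, pop.sigma_q, size=n))
    tau = np.exp(rng.normal(np.log(design.tau_mean), design.tau_log_sd, size=n))
    x1_low = rng.normal(
        design.baseline_fc_mean[HeightClass.LOW],
        design.baseline_fc_sd[HeightClass.LOW], size=n,
    )
    x1_high = rng.normal(
        design.baseline_fc_mean[HeightClass.HIGH],
        design.baseline_fc_sd[HeightClass.HIGH], size=n,
    )
    # keep initial clearances physically sensible (above the success range floor)
    x1_low = np.clip(x1_low, 0.02, None)
    x1_high = np.clip(x1_high, 0.01, None)
    return [
        ParticipantParams(
            B=float(B[i]), q=float(q[i]), tau=float(tau[i]),
            k=design.k_value, x1_low=float(x1_low[i]), x1_high=float(x1_high[i]),
        )
        for i in range(n)
    ]


def generate_schedule(design: CohortDesign, seed) -> list[ObstacleSpec]:
    """Balanced pseudorandom LOW/HIGH interleaving across acquisition bouts.

    Each bout contains exactly bout_size/2 obstacles of each height and no
    more than ``design.max_run`` consecutive same-height obstacles anywhere
    in the concatenated sequence.
    """
    rng = _rng(seed)
    half = design.bout_size // 2
    codes: list[int] = []
    for _ in range(design.n_bouts):
        bout = np.array([0] * half + [1] * half)
        for _attempt in range(10_000):
            rng.shuffle(bout)
            tail = codes[-design.max_run:] if codes else []
            if _max_run(tail + bout.tolist()) <= design.max_run:
                break
        else:  # pragma: no cover - rejection virtually never exhausts
            raise RuntimeError("could not satisfy run-length constraint")
        codes.extend(bout.tolist())
    lut = {0: design.obstacles[HeightClass.LOW], 1: design.obstacles[HeightClass.HIGH]}
    return [lut[c] for c in codes]


def _max_run(codes) -> int:
    best = run = 0
    prev = None
    for c in codes:
        run = run + 1 if c == prev else 1
        best = max(best, run)
        prev = c
    return best


def _interleaved(design: CohortDesign, n_per_height: int, rng) -> list[ObstacleSpec]:
    codes = np.array([0] * n_per_height + [1] * n_per_height)
    rng.shuffle(codes)
    lut = {0: design.obstacles[HeightClass.LOW], 1: design.obstacles[HeightClass.HIGH]}
    return [lut[c] for c in codes]


def generate_cohort(
    pop_control: PopulationParams,
    pop_pd: PopulationParams,
    design: CohortDesign,
    seed: int = 0,
) -> CohortData:
    """Generate a complete synthetic study dataset.

    Emits BASELINE records (noisy stepping around each participant's natural
    clearance, no learning), ACQUISITION records simulated from the forward
    model with Student-t observation noise (the no-feedback bout keeps
    updating — errors remain visible), and RETENTION records generated from
    the end-of-acquisition state, optionally decayed toward the initial
    state by ``design.forgetting_factor``.
    """
    master = np.random.SeedSequence(seed)
    ss_ctrl, ss_pd, ss_trials = master.spawn(3)
    participants: list[tuple[str, Group, ParticipantParams]] = []
    for prefix, group, pop, n, ss in (
        ("C", Group.CONTROL, pop_control, design.n_control, ss_ctrl),
        ("P", Group.PD, pop_pd, design.n_pd, ss_pd),
    ):
        drawn = draw_participants(pop, n, np.random.default_rng(ss), design)
        for i, p in enumerate(drawn, start=1):
            participants.append((f"{prefix}{i:02d}", group, p))

    nu = pop_control.nu  # shared dof across groups per the model
    rows: list[dict] = []
    truth_rows: list[dict] = []
    trial_rngs = [np.random.default_rng(s) for s in ss_trials.spawn(len(participants))]

    for (pid, group, params), rng in zip(participants, trial_rngs):
        truth_rows.append(
            {
                "participant_id": pid, "group": group.value,
                "B": params.B, "q": params.q, "tau": params.tau, "k": params.k,
                "x1_low": params.x1_low, "x1_high": params.x1_high,
            }
        )
        # --- baseline: no learning, noise around the initial state ---
        for height, x1 in (
            (HeightClass.LOW, params.x1_low),
            (HeightClass.HIGH, params.x1_high),
        ):
            fc = x1 + params.tau * rng.standard_t(nu, size=design.n_baseline_per_height)
            for j, v in enumerate(fc, start=1):
                rows.append(_row(pid, group, Phase.BASELINE, 0, j, height, max(v, 0.0)))

        # --- acquisition ---
        schedule = generate_schedule(design, rng)
        sim = simulate_sequence(
            params, schedule, noise="student_t", nu=nu, seed=rng,
            variant=design.output_variant,
        )
        for i, (spec, res) in enumerate(zip(schedule, sim)):
            bout = 1 + i // design.bout_size
            phase = Phase.NO_FEEDBACK if bout == design.no_feedback_bout else Phase.ACQUISITION
            rows.append(
                _row(pid, group, phase, bout, i + 1, spec.height_class,
                     max(res.fc_observed, 0.0))
            )
        # state after the final trial's update
        end_state = state_update(
            sim[-1].state, sim[-1].error, schedule[-1].height_class, params
        )

        # --- retention: carry (possibly decayed) state, no updates ---
        f = design.forgetting_factor
        x_ret_low = params.x1_low + f * (end_state.x_low - params.x1_low)
        x_ret_high = params.x1_high + f * (end_state.x_high - params.x1_high)
        ret_params = ParticipantParams(
            B=0.0, q=params.q, tau=params.tau, k=params.k,
            x1_low=x_ret_low, x1_high=x_ret_high,
        )
        ret_schedule = _interleaved(design, design.n_retention_per_height, rng)
        ret = simulate_sequence(
            ret_params, ret_schedule, noise="student_t", nu=nu, seed=rng,
            variant=design.output_variant,
        )
        for j, (spec, res) in enumerate(zip(ret_schedule, ret), start=1):
            rows.append(
                _row(pid, group, Phase.RETENTION, 0, j, spec.height_class,
                     max(res.fc_observed, 0.0))
            )

    trials = pd.DataFrame(rows)
    # Baseline rows were appended per height with per-block indices; renumber
    # within participant x phase so the strictly-increasing invariant holds.
    mask = trials["phase"].isin([Phase.ACQUISITION.value, Phase.NO_FEEDBACK.value])
    trials.loc[~mask, "obstacle_index"] = (
        trials.loc[~mask].groupby(["participant_id", "phase"], sort=False).cumcount() + 1
    )

    populations = pd.DataFrame(
        [
            {
                "group": Group.CONTROL.value, "theta_B": pop_control.theta_B,
                "sigma_B": pop_control.sigma_B, "theta_q": pop_control.theta_q,
                "sigma_q": pop_control.sigma_q, "nu": nu,
                "B_pop": float(sigmoid(pop_control.theta_B)),
                "q_pop": float(sigmoid(pop_control.theta_q)),
            },
            {
                "group": Group.PD.value, "theta_B": pop_pd.theta_B,
                "sigma_B": pop_pd.sigma_B, "theta_q": pop_pd.theta_q,
                "sigma_q": pop_pd.sigma_q, "nu": pop_pd.nu,
                "B_pop": float(sigmoid(pop_pd.theta_B)),
                "q_pop": float(sigmoid(pop_pd.theta_q)),
            },
        ]
    )
    return CohortData(
        trials=trials, truth=pd.DataFrame(truth_rows), populations=populations, seed=seed
    )


def _row(pid, group, phase, bout, idx, height, fc) -> dict:
    return {
        "participant_id": pid,
        "group": group.value,
        "phase": phase.value,
        "bout": bout,
        "obstacle_index": idx,
        "height_class": height.value,
        "fc_observed": fc,
    }
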