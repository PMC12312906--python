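"""Model specification types and trial-table preparation for fitting."""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..core_model import DEFAULT_OBSTACLES, HeightClass, ObstacleSpec, OutputVariant, Phase

__all__ = [
    "ModelVariant",
    "PriorSettings",
    "MCMCSettings",
    "HierarchicalModelSpec",
    "FitData",
    "prepare_fit_data",
]


class ModelVariant(enum.Enum):
    FULL = "FULL"        # learning rate and interference per participant
    B_ONLY = "B_ONLY"    # interference fixed at 0
    Q_ONLY = "Q_ONLY"    # one learning rate shared across participants


@dataclass(frozen=True)
class PriorSettings:
    """Hyper-prior constants.

    Location hyper-parameters get vague Normal(0, theta_sd) priors; the
    variance hyper-parameters and the Student-t degrees of freedom get
    InverseGamma(1e-3, 1e-3).  Positive participant-level scales (tau) and
    the baseline scaling k get vague half-normal / truncated-normal priors.
    nu is floored at ``nu_floor`` to keep the likelihood proper.
    """

    theta_sd: float = 31.6227766
    sigma_a: float = 1e-3
    sigma_b: float = 1e-3
    tau_sd: float = 31.6227766
    k_sd: float = 31.6227766
    nu_a: float = 1e-3
    nu_b: float = 1e-3
    nu_floor: float = 1.0
    # the printed InverseGamma(1e-3, 1e-3) is near-flat in log(nu); the cap
    # bounds the random walk where Student-t is indistinguishable from normal
    nu_cap: float = 200.0


@dataclass(frozen=True)
class MCMCSettings:
    """Sampler protocol; defaults mirror the reference protocol
    (3 chains x 20,000 iterations, 10,000 burn-in, thinning 10 -> 3,000
    retained draws)."""

    n_chains: int = 3
    n_iter: int = 20_000
    burn_in: int = 10_000
    thin: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("burn_in must lie in [0, n_iter)")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_keep_per_chain(self) -> int:
        return (self.n_iter - self.burn_in + self.thin - 1) // self.thin


@dataclass(frozen=True)
class HierarchicalModelSpec:
    variant: ModelVariant = ModelVariant.FULL
    output_variant: OutputVariant = OutputVariant.DOT
    priors: PriorSettings = field(default_factory=PriorSettings)
    include_no_feedback: bool = True
    obstacles: dict[HeightClass, ObstacleSpec] = field(
        default_factory=lambda: dict(DEFAULT_OBSTACLES)
    )


@dataclass
class FitData:
    """Flat arrays for the sampler, one participant per offset segment."""

    participant_ids: list[str]
    groups: list[str]
    group_idx: np.ndarray
    heights: np.ndarray
    fc_obs: np.ndarray
    lik_mask: np.ndarray
    h_lo: np.ndarray
    h_hi: np.ndarray
    offsets: np.ndarray
    base_mu_l: np.ndarray
    base_mu_h: np.ndarray
    base_sd_l: np.ndarray
    base_sd_h: np.ndarray

    @property
    def n_participants(self) -> int:
        return len(self.participant_ids)

    @property
    def n_obs(self) -> int:
        return int(self.lik_mask.sum())

    def data_fingerprint(self) -> tuple:
        """Identity of the likelihood-contributing observations (for WAIC)."""
        obs = self.fc_obs[self.lik_mask.astype(bool)]
        return (self.n_obs, float(np.nansum(obs)), tuple(self.participant_ids))


_GROUP_ORDER = ("CONTROL", "PD")


def prepare_fit_data(trials: pd.DataFrame, spec: HierarchicalModelSpec) -> FitData:
    """Assemble sampler arrays from a validated trial table.

    Uses ACQUISITION plus (by default) NO_FEEDBACK records, sorted by
    obstacle_index within participant; when ``include_no_feedback`` is
    False the no-feedback bout still drives state updates but contributes
    no likelihood.  Baseline summaries (mean/SD per height) come from each
    participant's BASELINE records.
    """
    required = {"participant_id", "group", "phase", "obstacle_index", "height_class", "fc_observed"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")

    acq_phases = [Phase.ACQUISITION.value, Phase.NO_FEEDBACK.value]
    acq = trials[trials["phase"].isin(acq_phases)].copy()
    if acq.empty:
        raise ValueError("no acquisition-phase records in trial table")
    base = trials[trials["phase"] == Phase.BASELINE.value]

    pids = sorted(acq["participant_id"].unique())
    group_of = acq.drop_duplicates("participant_id").set_index("participant_id")["group"]
    for g in group_of.unique():
        if g not in _GROUP_ORDER:
            raise ValueError(f"unknown group label: {g!r}")
    counts = group_of.value_counts()
    for g in _GROUP_ORDER:
        if counts.get(g, 0) < 2:
            raise ValueError(f"need >= 2 participants in group {g}, got {counts.get(g, 0)}")

    lo_spec = spec.obstacles[HeightClass.LOW]
    hi_spec = spec.obstacles[HeightClass.HIGH]

    heights_l, fc_l, mask_l, hlo_l, hhi_l = [], [], [], [], []
    offsets = [0]
    base_mu_l, base_mu_h, base_sd_l, base_sd_h = [], [], [], []
    groups = []
    for pid in pids:
        sub = acq[acq["participant_id"] == pid].sort_values("obstacle_index")
        idx = sub["obstacle_index"].to_numpy()
        if len(idx) > 1 and not np.all(np.diff(idx) > 0):
            raise ValueError(f"obstacle_index not strictly increasing for {pid}")
        h = (sub["height_class"] == HeightClass.HIGH.value).to_numpy().astype(np.int64)
        fc = sub["fc_observed"].to_numpy(dtype=float)
        observed = np.isfinite(fc)
        in_lik = observed.copy()
        if not spec.include_no_feedback:
            in_lik &= (sub["phase"] != Phase.NO_FEEDBACK.value).to_numpy()
        heights_l.append(h)
        fc_l.append(np.where(observed, fc, np.nan))
        mask_l.append(in_lik.astype(np.uint8))
        hlo_l.append(np.where(h == 0, lo_spec.h_lower, hi_spec.h_lower))
        hhi_l.append(np.where(h == 0, lo_spec.h_upper, hi_spec.h_upper))
        offsets.append(offsets[-1] + len(h))
        groups.append(str(group_of[pid]))

        bsub = base[base["participant_id"] == pid]
        mu_sd = {}
        for hc, default_mu in ((HeightClass.LOW, 0.15), (HeightClass.HIGH, 0.10)):
            vals = bsub.loc[bsub["height_class"] == hc.value, "fc_observed"].dropna()
            if len(vals) >= 2:
                mu_sd[hc] = (float(vals.mean()), max(float(vals.std(ddof=1)), 1e-3))
            else:
                # no baseline records: fall back to a weak default prior
                mu_sd[hc] = (default_mu, 0.05)
        base_mu_l.append(mu_sd[HeightClass.LOW][0])
        base_sd_l.append(mu_sd[HeightClass.LOW][1])
        base_mu_h.append(mu_sd[HeightClass.HIGH][0])
        base_sd_h.append(mu_sd[HeightClass.HIGH][1])

    return FitData(
        participant_ids=list(pids),
        groups=groups,
        group_idx=np.array([_GROUP_ORDER.index(g) for g in groups], dtype=np.int64),
        heights=np.concatenate(heights_l),
        fc_obs=np.concatenate(fc_l),
        lik_mask=np.concatenate(mask_l),
        h_lo=np.concatenate(hlo_l),
        h_hi=np.concatenate(hhi_l),
        offsets=np.array(offsets, dtype=np.int64),
        base_mu_l=np.array(base_mu_l),
        base_mu_h=np.array(base_mu_h),
        base_sd_l=np.array(base_sd_l),
        base_sd_h=np.array(base_sd_h),
    )
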