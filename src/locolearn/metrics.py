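"""Behavioral performance metrics and learning-parameter associations.

Per-trial performance error is the absolute distance from the observed
foot clearance to the nearer success-range threshold (zero inside the
range).  Online improvement is the change in mean error from baseline to
the Day-1 no-feedback bout (negative = improvement); the overnight
retention delta is the change from the end of Day-1 practice (the final
bout) to the Day-2 retention trials (positive = forgetting).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_model import (
    DEFAULT_OBSTACLES,
    HeightClass,
    ObstacleSpec,
    OutputVariant,
    ParticipantParams,
    Phase,
    compute_error,
    simulate_sequence,
)

__all__ = [
    "PerformanceSummary",
    "performance_error",
    "summarize_participant",
    "summarize_cohort",
    "association_models",
]


@dataclass
class PerformanceSummary:
    """Per-participant behavioral summary; absent phases leave fields None."""

    participant_id: str
    group: str | None = None
    phase_height_error: dict = field(default_factory=dict)
    baseline_error: float | None = None
    no_feedback_error: float | None = None
    end_practice_error: float | None = None
    retention_error: float | None = None
    online_improvement: float | None = None
    retention_delta: float | None = None
    model_end_error: float | None = None

    def as_dict(self) -> dict:
        d = {
            "participant_id": self.participant_id,
            "group": self.group,
            "baseline_error": self.baseline_error,
            "no_feedback_error": self.no_feedback_error,
            "end_practice_error": self.end_practice_error,
            "retention_error": self.retention_error,
            "online_improvement": self.online_improvement,
            "retention_delta": self.retention_delta,
            "model_end_error": self.model_end_error,
        }
        for (phase, height), v in self.phase_height_error.items():
            d[f"err_{phase.lower()}_{height.lower()}"] = v
        return d


def performance_error(fc: float, spec: ObstacleSpec) -> float:
    """Absolute distance to the nearer success-range threshold (0 inside)."""
    return abs(compute_error(fc, spec))


def _spec_for(height: str, obstacles) -> ObstacleSpec:
    return obstacles[HeightClass(height)]


def _mean_pe(frame: pd.DataFrame, obstacles) -> float | None:
    vals = [
        performance_error(fc, _spec_for(h, obstacles))
        for fc, h in zip(frame["fc_observed"], frame["height_class"])
        if fc is not None and math.isfinite(fc)
    ]
    return float(np.mean(vals)) if vals else None


def summarize_participant(
    trials: pd.DataFrame,
    obstacles: dict[HeightClass, ObstacleSpec] | None = None,
    model_params: ParticipantParams | None = None,
    output_variant: OutputVariant = OutputVariant.DOT,
    end_practice_bout: int | None = None,
) -> PerformanceSummary:
    """Phase x height mean performance errors and the derived deltas.

    ``model_params`` (typically posterior medians) enables
    ``model_end_error``: the mean performance error of the noiseless model
    output over the final acquisition bout.
    """
    obstacles = obstacles or DEFAULT_OBSTACLES
    pid = trials["participant_id"].iloc[0]
    if (trials["participant_id"] != pid).any():
        raise ValueError("expected trials for exactly one participant")
    group = trials["group"].iloc[0] if "group" in trials else None
    s = PerformanceSummary(participant_id=str(pid), group=group)

    for (phase, height), sub in trials.groupby(["phase", "height_class"]):
        v = _mean_pe(sub, obstacles)
        if v is not None:
            s.phase_height_error[(phase, height)] = v

    by_phase = {phase: sub for phase, sub in trials.groupby("phase")}
    if Phase.BASELINE.value in by_phase:
        s.baseline_error = _mean_pe(by_phase[Phase.BASELINE.value], obstacles)
    if Phase.NO_FEEDBACK.value in by_phase:
        s.no_feedback_error = _mean_pe(by_phase[Phase.NO_FEEDBACK.value], obstacles)
    if Phase.RETENTION.value in by_phase:
        s.retention_error = _mean_pe(by_phase[Phase.RETENTION.value], obstacles)

    acq = trials[trials["phase"].isin([Phase.ACQUISITION.value, Phase.NO_FEEDBACK.value])]
    if not acq.empty:
        last_bout = end_practice_bout if end_practice_bout is not None else acq["bout"].max()
        s.end_practice_error = _mean_pe(acq[acq["bout"] == last_bout], obstacles)

    if s.baseline_error is not None and s.no_feedback_error is not None:
        s.online_improvement = s.no_feedback_error - s.baseline_error
    if s.end_practice_error is not None and s.retention_error is not None:
        s.retention_delta = s.retention_error - s.end_practice_error

    if model_params is not None and not acq.empty:
        acq_sorted = acq.sort_values("obstacle_index")
        schedule = [_spec_for(h, obstacles) for h in acq_sorted["height_class"]]
        sim = simulate_sequence(model_params, schedule, noise="none", variant=output_variant)
        last_bout = end_practice_bout if end_practice_bout is not None else acq["bout"].max()
        in_last = (acq_sorted["bout"] == last_bout).to_numpy()
        pes = [
            performance_error(r.fc_est, spec)
            for r, spec, keep in zip(sim, schedule, in_last)
            if keep
        ]
        s.model_end_error = float(np.mean(pes)) if pes else None
    return s


def summarize_cohort(
    trials: pd.DataFrame,
    obstacles: dict[HeightClass, ObstacleSpec] | None = None,
    participant_params: pd.DataFrame | None = None,
    output_variant: OutputVariant = OutputVariant.DOT,
) -> pd.DataFrame:
    """Per-participant summaries as a flat table.

    ``participant_params`` (e.g. ``PosteriorDraws.participant_medians()``)
    supplies B/q/tau/k/x1 columns used for the model-based end-of-practice
    error and carried into the output for the association regressions.
    """
    rows = []
    for pid, sub in trials.groupby("participant_id"):
        mp = None
        extra = {}
        if participant_params is not None:
            match = participant_params[participant_params["participant_id"] == pid]
            if len(match) == 1:
                r = match.iloc[0]
                mp = ParticipantParams(
                    B=float(np.clip(r["B"], 0.0, 1.0)),
                    q=float(np.clip(r.get("q", 0.0), 0.0, 1.0)),
                    tau=float(r["tau"]), k=float(r["k"]),
                    x1_low=float(r["x1_low"]), x1_high=float(r["x1_high"]),
                )
                extra = {"B": float(r["B"]), "q": float(r.get("q", 0.0))}
        summary = summarize_participant(
            sub, obstacles, model_params=mp, output_variant=output_variant
        )
        rows.append({**summary.as_dict(), **extra})
    return pd.DataFrame(rows)


def _check_design(exog: pd.DataFrame) -> None:
    x = exog.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify columns whose removal does not reduce the rank
        collinear = [
            c for i, c in enumerate(exog.columns)
            if np.linalg.matrix_rank(np.delete(x, i, axis=1)) == rank
        ]
        raise ValueError(f"rank-deficient design; collinear terms: {collinear}")


def association_models(summaries: pd.DataFrame) -> dict[str, dict]:
    """OLS association fits between learning parameters and behavior.

    Fits (a) online_improvement ~ B * group, (b) retention_delta ~
    q * group, and (c) retention_error ~ model_end_error, returning
    coefficients, t statistics, p values and adjusted R^2 per model.
    Requires at least 3 participants per group.
    """
    import statsmodels.formula.api as smf

    counts = summaries.groupby("group")["participant_id"].count()
    if (counts < 3).any() or len(counts) < 2:
        raise ValueError("need at least 3 participants in each of two groups")

    specs = {
        "online_improvement_vs_B": ("online_improvement ~ B * C(group)", ["B"]),
        "retention_delta_vs_q": ("retention_delta ~ q * C(group)", ["q"]),
        "retention_vs_model_end_error": ("retention_error ~ model_end_error", ["model_end_error"]),
    }
    out: dict[str, dict] = {}
    for label, (formula, needed) in specs.items():
        cols = [c for c in needed if c in summaries.columns]
        if len(cols) < len(needed):
            continue
        df = summaries.dropna(subset=needed + [formula.split("~")[0].strip()])
        model = smf.ols(formula, data=df)
        _check_design(pd.DataFrame(model.exog, columns=model.exog_names))
        res = model.fit()
        out[label] = {
            "formula": formula,
            "n": int(res.nobs),
            "coef": dict(res.params),
            "t": dict(res.tvalues),
            "p": dict(res.pvalues),
            "adj_r2": float(res.rsquared_adj),
        }
    return out
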