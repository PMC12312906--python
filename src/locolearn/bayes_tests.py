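"""Population-level Bayesian hypothesis tests.

Probability of direction on group-difference draws (control minus PD on
the sigmoid scale) and ROPE testing on standardized effect-size draws
computed from the untransformed hyper-parameters.

Note the probability of direction here follows the trim-then-count recipe:
draws outside the central 95% credible interval are discarded before the
sign fractions are computed.  The conventional untrimmed definition is
available via ``trim=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .inference import PosteriorDraws

__all__ = [
    "DirectionResult",
    "RopeResult",
    "GroupContrast",
    "probability_of_direction",
    "effect_size_draws",
    "rope_test",
    "group_contrast",
]

DEFAULT_ROPE = (-0.1, 0.1)


@dataclass(frozen=True)
class DirectionResult:
    pd: float                  # probability of direction, in [0.5, 1]
    direction: str             # "pd_greater" | "control_greater" | "undefined"
    frac_below_zero: float
    frac_above_zero: float
    trimmed: bool

    @property
    def pd_percent(self) -> float:
        return 100.0 * self.pd


@dataclass(frozen=True)
class RopeResult:
    frac_outside: float
    frac_inside: float
    verdict: str               # "meaningful" | "negligible" | "inconclusive"
    rope: tuple[float, float]


def probability_of_direction(
    diff_draws: np.ndarray,
    trim: bool = True,
    ci: float = 0.95,
    hdi: bool = False,
) -> DirectionResult:
    """Dominant-sign posterior probability of a group difference.

    With ``trim=True`` (the default recipe) draws outside the central
    equal-tailed ``ci`` interval are discarded first; ``hdi=True`` trims to
    the highest-density interval instead.  Negative differences mean the
    parameter is greater in the PD group (differences are control - PD).
    """
    draws = np.asarray(diff_draws, dtype=float)
    if draws.size < 100:
        raise ValueError("need at least 100 draws")
    if not np.all(np.isfinite(draws)):
        raise ValueError("diff_draws must be finite")
    if trim:
        if hdi:
            import arviz as az

            lo, hi = az.hdi(draws, hdi_prob=ci)
        else:
            alpha = (1.0 - ci) / 2.0
            lo, hi = np.quantile(draws, [alpha, 1.0 - alpha])
        kept = draws[(draws >= lo) & (draws <= hi)]
    else:
        kept = draws
    if np.all(kept == 0.0):
        raise ValueError("all retained draws are exactly zero; direction undefined")
    below = float(np.mean(kept < 0))
    above = float(np.mean(kept > 0))
    if below >= above:
        return DirectionResult(below, "pd_greater", below, above, trim)
    return DirectionResult(above, "control_greater", below, above, trim)


def effect_size_draws(
    theta_a: np.ndarray,
    sigma_a: np.ndarray,
    theta_b: np.ndarray,
    sigma_b: np.ndarray,
) -> np.ndarray:
    """Standardized effect size per draw: (theta_a - theta_b) / pooled SD."""
    theta_a, sigma_a, theta_b, sigma_b = (
        np.asarray(v, dtype=float) for v in (theta_a, sigma_a, theta_b, sigma_b)
    )
    if not (theta_a.shape == sigma_a.shape == theta_b.shape == sigma_b.shape):
        raise ValueError("draw vectors must be aligned and equal length")
    if np.any(sigma_a <= 0) or np.any(sigma_b <= 0):
        raise ValueError("sigma draws must be strictly positive")
    return (theta_a - theta_b) / np.sqrt((sigma_a**2 + sigma_b**2) / 2.0)


def rope_test(es_draws: np.ndarray, rope: tuple[float, float] = DEFAULT_ROPE) -> RopeResult:
    """Fraction of effect-size draws outside the region of practical
    equivalence, with a strong-evidence verdict at the 95% level."""
    lo, hi = rope
    if lo >= hi:
        raise ValueError(f"invalid ROPE interval [{lo}, {hi}]")
    draws = np.asarray(es_draws, dtype=float)
    if draws.size == 0 or not np.all(np.isfinite(draws)):
        raise ValueError("es_draws must be non-empty and finite")
    outside = float(np.mean((draws < lo) | (draws > hi)))
    inside = 1.0 - outside
    if outside >= 0.95:
        verdict = "meaningful"
    elif inside >= 0.95:
        verdict = "negligible"
    else:
        verdict = "inconclusive"
    return RopeResult(outside, inside, verdict, (lo, hi))


@dataclass(frozen=True)
class GroupContrast:
    """Full contrast report for one learning parameter (control vs PD)."""

    parameter: str
    diff_draws: np.ndarray
    es_draws: np.ndarray
    direction: DirectionResult
    rope: RopeResult
    median_diff: float = field(default=np.nan)

    def summary(self) -> dict:
        return {
            "parameter": self.parameter,
            "pd_percent": self.direction.pd_percent,
            "direction": self.direction.direction,
            "median_diff": self.median_diff,
            "diff_ci95": list(np.quantile(self.diff_draws, [0.025, 0.975])),
            "es_median": float(np.median(self.es_draws)),
            "frac_outside_rope": self.rope.frac_outside,
            "rope_verdict": self.rope.verdict,
            "rope": list(self.rope.rope),
        }


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def group_contrast(
    draws: PosteriorDraws,
    parameter: str = "B",
    rope: tuple[float, float] = DEFAULT_ROPE,
    trim: bool = True,
) -> GroupContrast:
    """Control-minus-PD contrast of a population parameter from one fit.

    The difference draws use the sigmoid-transformed location
    hyper-parameters; the effect-size draws use the untransformed location
    and scale hyper-parameters.
    """
    name = {"B": ("theta_B", "sigma_B"), "q": ("theta_q", "sigma_q")}.get(parameter)
    if name is None:
        raise ValueError("parameter must be 'B' or 'q'")
    theta_name, sigma_name = name
    if theta_name not in draws.ds:
        raise ValueError(f"fit does not estimate {theta_name} (variant {draws.variant.value})")
    th_c = draws.group_draws(theta_name, "CONTROL")
    th_p = draws.group_draws(theta_name, "PD")
    sg_c = draws.group_draws(sigma_name, "CONTROL")
    sg_p = draws.group_draws(sigma_name, "PD")
    diff = _sigmoid(th_c) - _sigmoid(th_p)
    es = effect_size_draws(th_c, sg_c, th_p, sg_p)
    return GroupContrast(
        parameter=parameter,
        diff_draws=diff,
        es_draws=es,
        direction=probability_of_direction(diff, trim=trim),
        rope=rope_test(es, rope),
        median_diff=float(np.median(diff)),
    )
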