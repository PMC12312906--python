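"""MCMC convergence diagnostics: split R-hat and rank-normalized R-hat.

The split R-hat here is implemented directly (it is the reported
convergence gate, R-hat < 1.05); the rank-normalized variant is delegated
to :mod:`arviz` and serves as an independent cross-check.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .sampler import PosteriorDraws

__all__ = ["split_rhat", "diagnose", "RHAT_THRESHOLD"]

RHAT_THRESHOLD = 1.05


def split_rhat(chains: np.ndarray) -> float:
    """Split potential scale reduction factor for one scalar parameter.

    ``chains`` has shape (n_chains, n_draws).  Each chain is split in half;
    R-hat compares between- and within-half variances.  Returns NaN (with a
    warning) for degenerate, zero-variance input.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2:
        raise ValueError("expected (n_chains, n_draws) array")
    m, n = chains.shape
    if m < 2 and n < 4:
        raise ValueError("need at least 2 chains or 4 draws to split")
    half = n // 2
    halves = np.concatenate([chains[:, :half], chains[:, half: 2 * half]], axis=0)
    w = halves.var(axis=1, ddof=1).mean()
    if w == 0 or not np.isfinite(w):
        warnings.warn("zero within-chain variance; R-hat undefined", RuntimeWarning)
        return float("nan")
    b = half * halves.mean(axis=1).var(ddof=1)
    var_hat = (half - 1) / half * w + b / half
    return float(np.sqrt(var_hat / w))


def _rank_normalized_rhat(chains: np.ndarray) -> float:
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = az.rhat(az.convert_to_dataset(np.asarray(chains)), method="rank")
    return float(res["x"].values)


def diagnose(draws: PosteriorDraws) -> pd.DataFrame:
    """R-hat table for every scalar component of the posterior.

    Returns one row per parameter with split R-hat and rank-normalized
    R-hat; the frame's ``attrs["converged"]`` flag is True when every
    defined split R-hat is below 1.05.
    """
    if draws.n_chains < 2:
        raise ValueError("diagnosis requires at least 2 chains")
    rows = []
    for name, mat in draws.scalar_table().items():
        rs = split_rhat(mat)
        rr = _rank_normalized_rhat(mat)
        rows.append({"parameter": name, "rhat_split": rs, "rhat_rank": rr})
    table = pd.DataFrame(rows)
    finite = table["rhat_split"].dropna()
    table.attrs["converged"] = bool((finite < RHAT_THRESHOLD).all()) if len(finite) else False
    table.attrs["threshold"] = RHAT_THRESHOLD
    return table
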