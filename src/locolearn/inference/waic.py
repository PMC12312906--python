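"""WAIC model comparison from pointwise posterior log likelihoods."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import FitData, HierarchicalModelSpec, prepare_fit_data
from .sampler import PosteriorDraws, pointwise_loglik

__all__ = ["compute_waic", "waic_compare"]


def compute_waic(pointwise: np.ndarray) -> dict[str, float]:
    """WAIC = -2 (lppd - p_waic) from an (n_draws, n_obs) log-lik matrix.

    lppd is the summed log of draw-averaged pointwise likelihoods
    (computed stably with log-sum-exp); p_waic is the summed posterior
    variance of pointwise log likelihoods.
    """
    pointwise = np.asarray(pointwise, dtype=float)
    if pointwise.ndim != 2 or pointwise.size == 0:
        raise ValueError("expected a non-empty (n_draws, n_obs) matrix")
    n_draws = pointwise.shape[0]
    mx = pointwise.max(axis=0)
    lppd = float(np.sum(mx + np.log(np.exp(pointwise - mx).mean(axis=0))))
    p_waic = float(pointwise.var(axis=0, ddof=1).sum())
    waic = -2.0 * (lppd - p_waic)
    return {"waic": waic, "lppd": lppd, "p_waic": p_waic, "elpd_waic": lppd - p_waic}


def waic_compare(
    data: pd.DataFrame,
    spec_list: list[HierarchicalModelSpec],
    fits: list[PosteriorDraws],
    labels: list[str] | None = None,
) -> pd.DataFrame:
    """Rank fitted model variants by WAIC (lower is better).

    All fits must be on the identical likelihood data; mismatched
    observation sets raise.
    """
    if len(spec_list) != len(fits):
        raise ValueError("spec_list and fits must align")
    labels = labels or [s.variant.value for s in spec_list]
    fingerprints = []
    rows = []
    for label, spec, draws in zip(labels, spec_list, fits):
        fd = prepare_fit_data(data, spec)
        fingerprints.append(fd.data_fingerprint())
        attrs = draws.ds.attrs
        if "n_obs" in attrs:
            if int(attrs["n_obs"]) != fd.n_obs or not np.isclose(
                float(attrs["obs_sum"]), fd.data_fingerprint()[1]
            ):
                raise ValueError(
                    f"fit {label!r} was not computed on the supplied data"
                )
        lp = pointwise_loglik(draws, fd, spec)
        res = compute_waic(lp)
        res["model"] = label
        rows.append(res)
    if len(set(fingerprints)) > 1:
        raise ValueError("fits were not computed on identical data")
    table = pd.DataFrame(rows).sort_values("waic").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table[["rank", "model", "waic", "lppd", "p_waic", "elpd_waic"]]
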