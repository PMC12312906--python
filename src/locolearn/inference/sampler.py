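"""Fitting the hierarchical model and the PosteriorDraws container."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

from ..core_model import HeightClass, OutputVariant, ParticipantParams, Phase
from . import _kernels
from .model import (
    FitData,
    HierarchicalModelSpec,
    MCMCSettings,
    ModelVariant,
    prepare_fit_data,
)

__all__ = ["PosteriorDraws", "fit", "log_likelihood", "pointwise_loglik"]

_MODE_CODE = {
    ModelVariant.FULL: _kernels.MODE_FULL,
    ModelVariant.B_ONLY: _kernels.MODE_B_ONLY,
    ModelVariant.Q_ONLY: _kernels.MODE_Q_ONLY,
}


def _sigmoid(x):
    # clipped so constrained draws stay strictly inside (0, 1) even when the
    # unconstrained chain wanders into float saturation
    with np.errstate(over="ignore"):
        s = 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))
    return np.clip(s, 1e-12, 1.0 - 1e-12)


class PosteriorDraws:
    """Labeled MCMC draws (chain x draw x parameter) with run metadata.

    Wraps an :class:`xarray.Dataset`; participant-level variables carry a
    ``participant`` dimension, group-level hyper-parameters a ``group``
    dimension, and scalars only ``(chain, draw)``.
    """

    def __init__(self, dataset: xr.Dataset):
        self.ds = dataset

    # -- metadata ---------------------------------------------------------
    @property
    def variant(self) -> ModelVariant:
        return ModelVariant(self.ds.attrs["variant"])

    @property
    def output_variant(self) -> OutputVariant:
        return OutputVariant(self.ds.attrs["output_variant"])

    @property
    def n_chains(self) -> int:
        return self.ds.sizes["chain"]

    @property
    def n_draws_per_chain(self) -> int:
        return self.ds.sizes["draw"]

    @property
    def participant_ids(self) -> list[str]:
        return [str(v) for v in self.ds["participant"].values]

    @property
    def participant_groups(self) -> list[str]:
        return [str(v) for v in self.ds.attrs["participant_groups"]]

    # -- access -----------------------------------------------------------
    def flat(self, name: str) -> np.ndarray:
        """All draws of a variable with chain and draw dims flattened first."""
        da = self.ds[name]
        return da.stack(sample=("chain", "draw")).transpose("sample", ...).values

    def group_draws(self, name: str, group: str) -> np.ndarray:
        """Flattened draws of a group-level hyper-parameter for one group."""
        return self.flat(name)[:, list(self.ds["group"].values).index(group)]

    def participant_medians(self) -> pd.DataFrame:
        """Posterior medians of participant-level parameters."""
        cols = {"participant_id": self.participant_ids, "group": self.participant_groups}
        for name in ("B", "q", "tau", "k", "x1_low", "x1_high"):
            if name in self.ds:
                if "participant" in self.ds[name].dims:
                    cols[name] = np.median(self.flat(name), axis=0)
                else:
                    cols[name] = np.full(
                        len(self.participant_ids), float(np.median(self.flat(name)))
                    )
        return pd.DataFrame(cols)

    def scalar_table(self) -> pd.DataFrame:
        """Every scalar posterior dimension as a (chain, draw) matrix table."""
        rows = {}
        for name, da in self.ds.data_vars.items():
            if set(da.dims) == {"chain", "draw"}:
                rows[name] = da.values
            else:
                extra = [d for d in da.dims if d not in ("chain", "draw")][0]
                for i, lab in enumerate(self.ds[extra].values):
                    rows[f"{name}[{lab}]"] = da.isel({extra: i}).values
        return rows

    # -- persistence ------------------------------------------------------
    def to_netcdf(self, path: str | Path) -> None:
        ds = self.ds.copy()
        ds.attrs = {k: _attr_encode(v) for k, v in self.ds.attrs.items()}
        ds.to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path: str | Path) -> "PosteriorDraws":
        ds = xr.load_dataset(path, engine="scipy")
        ds.attrs = {k: _attr_decode(v) for k, v in ds.attrs.items()}
        ds.attrs["include_no_feedback"] = bool(ds.attrs.get("include_no_feedback", True))
        return cls(ds)

    def to_csv(self, path: str | Path) -> None:
        """Long-format plain-CSV export: chain,draw,parameter,value."""
        frames = []
        for name, mat in self.scalar_table().items():
            n_chain, n_draw = mat.shape
            frames.append(
                pd.DataFrame(
                    {
                        "chain": np.repeat(np.arange(n_chain), n_draw),
                        "draw": np.tile(np.arange(n_draw), n_chain),
                        "parameter": name,
                        "value": mat.ravel(),
                    }
                )
            )
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def _attr_encode(v):
    """scipy's netCDF3 writer only takes scalars/strings; lists go as JSON."""
    if isinstance(v, (list, tuple)):
        import json

        return "json:" + json.dumps(list(v))
    if isinstance(v, bool):
        return int(v)
    return v


def _attr_decode(v):
    if isinstance(v, str) and v.startswith("json:"):
        import json

        return json.loads(v[5:])
    if isinstance(v, bytes):
        v = v.decode()
        if v.startswith("json:"):
            import json

            return json.loads(v[5:])
    return v


def fit(
    data: pd.DataFrame | FitData,
    spec: HierarchicalModelSpec | None = None,
    mcmc: MCMCSettings | None = None,
) -> PosteriorDraws:
    """Sample the hierarchical posterior by adaptive Metropolis-within-Gibbs.

    Participant blocks are updated by random walk on the unconstrained
    (logit/log) scale; group location/scale hyper-parameters and the
    baseline scaling k use exact Gibbs conditionals; the shared Student-t
    degrees of freedom uses a log-scale random walk.  Chains run
    sequentially with seeds derived from ``mcmc.seed``.
    """
    spec = spec or HierarchicalModelSpec()
    mcmc = mcmc or MCMCSettings()
    fd = data if isinstance(data, FitData) else prepare_fit_data(data, spec)

    mode = _MODE_CODE[spec.variant]
    select = 1 if spec.output_variant is OutputVariant.SELECT else 0
    pr = spec.priors

    chains = []
    acc_rates = []
    for c in range(mcmc.n_chains):
        chain_seed = (mcmc.seed * 1_000_003 + 7919 * c + 1) % (2**31 - 1)
        out = _kernels.run_chain(
            fd.heights, fd.fc_obs, fd.lik_mask, fd.h_lo, fd.h_hi, fd.offsets,
            fd.group_idx, fd.base_mu_l, fd.base_mu_h, fd.base_sd_l, fd.base_sd_h,
            mode, select,
            pr.theta_sd, pr.sigma_a, pr.sigma_b, pr.tau_sd, pr.k_sd,
            pr.nu_a, pr.nu_b, pr.nu_floor, pr.nu_cap,
            mcmc.n_iter, mcmc.burn_in, mcmc.thin, chain_seed,
        )
        chains.append(out[:-1])
        acc_rates.append(float(out[-1]))

    P = fd.n_participants
    stack = lambda i: np.stack([ch[i] for ch in chains])  # noqa: E731
    btil, qtil, logtau, k, x1l, x1h = (stack(i) for i in range(6))
    thetaB, sigB, thetaQ, sigQ = (stack(i) for i in range(6, 10))
    nu = stack(10)

    coords = {
        "chain": np.arange(mcmc.n_chains),
        "draw": np.arange(btil.shape[1]),
        "participant": fd.participant_ids,
        "group": ["CONTROL", "PD"],
    }
    dv = {}
    pdims = ("chain", "draw", "participant")
    gdims = ("chain", "draw", "group")
    if spec.variant is ModelVariant.Q_ONLY:
        dv["B"] = (("chain", "draw"), _sigmoid(btil[:, :, 0]))
    else:
        dv["B"] = (pdims, _sigmoid(btil))
        dv["theta_B"] = (gdims, thetaB)
        dv["sigma_B"] = (gdims, sigB)
    if spec.variant is not ModelVariant.B_ONLY:
        dv["q"] = (pdims, _sigmoid(qtil))
        dv["theta_q"] = (gdims, thetaQ)
        dv["sigma_q"] = (gdims, sigQ)
    dv["tau"] = (pdims, np.exp(logtau))
    dv["k"] = (pdims, k)
    dv["x1_low"] = (pdims, x1l)
    dv["x1_high"] = (pdims, x1h)
    dv["nu"] = (("chain", "draw"), nu)

    ds = xr.Dataset(dv, coords=coords)
    ds.attrs.update(
        variant=spec.variant.value,
        output_variant=spec.output_variant.value,
        include_no_feedback=spec.include_no_feedback,
        n_chains=mcmc.n_chains,
        n_iter=mcmc.n_iter,
        burn_in=mcmc.burn_in,
        thinning=mcmc.thin,
        seed=mcmc.seed,
        participant_groups=list(fd.groups),
        acceptance_rates=acc_rates,
        n_obs=fd.n_obs,
        obs_sum=fd.data_fingerprint()[1],
    )
    return PosteriorDraws(ds)


def log_likelihood(
    trials: pd.DataFrame,
    params: ParticipantParams,
    nu: float,
    output_variant: OutputVariant = OutputVariant.DOT,
    include_no_feedback: bool = True,
    obstacles=None,
) -> tuple[float, np.ndarray]:
    """Student-t log likelihood of one participant's acquisition trials.

    Runs the deterministic forward model to obtain fc_est per trial and
    returns ``(total, pointwise)`` where missing observations contribute 0.
    """
    from ..core_model import DEFAULT_OBSTACLES

    obstacles = obstacles or DEFAULT_OBSTACLES
    if trials["participant_id"].nunique() != 1:
        raise ValueError("expected trials for exactly one participant")
    phases = [Phase.ACQUISITION.value, Phase.NO_FEEDBACK.value]
    sub = trials[trials["phase"].isin(phases)]
    idx = sub["obstacle_index"].to_numpy()
    if not np.all(np.diff(idx) > 0):
        raise ValueError("trials must be sorted by obstacle_index")
    schedule = [
        obstacles[HeightClass(h)] for h in sub["height_class"]
    ]
    from ..core_model import simulate_sequence

    sim = simulate_sequence(params, schedule, noise="none", variant=output_variant)
    fc_est = np.array([r.fc_est for r in sim])
    fc_obs = sub["fc_observed"].to_numpy(dtype=float)
    use = np.isfinite(fc_obs)
    if not include_no_feedback:
        use &= (sub["phase"] != Phase.NO_FEEDBACK.value).to_numpy()
    pointwise = np.zeros(len(sub))
    pointwise[use] = stats.t.logpdf(fc_obs[use], df=nu, loc=fc_est[use], scale=params.tau)
    return float(pointwise.sum()), pointwise


def pointwise_loglik(draws: PosteriorDraws, fd: FitData, spec: HierarchicalModelSpec) -> np.ndarray:
    """(n_total_draws, n_obs) pointwise log likelihood matrix for WAIC."""
    P = fd.n_participants
    n = draws.flat("tau").shape[0]
    B = draws.flat("B")
    if B.ndim == 1:  # shared learning rate (Q_ONLY)
        B = np.repeat(B[:, None], P, axis=1)
    if "q" in draws.ds:
        q = draws.flat("q")
    else:
        q = np.zeros((n, P))
    return _kernels.pointwise_loglik_draws(
        fd.heights, fd.fc_obs, fd.lik_mask, fd.h_lo, fd.h_hi, fd.offsets,
        1 if spec.output_variant is OutputVariant.SELECT else 0,
        np.ascontiguousarray(B), np.ascontiguousarray(q),
        np.ascontiguousarray(draws.flat("tau")),
        np.ascontiguousarray(draws.flat("x1_low")),
        np.ascontiguousarray(draws.flat("x1_high")),
        np.ascontiguousarray(draws.flat("nu")),
    )
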