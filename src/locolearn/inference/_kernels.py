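"""Numba kernels for the hierarchical sampler.

Everything here operates on flat arrays; the public API lives in
``locolearn.inference``.  Participants are concatenated: trial arrays are
indexed by ``offsets[p]:offsets[p+1]``.  Height codes are 0 (LOW) / 1
(HIGH).  Model modes: 0 = FULL, 1 = B_ONLY (q fixed at 0), 2 = Q_ONLY
(one learning rate shared by all participants).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

MODE_FULL = 0
MODE_B_ONLY = 1
MODE_Q_ONLY = 2


@njit(cache=True)
def _t_logpdf(r, tau, nu):
    """log density of a Student-t(nu) with location 0 and scale tau at r."""
    z = r / tau
    return (
        math.lgamma(0.5 * (nu + 1.0))
        - math.lgamma(0.5 * nu)
        - 0.5 * math.log(nu * math.pi)
        - math.log(tau)
        - 0.5 * (nu + 1.0) * math.log(1.0 + z * z / nu)
    )


@njit(cache=True)
def _norm_logpdf(x, mu, sd):
    z = (x - mu) / sd
    return -0.5 * z * z - math.log(sd) - 0.9189385332046727


@njit(cache=True)
def forward_resid(
    heights, fc_obs, lik_mask, h_lo, h_hi, start, stop,
    select, B, q, x1l, x1h, resid,
):
    """Forward-simulate one participant, writing observation residuals.

    ``resid[i]`` = fc_obs[i] - fc_est[i] for likelihood-contributing trials,
    NaN otherwise.  The update error is computed from the noiseless fc_est.
    """
    xl = x1l
    xh = x1h
    for i in range(start, stop):
        if heights[i] == 0:
            fc = xl if select else xl + q * xh
            w_l = 1.0
            w_h = q
        else:
            fc = xh if select else q * xl + xh
            w_l = q
            w_h = 1.0
        if fc > h_hi[i]:
            e = h_hi[i] - fc
        elif fc < h_lo[i]:
            e = h_lo[i] - fc
        else:
            e = 0.0
        if lik_mask[i] == 1:
            resid[i] = fc_obs[i] - fc
        else:
            resid[i] = np.nan
        step = B * e
        xl += step * w_l
        xh += step * w_h


@njit(cache=True)
def participant_loglik(
    heights, fc_obs, lik_mask, h_lo, h_hi, start, stop,
    select, B, q, x1l, x1h, tau, nu, resid,
):
    """Student-t log likelihood of one participant; fills ``resid``."""
    forward_resid(
        heights, fc_obs, lik_mask, h_lo, h_hi, start, stop, select, B, q, x1l, x1h, resid
    )
    total = 0.0
    for i in range(start, stop):
        if not np.isnan(resid[i]):
            total += _t_logpdf(resid[i], tau, nu)
    return total


@njit(cache=True)
def _sigmoid(x):
    if x >= 0.0:
        return 1.0 / (1.0 + math.exp(-x))
    ex = math.exp(x)
    return ex / (1.0 + ex)


@njit(cache=True)
def _trunc_normal_pos(mu, sd):
    """Draw from Normal(mu, sd) truncated to [0, inf)."""
    if mu / sd > -4.0:
        for _ in range(1000):
            v = mu + sd * np.random.standard_normal()
            if v >= 0.0:
                return v
        return abs(mu) * 1e-12
    # far-tail case: exponential rejection (Robert 1995) at the boundary
    a = -mu / sd
    alpha = 0.5 * (a + math.sqrt(a * a + 4.0))
    while True:
        z = a + np.random.exponential(1.0 / alpha)
        rho = math.exp(-0.5 * (z - alpha) * (z - alpha))
        if np.random.random() <= rho:
            return mu + sd * z


@njit(cache=True)
def _half_normal_logpdf_from_log(logv, sd):
    """Prior log-density for a positive scale sampled on the log scale.

    Normal(0, sd) truncated to v > 0, plus the log-scale Jacobian.
    """
    v = math.exp(logv)
    return _norm_logpdf(v, 0.0, sd) + math.log(2.0) + logv


@njit(cache=True)
def _invgamma_logpdf(x, a, b):
    return a * math.log(b) - math.lgamma(a) - (a + 1.0) * math.log(x) - b / x


@njit(cache=True)
def run_chain(
    heights, fc_obs, lik_mask, h_lo, h_hi, offsets, group_idx,
    base_mu_l, base_mu_h, base_sd_l, base_sd_h,
    mode, select,
    theta_sd, sig_a, sig_b, tau_sd, k_sd, nu_a, nu_b, nu_floor, nu_cap,
    n_iter, burn_in, thin, seed,
):
    """One MCMC chain: adaptive Metropolis-within-Gibbs.

    Per-participant blocks (b~, q~, log tau, x1_low, x1_high) use an adaptive
    random-walk (adapted during burn-in only); k and the group hyper-
    parameters have exact Gibbs conditionals; nu uses a random walk on
    log(nu - nu_floor).  Returns thinned post-burn-in draws.
    """
    np.random.seed(seed)
    P = len(offsets) - 1
    N = len(heights)
    G = 2

    # --- initial values (jittered for chain dispersion) ---
    btil = np.empty(P)
    qtil = np.empty(P)
    logtau = np.empty(P)
    kk = np.empty(P)
    x1l = np.empty(P)
    x1h = np.empty(P)
    for p in range(P):
        btil[p] = -2.0 + 0.5 * np.random.standard_normal()
        qtil[p] = -1.0 + 0.5 * np.random.standard_normal()
        logtau[p] = math.log(0.03) + 0.2 * np.random.standard_normal()
        kk[p] = 1.0
        x1l[p] = base_mu_l[p] + 0.25 * base_sd_l[p] * np.random.standard_normal()
        x1h[p] = base_mu_h[p] + 0.25 * base_sd_h[p] * np.random.standard_normal()
    if mode == MODE_B_ONLY:
        for p in range(P):
            qtil[p] = -1e10  # q == 0 exactly via sigmoid underflow guard below
    theta_B = np.zeros(G)
    sig_B = np.ones(G)
    theta_q = np.zeros(G)
    sig_q = np.ones(G)
    nu = nu_floor + 4.0 + abs(np.random.standard_normal())

    resid = np.empty(N)
    resid_prop = np.empty(N)
    loglik_p = np.empty(P)
    for p in range(P):
        q_p = 0.0 if mode == MODE_B_ONLY else _sigmoid(qtil[p])
        b_p = _sigmoid(btil[0]) if mode == MODE_Q_ONLY else _sigmoid(btil[p])
        loglik_p[p] = participant_loglik(
            heights, fc_obs, lik_mask, h_lo, h_hi, offsets[p], offsets[p + 1],
            select, b_p, q_p, x1l[p], x1h[p], math.exp(logtau[p]), nu, resid,
        )

    # adaptive step sizes (log scale): joint block, B/q pair and x1 pair
    # refreshes per participant, plus shared-B and nu walks
    log_step = np.full((3, P), math.log(0.1))
    log_step_tau = np.full(P, math.log(0.2))
    log_step_shared = math.log(0.05)
    log_step_nu = math.log(0.5)
    target = 0.25
    # proposal preconditioner for (btil, qtil, logtau, x1l, x1h)
    scale0 = 1.0
    scale1 = 1.0
    scale2 = 0.3
    scale3 = 0.02
    scale4 = 0.02

    n_keep = (n_iter - burn_in + thin - 1) // thin
    out_btil = np.empty((n_keep, P))
    out_qtil = np.empty((n_keep, P))
    out_logtau = np.empty((n_keep, P))
    out_k = np.empty((n_keep, P))
    out_x1l = np.empty((n_keep, P))
    out_x1h = np.empty((n_keep, P))
    out_thetaB = np.empty((n_keep, G))
    out_sigB = np.empty((n_keep, G))
    out_thetaQ = np.empty((n_keep, G))
    out_sigQ = np.empty((n_keep, G))
    out_nu = np.empty(n_keep)
    kept = 0
    acc_block = 0.0
    n_block = 0.0

    for t in range(n_iter):
        adapting = t < burn_in
        gamma = 1.0 / ((t + 10.0) ** 0.6) if adapting else 0.0

        # ---- per-participant updates: joint block then coordinate pairs ----
        for rep in range(3):
          # rep 0: all five coordinates; rep 1: (b~, q~); rep 2: (x1_low, x1_high)
          for p in range(P):
            s = math.exp(log_step[rep, p])
            do_bq = rep != 2
            do_tx = rep != 1
            nb = btil[p]
            if do_bq and mode != MODE_Q_ONLY:
                nb = btil[p] + s * scale0 * np.random.standard_normal()
            nq = qtil[p]
            if do_bq and mode != MODE_B_ONLY:
                nq = qtil[p] + s * scale1 * np.random.standard_normal()
            nlt = logtau[p]
            if rep == 0:
                nlt = logtau[p] + s * scale2 * np.random.standard_normal()
            nxl = x1l[p]
            nxh = x1h[p]
            if do_tx:
                nxl = x1l[p] + s * scale3 * np.random.standard_normal()
                nxh = x1h[p] + s * scale4 * np.random.standard_normal()

            g = group_idx[p]
            b_cur = _sigmoid(btil[0]) if mode == MODE_Q_ONLY else _sigmoid(btil[p])
            b_new = b_cur if mode == MODE_Q_ONLY else _sigmoid(nb)
            q_cur = 0.0 if mode == MODE_B_ONLY else _sigmoid(qtil[p])
            q_new = 0.0 if mode == MODE_B_ONLY else _sigmoid(nq)

            ll_new = participant_loglik(
                heights, fc_obs, lik_mask, h_lo, h_hi, offsets[p], offsets[p + 1],
                select, b_new, q_new, nxl, nxh, math.exp(nlt), nu, resid_prop,
            )
            lp_new = ll_new
            lp_old = loglik_p[p]
            if mode != MODE_Q_ONLY:
                lp_new += _norm_logpdf(nb, theta_B[g], sig_B[g])
                lp_old += _norm_logpdf(btil[p], theta_B[g], sig_B[g])
            if mode != MODE_B_ONLY:
                lp_new += _norm_logpdf(nq, theta_q[g], sig_q[g])
                lp_old += _norm_logpdf(qtil[p], theta_q[g], sig_q[g])
            lp_new += _half_normal_logpdf_from_log(nlt, tau_sd)
            lp_old += _half_normal_logpdf_from_log(logtau[p], tau_sd)
            lp_new += _norm_logpdf(nxl, kk[p] * base_mu_l[p], base_sd_l[p])
            lp_old += _norm_logpdf(x1l[p], kk[p] * base_mu_l[p], base_sd_l[p])
            lp_new += _norm_logpdf(nxh, kk[p] * base_mu_h[p], base_sd_h[p])
            lp_old += _norm_logpdf(x1h[p], kk[p] * base_mu_h[p], base_sd_h[p])

            accept = math.log(np.random.random() + 1e-300) < lp_new - lp_old
            if accept:
                btil[p] = nb
                qtil[p] = nq
                logtau[p] = nlt
                x1l[p] = nxl
                x1h[p] = nxh
                loglik_p[p] = ll_new
                for i in range(offsets[p], offsets[p + 1]):
                    resid[i] = resid_prop[i]
                acc_block += 1.0
            n_block += 1.0
            if adapting:
                a = 1.0 if accept else 0.0
                log_step[rep, p] += gamma * (a - target)

        # ---- shared learning rate (Q_ONLY) ----
        if mode == MODE_Q_ONLY:
            nb = btil[0] + math.exp(log_step_shared) * np.random.standard_normal()
            ll_new_tot = 0.0
            ll_old_tot = 0.0
            b_new = _sigmoid(nb)
            for p in range(P):
                ll = participant_loglik(
                    heights, fc_obs, lik_mask, h_lo, h_hi, offsets[p], offsets[p + 1],
                    select, b_new, _sigmoid(qtil[p]), x1l[p], x1h[p],
                    math.exp(logtau[p]), nu, resid_prop,
                )
                ll_new_tot += ll
                ll_old_tot += loglik_p[p]
            lp_new = ll_new_tot + _norm_logpdf(nb, 0.0, theta_sd)
            lp_old = ll_old_tot + _norm_logpdf(btil[0], 0.0, theta_sd)
            accept = math.log(np.random.random() + 1e-300) < lp_new - lp_old
            if accept:
                for p in range(P):
                    btil[p] = nb
                # recompute residual cache and per-participant logliks
                for p in range(P):
                    loglik_p[p] = participant_loglik(
                        heights, fc_obs, lik_mask, h_lo, h_hi,
                        offsets[p], offsets[p + 1],
                        select, b_new, _sigmoid(qtil[p]), x1l[p], x1h[p],
                        math.exp(logtau[p]), nu, resid,
                    )
            if adapting:
                a = 1.0 if accept else 0.0
                log_step_shared += gamma * (a - target)

        # ---- independence refreshes from the hierarchical prior ----
        # proposal density cancels the prior term, so the acceptance ratio is
        # the bare likelihood ratio; this jumps weakly identified effects
        # (notably interference) across the whole (0, 1) range in one move.
        for p in range(P):
            g = group_idx[p]
            b_cur = _sigmoid(btil[0]) if mode == MODE_Q_ONLY else _sigmoid(btil[p])
            if mode != MODE_B_ONLY:
              for _ in range(2):
                nq = theta_q[g] + sig_q[g] * np.random.standard_normal()
                ll_new = participant_loglik(
                    heights, fc_obs, lik_mask, h_lo, h_hi, offsets[p], offsets[p + 1],
                    select, b_cur, _sigmoid(nq), x1l[p], x1h[p],
                    math.exp(logtau[p]), nu, resid_prop,
                )
                if math.log(np.random.random() + 1e-300) < ll_new - loglik_p[p]:
                    qtil[p] = nq
                    loglik_p[p] = ll_new
                    for i in range(offsets[p], offsets[p + 1]):
                        resid[i] = resid_prop[i]
            if mode != MODE_Q_ONLY:
                nb = theta_B[g] + sig_B[g] * np.random.standard_normal()
                q_cur = 0.0 if mode == MODE_B_ONLY else _sigmoid(qtil[p])
                ll_new = participant_loglik(
                    heights, fc_obs, lik_mask, h_lo, h_hi, offsets[p], offsets[p + 1],
                    select, _sigmoid(nb), q_cur, x1l[p], x1h[p],
                    math.exp(logtau[p]), nu, resid_prop,
                )
                if math.log(np.random.random() + 1e-300) < ll_new - loglik_p[p]:
                    btil[p] = nb
                    loglik_p[p] = ll_new
                    for i in range(offsets[p], offsets[p + 1]):
                        resid[i] = resid_prop[i]
            # initial-state pair from its baseline-informed prior
            nxl = kk[p] * base_mu_l[p] + base_sd_l[p] * np.random.standard_normal()
            nxh = kk[p] * base_mu_h[p] + base_sd_h[p] * np.random.standard_normal()
            b_cur = _sigmoid(btil[0]) if mode == MODE_Q_ONLY else _sigmoid(btil[p])
            q_cur = 0.0 if mode == MODE_B_ONLY else _sigmoid(qtil[p])
            ll_new = participant_loglik(
                heights, fc_obs, lik_mask, h_lo, h_hi, offsets[p], offsets[p + 1],
                select, b_cur, q_cur, nxl, nxh,
                math.exp(logtau[p]), nu, resid_prop,
            )
            if math.log(np.random.random() + 1e-300) < ll_new - loglik_p[p]:
                x1l[p] = nxl
                x1h[p] = nxh
                loglik_p[p] = ll_new
                for i in range(offsets[p], offsets[p + 1]):
                    resid[i] = resid_prop[i]

        # ---- tau-only refresh on cached residuals (cheap, improves mixing) ----
        for p in range(P):
            nlt = logtau[p] + math.exp(log_step_tau[p]) * np.random.standard_normal()
            tau_old = math.exp(logtau[p])
            tau_new = math.exp(nlt)
            ll_old = 0.0
            ll_new = 0.0
            for i in range(offsets[p], offsets[p + 1]):
                if not np.isnan(resid[i]):
                    ll_old += _t_logpdf(resid[i], tau_old, nu)
                    ll_new += _t_logpdf(resid[i], tau_new, nu)
            lp_old = ll_old + _half_normal_logpdf_from_log(logtau[p], tau_sd)
            lp_new = ll_new + _half_normal_logpdf_from_log(nlt, tau_sd)
            accept = math.log(np.random.random() + 1e-300) < lp_new - lp_old
            if accept:
                logtau[p] = nlt
                loglik_p[p] = ll_new
            if adapting:
                a = 1.0 if accept else 0.0
                log_step_tau[p] += gamma * (a - target)

        # ---- k: exact truncated-normal Gibbs ----
        for p in range(P):
            prec = 1.0 / (k_sd * k_sd)
            mean_num = 0.0
            prec += (base_mu_l[p] * base_mu_l[p]) / (base_sd_l[p] * base_sd_l[p])
            mean_num += base_mu_l[p] * x1l[p] / (base_sd_l[p] * base_sd_l[p])
            prec += (base_mu_h[p] * base_mu_h[p]) / (base_sd_h[p] * base_sd_h[p])
            mean_num += base_mu_h[p] * x1h[p] / (base_sd_h[p] * base_sd_h[p])
            mu_k = mean_num / prec
            sd_k = 1.0 / math.sqrt(prec)
            kk[p] = _trunc_normal_pos(mu_k, sd_k)

        # ---- group hyper-parameters: exact Gibbs ----
        for g in range(G):
            ng = 0
            for p in range(P):
                if group_idx[p] == g:
                    ng += 1
            if ng == 0:
                continue
            if mode != MODE_Q_ONLY:
                sm = 0.0
                for p in range(P):
                    if group_idx[p] == g:
                        sm += btil[p]
                prec = 1.0 / (theta_sd * theta_sd) + ng / (sig_B[g] * sig_B[g])
                mu_post = (sm / (sig_B[g] * sig_B[g])) / prec
                theta_B[g] = mu_post + np.random.standard_normal() / math.sqrt(prec)
                ssq = 0.0
                for p in range(P):
                    if group_idx[p] == g:
                        d = btil[p] - theta_B[g]
                        ssq += d * d
                a_post = sig_a + 0.5 * ng
                b_post = sig_b + 0.5 * ssq
                var = b_post / np.random.gamma(a_post, 1.0)
                sig_B[g] = math.sqrt(var)
            if mode != MODE_B_ONLY:
                sm = 0.0
                for p in range(P):
                    if group_idx[p] == g:
                        sm += qtil[p]
                prec = 1.0 / (theta_sd * theta_sd) + ng / (sig_q[g] * sig_q[g])
                mu_post = (sm / (sig_q[g] * sig_q[g])) / prec
                theta_q[g] = mu_post + np.random.standard_normal() / math.sqrt(prec)
                ssq = 0.0
                for p in range(P):
                    if group_idx[p] == g:
                        d = qtil[p] - theta_q[g]
                        ssq += d * d
                a_post = sig_a + 0.5 * ng
                b_post = sig_b + 0.5 * ssq
                var = b_post / np.random.gamma(a_post, 1.0)
                sig_q[g] = math.sqrt(var)

        # ---- funnel-breaking scale moves: rescale group effects with sigma ----
        # propose sigma' = sigma e^d and move each member's unconstrained
        # effect to theta + (effect - theta) e^d; acceptance needs only the
        # likelihood ratio, the InvGamma prior ratio on sigma^2 and e^{2d}.
        for g in range(G):
            for which2 in range(4):  # interference scale moved twice per sweep
                which = 0 if which2 == 0 else 1
                if which == 0 and mode == MODE_Q_ONLY:
                    continue
                if which == 1 and mode == MODE_B_ONLY:
                    continue
                d = 0.3 * np.random.standard_normal()
                ed = math.exp(d)
                if which == 0:
                    sig_old = sig_B[g]
                    theta = theta_B[g]
                else:
                    sig_old = sig_q[g]
                    theta = theta_q[g]
                sig_new = sig_old * ed
                ll_old = 0.0
                ll_new = 0.0
                for p in range(P):
                    if group_idx[p] != g:
                        continue
                    if which == 0:
                        b_new_p = _sigmoid(theta + (btil[p] - theta) * ed)
                        q_new_p = 0.0 if mode == MODE_B_ONLY else _sigmoid(qtil[p])
                    else:
                        b_new_p = _sigmoid(btil[0]) if mode == MODE_Q_ONLY else _sigmoid(btil[p])
                        q_new_p = _sigmoid(theta + (qtil[p] - theta) * ed)
                    ll_new += participant_loglik(
                        heights, fc_obs, lik_mask, h_lo, h_hi,
                        offsets[p], offsets[p + 1], select,
                        b_new_p, q_new_p, x1l[p], x1h[p],
                        math.exp(logtau[p]), nu, resid_prop,
                    )
                    ll_old += loglik_p[p]
                lp = (
                    ll_new - ll_old
                    + _invgamma_logpdf(sig_new * sig_new, sig_a, sig_b)
                    - _invgamma_logpdf(sig_old * sig_old, sig_a, sig_b)
                    + 2.0 * d
                )
                if math.log(np.random.random() + 1e-300) < lp:
                    for p in range(P):
                        if group_idx[p] != g:
                            continue
                        if which == 0:
                            btil[p] = theta + (btil[p] - theta) * ed
                        else:
                            qtil[p] = theta + (qtil[p] - theta) * ed
                        b_p = _sigmoid(btil[0]) if mode == MODE_Q_ONLY else _sigmoid(btil[p])
                        q_p = 0.0 if mode == MODE_B_ONLY else _sigmoid(qtil[p])
                        loglik_p[p] = participant_loglik(
                            heights, fc_obs, lik_mask, h_lo, h_hi,
                            offsets[p], offsets[p + 1], select,
                            b_p, q_p, x1l[p], x1h[p],
                            math.exp(logtau[p]), nu, resid,
                        )
                    if which == 0:
                        sig_B[g] = sig_new
                    else:
                        sig_q[g] = sig_new

        # ---- nu: random walk on log(nu - floor), cached residuals ----
        eta = math.log(nu - nu_floor)
        eta_new = eta + math.exp(log_step_nu) * np.random.standard_normal()
        nu_new = nu_floor + math.exp(eta_new)
        if nu_new > nu_cap:  # truncation keeps the near-flat tail bounded
            nu_new = nu
        ll_old = 0.0
        ll_new = 0.0
        for p in range(P):
            tau_p = math.exp(logtau[p])
            for i in range(offsets[p], offsets[p + 1]):
                if not np.isnan(resid[i]):
                    ll_old += _t_logpdf(resid[i], tau_p, nu)
                    ll_new += _t_logpdf(resid[i], tau_p, nu_new)
        lp_old = ll_old + _invgamma_logpdf(nu, nu_a, nu_b) + math.log(nu - nu_floor)
        lp_new = ll_new + _invgamma_logpdf(nu_new, nu_a, nu_b) + math.log(nu_new - nu_floor)
        accept = math.log(np.random.random() + 1e-300) < lp_new - lp_old
        if accept:
            nu = nu_new
            for p in range(P):
                q_p = 0.0 if mode == MODE_B_ONLY else _sigmoid(qtil[p])
                b_p = _sigmoid(btil[0]) if mode == MODE_Q_ONLY else _sigmoid(btil[p])
                tot = 0.0
                tau_p = math.exp(logtau[p])
                for i in range(offsets[p], offsets[p + 1]):
                    if not np.isnan(resid[i]):
                        tot += _t_logpdf(resid[i], tau_p, nu)
                loglik_p[p] = tot
        if adapting:
            a = 1.0 if accept else 0.0
            log_step_nu += gamma * (a - target)

        # ---- store ----
        if t >= burn_in and (t - burn_in) % thin == 0:
            for p in range(P):
                out_btil[kept, p] = btil[p]
                out_qtil[kept, p] = qtil[p]
                out_logtau[kept, p] = logtau[p]
                out_k[kept, p] = kk[p]
                out_x1l[kept, p] = x1l[p]
                out_x1h[kept, p] = x1h[p]
            for g in range(G):
                out_thetaB[kept, g] = theta_B[g]
                out_sigB[kept, g] = sig_B[g]
                out_thetaQ[kept, g] = theta_q[g]
                out_sigQ[kept, g] = sig_q[g]
            out_nu[kept] = nu
            kept += 1

    acc_rate = acc_block / n_block if n_block > 0 else 0.0
    return (
        out_btil, out_qtil, out_logtau, out_k, out_x1l, out_x1h,
        out_thetaB, out_sigB, out_thetaQ, out_sigQ, out_nu, acc_rate,
    )


@njit(cache=True)
def pointwise_loglik_draws(
    heights, fc_obs, lik_mask, h_lo, h_hi, offsets,
    select, B_draws, q_draws, tau_draws, x1l_draws, x1h_draws, nu_draws,
):
    """Per-trial Student-t log likelihood for every retained draw.

    Returns a (n_draws, n_obs) matrix over likelihood-contributing trials
    (column order follows trial order within the concatenated arrays).
    """
    n_draws = B_draws.shape[0]
    P = len(offsets) - 1
    N = len(heights)
    n_obs = 0
    for i in range(N):
        if lik_mask[i] == 1:
            n_obs += 1
    out = np.empty((n_draws, n_obs))
    resid = np.empty(N)
    for d in range(n_draws):
        col = 0
        for p in range(P):
            participant_loglik(
                heights, fc_obs, lik_mask, h_lo, h_hi, offsets[p], offsets[p + 1],
                select, B_draws[d, p], q_draws[d, p], x1l_draws[d, p], x1h_draws[d, p],
                tau_draws[d, p], nu_draws[d], resid,
            )
            for i in range(offsets[p], offsets[p + 1]):
                if lik_mask[i] == 1:
                    out[d, col] = _t_logpdf(resid[i], tau_draws[d, p], nu_draws[d])
                    col += 1
    return out
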