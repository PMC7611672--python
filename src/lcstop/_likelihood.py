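"""Vectorised race-model likelihood kernels.

These kernels are shared by the public per-trial likelihood API and the
hierarchical sampler.  A participant-session's trials are compiled once
into flat arrays (:func:`build_trial_arrays`); the log-likelihood is then
evaluated for a whole matrix of parameter vectors at once (one row per
MCMC chain), which is what makes the 33-chain DE-MCMC affordable.

Parameter vector layout (``PARAM_NAMES``): the nine ex-Gaussian
parameters of the go-match, go-mismatch and stop runners, followed by the
trigger-failure and go-failure probabilities on the probit scale
(p = Phi(z)).

Because staircased stop-signal delays live on a 50 ms lattice, inhibited
trials are collapsed to unique (SSD, count) pairs before the quadrature —
the inhibition integral is by far the most expensive term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .exgauss import _logpdf, _logsf, _sf

PARAM_NAMES = [
    "mu_go_match",
    "sigma_go_match",
    "tau_go_match",
    "mu_go_mismatch",
    "sigma_go_mismatch",
    "tau_go_mismatch",
    "mu_stop",
    "sigma_stop",
    "tau_stop",
    "z_tf",
    "z_gf",
]
N_PARAMS = len(PARAM_NAMES)

# Gauss-Legendre rule used for the inhibition integral inside the sampler;
# applied on two panels (Gaussian core, exponential tail) so small
# sigma_stop does not starve the core of nodes.
_GL_POINTS = 24
_GL_X, _GL_W = np.polynomial.legendre.leggauss(_GL_POINTS)


@dataclass(frozen=True)
class TrialArrays:
    """One participant-session compiled for likelihood evaluation."""

    go_t_match: np.ndarray    # RTs of correct (matching) go responses
    go_t_mismatch: np.ndarray  # RTs of commission errors
    n_go_omit: int
    sr_t: np.ndarray          # signal-respond RTs (stop/no-go with response)
    sr_d: np.ndarray          # their SSDs
    sr_match: np.ndarray
    inh_d: np.ndarray         # unique SSDs of inhibited stop/no-go trials
    inh_count: np.ndarray     # multiplicity of each unique SSD
    n_trials: int

    @property
    def n_go_resp(self) -> int:
        return self.go_t_match.size + self.go_t_mismatch.size


def build_trial_arrays(trials: pd.DataFrame) -> TrialArrays:
    kind = trials["kind"].to_numpy()
    resp = trials["response"].to_numpy()
    rt = trials["rt"].to_numpy(dtype=float)
    ssd = trials["ssd"].to_numpy(dtype=float)
    stim = trials["stimulus"].to_numpy()

    responded = resp != "none"
    is_go = kind == "go"
    is_sig = ~is_go

    go_r = is_go & responded
    sr = is_sig & responded
    inh = is_sig & ~responded
    if np.any(rt[sr] < 0):
        raise ValueError("signal-respond RT must be non-negative")
    if np.any(~np.isfinite(ssd[is_sig])):
        raise ValueError("stop/no-go trials must have a defined SSD")
    match = resp == stim
    inh_d, inh_count = np.unique(np.round(ssd[inh], 9), return_counts=True)
    return TrialArrays(
        go_t_match=rt[go_r & match],
        go_t_mismatch=rt[go_r & ~match],
        n_go_omit=int(np.sum(is_go & ~responded)),
        sr_t=rt[sr],
        sr_d=ssd[sr],
        sr_match=match[sr],
        inh_d=inh_d,
        inh_count=inh_count.astype(float),
        n_trials=len(trials),
    )


def _xlogp(n, p):
    """n * log(p) with the convention 0 * log(0) = 0 and n>0, p=0 -> -inf."""
    with np.errstate(divide="ignore"):
        lp = np.log(p)
    return np.where(n > 0, n * lp, 0.0)


def inhibit_integral_gl(d, mu_s, sg_s, ta_s, mu_m, sg_m, ta_m, mu_mm, sg_mm, ta_mm):
    """P(stop beats both go runners) at delays ``d`` (shape (T,)), for chain
    parameter columns of shape (C, 1).

    The integral over the stop finish offset u in (0, inf) is evaluated by
    two-panel Gauss-Legendre quadrature on [max(0, mu-8 sigma), mu+8 sigma]
    and [mu+8 sigma, mu+8 sigma+30 tau], outside of which the stop density
    carries negligible mass.  Returns an array of shape (C, T).
    """
    u_lo = np.maximum(0.0, mu_s - 8.0 * sg_s)[..., None]       # (C,1,1)
    u_mid = np.maximum(u_lo, (mu_s + 8.0 * sg_s)[..., None])
    u_hi = u_mid + (30.0 * ta_s)[..., None]
    half1 = 0.5 * (u_mid - u_lo)
    half2 = 0.5 * (u_hi - u_mid)
    u = np.concatenate(
        [
            0.5 * (u_mid + u_lo) + half1 * _GL_X,
            0.5 * (u_hi + u_mid) + half2 * _GL_X,
        ],
        axis=-1,
    )                                                           # (C,1,2Q)
    w = np.concatenate(
        [half1 * _GL_W, half2 * _GL_W], axis=-1
    )                                                           # (C,1,2Q)
    f_stop = np.exp(_logpdf(u, mu_s[..., None], sg_s[..., None], ta_s[..., None]))
    targ = d[None, :, None] + u                                 # (C,T,2Q)
    surv = _sf(targ, mu_m[..., None], sg_m[..., None], ta_m[..., None]) * _sf(
        targ, mu_mm[..., None], sg_mm[..., None], ta_mm[..., None]
    )
    return (f_stop * surv * w).sum(axis=-1)


def loglik_matrix(theta: np.ndarray, arrs: TrialArrays) -> np.ndarray:
    """Dataset log-likelihood for each parameter row.

    ``theta`` has shape (C, 11) following ``PARAM_NAMES``; returns (C,).
    -inf is returned (never raised) for zero-probability configurations so
    samplers can simply reject.
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    cols = {name: theta[:, k : k + 1] for k, name in enumerate(PARAM_NAMES)}
    mu_m, sg_m, ta_m = cols["mu_go_match"], cols["sigma_go_match"], cols["tau_go_match"]
    mu_mm, sg_mm, ta_mm = (
        cols["mu_go_mismatch"],
        cols["sigma_go_mismatch"],
        cols["tau_go_mismatch"],
    )
    mu_s, sg_s, ta_s = cols["mu_stop"], cols["sigma_stop"], cols["tau_stop"]
    p_tf = ndtr(theta[:, 9])
    p_gf = ndtr(theta[:, 10])

    C = theta.shape[0]
    ll = np.zeros(C)

    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        # go trials with a response: winner density x loser survival
        if arrs.go_t_match.size:
            t = arrs.go_t_match[None, :]
            ll += (
                _logpdf(t, mu_m, sg_m, ta_m) + _logsf(t, mu_mm, sg_mm, ta_mm)
            ).sum(axis=1)
        if arrs.go_t_mismatch.size:
            t = arrs.go_t_mismatch[None, :]
            ll += (
                _logpdf(t, mu_mm, sg_mm, ta_mm) + _logsf(t, mu_m, sg_m, ta_m)
            ).sum(axis=1)
        if arrs.n_go_resp:
            ll += arrs.n_go_resp * np.log1p(-p_gf)
        # go omissions
        ll += _xlogp(arrs.n_go_omit, p_gf)
        # signal-respond trials: go outcome density x P(stop did not beat it)
        if arrs.sr_t.size:
            t = arrs.sr_t[None, :]
            lp_m = _logpdf(t, mu_m, sg_m, ta_m)
            ls_m = _logsf(t, mu_m, sg_m, ta_m)
            lp_mm = _logpdf(t, mu_mm, sg_mm, ta_mm)
            ls_mm = _logsf(t, mu_mm, sg_mm, ta_mm)
            go_part = np.where(arrs.sr_match[None, :], lp_m + ls_mm, lp_mm + ls_m)
            s_stop = _sf(arrs.sr_t[None, :] - arrs.sr_d[None, :], mu_s, sg_s, ta_s)
            censor = np.log(p_tf[:, None] + (1.0 - p_tf[:, None]) * s_stop)
            ll += (go_part + censor).sum(axis=1) + arrs.sr_t.size * np.log1p(-p_gf)
        # inhibited stop/no-go trials (unique SSDs with multiplicities)
        if arrs.inh_d.size:
            integral = inhibit_integral_gl(
                arrs.inh_d, mu_s, sg_s, ta_s, mu_m, sg_m, ta_m, mu_mm, sg_mm, ta_mm
            )
            prob = (
                p_gf[:, None]
                + (1.0 - p_gf[:, None]) * (1.0 - p_tf[:, None]) * integral
            )
            ll += (arrs.inh_count[None, :] * np.log(prob)).sum(axis=1)

    ll = np.where(np.isnan(ll), -np.inf, ll)
    return ll
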