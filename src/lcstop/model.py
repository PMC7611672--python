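"""Hierarchical Bayesian estimation of the ex-Gaussian race model.

The model object (:class:`HierarchicalRaceModel`) is built from trial-level
data for one group of participants; :meth:`~HierarchicalRaceModel.fit` runs
a differential-evolution MCMC (DE-MCMC) sampler — crossover proposals across
chains, occasional chain migration during burn-in, thinning — until the
split-chain potential scale reduction statistic (R-hat) of every group-level
parameter falls below threshold, then retains a further block of iterations
as the final posterior, returned as a :class:`RaceModelResults` object.

Hierarchy: each participant's 11 parameters (three ex-Gaussian runners plus
probit-scale trigger/go-failure probabilities) are drawn from independent
truncated-normal group distributions with location and scale to be
estimated; weakly-informative hyperpriors live in
``priors/default_priors.yaml``.  The number of chains defaults to three
times the per-participant parameter count (33 for the full model).

Derived quantities follow the race model's conventions: SSRT is the mean
stop finish time mu_stop + tau_stop, go RT is mu_go-match + tau_go-match,
and group or drug contrasts are computed by subtracting matched MCMC
samples.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import log_ndtr, ndtr, ndtri

from ._likelihood import N_PARAMS, PARAM_NAMES, TrialArrays, build_trial_arrays, loglik_matrix
from .race import PreprocessRule, preprocess_rts

__all__ = [
    "ParamPrior",
    "HierarchicalPrior",
    "SamplerConfig",
    "PosteriorDraws",
    "HierarchicalRaceModel",
    "RaceModelResults",
    "ContrastResult",
    "split_rhat",
    "contrast",
    "fit_by_group",
    "posterior_predictive",
]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# truncated-normal helpers
# ---------------------------------------------------------------------------

def _log_gauss_mass(a, b):
    """log(Phi(b) - Phi(a)) computed stably for any tail location."""
    a, b = np.broadcast_arrays(np.asarray(a, float), np.asarray(b, float))
    out = np.empty(a.shape)
    right = a >= 0  # both bounds in the right tail: reflect
    lo = np.where(right, -b, a)
    hi = np.where(right, -a, b)
    l_hi = log_ndtr(hi)
    l_lo = log_ndtr(lo)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = l_hi + np.log1p(-np.exp(l_lo - l_hi))
    return out


def truncnorm_logpdf(x, loc, scale, lower, upper):
    """Log-density of a normal(loc, scale) truncated to [lower, upper]."""
    x, loc, scale, lower, upper = np.broadcast_arrays(
        *(np.asarray(v, float) for v in (x, loc, scale, lower, upper))
    )
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        z = (x - loc) / scale
        lp = (
            -0.5 * z * z
            - _LOG_SQRT_2PI
            - np.log(scale)
            - _log_gauss_mass((lower - loc) / scale, (upper - loc) / scale)
        )
        return np.where((x >= lower) & (x <= upper) & (scale > 0), lp, -np.inf)


def _truncnorm_rvs(loc, scale, lower, upper, rng, max_tries=200):
    """Vectorised rejection sampling from a truncated normal; falls back to
    clipping for pathological acceptance regions."""
    loc, scale, lower, upper = np.broadcast_arrays(
        *(np.asarray(v, float) for v in (loc, scale, lower, upper))
    )
    out = loc + scale * rng.standard_normal(loc.shape)
    bad = (out < lower) | (out > upper)
    tries = 0
    while bad.any() and tries < max_tries:
        draw = loc[bad] + scale[bad] * rng.standard_normal(int(bad.sum()))
        out[bad] = draw
        bad = (out < lower) | (out > upper)
        tries += 1
    if bad.any():
        out[bad] = np.clip(loc[bad], lower[bad], upper[bad]) + 1e-6
    return out


# ---------------------------------------------------------------------------
# priors and sampler configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParamPrior:
    """Hyperprior for one base parameter: a truncated-normal prior on the
    group location and a truncated-normal (half-normal-like) prior on the
    group scale; ``lower``/``upper`` also bound the participant level."""

    loc_mean: float
    loc_sd: float
    lower: float
    upper: float
    scale_loc: float = 0.0
    scale_sd: float = 0.5
    scale_lower: float = 0.005
    scale_upper: float = 3.0


class HierarchicalPrior:
    """Per-parameter hyperpriors, keyed by the sampler parameter names."""

    def __init__(self, params: Mapping[str, ParamPrior]):
        missing = [n for n in PARAM_NAMES if n not in params]
        if missing:
            raise ValueError(f"missing priors for {missing}")
        self.params: Dict[str, ParamPrior] = {n: params[n] for n in PARAM_NAMES}

    @classmethod
    def default(cls) -> "HierarchicalPrior":
        ref = importlib.resources.files("lcstop").joinpath("priors/default_priors.yaml")
        return cls._from_mapping(yaml.safe_load(ref.read_text()))

    @classmethod
    def from_yaml(cls, path) -> "HierarchicalPrior":
        with open(path) as fh:
            return cls._from_mapping(yaml.safe_load(fh))

    @classmethod
    def _from_mapping(cls, doc: Mapping) -> "HierarchicalPrior":
        return cls({name: ParamPrior(**spec) for name, spec in doc["parameters"].items()})

    def to_yaml(self, path) -> None:
        doc = {
            "version": 1,
            "parameters": {n: vars(p).copy() for n, p in self.params.items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    def arrays(self, names: Sequence[str]):
        """Stacked hyperprior arrays for the given (free) parameter subset."""
        ps = [self.params[n] for n in names]
        get = lambda attr: np.array([getattr(p, attr) for p in ps])
        return {
            "loc_mean": get("loc_mean"),
            "loc_sd": get("loc_sd"),
            "lower": get("lower"),
            "upper": get("upper"),
            "scale_loc": get("scale_loc"),
            "scale_sd": get("scale_sd"),
            "scale_lower": get("scale_lower"),
            "scale_upper": get("scale_upper"),
        }


@dataclass
class SamplerConfig:
    """DE-MCMC settings.

    ``n_chains`` defaults to three times the per-participant parameter
    count.  Burn-in is adaptive: chunks of ``burn_chunk`` retained
    iterations are run until the split-chain R-hat of every group-level
    parameter over the last ``rhat_window`` retained draws falls below
    ``rhat_threshold`` (or ``max_burn`` retained iterations are exceeded,
    flagging non-convergence), after which ``final_iterations`` retained
    iterations per chain form the reported posterior.
    """

    n_chains: Optional[int] = None
    thin: int = 10
    migration_prob: float = 0.05
    final_iterations: int = 500
    rhat_threshold: float = 1.1
    burn_chunk: int = 100
    rhat_window: int = 200
    max_burn: int = 1500
    jitter: float = 1e-4
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.migration_prob <= 1.0:
            raise ValueError("migration_prob must lie in [0, 1]")
        if self.thin < 1 or self.final_iterations < 1:
            raise ValueError("thin and final_iterations must be >= 1")


@dataclass
class PosteriorDraws:
    """MCMC samples, chain x retained-iteration x parameter, at group and
    participant level, plus identifying metadata."""

    group: np.ndarray          # (chains, draws, 2 * k_free): locations then scales
    subject: np.ndarray        # (chains, draws, n_participants, k_free)
    group_names: list
    param_names: list          # free per-participant parameter names
    participants: list
    meta: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.group.shape[0]

    @property
    def n_draws(self) -> int:
        return self.group.shape[1]

    def group_param(self, name: str) -> np.ndarray:
        return self.group[:, :, self.group_names.index(name)]


# ---------------------------------------------------------------------------
# convergence diagnostics
# ---------------------------------------------------------------------------

def split_rhat(draws: np.ndarray) -> float:
    """Split-chain Gelman-Rubin statistic for one parameter.

    ``draws`` has shape (chains, iterations).  Each chain is split in half,
    and the classic potential scale reduction factor is computed over the
    resulting 2C sequences.  Degenerate cases: identical constant chains
    give 1.0; constant chains at different values give inf.
    """
    x = np.asarray(draws, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 chains and 2 iterations")
    if np.all(x == x.flat[0]):
        return 1.0
    half = x.shape[1] // 2
    seqs = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)
    means = seqs.mean(axis=1)
    within = seqs.var(axis=1, ddof=1).mean()
    between = half * means.var(ddof=1)
    if within == 0.0:
        return 1.0 if between == 0.0 else float("inf")
    var_plus = (half - 1) / half * within + between / half
    return float(np.sqrt(var_plus / within))


@dataclass
class ContrastResult:
    """Posterior of an element-wise difference between two sample sets."""

    samples: np.ndarray
    median: float
    qi: tuple
    reliable: bool  # 95% quantile interval excludes zero

    def __repr__(self) -> str:
        lo, hi = self.qi
        return (
            f"ContrastResult(median={self.median:.4f}, "
            f"95% QI=[{lo:.4f}, {hi:.4f}], reliable={self.reliable})"
        )


def contrast(draws_a: np.ndarray, draws_b: np.ndarray) -> ContrastResult:
    """Element-wise difference a - b of matched posterior sample sets.

    If lengths differ, the longer set is evenly subsampled to match, then
    the per-sample difference approximates the posterior of the difference.
    """
    a = np.asarray(draws_a, float).ravel()
    b = np.asarray(draws_b, float).ravel()
    n = min(a.size, b.size)
    if a.size != n:
        a = a[np.linspace(0, a.size - 1, n).round().astype(int)]
    if b.size != n:
        b = b[np.linspace(0, b.size - 1, n).round().astype(int)]
    diff = a - b
    lo, hi = np.quantile(diff, [0.025, 0.975])
    return ContrastResult(
        samples=diff,
        median=float(np.median(diff)),
        qi=(float(lo), float(hi)),
        reliable=bool(lo > 0 or hi < 0),
    )


# ---------------------------------------------------------------------------
# the DE-MCMC engine
# ---------------------------------------------------------------------------

class _DEMCSampler:
    def __init__(
        self,
        arrs: Sequence[TrialArrays],
        prior: HierarchicalPrior,
        free_names: Sequence[str],
        theta_template: np.ndarray,
        cfg: SamplerConfig,
        rng: np.random.Generator,
    ):
        self.arrs = list(arrs)
        self.N = len(arrs)
        self.free = list(free_names)
        self.free_idx = np.array([PARAM_NAMES.index(n) for n in self.free])
        self.k = len(self.free)
        self.template = theta_template  # (11,) with fixed slots filled, free slots NaN
        self.cfg = cfg
        self.rng = rng
        self.C = cfg.n_chains or 3 * self.k
        if self.C < 4:
            raise ValueError("need at least 4 chains for DE proposals")
        h = prior.arrays(self.free)
        self.h = h
        self.gamma = 2.38 / np.sqrt(2.0 * self.k)
        self.gamma_pair = 2.38 / np.sqrt(2.0 * 2)
        self.group_sweeps = 2  # cheap likelihood-free sweeps per iteration
        # the stop runner's mu/tau split (and the trigger-failure probit) is
        # the most weakly identified direction; alternating small-block
        # updates on it raises acceptance there at no extra likelihood cost
        stop_block = ("mu_stop", "sigma_stop", "tau_stop", "z_tf")
        self.stop_dims = np.array(
            [j for j, n in enumerate(self.free) if n in stop_block], dtype=int
        )
        # prior-dominated directions (few commission errors inform the
        # mismatch runner; lapse probits see few trials): refreshed by
        # independence proposals from the conditional group prior, whose
        # Metropolis ratio reduces to a pure likelihood ratio
        weak_block = (
            "mu_go_mismatch", "sigma_go_mismatch", "tau_go_mismatch", "z_tf", "z_gf",
        )
        self.weak_dims = np.array(
            [j for j, n in enumerate(self.free) if n in weak_block], dtype=int
        )
        # mu_stop and tau_stop trade off almost freely (their sum, the SSRT,
        # is what the data pin down); a dedicated pair update every
        # iteration keeps that valley direction moving
        self.stop_pair = np.array(
            [j for j, n in enumerate(self.free) if n in ("mu_stop", "tau_stop")],
            dtype=int,
        )
        self._iter = 0

    # -- state helpers ------------------------------------------------------

    def _full_theta(self, theta_free: np.ndarray) -> np.ndarray:
        full = np.tile(self.template, (theta_free.shape[0], 1))
        full[:, self.free_idx] = theta_free
        return full

    def _loglik(self, i: int, theta_free: np.ndarray) -> np.ndarray:
        return loglik_matrix(self._full_theta(theta_free), self.arrs[i])

    def _lp_theta_k(self, theta, loc, scale):
        """Participant-level prior terms, one per parameter (no summing)."""
        return truncnorm_logpdf(theta, loc, scale, self.h["lower"], self.h["upper"])

    def _lp_loc_terms(self, loc):
        return truncnorm_logpdf(
            loc, self.h["loc_mean"], self.h["loc_sd"], self.h["lower"], self.h["upper"]
        )

    def _lp_scale_terms(self, scale):
        return truncnorm_logpdf(
            scale,
            self.h["scale_loc"],
            self.h["scale_sd"],
            self.h["scale_lower"],
            self.h["scale_upper"],
        )

    def _start_values(self) -> np.ndarray:
        """Crude data-driven start values per participant (moment heuristics
        for the go runners, the nonparametric mean-method SSRT for the stop
        runner); chains are jittered around these so burn-in measures mixing
        in the typical set rather than a random walk in from the priors."""
        starts = np.empty((self.N, len(PARAM_NAMES)))
        for i, arrs in enumerate(self.arrs):
            g = arrs.go_t_match
            m = float(np.mean(g)) if g.size else 0.6
            s = float(np.std(g)) if g.size > 2 else 0.2
            s = max(s, 0.05)
            tau = 0.8 * s
            mu = max(m - tau, 0.05)
            sigma = max(0.6 * s, 0.02)
            e = arrs.go_t_mismatch
            if e.size >= 5:
                se = max(float(np.std(e)), 0.05)
                tau_e, mu_e, sigma_e = 0.8 * se, max(float(np.mean(e)) - 0.8 * se, 0.05), max(0.6 * se, 0.02)
            else:
                mu_e, sigma_e, tau_e = 1.4 * mu, 1.2 * sigma, 1.2 * tau
            d_all = np.concatenate([arrs.sr_d, np.repeat(arrs.inh_d, arrs.inh_count.astype(int))])
            d_bar = float(np.mean(d_all)) if d_all.size else 0.25
            ssrt0 = min(max(m - d_bar, 0.08), 1.0)
            n_go = arrs.n_go_resp + arrs.n_go_omit
            omit = arrs.n_go_omit / n_go if n_go else 0.02
            starts[i] = [
                mu, sigma, tau, mu_e, sigma_e, tau_e,
                0.75 * ssrt0, 0.05, 0.25 * ssrt0,
                ndtri(0.1), ndtri(min(max(omit, 0.005), 0.5)),
            ]
        return starts

    def _init_state(self) -> None:
        C, N, k, rng, h = self.C, self.N, self.k, self.rng, self.h
        starts = self._start_values()[:, self.free_idx]        # (N, k)
        positive = h["lower"] > 0.0                            # exgauss params
        lo = h["lower"] + 1e-4
        hi = h["upper"] - 1e-4

        def jitter(base, rel, add):
            out = np.where(
                positive,
                base * np.exp(rel * rng.standard_normal(base.shape)),
                base + add * rng.standard_normal(base.shape),
            )
            return np.clip(out, lo, hi)

        self.theta = np.empty((C, N, k))
        for i in range(N):
            self.theta[:, i, :] = jitter(np.tile(starts[i], (C, 1)), 0.12, 0.25)
        loc0 = starts.mean(axis=0)
        self.loc = jitter(np.tile(loc0, (C, 1)), 0.10, 0.20)
        scale0 = np.clip(
            starts.std(axis=0) + 0.02,
            h["scale_lower"] + 1e-4,
            h["scale_upper"] - 1e-4,
        )
        self.scale = np.clip(
            np.tile(scale0, (C, 1)) * np.exp(0.2 * rng.standard_normal((C, k))),
            h["scale_lower"] + 1e-4,
            h["scale_upper"] - 1e-4,
        )
        self.ll = np.empty((C, N))
        for i in range(N):
            self.ll[:, i] = self._loglik(i, self.theta[:, i, :])
        self.lp_tk = self._lp_theta_k(
            self.theta, self.loc[:, None, :], self.scale[:, None, :]
        )  # (C, N, k)
        self.lp_loc_k = self._lp_loc_terms(self.loc)      # (C, k)
        self.lp_scale_k = self._lp_scale_terms(self.scale)  # (C, k)

    # -- proposals ----------------------------------------------------------

    def _de_pairs(self):
        C, rng = self.C, self.rng
        base = np.arange(C)
        r1 = (base + rng.integers(1, C, C)) % C
        r2 = (base + rng.integers(1, C, C)) % C
        clash = r2 == r1
        while clash.any():
            r2[clash] = (base[clash] + rng.integers(1, C, int(clash.sum()))) % C
            clash = r2 == r1
        return r1, r2

    def _propose(self, x: np.ndarray, gamma: float) -> np.ndarray:
        r1, r2 = self._de_pairs()
        g = gamma * self.rng.uniform(0.6, 1.2)
        eps = self.rng.uniform(-self.cfg.jitter, self.cfg.jitter, x.shape)
        return x + g * (x[r1] - x[r2]) + eps

    # -- block updates ------------------------------------------------------

    def _update_participant(self, i: int, dims: Optional[np.ndarray] = None) -> None:
        cur = self.theta[:, i, :]
        if dims is None:
            prop = self._propose(cur, self.gamma)
        else:
            prop = cur.copy()
            prop[:, dims] = self._propose(
                cur[:, dims], 2.38 / np.sqrt(2.0 * len(dims))
            )
        ok = ((prop >= self.h["lower"]) & (prop <= self.h["upper"])).all(axis=1)
        if not ok.any():
            return
        lp_new = np.full((self.C, self.k), -np.inf)
        ll_new = np.full(self.C, -np.inf)
        lp_new[ok] = self._lp_theta_k(prop[ok], self.loc[ok], self.scale[ok])
        ll_new[ok] = self._loglik(i, prop[ok])
        logr = (ll_new + lp_new.sum(axis=1)) - (
            self.ll[:, i] + self.lp_tk[:, i, :].sum(axis=1)
        )
        accept = ok & (np.log(self.rng.random(self.C)) < logr)
        if accept.any():
            self.theta[accept, i, :] = prop[accept]
            self.ll[accept, i] = ll_new[accept]
            self.lp_tk[accept, i, :] = lp_new[accept]

    def _update_participant_indep(self, i: int, dims: np.ndarray) -> None:
        """Independence proposal from the conditional group prior on the
        given dimensions; proposal density equals the prior factor, so the
        acceptance ratio is the likelihood ratio alone."""
        cur = self.theta[:, i, :]
        prop = cur.copy()
        prop[:, dims] = _truncnorm_rvs(
            self.loc[:, dims], self.scale[:, dims],
            self.h["lower"][dims], self.h["upper"][dims], self.rng,
        )
        ll_new = self._loglik(i, prop)
        logr = ll_new - self.ll[:, i]
        accept = np.log(self.rng.random(self.C)) < logr
        if accept.any():
            self.theta[accept, i, :] = prop[accept]
            self.ll[accept, i] = ll_new[accept]
            self.lp_tk[accept, i, :] = self._lp_theta_k(
                prop[accept], self.loc[accept], self.scale[accept]
            )

    def _update_translation(self) -> None:
        """Joint translation of each group location together with every
        participant's value of that parameter.

        Shifting (loc_k, theta_1k, ..., theta_Nk) by a common delta leaves
        the participant-prior z-scores unchanged, so the move glides along
        the hierarchical valley that couples a group location to its
        participant mean — the slow mode for prior-dominated parameters.
        The acceptance ratio involves the likelihoods, the hyperprior and
        the (loc-dependent) truncation masses."""
        rng = self.rng
        r1, r2 = self._de_pairs()
        g = self.gamma * rng.uniform(0.6, 1.2)
        delta = g * (self.loc[r1] - self.loc[r2]) + rng.uniform(
            -self.cfg.jitter, self.cfg.jitter, self.loc.shape
        )
        loc_p = self.loc + delta
        theta_p = self.theta + delta[:, None, :]
        ok = (
            ((loc_p >= self.h["lower"]) & (loc_p <= self.h["upper"])).all(axis=1)
            & ((theta_p >= self.h["lower"]) & (theta_p <= self.h["upper"])).all(axis=(1, 2))
        )
        if not ok.any():
            return
        ll_new = np.full((self.C, self.N), -np.inf)
        for i in range(self.N):
            ll_new[ok, i] = self._loglik(i, theta_p[ok, i, :])
        lp_loc_new = self._lp_loc_terms(loc_p)
        lp_tk_new = self._lp_theta_k(theta_p, loc_p[:, None, :], self.scale[:, None, :])
        logr = (
            ll_new.sum(axis=1) + lp_tk_new.sum(axis=(1, 2)) + lp_loc_new.sum(axis=1)
        ) - (
            self.ll.sum(axis=1) + self.lp_tk.sum(axis=(1, 2)) + self.lp_loc_k.sum(axis=1)
        )
        accept = ok & (np.log(rng.random(self.C)) < logr)
        if accept.any():
            self.loc[accept] = loc_p[accept]
            self.theta[accept] = theta_p[accept]
            self.ll[accept] = ll_new[accept]
            self.lp_loc_k[accept] = lp_loc_new[accept]
            self.lp_tk[accept] = lp_tk_new[accept]

    def _update_scale_expansion(self) -> None:
        """Joint multiplicative move on each group scale and the spread of
        the participant values around their group location.

        scale_k -> scale_k e^d, theta_ik -> loc_k + (theta_ik - loc_k) e^d
        preserves the participant-prior z-scores and glides along the
        scale/spread valley (the funnel direction).  The proposal is a
        symmetric DE step on log scales; the Jacobian contributes
        (N + 1) d_k per parameter."""
        rng = self.rng
        r1, r2 = self._de_pairs()
        g = self.gamma * rng.uniform(0.6, 1.2)
        delta = g * (np.log(self.scale[r1]) - np.log(self.scale[r2])) + rng.uniform(
            -self.cfg.jitter, self.cfg.jitter, self.scale.shape
        )
        factor = np.exp(delta)
        scale_p = self.scale * factor
        theta_p = self.loc[:, None, :] + (self.theta - self.loc[:, None, :]) * factor[:, None, :]
        ok = (
            ((scale_p >= self.h["scale_lower"]) & (scale_p <= self.h["scale_upper"])).all(axis=1)
            & ((theta_p >= self.h["lower"]) & (theta_p <= self.h["upper"])).all(axis=(1, 2))
        )
        if not ok.any():
            return
        ll_new = np.full((self.C, self.N), -np.inf)
        for i in range(self.N):
            ll_new[ok, i] = self._loglik(i, theta_p[ok, i, :])
        lp_scale_new = self._lp_scale_terms(scale_p)
        lp_tk_new = self._lp_theta_k(theta_p, self.loc[:, None, :], scale_p[:, None, :])
        log_jac = (self.N + 1) * delta.sum(axis=1)
        logr = (
            ll_new.sum(axis=1) + lp_tk_new.sum(axis=(1, 2)) + lp_scale_new.sum(axis=1)
            + log_jac
        ) - (
            self.ll.sum(axis=1) + self.lp_tk.sum(axis=(1, 2)) + self.lp_scale_k.sum(axis=1)
        )
        accept = ok & (np.log(rng.random(self.C)) < logr)
        if accept.any():
            self.scale[accept] = scale_p[accept]
            self.theta[accept] = theta_p[accept]
            self.ll[accept] = ll_new[accept]
            self.lp_scale_k[accept] = lp_scale_new[accept]
            self.lp_tk[accept] = lp_tk_new[accept]

    def _update_group_pairs(self) -> None:
        """Per-parameter (location, scale) DE pair updates, vectorised over
        parameters.

        Given the participant-level parameters the group posterior
        factorises over base parameters, so every (loc_k, scale_k) pair can
        be Metropolis-updated independently and in parallel.  These blocks
        are likelihood-free and cheap; a few sweeps per iteration keep the
        group level well mixed."""
        h = self.h
        rng = self.rng
        r1, r2 = self._de_pairs()
        g = self.gamma_pair * rng.uniform(0.6, 1.2)
        loc_p = (
            self.loc + g * (self.loc[r1] - self.loc[r2])
            + rng.uniform(-self.cfg.jitter, self.cfg.jitter, self.loc.shape)
        )
        scale_p = (
            self.scale + g * (self.scale[r1] - self.scale[r2])
            + rng.uniform(-self.cfg.jitter, self.cfg.jitter, self.scale.shape)
        )
        ok = (
            (loc_p >= h["lower"]) & (loc_p <= h["upper"])
            & (scale_p >= h["scale_lower"]) & (scale_p <= h["scale_upper"])
        )  # (C, k)
        lp_loc_new = self._lp_loc_terms(loc_p)
        lp_scale_new = self._lp_scale_terms(scale_p)
        lp_tk_new = self._lp_theta_k(
            self.theta, loc_p[:, None, :], scale_p[:, None, :]
        )  # (C, N, k)
        logr = (lp_tk_new.sum(axis=1) + lp_loc_new + lp_scale_new) - (
            self.lp_tk.sum(axis=1) + self.lp_loc_k + self.lp_scale_k
        )
        with np.errstate(invalid="ignore"):
            accept = ok & (np.log(rng.random((self.C, self.k))) < logr)
        self.loc = np.where(accept, loc_p, self.loc)
        self.scale = np.where(accept, scale_p, self.scale)
        self.lp_loc_k = np.where(accept, lp_loc_new, self.lp_loc_k)
        self.lp_scale_k = np.where(accept, lp_scale_new, self.lp_scale_k)
        self.lp_tk = np.where(accept[:, None, :], lp_tk_new, self.lp_tk)

    def _logpost(self) -> np.ndarray:
        return (
            self.ll.sum(axis=1)
            + self.lp_tk.sum(axis=(1, 2))
            + self.lp_loc_k.sum(axis=1)
            + self.lp_scale_k.sum(axis=1)
        )

    def _migrate(self) -> None:
        """Cyclically offer a random subset of chains each other's states."""
        C, rng = self.C, self.rng
        m = int(rng.integers(2, max(3, C // 2 + 1)))
        idx = rng.choice(C, size=m, replace=False)
        src = np.roll(idx, 1)
        logpost = self._logpost()
        arrays = (
            self.loc, self.scale, self.theta, self.ll,
            self.lp_tk, self.lp_loc_k, self.lp_scale_k,
        )
        snap = tuple(a.copy() for a in arrays)
        for dst_c, src_c in zip(idx, src):
            if np.log(rng.random()) < logpost[src_c] - logpost[dst_c]:
                for live, frozen in zip(arrays, snap):
                    live[dst_c] = frozen[src_c]

    def _step(self, allow_migration: bool) -> None:
        if allow_migration and self.rng.random() < self.cfg.migration_prob:
            self._migrate()
        phase = self._iter % 3
        if phase == 1 and self.stop_dims.size >= 2:
            for i in range(self.N):
                self._update_participant(i, self.stop_dims)
        elif phase == 2 and self.weak_dims.size >= 1:
            for i in range(self.N):
                self._update_participant_indep(i, self.weak_dims)
        else:
            for i in range(self.N):
                self._update_participant(i)
        if self.stop_pair.size == 2:
            for i in range(self.N):
                self._update_participant(i, self.stop_pair)
        self._update_translation()
        self._update_scale_expansion()
        for _ in range(self.group_sweeps):
            self._update_group_pairs()
        self._iter += 1

    # -- main loop ----------------------------------------------------------

    def run(self):
        cfg = self.cfg
        self._init_state()
        burn_rec: list = []
        converged = False
        n_burn = 0
        while True:
            for _ in range(cfg.burn_chunk):
                for _ in range(cfg.thin):
                    self._step(allow_migration=True)
                burn_rec.append(np.concatenate([self.loc, self.scale], axis=1).copy())
            n_burn = len(burn_rec)
            w = min(cfg.rhat_window, n_burn // 2)
            if w >= 50:
                window = np.stack(burn_rec[-w:], axis=1)  # (C, W, 2k)
                worst = max(
                    split_rhat(window[:, :, j]) for j in range(window.shape[2])
                )
                if worst < cfg.rhat_threshold:
                    converged = True
                    break
            if n_burn >= cfg.max_burn:
                break
        group_rec = np.empty((self.C, cfg.final_iterations, 2 * self.k))
        subj_rec = np.empty((self.C, cfg.final_iterations, self.N, self.k))
        for t in range(cfg.final_iterations):
            for _ in range(cfg.thin):
                self._step(allow_migration=False)
            group_rec[:, t, :] = np.concatenate([self.loc, self.scale], axis=1)
            subj_rec[:, t, :, :] = self.theta
        return group_rec, subj_rec, converged, n_burn


# ---------------------------------------------------------------------------
# the model / results objects
# ---------------------------------------------------------------------------

def _normalize_fixed(fixed: Optional[Mapping[str, float]]):
    """Map user-facing fixed values (p_tf/p_gf on the probability scale) to
    sampler-layout slots."""
    template = np.full(N_PARAMS, np.nan)
    free = list(PARAM_NAMES)
    if fixed:
        for key, val in fixed.items():
            name = {"p_tf": "z_tf", "p_gf": "z_gf"}.get(key, key)
            if name not in PARAM_NAMES:
                raise ValueError(f"unknown parameter {key!r}")
            slot = PARAM_NAMES.index(name)
            template[slot] = ndtri(val) if key in ("p_tf", "p_gf") else float(val)
            free.remove(name)
    return template, free


class HierarchicalRaceModel:
    """Hierarchical ex-Gaussian race model for one group of participants.

    Parameters
    ----------
    data
        Either a tidy DataFrame with a ``subject`` column, or a mapping of
        participant id to trial DataFrame.  Trials are preprocessed with the
        standard RT trimming rule unless ``preprocess=False``.
    prior
        Hyperpriors; defaults to the packaged weakly-informative set.
    fixed
        Optional mapping of parameters to fix (e.g. ``{"p_tf": 0.0}`` for a
        no-trigger-failure variant); fixed parameters are removed from the
        sampled space.
    """

    def __init__(
        self,
        data,
        prior: Optional[HierarchicalPrior] = None,
        fixed: Optional[Mapping[str, float]] = None,
        preprocess: bool = True,
        rule: PreprocessRule = PreprocessRule(),
    ):
        if isinstance(data, pd.DataFrame):
            groups = {pid: df for pid, df in data.groupby("subject", sort=True)}
        else:
            groups = dict(data)
        if len(groups) < 2:
            raise ValueError("hierarchical fit requires at least 2 participants")
        self.participants = list(groups)
        self.reports = {}
        trials = {}
        for pid, df in groups.items():
            if preprocess:
                df, rep = preprocess_rts(df, rule)
                self.reports[pid] = rep
            trials[pid] = df
        self.trials = trials
        self._arrs = [build_trial_arrays(trials[p]) for p in self.participants]
        self.prior = prior or HierarchicalPrior.default()
        self.template, self.free_names = _normalize_fixed(fixed)
        self.fixed = dict(fixed or {})

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "HierarchicalRaceModel":
        return cls(df, **kwargs)

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    @property
    def n_free_params(self) -> int:
        return len(self.free_names)

    def fit(
        self,
        config: Optional[SamplerConfig] = None,
        seed: Optional[int] = None,
    ) -> "RaceModelResults":
        cfg = config or SamplerConfig()
        if seed is None:
            seed = cfg.seed
        rng = np.random.default_rng(seed)
        sampler = _DEMCSampler(
            self._arrs, self.prior, self.free_names, self.template, cfg, rng
        )
        group, subject, converged, n_burn = sampler.run()
        group_names = [f"loc_{n}" for n in self.free_names] + [
            f"scale_{n}" for n in self.free_names
        ]
        draws = PosteriorDraws(
            group=group,
            subject=subject,
            group_names=group_names,
            param_names=list(self.free_names),
            participants=list(self.participants),
            meta={
                "n_chains": sampler.C,
                "thin": cfg.thin,
                "burn_retained": n_burn,
                "fixed": dict(self.fixed),
            },
        )
        return RaceModelResults(self, draws, converged, cfg)


class RaceModelResults:
    """Posterior draws plus diagnostics and derived quantities."""

    def __init__(
        self,
        model: HierarchicalRaceModel,
        draws: PosteriorDraws,
        converged: bool,
        config: SamplerConfig,
    ):
        self.model = model
        self.draws = draws
        self.converged = converged
        self.config = config

    # -- diagnostics --------------------------------------------------------

    def rhat(self) -> pd.Series:
        """Split-chain R-hat for every group-level parameter."""
        vals = {
            name: split_rhat(self.draws.group[:, :, j])
            for j, name in enumerate(self.draws.group_names)
        }
        return pd.Series(vals, name="rhat")

    @property
    def max_rhat(self) -> float:
        return float(self.rhat().max())

    # -- derived posteriors -------------------------------------------------

    def _group_flat(self, name: str) -> np.ndarray:
        return self.draws.group_param(name).ravel()

    def derive_ssrt(self, level: str = "group") -> np.ndarray:
        """Posterior samples of SSRT = mu_stop + tau_stop.

        ``level='group'`` returns a flat vector of group-level samples;
        ``level='participant'`` returns an array (n_participants, n_samples).
        """
        return self._derive_sum("mu_stop", "tau_stop", level)

    def derive_go_rt(self, level: str = "group") -> np.ndarray:
        """Posterior samples of go RT = mu_go-match + tau_go-match."""
        return self._derive_sum("mu_go_match", "tau_go_match", level)

    def _derive_sum(self, a: str, b: str, level: str) -> np.ndarray:
        names = self.draws.param_names
        if a not in names or b not in names:
            raise ValueError(f"{a}/{b} not sampled in this model")
        ia, ib = names.index(a), names.index(b)
        if level == "group":
            return (
                self._group_flat(f"loc_{a}") + self._group_flat(f"loc_{b}")
            )
        if level == "participant":
            s = self.draws.subject
            out = s[:, :, :, ia] + s[:, :, :, ib]  # (C, T, N)
            return np.moveaxis(out, -1, 0).reshape(len(self.draws.participants), -1)
        raise ValueError("level must be 'group' or 'participant'")

    def subject_summaries(self) -> pd.DataFrame:
        """Per-participant posterior medians and 95% QIs of SSRT and go RT."""
        ssrt = self.derive_ssrt("participant")
        gort = self.derive_go_rt("participant")
        rows = []
        for i, pid in enumerate(self.draws.participants):
            s_lo, s_hi = np.quantile(ssrt[i], [0.025, 0.975])
            g_lo, g_hi = np.quantile(gort[i], [0.025, 0.975])
            rows.append(
                {
                    "subject": pid,
                    "ssrt_median": float(np.median(ssrt[i])),
                    "ssrt_qi_low": float(s_lo),
                    "ssrt_qi_high": float(s_hi),
                    "gort_median": float(np.median(gort[i])),
                    "gort_qi_low": float(g_lo),
                    "gort_qi_high": float(g_hi),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> pd.DataFrame:
        """Posterior median, 95% quantile interval and R-hat per group-level
        parameter, plus the derived group SSRT and go RT."""
        rh = self.rhat()
        rows = {}
        for j, name in enumerate(self.draws.group_names):
            flat = self.draws.group[:, :, j].ravel()
            lo, hi = np.quantile(flat, [0.025, 0.975])
            rows[name] = {
                "median": float(np.median(flat)),
                "qi_low": float(lo),
                "qi_high": float(hi),
                "rhat": float(rh[name]),
            }
        for label, fn in (("ssrt", self.derive_ssrt), ("go_rt", self.derive_go_rt)):
            try:
                flat = fn("group")
            except ValueError:
                continue
            lo, hi = np.quantile(flat, [0.025, 0.975])
            rows[f"group_{label}"] = {
                "median": float(np.median(flat)),
                "qi_low": float(lo),
                "qi_high": float(hi),
                "rhat": np.nan,
            }
        out = pd.DataFrame(rows).T
        out.index.name = "parameter"
        return out

    # -- export -------------------------------------------------------------

    def to_inference_data(self):
        """Posterior draws as an arviz InferenceData (group level)."""
        import arviz as az

        data = {
            name: self.draws.group[:, :, j]
            for j, name in enumerate(self.draws.group_names)
        }
        return az.from_dict(posterior=data)

    def posterior_predictive(self, n_draws: int = 100, seed=None) -> "PPCResult":
        return posterior_predictive(self, n_draws=n_draws, seed=seed)


def fit_by_group(
    df: pd.DataFrame,
    group_col: str = "group",
    prior: Optional[HierarchicalPrior] = None,
    config: Optional[SamplerConfig] = None,
    seed: Optional[int] = None,
    **model_kwargs,
) -> Dict[str, RaceModelResults]:
    """Fit the hierarchical model independently per group label with
    identical priors (the three-group convention: controls, placebo,
    drug)."""
    out = {}
    ss = np.random.SeedSequence(seed)
    for (label, sub), child in zip(df.groupby(group_col, sort=True), ss.spawn(df[group_col].nunique())):
        model = HierarchicalRaceModel(
            sub.drop(columns=[group_col]), prior=prior, **model_kwargs
        )
        out[label] = model.fit(config, seed=child.generate_state(1)[0] % (2**31))
    return out


# ---------------------------------------------------------------------------
# posterior predictive checks
# ---------------------------------------------------------------------------

@dataclass
class PPCResult:
    """Observed vs posterior-predictive summaries.

    Deciles of go RTs and signal-respond RTs, and the inhibition function
    (stop accuracy per SSD bin); predictive bands are 2.5-97.5 percentiles
    across posterior draws.
    """

    go_deciles_obs: np.ndarray
    go_deciles_band: np.ndarray        # (2, 9)
    sr_deciles_obs: np.ndarray
    sr_deciles_band: np.ndarray
    ssd_bin_centers: np.ndarray
    inhib_obs: np.ndarray
    inhib_band: np.ndarray             # (2, n_bins)
    n_draws: int

    def go_deciles_inside(self) -> float:
        ok = (self.go_deciles_obs >= self.go_deciles_band[0]) & (
            self.go_deciles_obs <= self.go_deciles_band[1]
        )
        return float(np.mean(ok))

    def inhib_inside(self) -> float:
        m = np.isfinite(self.inhib_obs)
        ok = (self.inhib_obs[m] >= self.inhib_band[0][m]) & (
            self.inhib_obs[m] <= self.inhib_band[1][m]
        )
        return float(np.mean(ok))

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(1, 3, figsize=(12, 3.5))
        q = np.arange(1, 10) / 10.0
        ax[0].fill_between(q, self.go_deciles_band[0], self.go_deciles_band[1], alpha=0.3)
        ax[0].plot(q, self.go_deciles_obs, "ko-", ms=3)
        ax[0].set(title="go RT deciles", xlabel="quantile", ylabel="RT (s)")
        ax[1].fill_between(q, self.sr_deciles_band[0], self.sr_deciles_band[1], alpha=0.3)
        ax[1].plot(q, self.sr_deciles_obs, "ko-", ms=3)
        ax[1].set(title="signal-respond RT deciles", xlabel="quantile")
        ax[2].fill_between(
            self.ssd_bin_centers, self.inhib_band[0], self.inhib_band[1], alpha=0.3
        )
        ax[2].plot(self.ssd_bin_centers, self.inhib_obs, "ko-", ms=3)
        ax[2].set(title="inhibition function", xlabel="SSD (s)", ylabel="stop accuracy")
        return ax


def _replay(full_theta: np.ndarray, kinds, ssd, window: float, rng) -> tuple:
    """Simulate one dataset with the observed trial/SSD structure."""
    from .exgauss import exgauss_rvs

    n = len(kinds)
    mu_m, sg_m, ta_m, mu_mm, sg_mm, ta_mm, mu_s, sg_s, ta_s, z_tf, z_gf = full_theta
    p_tf, p_gf = ndtr(z_tf), ndtr(z_gf)
    gm = exgauss_rvs(mu_m, sg_m, ta_m, n, rng)
    gmm = exgauss_rvs(mu_mm, sg_mm, ta_mm, n, rng)
    stop_extra = exgauss_rvs(mu_s, sg_s, ta_s, n, rng)
    go_time = np.minimum(gm, gmm)
    gf = rng.random(n) < p_gf
    tf = rng.random(n) < p_tf
    sig = kinds != "go"
    stop_wins = sig & ~tf & (ssd + stop_extra <= go_time)
    responded = ~gf & ~stop_wins & (go_time <= window)
    return responded, go_time, sig


def _summaries(responded, rt, sig, ssd, bin_edges):
    qs = np.arange(1, 10) / 10.0
    go_rts = rt[responded & ~sig]
    sr_rts = rt[responded & sig]
    god = np.quantile(go_rts, qs) if go_rts.size else np.full(9, np.nan)
    srd = np.quantile(sr_rts, qs) if sr_rts.size else np.full(9, np.nan)
    inhib = []
    for lo, hi in zip(bin_edges[:-1], bin_edges[1:]):
        m = sig & (ssd >= lo) & (ssd <= hi)
        inhib.append(np.mean(~responded[m]) if m.any() else np.nan)
    return god, srd, np.array(inhib)


def posterior_predictive(
    results: RaceModelResults, n_draws: int = 100, seed=None
) -> PPCResult:
    """Compare observed go-RT deciles, signal-respond deciles and the
    inhibition function with data simulated from the posterior predictive
    distribution (observed trial and SSD structure replayed)."""
    rng = np.random.default_rng(seed)
    model = results.model
    draws = results.draws
    C, T = draws.n_chains, draws.n_draws

    kinds = []
    ssds = []
    for pid in draws.participants:
        df = model.trials[pid]
        kinds.append(df["kind"].to_numpy())
        ssds.append(df["ssd"].to_numpy(dtype=float))
    resp_obs = []
    rt_obs = []
    for pid in draws.participants:
        df = model.trials[pid]
        resp_obs.append((df["response"] != "none").to_numpy())
        rt_obs.append(df["rt"].to_numpy(dtype=float))

    all_ssd = np.concatenate([s[k != "go"] for s, k in zip(ssds, kinds)])
    edges = np.quantile(all_ssd, np.linspace(0, 1, 6))
    edges[0] -= 1e-9
    edges[-1] += 1e-9
    centers = 0.5 * (edges[:-1] + edges[1:])

    obs = _summaries(
        np.concatenate(resp_obs),
        np.concatenate(rt_obs),
        np.concatenate([k != "go" for k in kinds]),
        np.concatenate(ssds),
        edges,
    )

    sims = []
    for _ in range(n_draws):
        c = rng.integers(C)
        t = rng.integers(T)
        r_all, rt_all, sig_all = [], [], []
        for i in range(len(draws.participants)):
            full = np.array(results.model.template)
            full[
                [PARAM_NAMES.index(n) for n in draws.param_names]
            ] = draws.subject[c, t, i]
            responded, rts, sig = _replay(
                full, kinds[i], np.nan_to_num(ssds[i]), 4.5, rng
            )
            r_all.append(responded)
            rt_all.append(rts)
            sig_all.append(sig)
        sims.append(
            _summaries(
                np.concatenate(r_all),
                np.concatenate(rt_all),
                np.concatenate(sig_all),
                np.concatenate(ssds),
                edges,
            )
        )

    god = np.stack([s[0] for s in sims])
    srd = np.stack([s[1] for s in sims])
    inh = np.stack([s[2] for s in sims])
    band = lambda a: np.nanquantile(a, [0.025, 0.975], axis=0)
    return PPCResult(
        go_deciles_obs=obs[0],
        go_deciles_band=band(god),
        sr_deciles_obs=obs[1],
        sr_deciles_band=band(srd),
        ssd_bin_centers=centers,
        inhib_obs=obs[2],
        inhib_band=band(inh),
        n_draws=n_draws,
    )
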