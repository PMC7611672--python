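"""Ex-Gaussian race model with attentional failures: parameter container,
trial-level likelihood contributions, dataset log-likelihood and RT
preprocessing.

The model races three independent ex-Gaussian runners — stop, go-match and
go-mismatch — with two lapse probabilities: ``p_tf`` (trigger failure: the
stop runner never launches on a stop trial) and ``p_gf`` (go failure: the
go runners never launch, producing an omission).  Signal-respond RTs are
right-censored go RTs, the censoring point being the stop-signal delay
plus the stop runner's finish time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Tuple

import numpy as np
import pandas as pd
from scipy import integrate
from scipy.special import ndtr, ndtri

from . import _likelihood
from ._likelihood import PARAM_NAMES, build_trial_arrays, loglik_matrix
from .exgauss import ExGauss

__all__ = [
    "RaceParams",
    "PreprocessRule",
    "PreprocessReport",
    "QuadratureError",
    "preprocess_rts",
    "go_trial_loglik",
    "stop_respond_loglik",
    "stop_inhibit_loglik",
    "inhibit_probability",
    "dataset_loglik",
]


class QuadratureError(RuntimeError):
    """Adaptive quadrature failed to reach the requested tolerance."""


@dataclass(frozen=True)
class RaceParams:
    """Per-participant race-model parameters.

    ``stop``, ``go_match`` and ``go_mismatch`` are the ex-Gaussian finish
    time distributions; ``p_tf`` and ``p_gf`` are the trigger-failure and
    go-failure probabilities.
    """

    stop: ExGauss
    go_match: ExGauss
    go_mismatch: ExGauss
    p_tf: float = 0.0
    p_gf: float = 0.0

    def __post_init__(self) -> None:
        for runner in (self.stop, self.go_match, self.go_mismatch):
            if runner.mu <= 0:
                raise ValueError("runner mu must be > 0")
        for p in (self.p_tf, self.p_gf):
            if not 0.0 <= p <= 1.0:
                raise ValueError("failure probabilities must lie in [0, 1]")

    def to_dict(self) -> dict:
        """Flat dict with field names mu_stop, sigma_stop, ... p_tf, p_gf."""
        out = {}
        for label, runner in (
            ("stop", self.stop),
            ("go_match", self.go_match),
            ("go_mismatch", self.go_mismatch),
        ):
            out[f"mu_{label}"] = runner.mu
            out[f"sigma_{label}"] = runner.sigma
            out[f"tau_{label}"] = runner.tau
        out["p_tf"] = self.p_tf
        out["p_gf"] = self.p_gf
        return out

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "RaceParams":
        return cls(
            stop=ExGauss(d["mu_stop"], d["sigma_stop"], d["tau_stop"]),
            go_match=ExGauss(d["mu_go_match"], d["sigma_go_match"], d["tau_go_match"]),
            go_mismatch=ExGauss(
                d["mu_go_mismatch"], d["sigma_go_mismatch"], d["tau_go_mismatch"]
            ),
            p_tf=float(d.get("p_tf", 0.0)),
            p_gf=float(d.get("p_gf", 0.0)),
        )

    def theta(self) -> np.ndarray:
        """Parameter vector in sampler layout (probabilities on probit scale)."""
        d = self.to_dict()
        vec = [d[name] for name in PARAM_NAMES[:9]]
        vec.append(ndtri(self.p_tf))
        vec.append(ndtri(self.p_gf))
        return np.asarray(vec, dtype=float)

    @property
    def ssrt(self) -> float:
        """Mean stop finish time, mu_stop + tau_stop."""
        return self.stop.mean


@dataclass(frozen=True)
class PreprocessRule:
    """RT trimming rule: absolute floor/ceiling on all responded trials, then
    a +/- ``sd_mult`` SD trim on go RTs around that participant's go-RT mean."""

    rt_floor: float = 0.25
    rt_ceiling: float = 4.5
    sd_mult: float = 2.5

    def __post_init__(self) -> None:
        if not self.rt_floor < self.rt_ceiling:
            raise ValueError("rt_floor must be < rt_ceiling")
        if self.sd_mult <= 0:
            raise ValueError("sd_mult must be > 0")


@dataclass
class PreprocessReport:
    n_input: int
    removed_floor: int
    removed_ceiling: int
    removed_sd: int
    sd_rule_applied: bool

    @property
    def n_removed(self) -> int:
        return self.removed_floor + self.removed_ceiling + self.removed_sd


def preprocess_rts(
    trials: pd.DataFrame, rule: PreprocessRule = PreprocessRule()
) -> Tuple[pd.DataFrame, PreprocessReport]:
    """Trim implausible RTs for one participant-session.

    All responded trials with rt < floor or rt > ceiling are removed first;
    the SD trim is then applied to go-trial RTs only, using the mean/SD of
    the surviving go RTs (sequential application).  Omissions are untouched.
    With fewer than two surviving go RTs the SD rule is skipped with a
    warning.
    """
    rt = trials["rt"].to_numpy(dtype=float)
    responded = trials["response"].to_numpy() != "none"
    below = responded & (rt < rule.rt_floor)
    above = responded & (rt > rule.rt_ceiling)
    keep = ~(below | above)

    is_go = trials["kind"].to_numpy() == "go"
    go_kept = keep & is_go & responded
    go_rts = rt[go_kept]
    removed_sd = 0
    sd_applied = False
    if go_rts.size >= 2:
        sd_applied = True
        m, s = float(np.mean(go_rts)), float(np.std(go_rts, ddof=1))
        out = go_kept & (np.abs(rt - m) > rule.sd_mult * s)
        removed_sd = int(out.sum())
        keep &= ~out
    else:
        import warnings

        warnings.warn("fewer than 2 go RTs; SD trim skipped", stacklevel=2)

    report = PreprocessReport(
        n_input=len(trials),
        removed_floor=int(below.sum()),
        removed_ceiling=int(above.sum()),
        removed_sd=removed_sd,
        sd_rule_applied=sd_applied,
    )
    return trials.loc[keep].copy(), report


# ---------------------------------------------------------------------------
# trial-level likelihood contributions
# ---------------------------------------------------------------------------

def _runners(trial: Mapping, params: RaceParams):
    """Return (responding runner, other runner) for a responded trial."""
    if trial["response"] == trial["stimulus"]:
        return params.go_match, params.go_mismatch
    return params.go_mismatch, params.go_match


def go_trial_loglik(trial: Mapping, params: RaceParams) -> float:
    """Log-likelihood of a go trial outcome.

    Responded at t: log[(1 - p_gf) f_winner(t) S_loser(t)]; omission:
    log p_gf.  RTs outside the plausible support contribute -inf.
    """
    if trial["kind"] != "go":
        raise ValueError("go_trial_loglik requires a go trial")
    if trial["response"] == "none":
        return math.log(params.p_gf) if params.p_gf > 0 else -math.inf
    t = float(trial["rt"])
    if not np.isfinite(t) or t < 0:
        return -math.inf
    winner, loser = _runners(trial, params)
    if params.p_gf >= 1.0:
        return -math.inf
    return (
        math.log1p(-params.p_gf)
        + float(winner.logpdf(t))
        + float(loser.logsf(t))
    )


def stop_respond_loglik(trial: Mapping, params: RaceParams) -> float:
    """Log-likelihood of a signal-respond outcome (stop or no-go trial with a
    response at time t after go onset, stop-signal delay d = trial['ssd']).

    log{(1-p_gf) f_resp(t) S_other(t) [p_tf + (1-p_tf) S_stop(t - d)]}
    """
    if trial["kind"] not in ("stop", "nogo"):
        raise ValueError("stop_respond_loglik requires a stop or no-go trial")
    if trial["response"] == "none":
        raise ValueError("trial has no response; use stop_inhibit_loglik")
    t = float(trial["rt"])
    if t < 0 or not np.isfinite(t):
        raise ValueError("response time must be finite and non-negative")
    d = float(trial["ssd"])
    if params.p_gf >= 1.0:
        return -math.inf
    winner, loser = _runners(trial, params)
    censor = params.p_tf + (1.0 - params.p_tf) * float(params.stop.sf(t - d))
    if censor <= 0.0:
        return -math.inf
    return (
        math.log1p(-params.p_gf)
        + float(winner.logpdf(t))
        + float(loser.logsf(t))
        + math.log(censor)
    )


def inhibit_probability(d: float, params: RaceParams, tol: float = 1e-9) -> float:
    """P(stop runner beats both go runners | stop triggered) at delay ``d``,
    by adaptive quadrature over the stop finish offset u in (0, inf):

        integral of f_stop(u) S_match(d+u) S_mismatch(d+u) du.
    """
    s = params.stop

    def integrand(u):
        return float(
            s.pdf(u) * params.go_match.sf(d + u) * params.go_mismatch.sf(d + u)
        )

    upper = s.mu + 12.0 * s.sigma + 60.0 * s.tau
    pts = [p for p in (max(0.0, s.mu - 4 * s.sigma), s.mu, s.mu + 5 * s.tau) if 0 < p < upper]
    val, err, info, *msg = integrate.quad(
        integrand, 0.0, upper, epsabs=tol, limit=200, points=sorted(set(pts)),
        full_output=True,
    )
    if msg:
        raise QuadratureError(
            f"inhibition integral did not converge (d={d}, err={err:.3g}): {msg[0]}"
        )
    return float(min(max(val, 0.0), 1.0))


def stop_inhibit_loglik(trial: Mapping, params: RaceParams, tol: float = 1e-9) -> float:
    """Log-likelihood of successful inhibition (no response on a stop/no-go
    trial): log{p_gf + (1-p_gf)(1-p_tf) P(stop wins | triggered)}."""
    if trial["kind"] not in ("stop", "nogo"):
        raise ValueError("stop_inhibit_loglik requires a stop or no-go trial")
    if trial["response"] != "none":
        raise ValueError("trial has a response; use stop_respond_loglik")
    d = float(trial["ssd"])
    prob = params.p_gf
    w = (1.0 - params.p_gf) * (1.0 - params.p_tf)
    if w > 0.0:
        prob = prob + w * inhibit_probability(d, params, tol=tol)
    return math.log(prob) if prob > 0 else -math.inf


def dataset_loglik(trials: pd.DataFrame, params: RaceParams) -> float:
    """Sum of per-trial log-likelihood contributions; -inf propagates."""
    if len(trials) == 0:
        return 0.0
    arrs = build_trial_arrays(trials)
    return float(loglik_matrix(params.theta()[None, :], arrs)[0])
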