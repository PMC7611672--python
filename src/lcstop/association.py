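"""Final statistical stage: behavioural descriptives, the linear
mixed-model test of whether locus-coeruleus CNR moderates the drug effect
on SSRT, the drug-change correlation, and the group x subdivision ANOVA
on LC contrast.

The moderation model is, in R-style formula notation,

    SSRT ~ drug * CNR + session + (1 | subject)

fitted by REML on the patient crossover rows.  Continuous variables are
z-scored so fixed effects are reported as standardized betas; drug is
coded placebo = 0 / atomoxetine = 1 and session first = 0 / second = 1.
Denominator degrees of freedom use a containment (between-within) rule,
recorded in the result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BehaviouralSummary",
    "LMMResult",
    "DrugChangeCorrelation",
    "SubdivisionAnova",
    "descriptives",
    "empirical_logit",
    "ssrt_integration",
    "subject_condition_table",
    "fit_moderation_lmm",
    "drug_change_correlation",
    "subdivision_anova",
    "leave_one_out_interaction",
]


def empirical_logit(k: int, n: int) -> float:
    """Empirical logit log((k + 0.5) / (n - k + 0.5)); finite at 0 and n."""
    if n <= 0:
        raise ValueError("n must be positive")
    return math.log((k + 0.5) / (n - k + 0.5))


@dataclass
class BehaviouralSummary:
    stop_accuracy: float
    go_error_rate: float
    go_error_logit: float
    n_stop: int
    n_go: int


def descriptives(trials: pd.DataFrame) -> BehaviouralSummary:
    """Stop accuracy (inhibited / stop trials) and go error rate
    (commission + omission errors over go trials), with the go error rate
    also on the empirical-logit scale."""
    kind = trials["kind"].to_numpy()
    resp = trials["response"].to_numpy()
    stim = trials["stimulus"].to_numpy()
    is_stop = kind == "stop"
    is_go = kind == "go"
    n_stop = int(is_stop.sum())
    n_go = int(is_go.sum())
    if n_stop == 0 or n_go == 0:
        raise ValueError("need at least one stop and one go trial")
    inhibited = int((is_stop & (resp == "none")).sum())
    errors = int((is_go & ((resp == "none") | (resp != stim))).sum())
    return BehaviouralSummary(
        stop_accuracy=inhibited / n_stop,
        go_error_rate=errors / n_go,
        go_error_logit=empirical_logit(errors, n_go),
        n_stop=n_stop,
        n_go=n_go,
    )


def ssrt_integration(trials: pd.DataFrame) -> float:
    """Nonparametric SSRT estimate by the classic mean method: mean
    responded go RT minus mean stop-trial SSD.  Valid under ~50% staircase
    tracking; used for fast replicated checks where a full hierarchical fit
    is not warranted."""
    is_go = trials["kind"] == "go"
    go_rt = trials.loc[is_go & (trials["response"] != "none"), "rt"]
    ssd = trials.loc[trials["kind"] == "stop", "ssd"]
    if go_rt.empty or ssd.empty:
        raise ValueError("need responded go trials and stop trials")
    return float(go_rt.mean() - ssd.mean())


def subject_condition_table(study, ssrt: str = "integration") -> pd.DataFrame:
    """One row per subject x condition with SSRT, go RT, stop accuracy,
    logit go error rate and whole-LC CNR — the input table of the
    association stage.

    ``ssrt='integration'`` uses the nonparametric mean-method estimate;
    alternatively pass a mapping ``(subject, drug) -> ssrt`` (e.g.
    participant-level posterior medians from the hierarchical fits).
    """
    rows = []
    cnr = study.subjects.set_index("subject")["lc_cnr"]
    for (sid, grp, session, drug), df in study.trials.groupby(
        ["subject", "group", "session", "drug"], sort=True
    ):
        beh = descriptives(df)
        if ssrt == "integration":
            ssrt_val = ssrt_integration(df)
        else:
            ssrt_val = ssrt.get((sid, drug), np.nan)
        go_rt = float(df.loc[(df["kind"] == "go") & (df["response"] != "none"), "rt"].mean())
        rows.append(
            {
                "subject": sid,
                "group": grp,
                "session": session,
                "drug": drug,
                "ssrt": ssrt_val,
                "gort": go_rt,
                "stop_accuracy": beh.stop_accuracy,
                "go_error_logit": beh.go_error_logit,
                "lc_cnr": float(cnr.get(sid, np.nan)),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class LMMResult:
    """Fixed effects of the moderation mixed model.

    ``params`` are standardized betas when ``standardized`` is True; F
    statistics are squared Wald t ratios with containment denominator df.
    """

    params: pd.Series
    bse: pd.Series
    fvalues: pd.Series
    df_denom: float
    pvalues: pd.Series
    varcomps: dict
    formula: str
    outcome: str
    df_method: str
    standardized: bool
    singular: bool
    n_obs: int
    n_subjects: int
    model_result: object = field(repr=False, default=None)

    @property
    def interaction(self) -> float:
        return float(self.params["drug:cnr"])

    def summary(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "beta": self.params,
                "se": self.bse,
                "F": self.fvalues,
                "df_denom": self.df_denom,
                "p": self.pvalues,
            }
        )
        out.index.name = "term"
        return out


_DRUG_CODE = {"placebo": 0.0, "atomoxetine": 1.0}
_SESSION_CODE = {"first": 0.0, "second": 1.0}


def _prep_lmm_frame(rows: pd.DataFrame, outcome: str, standardize: bool) -> pd.DataFrame:
    d = rows[rows["drug"].isin(_DRUG_CODE)].copy()
    d = d.dropna(subset=[outcome, "lc_cnr"])
    d["drug"] = d["drug"].map(_DRUG_CODE)
    d["session"] = d["session"].map(_SESSION_CODE)
    d["y"] = d[outcome].astype(float)
    d["cnr"] = d["lc_cnr"].astype(float)
    if standardize:
        d["y"] = (d["y"] - d["y"].mean()) / d["y"].std(ddof=1)
        d["cnr"] = (d["cnr"] - d["cnr"].mean()) / d["cnr"].std(ddof=1)
    return d


def fit_moderation_lmm(
    rows: pd.DataFrame, outcome: str = "ssrt", standardize: bool = True
) -> LMMResult:
    """Random-intercept LMM ``outcome ~ drug * CNR + session + (1|subject)``
    fitted by REML on the patient crossover rows; the drug x CNR
    interaction is the estimand.  Subjects with a single session are
    retained (the random effect handles the missingness); fewer than three
    subjects with both sessions is refused.
    """
    import statsmodels.formula.api as smf

    d = _prep_lmm_frame(rows, outcome, standardize)
    both = d.groupby("subject")["drug"].nunique()
    if int((both == 2).sum()) < 3:
        raise ValueError("need at least 3 subjects with both sessions")
    md = smf.mixedlm("y ~ drug * cnr + session", data=d, groups=d["subject"])
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = md.fit(reml=True)
    fe = res.fe_params.drop(labels=["Intercept"], errors="ignore")
    fe.index = [i.replace("drug:cnr", "drug:cnr") for i in fe.index]
    bse = res.bse[fe.index]
    n_obs = len(d)
    n_subj = d["subject"].nunique()
    k_fixed = len(res.fe_params)
    df_denom = max(n_obs - n_subj - (k_fixed - 1), 1)
    tvals = fe / bse
    fvals = tvals**2
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df_denom)
    re_var = float(res.cov_re.iloc[0, 0])
    singular = bool(re_var < 1e-8 or not res.converged)
    return LMMResult(
        params=fe,
        bse=bse,
        fvalues=fvals,
        df_denom=float(df_denom),
        pvalues=pd.Series(pvals, index=fe.index),
        varcomps={"subject_var": re_var, "residual_var": float(res.scale)},
        formula=f"{outcome} ~ drug * cnr + session + (1 | subject)",
        outcome=outcome,
        df_method="between-within",
        standardized=standardize,
        singular=singular,
        n_obs=n_obs,
        n_subjects=n_subj,
        model_result=res,
    )


@dataclass
class DrugChangeCorrelation:
    """Pearson correlation between whole-LC CNR and the session-adjusted
    drug-induced change in the outcome (drug minus placebo)."""

    r: float
    p: float
    n: int
    session_effect: float
    deltas: pd.DataFrame
    defined: bool


def drug_change_correlation(rows: pd.DataFrame, outcome: str = "ssrt") -> DrugChangeCorrelation:
    """Per-patient Delta = outcome(drug) - outcome(placebo), adjusted for the
    session fixed effect (estimated from a random-intercept model with drug
    and session), correlated with whole-LC CNR.  Patients missing a session
    are excluded here (but not from the LMM)."""
    import statsmodels.formula.api as smf

    d = _prep_lmm_frame(rows, outcome, standardize=False)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = smf.mixedlm("y ~ drug + session", data=d, groups=d["subject"]).fit(reml=True)
    sess_eff = float(res.fe_params.get("session", 0.0))

    recs = []
    for sid, sub in d.groupby("subject"):
        if set(sub["drug"]) != {0.0, 1.0}:
            continue
        atx = sub[sub["drug"] == 1.0].iloc[0]
        pla = sub[sub["drug"] == 0.0].iloc[0]
        delta = (atx["y"] - sess_eff * atx["session"]) - (
            pla["y"] - sess_eff * pla["session"]
        )
        recs.append({"subject": sid, "delta": delta, "lc_cnr": atx["cnr"]})
    deltas = pd.DataFrame(recs)
    if (
        len(deltas) < 3
        or deltas["delta"].std(ddof=1) < 1e-10
        or deltas["lc_cnr"].std(ddof=1) < 1e-10
    ):
        return DrugChangeCorrelation(
            r=float("nan"), p=float("nan"), n=len(deltas),
            session_effect=sess_eff, deltas=deltas, defined=False,
        )
    r, p = stats.pearsonr(deltas["lc_cnr"], deltas["delta"])
    return DrugChangeCorrelation(
        r=float(r), p=float(p), n=len(deltas),
        session_effect=sess_eff, deltas=deltas, defined=True,
    )


@dataclass
class SubdivisionAnova:
    """Group (between) x subdivision (within) mixed ANOVA on LC CNR with
    sphericity correction, plus per-subdivision group contrasts."""

    anova: pd.DataFrame
    pairwise: pd.DataFrame
    sphericity_corrected: bool

    def _p_for(self, source: str) -> float:
        row = self.anova[self.anova["Source"] == source].iloc[0]
        for col in ("p_GG_corr", "p-GG-corr"):
            if self.sphericity_corrected and col in row.index and np.isfinite(row[col]):
                return float(row[col])
        for col in ("p_unc", "p-unc"):
            if col in row.index:
                return float(row[col])
        raise KeyError("no p-value column in ANOVA table")

    @property
    def interaction_p(self) -> float:
        return self._p_for("Interaction")

    @property
    def subdivision_p(self) -> float:
        return self._p_for("subdivision")

    def pairwise_p(self, subdivision: str) -> float:
        row = self.pairwise[self.pairwise["subdivision"] == subdivision].iloc[0]
        return float(row["p"])


def subdivision_anova(lc_long: pd.DataFrame) -> SubdivisionAnova:
    """Mixed ANOVA on a long table with columns
    (subject, group, subdivision, cnr); subdivision is the within factor.
    Follow-up: Welch two-sample tests between groups per subdivision."""
    import pingouin as pg

    aov = pg.mixed_anova(
        data=lc_long, dv="cnr", within="subdivision", subject="subject", between="group",
        correction=True,
    )
    pair_rows = []
    for sub, d in lc_long.groupby("subdivision"):
        gs = [g["cnr"].to_numpy() for _, g in d.groupby("group")]
        if len(gs) == 2:
            t, p = stats.ttest_ind(gs[0], gs[1], equal_var=False)
        else:
            t, p = np.nan, np.nan
        pair_rows.append({"subdivision": sub, "t": float(t), "p": float(p)})
    return SubdivisionAnova(
        anova=aov,
        pairwise=pd.DataFrame(pair_rows),
        sphericity_corrected=any(c in aov.columns for c in ("p_GG_corr", "p-GG-corr")),
    )


def leave_one_out_interaction(rows: pd.DataFrame, outcome: str = "ssrt") -> pd.DataFrame:
    """Simple influence utility: refit the moderation LMM leaving each
    subject out once and report the interaction estimate."""
    out = []
    for sid in rows["subject"].unique():
        sub = rows[rows["subject"] != sid]
        try:
            res = fit_moderation_lmm(sub, outcome)
            out.append({"excluded": sid, "interaction": res.interaction})
        except ValueError:
            out.append({"excluded": sid, "interaction": np.nan})
    return pd.DataFrame(out)
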