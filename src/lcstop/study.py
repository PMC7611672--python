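"""Whole-study simulation: cohorts, crossover randomization and the
drug x locus-coeruleus link.

Two cohorts are generated from hierarchical parameter distributions: a
control group tested in a single session and a patient group tested twice
in a double-blind placebo/drug crossover, with drug order randomized in
permuted blocks of six (three placebo-first, three drug-first per block).

Each patient carries a latent whole-LC contrast-to-noise ratio (CNR).
When a :class:`CNRLink` is supplied, the drug session shifts that
patient's stop-runner mean by a linear function of the standardised CNR,
planting a drug x CNR interaction on SSRT that the association stage
should recover.  The default group-level parameters are chosen so control
and patient-placebo SSRTs sit near 0.39 s and 0.46 s with go RTs near
1 s, i.e. the regime the analysis pipeline is meant for.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .exgauss import ExGauss
from .race import RaceParams
from .task import TaskConfig, simulate_participant

__all__ = [
    "GroupSpec",
    "CNRLink",
    "StudyConfig",
    "StudyData",
    "CONTROL_SPEC",
    "PATIENT_SPEC",
    "draw_participant_params",
    "randomize_crossover",
    "simulate_study",
]

# (location, between-subject SD); failure probabilities are given on the
# probability scale and drawn on the probit scale.
GroupSpec = Dict[str, Tuple[float, float]]

CONTROL_SPEC: GroupSpec = {
    "mu_go_match": (0.80, 0.10),
    "sigma_go_match": (0.12, 0.03),
    "tau_go_match": (0.25, 0.06),
    "mu_go_mismatch": (1.10, 0.12),
    "sigma_go_mismatch": (0.15, 0.04),
    "tau_go_mismatch": (0.30, 0.08),
    "mu_stop": (0.29, 0.04),
    "sigma_stop": (0.04, 0.01),
    "tau_stop": (0.10, 0.03),
    "p_tf": (0.05, 0.30),
    "p_gf": (0.02, 0.30),
}

PATIENT_SPEC: GroupSpec = {
    "mu_go_match": (0.75, 0.10),
    "sigma_go_match": (0.12, 0.03),
    "tau_go_match": (0.23, 0.06),
    "mu_go_mismatch": (1.05, 0.12),
    "sigma_go_mismatch": (0.15, 0.04),
    "tau_go_mismatch": (0.28, 0.08),
    "mu_stop": (0.35, 0.05),
    "sigma_stop": (0.05, 0.012),
    "tau_stop": (0.11, 0.03),
    "p_tf": (0.08, 0.30),
    "p_gf": (0.03, 0.30),
}

_LOWER = {"mu": 0.02, "sigma": 0.005, "tau": 0.005}


@dataclass(frozen=True)
class CNRLink:
    """Latent whole-LC CNR distribution and its link to the drug effect.

    On the drug session the stop-runner mean shifts by
    ``drug_mean + drug_slope * z`` where z is the participant's
    standardised CNR; a positive slope means high-CNR patients slow down
    (larger SSRT) on drug while low-CNR patients improve.
    """

    mean: float = 6.0
    sd: float = 1.5
    drug_mean: float = 0.01
    drug_slope: float = 0.022


@dataclass
class StudyConfig:
    n_controls: int = 26
    n_patients: int = 19
    task: TaskConfig = field(default_factory=TaskConfig)
    control_spec: GroupSpec = field(default_factory=lambda: dict(CONTROL_SPEC))
    patient_spec: GroupSpec = field(default_factory=lambda: dict(PATIENT_SPEC))
    cnr_link: Optional[CNRLink] = field(default_factory=CNRLink)
    session_mu_stop_shift: float = -0.015  # practice effect in session two

    def __post_init__(self) -> None:
        if self.n_controls < 0 or self.n_patients < 0:
            raise ValueError("cohort sizes must be non-negative")
        if self.n_controls == 0 and self.n_patients == 0:
            raise ValueError("at least one cohort must be non-empty")


@dataclass
class StudyData:
    """Tidy trial table plus a per-subject table of latent quantities."""

    trials: pd.DataFrame
    subjects: pd.DataFrame
    config: StudyConfig


def draw_participant_params(spec: GroupSpec, rng: np.random.Generator) -> RaceParams:
    """One participant's parameters from truncated group distributions."""
    vals = {}
    for name, (loc, sd) in spec.items():
        if name.startswith("p_"):
            vals[name] = float(ndtr(ndtri(loc) + sd * rng.standard_normal()))
        else:
            lower = _LOWER[name.split("_")[0]]
            x = loc + sd * rng.standard_normal()
            for _ in range(100):
                if x >= lower:
                    break
                x = loc + sd * rng.standard_normal()
            vals[name] = float(max(x, lower))
    return RaceParams.from_dict(vals)


def randomize_crossover(n: int, rng: np.random.Generator) -> list:
    """Drug-order assignment in permuted blocks of six: within each
    successive block of six recruits, exactly three are placebo-first and
    three drug-first, in random order."""
    orders = []
    while len(orders) < n:
        block = ["placebo_first"] * 3 + ["atomoxetine_first"] * 3
        rng.shuffle(block)
        orders.extend(block)
    return orders[:n]


def _session_params(
    base: RaceParams, mu_stop_shift: float
) -> RaceParams:
    stop = ExGauss(max(base.stop.mu + mu_stop_shift, 0.02), base.stop.sigma, base.stop.tau)
    return replace(base, stop=stop)


def _rng_for(seed: int, *key) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def simulate_study(config: Optional[StudyConfig] = None, seed: int = 0) -> StudyData:
    """Simulate the full study: control sessions plus the patient crossover.

    Every participant x session has its own named random substream, so any
    single participant can be re-simulated in isolation from the study seed.
    """
    cfg = config or StudyConfig()
    link = cfg.cnr_link
    trials_parts = []
    subject_rows = []

    for i in range(cfg.n_controls):
        sid = f"c{i:03d}"
        params = draw_participant_params(cfg.control_spec, _rng_for(seed, 0, i))
        cnr = (
            float(link.mean + link.sd * _rng_for(seed, 0, i, 9).standard_normal())
            if link
            else np.nan
        )
        df = simulate_participant(params, cfg.task, _rng_for(seed, 0, i, 1))
        df.insert(0, "subject", sid)
        df.insert(1, "group", "control")
        df.insert(2, "session", "first")
        df.insert(3, "drug", "none")
        trials_parts.append(df)
        subject_rows.append(
            {
                "subject": sid,
                "group": "control",
                "order": "none",
                "lc_cnr": cnr,
                "true_ssrt_none": params.ssrt,
                **{f"true_{k}": v for k, v in params.to_dict().items()},
            }
        )

    orders = randomize_crossover(cfg.n_patients, _rng_for(seed, 2))
    for i in range(cfg.n_patients):
        sid = f"p{i:03d}"
        base = draw_participant_params(cfg.patient_spec, _rng_for(seed, 1, i))
        cnr = (
            float(link.mean + link.sd * _rng_for(seed, 1, i, 9).standard_normal())
            if link
            else np.nan
        )
        z = (cnr - link.mean) / link.sd if link else 0.0
        row = {
            "subject": sid,
            "group": "patient",
            "order": orders[i],
            "lc_cnr": cnr,
            **{f"true_{k}": v for k, v in base.to_dict().items()},
        }
        for s_idx, session in enumerate(("first", "second"), start=1):
            if orders[i] == "placebo_first":
                drug = "placebo" if session == "first" else "atomoxetine"
            else:
                drug = "atomoxetine" if session == "first" else "placebo"
            shift = cfg.session_mu_stop_shift if session == "second" else 0.0
            if link and drug == "atomoxetine":
                shift += link.drug_mean + link.drug_slope * z
            params = _session_params(base, shift)
            row[f"true_ssrt_{drug}"] = params.ssrt
            df = simulate_participant(params, cfg.task, _rng_for(seed, 1, i, s_idx))
            df.insert(0, "subject", sid)
            df.insert(1, "group", "patient")
            df.insert(2, "session", session)
            df.insert(3, "drug", drug)
            trials_parts.append(df)
        subject_rows.append(row)

    trials = pd.concat(trials_parts, ignore_index=True)
    return StudyData(trials=trials, subjects=pd.DataFrame(subject_rows), config=cfg)
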