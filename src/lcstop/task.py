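"""Stop-signal task engine: trial sequencing, SSD staircase, and generative
race-model agents.

Trial-level data are carried as tidy :class:`pandas.DataFrame` tables with
columns ``block, trial, kind, ssd, stimulus, response, rt`` (times in
seconds; ``ssd`` is NaN on go trials and 0 on no-go trials; ``rt`` is NaN
iff ``response == "none"``).

The task design follows the two-choice stop-signal paradigm: blocks of
go / no-go / stop trials, a 20-trial go lead-in used to set the starting
stop-signal delay (mean lead-in RT minus 200 ms), and a one-up/one-down
50 ms staircase on the SSD that targets 50% stop accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exgauss import exgauss_rvs
from .race import RaceParams

__all__ = [
    "TaskConfig",
    "SequencingError",
    "TRIAL_COLUMNS",
    "generate_trial_sequence",
    "staircase_update",
    "initial_ssd",
    "simulate_participant",
]

GO, NOGO, STOP = "go", "nogo", "stop"
LEFT, RIGHT, NONE = "left", "right", "none"

TRIAL_COLUMNS = ["block", "trial", "kind", "ssd", "stimulus", "response", "rt"]


class SequencingError(RuntimeError):
    """Raised when no trial interleaving satisfies the run-length constraints
    within the retry budget."""


@dataclass(frozen=True)
class TaskConfig:
    """Stop-signal task design parameters (times in seconds).

    The defaults reproduce the standard design: four blocks of 140 trials
    (110 go, 10 no-go, 20 stop), a 20-trial go lead-in per block, SSD
    staircased in 50 ms steps over 50-1500 ms, and a starting SSD of the
    mean lead-in go RT minus 200 ms.
    """

    n_blocks: int = 4
    trials_per_block: int = 140
    go_per_block: int = 110
    nogo_per_block: int = 10
    stop_per_block: int = 20
    lead_go_trials: int = 20
    ssd_min: float = 0.050
    ssd_max: float = 1.500
    ssd_step: float = 0.050
    ssd_start_offset: float = 0.200
    max_consec_go: int = 7
    max_consec_signal: int = 2
    fixation: float = 0.500
    # simulation-side choices (not part of the task description proper)
    response_window: float = 4.5  # omission deadline, matches the RT ceiling
    fallback_start_ssd: float = 0.300  # used when no valid lead-in RT exists
    carry_ssd_across_blocks: bool = False
    nogo_feeds_staircase: bool = False
    max_sequence_attempts: int = 10_000

    def __post_init__(self) -> None:
        if self.go_per_block + self.nogo_per_block + self.stop_per_block != self.trials_per_block:
            raise ValueError("go + nogo + stop counts must sum to trials_per_block")
        if not (0 < self.ssd_min <= self.ssd_max):
            raise ValueError("require 0 < ssd_min <= ssd_max")
        if self.ssd_step <= 0:
            raise ValueError("ssd_step must be > 0")
        if self.lead_go_trials > self.go_per_block:
            raise ValueError("lead_go_trials cannot exceed go_per_block")
        if min(self.n_blocks, self.max_consec_go, self.max_consec_signal) < 1:
            raise ValueError("counts must be >= 1")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _runs_ok(kinds: np.ndarray, config: TaskConfig) -> bool:
    """Check the interleaving constraints: no more than ``max_consec_go``
    consecutive go trials and no more than ``max_consec_signal`` consecutive
    signal trials (no-go and stop pooled)."""
    is_go = kinds == GO
    run = 0
    for g in is_go:
        run = run + 1 if g else 0
        if run > config.max_consec_go:
            return False
    run = 0
    for g in is_go:
        run = 0 if g else run + 1
        if run > config.max_consec_signal:
            return False
    return True


def generate_trial_sequence(config: TaskConfig = TaskConfig(), seed=None) -> pd.DataFrame:
    """Generate a full trial sequence (responses absent).

    Each block starts with ``lead_go_trials`` go trials; the remaining
    trials are pseudorandomly interleaved by rejection resampling until the
    run-length constraints hold.  Deterministic given ``seed``.
    """
    rng = _as_rng(seed)
    rows = []
    for b in range(config.n_blocks):
        remainder = np.array(
            [GO] * (config.go_per_block - config.lead_go_trials)
            + [NOGO] * config.nogo_per_block
            + [STOP] * config.stop_per_block
        )
        for attempt in range(config.max_sequence_attempts):
            rng.shuffle(remainder)
            if _runs_ok(remainder, config):
                break
        else:
            raise SequencingError(
                f"no valid interleaving found in {config.max_sequence_attempts} attempts"
            )
        kinds = np.concatenate([np.array([GO] * config.lead_go_trials), remainder])
        stimulus = np.where(rng.random(config.trials_per_block) < 0.5, LEFT, RIGHT)
        ssd = np.where(kinds == NOGO, 0.0, np.nan)
        rows.append(
            pd.DataFrame(
                {
                    "block": b,
                    "trial": np.arange(config.trials_per_block),
                    "kind": kinds,
                    "ssd": ssd,
                    "stimulus": stimulus,
                    "response": NONE,
                    "rt": np.nan,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)[TRIAL_COLUMNS]


def staircase_update(ssd: float, stop_success: bool, config: TaskConfig = TaskConfig()) -> float:
    """One-up/one-down SSD staircase: a successful stop raises the SSD by one
    step, a failed stop lowers it, hard-clamped to [ssd_min, ssd_max]."""
    new = ssd + config.ssd_step if stop_success else ssd - config.ssd_step
    return float(min(max(new, config.ssd_min), config.ssd_max))


def initial_ssd(lead_go_rts: Sequence[float], config: TaskConfig = TaskConfig()) -> float:
    """Starting SSD: mean lead-in go RT minus ``ssd_start_offset``, clamped to
    the staircase range.  Omitted trials must be excluded by the caller."""
    rts = np.asarray(list(lead_go_rts), dtype=float)
    if rts.size == 0:
        raise ValueError("lead_go_rts must be non-empty")
    val = float(np.mean(rts)) - config.ssd_start_offset
    return float(min(max(val, config.ssd_min), config.ssd_max))


def _other(side: str) -> str:
    return RIGHT if side == LEFT else LEFT


def simulate_participant(
    params: RaceParams,
    config: TaskConfig = TaskConfig(),
    seed=None,
    sequence: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Simulate one participant-session from the generative race model.

    Go trials: with probability ``p_gf`` the go process never launches
    (omission); otherwise the faster of the match/mismatch runners determines
    the response side and RT.  Stop and no-go trials: the go side is drawn
    the same way; with probability ``p_tf`` the stop runner never launches,
    otherwise its finish time is SSD plus an ex-Gaussian draw, and a response
    is emitted iff the winning go time beats the stop finish.  The SSD is
    staircased online from the lead-in starting value.  Responses slower than
    ``config.response_window`` are recorded as omissions.
    """
    rng = _as_rng(seed)
    seq = generate_trial_sequence(config, rng) if sequence is None else sequence.copy()

    out_ssd = seq["ssd"].to_numpy(dtype=float).copy()
    out_resp = np.full(len(seq), NONE, dtype=object)
    out_rt = np.full(len(seq), np.nan)

    current_ssd = config.fallback_start_ssd
    for b, block in seq.groupby("block", sort=True):
        idx = block.index.to_numpy()
        n = len(idx)
        gm = params.go_match.rvs(n, rng)
        gmm = params.go_mismatch.rvs(n, rng)
        stop_extra = params.stop.rvs(n, rng)
        go_fail = rng.random(n) < params.p_gf
        trig_fail = rng.random(n) < params.p_tf
        go_time = np.minimum(gm, gmm)
        go_is_match = gm <= gmm

        kinds = block["kind"].to_numpy()
        stims = block["stimulus"].to_numpy()

        lead_rts = []
        block_start_done = config.carry_ssd_across_blocks and b > 0
        for j in range(n):
            i = idx[j]
            kind = kinds[j]
            if kind == GO:
                if not (go_fail[j] or go_time[j] > config.response_window):
                    side = stims[j] if go_is_match[j] else _other(stims[j])
                    out_resp[i] = side
                    out_rt[i] = go_time[j]
                    if j < config.lead_go_trials and side == stims[j]:
                        lead_rts.append(go_time[j])
                continue
            # first signal trial of the block: fix the starting SSD
            if not block_start_done:
                current_ssd = (
                    initial_ssd(lead_rts, config)
                    if lead_rts
                    else float(
                        min(max(config.fallback_start_ssd, config.ssd_min), config.ssd_max)
                    )
                )
                block_start_done = True
            d = 0.0 if kind == NOGO else current_ssd
            out_ssd[i] = d
            responded = False
            if not go_fail[j]:
                t = go_time[j]
                stop_wins = (not trig_fail[j]) and (d + stop_extra[j] <= t)
                if not stop_wins and t <= config.response_window:
                    side = stims[j] if go_is_match[j] else _other(stims[j])
                    out_resp[i] = side
                    out_rt[i] = t
                    responded = True
            if kind == STOP or (kind == NOGO and config.nogo_feeds_staircase):
                current_ssd = staircase_update(current_ssd, not responded, config)

    seq["ssd"] = out_ssd
    seq["response"] = out_resp
    seq["rt"] = out_rt
    return seq
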