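"""Race-model likelihood machinery: trivial identities, Monte-Carlo
oracles, censoring structure and RT preprocessing."""

import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from lcstop import (
    ExGauss,
    PreprocessRule,
    RaceParams,
    TaskConfig,
    dataset_loglik,
    go_trial_loglik,
    inhibit_probability,
    preprocess_rts,
    simulate_participant,
    stop_inhibit_loglik,
    stop_respond_loglik,
)
from conftest import make_trial, trials_frame


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def test_preprocess_floor_rule():
    df = trials_frame(
        [make_trial(rt=r) for r in (0.1, 0.5, 0.6)]
    )
    kept, rep = preprocess_rts(df)
    assert rep.removed_floor == 1 and rep.removed_ceiling == 0
    assert sorted(kept["rt"]) == [0.5, 0.6]


def test_preprocess_identity_when_clean():
    df = trials_frame([make_trial(rt=r) for r in np.linspace(0.4, 0.6, 20)])
    kept, rep = preprocess_rts(df)
    assert len(kept) == len(df) and rep.n_removed == 0


def test_preprocess_known_outlier_counts():
    """Hand-enumerated 100-trial set.

    95 go responses around 0.5 s, two at 0.1 s (floor), one at 5.0 s
    (ceiling), two at 3.0 s.  After the absolute rules 97 go RTs remain
    (90 x 0.50, 5 x 0.52, 2 x 3.0); their mean is 0.5526 and SD 0.3557, so
    mean + 2.5 SD = 1.4418: the two 3.0 s RTs are SD-trimmed.  95 trials
    survive.
    """
    rts = [0.50] * 90 + [0.52] * 5 + [0.1, 0.1, 5.0, 3.0, 3.0]
    df = trials_frame([make_trial(rt=r) for r in rts])
    assert len(df) == 100
    kept, rep = preprocess_rts(df)
    assert rep.removed_floor == 2
    assert rep.removed_ceiling == 1
    assert rep.removed_sd == 2
    assert len(kept) == 95


def test_preprocess_leaves_omissions_and_skips_sd_rule_when_sparse():
    df = trials_frame(
        [
            make_trial(response="none", rt=np.nan),
            make_trial(rt=0.5),
            make_trial(kind="stop", ssd=0.2, rt=0.4),
        ]
    )
    with pytest.warns(UserWarning):
        kept, rep = preprocess_rts(df)
    assert not rep.sd_rule_applied
    assert (kept["response"] == "none").sum() == 1


def test_preprocess_sd_rule_spares_signal_respond_rts():
    """Only go RTs are subject to the 2.5 SD trim."""
    recs = [make_trial(rt=0.5) for _ in range(50)]
    recs.append(make_trial(rt=0.8))  # mild go spread so SD > 0
    recs.append(make_trial(kind="stop", ssd=0.2, rt=4.4))  # extreme but signal-respond
    df = trials_frame(recs)
    kept, rep = preprocess_rts(df)
    assert 4.4 in kept["rt"].to_numpy()


# ---------------------------------------------------------------------------
# trivial likelihood identities
# ---------------------------------------------------------------------------

def test_go_omission_impossible_without_go_failure(generic_params):
    p = replace(generic_params, p_gf=0.0)
    tr = make_trial(response="none", rt=np.nan)
    assert go_trial_loglik(tr, p) == -math.inf


def test_go_symmetric_runners_equal_likelihood():
    p = RaceParams(
        stop=ExGauss(0.2, 0.03, 0.05),
        go_match=ExGauss(0.5, 0.05, 0.1),
        go_mismatch=ExGauss(0.5, 0.05, 0.1),
    )
    correct = make_trial(response="left", rt=0.45)
    error = make_trial(response="right", rt=0.45)
    assert go_trial_loglik(correct, p) == pytest.approx(go_trial_loglik(error, p))


def test_stop_respond_reduces_to_go_when_trigger_always_fails(generic_params):
    p = replace(generic_params, p_tf=1.0)
    stop_tr = make_trial(kind="stop", ssd=0.2, rt=0.45)
    go_tr = make_trial(rt=0.45)
    assert stop_respond_loglik(stop_tr, p) == pytest.approx(go_trial_loglik(go_tr, p))


def test_inhibit_impossible_when_trigger_always_fails():
    p = RaceParams(
        stop=ExGauss(0.2, 0.03, 0.05),
        go_match=ExGauss(0.5, 0.05, 0.1),
        go_mismatch=ExGauss(0.6, 0.07, 0.12),
        p_tf=1.0,
        p_gf=0.0,
    )
    tr = make_trial(kind="stop", ssd=0.2, response="none", rt=np.nan)
    assert stop_inhibit_loglik(tr, p) == -math.inf


def test_inhibit_via_go_failure_only():
    p = RaceParams(
        stop=ExGauss(0.2, 0.03, 0.05),
        go_match=ExGauss(0.5, 0.05, 0.1),
        go_mismatch=ExGauss(0.6, 0.07, 0.12),
        p_tf=1.0,
        p_gf=0.2,
    )
    tr = make_trial(kind="stop", ssd=0.2, response="none", rt=np.nan)
    assert stop_inhibit_loglik(tr, p) == pytest.approx(math.log(0.2))


def test_negative_rt_rejected(generic_params):
    with pytest.raises(ValueError):
        stop_respond_loglik(make_trial(kind="stop", ssd=0.2, rt=-0.1), generic_params)


# ---------------------------------------------------------------------------
# Monte-Carlo oracles
# ---------------------------------------------------------------------------

def _race_mc(params, d, n, rng):
    gm = params.go_match.rvs(n, rng)
    gmm = params.go_mismatch.rvs(n, rng)
    st = params.stop.rvs(n, rng)
    gf = rng.random(n) < params.p_gf
    tf = rng.random(n) < params.p_tf
    go_t = np.minimum(gm, gmm)
    stop_wins = ~tf & (d + st <= go_t)
    inhibited = gf | stop_wins
    return inhibited, go_t, gm <= gmm


def test_inhibition_probability_matches_simulation(generic_params, rng):
    n = 200_000
    for d in (0.15, 0.3):
        inhibited, _, _ = _race_mc(generic_params, d, n, rng)
        mc = inhibited.mean()
        se = math.sqrt(mc * (1 - mc) / n)
        pred = math.exp(
            stop_inhibit_loglik(
                make_trial(kind="stop", ssd=d, response="none", rt=np.nan),
                generic_params,
            )
        )
        assert abs(pred - mc) < 4 * se


def test_signal_respond_density_matches_simulation(generic_params, rng):
    d = 0.25
    n = 200_000
    inhibited, go_t, is_match = _race_mc(generic_params, d, n, rng)
    resp_t = go_t[~inhibited]
    edges = np.quantile(resp_t, np.linspace(0, 1, 9))
    edges[0], edges[-1] = 0.0, 10.0

    def density(t):
        out = 0.0
        for match in (True, False):
            tr = make_trial(
                kind="stop", ssd=d,
                response="left" if match else "right", stimulus="left", rt=t,
            )
            out += math.exp(stop_respond_loglik(tr, generic_params))
        return out

    p_resp = 1 - inhibited.mean()
    for lo, hi in zip(edges[:-1], edges[1:]):
        pred_mass, _ = integrate.quad(density, lo, hi, limit=200)
        mc_mass = np.mean((go_t >= lo) & (go_t < hi) & ~inhibited)
        se = math.sqrt(max(mc_mass * (1 - mc_mass), 1e-12) / n)
        assert abs(pred_mass - mc_mass) < 4 * se + 1e-4


def test_go_choice_rt_density_matches_simulation(generic_params, rng):
    """Defective choice/RT density from the likelihood matches simulated go
    trials (choice proportions x RT histogram)."""
    n = 200_000
    gm = generic_params.go_match.rvs(n, rng)
    gmm = generic_params.go_mismatch.rvs(n, rng)
    gf = rng.random(n) < generic_params.p_gf
    t = np.minimum(gm, gmm)
    correct = (gm <= gmm) & ~gf
    error = (gm > gmm) & ~gf

    def dens(t, match):
        tr = make_trial(response="left" if match else "right", stimulus="left", rt=t)
        return math.exp(go_trial_loglik(tr, generic_params))

    # total correct-response probability
    pc_pred, _ = integrate.quad(lambda x: dens(x, True), 0, 10, limit=200)
    pc_mc = correct.mean()
    assert abs(pc_pred - pc_mc) < 4 * math.sqrt(pc_mc * (1 - pc_mc) / n)
    # decile masses of the correct-RT distribution
    edges = np.quantile(t[correct], np.linspace(0, 1, 9))
    edges[0], edges[-1] = 0.0, 10.0
    for lo, hi in zip(edges[:-1], edges[1:]):
        pred, _ = integrate.quad(lambda x: dens(x, True), lo, hi, limit=200)
        mc = np.mean(correct & (t >= lo) & (t < hi))
        assert abs(pred - mc) < 4 * math.sqrt(mc * (1 - mc) / n) + 1e-4


# ---------------------------------------------------------------------------
# structural properties
# ---------------------------------------------------------------------------

def test_outcome_probabilities_sum_to_one(generic_params):
    d = 0.25
    p_inh = math.exp(
        stop_inhibit_loglik(
            make_trial(kind="stop", ssd=d, response="none", rt=np.nan), generic_params
        )
    )

    def density(t):
        out = 0.0
        for match in (True, False):
            tr = make_trial(
                kind="stop", ssd=d,
                response="left" if match else "right", stimulus="left", rt=t,
            )
            out += math.exp(stop_respond_loglik(tr, generic_params))
        return out

    p_resp, _ = integrate.quad(density, 0, 30, limit=300)
    assert p_inh + p_resp == pytest.approx(1.0, abs=1e-6)


def test_earlier_stop_signal_censors_more(generic_params):
    """Signal-respond density is suppressed as the SSD decreases."""
    t = 0.5
    lls = [
        stop_respond_loglik(make_trial(kind="stop", ssd=d, rt=t), generic_params)
        for d in (0.1, 0.2, 0.3, 0.45)
    ]
    assert all(a < b for a, b in zip(lls[:-1], lls[1:]))


def test_nogo_uses_zero_delay(generic_params):
    tr_nogo = make_trial(kind="nogo", ssd=0.0, response="none", rt=np.nan)
    tr_stop = make_trial(kind="stop", ssd=0.0, response="none", rt=np.nan)
    assert stop_inhibit_loglik(tr_nogo, generic_params) == pytest.approx(
        stop_inhibit_loglik(tr_stop, generic_params)
    )


def test_dataset_loglik_empty_and_permutation(generic_params):
    df = simulate_participant(generic_params, TaskConfig(n_blocks=1), seed=6)
    assert dataset_loglik(df.iloc[0:0], generic_params) == 0.0
    shuffled = df.sample(frac=1, random_state=1)
    assert dataset_loglik(df, generic_params) == pytest.approx(
        dataset_loglik(shuffled, generic_params)
    )


def test_dataset_loglik_equals_sum_of_trial_contributions(generic_params):
    df = simulate_participant(generic_params, TaskConfig(n_blocks=1), seed=7)
    total = 0.0
    for _, tr in df.iterrows():
        if tr["kind"] == "go":
            total += go_trial_loglik(tr, generic_params)
        elif tr["response"] != "none":
            total += stop_respond_loglik(tr, generic_params)
        else:
            total += stop_inhibit_loglik(tr, generic_params)
    assert dataset_loglik(df, generic_params) == pytest.approx(total, abs=1e-6)


def test_trigger_failure_improves_fit_on_tf_data(generic_params):
    """Data generated with p_tf = 0.2 are better explained at the true
    trigger-failure rate than with p_tf forced to zero."""
    p_true = replace(generic_params, p_tf=0.2)
    df = simulate_participant(p_true, TaskConfig(n_blocks=8), seed=8)
    ll_true = dataset_loglik(df, p_true)
    ll_no_tf = dataset_loglik(df, replace(p_true, p_tf=0.0))
    assert ll_true > ll_no_tf


def test_params_roundtrip_and_validation(generic_params):
    d = generic_params.to_dict()
    assert RaceParams.from_dict(d) == generic_params
    with pytest.raises(ValueError):
        RaceParams(
            stop=ExGauss(0.2, 0.03, 0.05),
            go_match=ExGauss(0.5, 0.05, 0.1),
            go_mismatch=ExGauss(0.6, 0.07, 0.12),
            p_tf=1.5,
        )
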