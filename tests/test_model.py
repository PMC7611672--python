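"""Inference machinery: R-hat diagnostics, contrasts, derived posteriors,
sampler determinism and posterior-predictive self-consistency."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lcstop import (
    ExGauss,
    HierarchicalPrior,
    HierarchicalRaceModel,
    PosteriorDraws,
    RaceModelResults,
    RaceParams,
    SamplerConfig,
    TaskConfig,
    contrast,
    simulate_participant,
    split_rhat,
)
from lcstop._likelihood import PARAM_NAMES
from lcstop.model import truncnorm_logpdf


# ---------------------------------------------------------------------------
# R-hat
# ---------------------------------------------------------------------------

def test_rhat_identical_constant_chains_is_one():
    draws = np.full((4, 100), 3.14)
    assert split_rhat(draws) == 1.0


def test_rhat_constant_chains_at_different_values_is_inf():
    draws = np.vstack([np.zeros((2, 50)), np.ones((2, 50))])
    assert split_rhat(draws) == np.inf


def test_rhat_iid_stationary_chains_near_one(rng):
    draws = rng.standard_normal((4, 10_000))
    assert split_rhat(draws) == pytest.approx(1.0, abs=0.01)


def test_rhat_separated_chains_matches_hand_computation():
    """Two chains centred at 0 and 10 with unit-ish spread: B/W is enormous
    and R-hat >> 1.1; compare against the closed-form split-chain value."""
    rng = np.random.default_rng(5)
    a = rng.standard_normal(1000)
    b = rng.standard_normal(1000) + 10.0
    draws = np.vstack([a, b])
    # hand computation on the four split sequences
    seqs = [a[:500], a[500:], b[:500], b[500:]]
    means = np.array([s.mean() for s in seqs])
    W = np.mean([s.var(ddof=1) for s in seqs])
    B = 500 * means.var(ddof=1)
    expected = np.sqrt(((499 / 500) * W + B / 500) / W)
    assert split_rhat(draws) == pytest.approx(expected, rel=1e-12)
    assert split_rhat(draws) > 5.0


def test_rhat_agrees_with_arviz(rng):
    import arviz as az

    draws = rng.standard_normal((4, 500)).cumsum(axis=1) * 0.01 + rng.standard_normal(
        (4, 500)
    )
    ours = split_rhat(draws)
    theirs = float(az.rhat(az.convert_to_dataset(draws[None, ...][0]), method="split")["x"])
    assert ours == pytest.approx(theirs, rel=1e-6)


def test_rhat_requires_two_chains():
    with pytest.raises(ValueError):
        split_rhat(np.zeros((1, 100)))


# ---------------------------------------------------------------------------
# contrasts
# ---------------------------------------------------------------------------

def test_contrast_identical_sets(rng):
    a = rng.standard_normal(1000)
    res = contrast(a, a)
    assert res.median == 0.0
    assert res.qi[0] <= 0.0 <= res.qi[1]
    assert not res.reliable


def test_contrast_recovers_shift(rng):
    a = rng.standard_normal(2000) * 0.01 + 0.46
    res = contrast(a, a - 0.07)
    assert res.median == pytest.approx(0.07, abs=1e-12)
    assert res.reliable


def test_contrast_subsamples_longer_run(rng):
    a = rng.standard_normal(1500) + 1.0
    b = rng.standard_normal(1000)
    res = contrast(a, b)
    assert res.samples.size == 1000
    assert res.median == pytest.approx(1.0, abs=0.15)


# ---------------------------------------------------------------------------
# truncated-normal prior machinery
# ---------------------------------------------------------------------------

def test_truncnorm_logpdf_matches_scipy():
    x = np.linspace(0.1, 2.5, 25)
    loc, scale, lo, hi = 0.8, 0.5, 0.0, 3.0
    ref = stats.truncnorm.logpdf(x, (lo - loc) / scale, (hi - loc) / scale, loc, scale)
    np.testing.assert_allclose(truncnorm_logpdf(x, loc, scale, lo, hi), ref, rtol=1e-9)
    assert truncnorm_logpdf(-0.1, loc, scale, lo, hi) == -np.inf


def test_truncnorm_logpdf_deep_tail_finite():
    lp = truncnorm_logpdf(0.01, -5.0, 0.3, 0.005, 5.0)
    assert np.isfinite(lp)


def test_default_prior_has_all_parameters():
    prior = HierarchicalPrior.default()
    assert list(prior.params) == PARAM_NAMES
    # the three location means that encode slower ageing RTs
    assert prior.params["mu_go_match"].loc_mean == 1.5
    assert prior.params["mu_go_mismatch"].loc_mean == 1.5
    assert prior.params["mu_stop"].loc_mean == 1.0


def test_prior_yaml_roundtrip(tmp_path):
    prior = HierarchicalPrior.default()
    path = tmp_path / "p.yaml"
    prior.to_yaml(path)
    again = HierarchicalPrior.from_yaml(path)
    assert vars(again.params["tau_stop"]) == vars(prior.params["tau_stop"])


# ---------------------------------------------------------------------------
# derived posteriors on hand-built draws
# ---------------------------------------------------------------------------

def _toy_results(group, subject=None, names=None):
    names = names or PARAM_NAMES
    g_names = [f"loc_{n}" for n in names] + [f"scale_{n}" for n in names]
    if subject is None:
        subject = np.zeros((group.shape[0], group.shape[1], 2, len(names)))
    draws = PosteriorDraws(
        group=group, subject=subject, group_names=g_names,
        param_names=list(names), participants=["a", "b"],
    )
    return RaceModelResults(model=None, draws=draws, converged=True, config=SamplerConfig())


def test_derive_ssrt_is_mu_plus_tau():
    k = len(PARAM_NAMES)
    group = np.zeros((2, 3, 2 * k))
    i_mu = PARAM_NAMES.index("mu_stop")
    i_tau = PARAM_NAMES.index("tau_stop")
    group[:, :, i_mu] = 0.2
    group[:, :, i_tau] = 0.1
    res = _toy_results(group)
    np.testing.assert_allclose(res.derive_ssrt("group"), 0.3)
    # tau -> 0 limit
    group[:, :, i_tau] = 0.0
    np.testing.assert_allclose(_toy_results(group).derive_ssrt("group"), 0.2)


def test_summaries_invariant_to_chain_permutation(rng):
    k = len(PARAM_NAMES)
    group = rng.standard_normal((6, 50, 2 * k))
    a = _toy_results(group).summary()
    b = _toy_results(group[::-1]).summary()
    pd.testing.assert_frame_equal(a, b)
    assert _toy_results(group).max_rhat == pytest.approx(
        _toy_results(group[::-1]).max_rhat
    )


# ---------------------------------------------------------------------------
# sampler plumbing (tiny fits)
# ---------------------------------------------------------------------------

def _tiny_data(n_participants=3, seed=0):
    p = RaceParams(
        stop=ExGauss(0.25, 0.05, 0.1),
        go_match=ExGauss(0.6, 0.08, 0.2),
        go_mismatch=ExGauss(0.9, 0.1, 0.25),
        p_tf=0.1,
        p_gf=0.05,
    )
    cfg = TaskConfig(n_blocks=1)
    return {
        f"s{i}": simulate_participant(p, cfg, seed=seed + i)
        for i in range(n_participants)
    }


_TINY_CFG = SamplerConfig(
    final_iterations=5, thin=2, burn_chunk=5, rhat_window=10**9, max_burn=5
)


def test_default_chain_count_is_three_times_parameters():
    model = HierarchicalRaceModel(_tiny_data())
    assert model.n_free_params == 11
    res = model.fit(_TINY_CFG, seed=0)
    assert res.draws.meta["n_chains"] == 33


def test_fixing_trigger_failure_removes_parameter():
    model = HierarchicalRaceModel(_tiny_data(), fixed={"p_tf": 0.0})
    assert model.n_free_params == 10
    assert "z_tf" not in model.free_names
    res = model.fit(_TINY_CFG, seed=0)
    assert res.draws.meta["n_chains"] == 30
    assert res.draws.subject.shape[-1] == 10


def test_fit_deterministic_given_seed():
    data = _tiny_data()
    r1 = HierarchicalRaceModel(data).fit(_TINY_CFG, seed=9)
    r2 = HierarchicalRaceModel(data).fit(_TINY_CFG, seed=9)
    np.testing.assert_array_equal(r1.draws.group, r2.draws.group)
    np.testing.assert_array_equal(r1.draws.subject, r2.draws.subject)
    r3 = HierarchicalRaceModel(data).fit(_TINY_CFG, seed=10)
    assert not np.array_equal(r1.draws.group, r3.draws.group)


def test_fit_requires_two_participants():
    with pytest.raises(ValueError):
        HierarchicalRaceModel(_tiny_data(1))


def test_fit_by_group_independent_fits_with_shared_priors():
    import pandas as pd

    from lcstop import fit_by_group

    frames = []
    for label in ("controls", "placebo"):
        for pid, df in _tiny_data(2, seed=hash(label) % 100).items():
            d = df.copy()
            d["subject"] = f"{label}_{pid}"
            d["group"] = label
            frames.append(d)
    out = fit_by_group(pd.concat(frames), config=_TINY_CFG, seed=0)
    assert set(out) == {"controls", "placebo"}
    for res in out.values():
        assert res.draws.group.shape[1] == _TINY_CFG.final_iterations


def test_draws_finite_and_within_bounds():
    res = HierarchicalRaceModel(_tiny_data()).fit(_TINY_CFG, seed=3)
    assert np.isfinite(res.draws.group).all()
    assert np.isfinite(res.draws.subject).all()
    k = res.draws.group.shape[-1] // 2
    assert (res.draws.group[:, :, k:] > 0).all()  # scales positive


# ---------------------------------------------------------------------------
# posterior predictive checks
# ---------------------------------------------------------------------------

def _constant_results(params: RaceParams, data: dict) -> RaceModelResults:
    """Results whose posterior is a point mass at ``params``."""
    model = HierarchicalRaceModel(data, preprocess=False)
    theta = params.theta()
    k = len(PARAM_NAMES)
    C, T, N = 4, 30, len(data)
    subject = np.tile(theta, (C, T, N, 1))
    group = np.tile(np.concatenate([theta, np.full(k, 0.05)]), (C, T, 1))
    draws = PosteriorDraws(
        group=group, subject=subject,
        group_names=[f"loc_{n}" for n in PARAM_NAMES] + [f"scale_{n}" for n in PARAM_NAMES],
        param_names=list(PARAM_NAMES), participants=list(data),
    )
    return RaceModelResults(model=model, draws=draws, converged=True, config=SamplerConfig())


def test_posterior_predictive_self_consistency(generic_params):
    data = {
        f"s{i}": simulate_participant(generic_params, TaskConfig(n_blocks=2), seed=20 + i)
        for i in range(4)
    }
    res = _constant_results(generic_params, data)
    ppc = res.posterior_predictive(n_draws=60, seed=1)
    assert ppc.go_deciles_inside() >= 0.8
    assert ppc.inhib_inside() >= 0.6


def test_posterior_predictive_detects_misspecified_stop(generic_params):
    from dataclasses import replace

    data = {
        f"s{i}": simulate_participant(generic_params, TaskConfig(n_blocks=2), seed=30 + i)
        for i in range(4)
    }
    slow_stop = replace(generic_params, stop=ExGauss(0.45, 0.03, 0.05))
    good = _constant_results(generic_params, data).posterior_predictive(60, seed=2)
    bad = _constant_results(slow_stop, data).posterior_predictive(60, seed=2)
    assert bad.inhib_inside() < good.inhib_inside()
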