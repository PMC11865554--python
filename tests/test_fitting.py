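"""Transforms, likelihood evaluation, MAP fits and model comparison."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tacit.fitting import (
    FitOptions, fit_subject_map, model_comparison, negative_loglik,
    negative_loglik_reference,
)
from tacit.gridworld import GoalConfiguration, Message, neighbors
from tacit.likelihood import CompiledTrials
from tacit.planner import ModelParams, PlannerParams, VARIANTS
from tacit.transforms import (
    n_params, param_names, to_constrained, to_unconstrained,
)


@settings(deadline=None, max_examples=50)
@given(
    tau=st.floats(0.05, 50.0),
    epsilon=st.floats(0.01, 0.99),
    lam=st.floats(0.002, 0.299),
    gamma=st.floats(2.01, 9.99),
    alpha=st.floats(1.01, 6.0),
)
def test_transform_round_trip(tau, epsilon, lam, gamma, alpha):
    params = ModelParams(tau, epsilon, lam, gamma, alpha)
    back = to_constrained("surprise", to_unconstrained("surprise", params))
    for name in param_names("surprise"):
        assert getattr(back, name) == pytest.approx(getattr(params, name),
                                                    rel=1e-9, abs=1e-10)


def test_variant_parameter_counts():
    assert n_params("surprise") == 5
    assert n_params("state") == 3
    assert n_params("movement") == 4


@pytest.mark.parametrize("variant", VARIANTS)
def test_compiled_likelihood_matches_tree_reference(small_cohort_by_subject, variant):
    """The vectorized evaluator reproduces the step-by-step policy walk."""
    trials = small_cohort_by_subject[0][:15]
    rng = np.random.default_rng(3)
    for _ in range(4):
        theta = rng.normal(scale=0.8, size=n_params(variant))
        params = to_constrained(variant, theta)
        fast = negative_loglik(trials, params, variant)
        slow = negative_loglik_reference(trials, params, variant)
        assert fast == pytest.approx(slow, rel=1e-10, abs=1e-9)


def test_nll_uniform_policy_limit(direct_config):
    """tau -> 0: NLL equals the sum of log branching factors."""
    params = ModelParams(tau=1e-12, epsilon=0.4, lam=0.1, gamma=2.1, alpha=1.8)
    msg = Message([(1, 1), (1, 2), (1, 3)])
    nll = negative_loglik([(direct_config, msg)], params, "surprise")
    k = [len(neighbors(direct_config.board, s)) for s in [(1, 1), (1, 2)]]
    assert nll == pytest.approx(sum(math.log(x) for x in k), abs=1e-6)


def test_nll_additivity(small_cohort_by_subject, table1_params):
    trials = small_cohort_by_subject[1][:10]
    single = negative_loglik(trials, table1_params, "surprise")
    doubled = negative_loglik(list(trials) * 2, table1_params, "surprise")
    assert doubled == pytest.approx(2 * single, rel=1e-12)


def test_nll_lower_at_generating_than_perturbed_params(small_cohort_by_subject,
                                                       table1_params):
    """On average, the generating parameters beat a +50% tau perturbation."""
    perturbed = ModelParams(tau=table1_params.tau * 1.5,
                            epsilon=table1_params.epsilon,
                            lam=table1_params.lam, gamma=table1_params.gamma,
                            alpha=table1_params.alpha)
    diffs = [negative_loglik(trials, perturbed, "surprise")
             - negative_loglik(trials, table1_params, "surprise")
             for trials in small_cohort_by_subject]
    assert np.mean(diffs) > 0


def test_fit_subject_map_recovers_parameters(small_cohort_by_subject):
    """MAP estimates land near the generating values on a 40-trial subject."""
    from tacit.synthetic import DEFAULT_GROUP_PARAMS, SyntheticSpec
    trials = small_cohort_by_subject[2]
    fit = fit_subject_map(trials, "surprise",
                          options=FitOptions(n_starts=8, n_optimize=2, seed=0))
    assert fit.converged
    gen = DEFAULT_GROUP_PARAMS["surprise"]
    # loose sanity bounds: the cohort draws subjects around the group mean
    assert 0.03 <= fit.params.lam <= 0.25
    assert 1.2 <= fit.params.alpha <= 4.5
    assert fit.nll < negative_loglik(trials, gen, "surprise") + 5.0
    # Laplace evidence penalizes the fit relative to the raw optimum
    assert fit.log_evidence < -fit.nll + 10.0


def test_fit_flat_data_returns_prior_dominated_estimate():
    """A single repeated forced-ish trajectory carries almost no information;
    the posterior hugs the group prior mean."""
    config = GoalConfiguration((1, 1), (1, 2), (2, 1))
    msg = Message([(1, 1), (2, 1), (1, 1), (1, 2)])
    trials = [(config, msg)] * 3
    mu = np.zeros(n_params("state"))
    var = np.full(n_params("state"), 0.05)
    with pytest.warns(UserWarning):
        fit = fit_subject_map(trials, "state", group_prior=(mu, var),
                              options=FitOptions(n_starts=4, n_optimize=1))
    assert np.all(np.abs(fit.theta - mu) < 1.0)


def test_model_comparison_equal_evidences():
    L = np.zeros((12, 3))
    mc = model_comparison(L, VARIANTS, n_draws=200_000, rng=0)
    assert mc.frequencies == pytest.approx([1 / 3] * 3, abs=0.02)
    assert mc.protected_exceedance_probability == pytest.approx([1 / 3] * 3,
                                                                abs=0.05)
    assert mc.frequencies.sum() == pytest.approx(1.0)
    # the omnibus null (all variants equal) is favored
    assert mc.bayes_omnibus_risk > 0.5


def test_model_comparison_dominant_variant():
    rng = np.random.default_rng(1)
    L = rng.normal(-100.0, 1.0, size=(15, 3))
    L[:, 0] += 10.0  # one variant better by ~10 nats for every subject
    mc = model_comparison(L, VARIANTS, n_draws=200_000, rng=2)
    assert mc.protected_exceedance_probability[0] > 0.99
    assert np.argmax(mc.frequencies) == 0
    assert mc.frequencies.sum() == pytest.approx(1.0)


def test_model_comparison_identical_columns_split_evenly():
    rng = np.random.default_rng(4)
    col = rng.normal(-80, 5, size=15)
    L = np.stack([col, col], axis=1)
    mc = model_comparison(L, ("a", "b"), n_draws=100_000, rng=5)
    assert mc.frequencies == pytest.approx([0.5, 0.5], abs=0.02)


def test_model_comparison_single_variant_degenerate():
    mc = model_comparison(np.full((5, 1), -10.0), ("surprise",))
    assert mc.frequencies[0] == 1.0
    assert mc.protected_exceedance_probability[0] == 1.0


def test_model_comparison_rejects_non_finite():
    L = np.zeros((4, 2))
    L[0, 0] = np.nan
    with pytest.raises(ValueError):
        model_comparison(L, ("a", "b"))
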