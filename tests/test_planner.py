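"""Two-phase planning, lookahead values, softmax policy and likelihoods."""

import math

import numpy as np
import pytest

from tacit.gridworld import (
    Board, E, GoalConfiguration, Message, N, S, W, neighbors,
)
from tacit.planner import (
    ModelParams, PlannerParams, PolicyEngine, expected_values,
    generate_message, sequence_loglik, softmax_policy, step_value,
    validate_variant_params,
)
from tacit.priors import surprise

from conftest import all_board_symmetries

SYM_DIRS = {  # how each board symmetry maps absolute directions
}


def test_variant_parameter_validation():
    validate_variant_params("surprise", ModelParams(1.0, 0.5, 0.1, 2.0, 1.8))
    validate_variant_params("state", ModelParams(1.0, 0.5, alpha=1.8))
    validate_variant_params("movement", ModelParams(1.0, 0.5, lam=0.1, gamma=2.0))
    with pytest.raises(ValueError):
        validate_variant_params("state", ModelParams(1.0, 0.5, lam=0.1, alpha=1.8))
    with pytest.raises(ValueError):
        validate_variant_params("movement", ModelParams(1.0, 0.5, lam=0.1, gamma=2.0,
                                                        alpha=1.8))
    with pytest.raises(ValueError):
        validate_variant_params("surprise", ModelParams(1.0, 0.5, lam=0.1, gamma=2.0))
    with pytest.raises(ValueError):
        validate_variant_params("belief", ModelParams(1.0, 0.5))


def test_step_value_undiscounted_reduces_to_surprise_times_reward():
    dist = {N: 0.25, E: 0.5, S: 0.25}
    assert step_value("surprise", 1, dist, N, reward=3.0, depth_i=0,
                      epsilon=1.0 - 1e-12) == pytest.approx(2.0 * 3.0)
    # phase 2 of the full model scores by probability, not surprise
    assert step_value("surprise", 2, dist, N, reward=3.0, depth_i=0,
                      epsilon=0.5) == pytest.approx(0.25 * 3.0)


def test_step_value_zero_reward_and_discount():
    dist = {N: 0.5, S: 0.5}
    assert step_value("surprise", 1, dist, N, reward=0.0, depth_i=0, epsilon=0.4) == 0.0
    # epsilon = 0.39, depth 2, h = 1 bit, r = 5 -> 0.39^2 * 5
    assert step_value("surprise", 1, dist, N, reward=5.0, depth_i=2,
                      epsilon=0.39) == pytest.approx(0.7605)
    with pytest.raises(ValueError):
        step_value("surprise", 3, dist, N, 1.0, 0, 0.5)


def test_expected_values_horizon_one_is_single_step(indirect_config, table1_params):
    engine = PolicyEngine(indirect_config, "surprise", table1_params,
                          PlannerParams(horizon=1))
    ev = engine.expected_values(indirect_config.start, None, 0, False)
    for move, target in neighbors(indirect_config.board, indirect_config.start):
        dist = engine.action_dist(indirect_config.start, None, 1)
        r = engine._reward(target, 1, target == indirect_config.receiver_goal)
        assert ev[move] == pytest.approx(surprise(dist, move) * r)


def _brute_force_ev(config, s, heading, steps_taken, rg_visited, variant,
                    params, horizon):
    """Independent oracle: enumerate every move sequence explicitly."""
    engine = PolicyEngine(config, variant, params, PlannerParams(horizon=horizon))

    def all_paths(s, heading, rg_vis, depth):
        if depth == horizon:
            return [[]]
        out = []
        for d, t in neighbors(config.board, s):
            vis2 = rg_vis or t == config.receiver_goal
            if t == config.sender_goal and (vis2 or variant == "state"):
                out.append([(s, heading, rg_vis, d)])
                continue
            for tail in all_paths(t, d, vis2, depth + 1):
                out.append([(s, heading, rg_vis, d)] + tail)
        return out

    best = {}
    for path in all_paths(s, heading, rg_visited, 0):
        total = 0.0
        for i, (ps, ph, pvis, move) in enumerate(path):
            phase = 2 if pvis else 1
            dist = engine.action_dist(ps, ph, phase)
            t = dict(neighbors(config.board, ps))[move]
            vis2 = pvis or t == config.receiver_goal
            r = engine._reward(t, steps_taken + i + 1, vis2)
            total += step_value(variant, phase, dist, move, r, i, params.epsilon)
        first = path[0][3]
        best[first] = max(best.get(first, -np.inf), total)
    return best


@pytest.mark.parametrize("variant, params", [
    ("surprise", ModelParams(2.0, 0.5, 0.1, 2.0, 1.8)),
    ("state", ModelParams(2.0, 0.5, alpha=1.8)),
    ("movement", ModelParams(2.0, 0.5, lam=0.1, gamma=2.0)),
])
@pytest.mark.parametrize("shape", [(2, 2), (2, 3)])
def test_expected_values_match_brute_force_on_small_boards(variant, params, shape):
    board = Board(*shape)
    config = GoalConfiguration((0, 0), (shape[0] - 1, shape[1] - 1), (0, 1),
                               board)
    for horizon in (1, 2):
        ev = expected_values(config, (0, 0), None, 0, variant, params,
                             PlannerParams(horizon=horizon))
        oracle = _brute_force_ev(config, (0, 0), None, 0, False, variant,
                                 params, horizon)
        assert set(ev) == set(oracle)
        for move in ev:
            assert ev[move] == pytest.approx(oracle[move], abs=1e-12)


def test_expected_values_symmetry_invariance(table1_params):
    """EVs are equivariant under the board's symmetry group."""
    config = GoalConfiguration((1, 1), (0, 3), (2, 2))
    base = expected_values(config, (1, 1), None, 0, "surprise", table1_params)
    for sym in all_board_symmetries():
        mapped = GoalConfiguration(sym(config.start), sym(config.sender_goal),
                                   sym(config.receiver_goal))
        ev = expected_values(mapped, sym((1, 1)), None, 0, "surprise",
                             table1_params)
        # compare by landing cell rather than direction code
        base_by_cell = {sym(dict(neighbors(config.board, (1, 1)))[m]): v
                        for m, v in base.items()}
        ev_by_cell = {dict(neighbors(config.board, sym((1, 1))))[m]: v
                      for m, v in ev.items()}
        for cell, v in base_by_cell.items():
            assert ev_by_cell[cell] == pytest.approx(v, abs=1e-10)


def test_softmax_policy_examples():
    assert softmax_policy({N: 1.0, S: 1.0, E: 1.0}, tau=5.0) == pytest.approx(
        {N: 1 / 3, S: 1 / 3, E: 1 / 3})
    pol = softmax_policy({N: 1.0, S: 0.0}, tau=6.93)
    assert pol[N] == pytest.approx(0.99903, abs=1e-4)
    # tau -> 0+ approaches uniform
    pol = softmax_policy({N: 5.0, S: -3.0}, tau=1e-9)
    assert pol[N] == pytest.approx(0.5, abs=1e-6)
    # overflow safety
    pol = softmax_policy({N: 1e4, S: 0.0}, tau=10.0)
    assert pol[N] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        softmax_policy({}, 1.0)
    with pytest.raises(ValueError):
        softmax_policy({N: 1.0}, 0.0)


def test_softmax_argmax_probability_increases_with_tau():
    ev = {N: 1.0, S: 0.4, E: 0.1}
    probs = [softmax_policy(ev, tau)[N] for tau in (0.5, 1.0, 2.0, 4.0, 8.0)]
    assert all(a < b for a, b in zip(probs, probs[1:]))


def test_generate_message_deterministic_replay(indirect_config, table1_params):
    plan1 = generate_message(indirect_config, "surprise", table1_params, rng=123)
    plan2 = generate_message(indirect_config, "surprise", table1_params, rng=123)
    assert plan1.message.states == plan2.message.states
    assert plan1.message.step_surprise == plan2.message.step_surprise


def test_generate_message_structure(indirect_config, table1_params):
    plan = generate_message(indirect_config, "surprise", table1_params, rng=5)
    msg = plan.message
    assert msg.states[0] == indirect_config.start
    if not plan.aborted:
        assert msg.states[-1] == indirect_config.sender_goal
        assert msg.visits(indirect_config.receiver_goal)
        # phase switches exactly once, at the first arrival at the receiver goal
        arrival = msg.arrival_step(indirect_config.receiver_goal)
        phases = [s.phase for s in plan.steps]
        assert phases == [1] * arrival + [2] * (len(phases) - arrival)
    assert plan.total_points == 10.0 - msg.n_moves


def test_state_variant_high_tau_takes_shortest_path(indirect_config):
    """Goal-orientation alone walks the shortest route to the sender goal."""
    params = ModelParams(tau=500.0, epsilon=0.39, alpha=1.84)
    plan = generate_message(indirect_config, "state", params, rng=0)
    d = abs(1 - 1) + abs(1 - 3)
    assert plan.message.n_moves == d
    assert plan.message.states[-1] == indirect_config.sender_goal


def test_messages_visit_receiver_goal_before_sender_goal(table1_params):
    """Completed plans pass through the receiver goal before finishing."""
    from tacit.synthetic import sample_goal_configuration
    rng = np.random.default_rng(99)
    ok = total = 0
    for _ in range(200):
        config = sample_goal_configuration(rng=rng)
        plan = generate_message(config, "surprise", table1_params, rng=rng)
        if plan.aborted:
            continue
        total += 1
        arr_rg = plan.message.arrival_step(config.receiver_goal)
        ok += arr_rg is not None and plan.message.states[-1] == config.sender_goal
    assert total > 190
    assert ok / total >= 0.99


def test_sequence_loglik_uniform_limit(direct_config):
    """tau -> 0: every feasible move is equally likely."""
    params = ModelParams(tau=1e-12, epsilon=0.39, lam=0.1, gamma=2.14, alpha=1.84)
    msg = Message([(1, 1), (1, 2), (1, 3)])
    ll = sequence_loglik(msg, direct_config, "surprise", params)
    k1 = len(neighbors(direct_config.board, (1, 1)))
    k2 = len(neighbors(direct_config.board, (1, 2)))
    assert ll == pytest.approx(math.log(1 / k1) + math.log(1 / k2), abs=1e-6)


def test_sequence_loglik_rejects_off_config_message(direct_config, table1_params):
    with pytest.raises(ValueError):
        sequence_loglik(Message([(0, 0), (0, 1)]), direct_config, "surprise",
                        table1_params)


def test_sequence_loglik_consistent_with_generation(indirect_config, table1_params):
    """Sampled messages score higher under their own parameters than under
    a mis-specified temperature, on average."""
    rng = np.random.default_rng(17)
    perturbed = ModelParams(tau=table1_params.tau * 4.0,
                            epsilon=table1_params.epsilon,
                            lam=table1_params.lam, gamma=table1_params.gamma,
                            alpha=table1_params.alpha)
    diffs = []
    for _ in range(40):
        plan = generate_message(indirect_config, "surprise", table1_params,
                                rng=rng)
        if plan.aborted:
            continue
        ll_true = sequence_loglik(plan.message, indirect_config, "surprise",
                                  table1_params)
        ll_bad = sequence_loglik(plan.message, indirect_config, "surprise",
                                 perturbed)
        diffs.append(ll_true - ll_bad)
    assert np.mean(diffs) > 0
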