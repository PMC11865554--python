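"""Two-phase message planning by surprise maximization with discounted lookahead.

A message is planned in two phases.  In phase 1 (start -> Receiver's goal)
the full model scores each candidate move by its Shannon surprise under the
combined movement-state priors, multiplied by the discounted points that
would remain after the cheapest completion of the trajectory.  In phase 2
(Receiver's goal -> Sender's goal) signalling is abandoned: moves are scored
by the state-prior probability times the reward, which drives the token home
on a shortest path.

Planning looks ahead over a policy tree of configurable depth (horizon);
the value of a candidate first move is the best discounted score sum over
the branches that start with it (a {max, sum, mean} reduction switch is
exposed).  Final move probabilities come from a temperature-tau softmax over
these expected values.

Three model variants share this machinery:

* ``surprise`` — the full model (parameters tau, epsilon, lam, gamma, alpha);
* ``state``    — goal orientation only: p(a|s) x reward in both phases
  (tau, epsilon, alpha);
* ``movement`` — kinetic surprise only: h(a|s) x reward from the movement
  prior alone in both phases (tau, epsilon, lam, gamma).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .gridworld import (
    GoalConfiguration, Message, State,
    neighbors, relative_direction, validate_message, heading_of,
)
from .priors import (
    MovementParams, StateParams, movement_prior, state_prior, surprise,
)

__all__ = [
    "PlannerParams", "ModelParams", "VARIANTS", "VARIANT_FIELDS",
    "validate_variant_params", "StepRecord", "MessagePlan",
    "step_value", "expected_values", "softmax_policy",
    "generate_message", "sequence_loglik",
]

VARIANTS = ("surprise", "state", "movement")

# parameters each variant estimates (the degenerate variants drop the priors
# they do not use)
VARIANT_FIELDS = {
    "surprise": ("tau", "epsilon", "lam", "gamma", "alpha"),
    "state": ("tau", "epsilon", "alpha"),
    "movement": ("tau", "epsilon", "lam", "gamma"),
}


@dataclass(frozen=True)
class PlannerParams:
    """Planning configuration (not fitted): lookahead depth, length guard, reduction."""

    horizon: int = 3
    max_moves: int = 20
    branch_reduce: str = "max"  # {max, sum, mean} over branch score sums

    def __post_init__(self) -> None:
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        if self.branch_reduce not in ("max", "sum", "mean"):
            raise ValueError("branch_reduce must be one of max/sum/mean")


@dataclass(frozen=True)
class ModelParams:
    """Fitted parameters of one variant.

    tau: softmax temperature (> 0); epsilon: per-depth discount in (0, 1);
    lam, gamma: movement-prior parameters; alpha: state-prior slope.
    Fields a variant does not use stay ``None``.
    """

    tau: float
    epsilon: float
    lam: Optional[float] = None
    gamma: Optional[float] = None
    alpha: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError("tau must be positive")
        if not (0.0 < self.epsilon < 1.0):
            raise ValueError("epsilon must be in (0, 1)")


def validate_variant_params(variant: str, params: ModelParams) -> None:
    """Check that exactly the parameters of ``variant`` are set."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    required = VARIANT_FIELDS[variant]
    for name in ("lam", "gamma", "alpha"):
        value = getattr(params, name)
        if name in required and value is None:
            raise ValueError(f"variant {variant!r} requires parameter {name!r}")
        if name not in required and value is not None:
            raise ValueError(f"variant {variant!r} does not take parameter {name!r}")


@dataclass
class StepRecord:
    """Everything the planner computed for one executed move."""

    state: State
    heading: Optional[int]
    move: int
    policy: dict[int, float]
    expected_values: dict[int, float]
    surprise: float  # bits, under the variant's prior distribution
    phase: int


@dataclass
class MessagePlan:
    """A generated message with per-step planning records."""

    message: Message
    steps: list[StepRecord]
    total_points: float
    aborted: bool = False


def step_value(variant: str, phase: int, dist: dict[int, float], a: int,
               reward: float, depth_i: int, epsilon: float) -> float:
    """Score of one tree edge: (surprise or probability) x epsilon^i x reward.

    The surprise score h(a|s) applies in phase 1 of the full model and in both
    phases of the movement variant; the probability score p(a|s) applies in
    phase 2 of the full model and in both phases of the state variant (where
    ``dist`` must already be the appropriate prior-only distribution).
    """
    if phase not in (1, 2):
        raise ValueError("phase must be 1 or 2")
    if variant == "surprise":
        score = surprise(dist, a) if phase == 1 else dist[a]
    elif variant == "state":
        score = dist[a]
    elif variant == "movement":
        score = surprise(dist, a)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return score * (epsilon ** depth_i) * reward


class PolicyEngine:
    """Per-trial planner: caches priors/distances and walks the policy tree.

    One engine serves one (config, variant, params, planner) combination; the
    module-level functions construct it on the fly, heavier callers (message
    generation, likelihoods) reuse it across steps.
    """

    def __init__(self, config: GoalConfiguration, variant: str,
                 params: ModelParams, planner: PlannerParams = PlannerParams()):
        validate_variant_params(variant, params)
        self.config = config
        self.variant = variant
        self.params = params
        self.planner = planner
        board = config.board
        self._neighbors = {s: neighbors(board, s) for s in board.states()}
        if params.alpha is not None:
            self._field = state_prior(board, config.sender_goal,
                                      StateParams(params.alpha))
        else:
            self._field = None
        if params.lam is not None:
            self._mv = movement_prior(MovementParams(params.lam, params.gamma,
                                                     strict=False))
        else:
            self._mv = None
        # distance-to-completion tables for rewards
        rg, sg = config.receiver_goal, config.sender_goal
        self._d_sg = {s: abs(s[0] - sg[0]) + abs(s[1] - sg[1]) for s in board.states()}
        d_rg_sg = self._d_sg[rg]
        self._d_via_rg = {s: abs(s[0] - rg[0]) + abs(s[1] - rg[1]) + d_rg_sg
                          for s in board.states()}
        self._dist_cache: dict[tuple, dict[int, float]] = {}

    # -- distributions -----------------------------------------------------

    def action_dist(self, s: State, heading: Optional[int], phase: int) -> dict[int, float]:
        """The variant's action distribution at (s, heading, phase)."""
        key = (s, heading, phase)
        cached = self._dist_cache.get(key)
        if cached is not None:
            return cached
        use_movement = (self.variant == "movement"
                        or (self.variant == "surprise" and phase == 1))
        use_state = (self.variant == "state"
                     or (self.variant == "surprise"))
        if self.variant == "surprise" and phase == 2:
            use_movement = False  # phase 2 follows the state prior alone
        weights: dict[int, float] = {}
        for d, target in self._neighbors[s]:
            w = 1.0
            if use_movement and heading is not None:
                w *= self._mv.by_relative(relative_direction(heading, d))
            if use_state:
                w *= float(self._field[target])
            weights[d] = w
        total = sum(weights.values())
        dist = {d: w / total for d, w in weights.items()}
        self._dist_cache[key] = dist
        return dist

    def recorded_surprise(self, s: State, heading: Optional[int], move: int) -> float:
        """Shannon surprise of an executed move under the variant's priors.

        Always uses the phase-1 (signalling) distribution: the Receiver
        evaluates every step against the priors, regardless of the Sender's
        internal planning phase.
        """
        return surprise(self.action_dist(s, heading, 1), move)

    def _reward(self, s_next: State, steps: int, rg_visited: bool) -> float:
        # The state variant is the phase-2 policy everywhere: pure goal
        # achievement, so its completion cost never routes via the receiver's
        # goal (it reproduces the direct-path behavior of the degenerate
        # goal-orientation model).
        if self.variant == "state" or rg_visited or s_next == self.config.receiver_goal:
            d = self._d_sg[s_next]
        else:
            d = self._d_via_rg[s_next]
        return 10.0 - steps - d

    def _is_terminal(self, s: State, rg_visited: bool) -> bool:
        """A trajectory ends at the sender's goal; the full and movement
        variants only finish after the receiver's goal has been visited,
        the state variant heads straight home."""
        return s == self.config.sender_goal and (rg_visited or
                                                 self.variant == "state")

    # -- tree search -------------------------------------------------------

    def expected_values(self, s: State, heading: Optional[int], steps_taken: int,
                        rg_visited: bool) -> dict[int, float]:
        """EV of each feasible immediate move after lookahead to the horizon."""
        out: dict[int, float] = {}
        for d, _t in self._neighbors[s]:
            sums = self._branch_sums(s, heading, steps_taken, rg_visited, d, 0)
            reduce = self.planner.branch_reduce
            if reduce == "max":
                out[d] = max(sums)
            elif reduce == "sum":
                out[d] = sum(sums)
            else:
                out[d] = sum(sums) / len(sums)
        return out

    def _branch_sums(self, s: State, heading: Optional[int], steps_taken: int,
                     rg_visited: bool, move: int, depth: int) -> list[float]:
        """Score sums over every branch that starts with ``move`` at ``depth``."""
        cfg, p = self.config, self.params
        phase = 2 if rg_visited else 1
        dist = self.action_dist(s, heading, phase)
        s_next = next(t for d, t in self._neighbors[s] if d == move)
        steps_next = steps_taken + depth + 1
        visited_next = rg_visited or s_next == cfg.receiver_goal
        r = self._reward(s_next, steps_next, visited_next)
        ev = step_value(self.variant, phase, dist, move, r, depth, p.epsilon)
        terminal = self._is_terminal(s_next, visited_next)
        if terminal or depth + 1 >= self.planner.horizon:
            return [ev]
        sums: list[float] = []
        for d, _t in self._neighbors[s_next]:
            for tail in self._branch_sums(s_next, move, steps_taken,
                                          visited_next, d, depth + 1):
                sums.append(ev + tail)
        return sums

    def policy(self, s: State, heading: Optional[int], steps_taken: int,
               rg_visited: bool) -> dict[int, float]:
        return softmax_policy(self.expected_values(s, heading, steps_taken,
                                                   rg_visited), self.params.tau)


def expected_values(config: GoalConfiguration, s: State, heading: Optional[int],
                    steps_taken: int, variant: str, params: ModelParams,
                    planner: PlannerParams = PlannerParams(),
                    rg_visited: bool = False) -> dict[int, float]:
    """Discounted lookahead values of all feasible moves from ``s``."""
    return PolicyEngine(config, variant, params, planner).expected_values(
        s, heading, steps_taken, rg_visited)


def softmax_policy(ev: dict[int, float], tau: float) -> dict[int, float]:
    """Pr(a) = exp(tau EV(a)) / sum_a' exp(tau EV(a')), overflow-safe."""
    if not ev:
        raise ValueError("empty move set")
    if not tau > 0:
        raise ValueError("tau must be positive")
    moves = list(ev)
    z = np.array([tau * ev[m] for m in moves])
    z -= z.max()
    w = np.exp(z)
    w /= w.sum()
    return dict(zip(moves, w.tolist()))


def generate_message(config: GoalConfiguration, variant: str, params: ModelParams,
                     planner: PlannerParams = PlannerParams(),
                     rng: np.random.Generator | int | None = None) -> MessagePlan:
    """Sample a full message step by step from the softmax policy.

    Phase 1 runs until the first arrival at the Receiver's goal, phase 2
    until the Sender's goal.  A length guard (``planner.max_moves``) aborts
    runaway trajectories; aborted plans carry ``aborted=True``.
    """
    rng = np.random.default_rng(rng)
    engine = PolicyEngine(config, variant, params, planner)
    s, heading = config.start, None
    rg_visited = False
    states = [s]
    steps: list[StepRecord] = []
    aborted = False
    while True:
        phase = 2 if rg_visited else 1
        ev = engine.expected_values(s, heading, len(steps), rg_visited)
        pol = softmax_policy(ev, params.tau)
        moves = list(pol)
        move = moves[rng.choice(len(moves), p=[pol[m] for m in moves])]
        h_bits = engine.recorded_surprise(s, heading, move)
        steps.append(StepRecord(s, heading, move, pol, ev, h_bits, phase))
        s = next(t for d, t in engine._neighbors[s] if d == move)
        heading = move
        states.append(s)
        rg_visited = rg_visited or s == config.receiver_goal
        if engine._is_terminal(s, rg_visited):
            break
        if len(steps) >= planner.max_moves:
            aborted = True
            break
    msg = Message(states, step_surprise=[st.surprise for st in steps])
    return MessagePlan(msg, steps, total_points=10.0 - len(steps), aborted=aborted)


def sequence_loglik(message: Message, config: GoalConfiguration, variant: str,
                    params: ModelParams,
                    planner: PlannerParams = PlannerParams()) -> float:
    """Log-likelihood of an observed trajectory under a variant's policy.

    The planning phase is inferred from the first arrival at the Receiver's
    goal; every observed move contributes log Pr(move | policy).
    """
    validate_message(message, config, require_complete=False)
    engine = PolicyEngine(config, variant, params, planner)
    s, heading = config.start, None
    rg_visited = False
    ll = 0.0
    for t, s_next in enumerate(message.states[1:]):
        move = heading_of(s, s_next)
        pol = engine.policy(s, heading, t, rg_visited)
        ll += math.log(pol[move])
        s, heading = s_next, move
        rg_visited = rg_visited or s == config.receiver_goal
    return ll
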