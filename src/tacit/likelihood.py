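"""Vectorized sequence likelihoods for fitting.

For a fixed trajectory the policy tree at every decision step has fixed
geometry (states, feasible moves, rewards, phases); only the prior weights
depend on the parameters.  :class:`CompiledTrials` flattens all trees of a
subject's dataset into index arrays once, after which a negative
log-likelihood evaluation is a handful of numpy operations — orders of
magnitude faster than re-walking the trees, and exercised against the
reference :func:`tacit.planner.sequence_loglik` in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .gridworld import GoalConfiguration, Message, heading_of, neighbors, relative_direction
from .planner import ModelParams, PlannerParams, validate_variant_params
from .priors import MovementParams, movement_prior

__all__ = ["CompiledTrials"]

_REL_INDEX = {"F": 0, "L": 1, "R": 2, "B": 3, "first": 4}


@dataclass
class _Node:
    rel: int          # index into (p_f, p_l, p_r, p_b, 1.0)
    d_state: int      # Manhattan distance of the landing state to the sender goal
    reward: float
    depth: int
    phase: int        # phase of the move (1 before the receiver goal is reached)
    parent: int
    group: int        # normalization group (siblings of one expansion)
    slot: int         # id of (decision step, immediate move)
    terminal: bool


class CompiledTrials:
    """Flattened policy trees for one subject's trials under one variant."""

    def __init__(self, trials: Sequence[tuple[GoalConfiguration, Message]],
                 variant: str, planner: PlannerParams = PlannerParams()):
        self.variant = variant
        self.planner = planner
        nodes: list[_Node] = []
        slot_decision: list[int] = []     # decision id of each slot
        obs_slot: list[int] = []          # observed slot per decision
        group_count = 0
        for config, message in trials:
            self._compile_trial(config, message, nodes, slot_decision, obs_slot)
        self.n_decisions = len(obs_slot)
        self.n_slots = len(slot_decision)
        self.n_nodes = len(nodes)

        self.rel = np.array([n.rel for n in nodes], dtype=np.intp)
        self.d_state = np.array([n.d_state for n in nodes], dtype=float)
        self.reward = np.array([n.reward for n in nodes])
        self.depth = np.array([n.depth for n in nodes], dtype=np.intp)
        self.parent = np.array([n.parent for n in nodes], dtype=np.intp)
        self.group = np.array([n.group for n in nodes], dtype=np.intp)
        self.slot = np.array([n.slot for n in nodes], dtype=np.intp)
        phase = np.array([n.phase for n in nodes], dtype=np.intp)
        leaf = np.array([n.terminal or n.depth == planner.horizon - 1
                         for n in nodes], dtype=bool)
        self.leaf_idx = np.nonzero(leaf)[0]
        self.leaf_slot = self.slot[self.leaf_idx]
        self.n_groups = int(self.group.max()) + 1 if nodes else 0
        self.slot_decision = np.array(slot_decision, dtype=np.intp)
        self.obs_slot = np.array(obs_slot, dtype=np.intp)
        self.max_depth = int(self.depth.max()) if nodes else 0
        self.level_idx = [np.nonzero(self.depth == d)[0]
                          for d in range(1, self.max_depth + 1)]
        # which prior factors feed each node, given variant and phase
        if variant == "surprise":
            self.use_movement = phase == 1
            self.use_state = np.ones(self.n_nodes, dtype=bool)
            self.surprise_score = phase == 1
        elif variant == "state":
            self.use_movement = np.zeros(self.n_nodes, dtype=bool)
            self.use_state = np.ones(self.n_nodes, dtype=bool)
            self.surprise_score = np.zeros(self.n_nodes, dtype=bool)
        elif variant == "movement":
            self.use_movement = np.ones(self.n_nodes, dtype=bool)
            self.use_state = np.zeros(self.n_nodes, dtype=bool)
            self.surprise_score = np.ones(self.n_nodes, dtype=bool)
        else:
            raise ValueError(f"unknown variant {variant!r}")
        self.leaf_count = np.bincount(self.leaf_slot, minlength=self.n_slots)

    def _compile_trial(self, config: GoalConfiguration, message: Message,
                       nodes: list[_Node], slot_decision: list[int],
                       obs_slot: list[int]) -> None:
        board = config.board
        rg, sg = config.receiver_goal, config.sender_goal
        horizon = self.planner.horizon
        nbrs = {s: neighbors(board, s) for s in board.states()}
        d_sg = {s: abs(s[0] - sg[0]) + abs(s[1] - sg[1]) for s in board.states()}
        d_via = {s: abs(s[0] - rg[0]) + abs(s[1] - rg[1]) + d_sg[rg]
                 for s in board.states()}

        s, heading = config.start, None
        rg_visited = False
        for t, s_obs in enumerate(message.states[1:]):
            decision = len(obs_slot)
            move_obs = heading_of(s, s_obs)
            observed = None
            # expand the tree breadth-first from the decision root
            group = _fresh_group(nodes)
            frontier: list[tuple] = []  # (node_idx, state, heading, rg_visited)
            for d, target in nbrs[s]:
                slot = len(slot_decision)
                slot_decision.append(decision)
                if d == move_obs:
                    observed = slot
                node = self._make_node(d, heading, target, t, 0, rg_visited,
                                       rg, sg, d_sg, d_via, -1, group, slot,
                                       horizon)
                nodes.append(node)
                frontier.append((len(nodes) - 1, target, d,
                                 rg_visited or target == rg))
            for depth in range(1, horizon):
                next_frontier = []
                for parent_idx, ps, ph, pvisited in frontier:
                    if nodes[parent_idx].terminal:
                        continue
                    group = _fresh_group(nodes)
                    pslot = nodes[parent_idx].slot
                    for d, target in nbrs[ps]:
                        node = self._make_node(d, ph, target, t, depth,
                                               pvisited, rg, sg, d_sg, d_via,
                                               parent_idx, group, pslot,
                                               horizon)
                        nodes.append(node)
                        next_frontier.append((len(nodes) - 1, target, d,
                                              pvisited or target == rg))
                frontier = next_frontier
            obs_slot.append(observed)
            s, heading = s_obs, move_obs
            rg_visited = rg_visited or s == rg

    def _make_node(self, move: int, heading, target, t: int, depth: int,
                   rg_visited: bool, rg, sg, d_sg, d_via, parent: int,
                   group: int, slot: int, horizon: int) -> _Node:
        steps = t + depth + 1
        visited_next = rg_visited or target == rg
        # the state variant's completion cost ignores the receiver's goal
        if self.variant == "state" or visited_next:
            remaining = d_sg[target]
        else:
            remaining = d_via[target]
        return _Node(
            rel=_REL_INDEX[relative_direction(heading, move)],
            d_state=d_sg[target],
            reward=10.0 - steps - remaining,
            depth=depth,
            phase=2 if rg_visited else 1,
            parent=parent,
            group=group,
            slot=slot,
            terminal=target == sg and (visited_next or self.variant == "state"),
        )

    # -- evaluation --------------------------------------------------------

    def loglik(self, params: ModelParams) -> float:
        """Total log-likelihood of all compiled trials under ``params``."""
        validate_variant_params(self.variant, params)
        if self.n_decisions == 0:
            return 0.0
        weight = np.ones(self.n_nodes)
        if params.lam is not None:
            mv = movement_prior(MovementParams(params.lam, params.gamma,
                                               strict=False))
            table = np.array([mv.p_f, mv.p_l, mv.p_r, mv.p_b, 1.0])
            weight[self.use_movement] = table[self.rel[self.use_movement]]
        if params.alpha is not None:
            sw = params.alpha ** (-self.d_state)
            weight = np.where(self.use_state, weight * sw, weight)
        denom = np.bincount(self.group, weights=weight,
                            minlength=self.n_groups)[self.group]
        p = weight / denom
        score = np.where(self.surprise_score, -np.log2(p), p)
        ev = score * (params.epsilon ** self.depth) * self.reward
        path = ev.copy()
        for idx in self.level_idx:
            path[idx] += path[self.parent[idx]]
        # reduce branch sums to expected values per immediate move
        reduce = self.planner.branch_reduce
        leaf_vals = path[self.leaf_idx]
        if reduce == "max":
            ev_slot = np.full(self.n_slots, -np.inf)
            np.maximum.at(ev_slot, self.leaf_slot, leaf_vals)
        else:
            ev_slot = np.bincount(self.leaf_slot, weights=leaf_vals,
                                  minlength=self.n_slots)
            if reduce == "mean":
                ev_slot = ev_slot / self.leaf_count
        # softmax over the slots of each decision
        z = params.tau * ev_slot
        zmax = np.full(self.n_decisions, -np.inf)
        np.maximum.at(zmax, self.slot_decision, z)
        expz = np.exp(z - zmax[self.slot_decision])
        lse = np.log(np.bincount(self.slot_decision, weights=expz,
                                 minlength=self.n_decisions)) + zmax
        return float(np.sum(z[self.obs_slot] - lse))

    def nll(self, params: ModelParams) -> float:
        return -self.loglik(params)


def _fresh_group(nodes: list[_Node]) -> int:
    return nodes[-1].group + 1 if nodes else 0
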