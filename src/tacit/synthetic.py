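"""Synthetic TCG cohorts and surprise-coupled physiological fixtures.

Everything here is generated, seeded and desk-sized, so every analysis stage
of the package can be exercised end to end without any external download:

* goal configurations matching the task protocol (4x4 board, start in one of
  the four central cells, a requested direct/indirect mix);
* simulated Senders drawn from a group-level parameter distribution of any
  model variant, producing messages via the planner;
* a heuristic Receiver that decodes the most surprising visited state —
  a fixture mirroring the interpretation that Receivers detect expectation
  violations, not a scientific claim about Receiver cognition;
* pupil (PDR) values and EEG-like channel x time epochs linearly coupled to
  step-wise surprise plus noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .behavior import TrialRecord
from .gridworld import BOARD_4X4, Board, GoalConfiguration, Message, classify_trial
from .planner import (
    MessagePlan, ModelParams, PlannerParams, PolicyEngine, generate_message,
)
from .transforms import n_params, to_constrained, to_unconstrained

__all__ = [
    "DEFAULT_GROUP_PARAMS", "SyntheticSpec", "ReceiverParams", "PhysioCoupling",
    "sample_goal_configuration", "sample_subject_params", "simulate_sender",
    "simulate_cohort_records", "simulate_receiver", "simulate_pdr",
    "simulate_pdr_cohort", "simulate_eeg",
]

#: group-level parameter means used as generating values per variant
#: (posterior group estimates for the first behavioral sample)
DEFAULT_GROUP_PARAMS = {
    "surprise": ModelParams(tau=6.93, epsilon=0.39, lam=0.10, gamma=2.14, alpha=1.84),
    "state": ModelParams(tau=2.90, epsilon=0.39, alpha=1.11),
    "movement": ModelParams(tau=1.92, epsilon=0.62, lam=0.15, gamma=1.50),
}


@dataclass(frozen=True)
class ReceiverParams:
    """Surprise-decoding Receiver: softmax over per-state peak surprise.

    The Receiver re-evaluates each message step against its own priors and
    picks the visited state whose arrival was most surprising; ``temperature``
    (bits) sets decision noise, 0 meaning deterministic argmax.
    """

    lam: float = 0.10
    gamma: float = 2.14
    alpha: float = 1.84
    temperature: float = 0.5


@dataclass(frozen=True)
class PhysioCoupling:
    """Linear surprise coupling for the physiological fixtures.

    Pupil: slope 0.02 units/bit with Gaussian random intercepts/slopes per
    subject; EEG: injected amplitude on patterned channels at unit noise.
    """

    pdr_slope: float = 0.02
    pdr_noise_sd: float = 0.05
    pdr_intercept_sd: float = 0.01
    pdr_slope_sd: float = 0.005
    eeg_amplitude: float = 1.0
    eeg_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        for name in ("pdr_noise_sd", "pdr_intercept_sd", "pdr_slope_sd",
                     "eeg_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class SyntheticSpec:
    """Study-condition bundle for cohort simulation.

    Defaults emulate the first behavioral sample: 120 trials per subject,
    34% direct trials, surprise-variant Senders at the group posterior
    means with between-subject spread ``group_sd`` on the unconstrained
    parameter scale.
    """

    n_subjects: int = 20
    trials_per_subject: int = 120
    direct_fraction: float = 0.34
    variant: str = "surprise"
    group_params: Optional[ModelParams] = None
    group_sd: float = 0.5
    receiver: ReceiverParams = field(default=ReceiverParams())
    planner: PlannerParams = field(default=PlannerParams())
    physio: PhysioCoupling = field(default=PhysioCoupling())
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.direct_fraction <= 1.0):
            raise ValueError("direct_fraction must be in [0, 1]")
        if self.group_sd < 0:
            raise ValueError("group_sd must be >= 0")

    def resolved_group_params(self) -> ModelParams:
        return self.group_params or DEFAULT_GROUP_PARAMS[self.variant]


def sample_goal_configuration(board: Board = BOARD_4X4,
                              trial_type: Optional[str] = None,
                              rng: np.random.Generator | int | None = None,
                              max_rejections: int = 10_000) -> GoalConfiguration:
    """Draw a valid goal configuration, optionally of a requested trial type.

    The start is uniform over the four central cells; both goals are uniform
    over the remaining cells (distinct from the start and from each other),
    rejection-sampled until :func:`classify_trial` matches ``trial_type``.
    """
    if trial_type not in (None, "direct", "indirect"):
        raise ValueError("trial_type must be None, 'direct' or 'indirect'")
    rng = np.random.default_rng(rng)
    cells = list(board.states())
    centers = board.central_states()
    for _ in range(max_rejections):
        start = centers[rng.integers(len(centers))]
        sg = cells[rng.integers(len(cells))]
        rg = cells[rng.integers(len(cells))]
        if sg == start or rg == start or rg == sg:
            continue
        config = GoalConfiguration(start, sg, rg, board)
        if trial_type is None or classify_trial(config) == trial_type:
            return config
    raise RuntimeError(f"no {trial_type} configuration found after "
                       f"{max_rejections} rejections")


def sample_subject_params(spec: SyntheticSpec,
                          rng: np.random.Generator) -> ModelParams:
    """Individual parameters: Gaussian draw around the group mean, unconstrained scale."""
    mu = to_unconstrained(spec.variant, spec.resolved_group_params())
    theta = mu + spec.group_sd * rng.standard_normal(n_params(spec.variant))
    return to_constrained(spec.variant, theta)


def _trial_types(spec: SyntheticSpec, rng: np.random.Generator) -> list[str]:
    n_direct = int(round(spec.direct_fraction * spec.trials_per_subject))
    types = ["direct"] * n_direct + ["indirect"] * (spec.trials_per_subject - n_direct)
    rng.shuffle(types)
    return types


def simulate_sender(spec: SyntheticSpec, params: ModelParams,
                    configs: Sequence[GoalConfiguration],
                    rng: np.random.Generator) -> list[MessagePlan]:
    return [generate_message(c, spec.variant, params, spec.planner, rng)
            for c in configs]


def simulate_receiver(message: Message, config: GoalConfiguration,
                      params: ReceiverParams = ReceiverParams(),
                      rng: np.random.Generator | int | None = None,
                      ) -> tuple[int, int]:
    """The heuristic Receiver's goal choice for one observed message.

    Each visited state (start and Sender's goal excluded — the Receiver knows
    both) is scored by the maximum Shannon surprise of the moves that entered
    it, evaluated under the Receiver's own priors; the choice is a softmax
    over these scores (temperature 0 = argmax, ties to the earliest step).
    """
    rng = np.random.default_rng(rng)
    model = ModelParams(tau=1.0, epsilon=0.5, lam=params.lam,
                        gamma=params.gamma, alpha=params.alpha)
    engine = PolicyEngine(config, "surprise", model)
    scores: dict[tuple[int, int], float] = {}
    order: dict[tuple[int, int], int] = {}
    s, heading = message.states[0], None
    for i, s_next in enumerate(message.states[1:], start=1):
        move = message.actions[i - 1]
        h = engine.recorded_surprise(s, heading, move)
        if s_next not in (config.start, config.sender_goal):
            if s_next not in scores or h > scores[s_next]:
                scores[s_next] = h
                order.setdefault(s_next, i)
        s, heading = s_next, move
    if not scores:  # degenerate straight shot through nothing choosable
        return config.sender_goal
    cand = sorted(scores, key=lambda st: order[st])
    vals = np.array([scores[st] for st in cand])
    if params.temperature <= 0:
        return cand[int(np.argmax(vals))]  # argmax; earliest step wins ties
    z = vals / params.temperature
    z -= z.max()
    p = np.exp(z)
    p /= p.sum()
    return cand[rng.choice(len(cand), p=p)]


def simulate_cohort_records(spec: SyntheticSpec,
                            return_params: bool = False):
    """Full cohort: per-subject parameters, messages and Receiver choices.

    Returns a list of :class:`~tacit.behavior.TrialRecord` (and, optionally,
    the generating per-subject :class:`~tacit.planner.ModelParams`).  Pure
    function of the spec: identical specs give identical cohorts.
    """
    rng = np.random.default_rng(spec.rng_seed)
    records: list[TrialRecord] = []
    subject_params: list[ModelParams] = []
    for sub in range(spec.n_subjects):
        params = sample_subject_params(spec, rng)
        subject_params.append(params)
        configs = [sample_goal_configuration(BOARD_4X4, t, rng)
                   for t in _trial_types(spec, rng)]
        for config, plan in zip(configs, simulate_sender(spec, params, configs, rng)):
            choice = simulate_receiver(plan.message, config, spec.receiver, rng)
            records.append(TrialRecord(subject_id=sub, config=config,
                                       message=plan.message,
                                       receiver_choice=choice))
    if return_params:
        return records, subject_params
    return records


def simulate_pdr(step_surprise: Sequence[float], slope: float = 0.02,
                 intercept: float = 0.0,
                 subject_effects: tuple[float, float] = (0.0, 0.0),
                 noise_sd: float = 0.0,
                 rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Per-step pupil response linearly coupled to surprise.

    PDR_step = (intercept + u0) + (slope + u1) * surprise + noise, with
    ``subject_effects = (u0, u1)`` the subject's random intercept and slope.
    The default slope of 0.02 units per bit matches the scale of reported
    pupillary effects.
    """
    h = np.asarray(step_surprise, float)
    if np.any(h < 0):
        raise ValueError("surprise values must be non-negative")
    rng = np.random.default_rng(rng)
    u0, u1 = subject_effects
    return (intercept + u0) + (slope + u1) * h + noise_sd * rng.standard_normal(h.shape)


def simulate_pdr_cohort(spec: SyntheticSpec,
                        step_surprise: Sequence[Sequence[float]],
                        rng: np.random.Generator | int | None = None,
                        ) -> list[np.ndarray]:
    """Per-subject pupil responses under the spec's coupling parameters."""
    rng = np.random.default_rng(spec.rng_seed if rng is None else rng)
    c = spec.physio
    return [simulate_pdr(h, slope=c.pdr_slope, noise_sd=c.pdr_noise_sd,
                         subject_effects=(c.pdr_intercept_sd * rng.standard_normal(),
                                          c.pdr_slope_sd * rng.standard_normal()),
                         rng=rng)
            for h in step_surprise]


def simulate_eeg(step_surprise: Sequence[float],
                 channel_pattern: Sequence[int],
                 time_window: tuple[float, float],
                 amplitude: float,
                 noise_sd: float = 1.0,
                 n_channels: int = 16,
                 n_timepoints: int = 40,
                 epoch_ms: float = 1200.0,
                 noise_smooth_sigma: float = 2.0,
                 rng: np.random.Generator | int | None = None,
                 ) -> tuple[np.ndarray, np.ndarray]:
    """One subject's step-locked epochs with a surprise-coupled injection.

    Returns ``(epochs, times_ms)`` where ``epochs`` has shape
    (n_epochs, n_channels, n_timepoints).  Inside ``time_window`` (ms) the
    channels listed in ``channel_pattern`` carry ``amplitude * surprise``;
    everywhere, temporally smoothed Gaussian noise (rescaled back to
    ``noise_sd``) is added so epochs have realistic autocorrelation.
    """
    h = np.asarray(step_surprise, float)
    times = np.linspace(0.0, epoch_ms, n_timepoints, endpoint=False)
    lo, hi = time_window
    if not (0.0 <= lo < hi <= epoch_ms):
        raise ValueError("time_window must lie within the epoch")
    rng = np.random.default_rng(rng)
    noise = rng.standard_normal((len(h), n_channels, n_timepoints))
    if noise_smooth_sigma > 0:
        noise = gaussian_filter1d(noise, noise_smooth_sigma, axis=-1)
        sd = noise.std()
        if sd > 0:
            noise /= sd
    epochs = noise_sd * noise
    mask_t = (times >= lo) & (times < hi)
    for ch in channel_pattern:
        epochs[:, ch, mask_t] += amplitude * h[:, None]
    return epochs, times
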