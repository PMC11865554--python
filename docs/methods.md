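# Methods

## The task

The Tacit Communication Game (TCG) is a cooperative two-player game on a
4x4 grid.  Both players share a start cell (one of the four central cells).
The Sender sees three locations — the start, her own goal and the
Receiver's goal — and moves a token from the start to her own goal.  The
trajectory is the message: it must also tell the Receiver, who sees only
the start and the Sender's goal, where his own hidden goal is.  Moves are
4-connected (no diagonals).  A trial pays 10 points minus the number of
moves, shared on success, so short communicative messages are best.  A
trial is *direct* when the Receiver's goal lies on some shortest path from
the start to the Sender's goal (Manhattan-distance identity
d(start, rg) + d(rg, sg) = d(start, sg)) and *indirect* otherwise.

## The generative model

The Sender is modelled as signalling by expectation violation.  Two priors
define what an observer would expect:

* **Movement prior** (naive kinetics): relative to the previous move,
  p(f) = gamma/(gamma+1) (1-lambda), p(l) = p(r) = (1 - gamma/(gamma+1))
  (1-lambda)/2, p(b) = lambda.  `lambda` in [0.001, 0.3] is the backward
  probability, `gamma` in [2, 10] the forward-vs-turn odds.  The first move
  of a message has no heading; its movement factor is uniform (the
  maximum-entropy completion).
* **State prior** (goal orientation): a static field p(s) = alpha^-d(s, sg)
  with `alpha` > 1 and d the Manhattan distance, equal to 1 at the Sender's
  goal.  Equal-prior contours are diamonds, matching the legal moves.

At a state s with heading h, the two priors are multiplied over the
feasible moves and renormalized (moves off the board carry no mass):
p(a|s) ∝ p_move(a|h) p_state(s'(a)).  The Shannon surprise of a move is
h(a|s) = -log2 p(a|s).

**Reward.**  r(s') = 10 - steps_taken - c(s'), where c(s') is the cheapest
completion: through the Receiver's goal and on to the Sender's goal while
the Receiver's goal is unvisited, directly to the Sender's goal afterwards.
Rewards may go negative on long paths; they are deliberately not clamped so
the urgency gradient survives.

**Two phases.**  Until the first arrival at the Receiver's goal (phase 1)
the full model scores each candidate move by ev(a|s) = h(a|s) epsilon^i
r(s'), i.e. surprise weighted by discounted reward.  From the Receiver's
goal onward (phase 2) signalling is abandoned: ev(a|s) = p(a|s) epsilon^i
r(s') with the action distribution built from the state prior alone, which
drives the token home.

**Planning.**  Moves are chosen with a depth-limited policy tree (default
horizon 3): every move sequence up to the horizon is scored by the sum of
its discounted step values (epsilon^i at lookahead depth i, i = 0 for the
immediate move, so the one-step case is the undiscounted product).  The
expected value of an immediate move is the **maximum** over the branch sums
that start with it — best-continuation planning; `sum` and `mean`
reductions are exposed as configuration because the cross-branch reduction
is a genuinely open design choice.  A node that reaches the Sender's goal
(with the Receiver's goal already visited) is terminal.  Final move
probabilities are softmax(tau EV) with temperature `tau`; messages are
sampled step by step with a 20-move guard (aborted plans are flagged and
excluded from summaries).

**Variants.**  Three nested variants are compared:

| variant   | parameters                     | policy                                        |
|-----------|--------------------------------|-----------------------------------------------|
| surprise  | tau, epsilon, lambda, gamma, alpha | full two-phase model                       |
| state     | tau, epsilon, alpha            | phase-2 policy everywhere: p_state x reward, completion cost straight to the Sender's goal |
| movement  | tau, epsilon, lambda, gamma    | movement-prior surprise x reward in both phases |

The state variant's completion cost ignores the Receiver's goal entirely —
it is the pure goal-achievement model and walks direct shortest paths; the
movement variant keeps the via-receiver-goal reward and produces
reversal-heavy zigzags that do pass through the Receiver's goal.

The per-step surprise attached to generated messages (and consumed by the
physiological analyses) is always evaluated under the variant's
*signalling* distribution (phase-1 priors), because the observer scores
every step against the priors regardless of the Sender's internal phase.

## Behavioral indices

Message types are a deterministic function of the egocentric move sequence,
keyed on immediate reversals (relative direction B): 0 reversals ->
Pass-By; exactly 1 -> Enter-Exit; two or more reversals oscillating between
one pair of adjacent cells -> Wiggly; anything else -> `other` (a residual
bin so unusual trajectories are never force-fitted into the named types).
The rule is exposed as a swappable callable.  Message profiles count
F/L/R/B over moves 2..n; the first move has no relative direction and is
excluded.  "L" is fixed as the counter-clockwise quarter turn of the
heading; the priors are L/R symmetric, so the convention is observationally
neutral for the model but must be fixed for profiles.

## Fitting and model comparison

Each variant's parameters are estimated per subject by MAP on an
unconstrained scale (scaled logits for lambda, gamma, epsilon; log tau;
log(alpha-1)) under a Gaussian group prior, using L-BFGS-B with a screened
multi-start (16 random candidate starts, the best 3 optimized; later
refinement sweeps warm-start from the previous optimum).  The likelihood is
evaluated by a vectorized engine that compiles each trial's policy trees
into flat index arrays once; it is tested for exact agreement with the
step-by-step reference walk.  Model evidence uses the Laplace
approximation, -L(theta*) + d/2 log 2 pi - 1/2 log det H, with H the
central-difference curvature (step 1e-4) of the penalized objective,
regularized to positive-definite when finite differencing produces a
marginally indefinite matrix.

The group level alternates subject fits with responsibility-weighted
empirical-Bayes updates of the group mean and variance (weak inverse-gamma
style regularization so variances cannot collapse with few subjects) and
with per-subject responsibilities over variants, until no group mean moves
by more than 1e-3 (at most 50 sweeps).  The default prior on the
unconstrained scale is N(0, 6.25), a conventional weakly-informative choice
for behavioral-model fitting.

Random-effects model comparison treats per-subject log evidences as
observations of a latent variant assignment with Dirichlet(1, ..., 1) prior
over frequencies: a variational loop yields posterior Dirichlet counts
(model frequencies), the exceedance probability is estimated from 1e6
seeded Dirichlet draws, and the Bayes omnibus risk compares the
free-frequency free energy against the equal-frequency null, giving the
protected exceedance probability PEP = EP (1 - BOR) + BOR / K.

## Posterior predictive checks

A cohort is re-simulated from the fitted group parameters over exactly the
observed cohort's goal-configuration lists, so indices are directly
comparable.  Every index (type frequencies overall and by trial type,
profile components per type) is compared across subjects with a default
two-sample JZS Bayes factor: the Cauchy(0, r) prior on standardized effect
size, r = sqrt(2)/2 by default (exposed, since conventions differ across
software), integrated numerically over the inverse-gamma mixing density.
BF01 > 1 favors "no difference" (the model reproduces the index); BF01 < 1
flags a mismatch.  The implementation is cross-checked in the tests against
an independent JZS implementation to 1%.

## Physiological analyses

Epochs are step-locked channel x time arrays, one surprise value per epoch.
The pipeline is: (1) baseline correction by subtracting the per-epoch,
per-channel mean of a stated window (default 0-100 ms after step onset);
(2) per-subject mass-univariate OLS of signal on surprise (slope + intercept)
at every channel and time point; (3) a group-level one-sample t test of the
betas against zero with cluster-based permutation correction: cells above
the two-sided p = 0.005 t threshold are clustered under channel-neighbor x
temporal adjacency, cluster statistic = summed t (mass), and the null
distribution of the maximum |mass| comes from random whole-subject sign
flips (valid for a one-sample test; 1000 permutations by default).
Corrected p values are permutation ranks with the +1 correction, so they
are never zero.

The pupil analysis is a two-stage summary-statistics estimator: per-subject
OLS slope of PDR on surprise, then a one-sample t test of the slopes.  For
balanced designs this estimates the same fixed effect as a random-intercept,
random-slope mixed model; a full REML mixed model is intentionally out of
scope, and the simulation tests confirm the estimator is unbiased at the
generator's slope.  Per-type beta summaries repeat the regression within
message type over a significant cluster's channels and pair each type with
its mean model surprise.

## Synthetic data

The generator emulates the study conditions without any external data:
120 trials per subject; starts uniform over the four central cells; goals
rejection-sampled for a requested direct/indirect mix (default 34% direct,
matching the first sample's protocol); Sender parameters drawn per subject
as Gaussians around the group posterior means (tau 6.93, epsilon 0.39,
lambda 0.10, gamma 2.14, alpha 1.84 for the full model) with SD 0.5 on the
unconstrained scale; messages generated by the planner.  The Receiver is a
*fixture*, not a scientific claim: it re-scores each observed step under
its own priors and softmax-picks the visited state with the highest arrival
surprise (temperature 0.5 bits; start and Sender's goal excluded as known).
Physiological fixtures couple signal linearly to step surprise: PDR =
(intercept + u0) + (slope + u1) surprise + noise with slope 0.02 units/bit,
and EEG-like epochs inject amplitude x surprise on patterned channels
inside a time window on top of temporally smoothed (sigma 2 samples,
variance-renormalized) Gaussian noise on an abstract channel grid — no
electrode geometry beyond a configurable neighbor graph.

What the generator does **not** emulate: learning or strategy drift across
trials, pair-specific conventions, reaction times, the 5-second movement
limit, eye or EEG artifacts, volume conduction, or any real electrode
montage.  Passing tests therefore demonstrate internal consistency of the
pipeline (simulate -> fit -> compare -> predict), not fidelity to any
particular empirical dataset.

## Problem sizes and numerical choices

The packaged study sizes are 20 subjects x 120 trials for model and
parameter recovery, 40 configurations for the degenerate-variant
signatures, 100-200 null runs for the cluster test's family-wise error
calibration, 50-100 runs for its power, and 21 subjects x 150 steps for
the pupil slope; these are the sizes the test suite and the acceptance
script use.  Softmax uses max-subtraction; the policy-tree depth defaults
to 3 (deeper trees change little on a 4x4 board); logit transforms are
clipped at |x| = 30 to avoid overflow at saturated parameters; ties in the
Receiver fixture resolve to the earliest step.

## Known limitations

* Under surprise-times-reward planning, a reversal early on the
  reward-neutral corridor is worth as much as one at the Receiver's goal,
  so simulated full-model cohorts place their largest surprise at the
  Receiver's goal in only a minority of messages and the modal simulated
  type is Wiggly rather than Enter-Exit.  The surprise-decoding Receiver
  fixture's accuracy is correspondingly modest.  All recovery, comparison
  and predictive-check results are internally consistent under this
  behavior.
* `gamma` is weakly identified in recovery studies whose generating
  population is centered near its lower box bound: the box compresses the
  generating spread (SD about 0.08 at mean 2.14) below the per-subject
  estimation error (about 0.25), so generating-vs-recovered correlations
  for `gamma` are attenuation-limited even though absolute errors stay
  small.
* The hierarchical scheme is an empirical-Bayes approximation with
  diagonal group covariance, not a full variational treatment; evidences
  are Laplace approximations and can be optimistic for strongly
  non-Gaussian posteriors.
* The cluster permutation test controls family-wise error only under the
  exchangeability granted by whole-subject sign flips; it is conservative
  for very small clusters.
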