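# Methods

## The model

The package implements a reinforcement-learning account of how the
striatal dopamine system generalizes and then discriminates value.  The
learner ("OVaRLAP") estimates state values with a three-layer network in
which only the last layer learns:

* **Input.** A grid position `(x, y)`, `x, y ∈ {1..20}`, encoded as a
  one-hot 20×20 indicator (400 input units).
* **Fixed hidden layer.** 900 hidden units with Gaussian receptive
  fields.  Unit `k` is centred on the square with linear index
  `ceil(400k/900)` (so the 900 centres tile the 400 squares, 2–3 units
  per square), and responds to position `(i, j)` with

      M_{ij,k} = [ exp(−((i−a_k)² + (j−b_k)²) / 2σ_k²) + ε_{ij,k} ] / D,

  `D = 400`.  The per-unit variance is drawn once from
  `σ_k² ~ LogN(−0.7/θ, 0.7θ)`; the generalization metaparameter `θ > 0`
  widens both the location and the spread of the width distribution, so a
  mixture of narrowly and broadly tuned units emerges — the substrate of
  the generalization gradient.  We read the second log-normal argument as
  the **standard deviation** of the log (the common convention); a
  `log_scale_is_sd` switch selects the variance reading instead.  The
  optional connection noise `ε` equals `A` with probability `ρ` per entry
  (else 0), is drawn once per run before learning, and is never updated —
  it models a degraded cortical encoding, not observation noise.
* **Opponent readout.** Two nonnegative weight vectors over the hidden
  layer: `w1` (positive channel, D1-like) and `w2` (negative channel,
  D2-like).  Channel activities are `d_m = w_m · h` and the state value is
  `v = d1 − d2`.  Both start at zero, so every state starts at value 0.

Action values use the **afterstate** convention, `Q(s, a) = v(x′, y′)`
at the square the action points to — including impassable squares, which
is how walls acquire (negative) values.  Learning is on-policy SARSA:
`δ = r + γ·Q(s′, a′) − Q(s, a)` with the bootstrap action `a′` the one
actually drawn at the *actual* next state (after a wall hit, `s′ = s`),
and a zero bootstrap on terminal steps.

**The update.**  Positive errors grow `w1`, negative errors grow `w2`
(never shrink; discrimination works by the opposing channel offsetting,
not by unlearning):

    δ > 0:  Δw1 = α₁ δ  · h(x′,y′) / Σ_k h_k(x′,y′)²
    δ < 0:  Δw2 = α₂ (−δ) · h(x′,y′) / Σ_k h_k(x′,y′)²

The `Σ h²` normalization is chosen so that the value of the updated
square moves by **exactly** `α₁δ` (or `α₂δ`) — the typeset form of the
normalization term is ambiguous in isolation, but its stated purpose
(this exact-increment property) pins the rule down uniquely, and this
form is also well defined at zero initialization.  The property is
enforced to 1e−9 in the tests over randomized bases, weights, positions
and errors.  Because neighbouring squares share basis responses, each
increment spreads smoothly to nearby squares: that is the fast
generalization, and the single free choice `θ` controls its reach.

`α₂ = 0` is the **impaired** condition (no learning from negative
errors); `A, ρ > 0` is the **noised** condition.  Their combination is
what produces aberrant valuation: sparse noise entries of size `A/D`
rival a unit's own peak response `1/D`, so weight earned at a goal leaks
to arbitrary distant squares, and with `α₂ = 0` nothing ever trims it.

## Comparison agents

* **Tabular SARSA** — one 20×20 state-value table, afterstate action
  values, `v(x′,y′) += α_s δ_s`.  No generalization: one cell per update.
* **MaxPain variant** — separate reward and pain tables `v_r, v_p`
  updated from the rectified reward `φ(r) = max(r, 0)` and rectified pain
  `φ(−r)`.  The reward error bootstraps on-policy; the pain error
  bootstraps off-policy on `argmin_a Q_L(s′, a)` — the worst case under
  the combined value `v_L = v_r − v_p` (no mixture normalization).
  Argmin ties are broken uniformly at random from the agent's own seeded
  stream: zero-initialized tables make ties ubiquitous early, and a
  fixed-index rule would bias the exploration geometry.

All three agents choose actions by a softmax over the four afterstate
values with temperature τ = 0.5.

## Tasks and protocols

Worlds are 20×20 grids with an impassable border ring (the tasks never
define off-grid moves, and the encoder only covers `1..20`, so every
intended target must be a representable square).  Coordinates are
1-based; the action order is fixed (E, W, S, N).  Goals are absorbing:
entering one delivers its reward and ends the episode.

* **Painful navigation** — a corridor maze: a 3-wide passage with the
  start at one end and a safe reward-1 goal at the other, plus a risky
  reward-2 goal at the end of a 1-wide branch.  Wall hits cost −1 and the
  agent stays put.  Defaults per run: 500 episodes; metaparameters
  α₁ = α₂ = 0.1, γ = 0.95 (all agents share α = 0.1, γ = 0.95; MaxPain
  additionally γ_p = 0.5); θ ∈ {0.44, 0.66, 1.0, 1.5, 2.2} probes the
  generalization level.  Value-map snapshots at episodes 5, 30, 150, 500.
  The shipped `two_goal_corridor` fixture is one hand-coded instance of
  this construction; the rule-based random generator
  (`generate_painful_maze`: wide passage ≥ 8 squares long, widths 3 and
  1, symmetric-duplicate rejection in batches) draws further layouts
  from the same rules.
* **Relearning** — train with painful walls to episode 500, then switch
  the wall penalty to 0 and continue (default 500 more episodes,
  configurable); the value map's mean over all impassable squares is
  logged each episode.  Wall-value means include the border ring by
  default (an `include_border=False` mask restricts to interior walls).
* **Disturbed valuation** — a painless open arena with four reward-1
  goals and a central start; γ = 0.8, θ = 1, wall hits cost 0.  A run is
  a **global budget of 40,000 environment steps**, the final episode
  truncated mid-flight (which is why average episode counts per run are
  fractional).  The 2×2 design crosses {intact α₂ = 0.1, impaired
  α₂ = 0} with {unnoised A = ρ = 0, noised}; the noised grid spans
  A ∈ {0.25, 0.5, 1, 2, 4} × ρ ∈ {0.00125, 0.0025, 0.005, 0.01, 0.02},
  with noise redrawn independently per run.  Each run's final value map
  is summarized by its maximum, argmax position (ties: smallest x, then
  y; the search includes wall squares) and Manhattan distance to the
  nearest goal.

The episode step cap is 100,000 in episodic protocols — a guard against
non-terminating configurations, recorded as truncation rather than
raised, and never reached in practice.

## Randomness and reproducibility

One master seed per experiment expands through named
`numpy.random.SeedSequence` substreams — (agent kind, run index) selects
a run stream, which spawns policy, basis-width, basis-noise, tie-break
and start-randomization children.  Consequently (a) identical
(config, seed) pairs reproduce runs bit for bit, (b) changing the noise
setting does not perturb the width draws, and (c) runs are independent
across indices.  Basis tables are bit-reproducible from their spec.

## Metrics

Per episode: steps (wall hits count as steps), total signed reward, wall
hits, reward per step.  Learning curves are smoothed with a trailing
11-episode moving window (current episode plus the 10 preceding; the
head is truncated to available history — window width is a parameter).
Cross-run aggregation is a pointwise mean with **population** SD (bands
are descriptive, not inferential); ragged tails from step-budgeted runs
are excluded pointwise with the per-point n recorded.  The
single-update generalization gradient is summarized by a ring-averaged
radial profile (mean value over squares at each rounded Euclidean
distance from the updated square).

## Numerical notes

* The exact-increment contract holds to ~1e−15 in practice; tests assert
  1e−9.
* Distant tails of narrowly tuned Gaussians underflow to 0.0 in double
  precision.  This is harmless: every unit's centre response is exactly
  `1/D`, so the activity norm `Σ h²` is strictly positive everywhere
  (asserted before each update).
* δ = 0 performs no update; neither channel moves.
* The softmax subtracts the max value before exponentiation.

## What the synthetic worlds do and do not show

All inputs are synthetic by construction — this is a simulation study,
and the grid worlds *are* the experimental conditions, so there is no
separate "real data" regime.  The corridor fixture is one instance of
the passage-construction rules (passage widths, goal placement, reward
sizes), not a canonical layout: quantitative levels of the learning
curves are layout-dependent, while the qualitative regularities the
tests assert (early-phase safety and speed of the generalizing learner,
the non-monotone effect of the generalization level, fast wall-value
relearning, the disturbance dissociation) hold across rule-generated
layout variants and randomized starts.

## Problem sizes used by the test suite

The property and ordering tests run the full protocols at reduced
replication chosen to keep the default suite fast while leaving the
orderings clearly resolved: 10 runs (instead of 50) for the painful,
generalization-level and relearning comparisons, with 120 post-switch
episodes for relearning; the disturbed-valuation conditions run at the
full 50 runs × 40,000 steps, since run-level counts (49/50 at-goal runs)
are the claim itself.  The acceptance script's single-update target is
seed-independent by the exact-increment property.

## Known limitations

* Transitions are deterministic and the action set is fixed at four
  moves; no stochastic worlds, no continuous state.
* Grid sizes other than 20×20 work internally (the baselines and the
  environment are size-generic) but are exercised only by small oracle
  tests; the basis defaults assume 20×20.
* The output mixing weights of the two channels are fixed at (+1, −1);
  risk-sensitive reweighting is out of scope.
* Eligibility traces, recurrent (reservoir) encoders and learned
  encoders are out of scope by design: the fixed feed-forward encoding
  is the modelling claim.
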