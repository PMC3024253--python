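# Methods

## The generative task

The environment is a six-arm restless bandit with two colour groups of
three arms. Blue arms pay (−1, 0, +1) CHF, red arms (−2, 0, +2), each
according to a latent probability triplet on the 3-simplex. The triplets
of a colour group are redrawn *simultaneously* ("jump") with a per-trial
hazard; the defaults are `hazard_blue = 0.04`, `hazard_red = 0.16`. Only
the 4× red/blue hazard ratio is a fixed feature of the task design; the
absolute hazard levels are our calibration choice — a blue arm then jumps
about once per 25 trials and a red arm about once per 6, which produces
clearly distinct average unexpected uncertainty between the colours within
a 500-trial session while leaving enough calm stretches for estimation
uncertainty to fall. Both hazards are configurable.

A jump at trial T is resolved *before* the trial-T outcome is drawn, so
the outcome already reflects the post-jump probabilities; this matches the
learner's re-learning semantics (evidence for a jump arrives with the
first post-jump outcome).

Jump targets are drawn per arm according to an entropy profile:
`random` arms redraw from the flat Dirichlet(1,1,1), `intermediate` from
Dirichlet(2,2,2), and `biased` arms put a uniform(0.7, 0.9) mass on one
outcome (picked uniformly) and split the remainder uniformly. The profiles
stratify outcome entropy in expectation (biased ≈ 0.64 nats vs random
≈ 0.83 nats), reproducing a board in which one location per colour is
predictable and another close to random. The exact generative
distributions of the original task are not recoverable, so these samplers
are the package's own choice; only the biased < random entropy ordering is
asserted in tests.

Sessions are logged as tidy CSV (trial, arm, colour, outcome), optionally
with the latent triplets and per-colour jump indicators. Each session
consumes one seeded NumPy generator split into independent environment and
agent sub-streams, so changing the agent never perturbs the environment's
jump/outcome sequence.

## The forgetting-Bayesian learner

Per arm, beliefs are Dirichlet with parameters `α = ν0 c0 + n z`:

- `c0` — prior centre (default uniform), `ν0` — prior precision
  (default 3, the flat-Dirichlet scale; the original precision value is
  not recoverable, so the least-informative conventional choice is used);
- `n` — effective number of observations (init 1: the prior centre counts
  as one pseudo-observation, giving initial learning rate 1);
- `z` — sufficient statistic, a convex running average of outcome
  indicator triplets.

After outcome `x` on chosen arm with colour hazard `q`:

```
π  = (1−q)·(α_x/Σα) / [ (1−q)·(α_x/Σα) + q·c0_x ]      no-jump probability
n' = π n + 1,  η' = 1/n'                                chosen arm
z' = (1−η') z + η' e_x
n' = π n                                                same-colour unchosen
n' = (1−q_other) n                                      other colour
```

Properties that pin this scheme down:

- with `π ≡ 1` it is *exactly* conjugate Dirichlet-multinomial updating
  with prior `(ν0+1) c0` (the `1/T` learning-rate law, with the prior
  centre counted as the first pseudo-observation in the running mean);
- as `π → 0` the learning rate snaps to 1 and the sufficient statistic to
  the newest outcome, regardless of history (full re-learning);
- the effective count admits the closed product form
  `n_T = n_0 Π π_t + Σ_{visits s} Π_{t>s} π_t`, which the tests use as an
  independent oracle for the recursion;
- the belief mixing underlying the decay is a weighted geometric mean of
  the no-jump posterior and the reset prior: Dirichlet densities are
  closed under it, with parameters `π α_post + (1−π) α_0`.

Two genuinely open design points, resolved as follows:

- **Update order.** Whether the newest observation is itself discounted by
  `π` (update-then-forget, `α' = π(α + e_x) + (1−π)α_0`) or added at full
  weight after forgetting (`α' = πα + (1−π)α_0 + e_x`) is not determined
  by the geometric-mean closure alone. The forget-then-increment order is
  used because it is the only one whose learning rate converges to exactly
  1 as `π → 0` irrespective of history; under the other order the weight on
  the newest observation would itself shrink with `π`. The standalone
  `forgetting_operator` exposes the pure mixing step on raw parameters.
- **Jump evidence.** `π` is computed as a hazard-weighted Bayes factor
  between the posterior-predictive probability of the realised outcome
  (stay) and its reset-prior predictive (jump). This form reproduces the
  required qualitative behaviour: a fresh or maximally risky belief gives
  `π = 1 − q` (surprises carry no jump information when risk is high or
  precision low), and surprise under a precise belief drives `π` down.
  An `evidence_exponent` hook (default 1) allows sharpening or flattening
  the predictive ratio; it is not used anywhere by default.

The learner's hazards default to the environment's true values (the
no-structural-uncertainty condition); they can be set independently and
are in principle fittable, but the shipped fitting routine treats them as
known to keep the Bayesian models at one free parameter (β).

Because jumps are colour-wide, the inferred `π` is applied to every arm of
the chosen colour. The unobserved colour still decays — at its prior
no-jump probability `1 − q` — since jumps there occur unobserved. An
unvisited arm's effective count therefore decays geometrically, its
posterior mean relaxes monotonically to the prior centre, and its
"imaginary" learning rate `1/max(n, 1)` creeps back towards 1.

## Uncertainty metrics

- Risk: Shannon entropy (nats) of the posterior-mean triplet; maximal at
  `ln 3`.
- Estimation uncertainty, variance metric: summed component variances of
  the posterior Dirichlet (a mean-aggregation option exists).
- Estimation uncertainty, entropy metric: the Dirichlet differential
  entropy `ln B(α) + (α0−K)ψ(α0) − Σ(α_i−1)ψ(α_i)`. It is negative for
  concentrated beliefs — the flat Dirichlet(1,1,1) gives `−ln 2` — which is
  the correct differential-entropy value; a `negate` flag exposes the
  opposite (precision-style) sign convention. Only relative ordering
  matters in the bonus/penalty valuations.
- Unexpected uncertainty: `1 − π`, per colour.

Natural logarithms are used throughout; the digamma-based entropy formula
fixes nats as the natural unit.

## Choice models and fitting

Values enter a softmax with inverse temperature `β ∈ (0, 50]`. The
bonus/penalty variants replace `Q` with `(1−w)Q ± wU`, `w = 1/2` by
default (exposed in the spec object). Bonus/penalty is restricted to the
Bayesian learner: model-free learners have no posterior and hence no
estimation uncertainty to weigh.

Comparators: Rescorla-Wagner with colour-specific rates
(`Q ← Q + α_colour δ`, unchosen arms frozen; equal rates reduce exactly to
the single-rate model) and Pearce-Hall (value updated with the current
associability, associability then reset to `|δ|` normalised by the
colour's maximal payoff magnitude and clipped to [0, 1]). Initial values
are 0 (payoff-centred) and initial associability 1 (first outcome fully
absorbed); the replacement rule — rather than an exponentially smoothed
associability — is the one-free-parameter form, keeping β the only fitted
parameter as for the Bayesian models.

Fitting maximises the causal session log-likelihood
`Σ_t ln P(choice_t | trials < t)`. The optimiser is deterministic: a
50-point log-spaced β grid (plus a 21×21 linear grid over the two RW
rates), then bounded local refinement (Brent on β; L-BFGS-B on
(β, α_blue, α_red)); no stochastic restarts, so refits are bit-identical.
The RW grid scan is vectorised over all rate pairs and performed in float32
with the winner re-scored in float64 — float32 affects only which grid
point seeds the refinement. Per-trial choice probabilities are floored at
1e-12 (with a warning) so extreme β values keep the objective finite
during search. `BIC = −2 LL + k ln n` with k = 1 (Bayesian, Pearce-Hall)
or 3 (RW); cohort comparisons report per-subject BIC differences, paired
two-sided t-tests and the fraction of subjects favouring each model, with
the degenerate zero-variance case mapped to t = 0, p = 1.

## What the synthetic cohorts do and do not show

Synthetic subjects are softmax agents with known parameters playing
fresh environment realisations (one seed per subject). Default study
sizes mirror the task's scale: 500-trial sessions, 50 replications for
parameter recovery, 30-subject cohorts for model recovery. Generating
parameters for the studies are `β = 5` for Bayesian agents and
`(β, α_blue, α_red) = (3, 0.1, 0.4)` for RW agents — values at which the
agents are decisive but still exploratory.

Passing recovery tests shows the pipeline is self-consistent: the
generating model's parameters and identity are recovered from data it
generated. It does not show that human choices follow any of these models;
real data add within-subject non-stationarity (fatigue, instruction
effects, structural ignorance) that no synthetic agent here emulates.
Likewise the `π`-calibration checks (higher inferred jump probability on
true jump trials) validate detection against the simulator's own
generative process, with hazards known to the learner.

## Numerical notes and limitations

- Simplex quantities are renormalised on storage; tests assert sums to
  1 within 1e-12.
- Beliefs keep `n` as a float; `η = 1/max(n, 1)` caps the learning rate at
  1 when decay pushes `n` below one.
- The learning-rate recursion `η' = η/(π+η)` and the implementation's
  `η' = 1/(πn+1)` coincide exactly while `n ≥ 1`; in the capped regime the
  count form is authoritative.
- Only per-subject fits are provided; no hierarchical/group-level
  estimation.
- No stochastic-volatility (continuously drifting probability) variant:
  discrete jumps are a deliberately distinct regime.
- Treatments differing only in instructions are analysis-time labels; the
  simulator is identical across them and instruction effects are out of
  scope.
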