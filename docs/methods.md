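# Methods

## The task family

The core task is a two-stage timing-inference problem. A ball moves at
constant speed through an H-shaped maze: down an entry hallway, left or
right along a horizontal arm, then up or down along a vertical arm to one of
four exits (LU, LD, RU, RD). The ball is invisible inside the maze; three
auditory clicks mark the junctions, so the two inter-click intervals
(ts1, ts2) encode the lengths of the traversed arms. The agent reports the
exit.

Two geometry regimes are implemented. In the *human* regime, arm lengths
are drawn from {3..7} dva with each arm pair (L+R, LU+LD, RU+RD) summing to
10 dva and ball speed 8 or 12 dva/s; enumerating ordered pairs per slot and
speeds gives exactly 250 geometry×speed cells, and the extreme arms (3 and
7 dva) map to traversal times of 0.25 and 0.875 s. In the *rnn* regime, six
arm lengths are i.i.d. uniform on {4,5,6,7} (4^6 = 4096 geometries, split
75/25 into 3072 train and 1024 test) and speed is one length unit per
timestep.

Three task variants probe specific computational constraints:

1. **Parallel tracking** — four independent arms each carry a ball that
   reflects off the arm ends (triangle-wave kinematics); the agent must say
   which ball sits at an endpoint when the second cue sounds. Trials are
   constructed so the target ball is exactly at an endpoint while the other
   three are interior by a clearance margin of 0.5 dva (one arm width; the
   constraint is stated by the task design, the margin value is ours).
2. **Order reversal** — a half-maze discrimination in which condition 2
   presents the maze *after* the auditory cues, forcing the comparison to
   run on remembered intervals.
3. **Optional reveal** — a half-maze whose hidden side can be revealed on
   request before the final choice.

## Timing noise and the psychophysical model

Measured intervals follow scalar variability: tm = ts (1 + w ε) with
ε ~ N(0,1), so tm | ts is Gaussian with mean ts and standard deviation
w·ts. Draws with tm ≤ 0 are rejected and resampled (rather than truncated)
to preserve the scalar shape near zero. The Weber fraction w is estimated
from the two-arm (T-maze) discrimination by maximum likelihood with two
nuisance parameters: a criterion shift and a lapse rate Γ (a lapse trial is
a fair coin flip):

    p(choose t1 | true t1) = Γ/2 + (1−Γ) Φ((t_c − t1)/(w t1))
    p(choose t2 | true t2) = Γ/2 + (1−Γ) (1 − Φ((t_c − t2)/(w t2)))

The criterion t_c sits at the crossing of the two scaled likelihoods, which
solves a quadratic in tm (the root between t1 and t2). Because the task
mixes several (t1, t2) pairs, a single global criterion is dimensionally
awkward; we model t_c per pair at its likelihood crossing plus one shared
additive bias, keeping three free parameters (w, bias, Γ). A global-t_c
variant is available behind `criterion="global"`. Optimization is
multi-start L-BFGS-B (8 seeded starts) over w ∈ (0.01, 1), bias within the
interval span, Γ ∈ (0, 0.5); per-trial likelihoods are floored at 1e−12.

For the order-reversal variant the per-condition noise σ is estimated from
correct/incorrect responses through the cumulative-Gaussian psychometric
p(correct) = Φ(|t1−t2|/σ) (1-D bounded MLE on log σ), and the effect is
summarized as 100 (σ₂ − σ₁)/σ₁.

## Strategy models

All five strategies consume (tm1, tm2), the geometry and a fixed w
estimated independently from the T-maze — the maze-task fits never
re-estimate timing noise.

* **optimal** — argmax over the four exits of the joint likelihood
  p(tm1|t_h) p(tm2|t_v) (conditionally independent measurements).
* **hierarchical** — commit left/right on p(tm1|t_L) vs p(tm1|t_R), then
  choose the committed side's vertical arm on tm2; no revision.
* **postdictive** — the horizontal commitment compares side-summed joint
  likelihoods; the vertical stage is hierarchical.
* **counterfactual** — hierarchical, but when the committed side's best
  vertical log-likelihood X = max p(tm2|·) falls below a threshold θ, the
  intervals are recalled from memory with noise (mean β, sd α·tm) and the
  decision switches unconditionally to the other side's vertical argmax
  under the recalled tm2.
* **mixed** — hierarchical when |log p(tm1|t_L) − log p(tm1|t_R)| > θ;
  otherwise uncommitted, choosing the exit whose vertical arm best matches
  tm2.

Design choices that were genuinely open: the revision trigger X is the
maximum of the committed side's two vertical likelihoods (matching the
description that revision fires when *both* are below threshold), expressed
on the log scale for numerical stability; revision is an unconditional
switch, with a side-comparing trigger available behind
`revise_trigger="compare"` (with perfect recall that variant reproduces the
optimal decisions exactly, which the tests exploit); recall noise is
applied to both recalled intervals although only tm2′ enters the
post-revision choice; the model revises at most once. Ties are broken by
fixed exit order (LU, LD, RU, RD) in the scalar API and uniformly at random
(seeded) inside Monte-Carlo distributions — without the random tie-break,
symmetric mazes (5,5 pairs) would collapse onto the first exit. There is no
lapse parameter in the maze-task strategy models.

## Likelihood evaluation and model comparison

The choice model p(exit | geometry, true path, strategy, params) is
estimated by Monte Carlo over measurement draws, floored at 1e−4 per exit
cell and renormalized so finite sampling never yields infinite NLL.
Draws (measurement, recall deviates, tie jitter) are cached per unique
trial condition and reused across parameter values (common random numbers),
making the NLL deterministic given the seed and cheap inside optimizers.

The optimal, hierarchical and postdictive strategies are parameter-free and
evaluated predictively. The counterfactual fit searches a coarse θ grid at
quantiles of the simulated X distribution (the NLL is piecewise-flat in θ
under finite Monte Carlo) followed by Nelder-Mead over (θ, α, β); the mixed
fit is grid-then-bounded-refinement in θ. Cross-validation uses seeded
k-fold partitions stratified by horizontal difficulty |L−R| so difficulty
is balanced across folds; free parameters are refit per training split and
the report is mean held-out NLL per trial. Default Monte-Carlo counts are
4000 draws per condition for fitting and evaluation in the library API;
the test suite and acceptance script use 1000–2000 to keep desk runs short
(NLL standard errors remain small relative to the model differences at
session size).

## Synthetic participants

`ParticipantProfile` + `simulate_session` generate full sessions for every
task with the paper-battery sizes as defaults (168 T-maze, 540 H-maze,
170 variant-1, 160 per variant-2 condition, 324 variant-3 trials).
Condition 2 of the order-reversal variant inflates the condition noise by a
configurable factor (default 1.2). For the optional-reveal variant no
generative reveal rule is given by the behavioural data, only a correlation
structure; we adopt a bounded-rationality policy — reveal iff the visible
side's best vertical log-likelihood X < θ0 − slope·α (defaults θ0 = 0.5,
slope = 4) — whose single purpose is to reproduce the *sign* of the
association between recall-noise and reveal rate on hidden-correct trials.
What the generator does not emulate: reaction-time distributions, sequential
(trial-history) effects, learning, and idiosyncratic strategy mixtures;
passing recovery tests on these cohorts therefore shows the estimators are
consistent under the models' own assumptions, not that human data are free
of such structure.

## The constrained recurrent network

A vanilla tanh RNN, r_{t+1} = tanh(W_rec r_t + W_in I_{t+1}), with sigmoid
readouts (h_t, v_t) = σ(W_out r_t) for the horizontal and vertical choices,
trained by backpropagation-through-time written directly in numpy (gradient
checked against central finite differences to ~1e−10 relative error) with
an Adam optimizer. Trials use 32 timesteps; the ball reaches the first
junction at timestep 6, after which the first input channel ramps linearly
from 0 to tm1 over int(tm1) timesteps (truncation toward zero, minimum one
step, capped at 12 so ramps always finish) and the second channel then
ramps to tm2. Arm lengths enter as constant channels. Inputs are scaled by
0.15 to keep task units inside tanh's linear range. Choices are binarized
at 0.5 at the final timestep (the readout timestep is not dictated by the
task; the last step is the natural choice point).

Constraints:

* **attention** — the network sees the vertical arms only through the gate
  U_t = h_t LU + (1−h_t) RU, D_t = h_t LD + (1−h_t) RD (input shrinks to 6
  channels; the gate at step t+1 uses h_t).
* **rationality** — the supervised MSE-to-label objective is replaced by the
  squared-relative-error surrogate of the chosen exit's log-likelihood,
  h ((tm1−L)/L)² + (1−h)((tm1−R)/R)² + v ((tm2−U)/U)² + (1−v)((tm2−D)/D)²,
  summed over timesteps after tm2 finishes ramping (as is the supervised
  loss). For rationality without attention the gated U, D enter the loss
  only.
* **counterfactual noise** — after tm2 finishes ramping, every 0.5-crossing
  of h multiplies both perceived intervals by (1 + σ_noise ε) for all
  subsequent timesteps (σ_noise = 0.5 when the constraint is on). The
  crossing event and noise draw are non-differentiable (gradient stopped).
  Enabling this constraint without attention is ruled out, since crossings
  are attention switches.

Training choices (unspecified by the task, recorded here): Adam at 3e−3,
batch 64, up to 200 epochs with early stopping (patience 40) on held-out
loss; gradients clipped at norm 5. Early-stopping selection evaluates the
held-out loss *without* the counterfactual noise: with it active the loss
fluctuates with the injected draws and occasionally explodes on large
deviates, which turns selection into a lottery that favours undertrained
networks. The injected noise itself ramps from 0 to σ_noise over the first
half of training (a curriculum): a network that crosses randomly early in
training destroys its own inputs and never learns the task, whereas ramping
lets high penalties suppress switching in an already-competent network.

Strategy attribution computes each strategy's NLL over the network's
binarized test-set choices with w = 0.15; the counterfactual comparison
fixes its recall noise to the network's switching noise (α = 0.5, β = 0)
and fits θ by maximum likelihood with twofold cross-validation.

Desk-scale results (64 hidden units, 192 training geometries × 8 trials)
reproduce the qualitative continuum: unconstrained networks attribute to
the optimal strategy, attention-only to hierarchical, all-constraints to
counterfactual, switching falls with |L−R|, and attribution moves from
counterfactual toward hierarchical as σ_noise grows. Two effects need the
full-scale regime (128 units, 3072 geometries, many initializations) that
a desk run does not reach: the attention+rationality network at σ≈0 stays
mildly hierarchical rather than fully optimal (its NLL gap to optimal is
~0.03 nats/trial), and the optimal region of the σ sweep can be absorbed
into the counterfactual region by one grid point.

## Gaze rules

A hierarchical saccade is the earliest pre-third-cue sample with |x| > 2
dva inside a 10-dva region of interest (both axes); its sign gives the
side. A switch is any post-third-cue excursion beyond 2 dva on the opposite
side within the same region. Traces are median-filtered over 25 ms (the
artefact-removal filter is not otherwise specified); a single qualifying
sample suffices (no dwell requirement). The synthetic trace generator
produces fixation at the origin, a saccade to the first-choice side after
the second cue, and, for revised decisions, a jump to the opposite side
after the third cue, with 0.3 dva Gaussian sample noise at 250 Hz.

## Numerical conventions

Geometry serialization order is (L, R, LU, LD, RU, RD); exits are indexed
LU, LD, RU, RD; variant-1 arms are 0-based. All randomness flows from
explicit integer seeds (numpy Generator streams); simulation outputs carry
their seed. Probability floors: 1e−12 per trial in psychophysical fits,
1e−4 per exit cell in Monte-Carlo choice distributions. Likelihood ties are
resolved by a pre-drawn jitter ~1e−9 below any genuine log-likelihood
difference, which makes tied exits uniform without perturbing non-tied
comparisons.

## Known limitations

The Monte-Carlo choice model makes fitted θ estimates piecewise-flat; θ is
recovered only up to an identifiability band (about ±1 log-likelihood unit
at 5000 trials). The recall-noise scale α is weakly identified when
revisions are rare. The network experiments run at a deliberately reduced
scale; their attributions are majority statements over seeds, not
per-seed guarantees. The reveal policy of the optional-reveal variant is a
constructed mechanism, not an estimate from behaviour.
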