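# hmaze

Models of hierarchical and counterfactual decision strategies in maze
timing-inference tasks, for computational cognitive scientists studying
bounded rationality in multistage decisions.

In the H-maze task, a ball travels invisibly through an H-shaped maze —
left or right along a horizontal arm, then up or down along a vertical arm
— and auditory clicks mark the junctions. The two inter-click intervals
(t_h, t_v) encode the traversed arm lengths, and the agent must report the
exit. Interval measurements carry scalar timing noise: tm ~ N(ts, w·ts)
with Weber fraction w. The package provides:

- **Task simulators** — H-maze and T-maze geometry sampling, scalar-noise
  trial generation, and the three task variants (parallel reflecting balls;
  cue-order reversal; optional reveal of a hidden half-maze).
- **Psychophysics** — maximum-likelihood estimation of the Weber fraction w
  with criterion and lapse parameters from two-interval discrimination, and
  the cumulative-Gaussian condition-noise estimator
  p(correct) = Φ(|t1−t2|/σ) with its percent-change summary.
- **Five strategy models** mapping (tm1, tm2) to an exit:
  *optimal* (argmax of the joint likelihood p(tm1|t_h)p(tm2|t_v) over the
  four paths), *hierarchical* (commit horizontally on tm1, then choose
  vertically on tm2), *postdictive* (horizontal commitment from side-summed
  joint likelihoods), *counterfactual* (hierarchical with noisy
  memory-based revision when the committed side's vertical likelihood drops
  below a threshold θ; recall noise mean β, scale α), and *mixed*
  (hierarchical when the horizontal evidence |LLR| exceeds θ, otherwise
  vertical-only).
- **Model comparison** — Monte-Carlo choice likelihoods with k-fold
  cross-validated negative log-likelihood, stratified by difficulty.
- **Synthetic participants** — full behavioural sessions for every task,
  used for parameter- and strategy-recovery studies.
- **Constrained recurrent networks** — a numpy RNN (manual
  backpropagation-through-time) trained on the task under three
  manipulable constraints: an attentional bottleneck gating the vertical
  arm inputs by the network's own horizontal output, a rationality
  objective replacing supervised labels by the likelihood of the chosen
  exit, and counterfactual noise corrupting the remembered intervals at
  every attention switch.
- **Gaze rules** — classification of hierarchical saccades and
  counterfactual switches from (x, y) gaze traces, plus a synthetic trace
  generator.

## Worked example

Simulate a counterfactual decision maker, then ask which strategy explains
its choices best under tenfold cross-validation:

```python
import numpy as np
from hmaze import ParticipantProfile, simulate_session
from hmaze.strategies import StrategyParams
from hmaze.fitting import crossval_compare

profile = ParticipantProfile(
    strategy="counterfactual",
    params=StrategyParams(theta=0.0, alpha=0.3, beta=0.0),
    w=0.15, task="hmaze", n_trials=540, seed=11)
session = simulate_session(profile)

result = crossval_compare(session, w_fixed=0.15, k=10, n_mc=1000, seed=7)
for name, nll in sorted(result.mean_heldout_nll.items(), key=lambda kv: kv[1]):
    print(f"{name:15s} {nll:.4f}")
print("best:", result.best())
```

Output:

```
counterfactual  0.6388
optimal         0.7018
mixed           0.7024
hierarchical    0.7055
postdictive     0.7223
best: counterfactual
```

Numbers are mean held-out negative log-likelihood in nats per trial
(chance = log 4 ≈ 1.386); the generating strategy wins by a clear margin,
and the other four strategies cluster ~0.06-0.08 nats/trial worse.

The same pipeline is scriptable from the shell:

```bash
hmaze --seed 11 simulate --task hmaze --strategy counterfactual --out run/
hmaze --seed 7 compare --data run/participant_000_hmaze.csv --out run/cmp.json
hmaze --seed 1 rnn --out run/rnn --n-geometries 192
```

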