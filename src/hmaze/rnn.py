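"""Task-optimized recurrent networks for the maze timing-inference task,
with three manipulable computational constraints.

The network is a vanilla tanh RNN (Eq.-style recurrence
``r_{t+1} = tanh(W_rec r_t + W_in I_{t+1})``) with sigmoid readouts
``h_t, v_t = sigmoid(W_out r_t)`` for the horizontal (left/right) and
vertical (up/down) choices.  Inputs are the six arm lengths plus two ramping
interval signals: a1 ramps linearly from 0 to the first perceived interval
tm1 (starting at the junction timestep) over int(tm1) steps, then a2 ramps
to tm2; both then stay constant.  The perceived intervals carry scalar noise
tm = ts (1 + w eps).

Constraints (any logical combination; counterfactual noise requires
attention):

* attention — the network only sees the vertical arm lengths through a soft
  gate driven by its own horizontal output:
  ``U_t = h_t LU + (1-h_t) RU`` and ``D_t = h_t LD + (1-h_t) RD``,
  shrinking the input to 6 channels.
* rationality — instead of supervised targets, training minimizes the
  squared-relative-error surrogate of the exit log-likelihood given the
  noisy intervals (self-consistency: only information available to the
  learner enters the loss).
* counterfactual noise — after the second interval finishes ramping, every
  0.5-crossing of h multiplies both perceived intervals by (1 + sigma eps),
  degrading all subsequent evidence; the crossing event is treated as
  non-differentiable.

The implementation is pure numpy with hand-written backpropagation through
time (gradient-checked against finite differences in the test suite) and an
Adam optimizer.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from hmaze.mazes import ALL_PATHS, MazeGeometry, Trial, \
    sample_measured_intervals
from hmaze.strategies import EXITS

__all__ = ["RNNConfig", "RNNTrialTensor", "RNNWeights", "build_inputs",
           "make_trial_set", "rnn_step", "rnn_outputs", "attention_gate",
           "rationality_loss", "supervised_loss", "forward", "train",
           "evaluate_choices", "classify_strategy",
           "attention_switch_analysis", "strategy_vs_sigma_sweep"]

MAX_RAMP_STEPS = 12  # keeps the slowest ramp finished well before trial end


@dataclass
class RNNConfig:
    """Architecture, constraint flags and training hyperparameters."""

    n_hidden: int = 128
    timesteps: int = 32
    junction_step: int = 6      # 1-based timestep at which a1 starts ramping
    w_noise: float = 0.15       # perceptual Weber noise on the intervals
    sigma_noise: float = 0.5    # counterfactual noise per attention switch
    attention: bool = False
    rationality: bool = False
    counterfactual_noise: bool = False
    input_scale: float = 0.15   # keeps task-unit inputs in tanh's linear range
    learning_rate: float = 3e-3
    batch_size: int = 64
    epochs: int = 200
    patience: int = 40          # early stopping on held-out loss
    grad_clip: float = 5.0
    sigma_warmup: float = 0.5   # fraction of epochs over which the
                                # counterfactual noise ramps from 0 to target
    seed: int = 0

    def __post_init__(self):
        if self.counterfactual_noise and not self.attention:
            raise ValueError(
                "counterfactual noise is triggered by attention switches; "
                "enabling it without the attention constraint is ruled out")
        if self.timesteps <= self.junction_step + 2:
            raise ValueError("too few timesteps for the input ramps")

    @property
    def n_inputs(self) -> int:
        return 6 if self.attention else 8

    def to_json(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RNNWeights:
    W_rec: np.ndarray   # (N, N)
    W_in: np.ndarray    # (N, n_inputs)
    W_out: np.ndarray   # (2, N)

    def copy(self) -> "RNNWeights":
        return RNNWeights(self.W_rec.copy(), self.W_in.copy(), self.W_out.copy())


def init_weights(config: RNNConfig, rng: np.random.Generator) -> RNNWeights:
    N = config.n_hidden
    return RNNWeights(
        W_rec=rng.standard_normal((N, N)) / np.sqrt(N),
        W_in=rng.standard_normal((N, config.n_inputs)) / np.sqrt(config.n_inputs),
        W_out=0.1 * rng.standard_normal((2, N)),
    )


@dataclass
class RNNTrialTensor:
    """Input ramps and metadata for a batch of trials (arrays over trials)."""

    arms: np.ndarray      # (B, 6) lengths in order L, R, LU, LD, RU, RD
    tm1: np.ndarray       # (B,)
    tm2: np.ndarray       # (B,)
    ts1: np.ndarray
    ts2: np.ndarray
    label_h: np.ndarray   # (B,) 1 = left
    label_v: np.ndarray   # (B,) 1 = up
    s1: np.ndarray        # (B,) 1-based timestep at which a1 saturates
    s2: np.ndarray        # (B,) 1-based timestep at which a2 saturates
    a1: np.ndarray        # (T+1, B) ramp values, index = 1-based timestep
    a2: np.ndarray        # (T+1, B)


def _ramp_steps(tm: np.ndarray) -> np.ndarray:
    """int(tm) ramp steps (truncation toward zero), at least 1, bounded."""
    return np.clip(tm.astype(int), 1, MAX_RAMP_STEPS)


def build_inputs(trials: Sequence[Trial] | pd.DataFrame,
                 config: RNNConfig) -> RNNTrialTensor:
    """Input tensors for a batch of rnn-regime trials.

    a1 is zero until the ball reaches the junction (timestep
    ``junction_step``), ramps linearly to tm1 over int(tm1) timesteps and
    stays constant; a2 starts ramping once a1 saturates.
    """
    if isinstance(trials, pd.DataFrame):
        arms = trials[["arm_L", "arm_R", "arm_LU", "arm_LD", "arm_RU",
                       "arm_RD"]].to_numpy(float)
        tm1 = trials["tm1"].to_numpy(float)
        tm2 = trials["tm2"].to_numpy(float)
        ts1 = trials["ts1"].to_numpy(float)
        ts2 = trials["ts2"].to_numpy(float)
        label_h = (trials["true_h"] == "L").to_numpy(float)
        label_v = (trials["true_v"] == "U").to_numpy(float)
    else:
        arms = np.array([t.geometry.arms for t in trials], float)
        tm1 = np.array([t.tm1 for t in trials])
        tm2 = np.array([t.tm2 for t in trials])
        ts1 = np.array([t.ts1 for t in trials])
        ts2 = np.array([t.ts2 for t in trials])
        label_h = np.array([t.true_path.horizontal == "L" for t in trials], float)
        label_v = np.array([t.true_path.vertical == "U" for t in trials], float)

    T = config.timesteps
    B = len(tm1)
    n1 = _ramp_steps(tm1)
    n2 = _ramp_steps(tm2)
    start = config.junction_step - 1       # a1 is zero through this timestep
    s1 = start + n1
    s2 = s1 + n2
    if np.any(s2 >= T):
        raise ValueError("ramps exceed the trial length; increase timesteps")
    t_idx = np.arange(T + 1)[:, None]      # 1-based timestep index
    a1 = tm1[None, :] * np.clip((t_idx - start) / n1[None, :], 0.0, 1.0)
    a2 = tm2[None, :] * np.clip((t_idx - s1[None, :]) / n2[None, :], 0.0, 1.0)
    return RNNTrialTensor(arms, tm1, tm2, ts1, ts2, label_h, label_v,
                          s1, s2, a1, a2)


def make_trial_set(
    geometries: Sequence[MazeGeometry],
    n_per_path: int,
    w: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Trials for the RNN regime: for every geometry, every path, n_per_path
    perceived-interval draws (the construction behind '40 trials per
    geometry' with n_per_path = 10)."""
    rows = []
    for g in geometries:
        for path in ALL_PATHS:
            ts1 = g.horizontal_time(path.horizontal)
            ts2 = g.vertical_time(path.exit)
            tm = sample_measured_intervals(
                np.tile([ts1, ts2], (n_per_path, 1)), w, rng)
            for j in range(n_per_path):
                rows.append((*g.arms, g.speed, path.horizontal, path.vertical,
                             ts1, ts2, tm[j, 0], tm[j, 1]))
    df = pd.DataFrame(rows, columns=["arm_L", "arm_R", "arm_LU", "arm_LD",
                                     "arm_RU", "arm_RD", "speed", "true_h",
                                     "true_v", "ts1", "ts2", "tm1", "tm2"])
    df.insert(0, "trial_id", np.arange(len(df)))
    df["regime"] = "rnn"
    return df


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def rnn_step(state: np.ndarray, inputs: np.ndarray,
             weights: RNNWeights) -> np.ndarray:
    """One recurrence step: r' = tanh(W_rec r + W_in I)."""
    if weights.W_rec.shape[0] != state.shape[-1] or \
            weights.W_in.shape[1] != inputs.shape[-1]:
        raise ValueError("weight/input shape mismatch")
    return np.tanh(state @ weights.W_rec.T + inputs @ weights.W_in.T)


def rnn_outputs(state: np.ndarray, weights: RNNWeights):
    """Sigmoid readouts (h, v) of a hidden state."""
    z = state @ weights.W_out.T
    out = 1.0 / (1.0 + np.exp(-z))
    return out[..., 0], out[..., 1]


def attention_gate(h_t, LU, LD, RU, RD):
    """Soft attentional bottleneck on the vertical arm inputs:
    U = h LU + (1-h) RU,  D = h LD + (1-h) RD."""
    U = h_t * LU + (1.0 - h_t) * RU
    D = h_t * LD + (1.0 - h_t) * RD
    return U, D


def rationality_loss(h_t, v_t, tm1, tm2, L, R, U_t, D_t):
    """Squared-relative-error surrogate of the chosen exit's log-likelihood:

    h ((tm1-L)/L)^2 + (1-h) ((tm1-R)/R)^2
      + v ((tm2-U)/U)^2 + (1-v) ((tm2-D)/D)^2
    """
    eL = ((tm1 - L) / L) ** 2
    eR = ((tm1 - R) / R) ** 2
    eU = ((tm2 - U_t) / U_t) ** 2
    eD = ((tm2 - D_t) / D_t) ** 2
    return h_t * eL + (1.0 - h_t) * eR + v_t * eU + (1.0 - v_t) * eD


def supervised_loss(h_t, v_t, label_h, label_v):
    """Squared error to the ground-truth choices."""
    return (h_t - label_h) ** 2 + (v_t - label_v) ** 2


def inject_counterfactual_noise(tm1, tm2, crossed, sigma, rng):
    """Multiplicative noise on both perceived intervals where a crossing
    occurred: tm <- tm (1 + sigma eps)."""
    if sigma == 0.0 or not np.any(crossed):
        return tm1, tm2
    n = int(crossed.sum())
    tm1 = tm1.copy()
    tm2 = tm2.copy()
    tm1[crossed] = tm1[crossed] * (1.0 + sigma * rng.standard_normal(n))
    tm2[crossed] = tm2[crossed] * (1.0 + sigma * rng.standard_normal(n))
    return tm1, tm2


# ---------------------------------------------------------------------------
# forward / backward
# ---------------------------------------------------------------------------

@dataclass
class ForwardPass:
    r: np.ndarray        # (T+1, B, N)
    h: np.ndarray        # (T+1, B)
    v: np.ndarray        # (T+1, B)
    I: np.ndarray        # (T+1, B, n_in); index 0 unused
    tm1_cur: np.ndarray  # (T+1, B) perceived tm1 in effect at each step
    tm2_cur: np.ndarray
    loss_mask: np.ndarray  # (T+1, B) steps entering the loss
    n_switches: np.ndarray  # (B,) h-crossings after a2 saturation
    loss: float


def forward(
    weights: RNNWeights,
    batch: RNNTrialTensor,
    config: RNNConfig,
    rng: Optional[np.random.Generator] = None,
    noise_active: bool = True,
    sigma: Optional[float] = None,
) -> ForwardPass:
    """Run the network on a batch, computing the configured loss.

    Counterfactual noise (if configured and ``noise_active``) multiplies the
    perceived intervals by (1 + sigma eps) at every post-ramp 0.5-crossing
    of h; the event is non-differentiable by construction.
    """
    T = config.timesteps
    B = batch.arms.shape[0]
    N = config.n_hidden
    rng = rng if rng is not None else np.random.default_rng()

    L, R = batch.arms[:, 0], batch.arms[:, 1]
    LU, LD, RU, RD = (batch.arms[:, i] for i in range(2, 6))

    r = np.zeros((T + 1, B, N))
    h = np.full((T + 1, B), 0.5)
    v = np.full((T + 1, B), 0.5)
    h[0], v[0] = rnn_outputs(r[0], weights)
    I = np.zeros((T + 1, B, config.n_inputs))
    tm1_cur = np.tile(batch.tm1, (T + 1, 1))
    tm2_cur = np.tile(batch.tm2, (T + 1, 1))
    n_switches = np.zeros(B, dtype=int)
    t_steps = np.arange(T + 1)
    loss_mask = (t_steps[:, None] > batch.s2[None, :])

    if sigma is None:
        sigma = config.sigma_noise
    sigma = sigma if (config.counterfactual_noise and noise_active) else 0.0
    use_noise = sigma > 0.0

    for t in range(1, T + 1):
        # input at step t (a-channels reflect noise injected before t)
        a1_t = np.where(t <= batch.s1, batch.a1[t], tm1_cur[t])
        a2_t = np.where(t <= batch.s2, batch.a2[t], tm2_cur[t])
        if config.attention:
            U, D = attention_gate(h[t - 1], LU, LD, RU, RD)
            I[t] = config.input_scale * np.stack(
                [a1_t, a2_t, L, R, U, D], axis=1)
        else:
            I[t] = config.input_scale * np.stack(
                [a1_t, a2_t, L, R, LU, LD, RU, RD], axis=1)
        r[t] = rnn_step(r[t - 1], I[t], weights)
        h[t], v[t] = rnn_outputs(r[t], weights)

        if use_noise:
            crossed = ((h[t] > 0.5) != (h[t - 1] > 0.5)) & (t > batch.s2)
            n_switches += crossed
            if np.any(crossed):
                tm1_new, tm2_new = inject_counterfactual_noise(
                    tm1_cur[t], tm2_cur[t], crossed, sigma, rng)
                tm1_cur[t + 1:] = tm1_new
                tm2_cur[t + 1:] = tm2_new
        else:
            crossed = ((h[t] > 0.5) != (h[t - 1] > 0.5)) & (t > batch.s2)
            n_switches += crossed

    if config.rationality:
        U_all, D_all = attention_gate(h, LU, LD, RU, RD)
        per_step = rationality_loss(h, v, tm1_cur, tm2_cur, L, R, U_all, D_all)
    else:
        per_step = supervised_loss(h, v, batch.label_h, batch.label_v)
    loss = float((per_step * loss_mask).sum() / B)
    return ForwardPass(r, h, v, I, tm1_cur, tm2_cur, loss_mask,
                       n_switches, loss)


def backward(
    weights: RNNWeights,
    batch: RNNTrialTensor,
    config: RNNConfig,
    fwd: ForwardPass,
) -> RNNWeights:
    """Gradients of the configured loss wrt all weights (BPTT).

    Noise-injection events are treated as constants (gradient stopped), as
    is the binarization implicit in crossing detection.
    """
    T = config.timesteps
    B = batch.arms.shape[0]
    L, R = batch.arms[:, 0], batch.arms[:, 1]
    LU, LD, RU, RD = (batch.arms[:, i] for i in range(2, 6))
    h, v, r, I = fwd.h, fwd.v, fwd.r, fwd.I
    mask = fwd.loss_mask

    # direct loss gradients wrt h_t and v_t
    if config.rationality:
        U_all, D_all = attention_gate(h, LU, LD, RU, RD)
        eL = ((fwd.tm1_cur - L) / L) ** 2
        eR = ((fwd.tm1_cur - R) / R) ** 2
        eU = ((fwd.tm2_cur - U_all) / U_all) ** 2
        eD = ((fwd.tm2_cur - D_all) / D_all) ** 2
        # d/dU of ((tm2-U)/U)^2 = -2 tm2 (tm2 - U) / U^3
        dU = -2.0 * fwd.tm2_cur * (fwd.tm2_cur - U_all) / U_all ** 3
        dD = -2.0 * fwd.tm2_cur * (fwd.tm2_cur - D_all) / D_all ** 3
        dLdh = (eL - eR + v * dU * (LU - RU) + (1.0 - v) * dD * (LD - RD))
        dLdv = eU - eD
    else:
        dLdh = 2.0 * (h - batch.label_h)
        dLdv = 2.0 * (v - batch.label_v)
    dLdh = dLdh * mask / B
    dLdv = dLdv * mask / B

    gW_rec = np.zeros_like(weights.W_rec)
    gW_in = np.zeros_like(weights.W_in)
    gW_out = np.zeros_like(weights.W_out)
    w_h, w_v = weights.W_out[0], weights.W_out[1]

    dpre_next = np.zeros((B, config.n_hidden))  # dL/d(pre-activation) at t+1
    gh_gate_next = np.zeros(B)  # dL/dh_t via the gated input at t+1
    for t in range(T, 0, -1):
        gh = dLdh[t] + gh_gate_next          # total dL/dh_t
        gv = dLdv[t]
        # through the sigmoid readouts
        gz_h = gh * h[t] * (1.0 - h[t])
        gz_v = gv * v[t] * (1.0 - v[t])
        gW_out[0] += gz_h @ r[t]
        gW_out[1] += gz_v @ r[t]
        dr = gz_h.reshape(B, 1) * w_h + gz_v.reshape(B, 1) * w_v \
            + dpre_next @ weights.W_rec
        dpre = dr * (1.0 - r[t] ** 2)
        gW_rec += dpre.T @ r[t - 1]
        gW_in += dpre.T @ I[t]
        if config.attention:
            # input at step t used U_{t-1}, D_{t-1} gated by h_{t-1}
            dI_U = dpre @ weights.W_in[:, 4]
            dI_D = dpre @ weights.W_in[:, 5]
            gh_gate_next = config.input_scale * (
                dI_U * (LU - RU) + dI_D * (LD - RD))
        else:
            gh_gate_next = np.zeros(B)
        dpre_next = dpre
    # h_0 receives gating gradient but r_0 is a constant zero state; W_out
    # still learns from it
    if config.attention:
        gz_h0 = gh_gate_next * h[0] * (1.0 - h[0])
        gW_out[0] += gz_h0 @ r[0]
    return RNNWeights(gW_rec, gW_in, gW_out)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, shapes, lr, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        out = []
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            out.append(p - self.lr * mhat / (np.sqrt(vhat) + self.eps))
        return out


def _clip(grads: RNNWeights, max_norm: float) -> RNNWeights:
    norm = np.sqrt(sum(np.sum(g ** 2) for g in
                       (grads.W_rec, grads.W_in, grads.W_out)))
    if norm > max_norm:
        s = max_norm / norm
        return RNNWeights(grads.W_rec * s, grads.W_in * s, grads.W_out * s)
    return grads


def train(
    config: RNNConfig,
    train_trials: pd.DataFrame,
    val_trials: Optional[pd.DataFrame] = None,
) -> tuple[RNNWeights, pd.DataFrame]:
    """Train a network on rnn-regime trials; reproducible from config.seed.

    Returns the best weights (lowest held-out loss when ``val_trials`` is
    given, else final) and a training log (epoch, train loss, val loss,
    val accuracy).
    """
    rng = np.random.default_rng(config.seed)
    weights = init_weights(config, rng)
    batch_all = build_inputs(train_trials, config)
    n = len(train_trials)
    val_batch = build_inputs(val_trials, config) if val_trials is not None else None

    adam = _Adam([weights.W_rec.shape, weights.W_in.shape, weights.W_out.shape],
                 config.learning_rate)
    log = []
    best = (np.inf, weights.copy(), 0)
    warm = max(1, int(config.sigma_warmup * config.epochs))
    for epoch in range(config.epochs):
        # noise curriculum: the switching penalty ramps in once the task
        # itself is partially learned, so high penalties suppress switching
        # instead of preventing learning altogether
        sigma_t = config.sigma_noise * min(1.0, (epoch + 1) / warm)
        order = rng.permutation(n)
        total = 0.0
        for i0 in range(0, n, config.batch_size):
            idx = order[i0:i0 + config.batch_size]
            sub = RNNTrialTensor(
                batch_all.arms[idx], batch_all.tm1[idx], batch_all.tm2[idx],
                batch_all.ts1[idx], batch_all.ts2[idx],
                batch_all.label_h[idx], batch_all.label_v[idx],
                batch_all.s1[idx], batch_all.s2[idx],
                batch_all.a1[:, idx], batch_all.a2[:, idx])
            fwd = forward(weights, sub, config, rng, sigma=sigma_t)
            if not np.isfinite(fwd.loss):
                raise FloatingPointError(
                    f"training diverged (loss={fwd.loss}) at epoch {epoch}")
            grads = _clip(backward(weights, sub, config, fwd), config.grad_clip)
            new = adam.step([weights.W_rec, weights.W_in, weights.W_out],
                            [grads.W_rec, grads.W_in, grads.W_out])
            weights = RNNWeights(*new)
            total += fwd.loss * len(idx)
        train_loss = total / n
        if val_batch is not None:
            # model selection on the noise-free task skeleton: with the
            # counterfactual noise active, held-out loss fluctuates with the
            # injected draws (and blows up on rare large deviates), turning
            # early stopping into a lottery that favours undertrained nets
            vfwd = forward(weights, val_batch, config,
                           np.random.default_rng([config.seed, epoch]),
                           noise_active=False)
            val_loss = vfwd.loss
            val_acc = _accuracy(vfwd, val_batch)
            if val_loss < best[0]:
                best = (val_loss, weights.copy(), epoch)
        else:
            val_loss, val_acc = np.nan, np.nan
        log.append({"epoch": epoch, "train_loss": train_loss,
                    "val_loss": val_loss, "val_accuracy": val_acc})
        if val_batch is not None and epoch - best[2] >= config.patience:
            break
    final = best[1] if val_batch is not None and np.isfinite(best[0]) else weights
    return final, pd.DataFrame(log)


def _choices(fwd: ForwardPass) -> np.ndarray:
    """Exit index per trial, binarizing (h, v) at the final timestep."""
    left = fwd.h[-1] > 0.5
    up = fwd.v[-1] > 0.5
    return np.where(left, 0, 2) + np.where(up, 0, 1)


def _accuracy(fwd: ForwardPass, batch: RNNTrialTensor) -> float:
    truth = np.where(batch.label_h > 0.5, 0, 2) + \
        np.where(batch.label_v > 0.5, 0, 1)
    return float(np.mean(_choices(fwd) == truth))


def evaluate_choices(
    weights: RNNWeights,
    trials: pd.DataFrame,
    config: RNNConfig,
    seed: int = 0,
) -> pd.DataFrame:
    """Trials plus the network's binarized exit choices and switch counts."""
    batch = build_inputs(trials, config)
    fwd = forward(weights, batch, config, np.random.default_rng([seed, 0xf0]))
    out = trials.copy().reset_index(drop=True)
    out["choice"] = [EXITS[i] for i in _choices(fwd)]
    out["n_switches"] = fwd.n_switches
    out["correct"] = out["choice"] == out["true_h"].str.cat(out["true_v"])
    return out


# ---------------------------------------------------------------------------
# behavioural analysis
# ---------------------------------------------------------------------------

def classify_strategy(
    choices: pd.DataFrame,
    w: float = 0.15,
    n_mc: int = 4000,
    seed: int = 0,
    counterfactual_alpha: float = 0.5,
) -> dict[str, float]:
    """Per-strategy mean NLL (nats/trial) of a set of exit choices.

    The parameter-free strategies are evaluated predictively; the
    counterfactual comparison fixes its recall noise to the network's
    switching-noise level (alpha = sigma_noise, beta = 0) and fits the
    revision threshold by maximum likelihood with twofold cross-validation.
    """
    from hmaze.fitting import ChoiceModelCache, stratified_folds
    from hmaze.strategies import StrategyParams

    cache = ChoiceModelCache(choices, w, n_mc, seed)
    n = len(choices)
    out = {s: cache.nll(s, None) / n
           for s in ("optimal", "hierarchical", "postdictive")}

    folds = stratified_folds(choices, 2, np.random.default_rng([seed, 2]))
    total = 0.0
    for f in range(2):
        train_m = folds != f
        xs = cache.X[np.unique(cache.trial_to_cond[train_m])]
        qs = np.quantile(xs, np.linspace(0.02, 0.98, 15))
        nlls = [cache.nll("counterfactual",
                          StrategyParams(t, counterfactual_alpha, 0.0),
                          train_m) for t in qs]
        theta = float(qs[int(np.argmin(nlls))])
        total += cache.nll("counterfactual",
                           StrategyParams(theta, counterfactual_alpha, 0.0),
                           ~train_m)
    out["counterfactual"] = total / n
    return out


def attention_switch_analysis(
    weights: RNNWeights,
    trials: pd.DataFrame,
    config: RNNConfig,
    seed: int = 0,
) -> pd.DataFrame:
    """Probability of at least one post-ramp attention switch per |L - R|
    stratum (first-choice difficulty)."""
    batch = build_inputs(trials, config)
    fwd = forward(weights, batch, config, np.random.default_rng([seed, 0xa5]))
    diff = np.abs(batch.arms[:, 0] - batch.arms[:, 1]).astype(int)
    rows = []
    for d in np.unique(diff):
        m = diff == d
        rows.append({"abs_LR_diff": int(d),
                     "p_switch": float(np.mean(fwd.n_switches[m] > 0)),
                     "n_trials": int(m.sum())})
    return pd.DataFrame(rows)


def strategy_vs_sigma_sweep(
    sigmas: Sequence[float],
    base_config: RNNConfig,
    train_trials: pd.DataFrame,
    test_trials: pd.DataFrame,
    n_mc: int = 3000,
    seed: int = 0,
) -> pd.DataFrame:
    """Retrain the all-constraints network at each counterfactual noise level
    and attribute its behaviour to a cognitive strategy."""
    rows = []
    for s in sigmas:
        cfg = dataclasses.replace(base_config, sigma_noise=float(s),
                                  counterfactual_noise=s > 0, attention=True,
                                  rationality=True)
        weights, _ = train(cfg, train_trials, test_trials)
        choices = evaluate_choices(weights, test_trials, cfg, seed=seed)
        nlls = classify_strategy(choices, w=base_config.w_noise, n_mc=n_mc,
                                 seed=seed)
        best = min(nlls, key=nlls.get)
        rows.append({"sigma_noise": float(s), "attribution": best, **nlls})
    return pd.DataFrame(rows)
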