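"""Recurrent networks task-optimized for the memory-guided saccade task.

A 50-unit network ``tau dx/dt = -x + W f(x) + B u(t) + noise`` receives a
condition-specific input channel during the cue period and must report the cue
through a linear readout. Four cost functions differ only in *when* stable
decoding is required:

- ``cue_delay``: from cue onset until the go cue,
- ``full_delay``: from cue offset until the go cue,
- ``after_go_time``: only during the response window after the go cue,
- ``just_in_time``: only during a short window immediately before the go cue.

All recurrent, input and readout weights are trained (backprop-through-time
in NumPy, Adam) with a penalty on the average squared firing rate over the
whole trial. The resulting networks differ sharply in dynamics — attractor-
like for cue-delay, sequential for after-go-time, and an amplifying-then-
persistent cross-over for just-in-time — which downstream overlap analyses
detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from infoload._rng import rng_from
from infoload.decode import TrialTensor
from infoload.errors import ConfigError, TrainingError

__all__ = ["TaskSpec", "TaskRNN", "make_task", "train_task_rnn", "run_trials"]

_COSTS = ("cue_delay", "full_delay", "after_go_time", "just_in_time")


@dataclass
class TaskSpec:
    """Timing and cost structure of the memory-guided saccade task.

    Time zero is cue onset; the go cue occurs at ``cue_duration + delay`` with
    the delay drawn per trial from ``delay_set``. The required-decoding
    interval is derived from ``cost_type``.
    """

    cost_type: str
    pre_cue: float = 0.5
    cue_duration: float = 0.5
    delay_set: tuple[float, ...] = (1.0, 1.375, 1.75)
    analysis_delay: float = 1.75
    response_duration: float = 0.2
    response_window: float = 0.2  # length of after-go / just-in-time boxcar
    n_conditions: int = 6

    def __post_init__(self) -> None:
        if self.cost_type not in _COSTS:
            raise ConfigError(f"cost_type must be one of {_COSTS}")
        for name in ("pre_cue", "cue_duration", "response_duration", "response_window"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if min(self.delay_set) <= 0:
            raise ConfigError("delays must be positive")
        if self.analysis_delay not in self.delay_set:
            raise ConfigError("analysis_delay must be a member of delay_set")
        for d in self.delay_set:
            lo, hi = self.required_interval(d)
            if hi <= lo or lo < -self.pre_cue or hi > self.trial_end(d):
                raise ConfigError(
                    f"required interval for delay {d} lies outside the trial "
                    "(go cue too early)")

    @property
    def cue_on(self) -> float:
        return 0.0

    @property
    def cue_off(self) -> float:
        return self.cue_duration

    def go_time(self, delay: float) -> float:
        return self.cue_duration + delay

    def trial_end(self, delay: float) -> float:
        return self.go_time(delay) + self.response_duration

    def required_interval(self, delay: float) -> tuple[float, float]:
        """Interval over which stable decoding is required, per cost type."""
        go = self.go_time(delay)
        if self.cost_type == "cue_delay":
            return (self.cue_on, go)
        if self.cost_type == "full_delay":
            return (self.cue_off, go)
        if self.cost_type == "after_go_time":
            return (go, go + self.response_window)
        return (go - self.response_window, go)  # just_in_time


def make_task(cost_type: str, **timing) -> TaskSpec:
    """Construct a TaskSpec for one of the four cost functions."""
    return TaskSpec(cost_type=cost_type, **timing)


@dataclass
class TaskRNN:
    """Trainable recurrent network for the saccade task."""

    weights: np.ndarray        # (N, N)
    input_map: np.ndarray      # (N, C)
    readout: np.ndarray        # (C, N)
    bias: np.ndarray           # (N,)
    readout_bias: np.ndarray   # (C,)
    tau: float = 0.2
    noise_sigma: float = 0.05
    nonlinearity: str = "tanh"

    def __post_init__(self) -> None:
        for arr in (self.weights, self.input_map, self.readout, self.bias,
                    self.readout_bias):
            if not np.all(np.isfinite(arr)):
                raise ConfigError("parameters must be finite")
        if self.nonlinearity != "tanh":
            raise ConfigError("only tanh nonlinearity is implemented")

    @property
    def n_neurons(self) -> int:
        return self.weights.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.input_map.shape[1]

    @classmethod
    def random(cls, n_neurons: int = 50, n_conditions: int = 6, gain: float = 0.9,
               tau: float = 0.2, noise_sigma: float = 0.05,
               seed: int | None = None) -> "TaskRNN":
        rng = rng_from(seed, "taskrnn_init")
        W = rng.normal(0.0, gain / np.sqrt(n_neurons), (n_neurons, n_neurons))
        B = rng.normal(0.0, 1.0 / np.sqrt(n_neurons), (n_neurons, n_conditions))
        C = rng.normal(0.0, 1.0 / np.sqrt(n_neurons), (n_conditions, n_neurons))
        return cls(W, B, C, np.zeros(n_neurons), np.zeros(n_conditions),
                   tau=tau, noise_sigma=noise_sigma)


def _unroll_spec(task: TaskSpec, delay: float, dt: float):
    """Bin-resolved layout of one trial: (n_steps, cue mask, required mask, time)."""
    t0 = -task.pre_cue
    t_end = task.trial_end(delay)
    n_steps = int(round((t_end - t0) / dt))
    time = t0 + dt * (np.arange(n_steps + 1))
    cue_mask = (time >= 0.0) & (time < task.cue_off)
    lo, hi = task.required_interval(delay)
    req_mask = (time >= lo - 1e-9) & (time <= hi + 1e-9)
    return n_steps, cue_mask, req_mask, time


def _forward_rnn(params, u_onehot, cue_mask, alpha, sigma_dt, n_steps, rng):
    """Unroll; u_onehot (batch, C) applied through input_map during the cue."""
    W, B, b = params["W"], params["B"], params["b"]
    batch = u_onehot.shape[0]
    N = W.shape[0]
    x = np.zeros((batch, N))
    rs = np.empty((n_steps + 1, batch, N))
    rs[0] = np.tanh(x)
    inp = u_onehot @ B.T
    for t in range(n_steps):
        drive = inp if cue_mask[t] else 0.0
        x = x + alpha * (-x + rs[t] @ W.T + drive + b)
        if sigma_dt > 0:
            x += sigma_dt * rng.standard_normal(x.shape)
        rs[t + 1] = np.tanh(x)
    return rs


def train_task_rnn(
    rnn: TaskRNN,
    task: TaskSpec,
    iters: int = 3000,
    rate_penalty: float = 0.01,
    batch: int = 48,
    lr: float = 3e-3,
    dt: float | None = None,
    seed: int | None = None,
) -> tuple[TaskRNN, "np.ndarray"]:
    """Train all weights on the task's cost function.

    Loss per iteration = softmax cross-entropy of the readout against the
    condition label, averaged over every time bin inside the required
    interval (delays sampled per trial from ``delay_set``), plus
    ``rate_penalty`` times the mean squared firing rate over the whole trial.
    Returns the trained network and the loss history.
    """
    if rate_penalty < 0:
        raise ConfigError("rate_penalty must be >= 0")
    dt = rnn.tau / 10.0 if dt is None else dt
    alpha = dt / rnn.tau
    sigma_dt = rnn.noise_sigma * np.sqrt(dt)
    C = rnn.n_conditions
    params = {"W": rnn.weights.copy(), "B": rnn.input_map.copy(),
              "C": rnn.readout.copy(), "b": rnn.bias.copy(),
              "c": rnn.readout_bias.copy()}
    from infoload.attractor import _Adam

    opt = _Adam({k: v.shape for k, v in params.items()}, lr)
    history = np.empty(iters)
    delays = np.asarray(task.delay_set)

    for it in range(iters):
        rng = rng_from(seed, "train", it)
        labels = rng.integers(0, C, size=batch)
        trial_delays = delays[rng.integers(0, len(delays), size=batch)]
        loss_acc = 0.0
        grads = {k: np.zeros_like(v) for k, v in params.items()}
        n_groups = 0
        for d in np.unique(trial_delays):
            sel = trial_delays == d
            frac = sel.mean()
            lab = labels[sel]
            onehot = np.eye(C)[lab]
            n_steps, cue_mask, req_mask, _ = _unroll_spec(task, float(d), dt)
            rs = _forward_rnn(params, onehot, cue_mask, alpha, sigma_dt,
                              n_steps, rng)
            loss, g = _loss_and_grads(params, rs, onehot, lab, cue_mask,
                                      req_mask, alpha, rate_penalty)
            loss_acc += frac * loss
            for k in grads:
                grads[k] += frac * g[k]
            n_groups += 1
        if not np.isfinite(loss_acc):
            raise TrainingError(f"non-finite loss at iteration {it}")
        history[it] = loss_acc
        opt.step(params, grads)

    trained = replace(rnn, weights=params["W"], input_map=params["B"],
                      readout=params["C"], bias=params["b"],
                      readout_bias=params["c"])
    return trained, history


def _loss_and_grads(params, rs, onehot, labels, cue_mask, req_mask, alpha, lam):
    """Cross-entropy over required bins + rate penalty; full BPTT gradients."""
    W, B, Cw, c = params["W"], params["B"], params["C"], params["c"]
    n_steps_p1, batch, N = rs.shape
    req_idx = np.where(req_mask)[0]
    n_req = len(req_idx)
    # per-bin readout terms
    ce = 0.0
    dlogit_at = {}
    for t in req_idx:
        logits = rs[t] @ Cw.T + c
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=1, keepdims=True)
        ce += -np.mean(np.log(p[np.arange(batch), labels] + 1e-12))
        dlogit_at[t] = (p - onehot) / (batch * n_req)
    ce /= n_req
    pen = lam * float(np.mean(rs**2))
    loss = ce + pen

    gC = np.zeros_like(Cw)
    gc = np.zeros_like(c)
    gW = np.zeros_like(W)
    gB = np.zeros_like(B)
    gb = np.zeros_like(params["b"])
    pen_scale = 2.0 * lam / rs.size
    delta = np.zeros((batch, N))
    for t in range(n_steps_p1 - 1, -1, -1):
        r = rs[t]
        inject = pen_scale * r * (1.0 - r**2)
        if t in dlogit_at:
            dl = dlogit_at[t]
            gC += dl.T @ r
            gc += dl.sum(axis=0)
            inject = inject + (dl @ Cw) * (1.0 - r**2)
        delta = delta + inject
        if t > 0:
            # accumulate param grads for the step t-1 -> t
            gW += alpha * (delta.T @ rs[t - 1])
            gb += alpha * delta.sum(axis=0)
            if cue_mask[t - 1]:
                gB += alpha * (delta.T @ onehot)
            delta = (1.0 - alpha) * delta + alpha * ((delta @ W) * (1.0 - rs[t - 1]**2))
    return loss, {"W": gW, "B": gB, "C": gC, "b": gb, "c": gc}


def run_trials(
    rnn: TaskRNN,
    task: TaskSpec,
    n_trials_per_cond: int = 20,
    delay: float | None = None,
    dt_bin: float = 0.05,
    seed: int | None = None,
) -> TrialTensor:
    """Simulate noisy trials at a fixed delay and bin the firing rates.

    Rates (f(x)) are averaged within ``dt_bin`` bins; the output TrialTensor
    carries per-trial cue and go event times, with time 0 at cue onset.
    """
    delay = task.analysis_delay if delay is None else delay
    if delay not in task.delay_set:
        raise ConfigError("delay must be a member of task.delay_set")
    dt = rnn.tau / 10.0
    stride = max(1, int(round(dt_bin / dt)))
    dt = dt_bin / stride
    alpha = dt / rnn.tau
    sigma_dt = rnn.noise_sigma * np.sqrt(dt)
    C = rnn.n_conditions
    labels = np.repeat(np.arange(C), n_trials_per_cond)
    onehot = np.eye(C)[labels]
    n_steps, cue_mask, _, time = _unroll_spec(task, delay, dt)
    rng = rng_from(seed, "run_trials")
    params = {"W": rnn.weights, "B": rnn.input_map, "b": rnn.bias}
    rs = _forward_rnn(params, onehot, cue_mask, alpha, sigma_dt, n_steps, rng)
    n_bins = (n_steps + 1) // stride
    rates = rs[:n_bins * stride].reshape(n_bins, stride, len(labels), rnn.n_neurons)
    rates = rates.mean(axis=1).transpose(1, 2, 0)
    bin_time = time[:n_bins * stride].reshape(n_bins, stride).mean(axis=1)
    n_tr = len(labels)
    events = {"cue_on": np.zeros(n_tr), "cue_off": np.full(n_tr, task.cue_off),
              "go": np.full(n_tr, task.go_time(delay))}
    return TrialTensor(rates, labels, bin_time, dt=dt_bin, events=events,
                       n_conditions=C)
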