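"""Nonlinear attractor networks with jointly optimized information loading.

Networks obey the rate equation ``tau dx/dt = -x + W f(x) + b + noise`` with
``f = tanh``, and store one attractor per cue condition. Both the recurrent
weights and the per-condition initial activities ``X0`` (the state in which
the cue leaves the network at the start of the delay) are optimized for cue
decodability at the end of the delay, under a hard norm bound on ``X0``.
Training runs backprop-through-time on the Euler-unrolled dynamics with an
Adam optimizer, implemented directly in NumPy.

Loading can be restricted to the *persistent subspace* (the span of the
mean-centered attractor states) or its orthogonal complement (the *persistent
nullspace*): symmetric networks need subspace loading (pattern completion),
whereas unconstrained networks perform better when loading in the nullspace —
the double dissociation that motivates optimal-information-loading theory.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from infoload._rng import derive_seed, rng_from
from infoload.decode import TrialTensor
from infoload.errors import ConfigError, TrainingError

__all__ = [
    "AttractorNet", "optimize_information_loading", "attractor_states",
    "persistent_subspace_projector", "init_final_correlation",
    "run_attractor_trials", "evaluate_readout_accuracy",
]


@dataclass
class AttractorNet:
    """Nonlinear attractor network with per-condition optimized initial states."""

    weights: np.ndarray          # (N, N)
    bias: np.ndarray             # (N,)
    init_states: np.ndarray      # (C, N)
    readout_weights: np.ndarray  # (C, N)
    readout_bias: np.ndarray     # (C,)
    tau: float = 1.0
    noise_sigma: float = 0.1
    kind: str = "unconstrained"
    nonlinearity: str = "tanh"
    init_bound: float | None = None  # R: max norm of an X0 row

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        N = self.weights.shape[0]
        if self.kind == "symmetric":
            self.weights = (self.weights + self.weights.T) / 2.0
        if self.nonlinearity != "tanh":
            raise ConfigError("only tanh nonlinearity is implemented")
        if self.init_bound is None:
            self.init_bound = 0.5 * np.sqrt(N)

    @property
    def n_neurons(self) -> int:
        return self.weights.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.init_states.shape[0]

    @classmethod
    def random(
        cls,
        n_neurons: int = 50,
        n_conditions: int = 6,
        kind: str = "unconstrained",
        gain: float = 1.2,
        tau: float = 1.0,
        noise_sigma: float = 0.1,
        init_bound: float | None = None,
        seed: int | None = None,
    ) -> "AttractorNet":
        rng = rng_from(seed, "attractor_init")
        W = rng.normal(0.0, gain / np.sqrt(n_neurons), (n_neurons, n_neurons))
        if kind == "symmetric":
            W = (W + W.T) / np.sqrt(2.0)
        R = 0.5 * np.sqrt(n_neurons) if init_bound is None else init_bound
        X0 = rng.standard_normal((n_conditions, n_neurons))
        X0 *= R / np.linalg.norm(X0, axis=1, keepdims=True)
        Rw = rng.normal(0.0, 1.0 / np.sqrt(n_neurons), (n_conditions, n_neurons))
        return cls(W, np.zeros(n_neurons), X0, Rw, np.zeros(n_conditions),
                   tau=tau, noise_sigma=noise_sigma, kind=kind, init_bound=R)


def _project_init_states(X0, R, projector):
    if projector is not None:
        X0 = X0 @ projector.T
    norms = np.linalg.norm(X0, axis=1, keepdims=True)
    scale = np.minimum(1.0, R / np.maximum(norms, 1e-12))
    return X0 * scale


def _forward(W, b, X0_batch, alpha, sigma_dt, n_steps, rng):
    """Euler unroll; returns stacked rates r_t for t=0..n_steps (list of arrays)."""
    x = X0_batch.copy()
    rs = np.empty((n_steps + 1,) + x.shape)
    rs[0] = np.tanh(x)
    for t in range(n_steps):
        r = rs[t]
        x = x + alpha * (-x + r @ W.T + b)
        if sigma_dt > 0:
            x += sigma_dt * rng.standard_normal(x.shape)
        rs[t + 1] = np.tanh(x)
    return x, rs


class _Adam:
    def __init__(self, shapes, lr):
        self.lr = lr
        self.m = {k: np.zeros(s) for k, s in shapes.items()}
        self.v = {k: np.zeros(s) for k, s in shapes.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] = params[k] - self.lr * mhat / (np.sqrt(vhat) + eps)
        return params


def optimize_information_loading(
    net: AttractorNet,
    delay_T: float | tuple[float, float] = 3.0,
    constraint: str = "free",
    R: float | None = None,
    n_train_trials: int = 16,
    iters: int = 2000,
    seed: int | None = None,
    projector: np.ndarray | None = None,
    lr: float = 5e-3,
    dt: float | None = None,
    train_weights: bool | None = None,
) -> tuple[AttractorNet, np.ndarray]:
    """Optimize initial activities (and weights) for end-of-delay decodability.

    Minimizes softmax cross-entropy between the linear readout of the firing
    rates at the end of the delay (averaged over ``n_train_trials`` noisy
    rollouts per condition per step) and the condition labels. After every
    Adam step the ``X0`` rows are projected into the designated subspace
    (for the restricted constraints) and renormalized to norm <= R.

    ``delay_T`` may be a (lo, hi) pair, in which case the delay is drawn
    uniformly per iteration — decodability must then hold at any readout time
    in the range, which drives the states into genuinely stable attractors
    rather than slowly drifting end-of-delay configurations.

    ``constraint``: "free", "persistent_subspace" or "persistent_nullspace";
    the restricted modes require ``projector`` (from
    :func:`persistent_subspace_projector`, complement projector for the
    nullspace) and freeze the recurrent weights by default (two-phase
    protocol: free training defines the attractors, then only the loading is
    re-optimized relative to them).

    Returns the trained network and the loss history.
    """
    if constraint not in ("free", "persistent_subspace", "persistent_nullspace"):
        raise ConfigError(f"unknown constraint {constraint!r}")
    if constraint != "free" and projector is None:
        raise ConfigError("restricted constraints require a projector")
    if train_weights is None:
        train_weights = constraint == "free"
    R = net.init_bound if R is None else R
    dt = net.tau / 20.0 if dt is None else dt
    alpha = dt / net.tau
    delay_range = delay_T if np.ndim(delay_T) else (delay_T, delay_T)
    sigma_dt = net.noise_sigma * np.sqrt(dt)
    N, C = net.n_neurons, net.n_conditions

    params = {
        "W": net.weights.copy(), "b": net.bias.copy(),
        "X0": _project_init_states(net.init_states.copy(), R, projector),
        "Rw": net.readout_weights.copy(), "Rb": net.readout_bias.copy(),
    }
    trained_keys = (["W", "b"] if train_weights else []) + ["X0", "Rw", "Rb"]
    opt = _Adam({k: params[k].shape for k in trained_keys}, lr)
    labels = np.repeat(np.arange(C), n_train_trials)
    onehot = np.eye(C)[labels]
    batch = C * n_train_trials
    history = np.empty(iters)

    for it in range(iters):
        rng = rng_from(seed, "opt", it)
        n_steps = int(round(rng.uniform(*delay_range) / dt))
        W, b = params["W"], params["b"]
        X0_batch = np.repeat(params["X0"], n_train_trials, axis=0)
        x, rs = _forward(W, b, X0_batch, alpha, sigma_dt, n_steps, rng)
        rT = rs[-1]
        logits = rT @ params["Rw"].T + params["Rb"]
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=1, keepdims=True)
        loss = -np.mean(np.log(p[np.arange(batch), labels] + 1e-12))
        if not np.isfinite(loss):
            raise TrainingError(f"non-finite loss at iteration {it}")
        history[it] = loss

        dlogits = (p - onehot) / batch
        grads = {"Rw": dlogits.T @ rT, "Rb": dlogits.sum(axis=0)}
        delta = (dlogits @ params["Rw"]) * (1.0 - rT**2)
        gW = np.zeros_like(W)
        gb = np.zeros_like(b)
        for t in range(n_steps - 1, -1, -1):
            r = rs[t]
            if train_weights:
                gW += alpha * (delta.T @ r)
                gb += alpha * delta.sum(axis=0)
            delta = (1.0 - alpha) * delta + alpha * ((delta @ W) * (1.0 - r**2))
        grads["X0"] = np.add.reduceat(delta, np.arange(0, batch, n_train_trials))
        if train_weights:
            if net.kind == "symmetric":
                gW = (gW + gW.T) / 2.0
            grads["W"] = gW
            grads["b"] = gb
        opt.step(params, {k: grads[k] for k in trained_keys})
        if net.kind == "symmetric":
            params["W"] = (params["W"] + params["W"].T) / 2.0
        params["X0"] = _project_init_states(params["X0"], R, projector)

    trained = replace(
        net, weights=params["W"], bias=params["b"], init_states=params["X0"],
        readout_weights=params["Rw"], readout_bias=params["Rb"], init_bound=R)
    return trained, history


def evaluate_readout_accuracy(
    net: AttractorNet,
    delay_T: float = 3.0,
    n_trials: int = 100,
    seed: int | None = None,
    dt: float | None = None,
) -> float:
    """End-of-delay classification accuracy of the network's own readout."""
    dt = net.tau / 20.0 if dt is None else dt
    alpha = dt / net.tau
    n_steps = int(round(delay_T / dt))
    sigma_dt = net.noise_sigma * np.sqrt(dt)
    C = net.n_conditions
    labels = np.repeat(np.arange(C), n_trials)
    X0 = np.repeat(net.init_states, n_trials, axis=0)
    rng = rng_from(seed, "eval")
    _, rs = _forward(net.weights, net.bias, X0, alpha, sigma_dt, n_steps, rng)
    logits = rs[-1] @ net.readout_weights.T + net.readout_bias
    return float(np.mean(np.argmax(logits, axis=1) == labels))


def attractor_states(
    net: AttractorNet,
    settle_T: float | None = None,
    dt: float | None = None,
    newton_iters: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """Stable fixed points reached from each optimized initial condition.

    Runs the noiseless dynamics from every ``X0`` row for ``settle_T``
    (default 20 tau), then polishes each endpoint with Newton iterations on
    ``F(x) = -x + W tanh(x) + b``. Returns ``(states, settled)`` where
    ``settled[c]`` is False when the fixed-point residual still exceeds
    ``1e-6 * ||x||`` (flagged, not raised).
    """
    settle_T = 20.0 * net.tau if settle_T is None else settle_T
    dt = net.tau / 20.0 if dt is None else dt
    alpha = dt / net.tau
    n_steps = int(round(settle_T / dt))
    x = net.init_states.copy()
    for _ in range(n_steps):
        x = x + alpha * (-x + np.tanh(x) @ net.weights.T + net.bias)
    W, b = net.weights, net.bias
    N = net.n_neurons
    settled = np.ones(net.n_conditions, dtype=bool)
    for c in range(net.n_conditions):
        xc = x[c]
        for _ in range(newton_iters):
            r = np.tanh(xc)
            F = -xc + W @ r + b
            if np.linalg.norm(F) <= 1e-9 * max(1.0, np.linalg.norm(xc)):
                break
            J = -np.eye(N) + W * (1.0 - r**2)[None, :]
            try:
                step = np.linalg.solve(J, -F)
            except np.linalg.LinAlgError:
                break
            xc = xc + step
        x[c] = xc
        r = np.tanh(xc)
        resid = np.linalg.norm(-xc + W @ r + b)
        settled[c] = resid <= 1e-6 * max(1e-12, np.linalg.norm(xc))
    return x, settled


def persistent_subspace_projector(
    attractors: np.ndarray, sv_tol: float = 1e-6
) -> tuple[np.ndarray, np.ndarray, int]:
    """Orthogonal projector onto the span of the mean-centered attractors.

    Returns ``(P, P_null, rank)`` where ``P`` projects onto the persistent
    subspace (row space of the mean-centered attractor matrix at relative
    singular-value tolerance ``sv_tol``) and ``P_null = I - P`` onto the
    persistent nullspace. For C generic attractor states the rank is C - 1.
    """
    X = np.asarray(attractors, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ConfigError("need at least 2 attractor states")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    if s.size == 0 or s[0] == 0:
        raise ConfigError("all attractor states identical: rank-0 subspace")
    rank = int(np.sum(s > sv_tol * s[0]))
    if rank == 0:
        raise ConfigError("all attractor states identical: rank-0 subspace")
    Vr = Vt[:rank]
    P = Vr.T @ Vr
    return P, np.eye(X.shape[1]) - P, rank


def run_attractor_trials(
    net: AttractorNet,
    delay_T: float = 3.0,
    n_trials_per_cond: int = 20,
    dt_bin: float | None = None,
    seed: int | None = None,
    noise_sigma: float | None = None,
) -> TrialTensor:
    """Simulate noisy delay-period trials; rates are f(x) binned at dt_bin.

    ``noise_sigma`` overrides the network's training noise for evaluation.
    """
    dt = net.tau / 20.0
    dt_bin = 2 * dt if dt_bin is None else dt_bin
    stride = max(1, int(round(dt_bin / dt)))
    alpha = dt / net.tau
    n_steps = int(round(delay_T / dt))
    sigma = net.noise_sigma if noise_sigma is None else noise_sigma
    sigma_dt = sigma * np.sqrt(dt)
    C = net.n_conditions
    labels = np.repeat(np.arange(C), n_trials_per_cond)
    X0 = np.repeat(net.init_states, n_trials_per_cond, axis=0)
    rng = rng_from(seed, "trials")
    _, rs = _forward(net.weights, net.bias, X0, alpha, sigma_dt, n_steps, rng)
    rates = rs[::stride].transpose(1, 2, 0)  # (trials, N, bins)
    n_bins = rates.shape[2]
    time = np.arange(n_bins) * (stride * dt)
    n_tr = len(labels)
    events = {"cue_on": np.full(n_tr, 0.0), "cue_off": np.full(n_tr, 0.0),
              "go": np.full(n_tr, delay_T)}
    return TrialTensor(rates, labels, time, dt=stride * dt, events=events,
                       n_conditions=C)


def init_final_correlation(trials: TrialTensor) -> np.ndarray:
    """Pearson correlation between initial and final mean-centered rates.

    At the first and last time bins, the condition-independent mean (over all
    trials) is subtracted; the per-condition trial-mean patterns are then
    correlated across neurons. Returns one r per condition; NaN marks
    conditions where either pattern has zero variance.
    """
    C = trials.n_conditions
    if C < 2:
        raise ConfigError("need at least 2 conditions")
    out = np.empty(C)
    first = trials.rates[:, :, 0]
    last = trials.rates[:, :, -1]
    first = first - first.mean(axis=0)
    last = last - last.mean(axis=0)
    for c in range(C):
        sel = trials.labels == c
        a = first[sel].mean(axis=0)
        b = last[sel].mean(axis=0)
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            out[c] = np.nan
        else:
            out[c] = float(np.corrcoef(a, b)[0, 1])
    return out
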