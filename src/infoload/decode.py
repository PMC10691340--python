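"""Template-based population decoding of cue identity.

Decoders are nearest-class-centroid classifiers on mean-centered firing rates
("templates" of activity at the training time), the standard analysis applied
to prefrontal recordings in delayed-response tasks. A *delay-trained* decoder
is fit on a late-delay window and tested at every time bin; the full
cross-temporal matrix trains at every bin and tests at every other bin. Poor
early-to-late generalization despite high same-time decodability is the
"dynamic coding" phenomenon these analyses quantify.

All centering uses the training folds' condition-independent mean only, so no
information leaks from held-out trials. A regularized multinomial (logistic)
decoder is available behind ``decoder="logistic"`` as a robustness check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from infoload._rng import derive_seed, rng_from
from infoload.errors import CalibrationError, ConfigError

__all__ = [
    "TrialTensor", "DecodingMatrix", "delay_decoder_timecourse",
    "cross_temporal_matrix", "match_performance_noise", "simulate_loading_trials",
]


@dataclass
class TrialTensor:
    """Trial-resolved population activity.

    rates : (n_trials, n_neurons, n_bins) firing rates.
    labels : (n_trials,) condition labels in 0..C-1 covering every condition.
    time : (n_bins,) seconds relative to cue onset, uniform spacing.
    events : per-trial event times, keys "cue_on", "cue_off", "go".
    """

    rates: np.ndarray
    labels: np.ndarray
    time: np.ndarray
    dt: float
    events: dict = field(default_factory=dict)
    n_conditions: int | None = None

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.time = np.asarray(self.time, dtype=float)
        if self.rates.ndim != 3:
            raise ConfigError("rates must be (n_trials, n_neurons, n_bins)")
        if len(self.labels) != self.rates.shape[0]:
            raise ConfigError("labels length must match n_trials")
        if len(self.time) != self.rates.shape[2]:
            raise ConfigError("time length must match n_bins")
        d = np.diff(self.time)
        if len(d) and (np.any(d <= 0) or not np.allclose(d, self.dt, rtol=1e-6, atol=1e-9)):
            raise ConfigError("time must increase uniformly with step dt")
        if self.n_conditions is None:
            self.n_conditions = int(self.labels.max()) + 1
        present = np.unique(self.labels)
        if not np.array_equal(present, np.arange(self.n_conditions)):
            raise ConfigError("labels must cover all conditions 0..C-1")

    @property
    def n_trials(self) -> int:
        return self.rates.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.rates.shape[1]

    @property
    def n_bins(self) -> int:
        return self.rates.shape[2]

    @property
    def chance(self) -> float:
        return 1.0 / self.n_conditions


@dataclass
class DecodingMatrix:
    """Cross-temporal decoding accuracies, train bin (rows) x test bin (cols)."""

    accuracy: np.ndarray
    time: np.ndarray
    cv_folds: int
    chance: float

    def __post_init__(self) -> None:
        if np.nanmin(self.accuracy) < 0 or np.nanmax(self.accuracy) > 1:
            raise ConfigError("accuracies must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        B = len(self.time)
        for i in range(B):
            for j in range(B):
                rows.append((self.time[i], self.time[j], self.accuracy[i, j]))
        return pd.DataFrame(rows, columns=["train_bin", "test_bin", "accuracy"])


def _window_bins(time: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    t0, t1 = window
    mask = (time >= t0) & (time <= t1)
    if not mask.any():
        raise ConfigError(f"train window {window} lies outside the data time range")
    return mask


def _folds(labels: np.ndarray, cv_folds: int, seed: int | None):
    counts = np.bincount(labels)
    if counts.min() < 2 * cv_folds:
        raise ConfigError("need at least 2 trials per condition per fold")
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True,
                          random_state=None if seed is None else derive_seed(seed, "folds"))
    return skf.split(np.zeros(len(labels)), labels)


def _centroid_predict(train_X, train_y, test_X, C):
    """Nearest-centroid prediction; X arrays are (n, N)."""
    templates = np.stack([train_X[train_y == c].mean(axis=0) for c in range(C)])
    d = ((test_X[:, None, :] - templates[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d, axis=1)


def delay_decoder_timecourse(
    trials: TrialTensor,
    train_window: tuple[float, float],
    cv_folds: int = 5,
    seed: int | None = None,
    decoder: str = "centroid",
) -> tuple[np.ndarray, np.ndarray]:
    """Accuracy over time of a decoder trained on a fixed time window.

    Rates are averaged over ``train_window`` to build per-condition templates
    on the training folds (after removing the training folds' condition-
    independent mean), then the decoder is applied at every bin of the
    held-out folds. Returns ``(accuracy(t), fold_accuracies)`` where the
    second array has shape (cv_folds, n_bins).
    """
    win = _window_bins(trials.time, train_window)
    C = trials.n_conditions
    fold_acc = []
    for tr_idx, te_idx in _folds(trials.labels, cv_folds, seed):
        mu = trials.rates[tr_idx].mean(axis=0)  # (N, B) condition-independent mean
        Xtr = trials.rates[tr_idx] - mu
        Xte = trials.rates[te_idx] - mu
        ytr, yte = trials.labels[tr_idx], trials.labels[te_idx]
        train_feat = Xtr[:, :, win].mean(axis=2)
        acc_t = np.empty(trials.n_bins)
        if decoder == "centroid":
            templates = np.stack([train_feat[ytr == c].mean(axis=0) for c in range(C)])
            for b in range(trials.n_bins):
                d = ((Xte[:, :, b][:, None, :] - templates[None]) ** 2).sum(axis=2)
                acc_t[b] = np.mean(np.argmin(d, axis=1) == yte)
        elif decoder == "logistic":
            clf = LogisticRegression(C=1.0, max_iter=2000)
            clf.fit(train_feat, ytr)
            for b in range(trials.n_bins):
                acc_t[b] = np.mean(clf.predict(Xte[:, :, b]) == yte)
        else:
            raise ConfigError(f"unknown decoder {decoder!r}")
        fold_acc.append(acc_t)
    fold_acc = np.stack(fold_acc)
    return fold_acc.mean(axis=0), fold_acc


def cross_temporal_matrix(
    trials: TrialTensor,
    cv_folds: int = 5,
    seed: int | None = None,
) -> DecodingMatrix:
    """Full train-time x test-time decoding accuracy matrix."""
    C = trials.n_conditions
    B = trials.n_bins
    acc = np.zeros((B, B))
    n_folds = 0
    for tr_idx, te_idx in _folds(trials.labels, cv_folds, seed):
        mu = trials.rates[tr_idx].mean(axis=0)
        Xtr = trials.rates[tr_idx] - mu
        Xte = trials.rates[te_idx] - mu
        ytr, yte = trials.labels[tr_idx], trials.labels[te_idx]
        # templates per condition per train bin: (C, N, B)
        templ = np.stack([Xtr[ytr == c].mean(axis=0) for c in range(C)])
        # squared distances: test trial i at bin b2 vs condition c template at bin b1
        te2 = np.einsum("inb,inb->ib", Xte, Xte)           # (n_te, B)
        tp2 = np.einsum("cnb,cnb->cb", templ, templ)       # (C, B)
        cross = np.einsum("inb,cnB->icBb", Xte, templ)     # (n_te, C, B_train, B_test)
        d2 = te2[:, None, None, :] - 2.0 * cross + tp2[None, :, :, None]
        pred = np.argmin(d2, axis=1)                       # (n_te, B_train, B_test)
        acc += (pred == yte[:, None, None]).mean(axis=0)
        n_folds += 1
    return DecodingMatrix(acc / n_folds, time=trials.time, cv_folds=n_folds,
                          chance=trials.chance)


def simulate_loading_trials(
    net,
    loading: np.ndarray,
    T: float,
    dt_bin: float = 0.05,
    n_trials_per_cond: int = 50,
    sigma: float | None = None,
    cue_duration: float = 0.0,
    input_strength: float = 1.0,
    seed: int | None = None,
) -> TrialTensor:
    """Simulate noisy trials of a linear network under per-condition loading.

    ``loading`` is (C, N): with ``cue_duration == 0`` each row is used as the
    initial condition at t=0; otherwise it is applied as a constant input over
    the cue period [0, cue_duration] starting from rest. State noise uses the
    network's sigma unless overridden. Rates are the raw states sampled at
    ``dt_bin``.
    """
    from infoload.linear import simulate

    loading = np.atleast_2d(np.asarray(loading, dtype=float))
    C, N = loading.shape
    if N != net.n_neurons:
        raise ConfigError("loading dimension does not match network size")
    sig = net.noise_sigma if sigma is None else sigma
    net_run = type(net)(net.weights, tau=net.tau, noise_sigma=sig, kind=net.kind,
                        persistent_vector=net.persistent_vector)
    dt_sim = net.tau / 50.0
    stride = max(1, int(round(dt_bin / dt_sim)))
    dt_sim = dt_bin / stride
    all_rates, labels = [], []
    from infoload.linear import PiecewiseConstantInput
    for c in range(C):
        if cue_duration > 0:
            inp = PiecewiseConstantInput([0.0, cue_duration],
                                         [input_strength * loading[c]])
            out = simulate(net_run, input_fn=inp, T=T, dt=dt_sim,
                           n_trials=n_trials_per_cond,
                           seed=None if seed is None else derive_seed(seed, "cond", c))
        else:
            out = simulate(net_run, x0=input_strength * loading[c], T=T, dt=dt_sim,
                           n_trials=n_trials_per_cond,
                           seed=None if seed is None else derive_seed(seed, "cond", c))
        if not isinstance(out, np.ndarray):  # single Trajectory
            out = out.states[None]
        all_rates.append(out[:, ::stride, :].transpose(0, 2, 1))
        labels.extend([c] * n_trials_per_cond)
    rates = np.concatenate(all_rates, axis=0)
    n_bins = rates.shape[2]
    time = np.arange(n_bins) * dt_bin
    n_tr = rates.shape[0]
    events = {"cue_on": np.zeros(n_tr), "cue_off": np.full(n_tr, cue_duration),
              "go": np.full(n_tr, T)}
    return TrialTensor(rates, np.array(labels), time, dt=dt_bin, events=events,
                       n_conditions=C)


def match_performance_noise(
    net,
    loading: np.ndarray,
    target_accuracy: float,
    tol: float = 0.02,
    seed: int | None = None,
    T: float = 10.0,
    n_trials: int = 600,
    cue_duration: float = 0.0,
    input_strength: float = 1.0,
    sigma_max: float = 2.0,
    max_iter: int = 30,
) -> float:
    """Noise level at which end-of-delay decoding hits a target accuracy.

    Bisection on the state-noise sigma: each evaluation simulates fresh noisy
    trials with the given loading, runs the delay-trained (end-of-delay)
    decoder, and compares the mean accuracy over the final 10% of the delay
    against ``target_accuracy``. Used to performance-match persistent/random
    loading against the most-amplifying reference before comparing dynamics.
    """
    C = np.atleast_2d(loading).shape[0]
    if not 1.0 / C < target_accuracy <= 1.0:
        raise ConfigError("target accuracy must lie in (chance, 1]")
    per_cond = max(2, int(round(n_trials / C)))
    window = (0.9 * T, T)

    def evaluate(sigma: float, tag: int) -> float:
        tt = simulate_loading_trials(
            net, loading, T=T, n_trials_per_cond=per_cond, sigma=sigma,
            cue_duration=cue_duration, input_strength=input_strength,
            seed=None if seed is None else derive_seed(seed, "calib", tag))
        acc_t, _ = delay_decoder_timecourse(
            tt, window, cv_folds=2,
            seed=None if seed is None else derive_seed(seed, "calibdec", tag))
        mask = (tt.time >= window[0]) & (tt.time <= window[1])
        return float(acc_t[mask].mean())

    acc0 = evaluate(0.0, 0)
    if acc0 < target_accuracy - tol:
        raise CalibrationError(
            f"target {target_accuracy} unreachable: noiseless accuracy {acc0:.3f}")
    if abs(acc0 - target_accuracy) <= tol:
        return 0.0
    lo, hi = 0.0, sigma_max
    acc_hi = evaluate(hi, 1)
    tries = 0
    while acc_hi > target_accuracy and tries < 5:
        hi *= 2.0
        tries += 1
        acc_hi = evaluate(hi, 1 + tries)
    for it in range(max_iter):
        mid = 0.5 * (lo + hi)
        acc = evaluate(mid, 100 + it)
        if abs(acc - target_accuracy) <= tol:
            return mid
        if acc > target_accuracy:
            lo = mid
        else:
            hi = mid
    raise CalibrationError(
        f"bisection did not converge to |accuracy - {target_accuracy}| <= {tol}")
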