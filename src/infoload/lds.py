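"""Low-dimensional linear dynamical system fits to population activity.

Recorded (or simulated) trial data are reduced with PCA to D dimensions
(default 20) and a discrete-time propagator ``A_d`` is fit to the centered
condition-mean trajectories by ridge-regularized least squares,

    z(t+1) ~ A_d z(t).

Working in discrete time throughout avoids matrix-logarithm branch issues on
fitted matrices: persistence is ranked by |eigenvalue| of ``A_d`` and the
amplifying modes come from the finite-horizon discrete observability Gramian
``sum_t (A_d')^t A_d^t``. Cross-validated fit quality is reported against a
time-shuffled control (destroying the lawful temporal order) and a train-vs-
test ceiling, making the comparison self-calibrating.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedShuffleSplit

from infoload._rng import derive_seed, rng_from
from infoload.errors import ConfigError
from infoload.overlap import (
    ConditionAverage,
    OverlapCurves,
    chance_overlap,
    condition_mean_center,
    overlap_timecourse,
)

__all__ = [
    "LDSFit", "fit_lds", "cv_fit_quality", "time_shuffle_control",
    "lds_overlap_pipeline", "discrete_persistent_basis", "discrete_amplifying_basis",
]


@dataclass
class LDSFit:
    """A fitted low-dimensional linear dynamical system."""

    dim: int
    pca_basis: np.ndarray       # (N, D), orthonormal columns
    A_d: np.ndarray             # (D, D) discrete-time propagator
    dt: float
    window: tuple[float, float]
    ridge: float
    singular_values: np.ndarray | None = None
    rank_warning: bool = False
    cv_quality: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        gram = self.pca_basis.T @ self.pca_basis
        if not np.allclose(gram, np.eye(self.pca_basis.shape[1]), atol=1e-8):
            raise ConfigError("pca_basis must have orthonormal columns")
        if not np.all(np.isfinite(self.A_d)):
            raise ConfigError("A_d must be finite")

    def project(self, means: np.ndarray) -> np.ndarray:
        """Project (C, N, B) activity into the fitted D-dim space -> (C, D, B)."""
        return np.einsum("cnb,nd->cdb", means, self.pca_basis)


def _window_slice(time: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    mask = (time >= window[0] - 1e-9) & (time <= window[1] + 1e-9)
    if mask.sum() < 3:
        raise ConfigError(f"window {window} must contain at least 3 bins")
    return mask


def fit_lds(
    condavg: ConditionAverage,
    D: int = 20,
    window: tuple[float, float] = (0.0, 1.0),
    ridge: float = 1e-6,
    dt: float | None = None,
) -> LDSFit:
    """Fit a D-dimensional discrete-time LDS to centered condition means.

    PCA is computed on the time-and-condition-concatenated centered means
    within ``window``; the propagator solves the ridge problem
    ``argmin_A sum_c sum_t ||z_c(t+1) - A z_c(t)||^2 + ridge ||A||_F^2``
    in closed form. With ``ridge=0`` this is the ordinary least-squares
    normal-equations solution.
    """
    N = condavg.means.shape[1]
    if D > N:
        raise ConfigError("D must not exceed the number of neurons")
    mask = _window_slice(condavg.time, window)
    Y = condavg.means[:, :, mask]                       # (C, N, B)
    C, _, B = Y.shape
    flat = Y.transpose(0, 2, 1).reshape(C * B, N)       # samples x neurons
    U, s, Vt = np.linalg.svd(flat, full_matrices=False)
    rank_warning = False
    if s.size >= D and s[D - 1] < 1e-10 * s[0]:
        rank_warning = True
        warnings.warn("fewer than D informative dimensions in the fit window",
                      RuntimeWarning, stacklevel=2)
    basis = Vt[:D].T                                    # (N, D)
    Z = np.einsum("cnb,nd->cdb", Y, basis)              # (C, D, B)
    Z0 = Z[:, :, :-1].transpose(1, 0, 2).reshape(D, -1)
    Z1 = Z[:, :, 1:].transpose(1, 0, 2).reshape(D, -1)
    A_d = (Z1 @ Z0.T) @ np.linalg.inv(Z0 @ Z0.T + ridge * np.eye(D))
    return LDSFit(dim=D, pca_basis=basis, A_d=A_d, dt=dt or condavg.dt,
                  window=window, ridge=ridge, singular_values=s,
                  rank_warning=rank_warning)


def time_shuffle_control(
    condavg: ConditionAverage,
    seed: int | None = None,
    window: tuple[float, float] | None = None,
) -> ConditionAverage:
    """Shuffle time bins (one permutation shared across neurons and conditions).

    Destroys the lawful temporal evolution of the trajectories while exactly
    preserving the multiset of population vectors, providing the null against
    which LDS fit quality is judged.
    """
    means = condavg.means.copy()
    time = condavg.time
    mask = np.ones(means.shape[2], dtype=bool) if window is None else \
        _window_slice(time, window)
    idx = np.where(mask)[0]
    if len(idx) < 3:
        raise ConfigError("need at least 3 bins to shuffle")
    rng = rng_from(seed, "time_shuffle")
    perm = rng.permutation(len(idx))
    means[:, :, idx] = means[:, :, idx[perm]]
    return ConditionAverage(means, time=time, dt=condavg.dt, centered=condavg.centered)


def _rollout(A_d: np.ndarray, z0: np.ndarray, n_steps: int) -> np.ndarray:
    """Roll the propagator forward: returns (..., D, n_steps) from z0 (..., D)."""
    out = np.empty(z0.shape + (n_steps,))
    z = z0
    out[..., 0] = z
    for t in range(1, n_steps):
        z = z @ A_d.T
        out[..., t] = z
    return out


def _quality(pred: np.ndarray, target: np.ndarray) -> float:
    """Variance-explained quality: 1 - ||pred-target||^2 / ||target||^2."""
    num = float(np.sum((pred - target) ** 2))
    den = float(np.sum(target**2))
    return 1.0 - num / den if den > 0 else np.nan


def _half_means(trials, idx):
    labels = trials.labels[idx]
    C = trials.n_conditions
    m = np.stack([trials.rates[idx][labels == c].mean(axis=0) for c in range(C)])
    return m - m.mean(axis=0, keepdims=True)


def cv_fit_quality(
    trials,
    D: int = 20,
    window: tuple[float, float] = (0.0, 1.0),
    n_splits: int = 10,
    seed: int | None = None,
    ridge: float = 1e-6,
) -> pd.DataFrame:
    """Cross-validated LDS fit quality vs. time-shuffled control and ceiling.

    Per split, trials are halved (stratified by condition); condition means
    are computed per half; the model is fit on the train half (PCA included,
    to avoid leakage) and rolled out from the test half's initial state over
    the window. Quality is variance explained of the full rollout against the
    held-out means (in the fitted D-dim space). The shuffle control fits the
    propagator after randomly permuting the train bins in time; the ceiling
    uses the train means directly as a prediction of the test means.

    Returns a DataFrame with columns ``split, model, shuffle, ceiling``.
    """
    counts = np.bincount(trials.labels)
    if counts.min() < 2:
        raise ConfigError("need at least 2 trials per condition")
    sss = StratifiedShuffleSplit(
        n_splits=n_splits, test_size=0.5,
        random_state=None if seed is None else derive_seed(seed, "cvsplit"))
    rows = []
    for k, (tr_idx, te_idx) in enumerate(
            sss.split(np.zeros(trials.n_trials), trials.labels)):
        mtr = _half_means(trials, tr_idx)
        mte = _half_means(trials, te_idx)
        ca_tr = ConditionAverage(mtr, time=trials.time, dt=trials.dt, centered=True)
        mask = _window_slice(trials.time, window)
        fit = fit_lds(ca_tr, D=D, window=window, ridge=ridge)
        Zte = np.einsum("cnb,nd->cdb", mte[:, :, mask], fit.pca_basis)
        Ztr = np.einsum("cnb,nd->cdb", mtr[:, :, mask], fit.pca_basis)
        B = Zte.shape[2]
        pred = _rollout(fit.A_d, Zte[:, :, 0], B)
        q_model = _quality(pred, Zte)
        ca_sh = time_shuffle_control(ca_tr, window=window,
                                     seed=None if seed is None else derive_seed(seed, "sh", k))
        fit_sh = fit_lds(ca_sh, D=D, window=window, ridge=ridge)
        Zte_sh = np.einsum("cnb,nd->cdb", mte[:, :, mask], fit_sh.pca_basis)
        pred_sh = _rollout(fit_sh.A_d, Zte_sh[:, :, 0], B)
        q_shuffle = _quality(pred_sh, Zte_sh)
        q_ceiling = _quality(Ztr, Zte)
        rows.append((k, q_model, q_shuffle, q_ceiling))
    return pd.DataFrame(rows, columns=["split", "model", "shuffle", "ceiling"])


def _real_directions_from_eig(ev: np.ndarray, V: np.ndarray, k: int,
                              order: np.ndarray):
    """Top-k real directions from a (possibly complex) eigendecomposition in
    the given ranking order, conjugate pairs kept together."""
    ev, V = ev[order], V[:, order]
    dirs: list[np.ndarray] = []
    used = np.zeros(len(ev), dtype=bool)
    i = 0
    while i < len(ev) and len(dirs) < k:
        if used[i]:
            i += 1
            continue
        lam, v = ev[i], V[:, i]
        if abs(lam.imag) <= 1e-9 * max(1.0, abs(lam)):
            dirs.append(v.real / np.linalg.norm(v.real))
        else:
            j = i + 1
            while j < len(ev) and (used[j] or abs(ev[j] - lam.conjugate()) > 1e-8 * max(1, abs(lam))):
                j += 1
            for part in (v.real, v.imag):
                n = np.linalg.norm(part)
                if n > 1e-12:
                    dirs.append(part / n)
            if j < len(ev):
                used[j] = True
        used[i] = True
        i += 1
    D = np.column_stack(dirs)
    Q, R = np.linalg.qr(D)
    keep = np.abs(np.diag(R)) > 1e-10
    return Q[:, keep]


def discrete_persistent_basis(A_d: np.ndarray, top_frac: float = 0.25) -> np.ndarray:
    """Orthonormal basis of the top-fraction most persistent modes of A_d.

    Persistence in discrete time is ranked by closeness of the eigenvalue to
    1 (ascending ``|lambda - 1|``): a persistent pattern is one the propagator
    changes least per step, which excludes both fast decay and
    rotation/expansion. For real spectra in (0, 1] — the typical case for
    dynamics fitted to decaying-plus-sustained activity — this ordering is
    identical to descending ``|lambda|`` and to the continuous-time ranking
    by ``Re(log lambda)/dt``.
    """
    D = A_d.shape[0]
    k = int(math.ceil(top_frac * D))
    ev, V = np.linalg.eig(A_d)
    order = np.argsort(np.abs(ev - 1.0))
    return _real_directions_from_eig(ev, V, k, order)


def discrete_amplifying_basis(
    A_d: np.ndarray, top_frac: float = 0.25, horizon_steps: int = 20
) -> np.ndarray:
    """Top eigenvectors of the discrete observability Gramian sum_t (A')^t A^t."""
    D = A_d.shape[0]
    k = int(math.ceil(top_frac * D))
    Q = np.eye(D)
    M = np.eye(D)
    for _ in range(horizon_steps):
        M = M @ A_d
        Q = Q + M.T @ M
    Q = (Q + Q.T) / 2.0
    w, V = np.linalg.eigh(Q)
    order = np.argsort(w)[::-1]
    return V[:, order[:k]]


def lds_overlap_pipeline(
    trials,
    D: int = 20,
    window: tuple[float, float] = (0.0, 1.0),
    top_frac: float = 0.25,
    horizon_steps: int | None = None,
    ridge: float = 1e-6,
    n_chance: int = 200,
    seed: int | None = None,
) -> tuple[OverlapCurves, LDSFit]:
    """Full overlap-signature pipeline on trial data.

    Fits the D-dim LDS to the centered condition means in ``window``, derives
    the top-fraction persistent and amplifying subspaces of the fitted
    propagator, projects the full-trial centered means into the fitted space,
    and computes both overlap time courses plus a 200-draw random-subspace
    chance band. Deterministic given the seed.
    """
    condavg = condition_mean_center(trials)
    fit = fit_lds(condavg, D=D, window=window, ridge=ridge)
    mask = _window_slice(condavg.time, window)
    if horizon_steps is None:
        horizon_steps = int(mask.sum())
    pers = discrete_persistent_basis(fit.A_d, top_frac)
    amp = discrete_amplifying_basis(fit.A_d, top_frac, horizon_steps)
    Z = fit.project(condavg.means)                       # (C, D, B_all)
    ca_z = ConditionAverage(Z, time=condavg.time, dt=condavg.dt, centered=True)
    pct_amp = overlap_timecourse(ca_z, amp)
    pct_pers = overlap_timecourse(ca_z, pers)
    k = int(math.ceil(top_frac * D))
    med, ci, _ = chance_overlap(ca_z, dim_k=k, n_draws=n_chance,
                                seed=None if seed is None else derive_seed(seed, "chance"))
    curves = OverlapCurves(
        time=condavg.time, amplifying_pct=pct_amp, persistent_pct=pct_pers,
        chance_median=med, chance_ci95=ci, top_frac=top_frac,
        subspace_dims=(amp.shape[1], pers.shape[1]))
    return curves, fit
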