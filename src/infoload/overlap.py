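"""Subspace-overlap time courses and the cross-over signature.

The central measure of this package: the percent of across-condition variance
of population activity captured, at each time bin, by the subspace spanned by
the top-fraction most amplifying or most persistent modes. Loading along the
most amplifying modes produces a characteristic *cross-over*: amplifying
overlap high early then falling, persistent overlap rising from chance —
distinguishing optimal loading from both classical pattern completion
(persistent overlap high throughout) and random input directions (both
overlaps start at chance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from infoload._rng import rng_from
from infoload.errors import ConfigError

__all__ = [
    "ConditionAverage", "OverlapCurves", "condition_mean_center",
    "overlap_timecourse", "chance_overlap", "crossover_signature",
]


@dataclass
class ConditionAverage:
    """Per-condition trial-mean activity, optionally mean-centered.

    ``means`` has shape (C, N, n_bins). When ``centered`` is True the
    across-condition mean is zero at every bin (the condition-independent
    time course has been removed).
    """

    means: np.ndarray
    time: np.ndarray
    dt: float
    centered: bool = False

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        if self.means.ndim != 3:
            raise ConfigError("means must have shape (C, N, n_bins)")
        if self.centered:
            resid = np.max(np.abs(self.means.mean(axis=0)))
            if resid > 1e-10 * max(1.0, np.max(np.abs(self.means))):
                raise ConfigError("centered=True but across-condition mean is nonzero")

    @property
    def n_conditions(self) -> int:
        return self.means.shape[0]


@dataclass
class OverlapCurves:
    """Overlap time courses for amplifying vs persistent subspaces + chance band."""

    time: np.ndarray
    amplifying_pct: np.ndarray
    persistent_pct: np.ndarray
    chance_median: float
    chance_ci95: tuple[float, float]
    top_frac: float
    subspace_dims: tuple[int, int]  # (amplifying, persistent)
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lo, hi = self.chance_ci95
        if not lo <= self.chance_median <= hi:
            raise ConfigError("chance CI must contain the chance median")
        for arr in (self.amplifying_pct, self.persistent_pct):
            finite = arr[np.isfinite(arr)]
            if finite.size and (finite.min() < -1e-9 or finite.max() > 100 + 1e-9):
                raise ConfigError("percentages must lie in [0, 100]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.time,
            "amplifying_pct": self.amplifying_pct,
            "persistent_pct": self.persistent_pct,
            "chance_median": self.chance_median,
            "chance_lo": self.chance_ci95[0],
            "chance_hi": self.chance_ci95[1],
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def condition_mean_center(trials) -> ConditionAverage:
    """Condition-mean activity relative to the condition-independent mean.

    Computes per-condition trial means and subtracts the across-condition mean
    at every bin, removing any condition-independent temporal drift.
    """
    labels = np.asarray(trials.labels)
    conds = np.unique(labels)
    C = trials.n_conditions
    if len(conds) < 2:
        raise ConfigError("need at least 2 conditions")
    if len(conds) != C or not np.array_equal(conds, np.arange(C)):
        raise ConfigError("labels must cover conditions 0..C-1")
    means = np.stack([trials.rates[labels == c].mean(axis=0) for c in range(C)])
    means = means - means.mean(axis=0, keepdims=True)
    return ConditionAverage(means, time=np.asarray(trials.time), dt=trials.dt,
                            centered=True)


def overlap_timecourse(condavg: ConditionAverage, modes) -> np.ndarray:
    """Percent variance of the centered condition means captured by a subspace.

    ``pct(t) = 100 * ||Y(t) P||_F^2 / ||Y(t)||_F^2`` where Y(t) is the (C, N)
    centered mean matrix at bin t and P projects onto the subspace basis
    (variance aggregated across conditions via Frobenius norms). Returns NaN
    where ``||Y(t)|| = 0``. ``modes`` may be a ModeSet or an orthonormal
    (N, k) basis matrix.
    """
    basis = getattr(modes, "basis", modes)
    basis = np.asarray(basis, dtype=float)
    if not condavg.centered:
        raise ConfigError("condavg must be centered")
    if basis.shape[0] != condavg.means.shape[1]:
        raise ConfigError("basis dimension does not match data")
    gram = basis.T @ basis
    if not np.allclose(gram, np.eye(basis.shape[1]), atol=1e-8):
        raise ConfigError("basis must be orthonormal")
    Y = condavg.means  # (C, N, B)
    proj = np.einsum("cnb,nk->ckb", Y, basis)
    num = np.sum(proj**2, axis=(0, 1))
    den = np.sum(Y**2, axis=(0, 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * num / den
    pct[den == 0] = np.nan
    return pct


def chance_overlap(
    condavg: ConditionAverage,
    dim_k: int,
    n_draws: int = 200,
    seed: int | None = None,
) -> tuple[float, tuple[float, float], np.ndarray]:
    """Chance band: time-averaged overlap with Haar-random k-dim subspaces.

    Draws ``n_draws`` random subspaces (orthonormalized standard-normal
    matrices), computes the time-averaged overlap for each, and returns
    (median, (2.5th, 97.5th percentile), per-draw values). For isotropic data
    the expected overlap is ``100 * k / N``; the data-dependent band is what
    real (anisotropic) recordings should be compared against.
    """
    N = condavg.means.shape[1]
    if not 1 <= dim_k <= N:
        raise ConfigError("need 1 <= dim_k <= N")
    rng = rng_from(seed, "chance_overlap")
    draws = np.empty(n_draws)
    for i in range(n_draws):
        M = rng.standard_normal((N, dim_k))
        Qb, _ = np.linalg.qr(M)
        pct = overlap_timecourse(condavg, Qb)
        draws[i] = np.nanmean(pct)
    lo, med, hi = np.percentile(draws, [2.5, 50.0, 97.5])
    return float(med), (float(lo), float(hi)), draws


def _window_mask(time: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    t0, t1 = window
    if t1 <= t0:
        raise ConfigError("window must have t1 > t0")
    return (time >= t0) & (time <= t1)


def crossover_signature(
    amp: np.ndarray,
    pers: np.ndarray,
    chance_ci: tuple[float, float],
    early_window: tuple[float, float],
    late_window: tuple[float, float],
    time: np.ndarray | None = None,
    min_run: int = 3,
) -> tuple[str, float | None]:
    """Classify a pair of overlap time courses.

    Returns ``(verdict, crossing_time)`` with verdict one of:

    - ``"crossover"``: amplifying overlap above chance and above persistent
      early and *falling* over the trial, persistent > amplifying late, and
      the early persistent overlap within/below the chance band — the
      signature of optimal (most-amplifying) information loading (high-then-
      falling amplifying overlap against rising-from-chance persistent
      overlap).
    - ``"persistent_first"``: persistent overlap already above chance early
      (pattern-completion loading).
    - ``"amplifying_only"``: amplifying above chance early and never overtaken
      by the persistent overlap (purely sequential dynamics).
    - ``"none"``: anything else (e.g. random loading, both overlaps at chance
      early).

    ``crossing_time`` is the first time where persistent >= amplifying for at
    least ``min_run`` consecutive bins (crossover verdict only).
    """
    amp = np.asarray(amp, dtype=float)
    pers = np.asarray(pers, dtype=float)
    if time is None:
        time = np.arange(len(amp), dtype=float)
    time = np.asarray(time, dtype=float)
    if not (len(amp) == len(pers) == len(time)):
        raise ConfigError("amp, pers and time must share one time axis")
    e0, e1 = early_window
    l0, l1 = late_window
    if max(e0, l0) < min(e1, l1):
        raise ConfigError("early and late windows must not overlap")
    me = _window_mask(time, early_window)
    ml = _window_mask(time, late_window)
    if not me.any() or not ml.any():
        raise ConfigError("windows must contain at least one bin")
    amp_e, pers_e = np.nanmean(amp[me]), np.nanmean(pers[me])
    amp_l, pers_l = np.nanmean(amp[ml]), np.nanmean(pers[ml])
    _, chance_hi = chance_ci

    if (amp_e > pers_e and amp_e > chance_hi and amp_e > amp_l
            and pers_l > amp_l and pers_e <= chance_hi):
        ge = pers >= amp
        ge[time < e0] = False  # search from the early window onward
        cross_t = None
        for i in range(len(ge) - min_run + 1):
            if ge[i:i + min_run].all():
                cross_t = float(time[i])
                break
        return "crossover", cross_t
    if pers_e > chance_hi and pers_l > chance_hi and pers_e > amp_e:
        return "persistent_first", None
    if amp_e > chance_hi and pers_e <= chance_hi and amp_l >= pers_l:
        return "amplifying_only", None
    return "none", None
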