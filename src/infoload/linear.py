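"""Linear integrator networks: persistent and most-amplifying modes.

This module analyzes continuous-time linear rate networks

    tau * dx/dt = -x + W x + b(t) + sigma * xi(t),

equivalently ``dx/dt = A x + ...`` with dynamics matrix ``A = (W - I)/tau``.
A network maintains working memory when ``W`` has exactly one eigenvalue with
real part 1, so that ``A`` has a single zero eigenvalue (the *persistent mode*,
an integrator direction) while all other modes decay.

The *most amplifying mode* is the unit input direction that evokes the largest
integrated response over a horizon ``T``: the top eigenvector of the
finite-horizon observability Gramian

    Q(T) = int_0^T exp(A' t) exp(A t) dt.

For symmetric (normal) dynamics the most amplifying and most persistent modes
coincide; for non-normal dynamics they can be near-orthogonal, and loading the
stimulus along the amplifying mode maximizes the activity ultimately reaching
the persistent mode — the core of the optimal-information-loading theory.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from infoload._rng import rng_from
from infoload.errors import ConfigError, StepSizeError, ToleranceError

__all__ = [
    "LinearNetwork", "ModeSet", "Trajectory", "PiecewiseConstantInput",
    "make_random_network", "simulate", "persistent_modes", "amplifying_modes",
    "optimal_loading_input", "henrici_index", "total_energy",
    "persistent_direction", "persistent_amplitude", "loading_vectors",
]

_SYM_TOL = 1e-12
_PERSISTENT_TOL = 1e-9


def _canonical_sign(v: np.ndarray) -> np.ndarray:
    """Flip ``v`` so its largest-magnitude entry is positive (sign convention)."""
    i = int(np.argmax(np.abs(v)))
    return -v if v[i] < 0 else v


@dataclass
class Trajectory:
    """A single simulated state trajectory on a uniform time grid."""

    states: np.ndarray  # (n_bins, N)
    dt: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=float)
        if self.states.ndim != 2 or self.states.shape[0] < 1:
            raise ConfigError("states must be a (n_bins, N) array with n_bins >= 1")
        if self.dt <= 0:
            raise ConfigError("dt must be positive")

    @property
    def time(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.states.shape[0])


@dataclass
class PiecewiseConstantInput:
    """Piecewise-constant input b(t): value ``values[i]`` on [times[i], times[i+1])."""

    times: np.ndarray   # (n_pieces + 1,) breakpoints, increasing
    values: np.ndarray  # (n_pieces, N)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if len(self.times) != self.values.shape[0] + 1:
            raise ConfigError("need len(times) == n_pieces + 1")
        if np.any(np.diff(self.times) <= 0):
            raise ConfigError("breakpoints must be strictly increasing")

    def __call__(self, t: float) -> np.ndarray:
        idx = np.searchsorted(self.times, t, side="right") - 1
        idx = int(np.clip(idx, 0, self.values.shape[0] - 1))
        if t < self.times[0] or t >= self.times[-1]:
            return np.zeros(self.values.shape[1])
        return self.values[idx]


@dataclass
class LinearNetwork:
    """Linear rate network ``tau dx/dt = -x + W x + input + noise``.

    Attributes
    ----------
    weights : (N, N) recurrent weight matrix W (dimensionless).
    tau : time constant in seconds.
    noise_sigma : state-noise scale per sqrt(second); 0 means deterministic.
    kind : "symmetric" or "unconstrained".
    persistent_vector : cached unit right eigenvector of the persistent mode
        (eigenvalue 1 of W), set by :func:`make_random_network`.
    """

    weights: np.ndarray
    tau: float = 1.0
    noise_sigma: float = 0.0
    kind: str = "unconstrained"
    persistent_vector: np.ndarray | None = field(default=None, repr=False)
    channels: np.ndarray | None = field(default=None, repr=False)
    _A: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[0] != self.weights.shape[1]:
            raise ConfigError("weights must be square")
        if self.tau <= 0:
            raise ConfigError("tau must be positive")
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be >= 0")
        if self.kind not in ("symmetric", "unconstrained"):
            raise ConfigError(f"unknown kind {self.kind!r}")
        if self.kind == "symmetric":
            asym = np.max(np.abs(self.weights - self.weights.T))
            if asym > _SYM_TOL:
                raise ConfigError(
                    f"kind='symmetric' requires W == W.T (max asymmetry {asym:.2e})"
                )

    @property
    def n_neurons(self) -> int:
        return self.weights.shape[0]

    @property
    def A(self) -> np.ndarray:
        """Dynamics matrix (W - I) / tau, cached."""
        if self._A is None:
            self._A = (self.weights - np.eye(self.n_neurons)) / self.tau
        return self._A

    def check_integrator(self, tol: float = _PERSISTENT_TOL) -> None:
        """Verify the integrator invariant: exactly one eigenvalue of W at Re=1."""
        ev = np.linalg.eigvals(self.weights)
        at_one = np.abs(ev.real - 1.0) <= tol
        if int(np.sum(at_one)) != 1:
            raise ConfigError(
                f"expected exactly one eigenvalue of W with Re=1, found {np.sum(at_one)}"
            )
        if np.any(ev.real[~at_one] >= 1.0):
            raise ConfigError("all non-persistent eigenvalues must have Re < 1")


@dataclass
class ModeSet:
    """A ranked set of persistent or amplifying directions.

    ``directions`` holds unit vectors as columns (N, n_modes), ordered by
    descending ``values`` (eigenvalue real parts for persistent modes, Gramian
    eigenvalues for amplifying modes). ``basis`` is an orthonormal matrix
    spanning the top-k selection. For persistent modes the matching left
    eigenvectors are stored in ``left_directions``.
    """

    kind: str  # "persistent" | "amplifying"
    directions: np.ndarray
    values: np.ndarray
    basis: np.ndarray
    horizon: float | None = None
    left_directions: np.ndarray | None = None
    eigenvalues: np.ndarray | None = None  # full (complex) spectrum, sorted
    warnings: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.directions = np.asarray(self.directions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        norms = np.linalg.norm(self.directions, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ConfigError("mode directions must be unit-norm")
        if np.any(np.diff(self.values) > 1e-10):
            raise ConfigError("mode values must be sorted descending")
        gram = self.basis.T @ self.basis
        if not np.allclose(gram, np.eye(self.basis.shape[1]), atol=1e-10):
            raise ConfigError("basis columns must be orthonormal")

    @property
    def top(self) -> np.ndarray:
        """Leading mode direction (unit vector)."""
        return self.directions[:, 0]

    @property
    def n_modes(self) -> int:
        return self.directions.shape[1]


def _top_k(top_frac: float, n: int) -> int:
    if not 0 < top_frac <= 1:
        raise ConfigError("top_frac must lie in (0, 1]")
    return int(math.ceil(top_frac * n))


def make_random_network(
    n: int,
    kind: str = "unconstrained",
    gain: float = 0.8,
    seed: int | None = None,
    tau: float = 1.0,
    noise_sigma: float = 0.0,
) -> LinearNetwork:
    """Random connectivity with an engineered persistent mode.

    Entries of W are i.i.d. N(0, gain^2/n) (symmetrized for ``kind='symmetric'``
    so that off-diagonal variance is preserved). The eigenvalue of W with the
    largest real part — among real eigenvalues where any exist — is then moved
    to exactly 1 while keeping every eigenvector fixed ("eigenvalue surgery"),
    turning that mode into a perfect integrator. If any remaining eigenvalue
    still has real part >= 1, the non-persistent spectrum is uniformly rescaled
    to put its maximum real part at 1 - 1e-3.
    """
    if n < 2:
        raise ConfigError("n must be >= 2")
    if gain <= 0:
        raise ConfigError("gain must be positive")
    rng = rng_from(seed)
    G = rng.normal(0.0, gain / np.sqrt(n), size=(n, n))

    if kind == "symmetric":
        W0 = (G + G.T) / np.sqrt(2.0)
        ev, V = np.linalg.eigh(W0)  # ascending
        i_star = n - 1
        ev = ev.copy()
        ev[i_star] = 1.0
        rest = np.delete(ev, i_star)
        if rest.size and rest.max() >= 1.0:
            ev[:i_star] *= (1.0 - 1e-3) / rest.max()
        W = (V * ev) @ V.T
        W = (W + W.T) / 2.0
        v_star = _canonical_sign(V[:, i_star])
    elif kind == "unconstrained":
        W0 = G
        ev, VL, VR = _eig_lr(W0)
        real_mask = np.abs(ev.imag) <= 1e-9
        if np.any(real_mask):
            cand = np.where(real_mask)[0]
            i_star = cand[np.argmax(ev.real[cand])]
            v = VR[:, i_star].real
            u = VL[:, i_star].real
            v /= np.linalg.norm(v)
            scale = u @ v
            # rank-1 spectral update: shifts lambda* to 1, keeps all eigenvectors
            W = W0 + (1.0 - ev[i_star].real) * np.outer(v, u / scale)
            rest = np.delete(ev.real, i_star)
        else:  # no real eigenvalue (vanishingly rare beyond tiny n): collapse the pair
            i_star = int(np.argmax(ev.real))
            lam = ev[i_star]
            v = VR[:, i_star]
            u = VL[:, i_star]
            upd = (1.0 - lam) * np.outer(v, u.conj()) / (u.conj() @ v)
            W = W0 + 2.0 * upd.real
            pair = np.abs(ev - lam.conj()) < 1e-10
            rest = ev.real[~pair & (np.arange(n) != i_star)]
            v = v.real / np.linalg.norm(v.real)
        if rest.size and rest.max() >= 1.0:
            W = _rescale_nonpersistent(W, target=1.0 - 1e-3)
        v_star = _canonical_sign(v)
    else:
        raise ConfigError(f"unknown kind {kind!r}")

    net = LinearNetwork(W, tau=tau, noise_sigma=noise_sigma, kind=kind,
                        persistent_vector=v_star)
    return net


def make_feedforward_network(
    n: int,
    n_slow: int | None = None,
    n_channels: int = 5,
    ff_gain: float = 5.0,
    slow_rates: tuple[float, float] = (0.05, 0.25),
    fast_rates: tuple[float, float] = (2.5, 4.0),
    seed: int | None = None,
    tau: float = 1.0,
    noise_sigma: float = 0.0,
) -> LinearNetwork:
    """Integrator network with explicit effective-feedforward structure.

    Built in Schur form: in a random orthonormal coordinate frame, coordinate
    0 is a perfect integrator (eigenvalue 0 of A), coordinates 1..n_slow-1
    decay slowly, and ``n_channels`` fast-decaying "source" coordinates feed
    the integrator and slow coordinates through strong feedforward couplings
    (strength ``ff_gain`` per channel); the remaining fast coordinates simply
    decay. This generalizes the canonical two-neuron network in which one
    neuron aligns with the persistent mode and the other with the amplifying
    mode: the most amplifying directions are the source channels, exactly
    orthogonal to the slow invariant subspace, so inputs along them are
    transiently amplified *into* the persistent subspace rather than starting
    inside it — while a random input direction barely touches the channels
    and is mostly dissipated. Decay rates are in 1/second (divided by tau
    when building W).

    ``n_slow`` defaults to ceil(n/4) so that the top-25% most persistent
    modes coincide with the slow block.
    """
    if n < 2:
        raise ConfigError("n must be >= 2")
    if ff_gain <= 0:
        raise ConfigError("ff_gain must be positive")
    rng = rng_from(seed)
    if n_slow is None:
        n_slow = int(math.ceil(n / 4))
    if not 1 <= n_slow < n:
        raise ConfigError("need 1 <= n_slow < n")
    n_fast = n - n_slow
    n_channels = min(n_channels, n_fast)
    T = np.zeros((n, n))
    rates = np.empty(n)
    rates[0] = 0.0
    rates[1:n_slow] = rng.uniform(*slow_rates, size=n_slow - 1)
    rates[n_slow:] = rng.uniform(*fast_rates, size=n_fast)
    T[np.arange(n), np.arange(n)] = -rates / tau
    ch = slice(n_slow, n_slow + n_channels)
    F = rng.normal(0.0, 1.0, size=(n_slow, n_channels))
    F *= ff_gain / np.linalg.norm(F, axis=0, keepdims=True)
    T[:n_slow, ch] = F / tau
    Q, _ = np.linalg.qr(rng.standard_normal((n, n)))
    A = Q @ T @ Q.T
    W = np.eye(n) + tau * A
    v_star = _canonical_sign(Q[:, 0])
    return LinearNetwork(W, tau=tau, noise_sigma=noise_sigma,
                         kind="unconstrained", persistent_vector=v_star,
                         channels=Q[:, ch].copy())


def _eig_lr(M: np.ndarray):
    """Eigendecomposition with left and right eigenvectors (columns)."""
    from scipy.linalg import eig

    ev, VL, VR = eig(M, left=True, right=True)
    return ev, VL, VR


def _rescale_nonpersistent(W: np.ndarray, target: float) -> np.ndarray:
    """Uniformly rescale the non-persistent spectrum of W to max real part ``target``."""
    ev, V = np.linalg.eig(W)
    i_star = int(np.argmin(np.abs(ev - 1.0)))
    rest = np.delete(np.arange(len(ev)), i_star)
    scale = target / ev.real[rest].max()
    ev2 = ev.copy()
    ev2[rest] = ev[rest] * scale
    Wn = (V * ev2) @ np.linalg.inv(V)
    return Wn.real


def persistent_direction(net: LinearNetwork) -> np.ndarray:
    """Unit right eigenvector of the persistent mode (eigenvalue 1 of W).

    Uses the vector cached at construction when available, otherwise extracts
    it by shift-inverted Arnoldi iteration around eigenvalue 1.
    """
    if net.persistent_vector is not None:
        return net.persistent_vector
    from scipy.sparse.linalg import eigs

    vals, vecs = eigs(net.weights, k=1, sigma=1.0)
    v = vecs[:, 0].real
    return _canonical_sign(v / np.linalg.norm(v))


def simulate(
    net: LinearNetwork,
    x0: np.ndarray | None = None,
    input_fn: PiecewiseConstantInput | None = None,
    T: float = 1.0,
    dt: float | None = None,
    n_trials: int = 1,
    seed: int | None = None,
) -> Trajectory | np.ndarray:
    """Integrate the network dynamics.

    Exactly one of ``x0`` (initial condition, zero input) or ``input_fn``
    (piecewise-constant input, zero initial condition) must be given. Noisy
    dynamics use Euler–Maruyama at step ``dt`` (default tau/50) with
    ``sigma*sqrt(dt)`` standard-normal increments; the noiseless single-trial
    case uses exact matrix-exponential propagation between input breakpoints.

    Returns a :class:`Trajectory` for ``n_trials == 1``, else an array of
    shape (n_trials, n_bins, N). Deterministic given ``seed``.
    """
    if (x0 is None) == (input_fn is None):
        raise ConfigError("give exactly one of x0 or input_fn")
    if T <= 0:
        raise ConfigError("T must be positive")
    N = net.n_neurons
    if dt is None:
        dt = net.tau / 50.0
    if dt >= net.tau:
        raise StepSizeError(f"dt={dt} must be smaller than tau={net.tau}")

    n_bins = int(round(T / dt)) + 1
    A = net.A

    if net.noise_sigma == 0.0 and n_trials == 1:
        states = _propagate_exact(A, x0, input_fn, n_bins, dt)
        return Trajectory(states, dt=dt)

    x = np.zeros((n_trials, N)) if x0 is None else np.tile(np.asarray(x0, float), (n_trials, 1))
    out = np.empty((n_trials, n_bins, N))
    out[:, 0] = x
    sig = net.noise_sigma * np.sqrt(dt)
    Ad = np.eye(N) + dt * A  # Euler propagator
    for k in range(1, n_bins):
        t = (k - 1) * dt
        drive = np.zeros(N) if input_fn is None else input_fn(t)
        x = x @ Ad.T + dt * drive
        if sig > 0:
            rng = rng_from(seed, "simulate", k)
            x = x + sig * rng.standard_normal((n_trials, N))
        out[:, k] = x
    if n_trials == 1:
        return Trajectory(out[0], dt=dt)
    return out


def _propagate_exact(A, x0, input_fn, n_bins, dt):
    """Exact propagation via matrix exponentials (noiseless, single trial)."""
    N = A.shape[0]
    states = np.empty((n_bins, N))
    x = np.zeros(N) if x0 is None else np.asarray(x0, dtype=float)
    states[0] = x
    if input_fn is None:
        E = expm(A * dt)
        for k in range(1, n_bins):
            x = E @ x
            states[k] = x
        return states
    # augmented-matrix trick handles singular A: exp([[A, b],[0,0]] dt)
    cache: dict[bytes, tuple[np.ndarray, np.ndarray]] = {}
    for k in range(1, n_bins):
        t = (k - 1) * dt
        b = np.asarray(input_fn(t), dtype=float)
        key = b.tobytes()
        if key not in cache:
            M = np.zeros((N + 1, N + 1))
            M[:N, :N] = A * dt
            M[:N, N] = b * dt
            EM = expm(M)
            cache[key] = (EM[:N, :N], EM[:N, N])
        E, f = cache[key]
        x = E @ x + f
        states[k] = x
    return states


def persistent_modes(net: LinearNetwork, top_frac: float = 0.25) -> ModeSet:
    """Eigenmodes of A ranked by persistence (descending real part).

    The top ``ceil(top_frac * N)`` right eigenvectors form the persistent
    subspace. A complex-conjugate pair contributes its real and imaginary
    parts as two real directions and is kept or dropped as a unit; if the
    pair straddles the cut-off it is kept, so the selection can exceed the
    nominal count by one. Left eigenvectors are stored alongside.
    """
    N = net.n_neurons
    k = _top_k(top_frac, N)
    warns: list[str] = []
    if net.kind == "symmetric":
        ev, V = np.linalg.eigh(net.A)
        order = np.argsort(ev)[::-1]
        ev, V = ev[order], V[:, order]
        directions = V[:, :k] / np.linalg.norm(V[:, :k], axis=0)
        return ModeSet("persistent", directions, ev[:k], basis=_orthonormalize(directions),
                       left_directions=directions.copy(), eigenvalues=ev.astype(complex),
                       warnings=warns)

    ev, VL, VR = _eig_lr(net.A)
    cond = np.linalg.cond(VR)
    if cond > 1e8:
        warns.append(f"eigenvector matrix ill-conditioned (cond={cond:.3g}); "
                     "modes may be inaccurate (near-defective dynamics)")
    order = np.argsort(ev.real)[::-1]
    ev, VL, VR = ev[order], VL[:, order], VR[:, order]

    dirs, lefts, vals = [], [], []
    used = np.zeros(N, dtype=bool)
    i = 0
    while i < N and len(dirs) < k:
        if used[i]:
            i += 1
            continue
        lam, v, u = ev[i], VR[:, i], VL[:, i]
        if abs(lam.imag) <= 1e-9:
            d = _canonical_sign(v.real / np.linalg.norm(v.real))
            dirs.append(d)
            lefts.append(_canonical_sign(u.real / np.linalg.norm(u.real)))
            vals.append(lam.real)
        else:
            # conjugate partner: next index with conjugate eigenvalue
            j = i + 1
            while j < N and (used[j] or abs(ev[j] - lam.conjugate()) > 1e-8 * max(1, abs(lam))):
                j += 1
            for part in (v.real, v.imag):
                d = part / np.linalg.norm(part)
                dirs.append(_canonical_sign(d))
                vals.append(lam.real)
            for part in (u.real, u.imag):
                nrm = np.linalg.norm(part)
                lefts.append(_canonical_sign(part / nrm) if nrm > 0 else part)
            if j < N:
                used[j] = True
        used[i] = True
        i += 1
    D = np.column_stack(dirs)
    return ModeSet("persistent", D, np.array(vals), basis=_orthonormalize(D),
                   left_directions=np.column_stack(lefts), eigenvalues=ev,
                   warnings=warns)


def _orthonormalize(D: np.ndarray) -> np.ndarray:
    Q, R = np.linalg.qr(D)
    keep = np.abs(np.diag(R)) > 1e-12 * max(1.0, np.abs(R).max())
    return Q[:, keep]


def _gramian_eig_closed_form(A: np.ndarray, T: float) -> np.ndarray:
    """Observability Gramian via the eigendecomposition of A (dense closed form).

    With A = V diag(lam) inv(V):
        Q(T) = inv(V)^H ( G * (V^H V) ) inv(V),
    where G_ij = (exp((conj(lam_i)+lam_j) T) - 1) / (conj(lam_i)+lam_j).
    """
    lam, V = np.linalg.eig(A)
    Vi = np.linalg.inv(V)
    s = lam.conj()[:, None] + lam[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        G = np.where(np.abs(s) < 1e-12, T, (np.exp(s * T) - 1.0) / s)
    Q = Vi.conj().T @ (G * (V.conj().T @ V)) @ Vi
    return Q.real


def _gramian_quadrature(A: np.ndarray, T: float, n_intervals: int = 200,
                        rtol: float = 1e-8, max_intervals: int = 1600) -> np.ndarray:
    """Composite-Simpson quadrature of the Gramian on the matrix exponential.

    Evaluates exp(A t) on a uniform grid by repeated multiplication with
    exp(A h) and Simpson-integrates exp(A t)' exp(A t); the grid is refined
    (with a coarse/fine self-check, Richardson style) until the estimate is
    stable to ``rtol`` in Frobenius norm.
    """
    def _simpson(n: int) -> np.ndarray:
        h = T / n
        E = expm(A * h)
        N = A.shape[0]
        M = np.eye(N)
        acc = np.zeros((N, N))
        for idx in range(n + 1):
            w = 1.0 if idx in (0, n) else (4.0 if idx % 2 == 1 else 2.0)
            acc += w * (M.T @ M)
            if idx < n:
                M = M @ E
        return acc * (h / 3.0)

    n = n_intervals if n_intervals % 2 == 0 else n_intervals + 1
    Q_coarse = _simpson(n // 2)
    while True:
        Q = _simpson(n)
        err = np.linalg.norm(Q - Q_coarse) / max(np.linalg.norm(Q), 1e-300)
        if err <= rtol:
            return Q
        if n >= max_intervals:
            raise ToleranceError(
                f"Gramian quadrature did not reach rtol={rtol} (err={err:.2e} at n={n})"
            )
        Q_coarse, n = Q, n * 2


def amplifying_modes(
    A: np.ndarray | LinearNetwork,
    top_frac: float = 0.25,
    horizon: float = 1.0,
    method: str = "auto",
) -> ModeSet:
    """Most-amplifying modes over a finite horizon.

    Eigenvectors of the observability Gramian ``Q(horizon)``, ordered by
    descending eigenvalue; the top eigenvector is the unit input direction
    that generates the largest integrated squared activity over the horizon.

    ``method``: "quadrature" (composite Simpson on the matrix exponential),
    "eig" (closed form through the eigendecomposition of A), or "auto"
    (closed form when A is well-conditioned diagonalizable, else quadrature).
    The two routes agree to the quadrature tolerance and are cross-checked in
    the test suite.
    """
    if isinstance(A, LinearNetwork):
        A = A.A
    A = np.asarray(A, dtype=float)
    if horizon <= 0:
        raise ConfigError("horizon must be positive")
    N = A.shape[0]
    symmetric = np.max(np.abs(A - A.T)) <= 1e-10 * max(1.0, np.abs(A).max())

    if symmetric:
        lam, V = np.linalg.eigh(A)
        s = 2.0 * lam
        q = np.where(np.abs(s) < 1e-12, horizon, (np.exp(s * horizon) - 1.0) / s)
        order = np.argsort(q)[::-1]
        q, V = q[order], V[:, order]
        k = _top_k(top_frac, N)
        D = np.apply_along_axis(_canonical_sign, 0, V[:, :k])
        return ModeSet("amplifying", D, q[:k], basis=D.copy(), horizon=horizon)

    if method == "auto":
        try:
            cond = np.linalg.cond(np.linalg.eig(A)[1])
        except np.linalg.LinAlgError:
            cond = np.inf
        method = "eig" if cond < 1e6 else "quadrature"
    if method == "eig":
        Q = _gramian_eig_closed_form(A, horizon)
    elif method == "quadrature":
        Q = _gramian_quadrature(A, horizon)
    else:
        raise ConfigError(f"unknown method {method!r}")
    Q = (Q + Q.T) / 2.0
    q, V = np.linalg.eigh(Q)
    order = np.argsort(q)[::-1]
    q, V = q[order], V[:, order]
    k = _top_k(top_frac, N)
    D = np.apply_along_axis(_canonical_sign, 0, V[:, :k])
    return ModeSet("amplifying", D, q[:k], basis=D.copy(), horizon=horizon)


def optimal_loading_input(
    A: np.ndarray | LinearNetwork,
    p: np.ndarray,
    T: float,
    method: str = "closed_form",
    n_restarts: int = 20,
    seed: int | None = None,
) -> np.ndarray:
    """Unit input maximizing the readout ``|p' exp(A T) u|`` at time T.

    The closed form is ``normalize(exp(A' T) p)``. The numeric route runs
    projected-gradient ascent on the unit sphere from ``n_restarts`` random
    initializations and agrees with the closed form to a fraction of a degree.
    """
    if isinstance(A, LinearNetwork):
        A = A.A
    A = np.asarray(A, dtype=float)
    p = np.asarray(p, dtype=float)
    if abs(np.linalg.norm(p) - 1.0) > 1e-8:
        raise ConfigError("p must be unit-norm")
    if T < 0:
        raise ConfigError("T must be >= 0")
    w = expm(A.T * T) @ p
    u_star = _canonical_sign(w / np.linalg.norm(w))
    if method == "closed_form":
        return u_star
    if method != "numeric":
        raise ConfigError(f"unknown method {method!r}")
    rng = rng_from(seed, "optimal_loading")
    best, best_val = None, -np.inf
    for _ in range(n_restarts):
        u = rng.standard_normal(len(p))
        u /= np.linalg.norm(u)
        lr = 0.5 / max(float(w @ w), 1e-12)  # inverse-Lipschitz step
        for _ in range(500):
            a = w @ u
            g = 2.0 * a * w
            g_t = g - (g @ u) * u  # tangent projection
            if np.linalg.norm(g_t) < 1e-14:
                break
            u = u + lr * g_t
            u /= np.linalg.norm(u)
        val = (w @ u) ** 2
        if val > best_val:
            best, best_val = u, val
    return _canonical_sign(best)


def henrici_index(A: np.ndarray) -> float:
    """Henrici departure from normality, normalized to [0, 1].

    ``H = sqrt(max(0, ||A||_F^2 - sum_i |lambda_i|^2)) / ||A||_F``; 0 for any
    normal matrix, approaching 1 for strongly feedforward (e.g. nilpotent)
    dynamics.
    """
    A = np.asarray(A, dtype=float)
    fro2 = float(np.sum(A * A))
    if fro2 == 0.0:
        raise ConfigError("Henrici index undefined for the zero matrix")
    ev = np.linalg.eigvals(A)
    return float(np.sqrt(max(0.0, fro2 - float(np.sum(np.abs(ev) ** 2))) / fro2))


def total_energy(traj: Trajectory) -> float:
    """Trapezoidal estimate of the integrated squared activity ∫ ||x(t)||² dt."""
    sq = np.sum(traj.states**2, axis=1)
    if len(sq) == 1:
        return 0.0
    return float(np.trapezoid(sq, dx=traj.dt))


def persistent_amplitude(net: LinearNetwork, x0: np.ndarray, T: float) -> float:
    """|activity along the persistent mode| at time T when starting from x0.

    Computed as ``|u1' exp(A T) x0|`` with the left eigenvector u1 of the
    persistent mode normalized so that ``u1' v1 = 1``; as T grows this is the
    asymptotic amplitude along the persistent mode.
    """
    ev, VL, VR = _eig_lr(net.A)
    i = int(np.argmin(np.abs(ev)))
    v = VR[:, i].real
    v /= np.linalg.norm(v)
    u = VL[:, i].real
    u = u / (u @ v)
    return float(abs(u @ (expm(net.A * T) @ np.asarray(x0, float))))


def loading_vectors(
    net: LinearNetwork,
    strategy: str,
    n_conditions: int = 2,
    horizon: float | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Per-condition unit loading directions for a given strategy.

    For two conditions, returns the +/- pair along a single direction
    (persistent mode, top amplifying mode, or a random direction). For more
    conditions, directions are drawn inside the top-``(C-1)`` persistent or
    amplifying subspace (random unit combinations, so the mean-centered
    loading spans the full C-1 dimensions), or fully at random.
    Shape (n_conditions, N).
    """
    N = net.n_neurons
    rng = rng_from(seed, "loading", strategy)
    if horizon is None:
        horizon = 5.0 * net.tau
    if strategy == "random":
        U = rng.standard_normal((n_conditions, N))
        if n_conditions == 2:
            U[1] = -U[0]
        return U / np.linalg.norm(U, axis=1, keepdims=True)
    if strategy == "persistent":
        base = persistent_direction(net)[:, None] if n_conditions == 2 else \
            persistent_modes(net, top_frac=min(1.0, (n_conditions - 1) / N)).basis
    elif strategy == "amplifying":
        k = 1 if n_conditions == 2 else n_conditions - 1
        if net.channels is not None and net.channels.shape[1] >= k:
            base = net.channels[:, :k]  # pure source channels (feedforward nets)
        else:
            base = amplifying_modes(net.A, top_frac=k / N, horizon=horizon).basis[:, :k]
    else:
        raise ConfigError(f"unknown loading strategy {strategy!r}")
    if n_conditions == 2:
        u = base[:, 0]
        return np.vstack([u, -u])
    C = rng.standard_normal((n_conditions, base.shape[1]))
    U = C @ base.T
    return U / np.linalg.norm(U, axis=1, keepdims=True)
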