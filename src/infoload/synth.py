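"""Synthetic population recordings with known ground truth.

Emulates the structure of multichannel prefrontal recordings during a
memory-guided saccade task — 6 cue conditions, cue -> delay -> go trials,
condition-independent temporal drift, and per-trial observation noise
(Gaussian rates or Poisson counts) — on top of a ground-truth latent network
whose cue inputs follow one of three loading strategies (persistent, random,
or most-amplifying). Because the generator keeps a sidecar with the true
network, modes, and loading vectors, every downstream analysis (decoding,
overlap signature, LDS fitting) can be tested as a parameter-recovery
problem without any external data.

The defaults are plausible placeholders for the real dataset's unpublished
statistics (trial counts, firing-rate scales): 300 neurons, 40 trials per
condition, 0.5 s cue, 1.75 s analysis delay, 50 ms bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import h5py

from infoload._rng import derive_seed, rng_from
from infoload.decode import TrialTensor
from infoload.errors import ConfigError, FormatError
from infoload.linear import LinearNetwork, make_random_network, \
    make_feedforward_network, loading_vectors, persistent_modes, \
    amplifying_modes, PiecewiseConstantInput, simulate

__all__ = ["RecordingConfig", "GroundTruth", "make_synthetic_recording",
           "save_recording", "load_recording"]

SCHEMA_VERSION = 1


@dataclass
class RecordingConfig:
    """Configuration of the synthetic-recording generator."""

    n_neurons: int = 300
    n_conditions: int = 6
    trials_per_condition: int = 40
    pre_cue: float = 0.3
    cue_duration: float = 0.5
    delay_set: tuple[float, ...] = (1.0, 1.375, 1.75)
    analysis_delay: float = 1.75
    dt: float = 0.05
    # linear_feedforward | linear_random | attractor_net | task_rnn
    ground_truth: str = "linear_feedforward"
    network: object = None                # trained net for the non-linear ground truths
    latent_n: int = 100
    latent_tau: float = 1.0
    latent_gain: float = 0.8              # linear_random only
    latent_ff_gain: float = 5.0           # linear_feedforward only
    latent_slow_rates: tuple[float, float] = (0.05, 0.25)  # 1/s
    latent_fast_rates: tuple[float, float] = (2.5, 4.0)    # 1/s
    latent_sigma: float = 0.05
    loading: str = "amplifying"           # persistent | amplifying | random
    input_strength: float = 12.0
    input_duration: float = 0.1           # phasic cue drive at cue onset, seconds
    observation: str = "gaussian"         # gaussian | poisson
    obs_sigma: float = 0.1
    poisson_baseline: float = 5.0         # Hz
    poisson_gain: float = 10.0            # Hz per unit latent activity
    drift_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ground_truth not in ("linear_feedforward", "linear_random",
                                     "attractor_net", "task_rnn"):
            raise ConfigError(f"unknown ground_truth {self.ground_truth!r}")
        if self.loading not in ("persistent", "amplifying", "random"):
            raise ConfigError(f"unknown loading {self.loading!r}")
        if self.observation not in ("gaussian", "poisson"):
            raise ConfigError(f"unknown observation {self.observation!r}")
        for name in ("pre_cue", "cue_duration", "dt", "analysis_delay"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.observation == "poisson" and self.poisson_baseline < 0:
            raise ConfigError("poisson baseline must be >= 0")
        if self.analysis_delay not in self.delay_set:
            raise ConfigError("analysis_delay must be in delay_set")


@dataclass
class GroundTruth:
    """Sidecar with the latent network and loading geometry used to generate data."""

    network: object
    loading_vectors: np.ndarray   # (C, latent_n)
    embedding: np.ndarray         # (n_neurons, latent_n)
    strategy: str
    persistent_mode: np.ndarray | None = None
    amplifying_basis: np.ndarray | None = None


def _softplus(x):
    return np.logaddexp(0.0, x)


def _latent_linear(cfg: RecordingConfig):
    """Latent trials from a linear integrator network with cue-period inputs."""
    if cfg.ground_truth == "linear_feedforward":
        net = make_feedforward_network(
            cfg.latent_n, ff_gain=cfg.latent_ff_gain,
            slow_rates=cfg.latent_slow_rates, fast_rates=cfg.latent_fast_rates,
            seed=derive_seed(cfg.seed, "latentnet"),
            tau=cfg.latent_tau, noise_sigma=cfg.latent_sigma)
    else:
        net = make_random_network(cfg.latent_n, "unconstrained", cfg.latent_gain,
                                  seed=derive_seed(cfg.seed, "latentnet"),
                                  tau=cfg.latent_tau, noise_sigma=cfg.latent_sigma)
    U = loading_vectors(net, cfg.loading, n_conditions=cfg.n_conditions,
                        horizon=cfg.analysis_delay,
                        seed=derive_seed(cfg.seed, "loadvec"))
    T_total = cfg.pre_cue + cfg.cue_duration + cfg.analysis_delay
    dt_sim = cfg.latent_tau / 20.0
    stride = max(1, int(round(cfg.dt / dt_sim)))
    dt_sim = cfg.dt / stride
    lat = []
    drive_T = min(cfg.input_duration, cfg.cue_duration)
    for c in range(cfg.n_conditions):
        inp = PiecewiseConstantInput(
            [cfg.pre_cue, cfg.pre_cue + drive_T],
            [cfg.input_strength * U[c]])
        out = simulate(net, input_fn=inp, T=T_total, dt=dt_sim,
                       n_trials=cfg.trials_per_condition,
                       seed=derive_seed(cfg.seed, "latsim", c))
        if not isinstance(out, np.ndarray):
            out = out.states[None]
        lat.append(out[:, ::stride, :])
    lat = np.concatenate(lat, axis=0)           # (trials, bins, latent_n)
    labels = np.repeat(np.arange(cfg.n_conditions), cfg.trials_per_condition)
    n_bins = lat.shape[1]
    time = -cfg.pre_cue + cfg.dt * np.arange(n_bins)
    gt = GroundTruth(network=net, loading_vectors=U, embedding=None,
                     strategy=cfg.loading,
                     persistent_mode=net.persistent_vector,
                     amplifying_basis=amplifying_modes(
                         net.A, 0.25, horizon=cfg.analysis_delay).basis)
    return lat, labels, time, gt


def _latent_from_net(cfg: RecordingConfig):
    """Latent trials generated by a user-supplied trained nonlinear network."""
    if cfg.network is None:
        raise ConfigError(
            f"ground_truth={cfg.ground_truth!r} requires a trained network "
            "in cfg.network")
    if cfg.ground_truth == "attractor_net":
        from infoload.attractor import run_attractor_trials
        trials = run_attractor_trials(cfg.network, delay_T=cfg.analysis_delay,
                                      n_trials_per_cond=cfg.trials_per_condition,
                                      dt_bin=cfg.dt,
                                      seed=derive_seed(cfg.seed, "latsim"))
    else:
        from infoload.taskrnn import run_trials
        trials = run_trials(cfg.network, cfg.task_spec, cfg.trials_per_condition,
                            delay=cfg.analysis_delay, dt_bin=cfg.dt,
                            seed=derive_seed(cfg.seed, "latsim"))
    lat = trials.rates.transpose(0, 2, 1)
    gt = GroundTruth(network=cfg.network, loading_vectors=None, embedding=None,
                     strategy=cfg.loading)
    return lat, trials.labels, trials.time, gt


def make_synthetic_recording(cfg: RecordingConfig) -> tuple[TrialTensor, GroundTruth]:
    """Generate a trial-resolved synthetic recording plus its ground truth.

    The latent network is simulated per condition with the configured loading
    strategy, embedded into ``n_neurons`` observed channels through a random
    unit-row-norm matrix, and read out with condition-independent drift and
    the chosen observation model. Deterministic given ``cfg.seed``.
    """
    if cfg.ground_truth in ("linear_feedforward", "linear_random"):
        lat, labels, time, gt = _latent_linear(cfg)
    else:
        lat, labels, time, gt = _latent_from_net(cfg)
    n_latent = lat.shape[2]
    rng = rng_from(cfg.seed, "embed")
    E = rng.standard_normal((cfg.n_neurons, n_latent))
    E /= np.linalg.norm(E, axis=1, keepdims=True)
    gt.embedding = E
    act = np.einsum("tbl,nl->tnb", lat, E)      # (trials, neurons, bins)

    if cfg.drift_amplitude > 0:
        T_span = time[-1] - time[0]
        phase = rng.uniform(0, 2 * np.pi, size=cfg.n_neurons)
        coeff = rng.standard_normal(cfg.n_neurons)
        s = np.sin(2 * np.pi * (time - time[0]) / max(T_span, 1e-9))
        drift = cfg.drift_amplitude * (
            coeff[:, None] * np.sin(2 * np.pi * (time[None, :] - time[0])
                                    / max(T_span, 1e-9) + phase[:, None]))
        act = act + drift[None, :, :]

    obs_rng = rng_from(cfg.seed, "observe")
    if cfg.observation == "gaussian":
        rates = act + cfg.obs_sigma * obs_rng.standard_normal(act.shape)
    else:
        lam = _softplus(cfg.poisson_baseline + cfg.poisson_gain * act)
        counts = obs_rng.poisson(lam * cfg.dt)
        rates = counts / cfg.dt

    n_tr = rates.shape[0]
    go = cfg.cue_duration + cfg.analysis_delay
    events = {"cue_on": np.zeros(n_tr), "cue_off": np.full(n_tr, cfg.cue_duration),
              "go": np.full(n_tr, go)}
    trials = TrialTensor(rates, labels, time, dt=cfg.dt, events=events,
                         n_conditions=cfg.n_conditions)
    return trials, gt


_EVENT_FIELDS = ("cue_on", "cue_off", "go")


def save_recording(path, trials: TrialTensor, ground_truth: GroundTruth | None = None,
                   provenance: dict | None = None) -> None:
    """Write a TrialTensor (and optional ground truth) to the HDF5 schema.

    Layout: /rates float32 (trials x neurons x bins), /labels int16,
    /time float64 (seconds, 0 = cue onset), /events compound table
    (cue_on, cue_off, go per trial); attrs dt_s, n_conditions, schema_version.
    """
    with h5py.File(path, "w") as f:
        f.create_dataset("rates", data=trials.rates.astype(np.float32))
        f.create_dataset("labels", data=trials.labels.astype(np.int16))
        f.create_dataset("time", data=trials.time.astype(np.float64))
        ev_dtype = np.dtype([(k, "f8") for k in _EVENT_FIELDS])
        ev = np.zeros(trials.n_trials, dtype=ev_dtype)
        for k in _EVENT_FIELDS:
            ev[k] = trials.events.get(k, np.zeros(trials.n_trials))
        f.create_dataset("events", data=ev)
        f.attrs["dt_s"] = trials.dt
        f.attrs["n_conditions"] = trials.n_conditions
        f.attrs["schema_version"] = SCHEMA_VERSION
        for key, val in (provenance or {}).items():
            f.attrs[f"prov_{key}"] = val
        if ground_truth is not None:
            g = f.create_group("ground_truth")
            g.attrs["strategy"] = ground_truth.strategy
            if ground_truth.embedding is not None:
                g.create_dataset("embedding", data=ground_truth.embedding)
            if ground_truth.loading_vectors is not None:
                g.create_dataset("loading_vectors", data=ground_truth.loading_vectors)
            if ground_truth.persistent_mode is not None:
                g.create_dataset("persistent_mode", data=ground_truth.persistent_mode)
            if ground_truth.amplifying_basis is not None:
                g.create_dataset("amplifying_basis", data=ground_truth.amplifying_basis)
            net = ground_truth.network
            if isinstance(net, LinearNetwork):
                gn = g.create_group("network")
                gn.create_dataset("W", data=net.weights)
                gn.attrs["tau"] = net.tau
                gn.attrs["sigma"] = net.noise_sigma
                gn.attrs["kind"] = net.kind


def load_recording(path, with_ground_truth: bool = False):
    """Load a recording written by :func:`save_recording` (lossless round-trip)."""
    with h5py.File(path, "r") as f:
        for name in ("rates", "labels", "time", "events"):
            if name not in f:
                raise FormatError(f"missing dataset /{name} in {path}")
        for attr in ("dt_s", "n_conditions"):
            if attr not in f.attrs:
                raise FormatError(f"missing attribute {attr} in {path}")
        ev = f["events"][()]
        events = {k: np.array(ev[k]) for k in _EVENT_FIELDS}
        trials = TrialTensor(
            rates=f["rates"][()].astype(float),
            labels=f["labels"][()].astype(int),
            time=f["time"][()],
            dt=float(f.attrs["dt_s"]),
            events=events,
            n_conditions=int(f.attrs["n_conditions"]),
        )
        if not with_ground_truth:
            return trials
        gt = None
        if "ground_truth" in f:
            g = f["ground_truth"]
            net = None
            if "network" in g:
                gn = g["network"]
                net = LinearNetwork(gn["W"][()], tau=float(gn.attrs["tau"]),
                                    noise_sigma=float(gn.attrs["sigma"]),
                                    kind=str(gn.attrs["kind"]))
            gt = GroundTruth(
                network=net,
                loading_vectors=g["loading_vectors"][()] if "loading_vectors" in g else None,
                embedding=g["embedding"][()] if "embedding" in g else None,
                strategy=str(g.attrs["strategy"]),
                persistent_mode=g["persistent_mode"][()] if "persistent_mode" in g else None,
                amplifying_basis=g["amplifying_basis"][()] if "amplifying_basis" in g else None,
            )
        return trials, gt


def analysis_windows(cfg: RecordingConfig) -> dict:
    """Default analysis windows for recordings from this generator.

    The LDS fit window starts just after the phasic cue drive ends (an
    autonomous model cannot represent input-driven bins), the early window
    covers the initial loading phase, and the late window the final part of
    the delay.
    """
    go = cfg.cue_duration + cfg.analysis_delay
    t0 = cfg.input_duration + 0.05
    return {
        "fit_window": (t0, t0 + 1.0),
        "early_window": (0.0, cfg.input_duration + 0.05),
        "late_window": (go - 0.5, go),
    }
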