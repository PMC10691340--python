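# infoload

Tools for studying **optimal information loading** into attractor
working-memory networks: how a transient stimulus input should be oriented in
neural state space so that a recurrent network best maintains the stimulus as
persistent activity — and how to detect that strategy in population
recordings.

## The science in brief

A linear rate network `tau dx/dt = -x + W x + input` maintains a memory when
`W` has one eigenvalue at 1: the corresponding eigendirection (the
**persistent mode** `v1`) neither grows nor decays, and the memory is the
activity amplitude along it. The classical intuition — load the stimulus
directly onto `v1` (pattern completion) — is only optimal for *symmetric*
connectivity. For non-normal connectivity, the input direction that maximizes
the persistent amplitude at long delays is the **most amplifying mode**: the
top eigenvector of the finite-horizon observability Gramian

    Q(T) = ∫₀ᵀ e^{A't} e^{At} dt,        A = (W − I)/tau,

which converges to the persistent mode's *left* eigenvector `u1` and can be
near-orthogonal to `v1`. Loading there multiplies the stored amplitude by up
to `‖u1‖` at no extra input magnitude. The behavioral fingerprint of this
strategy is *dynamic coding* — decoders trained late in the delay fail early
in the trial — and its population-level signature is a **cross-over**: the
fraction of across-condition variance captured by the top-25% amplifying
modes starts high and falls, while the persistent-mode fraction starts at
chance and rises.

The package implements the full toolchain around this idea:

| module | what it does |
|---|---|
| `infoload.linear` | linear integrator networks, persistent/amplifying modes, optimal loading inputs, Henrici non-normality index, energy |
| `infoload.attractor` | nonlinear attractor networks with jointly optimized weights and initial conditions; persistent-subspace/nullspace restricted loading |
| `infoload.taskrnn` | 50-unit networks trained on the memory-guided saccade task under four cost functions (cue-delay, full-delay, after-go-time, just-in-time) |
| `infoload.decode` | delay-trained and cross-temporal template decoders, performance-matching noise calibration |
| `infoload.overlap` | subspace-overlap time courses, random-subspace chance bands, cross-over verdicts |
| `infoload.lds` | 20-dimensional linear-dynamical-system fits to trial data, time-shuffled controls, the fitted-modes overlap pipeline |
| `infoload.synth` | synthetic population recordings (6 conditions, cue→delay→go, drift, Gaussian/Poisson observations) with ground-truth sidecars |
| `infoload.experiments` | the canonical end-to-end experiment protocols |
| `infoload.cli` | `infoload` command-line pipeline driver (YAML config, staged artifacts) |

All gradient-based training (attractor nets, task networks) runs on a
NumPy backprop-through-time engine with Adam; no GPU or autodiff framework is
required.

## Worked example

Compute the optimal loading direction of the canonical two-neuron network and
verify the amplification it buys:

```python
import numpy as np
from infoload import (LinearNetwork, amplifying_modes, optimal_loading_input,
                      henrici_index)
from infoload.linear import persistent_amplitude

A = np.array([[0.0, 5.0], [0.0, -1.0]])   # neuron 2 feeds neuron 1 (integrator)
net = LinearNetwork(np.eye(2) + A)

amp = amplifying_modes(A, top_frac=0.5, horizon=15.0).top
print("most amplifying mode:", amp.round(3))
print("persistent amplitude, amplifying loading:",
      round(persistent_amplitude(net, amp, T=50.0), 3))
print("persistent amplitude, persistent loading:",
      round(persistent_amplitude(net, np.array([1.0, 0.0]), T=50.0), 3))
print("Henrici non-normality index:", round(henrici_index(A), 4))
```

prints

```
most amplifying mode: [0.203 0.979]
persistent amplitude, amplifying loading: 5.099
persistent amplitude, persistent loading: 1.0
Henrici non-normality index: 0.9806
```

— loading along the amplifying mode (nearly orthogonal to the persistent
direction `(1, 0)`) stores a `sqrt(26) ≈ 5.1`-fold larger memory than loading
on the persistent mode itself.

The same logic end to end on a synthetic recording, via the pipeline driver:

```bash
cat > run.yaml <<'YAML'
seed: 3
synth: {loading: amplifying}
lds: {window: [0.15, 1.15]}
signature: {early_window: [0.0, 0.15], late_window: [1.75, 2.25]}
YAML
infoload --config run.yaml --stage all --out runs/demo
python -c "import json; print(json.load(open('runs/demo/metrics.json'))['signature']['verdict'])"
# -> crossover
```

The `signature` section of `runs/demo/metrics.json` reports the verdict, the
crossing time, the overlap-curve endpoints, the chance band, and the Henrici
index of the fitted dynamics; recordings generated with `loading: persistent`
or `loading: random` instead yield `persistent_first` and `none`.

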