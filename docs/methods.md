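# Methods

This note documents the models, measures and numerical choices behind
`infoload`, and what its synthetic benchmarks do and do not establish.

## Linear integrator networks

The core model is the linear rate network

    tau dx/dt = -x + W x + b(t) + sigma * xi(t),      A = (W - I)/tau,

with `tau = 1 s` by default (all times are in units of the membrane/network
time constant unless noted). A network maintains a memory when `W` has exactly
one eigenvalue with real part 1, i.e. `A` has a single zero eigenvalue — the
**persistent mode** `v1` — while every other mode decays. The memory at long
delays is the amplitude along `v1`, which equals `u1' x0` for an initial
condition `x0`, with `u1` the matching left eigenvector (`u1'v1 = 1`).

**Most amplifying mode.** We use the finite-horizon observability Gramian

    Q(T) = \int_0^T e^{A't} e^{At} dt,

whose top eigenvector is the unit input direction producing the largest
integrated squared response over the horizon. The infinite-horizon integral
diverges for an integrator (the zero eigenvalue contributes energy linearly in
T), so a finite horizon — by default the delay length being analyzed — is the
natural definition; as `T` grows the top amplifying mode converges to the
normalized `u1`. For normal (e.g. symmetric) dynamics `Q(T)` commutes with
`A`, so amplifying and persistent modes coincide; non-normal dynamics
dissociate them, and loading along the amplifying mode multiplies the final
persistent amplitude by up to `||u1||` (`sqrt(26) ≈ 5.1` in the canonical
two-neuron example `A = [[0,5],[0,-1]]`).

Two independent routes compute `Q(T)`: composite Simpson quadrature on the
matrix exponential with a coarse/fine self-check (refined until stable to
1e-8), and a closed form through the eigendecomposition of `A`
(`G_ij = (e^{(conj(l_i)+l_j)T}-1)/(conj(l_i)+l_j)`). They agree to the
quadrature tolerance and cross-check each other in the test suite; the
eigendecomposition route is used for large matrices when the eigenvector
basis is well-conditioned.

**Random integrators ("eigenvalue surgery").** `make_random_network` samples
i.i.d. Gaussian weights with variance `g^2/n` (default gain `g = 0.8`,
symmetrized when requested) and moves the largest-real-part real eigenvalue
to exactly 1 by a rank-one spectral update `W + (1-l*) v u'/(u'v)`, which
keeps every eigenvector fixed and leaves the remaining spectrum untouched
(a full reconstruction with uniform rescaling is used in the rare case that
another eigenvalue reaches 1). The persistent eigenvector is cached on the
network object.

**Feedforward integrators.** A second constructor, `make_feedforward_network`,
builds the dynamics in Schur form in a random orthonormal frame: one perfect
integrator coordinate, a block of slowly decaying coordinates (0.05–0.25 s^-1
by default), and fast "source" coordinates (2.5–4 s^-1) of which a few
channels feed the slow block with strong couplings. This generalizes the
canonical two-neuron example and gives exact control of the geometry: the
source channels are the amplifying directions and are exactly orthogonal to
the slow invariant subspace. We use it wherever a ground truth must cleanly
dissociate amplifying from persistent *subspaces*, for the following reason.
For Ginibre-type random integrators, the span of the top-25% slowest right
eigenvectors almost contains the integrator's left eigenvector (a consequence
of biorthogonality: the slow right eigenvectors are nearly collinear and
their span approaches the orthogonal complement of the remaining modes), so
the top amplifying direction has a 0.5–0.8 squared projection onto the
"persistent subspace" even though its overlap with the persistent *mode* is
near zero. Mode-level ensemble statements therefore use the
random construction, while subspace-overlap experiments use the feedforward
construction, where the containment is removed by design.

## Decoding

Decoders are nearest-class-centroid classifiers on rates that have been
centered by the *training folds'* condition-independent mean (no test
leakage); a regularized multinomial decoder is available as a robustness
check. The delay-trained decoder averages the training window's rates into
per-condition templates and is applied at every time bin of held-out,
stratified folds (5 by default); the cross-temporal matrix repeats this for
every training bin. Noise calibration (`match_performance_noise`) bisects the
state-noise level until the end-of-delay accuracy matches a target, so that
loading strategies can be compared at equal asymptotic performance.

## Subspace overlap and the cross-over signature

For centered condition means `Y(t)` (conditions x neurons) and an orthonormal
basis `P` of a candidate subspace, the overlap is
`100 * ||Y(t)P||_F^2 / ||Y(t)||_F^2` — the percent of across-condition
variance the subspace captures at each time, aggregated across conditions by
Frobenius norms. The chance band is data-dependent: the median and 2.5/97.5
percentiles of the time-averaged overlap across 200 Haar-random subspaces of
the same dimension (for isotropic data the expectation is `k/N`, verified as
an oracle; real data are anisotropic, hence the empirical band).

The verdict classifier labels a pair of overlap time courses as:

- **crossover** — amplifying overlap above the chance band and above the
  persistent overlap in the early window *and falling from the early to the
  late window*, persistent above amplifying in the late window, and early
  persistent overlap within/below the chance band. The above-chance and
  falling requirements on the amplifying overlap are both essential: without
  them, random loading produces spurious marginal crossovers — its fitted
  amplifying basis tautologically tracks the realized late code, so its
  overlap rises over the trial instead of falling.
- **persistent_first** — persistent overlap above chance early and late, and
  above the amplifying overlap early (pattern completion).
- **amplifying_only** — amplifying above chance early, never overtaken
  (sequential dynamics).
- **none** — anything else (e.g. random loading).

The crossing time is the first time at which the persistent overlap stays at
or above the amplifying overlap for three consecutive bins, searched from the
early window onward.

## Low-dimensional LDS fits

Trial data are reduced by PCA (computed on the time-and-condition-
concatenated centered means inside the fit window; on the training half only
during cross-validation) to `D = 20` dimensions, and a discrete-time
propagator is fit by ridge least squares `z(t+1) ~ A_d z(t)` (closed form;
ridge 1e-6 by default, exactly the normal equations at 0). Everything stays
in discrete time to avoid matrix-logarithm branch ambiguity on fitted
matrices.

**Persistence ranking.** The top-fraction "most persistent" modes of `A_d`
are the eigenvectors whose eigenvalues are closest to 1 (ascending
`|lambda - 1|`): a persistent pattern is one the propagator changes least per
step. On real spectra in (0, 1] — the generic case for decaying-plus-
sustained activity — this ordering is identical to descending `|lambda|` and
to the continuous-time ranking by `Re(log lambda)/dt`. The distinction
matters on fitted matrices, where residual input-driven growth appears as
weakly expanding complex pairs (`|lambda| ~ 1.01` with a small phase): such
rotation planes span both amplifying and persistent directions, and ranking
them "most persistent" by `|lambda|` alone contaminates the persistent basis.
Amplifying modes are the top eigenvectors of the finite discrete Gramian
`sum_{t=0}^{H} (A_d')^t A_d^t` with `H` the window length in bins. Conjugate
pairs contribute their real and imaginary parts together and the selection is
orthonormalized.

**Fit windows.** The default fit window is the cue and early delay (0–1 s
after cue onset). An autonomous LDS cannot represent bins in which an
external input drives the state, and fitting through such bins manufactures
spurious expanding modes aligned with the input directions; analyses of the
synthetic recordings therefore start the window just after the phasic cue
drive ends (0.15–1.15 s), and analyses of task networks (which receive input
throughout the cue) start it at cue offset. Fit quality is validated per
stratified half-split as variance explained of a full rollout from the test
half's initial state, against (i) a control fitted to time-shuffled training
bins (one permutation shared across neurons and conditions, destroying the
temporal order while preserving the population vectors) and (ii) a
train-vs-test ceiling (training means used directly as predictions).

## Synthetic recordings

The generator emulates the structure of multichannel prefrontal recordings in
a memory-guided saccade task: 6 cue conditions, 0.3 s pre-cue, 0.5 s cue,
1.75 s analysis delay (from a variable-delay set {1.0, 1.375, 1.75} s), 50 ms
bins, 300 observed channels, 40 trials per condition. A feedforward latent
integrator (100 units, 5 source channels, feedforward gain 5 s^-1) is driven
by a 0.1 s phasic cue pulse whose direction implements the loading strategy:
the source channels (most-amplifying loading), random combinations of the
C-1 slowest modes (persistent loading), or random directions. Latent activity
is embedded through a random unit-row-norm matrix, optionally combined with a
condition-independent sinusoidal drift, and observed either with additive
Gaussian noise or as Poisson counts of a softplus-rectified intensity.

Two calibration points deserve emphasis. First, the amplifying loading uses
the pure source channels rather than the top Gramian eigenvectors: the
optimal input direction also pushes the integrator directly and therefore
carries a 30–60% persistent-subspace component, which would blur the
early-persistent-overlap-at-chance signature the generator exists to emulate.
Second, the feedforward transfer is fast (crossover ~0.2 s after the pulse)
so that the fit window mostly sees saturated persistent patterns — if the
transfer unfolds inside the window, the fitted propagator represents it as
expanding rotations that entangle the two mode sets.

What the generator does **not** emulate: realistic spike-count statistics
beyond Poisson, electrode drift or sorting artifacts, heterogeneous per-trial
delays inside one tensor, adaptation, or any structure of the real lPFC data
set beyond its trial format. Passing the recovery tests shows the analysis
pipeline is correct and sensitive at realistic noise levels — not that real
cortex matches the generator.

## Attractor networks and information loading

The nonlinear model is `tau dx/dt = -x + W tanh(x) + b + noise` with 50
units, 6 conditions, and per-condition initial states `X0` (norm-bounded by
R, enforced by projection after every step). Training minimizes softmax
cross-entropy of a linear readout of `tanh(x)` at the end of the delay,
averaged over noisy rollouts (backprop-through-time on the Euler unroll at
`dt = tau/20`, Adam, symmetric variants parameterized by gradient
symmetrization). The delay may be a range, in which case it is sampled per
iteration.

Two training regimes are used deliberately:

- *Stable-attractor regime* (variable delays 3–12 tau, state noise 0.45):
  decodability at an unpredictable readout time forces six genuinely stable,
  well-separated fixed points. Training is continued in extra rounds until
  all six settled attractors are distinct — a convergence criterion on the
  stored memories. Six distinct states give a mean-centered attractor matrix
  of rank exactly C-1 = 5, which is the geometry the rank experiment
  measures. With a single fixed readout time and weak noise, by contrast,
  conditions can share or later merge attractors while end-of-delay accuracy
  stays perfect.
- *Dissociation regime* (fixed 4 tau delay, noise 0.3, tight bound R = 0.5,
  initialization gain 1.5): the tight magnitude bound forces loading to
  exploit the network's dynamics. After free training, the attractors define
  the persistent subspace (span of the mean-centered attractor states) and
  its orthogonal complement; initial conditions are then re-optimized with
  frozen weights restricted to either. Symmetric networks tolerate subspace
  loading and fail badly from the nullspace; unconstrained networks can
  exploit transient amplification from the nullspace. At this training scale
  the unconstrained half of the dissociation is seed-dependent (free
  optimization does not always land in a strongly non-normal solution), a
  known limitation discussed with the experiment.

## Task-optimized networks

Task networks (`tau dx/dt = -x + W tanh(x) + B u(t) + noise`, 50 units,
tau = 0.2 s, Euler at tau/10) receive a condition-specific input channel
during the cue and are trained end to end (all of W, B, readout; Adam,
BPTT with gradients verified against finite differences) to minimize
cross-entropy averaged over every bin of the cost-specific required interval
— [cue on, go], [cue off, go], [go, go+0.2 s] or [go-0.2 s, go] — plus a
penalty on the mean squared rate over the whole trial. Delays are sampled per
trial from {1.0, 1.375, 1.75} s; the after-go cost is also available with a
fixed delay (the variant in which purely sequential solutions are expected),
selected by restricting the delay set. No explicit go signal enters the
network; the go time appears only in the loss, so under variable delays
stable late coding is structurally required of any solution.

The phenotype experiments use one shared configuration for every cost
(initialization gain 1.2, noise 0.1, rate penalty 0.15, 600 iterations,
batch 24) so that differences between costs are attributable to the costs
alone. At this budget the cue-delay phenotype reproduces quantitatively;
the after-go and just-in-time networks show the correct decoder phenotypes
and the qualitative overlap shapes, but commit to their persistent code
earlier than the published large-budget networks, so the strictest overlap
clauses (persistent never exceeding amplifying for after-go; clear
early-persistent-at-chance for just-in-time) are only approached, not met.

## Numerical conventions

- Every stochastic operation takes an integer seed; derived streams come from
  a stable hash of the seed and a stage/trial tag, so one top-level seed
  reproduces a pipeline bit for bit.
- Noiseless single-trial simulation uses exact matrix exponentials (the
  augmented-matrix form handles the singular `A` with constant input); noisy
  simulation uses Euler–Maruyama at `tau/50` with `sigma*sqrt(dt)` increments.
- Mode directions are unit-norm with a canonical sign (largest-magnitude
  entry positive); top-fraction selections round up (`ceil`), and a complex
  pair straddling the cut-off is kept whole.
- Degenerate inputs are either rejected (`ConfigError` and friends) or
  flagged (non-settled attractors, NaN overlap at zero-activity bins,
  ill-conditioned eigenvector warnings) rather than silently propagated.
- Problem sizes in tests and the acceptance script are desk scale by design:
  1000-neuron ensembles for spectral claims, 40–100 networks per ensemble,
  600–800 training iterations, 15–40 trials per condition. The methods above
  state which conclusions are insensitive to this scale and which (the
  training-emergent phenotypes) are approached but not saturated.
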