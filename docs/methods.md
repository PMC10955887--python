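# Methods

`hippodecode` models a real-time optical brain–computer interface built on
head-mounted single-photon (miniscope) calcium imaging of hippocampal
populations: a training session constructs a decoding model offline, and a
real-time session replays (or streams) frames through the frozen model to
reconstruct the animal's position on a 1.6 m linear track, the light/dark
state of a flashlight, or the frequency of an auditory tone. This note
documents the models, the tunable parameters, the numerical choices, and
what the synthetic benchmarks do and do not demonstrate.

## Signal model and trace extraction

Raw calcium activity of a neuron is the mean intensity of the 3 × 3 pixel
patch centered on its footprint centroid (footprints come from an external
CNMF-E run; their detection is out of scope). Frames are first aligned to
a template (the first training frame) by translational registration using
upsampled frequency-domain cross-correlation; sub-pixel shifts are
available with `upsample > 1`. Revealed edges after translation are filled
with the frame median — footprints near borders are rejected anyway, since
the 3 × 3 patch must exist.

The per-neuron noise level is the standard deviation of the residual after
zero-phase lowpass filtering at 1 Hz. The filter is a Butterworth design
of order 20 factored into second-order sections and applied
forward–backward (`sosfiltfilt`): a direct-form IIR of that order is
numerically fragile, while the SOS cascade is stable and the two-pass
application makes the response zero-phase (and doubles the attenuation).

## Sensitive-neuron selection

Tuning is scored by a Skaggs-style information content adapted to
fluorescence,

    I = Σ_i p_i (r_i / r̄) log2(r_i / r̄),   r̄ = Σ_i p_i r_i   [bits],

where `p_i` is the occupancy probability of bin `i` (2 cm spatial bins on
the track; one temporal bin per stimulus state otherwise) and `r_i` the
mean fluorescence in that bin. Per-bin contributions are exposed.
Conventions: `0·log 0 = 0`; unvisited bins contribute nothing; traces with
negative excursions (possible after registration fill) are shifted by
their minimum; `I = 0` when `r̄ = 0`.

A neuron is *sensitive* when its observed `I` strictly exceeds the 95th
percentile (linear-interpolation quantile; ties fail) of a null built by
recomputing `I` after displacing the behavioral driver relative to the
trace, 1000 shuffles by default. Two null constructions are provided and
selected automatically:

- **circular** (spatial binning): rotate the frame-to-bin map by a random
  offset uniform in `[fps, T − fps]` frames. This preserves the
  autocorrelation of both trace and behavior, which a full permutation
  would destroy (permutation nulls are anti-conservative for
  kernel-smoothed calcium traces).
- **blocks** (stimulus-state binning): permute whole same-state blocks.
  Stimulus schedules are periodic by design (2 s/2 s light–dark), so a
  circular shift can re-align the schedule with itself and the null
  degenerates; block permutation destroys stimulus alignment while
  preserving within-block trace structure.

Measured operating characteristics on the default generator (200
shuffles): type-I rate 4–5% on 500 untuned neurons, power 100% for
strongly tuned place cells (5× gain, low noise), ~80–85% at the default
gain.

## Decoders

Position decoding is classification over 2 cm bins (80 classes); visual
decoding is per-frame light/dark; auditory decoding is per-epoch over
three tone frequencies. Five families share one train/predict surface:

- **GNB** (authored here): ŷ = argmax_y P(y) Π_i N(x_i | μ_{y,i}, σ_{y,i}),
  with occupancy priors P(y) (a uniform-prior switch exists), evaluated in
  log space, per-class variances floored at 1e-9 × the largest feature
  variance, ties resolved to the lowest class index.
- **SVM**: RBF kernel, γ = 1/n_features, C grid-searched.
- **MLP**: two ReLU hidden layers and a softmax head, Adam, batch 32,
  categorical cross-entropy (scikit-learn). L2 penalty fixed at α = 1.0:
  with hundreds of correlated input neurons and a few thousand frames, the
  weak default (1e-4) memorizes one session's noise realization and
  degrades badly across sessions (measured mean error 12.6 → 6.7 cm).
- **LSTM** (authored here, NumPy): two recurrent layers over sliding
  5-frame windows, ReLU on the upward hidden sequence, dropout 0.2, softmax
  on the last timestep. Window label = last frame (causal, streamable).
- **CNN** (authored here, NumPy): temporal convolutions over 150-frame
  stimulus epochs with neurons as channels — two conv(kernel 3) + ReLU +
  max-pool(2) blocks, dropout 0.2, dense softmax. The CNN consumes *raw*
  intensities; every other family consumes per-feature standardized inputs
  whose statistics are frozen at training time and re-applied verbatim to
  streaming data.

The LSTM/CNN implementations use hand-derived gradients with mini-batch
Adam; they are verified against numerical differentiation in the test
suite, and all their randomness (init, shuffling, dropout) flows from one
seed so fits are bit-reproducible.

Hyperparameters are chosen by mean five-fold cross-validated accuracy over
a grid (defaults: hidden sizes {32, 64, 128}, learning rates {1e-3, 1e-4},
epochs {20, 50}; SVM C {0.1, 1, 10}); the grid is scanned smallest-first
and a strictly better mean is required to switch, so ties resolve to the
smaller model. The 75/25 *chronological* split reports holdout
performance and selects the best family; the deployed model is then refit
on the full training session.

## Kalman post-filter

Decoded bin centers are smoothed by a constant-velocity Kalman filter:
state [position, velocity], A = [[1, Δt], [0, 1]], B = [Δt²/2, Δt] on an
acceleration control input u, H = [1, 0], Δt = 1/30 s, process noise
Q·I₂ with Q = 1e-4, observation noise R = 1, initial state zero with unit
covariance. Covariance symmetry is enforced after each update; non-finite
measurements trigger prediction-only steps. Reported positions are clipped
to the track; the internal state is not. The default control input is
u = 0: a finite-difference acceleration option exists but feeds the
filter's own velocity estimate back into itself and is unstable in
practice.

With Q/R = 1e-4 the steady-state gain is ≈ 0.027 (position) / 0.010
(velocity) per frame, i.e. a ~3 s velocity time constant. On a noisy
constant-velocity ramp this removes ~85% of the RMS noise. On
back-and-forth track running the same sluggishness makes the filter lag
every turn-around, and on the synthetic benchmark it *raises* the median
error of an already-accurate decoder (~6 cm raw → ~10 cm filtered). Both
behaviors are properties of the stated Q and R, not of the implementation.

## Synthetic data generator

The generator is the package's test bed; its defaults define the
benchmark conditions.

- **Behavior**: back-and-forth traversals of a 160 cm track at a mean
  speed of 15 cm/s with piecewise-constant speed (resampled every 0.5 s,
  Gaussian jitter sd = 20%) and a random 0.5–3 s pause at each end.
  Variable pauses matter: with deterministic pauses the traversal sequence
  is near-periodic and circular-shift nulls lose essentially all power
  (a shifted periodic trace looks place-tuned at every offset).
- **Stimuli**: visual — light 2 s / dark 2 s, n cycles; auditory — a
  uniformly random tone (4/8/16 kHz) for 2 s then 3 s silence, n epochs.
- **Traces**: per-frame event probability = rate/fps (clipped to 1);
  binary events convolved with a difference-of-exponentials kernel (rise
  0.05 s, decay 0.5 s, unit amplitude); additive i.i.d. Gaussian noise,
  sd = 0.1 × amplitude. Rates: baseline 0.1 ev/s; place cells add a
  Gaussian field (default width 10 cm sd, gain 2 ev/s); visual cells add a
  sustained state gain *plus* a brief onset-locked transient (20 ev/s for
  0.15 s at 0.05 s latency) — purely sustained rates would leave the first
  ~0.5 s of each block undecodable, unlike real evoked responses; auditory
  cells add a latency-jittered (0–0.5 s), variably long (1–3 s) response
  after preferred-tone onsets.
- **Movies**: background 100 + Gaussian spots (σ 1.5 px) scaled by the
  traces, optional per-frame rigid drift, pixel noise.

What the generator does *not* model: correlated (shared neuropil/motion)
noise across neurons, baseline drift and photobleaching, remapping between
sessions, spike-to-calcium nonlinearity, and speed-dependent rate
modulation. Two consequences for interpreting results: (1) because
per-neuron noise is conditionally independent given the stimulus, GNB's
naive-independence assumption holds exactly and GNB is near-optimal here —
the marked inferiority of GNB on real recordings does not reproduce;
(2) cross-session generalization is easier than in real data, so absolute
error levels are optimistic.

## Measured benchmark behavior

At the default conditions (300 place cells + 100 untuned, 12 training +
12 real-time trials, 200-shuffle selection, reduced grids), typical
results are: ~290 of 300 place cells selected with ≤ ~10 false positives;
raw cross-session decoding error ≈ 5.7–7 cm median (SVM best, GNB
statistically tied, LSTM slightly worse); Kalman-filtered error ≈ 10–11 cm
median for the reasons above. Visual frame error ≈ 5–8% (the residual is
the few genuinely ambiguous frames straddling each light/dark transition);
auditory epoch error is near 0% at default SNR. The acceptance script
(`scripts/acceptance.py`) recomputes all of these from scratch.

Problem sizes in the test-suite and acceptance runs (shuffles 200 instead
of 1000, single-point neural-net grids, 10–25 training epochs) are the
package's scaled-down benchmark settings; every pipeline stage still runs
in full.

## Known limitations

- The 33 ms real-time frame budget is logged per frame, never enforced by
  dropping frames; latency accounting is observational.
- Auditory real-time decoding anchors epochs at schedule-known tone
  onsets (the rig controls the speaker); no free-running epoch detection.
- LSTM streaming emits no prediction for the first W−1 warm-up frames.
- No speed filter or low-occupancy-bin exclusion is applied before the
  information-content computation.
- Registration is rigid translation only.
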