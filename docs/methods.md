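# Methods

## Problem setting

Given two groups of animal movement trajectories (class A and class B — e.g.
control vs. treated worms, normal vs. lesioned mice), the package trains a
neural classifier to tell the groups apart and then inspects *where* the
network looks when it succeeds.  Segments that receive high attention in a
well-chosen layer are candidate group-specific behaviors; correlating the
attention signal with handcrafted movement features, and comparing the
distributions of those features inside highlighted segments, turns the
highlights into interpretable hypotheses.

## Preprocessing and features

A trajectory is a strictly increasing series of timestamps with planar (or
lon/lat) coordinates and optional extra sensor channels.  The network input
is position- and rotation-invariant: step speed `v_i = ||p_i − p_{i−1}|| /
Δt_i` and relative angular speed (heading change per unit time, wrapped into
(−π, π]).  Zero-length steps carry the previous heading forward so
stationary animals do not produce NaNs.  Three further handcrafted channels
are always computed for interpretation: cumulative travel distance,
straight-line distance from the start, and the unsigned angle in [0, π]
between the +y axis and the vector from the start.

Speed loses one sample and angular speed two, so all channels are truncated
to the common length `n − 2` (the first two raw samples are dropped); row
`k` of every channel refers to trajectory point `k + 2`, which keeps
attention indexing exact.

Channels are z-scored with **dataset-global** statistics (mean/SD pooled
over the valid steps of all trajectories).  Per-trajectory standardization
would erase between-trajectory magnitude differences that the classifier
legitimately uses; the global choice is flagged here because either
convention is defensible.  Variable-length series are padded to the longest
length `l_MAX` with the sentinel −1.0 plus a boolean validity mask.

Moving statistics (average, population variance, first-difference
derivative) use a centered window that shrinks at the edges; the default
window is 21 steps and is configurable, since no canonical value exists for
it.

## The network

Eight parallel stacks process the input series: four 1-D convolutional
stacks with kernels spanning 3 %, 6 %, 9 % and 12 % of `l_MAX` (rounded,
stride 1, zero 'same' padding) and four LSTM stacks returning full
sequences.  Each stack holds `layers_per_stack` layers (default 4) of 16
units with dropout 0.5 after every layer.  Every layer output `Z ∈
R^{l_MAX×N}` feeds one attention neuron

    a = softmax(tanh(W_a Zᵀ + b_a)),   W_a ∈ R^{1×N},  b_a ∈ R^{1×l_MAX},

whose output weights that layer's sequence elementwise; the weighted
sequences are concatenated channel-wise, mean-pooled over valid time steps
and classified by a dense two-way softmax head.  The tanh keeps pre-softmax
logits in [−1, 1] so no single time step can monopolize the attention
(max/min ratio ≤ e²), which keeps highlights readable.  `b_a` is a
per-time-step bias, making the attention mildly position-aware; inputs
shorter than `l_MAX` use its leading slice.

Design points that the architecture description leaves open, and the
choices made here:

- **Softmax masking.**  The softmax runs over valid steps only and padded
  steps get attention exactly 0.  Otherwise padding would absorb attention
  mass and the length-normalized layer score below would be distorted.
- **Time reduction before the head.**  Mean pooling over valid steps after
  concatenation — the simplest reduction consistent with the stated blocks.
- **Conv activation.**  tanh; bounded outputs keep the attention-weighted,
  concatenated head well-scaled.
- **Padding semantics.**  The input is zeroed at padded steps and every
  layer output is re-masked, so predictions and attentions are *exactly*
  independent of the amount of trailing padding and of whatever values sit
  in padded cells.

The network and its backpropagation are implemented on a small in-package
reverse-mode autodiff core (numpy + numba-compiled LSTM kernels, float32).
All hand-derived gradients are verified against central finite differences
in the test suite.

## Training protocol

A stratified random 80/20 trajectory split (stratification keeps both
classes in both parts, which plain random splitting does not guarantee on
small datasets); Adam (default learning rate 1e-3, batch size 32) on the
softmax cross-entropy with inverse-class-frequency sample weights to handle
imbalanced designs; early stopping when the training loss stops improving
(default patience 10).  Learning rate, batch size and epoch budget have no
canonical published values and are exposed in `TrainConfig`.  Everything —
split, initialization, batch order, dropout — derives from one seed, so
runs are exactly reproducible.  Held-out accuracy is the diagnostic for
whether the classes differ at all: accuracy near 50 % means no detectable
difference (or too little data), and the attention analysis should not be
trusted in that regime.

## Attention analysis

For layer *i* with attention sets `A_A`, `A_B` (vectors trimmed to valid
lengths, partitioned by true class):

- `s_fc = sqrt( Σ_a V(a) / (|A|·l̄) )` with `A = A_A ∪ A_B`, `V` the
  population variance and `l̄` the mean valid length — concentration of
  attention.  The softmax constraint makes attention variance scale like
  1/length, hence the normalization.
- `s_it = 1 − Σ_bins min(h(A_A), h(A_B))` with `h` a normalized 200-bin
  histogram over the pooled min–max range of both classes — class contrast.
- Layers are ranked by `s = s_fc + s_it`, ties broken by architectural
  order (conv stacks first, shallow → deep).

Per-trajectory screening uses `V(a)` directly: near-uniform attention means
the layer found nothing localized in that trajectory.  A step counts as
*highlighted* when its attention exceeds `c / T` with `c = 1.2` and `T` the
valid length; uniform attention (1/T) therefore never produces highlights,
by construction.

Attention is explained two ways: (i) Pearson correlation between the pooled
attention values and every handcrafted feature, plus its moving average,
moving variance and derivative (pooling concatenates the valid steps of all
trajectories; per-class coefficients are reported alongside); (ii) the
within-highlight distribution difference `1 − Intersect` of the 200-bin
histograms of a feature's values at highlighted steps of each class, over
the pooled range.  The histogram convention (200 bins, pooled min–max
range) is applied to both uses for consistency; bin count and range are
only partially pinned down by the method's description.  Zero-variance
features yield an undefined (NaN) correlation rather than an error, and a
class with no highlighted steps yields an undefined distribution
difference.

All variances are population variances (divide by n), which matches the
closed-form checks (a one-hot attention vector of length 4 has V = 3/16).

## Synthetic data generator

The generator emulates the two-state structure of worm locomotion — a
straight *run* state and a reorienting *turn* state — as a two-state
semi-Markov correlated random walk: geometric dwell times (means 20 and 5
steps), per-step speed drawn around the state mean (run 1.0 units/step,
turn 0.3×, CV 0.25), heading incremented by Gaussian turning noise (SD 0.1
rad in runs, 1.0 rad in turns), Gaussian positional noise (SD 0.05) on the
integrated path.  Defaults: 100 trajectories per class, 200 steps at 1 Hz.

Class B carries a planted, localized effect with an exact ground-truth
mask:

- `speed_burst` — each run bout is amplified ×magnitude with probability
  0.5 (at least one per trajectory), mimicking learned fast runs;
- `sharp_turn` — selected turn bouts get magnitude× turning-angle SD;
- `origin_drift` — one contiguous window (30 % of the trajectory) gains a
  slow constant drift, mimicking a distance-from-start signature.

Magnitude 1 turns every effect off, giving an exchangeable null.  Each
trajectory uses an independent RNG substream keyed by (seed, counter), so
datasets are bit-reproducible and independent of generation order.

What the generator does *not* emulate: measurement dropout, heteroscedastic
GPS error, inter-individual baseline variation, or any coupling between
speed and turning beyond the two states.  Passing the recovery tests
therefore shows the pipeline can find strong localized effects under clean
conditions, not that it will on noisy field data.

## Synthetic study protocol and problem sizes

`deephl.protocols.run_speed_burst_study` runs the full pipeline on the
default conditions (speed burst, magnitude 3, 100/class, 200 steps) for one
seed: train with a short budget (12 epochs, early-stopping patience 4 — the
planted effect is strong and separates within a few epochs), evaluate on
the held-out 20 %, rank layers on the whole dataset's attentions, then
score the top layer by (i) the fraction of correctly classified class-B
test trajectories whose mean attention inside the planted mask exceeds the
mean outside and (ii) the |r|-rank of the moving variance of speed among
all (feature, derivation) pairs.  `run_null_study` repeats this with
permuted labels (6 epochs; nothing to learn).  Aggregate checks over five
seeds use the across-seed mean, since single-seed held-out accuracy on 40
trajectories carries binomial noise of ±0.08.

## Case-study features

- **Mouse open-field segmentation** — ambulation: trailing 0.5-s average
  center-point speed > 2 cm/s sustained ≥ 0.5 s; immobility: trailing 1-s
  path change < 1 cm sustained ≥ 1 s; everything else fine movement.
  Overlaps resolve as immobility > ambulation > fine movement (a precedence
  the verbal rules leave open).  Units must be declared as cm; anything
  else is an error rather than a silent mislabeling.
- **Windowed excursion** — for each point, the maximum straight-line
  distance to any point within ±60 s (window shrinks at the edges); the
  per-trajectory summary is the maximum of the series.
- **Beetle curvature angle** — circle of radius 100 mm centered at each
  point; first crossings of the track before and after the point are found
  by linear interpolation between the straddling samples; the angle between
  the two crossing directions (in [0, π]) measures local curvature.  Points
  without both crossings are NaN and counted.
- **Worm dominant frequency** — 128-s sliding FFT window shifted one sample
  at a time; the reported frequency is the non-DC bin with the largest
  amplitude (DC is excluded because a constant offset is not an
  oscillation); an all-zero spectrum is flagged via the returned amplitude.
- **Information gain** — entropy reduction of the best single-threshold
  decision stump, in bits; the standard scalar-feature usefulness measure
  for a binary comparison.

## Numerical notes and limitations

- The network runs in float32 (CPU memory-bandwidth bound); analysis
  statistics are float64.  Attention normalization holds to 1e-5; padding
  invariance is exact by construction.
- Histogram edge conventions follow numpy (`[lo, hi)` half-open bins, last
  bin closed); a degenerate pooled range (all values equal) widens to a
  unit interval so identical degenerate distributions intersect fully.
- The layer score compares layers within one trained model; scores are not
  comparable across models or datasets.
- Binary classification only; more than two groups require pairwise runs.
- GeoJSON export requires geographic coordinates; planar data exports as
  CSV with RGB columns (yellow → red over each trajectory's own attention
  range, constant attention mapping to yellow).
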