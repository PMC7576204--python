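# deephl

Attention-assisted comparative analysis of animal movement trajectories.

## What problem this solves

Comparative designs — treated vs. control worms, lesioned vs. normal mice,
male vs. female seabirds — produce hundreds of trajectories per group, and
the group-specific behavior is often a *localized* segment (a sprint, a
sharp turn, an excursion) that is easy to miss when browsing plots or when
only whole-trajectory summary features are tested.  `deephl` trains a
neural classifier on the two groups and then uses the network's own
attention to point at the trajectory segments that drive the
classification, so a biologist can look exactly where the difference lives
and design an interpretable feature for it.

## The model in brief

The classifier is a multi-scale layer-wise attention network: four 1-D
convolutional stacks (kernels 3–12 % of the maximum sequence length) and
four LSTM stacks, each layer (default 4 × 16 units, dropout 0.5) feeding an
attention neuron

    a = softmax(tanh(W_a Zᵀ + b_a))

over its output sequence Z.  Attention-weighted layer outputs are
concatenated, mean-pooled over valid time steps and classified by a softmax
head.  Inputs are the position- and rotation-invariant primitive features
(speed, relative angular speed), standardized and padded with a mask.

Layers are ranked by `s = s_fc + s_it`: `s_fc` (length-normalized root mean
attention variance) rewards attention concentrated on limited segments, and
`s_it = 1 − Intersect(h(A_A), h(A_B))` (one minus the 200-bin histogram
intersection of the two classes' pooled attention values) rewards layers
that attend differently to the two classes.  Per-trajectory screening uses
the attention variance V(**a**); steps with attention above `1.2/T` count
as highlighted; highlights are explained by Pearson correlation with
handcrafted features (and their moving average/variance/derivative) and by
the within-highlight distribution difference `1 − Intersect` of feature
histograms between classes.  Details and all tie-breaking/normalization
conventions are in `docs/methods.md`.

A synthetic two-state (run/turn) correlated-random-walk generator with
planted, localized class effects and exact ground-truth masks makes the
whole pipeline testable end to end without animal data.

## Worked example

```bash
deephl simulate --seed 3 --out demo/data
deephl train --manifest demo/data/manifest.yaml --out demo/run \
             --seed 3 --epochs 12
deephl rank-layers --checkpoint demo/run/checkpoint.npz \
                   --manifest demo/data/manifest.yaml --out demo/ranks
deephl highlight --checkpoint demo/run/checkpoint.npz \
                 --manifest demo/data/manifest.yaml \
                 --layer conv2_l3 --out demo/hl
deephl explain --checkpoint demo/run/checkpoint.npz \
               --manifest demo/data/manifest.yaml \
               --layer conv2_l3 --out demo/ex
```

`simulate` writes 200 trajectories (100 per class; class B carries speed
bursts of magnitude 3 in some run bouts) plus `truth_masks.csv`.  On this
run, training reported

```
held-out accuracy 1.000
```

(`demo/run/accuracy.json`: `{"test_accuracy": 1.0, "n_test": 40}`), i.e.
the two classes are clearly separable — the precondition for trusting the
attention analysis.  `rank-layers` prints the top of the layer-score table:

```
         layer      s_fc      s_it         s
rank
0     conv2_l3  0.000202  0.999343  0.999546
1     conv1_l4  0.000216  0.999242  0.999458
2     conv2_l4  0.000209  0.999242  0.999451
3     conv1_l3  0.000214  0.998384  0.998598
```

and the top-ranked layer is passed to `highlight` (per-trajectory CSVs with
attention and yellow→red RGB columns, plus `trajectory_scores.csv` with
V(**a**) for screening) and to `explain`, whose `correlations.csv` starts
with the features most correlated with attention:

```
         feature       derivation         r       r_A       r_B     abs_r
0          speed   moving_average  0.617229  0.104429  0.742653  0.617229
1          speed              raw  0.527462  0.087002  0.598244  0.527462
2          speed  moving_variance  0.517025  0.011619  0.620065  0.517025
```

— the attention tracks speed and its moving statistics, which is exactly
the planted group difference, and the correlation is carried by the
affected class (`r_B` ≫ `r_A`).  `dist_diff.csv` lists the
within-highlight distribution differences of each feature between the
classes.

The same pipeline is available as a library (`deephl.generate_dataset`,
`deephl.build_feature_tensor`, `deephl.DeepHLNet`, `deephl.train`,
`deephl.rank_layers`, ...); `deephl.protocols.run_speed_burst_study(seed)`
runs everything at once and returns the metrics.

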