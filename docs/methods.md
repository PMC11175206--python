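# Methods

This note documents the model implemented by `fedlatent`, the parameter
defaults and why they were chosen, the scope of the synthetic generators,
and the numerical choices. No empirical claim here goes beyond what the
test suite and `scripts/acceptance.py` compute.

## 1. Model

### 1.1 Federated setting

K clients each hold a private labeled dataset. Training proceeds in
rounds: the server broadcasts the global parameter vector, every client
runs local SGD (default: one epoch, batch 32, learning rate 0.01), and
the server aggregates the returned local models. Two aggregation rules
are implemented:

- **FedAvg baseline**: weights n_k / Σ n_j by sample count.
- **Proposed two-level aggregation**: clients are first partitioned into
  groups (Section 1.3). Within group m, client k receives weight

  ```
  w_k = (1 − γ − β) · n_k/n_m  +  (1 − α − γ) · l_k/l_m  +  (1 − α − β) · δ_k/δ_m
  ```

  where n is sample count, l is the number of label classes present, δ is
  the latent-space variance from the client's signature, and the
  denominators are group totals. Group models are then averaged globally
  with weights of the same form over group totals. Under the simplex
  constraint α + β + γ = 1, the three coefficients (1−γ−β), (1−α−γ),
  (1−α−β) equal α, β, γ and each weight set sums to exactly 1; this is
  enforced at configuration time and verified to 1e-9 over 500 random
  simplex draws in the acceptance suite. With α = 1 (volume-only) and one
  group, the rule reduces bitwise to FedAvg, which is tested to 1e-12 per
  coordinate over 5 rounds.

### 1.2 Latent signatures

Each client trains a small VAE (dense encoder/decoder, Gaussian
likelihood with unit variance, so the reconstruction term is 0.5·SSE/n;
closed-form KL to a standard-normal prior; reparameterization
z = μ + exp(½ logvar)·ε). The signature is:

- per-dimension histograms of the posterior means over [−4, 4] with 20
  bins each, concatenated (latent_dim × 20 entries), out-of-range values
  clipped into the end bins, smoothed with +1e-10 and renormalized;
- the pooled population variance of the latents (the δ in Section 1.1);
- the sample count n and the label-class count l.

Two deliberate design choices:

- **Shared encoder initialization.** Independently initialized VAEs are
  non-identifiable: two clients with identical data can land in latent
  spaces that differ by an arbitrary rotation, which makes histogram
  comparison meaningless. All clients therefore start from one broadcast
  initialization seed and train with their own noise streams — the same
  communication pattern as broadcasting the global classifier.
- **Light training.** A VAE trained to convergence pushes the aggregate
  posterior toward the N(0,1) prior, which *erases* between-client
  contrast. Short training (5 epochs, learning rate 0.001) keeps the
  encoder close to the shared map while letting the data shift the latent
  distribution. Both effects were observed directly on the planted-group
  generators during development: long independent training drove recovery
  to chance, the shared-light regime recovers the planted partition
  perfectly in ≥ 9/10 seeds (acceptance criterion 5).

### 1.3 Divergence grouping

Signature histograms are compared with the Jensen–Shannon divergence in
nats, JSD(p,q) = ½KL(p‖m) + ½KL(q‖m) with m = (p+q)/2, using the
0·ln(0/x) = 0 convention; it is symmetric, non-negative, and bounded by
ln 2. The K(K−1)/2 pairwise evaluations are instrumented and the count is
asserted exactly (criterion 7). Clients whose divergence falls below a
threshold are connected; groups are the connected components of that
graph. The group head is the member with the largest latent variance
(ties break to the lowest client id).

When no threshold is given, one is suggested by an Otsu two-class split
on the *logarithms* of the pairwise divergences, returning the geometric
midpoint between the two clusters. The log transform matters: within-group
divergences concentrate orders of magnitude below between-group ones, and
a linear split lands inside the broad upper mode.

## 2. Parameter defaults and rationale

| Parameter | Default | Rationale |
|---|---|---|
| α, β, γ | 1/3 each | Neutral prior over the three ratios; any simplex point is accepted, including per-group overrides. |
| JSD threshold | suggested from data | The meaningful scale depends on histogram granularity and VAE regime; the log-Otsu suggestion adapts to the observed bimodality. Must lie in (0, ln 2). |
| latent_dim | 8 | Enough dimensions that a group shift confined to a few directions of the input survives encoding; 2 dimensions lost recoverability on the planted generators. |
| histogram_bins / range | 20 / [−4, 4] | Posterior means under a near-standard-normal aggregate posterior lie almost surely in ±4; 20 bins resolves shifts of ~0.4 latent units without becoming noise-limited at n ≈ 100. |
| VAE epochs / lr | 5 / 0.001 | The light-training regime of Section 1.2. |
| VAE gradient clip | 5.0 (global norm) | Prevents the occasional exploding step on large-magnitude inputs early in training; divergence raises `TrainingDivergenceError` rather than returning NaNs. |
| client lr / batch / epochs | 0.01 / 32 / 1 | Standard local-SGD settings used by the end-to-end criterion. |
| DNN | 4 hidden layers × 500 units, ReLU, softmax | Reference classifier; at 28×28 input and 10 classes it has exactly 1,149,010 parameters (asserted in tests). Tests and examples use a narrower `hidden_width` for speed. |
| CNN | 3 conv layers (3×3, valid, stride 1, 32 filters, ReLU), flatten, 2 hidden dense layers, softmax | A minimal convolutional family with no pooling; spatial size shrinks by 2 per conv layer, so input side must be ≥ 8. |

## 3. Synthetic generators (scope and limits)

The generators are *study conditions*, not tunable dials: their defaults
define the experiments.

**Tabular** (`generate_federation`): clients are assigned to groups
round-robin. Class c has center `class_separation · N(0, I)` (drawn once);
group g adds an offset along one of `num_groups` orthonormal directions
(QR of a Gaussian matrix) scaled by `feature_separation`; samples are
center + offset + N(0, I). Label mixes are drawn once per *group* from a
symmetric Dirichlet (`label_skew` is the concentration; smaller = more
skew), so clients within a group share a label distribution and the
grouping task is learnable from features. The held-out test set is drawn
from the pooled mixture over groups.

**Image** (`generate_image_federation`): classes are geometric templates
(bars, disk, diagonal, checkerboard, cross) on a `feature_dim`-sided
square; groups differ by contrast (scaled down with group index) and
additive noise level; pixels are clipped to [0, 1].

Limits: groups differ by a mean shift (or contrast/noise), not by shape
of the within-class distribution; covariances are identity; clients
within a group are exchangeable. Conclusions about recovery therefore
speak to mean-shift/contrast heterogeneity only.

## 4. Numerical choices

- All model parameters and data are float64; aggregation is a single
  weighted sum over stacked parameter vectors, so identical weights give
  bitwise-identical results regardless of code path.
- Backpropagation (dense, ReLU, conv via `sliding_window_view` im2col,
  softmax cross-entropy) is verified against central differences to 1e-7.
- log-variance outputs of the encoder are clipped to ±10 before
  exponentiation.
- KL and JSD renormalize their inputs and raise on genuinely infinite KL
  (zero in q where p has mass); signature smoothing (+1e-10) keeps
  pairwise JSD finite and strictly below ln 2.
- Seeds: one master seed is split with `numpy.random.SeedSequence` into
  data / model-init / shared-VAE-init / per-client streams; per-(client,
  round) streams come from `SeedSequence([client_seed, round])`. All
  recorded seeds are reduced mod 2^31.

## 5. Problem sizes exercised

Tests and the acceptance script run federations of K = 4–12 clients,
feature dimension 8 (or 8–12-sided images), 60–120 samples per client,
3 classes, and 1–20 rounds; pairwise-divergence instrumentation is
checked up to K = 50. Runtime for the full suite is well under a minute
on one CPU; the acceptance script takes a few seconds.

## 6. Limitations

- Single-process simulation: no communication failures, stragglers, or
  client sampling; every client participates every round.
- Privacy is architectural (only signatures leave the client), not
  formal: no differential-privacy accounting of the histogram release.
- Grouping happens once, before training; drifting clients are not
  re-grouped.
- The suggested threshold assumes the divergence multiset is bimodal;
  with a single true group (no structure) it will still split somewhere,
  so a domain-chosen threshold is preferable when structure is uncertain.
- The VAE is dense; image inputs are flattened for signature purposes.
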