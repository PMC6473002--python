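# Methods

## Scope

`streetdecile` implements a measurement pipeline for small-area urban
inequality deciles from per-location image embeddings: an ordinal deep
classifier with a binomial-unimodal output head, postcode→LSOA score
aggregation with equal-frequency decile conversion, a decile-allocation
evaluation battery, five-fold cross-validation, and a source→target
city transfer/fine-tuning protocol. Real street imagery and government
label data are proprietary or city-specific, so the package ships a
synthetic-city generator that emulates the statistical structure of
those inputs; everything downstream of the embeddings is the real
method, exercised at desk scale.

## Ordinal model

Decile assignment is ordinal K = 10 classification. The network maps a
postcode's four D-dimensional views (camera directions 0°, 90°, 180°,
270°) through a shared fully connected encoder (default D→256→64 per
view), concatenates the four 64-unit channel embeddings in fixed view
order, applies one more hidden layer (256→64) and a scalar output
z. Batch normalization precedes every ReLU; the output layer has none.
p = sigmoid(z) parameterizes Binomial(K−1, p); success counts 0..9 map
to deciles 1..10. This is the standard unimodal construction for
ordinal outputs: a single scalar controls the whole class distribution,
and the mode moves monotonically with p.

A variant that evaluates Binomial(K, p) at 1..K successes and
renormalizes is available behind `parameterization="binom_k_renorm"`
for sensitivity checks; the K−1 form is the default because K trials
have K+1 outcomes and the renormalized form is not a true binomial law.

The loss is the negative cross-entropy −Σ y ln p_m (class probabilities
floored at 1e-12 inside the log, so p ∈ {0, 1} never produces −∞; the
loss plateaus where the true-class probability is below the floor). Its
gradient through the sigmoid and binomial transform reduces to
dNLL/dz = (K−1)·p − m for true success count m, which the tests verify
against central finite differences to 1e-4 relative error, for the full
network including train-mode batch normalization.

### Optimization and model selection

Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8) on mini-batches sampled with a
seeded generator. 10% of the training postcodes form an internal
validation set scored every `eval_every` iterations; the returned
parameters are the snapshot with the lowest validation MAE (argmax
class vs true label) within the final `selection_window_fraction`
(default 5%) of iterations.

Two presets exist. The desk default — 5,000 iterations, batch 64,
learning rate 1e-4 — keeps a five-fold run under two minutes on one
CPU at the 300-LSOA problem size and trains to convergence there. The
documented replication preset (`replication_train_config()`) is
learning rate 5e-6 for 100,000 iterations with selection over the last
5,000, matching the original full-scale regime.

All passes are explicit NumPy (the model is a small MLP over fixed
embeddings; no convolution and no GPU), which also makes every run
bit-reproducible from its seed.

## Aggregation and decile conversion

Postcode-level *pre-sigmoid* outputs z are averaged per LSOA over the
scored subset (e.g. a fold's test postcodes); LSOAs with no scored
postcode are omitted, never zero-filled. LSOA means are converted to
deciles by the same equal-frequency rank cut used for the labels:
rank by badness with ties broken by stable input order, cut into ten
contiguous blocks, sizes n//10 with the n mod 10 leftovers allocated
from decile 1 upward. Rank-cut conversion preserves the uniform decile
marginal that defines deciles and is invariant to any strictly
monotone recalibration of the scores; an argmax-of-binomial-mode
conversion is available behind a flag but does not preserve the
marginal. In cross-validation the cut is applied per fold over that
fold's scored LSOAs (default); a pooled-conversion variant is always
reported alongside since either reading of the protocol is defensible.

## Evaluation battery

Computed on LSOA-level deciles only: exact, ±1 and ±2 allocation
accuracy; MAE in decile classes; Kendall's τ-b (decile vectors are
heavily tied, so the tie-corrected variant is the right choice);
Pearson's r; Cohen's κ with linear weights w_ij = 1 − |i−j|/9; and the
10×10 observed-vs-predicted allocation matrix. τ, r and κ go through
scipy/scikit-learn; every metric is cross-checked in the tests against
a naive from-scratch implementation. A constant vector makes r
undefined and raises rather than returning 0. Useful references: under
independent uniform deciles the expected exact accuracy is 0.10 and the
expected MAE is exactly 3.3.

The extremes-separation analysis groups LSOA mean scores by observed
decile and asks how often the worst-off (decile 1) and best-off
(decile 10) areas fall on the wrong side of a threshold. The default
threshold is the midpoint of the two deciles' score medians —
deterministic and distribution-free; a predicted-decile rule
(misclassified = predicted into the wrong half) is available, and the
report records which rule produced it.

## Cross-validation and transfer

Five-fold splits are seeded random partitions of postcodes (the
literal protocol). Because all postcodes of an LSOA share a label, a
postcode-level split leaks LSOA-level information across folds; a
grouped `unit="lsoa"` split is provided so users can measure that gap.
Each fold trains on 80% of postcodes and scores the held-out 20%;
metrics are computed on the pooled (LSOA, fold) predictions.

Transfer trains one model on all source postcodes, then permutes the
target postcodes once: the fine-tune subset at fraction f is the first
⌊f·n⌋ of the permutation (subsets are nested across fractions), and
the shared evaluation set is the complement of the largest subset, so
every regime — direct application, each fine-tune fraction, and
train-from-scratch — is evaluated on the same postcodes, none of which
were seen by any training or fine-tuning run. Train-from-scratch uses
the target training pool (the complement of the evaluation set) rather
than all target data: evaluating a model on its own training postcodes
would contaminate the comparison, and the package treats the
no-leakage guarantee as non-negotiable. Fine-tuning resumes training
of *all* weights (including batch-norm statistics, which matters under
affine input shifts) with a fresh optimizer state; a frozen-encoder
option exists but is off by default. Target deciles are always
computed over target-city LSOAs only.

## Synthetic-city generator

What it emulates, and how:

- **Geography.** LSOA centroids are uniform on a √n × √n square (unit
  average density), each LSOA holding max(1, Poisson(λ)) postcodes;
  λ defaults to 32 ≈ 156,581 London postcodes / 4,838 LSOAs.
- **Outcomes.** A latent wellbeing vector per LSOA (one entry per
  outcome) drawn from a Gaussian process with exponential spatial
  kernel exp(−d/ℓ) (default ℓ = 2 grid units; ℓ = 0 disables spatial
  structure) and a configurable cross-outcome correlation matrix, so
  the generator can reproduce the observed structure of UK deprivation
  outcomes — income vs employment deprivation correlated at r = 0.95,
  living environment and crime only weakly coupled to the rest
  (average r ≈ 0.28 and 0.42). Raw values are the latent, sign-flipped
  for "higher = worse" outcomes (the deprivation-index convention;
  mean income is the canonical "higher = better" case), then cut into
  deciles.
- **Features.** Postcode latent = LSOA latent + isotropic jitter
  (default sd 0.1 against unit-variance latents; real within-LSOA
  visual heterogeneity is not quantified anywhere, so this is a free
  generator parameter, not an estimate). Each view applies a fixed
  random unit-norm linear map to tanh(latent) — the squashing makes
  the learning task nonlinear but solvable, so the MLP is not
  redundant — plus Gaussian noise with variance = signal variance /
  `signal_to_noise`. `signal_to_noise=0` yields pure noise; `inf`
  disables noise. Default D = 64 for speed; D = 4096 mirrors the fc6
  embedding contract.
- **Domain shift.** A per-feature affine transform (scalar, per-D, or
  per-view-per-D) plus optional extra Gaussian noise stands in for the
  photometric/content gap between cities.

What it does **not** emulate: real spatial geometry of postcodes
within LSOAs, outcome-specific distributional shapes (all latents are
Gaussian), view-specific scene content (all four views are
statistically exchangeable maps of the same latent), temporal mismatch
between imagery and labels, and missing panoramas. Passing tests
therefore demonstrate correctness and calibration of the *method* —
not that any particular real outcome is predictable from imagery at a
given accuracy.

## Study conditions used in tests and the acceptance script

Desk-scale experiments run a 300-LSOA city with 8 postcodes per LSOA
(≈ 2,400 postcodes) and D = 64: large enough that decile conversion,
five-fold CV and the transfer protocol are all well-posed, small
enough for minutes-scale runs on one CPU. High-signal runs use
signal_to_noise = 10, the regime in which the pipeline reaches the
qualitative scale of the best published outcomes (r ≈ 0.86); the null
runs use signal_to_noise = 0. The transfer experiment uses a fixed
affine shift (scale 2, offset 0.5, extra noise sd 0.3) strong enough
that direct transfer visibly degrades while 1% fine-tuning (~24
postcodes) recovers performance to within 0.3 MAE of training from
scratch. Generator fidelity is checked at 2,000 LSOAs, where the
sampling error of an empirical correlation is well inside ±0.06.

## Numerical choices and edge cases

- Probability floor 1e-12 inside every log; gradients of the default
  parameterization are exact and floor-free.
- Batch-norm: ε = 1e-5, running-moment momentum 0.9; eval-mode forward
  before any training step is refused (no running moments exist).
- Decile ties: stable input order breaks ties, so generation and
  conversion are deterministic; remainder units go to the worst
  deciles first.
- Degenerate inputs refused with informative errors: < 10 areas for a
  decile cut, non-finite raw values (offender named), non-PSD
  correlation matrices, empty aggregation subsets, orphan postcodes,
  single-class label sets, fractions selecting zero postcodes, folds
  covering < 10 LSOAs.
- Seeds: every stochastic component derives an independent stream from
  its seed via `numpy.random.SeedSequence`; identical (config, seed)
  pairs give byte-identical output files.

## Known limitations

- The linear-weighted κ is invariant to shared distance-preserving
  relabelings of both vectors (shifts), not to arbitrary monotone
  relabelings, which change the |i−j| weights.
- The encoder layout of the original full-scale network (whether view
  channels shared weights, and the exact widths) is not public; both
  are configuration here, with shared weights and D→256→64 / 256→64→1
  as defaults.
- Fine-tune evaluation excludes fine-tuning postcodes (and
  from-scratch trains on the evaluation complement); a protocol that
  evaluates on all target postcodes would report slightly different,
  leakage-inflated numbers.
- The desk-scale training preset is tuned for ~2,400-postcode
  problems; much larger synthetic cities should use the replication
  preset or more iterations.
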