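# Methods

## Problem setting and model

`embedfuse` addresses representation selection for biomedical image
classification when several frozen pre-trained encoders are available.  Each
encoder `i` maps an image to an embedding `e_i ∈ R^{d_i}`; nothing is
fine-tuned.  The working hypothesis is that encoders trained on different
domains carry partly complementary, partly redundant information, so some
subset of them — fused into one vector — outperforms any single encoder on a
given task.

The default fusion is concatenation, `e_fused = [e_1; …; e_n]` with
`d_fused = Σ d_i`.  It is parameter-free and lossless: each model's features
occupy an isolated, contiguous sub-block (offsets are cumulative sums in
registration order), and the original blocks are recoverable bitwise.  No
cross-model normalisation is applied by default.  The downstream probe is a
gradient-boosted tree ensemble whose split decisions depend on the ordering
of feature values within each feature, so heterogeneous scales across blocks
do not bias it; an optional per-block z-scoring flag (`zscore_blocks`) exists
for scale-sensitive downstream learners and defaults off.

Subset selection is exhaustive.  For `n` registered models all `2^n − 1`
non-empty subsets are enumerated (by increasing size, then lexicographic
position; each subset internally in registration order), fused, and scored by
the validation accuracy of a probe with one fixed configuration.  Validation
accuracy is the only selection signal; AUC is reported but never drives the
choice.  The concatenation order is fixed at registration and never
permuted: optimising order as well as membership would multiply the space by
`n!` per subset for an effect that tree probes are largely insensitive to.
A `singles_only` mode restricts candidates to the `n` singletons; its winner
is the best individual backbone ("oracle-single"), the natural baseline for
quantifying what fusion adds.

Tie-breaking is deterministic: at equal validation accuracy the smaller
subset wins (a cheaper embedding generator for the same measured quality);
at equal size, the subset enumerated first.  Since enumeration is by size
then position, taking the first maximum in enumeration order implements both
rules.

## Probing and final evaluation

The search-phase probe is XGBoost with `n_estimators=250`,
`learning_rate=0.1`, `max_depth=6`, single-threaded and seeded so that every
fit is bit-reproducible.  Objectives follow the task: binary logistic for
two-class problems, multi-class softprob otherwise, and an independent
binary probe per label (one-vs-rest) for multi-label tasks.  Ordinal tasks
are treated as plain multi-class.  Multi-label "accuracy" is the mean
per-label binary accuracy (label decisions scored independently), which is
the convention consistent with multi-label benchmarks reporting accuracy far
above exact-match levels.

For final evaluation the probe is re-tuned per dataset: a budgeted search
(default 100 trials) over nine hyperparameters — `n_estimators` 50–1000,
`learning_rate` 0.01–0.3 (log-uniform), `max_depth` 3–10,
`min_child_weight` 1–10, `subsample` and `colsample_bytree` 0.5–1.0,
`gamma`, `reg_alpha`, `reg_lambda` 0–5 — selecting the configuration with
the highest validation accuracy.  Trial 0 always evaluates the default
configuration (missing axes filled with the booster's own defaults), so the
tuner can never return something worse than the fixed probe on validation.
The default sampler is a tree-structured density-ratio estimator: after a
10-trial random warm-up, trials are split into the top 25% and the rest,
per-parameter Gaussian KDEs `l(x)` (good) and `g(x)` (bad) are fitted, and
the candidate maximising `Π l/g` among 24 random draws is proposed.  A pure
random sampler is available behind the same interface.  Test metrics are
means over three probe seeds (`seed`, `seed+1`, `seed+2`), with per-seed
values retained in the report.

## Self-attention fusion

The learnable alternative replaces concatenation with multi-head
self-attention across per-model tokens: block `i` is linearly projected to
`proj_dim = n_heads × d_head` (default head width 64; head counts swept over
4, 8, 12, i.e. `proj_dim ∈ {256, 512, 768}`), the `n` tokens attend to each
other via scaled dot-product attention, and the output is mean-pooled over
tokens.  The head-count sweep keeps whichever `proj_dim` scores best on
validation with the fixed probe.

The training recipe is a design decision of this package: a temporary linear
softmax head on the pooled output, cross-entropy loss (per-label sigmoid
cross-entropy for multi-label), Adam at learning rate 1e-3, batch size 64,
at most 100 epochs with early stopping on validation accuracy at patience
10; the head is discarded after training.  No residual connections or layer
normalisation — at one token per model the network is shallow enough that
they buy nothing measurable at this scale.  The implementation is plain
numpy with hand-derived gradients; a finite-difference check in the test
suite pins the derivation to 1e-6.  Training is deterministic given the
seed.

## Synthetic data generator

The generator emulates the study conditions end to end: `K`-class samples
observed through `n` virtual models of differing informativeness.  For model
`m`, sample `i` with class `y_i`:

```
x_mi = s_m · mu[m, y_i] + w · z_i P_m + eps,   eps ~ N(0, noise_sd²)
```

* `mu[m, c]` — per-(model, class) mean direction, drawn once from a standard
  normal and normalised to unit length.  Unit norm makes `s_m` a
  signal-to-noise ratio independent of the block's dimensionality; without
  it, separation would grow as `√d` and every signal model would saturate
  the probe, erasing the fusion benefit the search is supposed to detect.
* `s_m` — per-model signal strength; 0 is a pure noise model.
* `z_i` — a 4-dim shared latent factor per sample, identical across models
  but projected through independent per-model maps `P_m`; its weight `w`
  (default 0.3) induces positive cross-model correlation, so fused subsets
  gain less than the sum of their parts — the redundancy that makes subset
  selection non-trivial.
* `noise_sd` — i.i.d. noise, default 1.0.

Defaults are the planted-truth study conditions used throughout the tests:
five models of 16 dimensions each, exactly two informative (`s = 2.0`) and
three pure noise, binary task, splits of 500/200/200.  At `s = 2.0` a single
informative model reaches roughly 0.88 validation accuracy and the fused
pair roughly 0.95, so recovery of the planted pair is expected but not
trivially forced.  Multi-label tasks plant one unit direction per label,
added for each active label.

Corruption is modelled at the embedding level: corruption id and model fix a
unit direction, and severity `v ∈ 1..5` applies an additive shift of `0.5·v`
along it plus extra noise of sd `0.4·v` to the *test split only*.  This
preserves the property the robustness metrics need — probe error monotone in
severity — without re-creating image-space artefacts.

What the generator does **not** emulate: real encoder embeddings are not
Gaussian mixtures, their informativeness varies per class rather than
globally, cross-model redundancy is not low-rank linear, and real corruption
effects are neither isotropic nor monotone by construction.  Passing tests
therefore demonstrate that the selection, fusion, caching and metric
machinery is correct under controlled conditions — not that any particular
encoder pool will show fusion gains on real data.

## Robustness metrics

Balanced error is `1 − mean(per-class recall)`.  For corruption benchmarks
with `C` corruptions at `S` severities (the canonical grid is 11×5 = 55
conditions), two reference-normalised scores are computed from a model's and
a reference model's balanced-error tables:

* `BE = mean_c [ Σ_s err_model(c,s) / Σ_s err_ref(c,s) ]`
* `rBE` — the same with `err − err_clean` in numerator and denominator.

The default aggregates severities within a corruption before taking the
ratio (the ImageNet-C-family convention); a literal mean over the 55
per-condition ratios is available as `aggregation="pair_mean"` because the
phrase "averaged over all pairs" is genuinely ambiguous.  Scores default to
the raw ratio scale (reference = 1); `scale_100` multiplies by 100.
Negative rBE is meaningful (the model's error increases less than the
reference's, or even decreases) and passes through unclamped.  Zero
reference denominators raise rather than silently yielding infinities.

## Caching and determinism

Embeddings are cached as NPY arrays with JSON manifests
(`<root>/<dataset>/<model>/<split>.npy` + `.manifest.json`) holding sample
IDs, labels, shape, and a SHA-256 of the array bytes; a mismatch raises an
integrity error rather than being treated as a miss.  Within a process a
memo guarantees each provider is invoked at most once per key, so a full
nine-model search costs 27 extractions against 511 subset evaluations.
Search results are identical with the cache on or off.

Every stochastic component (generator, probe, tuner, attention training)
takes an explicit seed; fixed seed plus single-threaded boosting implies
bit-identical reruns, and the pipeline persists its resolved config so a run
is reproducible from two files.

## Numerical and scale choices

Problem sizes in the tests and the acceptance script are desk-scale by
design: 4–16-dim blocks, hundreds of samples per split, 40–250 boosting
rounds.  These sizes keep the planted-recovery experiment (10 seeds × 31
subsets at the fixed probe) and the 511-subset cache experiment (lighter
40-tree probe, since that experiment measures extraction counts, not probe
quality) comfortably within a single-CPU session while leaving the
recovery margin well clear of chance.  The AUC implementation delegates to
scikit-learn's rank-based computation and is cross-checked against an
independent brute-force pairwise count (ties as one half) in the tests and
the acceptance script.  Attention-oracle comparisons use 1e-6 tolerance;
observed agreement is at machine precision.

## Known limitations

* Exhaustive search is exponential in the pool size; it is intended for
  pools of ~10 models.  No greedy or heuristic shortcut is provided.
* Real foundation-model adapters are an extension point (any callable
  `provider(split) -> EmbeddingSet`); the shipped providers are the
  synthetic generator and a flatten-pixels baseline for NPZ image bundles,
  so no pre-trained weights are downloaded or bundled.
* The attention block is trained on CPU in numpy; it is sized for desk-scale
  ablations, not for large-batch GPU training.
* Resuming a pipeline past the search stage is supported for concatenation
  only; a resumed self-attention run would need its fitted fusion block
  re-trained, so the pipeline refuses rather than silently refitting.
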