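# embedfuse

Model-agnostic fusion of frozen image-encoder embeddings for biomedical
classification.

Pre-trained image encoders ("foundation models") from different biomedical
subdomains — histopathology, radiology, OCT, and so on — each capture a
partial view of an image. `embedfuse` treats every encoder as a frozen
feature extractor and asks a purely combinatorial question: *which subset of
encoders, fused into one representation, yields the best task-specific
embedding?* It is aimed at practitioners who have (or can compute) per-model
embedding matrices for a labelled dataset and want an automatically selected,
reproducible fused representation — without fine-tuning any backbone.

## The method

Given embeddings `e_i ∈ R^{d_i}` from `n` registered models, the fused
representation of a sample is the feature-wise concatenation

```
e_fused = [e_1; e_2; …; e_n],      d_fused = Σ d_i
```

so a 512-dim and a 768-dim block fuse into a 1280-dim vector.  Concatenation
is parameter-free, preserves every model's features in an isolated sub-block,
and needs no cross-model normalisation — the downstream probe is a
gradient-boosted tree ensemble (XGBoost) whose splits depend on feature
ordering, not scale.

Model selection is exhaustive: all `2^n − 1` non-empty subsets (511 for a
nine-model pool) are fused and scored by the validation accuracy of a probe
with a fixed configuration (250 trees, learning rate 0.1, depth 6); the
highest-scoring subset wins, with ties broken toward fewer models.  An
on-disk cache guarantees each model's embeddings are extracted at most once
per split — 27 extractions back 511 subset evaluations for nine models.  The
winner becomes a reusable embedding generator for new splits; a budgeted
hyperparameter search (100 trials over nine XGBoost parameters) then tunes
the final classifier, and test metrics (accuracy, AUC-ROC) are averaged over
three probe seeds.

Also included:

* a learnable **self-attention fusion** alternative — one token per model,
  projected to `proj_dim = n_heads × 64`, mixed by multi-head scaled
  dot-product attention and mean-pooled — implemented in pure numpy with a
  head-count sweep over {4, 8, 12};
* **robustness metrics** for corruption benchmarks: balanced error, plus the
  reference-normalised scores BE (mean per-corruption ratio of
  severity-summed balanced errors) and rBE (same construction on the error
  *increase* over the clean test set; legitimately negative when the model
  degrades less than the reference);
* a **synthetic multi-model generator** that plants class signal in a chosen
  subset of "virtual models" with controllable cross-model redundancy and an
  embedding-level corruption mechanism, so the whole pipeline is testable
  with no external data or downloads.

## Worked example

```python
import embedfuse as ef

# five virtual models (16-dim each): two informative, three pure noise
dataset = ef.generate(ef.SyntheticConfig(seed=0))
registry = ef.Registry()
dataset.register_all(registry)

result = ef.run_search(registry, probe_config=ef.ProbeConfig(), seed=0)
print(f"selected subset : {'+'.join(result.selected)}")
print(f"valid accuracy  : {result.selected_accuracy:.3f}")
print(f"best singleton  : {result.best_singleton_accuracy():.3f}")
print(f"subsets scored  : {result.n_evaluated}")

model = ef.build_fusion_model(result, registry)
train, test = model.transform("train"), model.transform("test")
report = ef.score_multi_seed(train, train.labels, test, test.labels,
                             ef.ProbeConfig(), n_runs=3)
print(f"test accuracy   : {report.accuracy:.3f}")
print(f"test AUC        : {report.auc:.3f}")
```

Output:

```
selected subset : synth0+synth1
valid accuracy  : 0.955
best singleton  : 0.885
subsets scored  : 31
test accuracy   : 0.900
test AUC        : 0.970
```

The search scored all 31 subsets of the five models and selected exactly the
two planted informative models (`synth0`, `synth1`); their fused 32-dim
representation beats the best single model by 7 accuracy points on
validation, and the final probe reaches 0.97 test AUC averaged over three
seeds.

The same pipeline runs from the shell:

```bash
embedfuse synth --out cache --seed 5
embedfuse search --cache cache --dataset synthetic --seed 5 --out leaderboard.csv
embedfuse run --cache cache --dataset synthetic --out run --seed 5
embedfuse report run
```

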