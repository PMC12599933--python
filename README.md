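# vteal

Active-learning and small neural classifiers for venous-thromboembolism
(VTE) imaging-report classification, bundled with a synthetic radiology
report generator so every experiment runs fully offline.

Reports are classified into seven anatomical classes (`No DVT or PE`,
`PE only`, `Proximal DVT`, `Distal DVT`, `Thrombophlebitis`, `Other DVT`,
`DVT and PE`). The package provides:

* **`vteal.data_model`** — record/corpus types, CSV and JSON-lines I/O,
  seeded (optionally stratified) 8:2 train/test splitting, 7-class to
  6-class restriction.
* **`vteal.synthetic_reports`** — a template-based generator whose default
  configuration reproduces the study-profile composition exactly
  (5,839 reports, 1,088 VTE-positive, per-class counts by deterministic
  largest-remainder apportionment, modality mix, 65.0% ICD-10 concordance
  among positives).
* **`vteal.embeddings`** — tokenization, term-frequency and smoothed
  TF-IDF vectorization, deterministic dense document embeddings
  (co-occurrence PPMI-SVD word-vector averaging, and latent-semantic
  per-document vectors), cosine similarity.
* **`vteal.query_strategies`** — random, least-confidence, margin,
  entropy, Length-Words, word/TF-IDF similarity novelty, and the combined
  word-similarity uncertainty strategies.
* **`vteal.al_loop`** — the epoch protocol: 8 seed labels, one query per
  iteration, retrain-from-scratch (RF / SVM / SVM-SGD / GBM), macro-F1 on
  a fixed test set, repeated over epochs and aggregated into learning
  curves.
* **`vteal.deep_models`** — NumPy implementations of an LSTM and 1D-CNN /
  multi-kernel 1D-CNN text classifiers (256-token pad/truncate encoding,
  Adam, early stopping at <1e-4 validation-accuracy improvement for two
  consecutive epochs, stratified 5-fold CV, 6- vs 7-class scenarios), an
  inference-timing harness, and a plug-in contract for external
  transformer classifiers.
* **`vteal.evaluation`** — per-class precision/recall/F1 with explicit
  zero-division conventions, macro/weighted/micro aggregation,
  composition and concordance summaries, learning-curve aggregation.

Note: the F1 averaging used for aggregate scores defaults to **macro**
(configurable); under heavy class imbalance the choice is material.

## CLI

```sh
# synthetic corpus with the default (study-profile) composition
vteal generate --out corpus.csv --seed 1

# Table-style composition + ICD-10 concordance report
vteal summarize corpus.csv --json summary.json

# active-learning curves (YAML config: corpus, ALConfig fields, runs list)
vteal run-al --config al.yaml --out curves/

# cross-validated neural models
vteal run-dl --config dl.yaml --out dl_results.json

# score a prediction file (id,label CSV) against gold labels
vteal evaluate --truth corpus.csv --predictions preds.csv
```

Every command writes a `*.manifest.json` recording the resolved config,
master seed and file digests; deterministic runs re-execute to identical
outputs. Exit codes: 0 success, 2 configuration error, 3 missing optional
dependency, 1 otherwise.

Example `al.yaml`:

```yaml
corpus: corpus.csv
epochs: 10
budget: 108          # absolute labeled-count target (<1 = pool fraction)
master_seed: 1
embedding: tf        # tf | tfidf | word_average | document
classifier: {family: random_forest}
runs:
  - {name: random,  strategy: {name: random}}
  - {name: margin,  strategy: {name: margin}}
  - {name: wordsim, strategy: {name: word_similarity}}
```

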