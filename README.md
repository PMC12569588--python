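# ppibias

Bias-aware evaluation of protein–protein interaction (PPI) classifiers.

Randomly split PPI benchmarks reward classifiers for memorising each
protein's *positivity* — the fraction of its interactions labeled positive —
rather than for learning anything about interactions. `ppibias` provides the
machinery to measure and correct that inflation:

- **`ppibias.metrics`** — raw Matthews correlation coefficient (MCC) and the
  per-protein utility metric **pp_MCC**: validation predictions are pooled
  across outer CV folds, each protein is scored on the confusion submatrix of
  the interactions involving it, proteins lacking actual positives or actual
  negatives are skipped, and the remaining per-protein MCCs are averaged
  weighted by validation interaction counts. A predictor that is constant per
  protein scores 0. F1 / balanced accuracy / Youden variants share the same
  per-protein machinery, and a paired t-test compares matched metric vectors.
- **`ppibias.splits`** — random interaction folds and **unseen-protein
  folds** (every training interaction touching a validation protein is
  removed), plus nested CV plans (inner folds reuse the outer mode; defaults
  random 3/3, unseen 50/40).
- **`ppibias.learners`** — KNN / logistic-regression / random-forest families
  with their benchmark hyperparameter grids, inner-CV grid search (MCC
  criterion), and the **positivity baseline** that predicts from learned
  per-protein positivity alone (`single_item` / `pair_mean` modes).
- **`ppibias.features`** — pair features from per-protein embeddings:
  concatenation, elementwise addition, elementwise multiplication.
- **`ppibias.synthetic`** — a generator for datasets with controllable
  per-protein positivity bias (pure single-class fraction, Beta-distributed
  target positivity, heavy-tailed degrees, optional positivity homophily,
  latent interaction signal) and matching identity/signal embeddings.
- **`ppibias.data_model`** — interaction TSV + FASTA I/O, composition
  summaries, gold-standard (train/validation/test) loading with
  protein-disjointness verification.
- **`ppibias.experiment`** — run matrices, the bias study, figures, CLI.

## CLI

```bash
# synthetic biased dataset + embeddings
ppibias generate --n-proteins 500 --n-interactions 10000 --seed 1 --out-dir scratch/demo

# composition statistics (positivity skew, single-class percentage)
ppibias summarize scratch/demo/interactions.tsv

# experiment matrix from a YAML config (see ExperimentConfig)
ppibias run --config config.yaml

# the inflation demonstration: {random, unseen} x {MCC, pp_MCC} + baseline
ppibias bias-study --seed 1 --out-dir scratch/bias

# figures from a results table
ppibias report --results scratch/bias/bias_study_cells.csv --out-dir scratch/figs
```

A typical bias-study result on identity-only synthetic data: random-split
raw MCC ≈ 0.4 while random-split pp_MCC and unseen-split raw MCC are both
near 0 — the random-split score is almost entirely positivity bias, and the
positivity baseline alone reaches the same raw MCC.

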