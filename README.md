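# butyrsite

Sequence-based prediction of histone lysine **butyrylation** sites.

Butyrylation is a recently characterised histone post-translational
modification with only a few dozen experimentally verified sites, so a
predictor has to work in an extreme small-sample regime. `butyrsite`
implements an information-entropy approach suited to it: every
candidate lysine is represented by the (2N+1)-residue window around it
(X-padded at protein termini), encoded by

- **IEE** — the variation of the Shannon entropies of the positive and
  negative training "systems" when the fragment is added to each. With
  per-position residue probabilities `P^i(α)`, the per-residue entropy
  is `IEA(α) = Σ_i −P^i(α) log₂ P^i(α)` and the per-position entropy
  `IEP(i) = Σ_α −P^i(α) log₂ P^i(α)`; the fragment's features are the
  differences of the entropy variations between the two systems,
  21 + (2N+1) values (48 at the default N = 13); and
- **CKSAAP** — the composition of k-spaced amino-acid pairs: ordered
  pair frequencies for gaps 0..k_max over the 21-letter alphabet,
  (k_max+1)·441 values (882 at the default k_max = 1),

then min–max normalized (parameters fitted on training data only) and
classified by a 100-tree random forest. Evaluation is stratified 3-fold
cross-validation with pooled-score ROC/AUC plus an independent test,
with harnesses for the window-size sweep (N ∈ 10..15) and feature
ablations. A synthetic-data module generates lysine-rich proteins with
a planted positional motif so the whole pipeline is testable offline,
and an analysis module exports sequence-logo, two-sample-logo,
entropy-profile and pair-heatmap statistics as TSV tables.

The scikit-learn estimator API is used throughout: `IEEEncoder` and
`CKSAAPEncoder` are transformers, `ButyrylationClassifier` a classifier
with `fit`/`predict_proba`, so everything composes with sklearn model
selection. See `docs/methods.md` for the model details and design
choices.

## Worked example

```bash
butyrsite simulate --out data --seed 42            # synthetic FASTA + sites TSV
butyrsite evaluate --fasta data/sequences.fasta --sites data/sites.tsv \
    --N 13 --seed 42 --out eval.json
```

prints

```
cross-validation AUC: 0.953
```

— the stratified 3-fold cross-validation AUC on a 35-fragment dataset
(17 butyrylated, 18 background) whose positives carry the default
planted motif; `eval.json` holds the full ROC curve, fold assignments
and config echo. Training a model and scoring candidate sites:

```bash
butyrsite train --fasta data/sequences.fasta --sites data/sites.tsv \
    --N 13 --seed 42 --model model
butyrsite predict --fasta data/sequences.fasta --sites data/sites.tsv \
    --model model --out pred.tsv
head -4 pred.tsv
```

```
protein_id	position	score	predicted_label
syn_pos0001	6	0.95	positive
syn_pos0002	23	0.93	positive
syn_pos0003	24	0.98	positive
```

`score` is the forest's positive-class vote fraction; labels use the
default 0.5 threshold. Note these training sites are scored by the
model that saw them — held-out performance is what `evaluate` (CV) and
`evaluate --test-fasta/--test-sites` (independent test) measure.
`butyrsite sweep --N 10:15`, `butyrsite ablate` and `butyrsite analyze`
run the window sweep, the feature ablation and the descriptive
statistics; `--help` lists every command.

The same pipeline from Python:

```python
from butyrsite import (build_dataset, cross_validate, generate_paper_scale)

data = generate_paper_scale(seed=42)
train = build_dataset(data.train_sequences, data.train_sites, 13)
print(cross_validate(train, folds=3, seed=42).auc)
```

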