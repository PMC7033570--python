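# Methods

## Problem

Histone lysine butyrylation is a post-translational modification (PTM)
for which experimentally verified sites are scarce — tens, not
thousands. `butyrsite` implements a sequence-based predictor suited to
that regime: fixed-width windows around candidate lysines, two
low-variance hand-crafted encodings, min–max normalization, and a
random forest, evaluated by stratified cross-validation and an
independent test with ROC/AUC.

## Fragments

Every candidate site is the lysine at the center of a window of
2N + 1 residues (default N = 13, window length 27). Where the window
overhangs a protein terminus the deficit is filled with the padding
symbol `X`, so the working alphabet has 21 letters: the 20 standard
amino acids in alphabetical one-letter order, then `X`. Input FASTA
containing non-standard residues (B, J, O, U, Z, `*`, or a literal X)
is rejected by default (`policy="strict"`); `policy="mask"` remaps them
to `X`. Site tables are 1-based TSV (`protein_id`, `position`,
`label ∈ {positive, negative, unlabeled}`); duplicate rows keep the
first occurrence with a warning.

## Entropy-variation encoding (IEE)

Each training class defines a stochastic "system": the 21 × (2N+1)
matrix of per-position residue probabilities `P^i(α)`, estimated as raw
occurrence frequencies over that class's training fragments (no
pseudocounts). Two entropy families summarise a system:

- per residue: `IEA(α) = Σ_i −P^i(α) log P^i(α)` — how dispersed one
  residue's usage is across window positions;
- per position: `IEP(i) = Σ_α −P^i(α) log P^i(α)` — how uncertain the
  residue identity is at one position;

with `0·log 0 := 0`. A fragment *s* is encoded by the entropy variation
it induces when added to each system (frequencies re-estimated over
n + 1 samples): per residue, `ΔIEA(α) = IEA(α) − IEA_s(α)`, computed
against both the positive and the negative system; the feature is the
difference of the two variations, and likewise per position. The
encoding has 21 + (2N+1) dimensions (48 at N = 13). A fragment that
"looks like" the butyrylated class perturbs that class's entropies
less, so the signed differences separate the classes.

Numerical choices:

- **Logarithm base**: 2 (bits) by default, configurable via
  `log_base`. The base rescales every entropy feature by the same
  constant and is therefore absorbed by the min–max normalization; the
  choice only affects reported entropy profiles.
- **Training-fragment encoding**: training fragments are encoded with
  the same transform as unseen fragments — the fragment is added to
  the system that already contains it. A leave-one-out variant
  (`IEEEncoder.transform_training`) removes the fragment from its own
  class first; it is exposed for sensitivity analysis and not used in
  the default pipeline, keeping a single consistent transform.
- **No leakage**: systems are estimated from training fragments only.
  Inside cross-validation the systems, the normalizer and the forest
  are re-fitted per fold from the fold's training part; this is
  asserted in tests from the system count matrices.

## k-spaced pair composition (CKSAAP)

For each gap k = 0..k_max (default k_max = 1), the encoder counts every
ordered pair `(window[j], window[j+k+1])` over the 21-letter alphabet —
`X` counts like any residue — and divides by the number of available
pair positions, `L − k − 1`, so each gap block is a proper frequency
distribution. Length: `(k_max+1) · 441` (882 at k_max = 1). Raw counts
versus per-gap frequencies only rescale features ahead of min–max
normalization; the frequency convention is the standard one and is the
package's documented choice.

## Normalization and classifier

Features are min–max normalized with parameters (per-feature min and
max) fitted on the training matrix only. Test values outside the
training range are clipped to [0, 1]; constant features map to 0
(divide-by-zero guard). The classifier is a random forest with 100
trees, `sqrt(M)` features per split, unlimited depth, and an explicit
seed; all hyperparameters are recorded in the saved model bundle. The
positive-class vote fraction is the prediction score; the default
decision threshold is 0.5.

## Evaluation protocol

- **Cross-validation**: stratified 3-fold (stratification avoids
  degenerate single-class folds at n = 35), pooled scores over folds on
  a single ROC curve — one curve per experiment rather than per-fold
  averaging.
- **ROC/AUC**: threshold sweep groups tied scores; AUC follows the
  Mann–Whitney convention (ties count 1/2), so constant scores give
  exactly 0.5 and perfect separation 1.0. Verified exactly against
  exhaustive pair counting in tests.
- **Independent test**: train on the training split, score the test
  split once.
- **Window sweep**: N ∈ {10..15}, the customary range for lysine-PTM
  predictors, re-extracting fragments and re-running cross-validation
  per N; the package default is N = 13.
- **Ablation**: cross-validation with the IEE block alone, the CKSAAP
  block alone, and both, sharing fold assignments so the comparison
  isolates the encoding.

## Synthetic data

`butyrsite.simulate` generates the fixture datasets all experiments and
tests run on. It emulates a small histone-butyrylation study: each site
lives in its own short lysine-rich host protein; positive windows are
drawn from per-position residue distributions carrying a planted motif,
negative windows from a uniform background over the 20 amino acids
(background entropy near-maximal, as real non-butyrylated fragments
show); `K` is forced at the center; a configurable fraction of sites
(default 15%) is placed within N residues of a terminus so the
X-padding path is exercised (`X` never arises any other way). The
default motif mirrors the conservation pattern reported for real
butyrylated histone fragments — alanine enriched at window positions
3, 6, 12, 13 and 26, lysine at 5, 10, 18, 21 and 24, glycine at 9, 11
and 22, arginine at 25 (1-based, center 14) — each motif residue at
probability 0.5 against the uniform 0.05 background, the conservation
level a strong logo stack displays. The `generate_paper_scale` preset
uses the study's sample sizes: 17 positive + 18 negative training
sites, 9 positive + 18 negative test sites, N = 13.

What the generator does **not** emulate: histone sequence homology and
phylogeny, compositional biases of real proteomes, multiple sites per
protein, and label noise. Passing tests on synthetic data therefore
demonstrate that the pipeline recovers a planted positional signal at
realistic sample sizes and stays at chance when none exists — not that
the published real-data accuracy transfers to new proteomes.

## Descriptive analyses

`butyrsite.analysis` exports the tabular counterparts of the standard
visual diagnostics: per-position residue frequencies with information
content `log2(21) − IEP(i)` (sequence logo), per-(position, residue)
two-proportion z-tests at α = 0.05 between classes (two-sample logo;
degenerate cells where both proportions are 0 or 1 are reported as
z = 0, p = 1), the four entropy series PIEA/NIEA/PIEP/NIEP computed
with the same code path as the encoder, and mean k-spaced pair
frequency matrices (heatmaps). Rendering is intentionally left to the
caller; every statistic is a TSV.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic
data at the study's own scale (35 training and 27 test fragments,
N = 13, 100-tree forests); multi-seed averages use 10 seeds for motif
recovery and 20 for the null control, and the goodness-of-fit check on
the generator uses 2000 windows. These sizes are the package's chosen
study conditions, matching the small-sample regime the method was
designed for.

## Known limitations

- Frequencies are maximum-likelihood with no smoothing; with tens of
  training fragments many probability cells are 0 and entropy features
  are coarse. That is intrinsic to the method, not a defect of the
  implementation.
- AUC on 35-fragment datasets has high seed-to-seed variance; all
  reported numbers are either multi-seed averages or carry their seed.
- The two-proportion z-test is a large-sample approximation applied to
  small counts; treat flags as descriptive, as the two-sample-logo
  convention does.
- Real-data performance depends on the Weka-era training details
  (forest settings, seeds) that are not recoverable; with equivalent
  forests the numbers are reproducible in distribution, not bitwise.
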