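# Methods

## Model

The chemical language model is an autoregressive next-token network over
SMILES tokens: embedding (default 64 dimensions) → batch normalization →
stacked LSTM layers (reference configuration 1024 + 256 units; a variant
with three 1024-unit layers is expressible through `recurrent_layers`) →
batch normalization → dense projection to vocabulary logits. It is
implemented directly in NumPy (forward pass, full backpropagation through
time, Adam) and verified against numerical differentiation in the test
suite; the architecture scales down to the toy configuration (embedding
16, one 64-unit layer) used throughout the tests.

Sequences are teacher-forced as `start + tokens + end` with post-padding;
the cross-entropy loss and the batch-normalization statistics are both
restricted to non-padded positions (padding cannot leak into the loss
because the recurrence is causal). The forget-gate bias is initialized
to 1; other weights use Glorot-uniform initialization from a seeded
generator, so model construction is fully reproducible.

### Tokenization

SMILES are segmented at atom level: bracket atoms (`[nH]`, `[N+]`, …),
two-letter halogens (`Cl`, `Br`) and two-digit ring closures (`%nn`) are
single tokens, everything else is one character. The vocabulary is the
sorted token union of the corpus plus three sentinels (pad, start, end).
`N` in the perplexity formula counts the scored positions — the chemical
tokens plus the terminating end sentinel, whose probability is part of
the model's judgment of a design. With this convention a uniform model
over a vocabulary of size V has perplexity exactly V for any sequence,
and PPL = 1 exactly when every realized token has probability 1.

### Training variants

* **canonical** — one canonical SMILES per molecule; dropout 0.2 on LSTM
  outputs; learning-rate reduction on plateau (factor 0.5, patience 3,
  floor 1e-4, minimum improvement 1e-4).
* **augmented** — ten randomized SMILES per molecule, fixed before
  training; same dropout and schedule as canonical.
* **randomized** — one fresh randomized SMILES per molecule re-drawn
  every epoch; no dropout; constant learning rate.

Pretraining defaults are 40 / 20 / 100 epochs for the three variants at
an initial learning rate of 1e-3; fine-tuning stages run 100 epochs at
1e-4 with 10% of the molecules (canonical forms) held out for
validation. After every stage the model — weights *and* Adam moments and
learning rate — is restored to the epoch with the minimum validation
loss; the randomized variant instead minimizes a 10-epoch trailing
moving average (best-mean window, earliest on ties; within that window
the epoch with the lowest raw loss, earliest on ties) because its
per-epoch loss is noisier. Incremental fine-tuning chains stages over
the potency-ordered subsets of a split, starting each stage from the
restored checkpoint of the previous one, so the learning rate in effect
at the restored epoch travels into the next stage.

Batch size defaults to 128. SMILES randomization permutes atom order
with a seeded generator and writes the non-canonical string, so
augmentation is reproducible and every randomized form canonicalizes
back to its source.

## Standardization and curation

`standardize_smiles` keeps the largest carbon-containing fragment
(ties: heavy atoms, then molecular weight), clears isotopes and
stereochemistry, neutralizes simple ionizable groups via RDKit's
Uncharger (permanently charged centers such as quaternary nitrogen are
kept), and rejects molecules longer than 140 tokens (checked first) or
heavier than 1000 Da, with machine-readable reasons.

Reference corpora are made ignorant of a target by removing annotated
ligands and every molecule with Tanimoto similarity strictly above 0.4
(Morgan, radius 2, 2048-bit) to any target ligand. SAR series use
radius-3 fingerprints: members whose *mean* similarity to the rest falls
below 0.5 are dropped iteratively (the outlier rule is read as mean, not
maximum, which is more stable on small series), then the series must
keep ≥ 25 members with mean internal pairwise similarity ≥ 0.3.

Splits: `values` makes k contiguous potency-ordered groups of equal
size, spreading any remainder over the *lowest*-potency groups so the
most-active step is never diluted; `focused` uses halving sizes ending
at the most potent group (the final group holds `n // (2^k - 1)`
records, leftovers join the first group); `scaffold` trains first on the
deduplicated Murcko scaffolds, then on the full molecules; `best` keeps
only the most-active values group; `all` is the classical single-stage
baseline. Holdout extraction withholds the most potent
`ceil(fraction · n)` records (default 25%), breaking potency ties by
canonical-SMILES order so the extraction is deterministic.

## Sampling, ranking and filtering

Designs are generated token-by-token by multinomial draws from the
temperature softmax until the end sentinel or 140 tokens. Strings that
hit the cap without terminating are counted invalid (a truncated
molecule is not trustworthy), as are unparsable strings and — a
deliberate choice — emissions whose RDKit-canonical form contains a
bracket token outside the model vocabulary, since such designs cannot be
scored. Valid designs are standardized and aggregated by canonical
SMILES, so duplicate identity is molecule identity, not raw-string
identity.

Ranking removes fine-tuning molecules and sorts ascending by perplexity
(augmented/randomized variants average PPL over 10 randomized forms);
ties break by higher sampling frequency, then lexicographically. The
prospective filter cascade applies, in order: a naive-model perplexity
floor (default 1.012 — a corpus-specific calibration exposed as
configuration), known-molecule lists, the classical-baseline top list,
substructure/isomer removal against the training set (isomer = same
molecular formula; substructure = subgraph of a training molecule), a
maximum-Tanimoto cap, substructure blacklists plus an optional maximum
ring size (any SSSR ring with more members is rejected), and finally a
stable partition that moves priority-pattern matches (e.g. sulfonamides)
to the front. Every removal is logged with exactly one rule.

## Evaluation

* **Rediscovery score** — multiplicative composition
  `(N_R/k) · (ΣF_R/ΣF_k) · (N_R/N_hold)` of the three factors, giving a
  score in [0, 1] that is zero exactly when nothing is rediscovered and
  compensates the extremes (many rare hits vs one frequent hit). The
  multiplicative reading of the three factors is a documented design
  choice.
* **Sampling statistics** — validity = parsable / emitted, uniqueness =
  unique canonical / valid, novelty = unique not in the reference set /
  unique. Which corpus counts as "the training set" is a caller choice.
* **Distributional similarity** — S_FCD = exp(−0.2·FCD) with the FCD
  supplied by an optional external backend; S_KL = (1/D)·Σ exp(−KL_d)
  over ten descriptors: Bertz complexity, logP, molecular weight, TPSA
  and maximum internal Tanimoto similarity (continuous; Gaussian KDE with
  Scott's-rule bandwidth on a shared 1000-point grid), plus H-bond
  acceptors/donors, rotatable bonds, aliphatic and aromatic ring counts
  (discrete; shared 10-bin histograms). KL(generated ‖ reference) uses a
  1e-10 density floor; a zero-variance continuous descriptor falls back
  to the histogram estimate with a warning.
* **Potency–perplexity regression** — ordinary least squares of −log10
  potency on mean perplexity (statsmodels), reporting slope, two-sided
  p and R²; constant perplexity returns a flagged degenerate result
  (slope 0, R² 0, p 1).

## The toy world

The synthetic space decorates a benzimidazole-like scaffold at three
positions with six short fragments each (216 enumerable molecules).
Pseudo-potency is `baseline (6.0) + Σ per-(position, fragment)
contributions (uniform ± 0.6 log units) + sparse pairwise interaction
terms (four pairs, ± 0.8)` — the interactions are the long-range
substituent dependencies a sequence model must capture — plus Gaussian
noise of 0.15 log units, small enough that the potency ordering used for
splitting is mostly preserved, as in curated assay data. Everything is
deterministic given the seed, so brute-force potency ranking is an exact
oracle for model-based claims.

A benchmark bundle samples a 60-molecule series spanning ≥ 2 log units,
generates a ~2000-molecule pretraining corpus from a disjoint
template/fragment grammar, verifies corpus ignorance with the same
0.4-similarity filter used for real corpora, and withholds the top-25%
most potent members as ground truth.

What the toy world does *not* emulate: assay heterogeneity, activity
cliffs outside the planted interactions, scaffold diversity within a
series, and the scale of real pretraining corpora. Passing the toy
benchmark therefore shows that the training, ranking and scoring
machinery behaves as designed and that staged fine-tuning concentrates
probability mass on the high-potency region of a controlled landscape —
not that any particular real-world potency gain is reproduced.

## Benchmark problem sizes and observed behavior

The retrospective toy benchmark pretrains the toy model (embedding 16,
one 64-unit LSTM layer) for 40 canonical epochs on the ~2000-molecule
corpus and runs five seeded repeats of incremental (values-split, k = 4,
100 epochs per stage at 1e-4) versus classical single-stage fine-tuning,
sampling 2048 designs per repeat and scoring the top 30. These sizes
keep a full run in the low minutes on one CPU. In this regime the
incremental strategy consistently attains a higher mean rediscovery
score than the classical baseline, and the mean holdout perplexity falls
from stage to stage in at least four of five runs; the test suite and
`scripts/acceptance.py` recompute both claims from scratch.

## Known limitations

* The NumPy implementation is CPU-bound and intended for desk-scale
  experiments; reproducing corpus-scale pretraining (hundreds of
  thousands of molecules, 1024-unit stacks) is out of scope.
* Validation splits on small fine-tuning subsets contain only one or two
  molecules, so canonical-variant epoch selection is noisy; the
  moving-average rule of the randomized variant or larger subsets
  mitigate this.
* The FCD backend (ChemNet) is pluggable and not bundled; only the
  similarity transform is provided.
* Rates such as the 1.012 naive-perplexity floor are calibrated to a
  specific pretraining corpus and must be recalibrated when the corpus
  changes.
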