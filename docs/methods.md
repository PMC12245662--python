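# Methods

This note records the model, the parameter choices and the numerical
decisions behind `hyperstab`, including every place where the design was
genuinely open.

## Model and procedure

The benchmark treats a classifier implementation as a stochastic map from
(training split, feature subset, internal seed) to a fitted model, and asks
how much of the validation-AUC variation is attributable to the *internal*
randomisation alone. External randomness (which samples, which features) is
held fixed within a grid cell: the q replicates of a cell share the training
partition and the signature and differ only in their derived seed.

Stages, with the containers that carry them:

1. **Feature selection** (`feature_selection`) — variance prefilter on
   log2(x+1) values retaining a configured count; per-resample rankings from
   averaged impurity (MDG-analog) and permutation (MDA-analog) importances,
   combined by mean-of-ranks; the selected size Nv′ is the smallest
   candidate whose top-size subsets meet the Kuncheva and Spearman floors
   across balanced resamples.
2. **Signature planning** (`signature_planning`) — three distinct uniform
   subsets per size in {2, …, Nv′ − 1}, S = 3·(Nv′ − 2) total.
3. **Resampling** (`resampling`) — k stratified splits at rate P; per class
   round-half-up(P · class size) training samples without replacement.
4. **Grid execution** (`benchmark_engine`) — S·k·q fits per backend; AUC
   against the declared positive class; wall time per fit+predict.
5. **Scoring** (`stability_scores`) — CV per cell, stable matrix at
   threshold t, HR/HS vectors, HRS/HSS (t = 0) or RRS/RSS (t > 0)
   aggregates, dot-matrix dependency typing.

## Tunable parameters

| parameter | default | units / meaning |
|---|---|---|
| k | 50 | partitions per benchmark |
| q | 25 | replicate models per (signature, partition) |
| P | 0.5 | training fraction per class (0.9 for OOB tuning) |
| t | 0.0 | CV threshold; 0 = hyper-stability, >0 = relative stability |
| ntree | 500 | trees per forest |
| plateau_tolerance | 0.005 | absolute OOB-error band for ntree selection |
| kuncheva_floor, spearman_floor | 0.6, 0.6 | stability floors for size selection |
| row/col_gap_frac, min_density | 0.2, 0.2, 0.05 | dot-matrix typing thresholds |

k = 50, q = 25, P = 0.5 (0.9 for tuning) and t = 0 are the canonical study
conditions; the reduced scales used in the test suite (k = 5, q = 5, S = 12,
tens of samples) are this package's own desk-scale choices so that the full
pipeline runs in seconds while exercising every code path.

## Decisions where the design was open

* **Signature size range.** "Three signatures per size" is impossible at the
  top size Nv′ (only one subset exists), and only the range 2..Nv′−1 is
  consistent with the closed-form count 3·(Nv′ − 2) and with the known
  per-cohort counts (21/78/108). The planner therefore uses 2..Nv′−1; the
  prose-vs-formula tension is resolved in favour of the arithmetic and
  documented here rather than silently.
* **CV denominator.** Sample standard deviation (n−1). The alternative
  (population sd) shifts CVs by ~2% at q = 25, which is material at
  thresholds of 0.002–0.008, so the choice is fixed and stated.
* **Exact equality at t = 0.** A cell is hyper-stable iff all q AUCs are
  bit-identical — no epsilon. AUC on a finite validation set is a ratio of
  integer counts, so exact equality is well-defined;
  `coefficient_of_variation` special-cases identical inputs to return
  exactly 0.0 so no floating-point residue can leak into the dot matrix.
* **Aggregates on an all-false matrix.** HRS/HSS are defined as 0 rather
  than NaN: total instability is a meaningful worst score. A singleton
  non-zero HR/HS entry contributes the mean of one value, taken literally.
* **ntree plateau rule.** "Optimised and stabilised" is operationalised as:
  smallest grid value whose mean OOB error is within `plateau_tolerance` of
  the grid minimum *and remains* within it at every larger grid value. The
  default tuning grid is {10..100 step 10} ∪ {150..1200 step 50}; the finer
  full ladder is available through configuration but costs k·q fits per
  point.
* **Rounding in stratified splits.** Round-half-up (⌊x+0.5⌋), which gives 48
  of 96 at P = 0.5 and 44 per class of 49 at P = 0.9 — a documented,
  deterministic rule.
* **Pair handling in resampling.** `pair_aware` co-samples the two members
  of a pair but defaults to off: a paired design does not by itself imply
  pairs were kept together during resampling, so the behaviour is an
  explicit flag rather than a guess.
* **Rank aggregation and stability floors.** Impurity and permutation
  importances are combined by mean-of-ranks (scale-free, standard); the 0.6
  floors for Kuncheva/Spearman are defaults, not constants — whether other
  combinations (rank product, weighted ranks) perform better is an open
  question, so everything is parameterised.
* **Dependency typing thresholds.** The Type A/B/C call is inherently a
  judgment about a picture; the implementation makes it reproducible with
  three explicit thresholds (blank-row fraction, blank-column fraction,
  minimum density) that default to 0.2/0.2/0.05 and are configurable.
* **Importance ties.** Broken by ascending feature id after mean-of-ranks,
  so rankings are deterministic. On noise-only data this makes the *order*
  reproducible per seed while first place still diffuses across features
  over independent seeds.
* **Frozen backend.** `random_forest_frozen` is the same estimator as
  `random_forest` but the engine derives its replicate seeds without the
  replicate index, so its q replicates are identical by construction. It is
  the positive control for the scoring pipeline (HRS = HSS = 1 on any
  dataset) and the reference point for a perfectly self-reproducible
  implementation.

## Seed discipline

All randomness flows from one base seed through
`derive_seed(*context) -> 31-bit int` (BLAKE2 over the context path): grid
cell (seed, backend, signature id, partition, replicate), tuning fit,
partition draw, plan draw, synthetic dataset. Streams are independent but
fully reproducible across processes; parallel (`n_jobs > 1`, thread pool)
and serial execution produce identical tensors.

## Synthetic data: what it does and does not emulate

The generator produces 2·n_pairs samples (one case + one control per pair)
with log-normal marginals: log2 values are a per-feature baseline
(Uniform(3, 8)) plus an optional shared per-pair intercept, a class shift of
`effect_size` noise-SDs on the informative features, and block-correlated
Gaussian noise (blocks of `block_size` features at correlation
`within_block_corr`). Exponentiation gives strictly positive, right-skewed
RPKM-like values.

It emulates: balanced paired designs, tunable separability (effect_size 0 ⇒
chance AUC; ≥6 ⇒ perfect separation in practice), co-expression-like block
correlation, and the three cohort shapes (96/182/98 samples with 9/28/38
post-selection features, so the planner reproduces 21/78/108 signatures).

It does not emulate: count-based noise (sequencing depth, zero inflation),
normalisation artefacts, batch effects, network-level connectivity
differences between cohorts, or label noise. Passing tests therefore show
the *scoring machinery* behaves correctly under controlled separability and
correlation — not that any particular forest implementation is stable on
real tumour data. The per-pair intercept defaults to 0 because a shared
intercept adds correlation across *all* features and would confound the
calibrated block correlation; set `pair_sd > 0` to exercise paired
structure (e.g. with pair-aware resampling).

## Degenerate inputs and error policy

* Datasets are audited by `validate_dataset`, which reports *every*
  violation (non-finite cells by sample/feature id, label levels, duplicate
  ids, broken pairs) instead of throwing on the first.
* A grid cell whose q AUCs are all 0 has an undefined CV; it is flagged
  (NaN in the CV matrix, unstable in the dot matrix), never scored.
* A failed backend fit aborts the grid with the cell coordinates; there are
  no silent retries (a retry with a fresh seed would bias stability upward)
  and partial grids are never returned.
* Config validation lists all defects before any compute starts; q = 1 is
  rejected because a CV needs at least two values.

## Known limitations

* Mean runtime appears in the ranking TSV as the tie-break column; it is
  wall-clock time and is the one column of the outputs that is not
  byte-reproducible across runs. All scientific columns are.
* The two reference backends are both scikit-learn tree ensembles; the
  adapter contract is the extension point for genuinely foreign
  implementations, and the taxonomy label (`split_strategy`) is metadata
  only.
* `select_stable_size` computes the Spearman floor on full rankings, so it
  is constant across candidate sizes; the Kuncheva curve is what
  discriminates sizes.
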