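# Methods

## Problem and model

Anti-CRISPRs are short, fast-evolving proteins with little mutual
sequence similarity, so the predictor works in *profile* space. Each
query protein is represented by its PSSM: an L×20 integer matrix of
log-odds conservation scores from an iterative PSI-BLAST search
(defaults: 3 iterations, inclusion e-value 0.001). Four fixed-dimension
descriptors summarize the profile from complementary angles —
residue-type composition of profile rows (PSSM-composition, 400-d),
adjacent-position column cross-products (DPC-PSSM, 400-d), per-column
autocovariance at lags 1–10 (PSSM-AC, 200-d), and variance/adjacent-row
statistics on a physicochemically reduced 10-column profile (RPSSM,
110-d). Two sequence baselines (AAC, DPC) are provided for comparison
but are not part of the ensemble.

Because validated anti-CRISPRs are scarce relative to background
proteins (the curated training corpus this design mirrors has 98
positives and 902 negatives), the classifier uses multiple
undersampling: for each descriptor, `n_subsets` (default 10) balanced
subsets are drawn — all positives plus an equal-size random negative
sample without replacement — and one RBF-SVM is trained per subset.
Cost and Gamma are selected per subset by exhaustive grid search over
powers of two 2^-10 … 2^10 (integer exponents), scored by stratified
5-fold CV accuracy inside the subset, ties broken toward the smallest
cost then the smallest gamma (smoother models). Subset scores are
averaged within a descriptor, and the four descriptor scores are
averaged (unweighted) into the final score. A protein is labelled
anti-CRISPR when the final score is ≥ 0.5; the comparison is `>=` so a
score of exactly 0.5 is positive and the boundary is deterministic.

## Assumptions and key choices

* **Probability calibration.** The ensemble averages scores on [0, 1]
  against a 0.5 cut-off, so each SVM must emit a probability-like
  score. Each fitted SVM is Platt-calibrated: a two-parameter sigmoid
  `P(y=1|f) = 1/(1+exp(a f + b))` is fitted by deterministic L-BFGS to
  the SVM's decision values on its own training subset, using Platt's
  smoothed targets `(N+ +1)/(N+ +2)` and `1/(N- +2)` so the fit stays
  finite on separable subsets. Fitting on the training decisions
  (Platt's original recipe) rather than on inner-CV decisions was a
  deliberate choice: on subsets of a few dozen samples, cross-validated
  decision values are noise-dominated and the CV-fitted sigmoid can
  *invert* the score ordering of a well-performing SVM. The
  training-decision fit guarantees the probability ordering equals the
  decision ordering; its known cost is mild overconfidence, which
  averaging over subsets and descriptors damps.
* **Feature standardization.** Each SVM pipeline standardizes features
  (zero mean, unit variance, fitted on its subset). The raw descriptors
  span orders of magnitude (composition averages vs. cross-products of
  integer scores), which would push the useful RBF gamma outside the
  fixed power-of-two grid.
* **PSSM columns and scaling.** Descriptors consume the first block of
  20 integer log-odds columns of the PSI-BLAST ASCII PSSM (not the
  weighted-percentage block), reordered internally to a canonical
  alphabetical residue order. Scores enter the formulas raw; an
  optional logistic rescaling `1/(1+e^-x)` is available behind
  `EncoderConfig(pssm_rescale=True)`, default off.
* **Flattening orders** are pinned for model portability:
  PSSM-composition row-major by residue type; DPC-PSSM as (y_{1,1} …
  y_{1,20}, …, y_{20,20}); PSSM-AC column-major (all lags of column 1,
  then column 2, …); RPSSM pair terms D_{s,t} (row-major) before the 10
  variances D_s.
* **Dataset filters.** The length filter keeps the closed interval
  [50, 350] (anti-CRISPRs are small; both bounds inclusive).
  Nonstandard residues are rejected by default; the permissive policy
  maps them to `X`, which contributes to no composition bin and to no
  δ-selected row, while L in the 1/L and 1/(L−1) prefactors remains the
  full sequence length.
* **Known-ACR filter.** In normal prediction mode, queries whose
  sequence exactly matches a list of experimentally validated
  anti-CRISPRs are reported as known (`Exp.`) without a score;
  benchmarking mode bypasses the list. Matching is exact full-sequence
  identity. The packaged list is a synthetic stand-in (three
  placeholder sequences) so the mechanism is exercised offline; real
  deployments should supply a curated FASTA via `--known-acrs`.
* **PSI-BLAST wrapper.** The parser targets the BLAST+
  `-out_ascii_pssm` dialect. Queries with no database hits produce no
  matrix; the default policy raises, and an opt-in fallback substitutes
  one BLOSUM62 row per residue, flagged `pseudo=True` in the result.
* **Determinism.** Every stochastic step (negative sampling, grid-CV
  folds, protocol draws) derives from explicit seeds; per-feature
  training seeds come from the master seed by fixed offsets so each
  single-feature model is independently reproducible. Persisted models
  carry seeds, grid and configuration but no wall-clock timestamp, so
  identical (data, seed) runs produce byte-identical model files.

## Evaluation protocols

Metrics are SN, SP, ACC, F-value and MCC computed literally from the
confusion table, plus the trapezoidal ROC-AUC (equal to the
positive-outscores-negative probability with ties counted ½).
Zero-denominator conventions keep averaging well-defined: MCC → 0 when
any marginal is zero, F → 0 when 2TP+FP+FN = 0, SN/SP → 0 when their
denominators vanish.

Repeated balanced cross-validation draws N (default 10) balanced
datasets (all positives + equal random negatives), splits each with a
seeded class-balanced stratified k-fold (each class is chunked
separately and chunks paired, so every fold — and hence every training
split — keeps the classes exactly balanced, which the undersampling
trainer requires), retrains the *full* ensemble (subset draws + grid
search) inside every training split, scores the held-out folds, and
averages the per-repeat reports arithmetically. Nothing is ever tuned
on held-out folds. The repeated independent test scores all independent
positives plus an equal-size random draw from a negative pool with a
fixed trained model, N times. Ranked screening sorts scored proteins by
final score (ties broken by protein id for reproducibility) and reports
marker retrieval per ranking cutoff and the lowest marker rank.

## Synthetic data

Real PSSMs require a large sequence database, so the test stack runs on
seeded synthetic data: uniform-random sequences over the 20 standard
residues and uniform integer score matrices in [−10, 10] (the scale of
real log-odds values), with the curated corpus's roughly 1:10 class
imbalance and 50–350 length structure. The two-class signal is injected
in PSSM space — positives get an integer shift on four fixed residue
columns (A, C, D, E) applied in alternating 10-row blocks. The block
pattern is essential: a uniform column shift would move column means
(visible to PSSM-composition and DPC-PSSM) but be invisible to the
mean-centred PSSM-AC and to the RPSSM variance terms, whereas
alternating blocks also inflate column variance and create short-lag
autocorrelation, so all four descriptors can see the class difference.

What the synthetic data does *not* emulate: realistic PSI-BLAST score
distributions, positional correlation from real alignments, residue
composition bias, homology structure within classes, or the
hard negatives (MGE proteins resembling Acrs) that make the real task
difficult. Passing tests therefore demonstrate that the pipeline
recovers a planted signal of realistic scale and finds nothing in null
data — correctness and calibration of the machinery, not field
performance on real proteomes. Benchmark figures on the curated
anti-CRISPR corpora additionally depend on UniRef50-derived PSSMs and
are out of scope here.

## Problem sizes and numerics

Test and acceptance runs scale the study down to keep full-pipeline
retraining tractable on one CPU, as the package's own defaults for its
synthetic studies: signal-recovery experiments use 40 positives / 400
negatives with shift 5 and a stride-2 exponent grid (11×11 cells,
`n_subsets=10`); protocol-structure checks use a pinned "golden"
fixture (15/120, lengths 50–120, seed 20200527) with `n_subsets=2` and
a 4×4 sub-grid {2^-10, 2^-8, 2^0, 2^4} chosen to span both the
low-gamma regime that high-dimensional standardized features need and a
high-cost/high-gamma corner. The full 21×21 grid remains the library
default. Grid-search tie-breaking uses a strict-improvement scan in
(cost, gamma) ascending order with a 1e-12 guard, so equal-accuracy
cells resolve to the smallest pair. Encoders compute in float64
regardless of integer input. Degenerate inputs (L < 2 for
adjacent-row descriptors, L ≤ LG for autocovariance, single-class
grids, empty FASTA/ranking inputs) raise explicit errors rather than
truncating silently.

## Known limitations

* Platt calibration on the training decisions yields overconfident
  probabilities for strongly separable subsets; score *rankings* and
  the 0.5 decision rule are unaffected, but absolute scores should not
  be read as calibrated posterior probabilities.
* The sigmoid slope is fitted per subset-classifier; with `n_subsets=1`
  and a tiny subset, final scores can sit close to 0.5.
* The known-ACR filter is exact-match only; trivially mutated known
  anti-CRISPRs will be scored rather than flagged.
* The PSI-BLAST wrapper assumes BLAST+ output; the legacy 2.x ASCII
  dialect is not parsed.
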