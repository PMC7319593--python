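# acrpred

Anti-CRISPR protein prediction from PSSM-derived evolutionary features.

Anti-CRISPRs (Acrs) are small phage- and mobile-genetic-element-encoded
proteins that inactivate bacterial CRISPR–Cas immunity. They evolve
rapidly and share almost no sequence similarity with one another, so
homology search misses most new families. `acrpred` predicts
anti-CRISPRs from *evolutionary* descriptors extracted from a protein's
position-specific scoring matrix (PSSM) — the L×20 profile of
per-position conservation scores produced by iterative PSI-BLAST search
— which carry signal even when direct sequence similarity is gone. It
is aimed at microbiologists and phage biologists screening genome- or
metagenome-derived protein sets for Acr candidates, and at method
developers who need the full training/evaluation stack.

## Model

Four descriptors are computed from each protein's PSSM `P` (length L,
canonical residue columns):

| descriptor | dim | definition |
|---|---|---|
| PSSM-composition | 400 | rows summed per residue type: `R_i = (1/L) Σ_k r_k δ_k`, `δ_k = 1` iff residue k is type `a_i`; 20×20 matrix flattened row-wise |
| DPC-PSSM | 400 | adjacent-row column products `y_{i,j} = (1/(L−1)) Σ_k P_{k,i} P_{k+1,j}` |
| PSSM-AC | 200 | per-column autocovariance `AC(j,lg) = Σ_i (P_{i,j}−P̄_j)(P_{i+lg,j}−P̄_j)/(L−lg)`, lags 1…10 |
| RPSSM | 110 | on a 10-column reduced PSSM (groups FYW, ML, IV, ATS, NH, QED, RK, C, G, P): adjacent-row terms `D_{s,t} = (1/(L−1)) Σ_i (p_{i,s}−p_{i+1,t})²/2` plus column variances `D_s` |

Training data for Acr recognition is heavily imbalanced (validated Acrs
are rare). The classifier therefore uses **multiple undersampling**:
per descriptor, 10 balanced subsets are drawn (all positives + an
equal-size random negative sample), one RBF-kernel SVM is trained per
subset with Cost and Gamma grid-searched over {2⁻¹⁰, …, 2¹⁰}, and the
Platt-calibrated probabilities are averaged. The final score is the
unweighted mean of the four single-feature model scores; a protein is
called anti-CRISPR when the score is ≥ 0.5.

Evaluation follows the matching protocols: repeated balanced 5-fold
cross-validation (N = 10 balanced draws, full retraining inside every
fold), repeated balanced independent tests, SN/SP/ACC/F/MCC plus
ROC-AUC, and ranked proteome screening against a marker list. Sequence
baselines (AAC, DPC) are included for comparison. A seeded synthetic
generator (`acrpred.fixtures`) produces sequences, PSSMs, and separable
two-class datasets so everything trains and tests offline.

## Worked example

```python
from acrpred import (
    FixtureSpec, gen_labeled_dataset, train_ensemble, predict,
)

# synthetic study: 10 anti-CRISPR-like positives, 60 negatives
dataset, records, pssms = gen_labeled_dataset(
    FixtureSpec(n_pos=10, n_neg=60, length_range=(100, 160),
                class_shift=5.0, seed=42)
)
model = train_ensemble(dataset, n_subsets=5, seed=42,
                       grid_exponents=(-10, -8, 0, 4), grid_folds=3)

query = records[0]  # a held-in positive, for illustration
result = predict(model, query, pssms[query.id], benchmarking_mode=True)
print(f"protein: {result.protein_id}")
for enc, score in result.per_feature_scores.items():
    print(f"  {enc:10s} score = {score:.3f}")
print(f"  final score = {result.final_score:.3f}  ->  "
      f"{'anti-CRISPR' if result.label else 'non-anti-CRISPR'}")
```

prints

```
protein: pos_1662057958
  PSSM_COMP  score = 0.917
  DPC_PSSM   score = 0.917
  PSSM_AC    score = 0.917
  RPSSM      score = 0.929
  final score = 0.920  ->  anti-CRISPR
```

Each line is one single-feature model's averaged subset-classifier
probability that the protein is an anti-CRISPR; the final score is
their mean and crosses the 0.5 decision threshold, so the protein is
called positive. On real data, pass `benchmarking_mode=False` (the
default) so proteins exactly matching a curated list of experimentally
validated anti-CRISPRs are reported as `known_acr` instead of being
rescored.

The same pipeline is available from the shell:

```bash
acrpred features proteins.fasta pssm_dir/ features.tsv
acrpred train pos.fasta neg.fasta pssm_dir/ model.joblib --seed 1
acrpred predict query.fasta pssm_dir/ model.joblib predictions.tsv
acrpred eval cv pos.fasta neg.fasta pssm_dir/ report.tsv --repeats 10
acrpred make-pssm query.fasta pssm_out/ --db /path/to/uniref50
```

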