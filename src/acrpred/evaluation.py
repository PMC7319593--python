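"""Performance metrics and evaluation protocols.

Metrics are the standard confusion-table quantities for binary protein
classification:

    SN  = TP / (TP + FN)
    SP  = TN / (TN + FP)
    ACC = (TP + TN) / (TP + FP + TN + FN)
    F   = 2 * TP / (2*TP + FP + FN)
    MCC = (TP*TN - FN*FP) / sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN))

plus the ROC curve and its trapezoidal AUC (equal to the probability
that a random positive outscores a random negative, ties counted 1/2).

Zero-denominator conventions keep every metric bounded and averaging
well-defined: MCC is 0 when any marginal is zero, F is 0 when
2*TP+FP+FN is zero, and SN/SP are 0 when their denominators are zero.

Two protocols mirror how imbalanced anti-CRISPR data is evaluated:

* repeated balanced cross-validation — N times (default 10), draw a
  balanced dataset (all positives + an equal random negative sample),
  run stratified k-fold CV retraining the full ensemble on the training
  folds, score held-out folds, and average the N reports;
* repeated balanced independent test — N times, score all independent
  positives plus an equal-size random negative draw with a fixed
  trained model, and average.

Nothing is ever tuned on held-out folds: subset construction and the
grid search happen inside each training split only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

from .io import InputError
from .model import (
    DEFAULT_GRID_EXPONENTS,
    EnsembleModel,
    LabeledDataset,
    PredictionResult,
    train_ensemble,
)

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "EvalProtocolConfig",
    "RankingReport",
    "confusion",
    "compute_metrics",
    "roc_auc",
    "draw_balanced_dataset",
    "repeated_balanced_cv",
    "repeated_independent_test",
    "rank_predictions",
    "write_metrics_tsv",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise InputError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """Confusion-derived metrics (plus optional AUC) for one evaluation run."""

    sn: float
    sp: float
    acc: float
    f_value: float
    mcc: float
    auc: float | None = None
    counts: ConfusionCounts | None = None

    _FIELDS = ("sn", "sp", "acc", "f_value", "mcc", "auc")

    def as_row(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in self._FIELDS}

    @staticmethod
    def average(reports: Sequence["MetricsReport"]) -> "MetricsReport":
        """Component-wise arithmetic mean of per-repeat reports."""
        if not reports:
            raise InputError("cannot average zero reports")
        vals = {}
        for name in MetricsReport._FIELDS:
            entries = [getattr(r, name) for r in reports]
            if name == "auc" and any(e is None for e in entries):
                vals[name] = None
            else:
                vals[name] = float(np.mean(entries))
        return MetricsReport(**vals, counts=None)


@dataclass(frozen=True)
class EvalProtocolConfig:
    """Settings for the repeated balanced protocols.

    n_repeats is the number of balanced draws N (default 10); k_folds
    the CV fold count (default 5); threshold the score cut-off for
    labelling (default 0.5). Training-cost knobs (n_subsets, the grid)
    are forwarded to the ensemble trainer.
    """

    n_repeats: int = 10
    k_folds: int = 5
    seed: int = 0
    threshold: float = 0.5
    n_subsets: int = 10
    grid_exponents: tuple[int, ...] = DEFAULT_GRID_EXPONENTS
    grid_folds: int = 5

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise InputError("n_repeats must be >= 1")
        if self.k_folds < 2:
            raise InputError("k_folds must be >= 2")


# ---------------------------------------------------------------------------
# Metrics


def confusion(labels: Sequence[int], predictions: Sequence[int]) -> ConfusionCounts:
    """Count TP/TN/FP/FN for binary labels and predictions."""
    y = np.asarray(labels)
    p = np.asarray(predictions)
    if y.size == 0:
        raise InputError("cannot build a confusion table from empty inputs")
    if y.shape != p.shape:
        raise InputError(f"length mismatch: {y.shape} labels vs {p.shape} predictions")
    for arr, name in ((y, "labels"), (p, "predictions")):
        if not np.isin(arr, (0, 1)).all():
            raise InputError(f"{name} must be binary (0/1)")
    return ConfusionCounts(
        tp=int(((y == 1) & (p == 1)).sum()),
        tn=int(((y == 0) & (p == 0)).sum()),
        fp=int(((y == 0) & (p == 1)).sum()),
        fn=int(((y == 1) & (p == 0)).sum()),
    )


def compute_metrics(counts: ConfusionCounts, auc: float | None = None) -> MetricsReport:
    """Apply the five metric formulas to a confusion table."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    sn = tp / (tp + fn) if (tp + fn) else 0.0
    sp = tn / (tn + fp) if (tn + fp) else 0.0
    acc = (tp + tn) / counts.total if counts.total else 0.0
    f_value = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    denom = (tp + fn) * (tn + fp) * (tp + fp) * (tn + fn)
    mcc = (tp * tn - fn * fp) / np.sqrt(denom) if denom else 0.0
    return MetricsReport(
        sn=float(sn), sp=float(sp), acc=float(acc),
        f_value=float(f_value), mcc=float(mcc), auc=auc, counts=counts,
    )


def roc_auc(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[np.ndarray, float]:
    """ROC curve points and trapezoidal AUC.

    Returns ``(points, auc)`` where ``points`` is an (n, 2) array of
    (FPR, TPR) pairs over all distinct score thresholds. The trapezoidal
    AUC equals the probability that a random positive outscores a random
    negative, with ties counted 1/2.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=np.float64)
    if y.shape != s.shape:
        raise InputError("scores and labels must align")
    if np.unique(y).size < 2:
        raise InputError("ROC requires both classes present")
    fpr, tpr, _ = _roc_curve(y, s, drop_intermediate=False)
    return np.column_stack([fpr, tpr]), float(_trapezoid_auc(fpr, tpr))


# ---------------------------------------------------------------------------
# Protocols


def draw_balanced_dataset(dataset: LabeledDataset, seed: int) -> LabeledDataset:
    """All positives plus an equal-size random negative draw (no replacement)."""
    pos = dataset.positive_ids
    neg = dataset.negative_ids
    if not pos:
        raise InputError("dataset has no positives")
    if len(neg) < len(pos):
        raise InputError("not enough negatives for a balanced draw")
    rng = np.random.default_rng(seed)
    drawn = rng.choice(len(neg), size=len(pos), replace=False)
    ids = pos + [neg[i] for i in sorted(drawn)]
    return dataset.subset_by_ids(ids)


def _balanced_stratified_folds(
    labels: np.ndarray, k: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified k-fold that keeps every fold class-balanced.

    Each class is shuffled and split into k chunks; fold i pairs the
    i-th chunks. On an equal-class dataset the chunk sizes match, so
    every training split retains equal positives and negatives (which
    the undersampling trainer requires) and both classes appear in
    every fold.
    """
    rng = np.random.default_rng(seed)
    pos = rng.permutation(np.flatnonzero(labels == 1))
    neg = rng.permutation(np.flatnonzero(labels == 0))
    if min(len(pos), len(neg)) < k:
        raise InputError(
            f"cannot split {len(pos)} positives / {len(neg)} negatives "
            f"into {k} folds with both classes present"
        )
    pos_chunks = np.array_split(pos, k)
    neg_chunks = np.array_split(neg, k)
    folds = []
    all_idx = np.arange(len(labels))
    for i in range(k):
        test_idx = np.concatenate([pos_chunks[i], neg_chunks[i]])
        train_idx = np.setdiff1d(all_idx, test_idx)
        folds.append((train_idx, test_idx))
    return folds


def repeated_balanced_cv(
    dataset: LabeledDataset, config: EvalProtocolConfig
) -> tuple[MetricsReport, list[MetricsReport]]:
    """Repeated balanced stratified k-fold cross-validation.

    For each of the N repeats, a balanced dataset is drawn, the full
    ensemble (undersampling + grid search) is retrained on every
    training split, and held-out folds are scored; metrics are computed
    on the pooled held-out predictions of the repeat. Returns the
    averaged report and the N per-repeat reports.
    """
    per_repeat: list[MetricsReport] = []
    for r in range(config.n_repeats):
        repeat_seed = (config.seed + 104729 * (r + 1)) % (2**31)
        balanced = draw_balanced_dataset(dataset, seed=repeat_seed)
        folds = _balanced_stratified_folds(
            balanced.labels, config.k_folds, seed=repeat_seed
        )
        y_all: list[int] = []
        scores_all: list[float] = []
        for fold, (train_idx, test_idx) in enumerate(folds):
            train = balanced.subset_by_rows(train_idx)
            test = balanced.subset_by_rows(test_idx)
            assert not set(train.ids) & set(test.ids)
            model = train_ensemble(
                train,
                n_subsets=config.n_subsets,
                seed=(repeat_seed + fold) % (2**31),
                grid_exponents=config.grid_exponents,
                grid_folds=config.grid_folds,
            )
            final, _ = model.score_features(test.features)
            y_all.extend(test.labels.tolist())
            scores_all.extend(final.tolist())
        preds = (np.asarray(scores_all) >= config.threshold).astype(int)
        _, auc_val = roc_auc(scores_all, y_all)
        per_repeat.append(compute_metrics(confusion(y_all, preds), auc=auc_val))
    return MetricsReport.average(per_repeat), per_repeat


def repeated_independent_test(
    model: EnsembleModel,
    positives: LabeledDataset,
    negative_pool: LabeledDataset,
    config: EvalProtocolConfig,
) -> tuple[MetricsReport, list[MetricsReport]]:
    """Repeated balanced independent test with a fixed trained model.

    Each repeat scores all positives together with an equal-size random
    draw from the negative pool; reports are averaged over repeats.
    """
    n_pos = int(positives.labels.sum())
    if n_pos == 0 or n_pos != len(positives):
        raise InputError("positives dataset must contain only positive samples")
    pool_neg = negative_pool.negative_ids
    if len(pool_neg) < n_pos:
        raise InputError("negative pool smaller than the positive set")
    per_repeat: list[MetricsReport] = []
    for r in range(config.n_repeats):
        rng = np.random.default_rng((config.seed + 15485863 * (r + 1)) % (2**31))
        drawn = rng.choice(len(pool_neg), size=n_pos, replace=False)
        negatives = negative_pool.subset_by_ids([pool_neg[i] for i in sorted(drawn)])
        y = np.concatenate([positives.labels, negatives.labels])
        features = {
            enc: np.vstack([positives.features[enc], negatives.features[enc]])
            for enc in positives.features
        }
        final, _ = model.score_features(features)
        preds = (final >= config.threshold).astype(int)
        _, auc_val = roc_auc(final, y)
        per_repeat.append(compute_metrics(confusion(y, preds), auc=auc_val))
    return MetricsReport.average(per_repeat), per_repeat


# ---------------------------------------------------------------------------
# Ranked screening


@dataclass(frozen=True)
class RankingReport:
    """Ranked screening of a protein set against known-marker proteins."""

    ranked_ids: tuple[str, ...]
    ranked_scores: tuple[float, ...]
    marker_ranks: dict[str, int]
    retrieval: tuple[tuple[int, int], ...]  # (cutoff, markers retrieved)
    lowest_marker_rank: int


def rank_predictions(
    results: Sequence[PredictionResult],
    markers: set[str] | Sequence[str],
    cutoff_step: int = 10,
) -> RankingReport:
    """Rank scored predictions and measure marker retrieval per cutoff.

    Proteins are sorted by final score descending, ties broken by
    protein id (lexicographic) for reproducibility. For each ranking
    cutoff (step, 2*step, ... up to the set size) the report counts how
    many marker proteins appear at or above the cutoff, and records the
    rank of the lowest-ranked marker.
    """
    markers = set(markers)
    scored = [r for r in results if r.final_score is not None]
    known_ids = {r.protein_id for r in scored}
    unknown = markers - known_ids
    if unknown:
        raise InputError(f"markers not present in results: {sorted(unknown)[:5]}")
    if not markers:
        raise InputError("empty marker set")
    ranked = sorted(scored, key=lambda r: (-r.final_score, r.protein_id))
    ranked_ids = tuple(r.protein_id for r in ranked)
    marker_ranks = {pid: i + 1 for i, pid in enumerate(ranked_ids) if pid in markers}
    cutoffs = list(range(cutoff_step, len(ranked) + 1, cutoff_step))
    if not cutoffs or cutoffs[-1] != len(ranked):
        cutoffs.append(len(ranked))
    retrieval = tuple(
        (c, sum(1 for rank in marker_ranks.values() if rank <= c)) for c in cutoffs
    )
    return RankingReport(
        ranked_ids=ranked_ids,
        ranked_scores=tuple(float(r.final_score) for r in ranked),
        marker_ranks=marker_ranks,
        retrieval=retrieval,
        lowest_marker_rank=max(marker_ranks.values()),
    )


# ---------------------------------------------------------------------------
# Report files


def write_metrics_tsv(
    path: str | Path,
    per_repeat: Sequence[MetricsReport],
    average: MetricsReport,
    header_lines: Sequence[str] = (),
) -> None:
    """Write per-repeat rows plus an AVERAGE row as TSV."""
    cols = ("sn", "sp", "acc", "f_value", "mcc", "auc")
    with Path(path).open("w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("repeat\t" + "\t".join(cols) + "\n")
        for i, rep in enumerate(per_repeat, start=1):
            row = rep.as_row()
            fh.write(
                f"{i}\t" + "\t".join(
                    "NA" if row[c] is None else f"{row[c]:.6f}" for c in cols
                ) + "\n"
            )
        row = average.as_row()
        fh.write(
            "AVERAGE\t" + "\t".join(
                "NA" if row[c] is None else f"{row[c]:.6f}" for c in cols
            ) + "\n"
        )
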