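"""Undersampling SVM ensemble for anti-CRISPR prediction.

Training data for anti-CRISPR recognition is heavily imbalanced (about
one validated anti-CRISPR per nine negatives). The model handles this
by multiple undersampling: for each feature type it builds ``n_subsets``
balanced subsets (all positives plus an equal-size random draw of
negatives), trains one RBF-kernel SVM per subset with Cost and Gamma
grid-searched over {2^-10, ..., 2^10}, and averages the classifiers'
positive-class probabilities. The final predictor averages the four
single-feature model scores and labels a protein anti-CRISPR when the
mean score is >= 0.5.

Classifier scores are Platt-calibrated probabilities (a two-parameter
sigmoid fitted to each subset's SVM decision values) so that averaging
and the 0.5 cut-off are meaningful on a [0, 1] scale. Each SVM pipeline standardizes its
features before the kernel; raw PSSM descriptors have widely varying
scales that would otherwise fall outside the fixed power-of-two Gamma
grid.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import (
    EVOLUTIONARY_ENCODERS,
    EncoderConfig,
    encode_all,
)
from .io import AcrPredError, InputError, ProteinRecord, PSSMatrix, read_fasta

__all__ = [
    "DEFAULT_GRID_EXPONENTS",
    "MODEL_FORMAT_VERSION",
    "LabeledDataset",
    "BalancedSubset",
    "SvmSpec",
    "SingleFeatureModel",
    "EnsembleModel",
    "PredictionResult",
    "ModelFormatError",
    "build_dataset",
    "make_balanced_subsets",
    "grid_search_svm",
    "train_single_feature_model",
    "predict_single_feature",
    "train_ensemble",
    "predict",
    "predict_batch",
    "save_model",
    "load_model",
    "load_builtin_acr_list",
]

#: Grid-search space for Cost and Gamma: powers of two with integer
#: exponents from -10 to 10 (21 values per parameter).
DEFAULT_GRID_EXPONENTS = tuple(range(-10, 11))

DEFAULT_THRESHOLD = 0.5
MODEL_FORMAT_VERSION = 1

# Fixed offsets deriving one reproducible seed per feature model from the
# master seed, so each single-feature model can be retrained independently.
_FEATURE_SEED_OFFSETS = {enc: 1000 * (i + 1) for i, enc in enumerate(EVOLUTIONARY_ENCODERS)}


class ModelFormatError(AcrPredError):
    """Persisted model file is corrupt, truncated, or incompatible."""


@dataclass
class LabeledDataset:
    """Feature matrices and binary labels for a set of proteins.

    ``features`` maps encoder name to an (n_samples, dim) matrix whose
    rows align with ``ids``; ``labels`` is 1 for anti-CRISPR.
    """

    ids: list[str]
    features: dict[str, np.ndarray]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise InputError("dataset ids are not unique")
        if self.labels.shape != (n,):
            raise InputError("labels do not align with ids")
        if not np.isin(self.labels, (0, 1)).all():
            raise InputError("labels must be binary (0/1)")
        for enc, mat in self.features.items():
            mat = np.asarray(mat, dtype=np.float64)
            if mat.shape[0] != n:
                raise InputError(f"feature matrix {enc!r} has {mat.shape[0]} rows, expected {n}")
            self.features[enc] = mat

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def positive_ids(self) -> list[str]:
        return [i for i, y in zip(self.ids, self.labels) if y == 1]

    @property
    def negative_ids(self) -> list[str]:
        return [i for i, y in zip(self.ids, self.labels) if y == 0]

    def subset_by_ids(self, ids: Sequence[str]) -> "LabeledDataset":
        index = {pid: k for k, pid in enumerate(self.ids)}
        missing = [i for i in ids if i not in index]
        if missing:
            raise InputError(f"unknown ids: {missing[:5]}")
        rows = [index[i] for i in ids]
        return LabeledDataset(
            ids=list(ids),
            features={enc: mat[rows] for enc, mat in self.features.items()},
            labels=self.labels[rows],
        )

    def subset_by_rows(self, rows: Sequence[int]) -> "LabeledDataset":
        rows = list(rows)
        return LabeledDataset(
            ids=[self.ids[r] for r in rows],
            features={enc: mat[rows] for enc, mat in self.features.items()},
            labels=self.labels[rows],
        )


@dataclass(frozen=True)
class BalancedSubset:
    """One balanced training subset: all positives plus sampled negatives."""

    positive_ids: tuple[str, ...]
    negative_ids: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        if len(self.negative_ids) != len(self.positive_ids):
            raise InputError("balanced subset must have equal class sizes")
        if set(self.positive_ids) & set(self.negative_ids):
            raise InputError("subset positives and negatives overlap")

    @property
    def ids(self) -> list[str]:
        return list(self.positive_ids) + list(self.negative_ids)


@dataclass(frozen=True)
class SvmSpec:
    """Selected RBF-SVM hyperparameters (kernel is always RBF)."""

    cost: float
    gamma: float

    def __post_init__(self) -> None:
        if self.cost <= 0 or self.gamma <= 0:
            raise InputError("SVM cost and gamma must be positive")


@dataclass
class SingleFeatureModel:
    """Undersampling ensemble of SVMs for one feature type."""

    encoder: str
    classifiers: list[Pipeline]
    specs: list[SvmSpec]
    subsets: list[BalancedSubset]

    @property
    def n_subsets(self) -> int:
        return len(self.classifiers)

    def score(self, X: np.ndarray) -> np.ndarray:
        """Mean positive-class probability over the member classifiers."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        probs = np.stack([clf.predict_proba(X)[:, 1] for clf in self.classifiers])
        return probs.mean(axis=0)


@dataclass
class EnsembleModel:
    """Final predictor: four single-feature models averaged, 0.5 cut-off."""

    feature_models: dict[str, SingleFeatureModel]
    threshold: float = DEFAULT_THRESHOLD
    encoder_config: EncoderConfig = field(default_factory=EncoderConfig)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [e for e in EVOLUTIONARY_ENCODERS if e not in self.feature_models]
        if missing:
            raise InputError(f"ensemble is missing feature models: {missing}")
        extra = [e for e in self.feature_models if e not in EVOLUTIONARY_ENCODERS]
        if extra:
            raise InputError(f"unexpected feature models: {extra}")
        if not (0.0 < self.threshold < 1.0):
            raise InputError("threshold must lie strictly between 0 and 1")

    def score_features(
        self, features: Mapping[str, np.ndarray]
    ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        """Score pre-encoded feature matrices.

        Returns ``(final_scores, per_feature_scores)`` where the final
        score of each sample is the unweighted mean of its four
        single-feature scores.
        """
        per_feature: dict[str, np.ndarray] = {}
        for enc in EVOLUTIONARY_ENCODERS:
            if enc not in features:
                raise InputError(f"missing {enc!r} features for scoring")
            per_feature[enc] = self.feature_models[enc].score(features[enc])
        final = np.mean([per_feature[enc] for enc in EVOLUTIONARY_ENCODERS], axis=0)
        return final, per_feature


@dataclass(frozen=True)
class PredictionResult:
    """Prediction for one protein.

    ``known_acr`` marks an exact full-sequence match against the list of
    experimentally validated anti-CRISPRs; such proteins bypass scoring
    in normal mode (scores are None) and are reported as positives.
    """

    protein_id: str
    per_feature_scores: dict[str, float] | None
    final_score: float | None
    label: int
    known_acr: bool = False


# ---------------------------------------------------------------------------
# Dataset construction


def build_dataset(
    records: Sequence[ProteinRecord],
    pssms: Mapping[str, PSSMatrix],
    labels: Mapping[str, int],
    config: EncoderConfig | None = None,
) -> LabeledDataset:
    """Encode record/PSSM pairs into a labelled dataset of the four
    evolutionary feature matrices."""
    config = config or EncoderConfig()
    ids: list[str] = []
    columns: dict[str, list[np.ndarray]] = {enc: [] for enc in EVOLUTIONARY_ENCODERS}
    y: list[int] = []
    for rec in records:
        if rec.id not in pssms:
            raise InputError(f"no PSSM provided for {rec.id!r}")
        if rec.id not in labels:
            raise InputError(f"no label provided for {rec.id!r}")
        encoded = encode_all(pssms[rec.id], rec, config)
        for enc in EVOLUTIONARY_ENCODERS:
            columns[enc].append(encoded[enc].values)
        ids.append(rec.id)
        y.append(int(labels[rec.id]))
    return LabeledDataset(
        ids=ids,
        features={enc: np.vstack(cols) for enc, cols in columns.items()},
        labels=np.array(y),
    )


# ---------------------------------------------------------------------------
# Undersampling and grid search


def make_balanced_subsets(
    dataset: LabeledDataset, n_subsets: int = 10, seed: int = 0
) -> list[BalancedSubset]:
    """Draw ``n_subsets`` balanced subsets by random undersampling.

    Every subset contains all positives plus an equal-size sample of
    negatives drawn without replacement; draws are independent across
    subsets and fully reproducible from ``seed``.
    """
    if n_subsets < 1:
        raise InputError("n_subsets must be >= 1")
    pos = dataset.positive_ids
    neg = dataset.negative_ids
    if not pos:
        raise InputError("dataset has no positive samples")
    if len(neg) < len(pos):
        raise InputError(
            f"undersampling needs at least as many negatives as positives "
            f"({len(neg)} < {len(pos)})"
        )
    rng = np.random.default_rng(seed)
    subsets = []
    for _ in range(n_subsets):
        drawn = rng.choice(len(neg), size=len(pos), replace=False)
        subsets.append(
            BalancedSubset(
                positive_ids=tuple(pos),
                negative_ids=tuple(neg[i] for i in sorted(drawn)),
                seed=seed,
            )
        )
    return subsets


def _fit_platt_sigmoid(decisions: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Fit Platt's sigmoid P(y=1|f) = 1 / (1 + exp(a*f + b)).

    Uses Platt's smoothed targets t+ = (N+ + 1)/(N+ + 2) and
    t- = 1/(N- + 2) so the fit stays finite on separable data, and a
    deterministic L-BFGS minimization of the cross-entropy.
    """
    f = np.asarray(decisions, dtype=np.float64)
    y = np.asarray(y)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    t = np.where(y == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def objective(ab):
        a, b = ab
        z = a * f + b
        # log p = -logaddexp(0, z); log(1-p) = z - logaddexp(0, z)
        lse = np.logaddexp(0.0, z)
        nll = -(t * (-lse) + (1.0 - t) * (z - lse)).sum()
        resid = expit(z) - (1.0 - t)
        return nll, np.array([(resid * f).sum(), resid.sum()])

    res = minimize(objective, x0=np.array([-1.0, 0.0]), jac=True, method="L-BFGS-B")
    return float(res.x[0]), float(res.x[1])


class PlattScaledSVC(BaseEstimator, ClassifierMixin):
    """RBF-SVM emitting Platt-calibrated positive-class probabilities.

    The SVM is fitted on the data, then a two-parameter sigmoid is
    fitted to its training decision values (Platt's method). The
    probability ordering therefore always agrees with the SVM's
    decision ordering, which keeps score averaging and the 0.5 cut-off
    meaningful on the small balanced subsets this model trains on.
    """

    def __init__(self, C: float = 1.0, gamma: float = 1.0):
        self.C = C
        self.gamma = gamma

    def fit(self, X, y):
        self.svc_ = SVC(C=self.C, gamma=self.gamma, kernel="rbf").fit(X, y)
        self.classes_ = self.svc_.classes_
        decisions = self.svc_.decision_function(X)
        self.a_, self.b_ = _fit_platt_sigmoid(decisions, y)
        return self

    def predict_proba(self, X):
        z = self.a_ * self.svc_.decision_function(X) + self.b_
        p1 = expit(-z)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def _svc_pipeline(cost: float, gamma: float, probability: bool = False) -> Pipeline:
    """Standardize-then-RBF-SVM pipeline, optionally Platt-calibrated."""
    est = PlattScaledSVC(C=cost, gamma=gamma) if probability else SVC(
        C=cost, gamma=gamma, kernel="rbf"
    )
    return Pipeline([("scale", StandardScaler()), ("svm", est)])


def grid_search_svm(
    X: np.ndarray,
    y: np.ndarray,
    grid_exponents: Sequence[int] = DEFAULT_GRID_EXPONENTS,
    folds: int = 5,
    seed: int = 0,
) -> SvmSpec:
    """Exhaustive power-of-two grid search for RBF-SVM Cost and Gamma.

    Every (cost, gamma) = (2^a, 2^b) cell is scored by mean stratified
    ``folds``-fold cross-validated accuracy; the best cell wins, with
    ties broken toward the smallest cost, then the smallest gamma
    (favouring smoother models). Deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    classes = np.unique(y)
    if classes.size < 2:
        raise InputError("grid search requires both classes present")
    exps = sorted(set(int(e) for e in grid_exponents))
    if not exps:
        raise InputError("empty grid")
    folds = min(folds, int(np.bincount(y).min()))
    if folds < 2:
        raise InputError("grid search needs at least 2 samples per class")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    best_acc = -1.0
    best: SvmSpec | None = None
    for a in exps:
        for b in exps:
            cost, gamma = 2.0**a, 2.0**b
            correct = 0
            for train_idx, test_idx in splits:
                clf = _svc_pipeline(cost, gamma)
                clf.fit(X[train_idx], y[train_idx])
                correct += int((clf.predict(X[test_idx]) == y[test_idx]).sum())
            acc = correct / len(y)
            if acc > best_acc + 1e-12:  # strict improvement: ties keep the
                best_acc = acc          # smallest (cost, gamma) seen first
                best = SvmSpec(cost=cost, gamma=gamma)
    assert best is not None
    return best


def train_single_feature_model(
    dataset: LabeledDataset,
    encoder: str,
    n_subsets: int = 10,
    seed: int = 0,
    grid_exponents: Sequence[int] = DEFAULT_GRID_EXPONENTS,
    grid_folds: int = 5,
) -> SingleFeatureModel:
    """Train the undersampling SVM ensemble for one feature type.

    For each balanced subset a grid search selects (Cost, Gamma) by
    stratified CV inside the subset, then a Platt-calibrated RBF-SVM is
    fitted on the whole subset. Reproducible from ``seed``.
    """
    if encoder not in dataset.features:
        raise InputError(f"dataset has no {encoder!r} features")
    subsets = make_balanced_subsets(dataset, n_subsets=n_subsets, seed=seed)
    classifiers: list[Pipeline] = []
    specs: list[SvmSpec] = []
    for k, subset in enumerate(subsets):
        sub = dataset.subset_by_ids(subset.ids)
        X, y = sub.features[encoder], sub.labels
        sub_seed = (seed + 7919 * (k + 1)) % (2**31)
        spec = grid_search_svm(
            X, y, grid_exponents=grid_exponents, folds=grid_folds, seed=sub_seed
        )
        clf = _svc_pipeline(spec.cost, spec.gamma, probability=True)
        clf.fit(X, y)
        classifiers.append(clf)
        specs.append(spec)
    return SingleFeatureModel(
        encoder=encoder, classifiers=classifiers, specs=specs, subsets=subsets
    )


def predict_single_feature(model: SingleFeatureModel, x) -> float:
    """Score one feature vector: mean of the member classifiers' scores."""
    values = getattr(x, "values", x)
    if hasattr(x, "encoder") and x.encoder != model.encoder:
        raise InputError(
            f"feature vector encoder {x.encoder!r} does not match model "
            f"encoder {model.encoder!r}"
        )
    return float(model.score(np.asarray(values, dtype=np.float64))[0])


def train_ensemble(
    dataset: LabeledDataset,
    n_subsets: int = 10,
    seed: int = 0,
    grid_exponents: Sequence[int] = DEFAULT_GRID_EXPONENTS,
    grid_folds: int = 5,
    encoder_config: EncoderConfig | None = None,
) -> EnsembleModel:
    """Train the full four-feature ensemble.

    Each single-feature model uses its own seed derived from the master
    seed by a fixed offset, so feature models are independently
    reproducible. The decision threshold is 0.5.
    """
    encoder_config = encoder_config or EncoderConfig()
    missing = [e for e in EVOLUTIONARY_ENCODERS if e not in dataset.features]
    if missing:
        raise InputError(f"dataset is missing encoders: {missing}")
    feature_models: dict[str, SingleFeatureModel] = {}
    feature_seeds: dict[str, int] = {}
    for enc in EVOLUTIONARY_ENCODERS:
        enc_seed = (seed + _FEATURE_SEED_OFFSETS[enc]) % (2**31)
        feature_seeds[enc] = enc_seed
        feature_models[enc] = train_single_feature_model(
            dataset,
            enc,
            n_subsets=n_subsets,
            seed=enc_seed,
            grid_exponents=grid_exponents,
            grid_folds=grid_folds,
        )
    metadata = {
        "master_seed": seed,
        "feature_seeds": feature_seeds,
        "n_subsets": n_subsets,
        "grid_exponents": list(grid_exponents),
        "grid_folds": grid_folds,
        "encoder_config": {
            "lag": encoder_config.lag,
            "pssm_rescale": encoder_config.pssm_rescale,
        },
        "n_train": len(dataset),
        "n_positive": int(dataset.labels.sum()),
    }
    return EnsembleModel(
        feature_models=feature_models,
        threshold=DEFAULT_THRESHOLD,
        encoder_config=encoder_config,
        metadata=metadata,
    )


# ---------------------------------------------------------------------------
# Prediction


def load_builtin_acr_list() -> dict[str, str]:
    """Sequences of the packaged known-anti-CRISPR list, keyed by id.

    The packaged file is a synthetic stand-in (see its header); supply a
    curated FASTA of experimentally validated anti-CRISPRs for real use.
    """
    resource = importlib.resources.files("acrpred").joinpath(
        "data/known_acrs_synthetic.fasta"
    )
    with importlib.resources.as_file(resource) as path:
        return {rec.id: rec.sequence for rec in read_fasta(path)}


def predict(
    model: EnsembleModel,
    record: ProteinRecord,
    pssm: PSSMatrix,
    benchmarking_mode: bool = False,
    known_acrs: Mapping[str, str] | None = None,
) -> PredictionResult:
    """Predict whether one protein is an anti-CRISPR.

    In normal mode a query whose sequence exactly matches the known
    anti-CRISPR list is reported as experimentally validated without a
    score; ``benchmarking_mode=True`` bypasses the list so every protein
    receives a prediction score. The label rule is final_score >=
    threshold (a score of exactly 0.5 is positive).
    """
    if known_acrs is None:
        known_acrs = load_builtin_acr_list()
    if not benchmarking_mode and record.sequence in set(known_acrs.values()):
        return PredictionResult(
            protein_id=record.id,
            per_feature_scores=None,
            final_score=None,
            label=1,
            known_acr=True,
        )
    encoded = encode_all(pssm, record, model.encoder_config)
    features = {enc: encoded[enc].values[None, :] for enc in EVOLUTIONARY_ENCODERS}
    final, per_feature = model.score_features(features)
    return PredictionResult(
        protein_id=record.id,
        per_feature_scores={enc: float(per_feature[enc][0]) for enc in EVOLUTIONARY_ENCODERS},
        final_score=float(final[0]),
        label=int(final[0] >= model.threshold),
        known_acr=False,
    )


def predict_batch(
    model: EnsembleModel,
    records: Sequence[ProteinRecord],
    pssms: Mapping[str, PSSMatrix],
    benchmarking_mode: bool = False,
    known_acrs: Mapping[str, str] | None = None,
) -> list[PredictionResult]:
    if known_acrs is None:
        known_acrs = load_builtin_acr_list()
    return [
        predict(model, rec, pssms[rec.id], benchmarking_mode, known_acrs)
        for rec in records
    ]


# ---------------------------------------------------------------------------
# Persistence


def save_model(model: EnsembleModel, path: str | Path) -> None:
    """Persist a trained ensemble as a versioned joblib archive."""
    payload = {
        "format": "acrpred-ensemble",
        "version": MODEL_FORMAT_VERSION,
        "threshold": model.threshold,
        "encoder_config": {
            "lag": model.encoder_config.lag,
            "pssm_rescale": model.encoder_config.pssm_rescale,
        },
        "metadata": model.metadata,
        "feature_models": {
            enc: {
                "classifiers": fm.classifiers,
                "specs": [(s.cost, s.gamma) for s in fm.specs],
                "subsets": [
                    (sub.positive_ids, sub.negative_ids, sub.seed) for sub in fm.subsets
                ],
            }
            for enc, fm in model.feature_models.items()
        },
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> EnsembleModel:
    """Load a persisted ensemble, validating format and encoder set."""
    path = Path(path)
    if not path.exists():
        raise ModelFormatError(f"model file not found: {path}")
    try:
        payload = joblib.load(path)
    except Exception as exc:
        raise ModelFormatError(f"cannot read model file {path}: {exc}") from None
    if not isinstance(payload, dict) or payload.get("format") != "acrpred-ensemble":
        raise ModelFormatError(f"{path} is not an acrpred ensemble model")
    if payload.get("version") != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"model format version {payload.get('version')!r} is not supported "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    raw = payload["feature_models"]
    if set(raw) != set(EVOLUTIONARY_ENCODERS):
        raise ModelFormatError(
            f"model encoder set {sorted(raw)} does not match the required "
            f"four evolutionary encoders"
        )
    cfg = payload["encoder_config"]
    feature_models = {
        enc: SingleFeatureModel(
            encoder=enc,
            classifiers=data["classifiers"],
            specs=[SvmSpec(c, g) for c, g in data["specs"]],
            subsets=[BalancedSubset(p, n, s) for p, n, s in data["subsets"]],
        )
        for enc, data in raw.items()
    }
    return EnsembleModel(
        feature_models=feature_models,
        threshold=payload["threshold"],
        encoder_config=EncoderConfig(lag=cfg["lag"], pssm_rescale=cfg["pssm_rescale"]),
        metadata=payload.get("metadata", {}),
    )
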