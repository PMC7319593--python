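import hashlib

import numpy as np
import pytest
from sklearn.datasets import make_blobs

from acrpred import (
    EVOLUTIONARY_ENCODERS,
    BalancedSubset,
    EnsembleModel,
    FixtureSpec,
    InputError,
    LabeledDataset,
    ModelFormatError,
    SingleFeatureModel,
    SvmSpec,
    gen_labeled_dataset,
    gen_pssm,
    gen_protein,
    grid_search_svm,
    load_builtin_acr_list,
    load_model,
    make_balanced_subsets,
    predict,
    predict_single_feature,
    save_model,
    train_ensemble,
    train_single_feature_model,
)
from acrpred.features import FeatureVector
from conftest import FAST_GRID


def tiny_dataset(n_pos=6, n_neg=30, seed=5):
    ds, _, _ = gen_labeled_dataset(
        FixtureSpec(n_pos=n_pos, n_neg=n_neg, length_range=(50, 70),
                    class_shift=5.0, seed=seed)
    )
    return ds


# ---------------------------------------------------------------------------
# Balanced subsets


def test_make_balanced_subsets_counts_and_balance():
    ds = tiny_dataset()
    subsets = make_balanced_subsets(ds, n_subsets=10, seed=3)
    assert len(subsets) == 10
    pos = set(ds.positive_ids)
    neg = set(ds.negative_ids)
    for sub in subsets:
        assert set(sub.positive_ids) == pos  # every subset keeps all positives
        assert len(sub.negative_ids) == len(sub.positive_ids)
        assert set(sub.negative_ids) <= neg
        assert len(set(sub.negative_ids)) == len(sub.negative_ids)


def test_make_balanced_subsets_deterministic_and_seed_independent_positives():
    ds = tiny_dataset()
    a = make_balanced_subsets(ds, n_subsets=4, seed=9)
    b = make_balanced_subsets(ds, n_subsets=4, seed=9)
    assert a == b
    c = make_balanced_subsets(ds, n_subsets=4, seed=10)
    assert [s.positive_ids for s in c] == [s.positive_ids for s in a]
    assert any(s1.negative_ids != s2.negative_ids for s1, s2 in zip(a, c))


def test_make_balanced_subsets_degenerate():
    ds = tiny_dataset()
    with pytest.raises(InputError):
        make_balanced_subsets(ds, n_subsets=0, seed=1)
    flipped = LabeledDataset(
        ids=ds.ids, features=ds.features, labels=1 - ds.labels
    )
    with pytest.raises(InputError, match="negatives"):
        make_balanced_subsets(flipped, seed=1)


def test_balanced_subset_invariants():
    with pytest.raises(InputError, match="equal class sizes"):
        BalancedSubset(("a", "b"), ("c",), seed=0)
    with pytest.raises(InputError, match="overlap"):
        BalancedSubset(("a",), ("a",), seed=0)


# ---------------------------------------------------------------------------
# Grid search


def test_grid_search_separates_blobs():
    X, y = make_blobs(
        n_samples=40, centers=[[-3, -3], [3, 3]], cluster_std=0.5, random_state=0
    )
    spec = grid_search_svm(X, y, grid_exponents=(-4, -2, 0, 2, 4), folds=5, seed=1)
    assert spec.cost in {2.0**e for e in (-4, -2, 0, 2, 4)}
    # the selected cell must itself reach perfect CV accuracy
    from sklearn.model_selection import StratifiedKFold
    from acrpred.model import _svc_pipeline
    skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=1)
    correct = 0
    for tr, te in skf.split(X, y):
        clf = _svc_pipeline(spec.cost, spec.gamma)
        clf.fit(X[tr], y[tr])
        correct += (clf.predict(X[te]) == y[te]).sum()
    assert correct == len(y)


def test_grid_search_single_cell_forced():
    X, y = make_blobs(n_samples=20, centers=2, random_state=1)
    spec = grid_search_svm(X, y, grid_exponents=(3,), folds=3, seed=0)
    assert spec == SvmSpec(cost=8.0, gamma=8.0)


def test_grid_search_rejects_single_class():
    X = np.random.default_rng(0).normal(size=(10, 3))
    with pytest.raises(InputError, match="both classes"):
        grid_search_svm(X, np.ones(10, dtype=int), folds=2, seed=0)


# ---------------------------------------------------------------------------
# Single-feature models


def test_train_single_feature_model_configuration():
    ds = tiny_dataset()
    model = train_single_feature_model(
        ds, "RPSSM", n_subsets=1, seed=2, grid_exponents=FAST_GRID, grid_folds=3
    )
    assert model.n_subsets == 1
    assert model.encoder == "RPSSM"


def test_train_single_feature_model_deterministic():
    ds = tiny_dataset()
    kwargs = dict(n_subsets=2, seed=4, grid_exponents=FAST_GRID, grid_folds=3)
    a = train_single_feature_model(ds, "PSSM_COMP", **kwargs)
    b = train_single_feature_model(ds, "PSSM_COMP", **kwargs)
    assert a.specs == b.specs
    assert a.subsets == b.subsets
    X = ds.features["PSSM_COMP"]
    assert np.array_equal(a.score(X), b.score(X))


def test_train_single_feature_model_missing_encoder():
    ds = tiny_dataset()
    with pytest.raises(InputError, match="AAC"):
        train_single_feature_model(ds, "AAC", n_subsets=1, seed=0)


class _FixedClassifier:
    """predict_proba stub returning a constant positive-class score."""

    def __init__(self, score):
        self.score = score

    def predict_proba(self, X):
        X = np.atleast_2d(X)
        return np.column_stack([1 - np.full(len(X), self.score),
                                np.full(len(X), self.score)])


def _stub_single(encoder, scores):
    return SingleFeatureModel(
        encoder=encoder,
        classifiers=[_FixedClassifier(s) for s in scores],
        specs=[SvmSpec(1.0, 1.0)] * len(scores),
        subsets=[BalancedSubset(("p",), ("n",), seed=0)] * len(scores),
    )


def test_predict_single_feature_is_member_mean():
    model = _stub_single("RPSSM", [0.0, 1.0])
    x = FeatureVector("q", "RPSSM", np.zeros(110))
    assert predict_single_feature(model, x) == pytest.approx(0.5)
    assert predict_single_feature(_stub_single("RPSSM", [1.0, 1.0, 1.0]), x) == 1.0


def test_predict_single_feature_encoder_mismatch():
    model = _stub_single("RPSSM", [0.5])
    x = FeatureVector("q", "PSSM_AC", np.zeros(200))
    with pytest.raises(InputError, match="does not match"):
        predict_single_feature(model, x)


def test_member_mean_within_bounds():
    rng = np.random.default_rng(11)
    scores = rng.uniform(size=5)
    model = _stub_single("RPSSM", scores)
    x = FeatureVector("q", "RPSSM", np.zeros(110))
    out = predict_single_feature(model, x)
    assert scores.min() <= out <= scores.max()


# ---------------------------------------------------------------------------
# Ensemble


def test_train_ensemble_shape_and_final_score_mean():
    ds = tiny_dataset()
    model = train_ensemble(ds, n_subsets=2, seed=1, grid_exponents=FAST_GRID,
                           grid_folds=3)
    assert set(model.feature_models) == set(EVOLUTIONARY_ENCODERS)
    assert all(fm.n_subsets == 2 for fm in model.feature_models.values())
    final, per_feature = model.score_features(ds.features)
    stacked = np.stack([per_feature[e] for e in EVOLUTIONARY_ENCODERS])
    assert np.allclose(final, stacked.mean(axis=0), atol=1e-12)
    assert np.all((final >= 0) & (final <= 1))


def test_train_ensemble_missing_encoder_named():
    ds = tiny_dataset()
    partial = LabeledDataset(
        ids=ds.ids,
        features={k: v for k, v in ds.features.items() if k != "RPSSM"},
        labels=ds.labels,
    )
    with pytest.raises(InputError, match="RPSSM"):
        train_ensemble(partial, n_subsets=1, seed=0)


def test_train_ensemble_persistence_deterministic(tmp_path):
    ds = tiny_dataset()
    kwargs = dict(n_subsets=2, seed=6, grid_exponents=FAST_GRID, grid_folds=3)
    paths = []
    for name in ("a", "b"):
        model = train_ensemble(ds, **kwargs)
        path = tmp_path / f"{name}.joblib"
        save_model(model, path)
        paths.append(path)
    digests = [hashlib.sha256(p.read_bytes()).hexdigest() for p in paths]
    assert digests[0] == digests[1]


def test_save_load_roundtrip_predictions(tmp_path):
    ds = tiny_dataset()
    model = train_ensemble(ds, n_subsets=2, seed=8, grid_exponents=FAST_GRID,
                           grid_folds=3)
    path = tmp_path / "model.joblib"
    save_model(model, path)
    restored = load_model(path)
    a, _ = model.score_features(ds.features)
    b, _ = restored.score_features(ds.features)
    assert np.allclose(a, b, atol=1e-12)
    assert restored.metadata["master_seed"] == 8


def test_load_model_rejects_corrupt_and_wrong_content(tmp_path):
    path = tmp_path / "junk.joblib"
    path.write_bytes(b"\x00\x01truncated")
    with pytest.raises(ModelFormatError):
        load_model(path)
    with pytest.raises(ModelFormatError, match="not found"):
        load_model(tmp_path / "absent.joblib")
    import joblib
    joblib.dump({"format": "acrpred-ensemble", "version": 99}, tmp_path / "v.joblib")
    with pytest.raises(ModelFormatError, match="version"):
        load_model(tmp_path / "v.joblib")


def test_ensemble_model_invariants():
    with pytest.raises(InputError, match="missing feature models"):
        EnsembleModel(feature_models={})


# ---------------------------------------------------------------------------
# Known-anti-CRISPR filter


@pytest.fixture(scope="module")
def trained_tiny(tmp_path_factory):
    ds = tiny_dataset()
    return train_ensemble(ds, n_subsets=1, seed=3, grid_exponents=FAST_GRID,
                          grid_folds=3)


def test_predict_known_acr_filter_and_benchmarking(trained_tiny):
    known = load_builtin_acr_list()
    known_id, known_seq = next(iter(known.items()))
    rec = gen_protein(1, seed=0, prefix="x")
    rec = type(rec)("query_known", "", known_seq)
    pssm = gen_pssm(rec, seed=44)
    normal = predict(trained_tiny, rec, pssm, benchmarking_mode=False)
    assert normal.known_acr and normal.final_score is None and normal.label == 1
    bench = predict(trained_tiny, rec, pssm, benchmarking_mode=True)
    assert not bench.known_acr
    assert 0.0 <= bench.final_score <= 1.0


def test_benchmarking_scores_superset(trained_tiny):
    """Benchmarking mode scores every protein the normal mode scores."""
    known_seq = next(iter(load_builtin_acr_list().values()))
    records = [gen_protein(60, seed=s, prefix=f"q{s}") for s in (1, 2)]
    records.append(type(records[0])("qk", "", known_seq))
    pssms = {r.id: gen_pssm(r, seed=50 + i) for i, r in enumerate(records)}
    normal = [predict(trained_tiny, r, pssms[r.id], False) for r in records]
    bench = [predict(trained_tiny, r, pssms[r.id], True) for r in records]
    scored_normal = {r.protein_id for r in normal if r.final_score is not None}
    scored_bench = {r.protein_id for r in bench if r.final_score is not None}
    assert scored_normal < scored_bench
    assert scored_bench == {r.id for r in records}


def test_predict_label_consistent_with_threshold(trained_tiny):
    rec = gen_protein(60, seed=21, prefix="q")
    pssm = gen_pssm(rec, seed=22)
    result = predict(trained_tiny, rec, pssm, benchmarking_mode=True)
    assert result.label == int(result.final_score >= trained_tiny.threshold)
    per = np.mean(list(result.per_feature_scores.values()))
    assert result.final_score == pytest.approx(per, abs=1e-12)
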