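"""CFS merit, best-first search, classifier and cross-validation."""

import numpy as np
import pandas as pd
import pytest

import exerscreen as ex
from exerscreen.modelsel import DictAssoc, build_report, symmetric_uncertainty


def random_dataset_assoc(rng, d, n=60):
    """Association structure derived from a random dataset with
    informative, redundant and noise features."""
    z = rng.integers(0, 3, n)
    X = {}
    for i in range(d):
        kind = rng.integers(0, 3)
        if kind == 0:
            X[f"f{i}"] = z + rng.normal(0, rng.uniform(0.5, 2.0), n)
        elif kind == 1:
            X[f"f{i}"] = z + rng.normal(0, 0.3, n)
        else:
            X[f"f{i}"] = rng.normal(0, 1, n)
    return list(X), ex.SymmetricUncertaintyAssoc(pd.DataFrame(X), z)


# ---------------------------------------------------------------- merit

def test_singleton_merit_is_class_association():
    assoc = DictAssoc({"a": 0.6}, {})
    assert ex.cfs_merit(["a"], assoc) == pytest.approx(0.6)


def test_fully_redundant_pair_adds_nothing():
    assoc = DictAssoc({"a": 0.5, "b": 0.5}, {("a", "b"): 1.0})
    assert ex.cfs_merit(["a", "b"], assoc) == pytest.approx(0.5)


def test_independent_pair_beats_singleton():
    assoc = DictAssoc({"a": 0.5, "b": 0.5}, {("a", "b"): 0.0})
    assert ex.cfs_merit(["a", "b"], assoc) == pytest.approx(1 / np.sqrt(2))


def test_empty_subset_merit_zero():
    assert ex.cfs_merit([], DictAssoc({}, {})) == 0.0


def test_symmetric_uncertainty_basics(rng):
    x = rng.integers(0, 4, 500)
    assert symmetric_uncertainty(x, x) == pytest.approx(1.0)
    y = rng.integers(0, 4, 500)
    assert symmetric_uncertainty(x, y) < 0.1
    assert symmetric_uncertainty(np.zeros(10), np.zeros(10)) == 0.0


# ---------------------------------------------------------------- search

def test_single_relevant_feature_selected():
    assoc = DictAssoc({"a": 0.0, "b": 0.7, "c": 0.0}, {})
    res = ex.best_first_select(["a", "b", "c"], assoc)
    assert res.selected == ["b"]
    assert res.merit == pytest.approx(0.7)


def test_search_matches_exhaustive_on_data_derived_structures(rng):
    for _ in range(60):
        names, assoc = random_dataset_assoc(rng, int(rng.integers(2, 9)))
        bf = ex.best_first_select(names, assoc, stale_limit=5)
        exh = ex.exhaustive_select(names, assoc)
        assert bf.merit == pytest.approx(exh.merit, abs=1e-9)
        assert bf.selected == exh.selected


def test_search_is_deterministic(rng):
    names, assoc = random_dataset_assoc(rng, 8)
    a = ex.best_first_select(names, assoc)
    b = ex.best_first_select(names, assoc)
    assert a.selected == b.selected and a.merit == b.merit


def test_tied_features_break_lexicographically():
    assoc = DictAssoc({"zeta": 0.5, "alpha": 0.5}, {("zeta", "alpha"): 1.0})
    res = ex.best_first_select(["zeta", "alpha"], assoc)
    assert res.selected == ["alpha"]


def test_empty_candidate_list_rejected():
    with pytest.raises(ValueError):
        ex.best_first_select([], DictAssoc({}, {}))


# ---------------------------------------------------------------- classifier

def _blobs(rng, n_per=50, d=4, sep=5.0):
    centers = rng.normal(scale=sep, size=(3, d))
    X, y = [], []
    for label, c in zip(("CN", "MCI", "MD"), centers):
        X.append(c + rng.normal(size=(n_per, d)))
        y += [label] * n_per
    return pd.DataFrame(np.vstack(X), columns=[f"x{i}" for i in range(d)]), np.array(y)


def test_classifier_fits_separable_blobs(rng):
    X, y = _blobs(rng)
    model = ex.train_classifier(X.to_numpy(), y, ex.ClassifierConfig(seed=0))
    assert (model.predict(X.to_numpy()) == y).mean() >= 0.95
    proba = model.predict_proba(X.to_numpy())
    assert np.allclose(proba.sum(axis=1), 1.0)


def test_classifier_deterministic_given_seed(rng):
    X, y = _blobs(rng, n_per=20)
    m1 = ex.train_classifier(X.to_numpy(), y, ex.ClassifierConfig(seed=7))
    m2 = ex.train_classifier(X.to_numpy(), y, ex.ClassifierConfig(seed=7))
    for w1, w2 in zip(m1["mlp"].coefs_, m2["mlp"].coefs_):
        assert np.array_equal(w1, w2)


def test_single_class_training_rejected():
    X = np.zeros((10, 2))
    with pytest.raises(ValueError):
        ex.train_classifier(X, ["CN"] * 10)


def test_cross_validate_rejects_bad_folds(rng):
    X, y = _blobs(rng, n_per=10)
    with pytest.raises(ValueError):
        ex.cross_validate(X, y, k=1)
    with pytest.raises(ValueError):
        ex.cross_validate(X, y, selection="magic")


def test_confusion_row_sums_equal_class_counts(small_study):
    feats = small_study.features
    X = feats.drop(columns=["participant_id", "label"])
    y = feats["label"].to_numpy()
    rep = ex.cross_validate(X, y, k=4, seed=0, selection="nested")
    counts = {c: int((y == c).sum()) for c in rep.classes}
    for i, c in enumerate(rep.classes):
        assert rep.confusion[i].sum() == counts[c]
    assert rep.confusion.sum() == len(y)


def test_report_identities_hold():
    """sensitivity = TP rate, specificity = 1 - FP rate and accuracy =
    trace/total on any report."""
    rng = np.random.default_rng(5)
    y = np.array(["CN"] * 38 + ["MCI"] * 64 + ["MD"] * 14)
    pred = rng.choice(["CN", "MCI", "MD"], size=116, p=[0.3, 0.55, 0.15])
    proba = rng.dirichlet(np.ones(3), size=116)
    rep = build_report(y, pred, proba, ("CN", "MCI", "MD"))
    total = rep.confusion.sum()
    for i, c in enumerate(rep.classes):
        tp = rep.confusion[i, i]
        fn = rep.confusion[i].sum() - tp
        fp = rep.confusion[:, i].sum() - tp
        tn = total - tp - fn - fp
        assert rep.sensitivity[c] == pytest.approx(rep.tp_rate[c])
        assert rep.specificity[c] == pytest.approx(1 - rep.fp_rate[c])
        assert rep.tp_rate[c] == pytest.approx(tp / (tp + fn))
        assert rep.fp_rate[c] == pytest.approx(fp / (fp + tn))
    assert rep.overall_accuracy == pytest.approx(100 * np.trace(rep.confusion) / total)


def test_no_leakage_from_test_folds(rng):
    """Shuffling labels of a held-out block never changes the training-fold
    selection: selection sees only its training rows."""
    feats, y = _blobs(rng, n_per=15)
    train_idx = np.arange(30)
    assoc = ex.SymmetricUncertaintyAssoc(feats.iloc[train_idx], y[train_idx])
    sel_before = ex.best_first_select(list(feats.columns), assoc).selected
    y2 = y.copy()
    y2[30:] = rng.permutation(y2[30:])
    assoc2 = ex.SymmetricUncertaintyAssoc(feats.iloc[train_idx], y2[train_idx])
    assert ex.best_first_select(list(feats.columns), assoc2).selected == sel_before


def test_pooled_and_nested_selection_both_run(small_study):
    feats = small_study.features
    X = feats.drop(columns=["participant_id", "label"])
    y = feats["label"].to_numpy()
    pooled = ex.cross_validate(X, y, k=3, seed=1, selection="pooled")
    assert len(set(map(tuple, pooled.selected_features))) == 1  # one shared subset
    nested = ex.cross_validate(X, y, k=3, seed=1, selection="nested")
    assert len(nested.selected_features) == 3
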