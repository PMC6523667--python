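"""Problem/cluster dataset assembly, CV protocol, and metric formulas."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import cohen_kappa_score, f1_score, precision_score

from eegad.classify import (
    PROBLEMS,
    MetricSet,
    alt_classifiers,
    build_dataset,
    cohen_kappa,
    metrics_from_confusion,
    run_cv,
    weighted_precision_f1,
)
from eegad.features import feature_columns
from eegad.montage import CHANNELS_1020, cluster_channels


def fake_feature_table(rng, n_per_group=30, shift=0.0):
    """A feature-shaped table with optional group mean shifts."""
    cols = feature_columns(CHANNELS_1020)
    rows, labels, subjects = [], [], []
    for gi, g in enumerate(("CN", "mild", "moderate")):
        for i in range(n_per_group):
            rows.append(rng.normal(size=len(cols)) + gi * shift)
            labels.append(g)
            subjects.append(f"{g}{i % 3}")
    df = pd.DataFrame(rows, columns=cols)
    df.insert(0, "label", labels)
    df.insert(0, "window_s", 12.0)
    df.insert(0, "subject_id", subjects)
    return df


# ---------------------------------------------------------------------------
# dataset assembly


def test_six_problems_defined():
    assert len(PROBLEMS) == 6
    assert PROBLEMS["CN/AD"]["mild"] == "AD"
    assert PROBLEMS["CN-mild/moderate"]["CN"] == "CN-mild"


def test_cn_moderate_drops_mild(rng):
    df = fake_feature_table(rng)
    X, y = build_dataset(df, "CN/moderate")
    assert set(y) == {"CN", "moderate"}
    assert len(X) == 60


def test_cn_ad_merges_patient_groups(rng):
    X, y = build_dataset(fake_feature_table(rng), "CN/AD")
    assert set(y) == {"CN", "AD"}
    assert (y == "AD").sum() == 60


def test_cluster_restriction_column_counts(rng):
    df = fake_feature_table(rng)
    X, _ = build_dataset(df, "CN/AD", "central")
    assert X.shape[1] == 38 * 3  # 114
    X, _ = build_dataset(df, "CN/AD", "whole")
    assert X.shape[1] == 722
    X, _ = build_dataset(df, "CN/AD", "posterior")
    assert X.shape[1] == 38 * 5
    assert all(c.split("_", 1)[0] in cluster_channels("posterior")
               for c in X.columns)


def test_unknown_problem_or_cluster_rejected(rng):
    df = fake_feature_table(rng)
    with pytest.raises(KeyError):
        build_dataset(df, "CN/severe")
    with pytest.raises(KeyError):
        build_dataset(df, "CN/AD", "occipital")


def test_empty_class_rejected(rng):
    df = fake_feature_table(rng)
    df = df[df.label != "moderate"]
    with pytest.raises(ValueError):
        build_dataset(df, "CN/moderate")


# ---------------------------------------------------------------------------
# cross-validation


def separable_data(rng, n=60):
    X = pd.DataFrame(rng.normal(size=(2 * n, 5)))
    X.iloc[n:] += 25.0  # disjoint supports
    y = pd.Series(["a"] * n + ["b"] * n)
    return X, y


def test_separable_data_gives_perfect_metrics(rng):
    X, y = separable_data(rng)
    m = run_cv(X, y, folds=10, seed=0)
    assert m.accuracy == 100.0
    assert m.kappa == 1.0 and m.f1 == 1.0
    assert m.n_epochs == len(y)


def test_cv_is_deterministic(rng):
    df = fake_feature_table(rng, shift=0.3)
    X, y = build_dataset(df, "CN/AD")
    m1 = run_cv(X, y, folds=5, seed=3)
    m2 = run_cv(X, y, folds=5, seed=3)
    assert m1 == m2


def test_permuted_labels_score_near_chance(rng):
    """Label permutation destroys signal: balanced accuracy ~ 50%."""
    X = pd.DataFrame(rng.normal(size=(400, 10)))
    y = pd.Series(rng.permutation(["a"] * 200 + ["b"] * 200))
    m = run_cv(X, y, folds=10, seed=1)
    assert abs(m.accuracy - 50.0) < 5.0
    assert abs(m.kappa) < 0.1


def test_too_few_epochs_per_class_rejected(rng):
    X = pd.DataFrame(rng.normal(size=(12, 3)))
    y = pd.Series(["a"] * 8 + ["b"] * 4)
    with pytest.raises(ValueError, match="folds"):
        run_cv(X, y, folds=10)


def test_grouped_cv_keeps_subject_epochs_together(rng):
    """In grouped mode no subject straddles a train/test boundary."""
    from sklearn.model_selection import StratifiedGroupKFold

    groups = np.repeat(np.arange(12), 10)
    y = pd.Series(np.where(groups % 2 == 0, "a", "b"))
    X = pd.DataFrame(rng.normal(size=(120, 4)))
    m = run_cv(X, y, folds=4, seed=0, groups=groups)
    assert m.n_epochs == 120  # every epoch tested exactly once


# ---------------------------------------------------------------------------
# metric formulas


def test_kappa_hand_computed_confusion():
    confusion = np.array([[40, 10], [20, 30]])
    m = metrics_from_confusion(confusion, ("a", "b"))
    assert m.accuracy == pytest.approx(70.0)
    # p_o = 0.7; p_e = 0.5*0.6 + 0.5*0.4 = 0.5
    assert m.kappa == pytest.approx((0.7 - 0.5) / 0.5)


def test_kappa_perfect_and_chance():
    assert cohen_kappa(np.diag([5, 7, 9])) == 1.0
    assert cohen_kappa(np.full((3, 3), 4)) == pytest.approx(0.0)


def test_kappa_degenerate_single_cell_warns():
    c = np.zeros((2, 2))
    c[0, 0] = 10
    with pytest.warns(UserWarning):
        assert cohen_kappa(c) == 0.0


def test_metrics_match_sklearn_on_random_confusions(rng):
    """kappa / weighted precision / weighted F1 equal sklearn oracles,
    and weighted recall equals accuracy, over random matrices."""
    for _ in range(200):
        k = int(rng.integers(2, 5))
        c = rng.integers(0, 30, size=(k, k))
        if c.sum() == 0 or (c.sum(axis=1) == 0).any():
            continue
        y_true = np.repeat(np.arange(k), c.sum(axis=1))
        y_pred = np.concatenate(
            [np.repeat(np.arange(k), c[i]) for i in range(k)])
        prec, f1 = weighted_precision_f1(c)
        assert prec / 100 == pytest.approx(
            precision_score(y_true, y_pred, average="weighted",
                            zero_division=0), abs=1e-12)
        assert f1 == pytest.approx(
            f1_score(y_true, y_pred, average="weighted", zero_division=0),
            abs=1e-12)
        expected_kappa = cohen_kappa_score(y_true, y_pred)
        if np.isfinite(expected_kappa):
            assert cohen_kappa(c) == pytest.approx(expected_kappa, abs=1e-12)
        # weighted recall is accuracy by construction
        support = c.sum(axis=1)
        recall = np.divide(np.diag(c), support, where=support > 0,
                           out=np.zeros(k, float))
        acc = np.trace(c) / c.sum()
        assert (support / c.sum() @ recall) == pytest.approx(acc, abs=1e-12)


def test_metricset_roundtrip():
    m = metrics_from_confusion(np.array([[5, 1], [2, 6]]), ("x", "y"))
    assert MetricSet.from_dict(m.to_dict()) == m


# ---------------------------------------------------------------------------
# alternate classifiers


def test_rf_model_name_matches_run_cv(rng):
    X, y = separable_data(rng, n=30)
    assert alt_classifiers(X, y, "RF", folds=5, seed=2) == run_cv(
        X, y, folds=5, seed=2)


def test_knn_on_separable_data_is_perfect(rng):
    X, y = separable_data(rng, n=30)
    m = alt_classifiers(X, y, "KNN", folds=5, seed=0)
    assert m.accuracy == 100.0


@pytest.mark.parametrize("name", ["RF", "MLP", "KNN", "SVM", "NB", "DT"])
def test_all_registry_models_accepted(rng, name):
    X, y = separable_data(rng, n=15)
    m = alt_classifiers(X, y, name, folds=3, seed=0)
    assert 0 <= m.accuracy <= 100


def test_unknown_model_rejected(rng):
    X, y = separable_data(rng, n=15)
    with pytest.raises(KeyError):
        alt_classifiers(X, y, "XGB", folds=3)
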