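"""Grouped CV, random search, final models and per-video verdicts."""

import numpy as np
import pandas as pd
import pytest

from planeqc import (
    FEATURE_COLUMNS,
    ORGANS,
    FeatureDataset,
    HyperparamSpace,
    OrganId,
    OrganModelSuite,
    TrainedModel,
    WindowingConfig,
    grouped_kfold,
    load_suite,
    random_search,
    save_suite,
    split_by_patient,
    train_final,
    train_suite,
)
from planeqc.classifier import balanced_accuracy
from planeqc.io import ValidationError


def test_grouped_kfold_even_division():
    groups = np.repeat([f"P{i}" for i in range(10)], 3)  # 10 patients x 3 rows
    folds = grouped_kfold(groups, k=5, seed=0)
    assert len(folds) == 5
    val_union = np.sort(np.concatenate([val for _, val in folds]))
    np.testing.assert_array_equal(val_union, np.arange(len(groups)))
    for train_idx, val_idx in folds:
        assert len(set(groups[val_idx])) == 2  # exactly 2 patients per fold
        assert not set(groups[train_idx]) & set(groups[val_idx])  # no leakage


def test_grouped_kfold_too_few_groups():
    with pytest.raises(ValidationError):
        grouped_kfold(["a", "a", "b", "c", "d"], k=5)


def _organ_train(small_dataset, organ=OrganId.anus):
    return small_dataset.for_organ(organ)


def test_random_search_singleton_returns_that_config(small_dataset):
    train = _organ_train(small_dataset)
    space = HyperparamSpace(n_iter=1, seed=3)
    result = random_search(train, space, k=5)
    assert len(result.trials) == 1
    assert result.best_params == result.trials[0]["params"]


def test_random_search_is_seed_deterministic(small_dataset):
    train = _organ_train(small_dataset)
    space = HyperparamSpace(n_iter=3, seed=4)
    a = random_search(train, space, k=5)
    b = random_search(train, space, k=5)
    assert a.best_params == b.best_params and a.best_score == b.best_score
    assert a.trials == b.trials


def test_random_search_rejects_single_class(small_dataset):
    train = _organ_train(small_dataset, OrganId.pubis)  # pubis is never lost
    assert len(np.unique(train.labels())) == 1
    with pytest.raises(ValidationError):
        random_search(train, HyperparamSpace(n_iter=1), k=5)


def test_train_predict_on_separable_cohort_is_accurate(small_dataset):
    train = _organ_train(small_dataset)
    result = random_search(train, HyperparamSpace(n_iter=2, seed=5), k=5)
    model = train_final(train, result.best_params, seed=5)
    pred = (model.predict_proba(train.features()) > 0.5).astype(int)
    assert balanced_accuracy(train.labels(), pred) >= 0.95


def test_retrain_same_seed_gives_identical_predictions(small_dataset):
    train = _organ_train(small_dataset)
    params = {"n_estimators": 60, "max_depth": 3, "learning_rate": 0.1}
    p1 = train_final(train, params, seed=9).predict_proba(train.features())
    p2 = train_final(train, params, seed=9).predict_proba(train.features())
    np.testing.assert_array_equal(p1, p2)


def test_manifest_guard_rejects_permuted_columns(small_dataset):
    train = _organ_train(small_dataset)
    model = train_final(train, {"n_estimators": 20, "max_depth": 2}, seed=0)
    permuted = tuple(reversed(FEATURE_COLUMNS))
    with pytest.raises(ValidationError, match="manifest"):
        model.predict_proba(train.features(), feature_names=permuted)


def _constant_suite(probabilities: dict) -> OrganModelSuite:
    models = {
        organ: TrainedModel(
            booster=None,
            feature_names=tuple(FEATURE_COLUMNS),
            hyperparams={},
            seed=0,
            constant_probability=probabilities.get(organ, 0.9),
        )
        for organ in ORGANS
    }
    return OrganModelSuite(models)


def _one_patient_rows(n_windows=1):
    rows = []
    for organ in ORGANS:
        for w in range(n_windows):
            row = {"patient_id": "P001", "organ": organ.value, "window_index": w}
            row.update({c: 0.0 for c in FEATURE_COLUMNS})
            row["label"] = 1
            rows.append(row)
    return FeatureDataset(pd.DataFrame(rows))


def test_plane_verdict_is_conjunction_of_organ_verdicts():
    rows = _one_patient_rows()
    assert _constant_suite({}).predict_video(rows).plane_correct == 1
    failing = _constant_suite({OrganId.rectum: 0.2})
    verdict = failing.predict_video(rows)
    assert verdict.organ_verdict[OrganId.rectum] == 0
    assert verdict.plane_correct == 0  # a single organ failure breaks the AND


def test_window_probabilities_average_before_threshold(small_dataset):
    # one organ with window probabilities 0.4 and 0.8 -> mean 0.6 -> verdict 1
    suite = _constant_suite({})
    rows = _one_patient_rows(n_windows=2)
    model = suite.models[OrganId.anus]
    model.predict_proba = lambda X, feature_names=None: np.array([0.4, 0.8])
    verdict = suite.predict_video(rows)
    assert verdict.organ_probability[OrganId.anus] == pytest.approx(0.6)
    assert verdict.organ_verdict[OrganId.anus] == 1


def test_missing_organ_rows_rejected():
    rows = _one_patient_rows()
    pruned = FeatureDataset(rows.table[rows.table["organ"] != "anus"].copy())
    with pytest.raises(ValidationError, match="anus"):
        _constant_suite({}).predict_video(pruned)


def test_suite_handles_constant_label_organs_and_roundtrips(tmp_path, small_dataset):
    patients = sorted(small_dataset.table["patient_id"].unique())
    train, test = split_by_patient(small_dataset, patients[:12], patients[12:])
    suite = train_suite(train, HyperparamSpace(n_iter=2, seed=2), k=5)
    assert suite.models[OrganId.vagina].is_constant
    assert suite.models[OrganId.vagina].constant_probability == 1.0
    assert not suite.models[OrganId.anus].is_constant
    verdicts = suite.predict_dataset(test)
    assert len(verdicts) == len(patients) - 12
    # serialization roundtrip preserves predictions
    save_suite(suite, tmp_path / "model")
    back = load_suite(tmp_path / "model")
    for organ in ORGANS:
        np.testing.assert_allclose(
            back.models[organ].predict_proba(test.features()),
            suite.models[organ].predict_proba(test.features()),
        )
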