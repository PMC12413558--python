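"""Gradient-boosted organ-correctness models and per-video plane verdicts.

One binary gradient-boosting (XGBoost) model is trained per organ, matching
the study design of judging each organ separately; the plane verdict is the
conjunction of the eight organ verdicts.  Because several dataset rows
(windows) come from the same patient, every model-selection fold and the
train/test split are grouped by patient: a patient's rows never appear on
both sides of any boundary.

Hyperparameters are chosen by random search over a standard gradient-boosting
space sized for datasets of roughly 1–2k rows, scored by mean balanced
accuracy over grouped 5-fold cross-validation (labels are imbalanced for most
organs).  Organs whose training labels are constant — which happens whenever
no defect mode ever removes them — get a constant predictor instead of a
fitted ensemble; they are retained and reported, not dropped.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.model_selection import GroupKFold
from xgboost import XGBClassifier

from .dataset import FEATURE_COLUMNS, FEATURE_NAMES_68, FeatureDataset

# scikit-learn >= 1.6 removed `_estimator_type` from its mixins, which breaks
# XGBClassifier.save_model/load_model in xgboost 3.0.x; restore the attribute.
if not hasattr(XGBClassifier, "_estimator_type"):
    XGBClassifier._estimator_type = "classifier"
from .io import ValidationError
from .organs import ORGANS, OrganId


@dataclasses.dataclass(frozen=True)
class HyperparamSpace:
    """Random-search space for the boosted trees.

    Ranges: tree count 50–500, depth 2–8, learning rate log-uniform on
    [0.01, 0.3], row and column subsampling 0.6–1.0, L2 regularization 0–5.
    """

    n_estimators: tuple[int, int] = (50, 500)
    max_depth: tuple[int, int] = (2, 8)
    learning_rate: tuple[float, float] = (0.01, 0.3)
    subsample: tuple[float, float] = (0.6, 1.0)
    colsample_bytree: tuple[float, float] = (0.6, 1.0)
    reg_lambda: tuple[float, float] = (0.0, 5.0)
    n_iter: int = 50
    seed: int = 0

    def sample(self, rng: np.random.Generator) -> dict:
        lo, hi = self.learning_rate
        return {
            "n_estimators": int(rng.integers(self.n_estimators[0], self.n_estimators[1] + 1)),
            "max_depth": int(rng.integers(self.max_depth[0], self.max_depth[1] + 1)),
            "learning_rate": float(np.exp(rng.uniform(np.log(lo), np.log(hi)))),
            "subsample": float(rng.uniform(*self.subsample)),
            "colsample_bytree": float(rng.uniform(*self.colsample_bytree)),
            "reg_lambda": float(rng.uniform(*self.reg_lambda)),
        }


def _make_booster(params: dict, seed: int) -> XGBClassifier:
    return XGBClassifier(
        **params,
        objective="binary:logistic",
        tree_method="hist",
        n_jobs=1,
        random_state=int(seed) & 0x7FFFFFFF,
        eval_metric="logloss",
    )


def grouped_kfold(
    groups: Sequence, k: int = 5, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Patient-grouped K-fold partitions of row indices.

    Every group's rows fall entirely inside exactly one validation fold and
    the validation folds partition all rows.
    """
    groups = np.asarray(groups)
    n_groups = len(np.unique(groups))
    if n_groups < k:
        raise ValidationError(f"need at least k={k} distinct groups, got {n_groups}")
    splitter = GroupKFold(n_splits=k, shuffle=True, random_state=int(seed) & 0x7FFFFFFF)
    return [
        (train_idx, val_idx)
        for train_idx, val_idx in splitter.split(np.zeros(len(groups)), groups=groups)
    ]


def balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean per-class recall over the classes present in ``y_true``."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    recalls = [
        float(np.mean(y_pred[y_true == cls] == cls)) for cls in np.unique(y_true)
    ]
    return float(np.mean(recalls))


@dataclasses.dataclass
class SearchResult:
    best_params: dict
    best_score: float
    trials: list[dict]  # one record per sampled configuration


def random_search(
    train: FeatureDataset,
    space: HyperparamSpace,
    k: int = 5,
) -> SearchResult:
    """Random hyperparameter search scored by grouped k-fold balanced accuracy.

    Fully reproducible from ``space.seed``.  Raises on single-class labels —
    callers must handle degenerate organs separately.
    """
    X = train.features()
    y = train.labels()
    groups = train.groups
    if train.n_rows == 0:
        raise ValidationError("training set is empty")
    if len(np.unique(y)) < 2:
        raise ValidationError("training labels are single-class; cannot search")
    rng = np.random.default_rng(np.random.SeedSequence([int(space.seed), 0x5EA]))
    folds = grouped_kfold(groups, k=k, seed=space.seed)
    trials = []
    best: tuple[float, dict] | None = None
    for i in range(space.n_iter):
        params = space.sample(rng)
        scores = []
        for train_idx, val_idx in folds:
            y_tr = y[train_idx]
            if len(np.unique(y_tr)) < 2:
                # A fold may isolate all minority patients; score it as chance.
                scores.append(0.5)
                continue
            model = _make_booster(params, space.seed)
            model.fit(X[train_idx], y_tr)
            pred = model.predict(X[val_idx])
            scores.append(balanced_accuracy(y[val_idx], pred))
        mean_score = float(np.mean(scores))
        trials.append({"params": params, "cv_balanced_accuracy": mean_score})
        if best is None or mean_score > best[0]:
            best = (mean_score, params)
    assert best is not None
    return SearchResult(best_params=best[1], best_score=best[0], trials=trials)


@dataclasses.dataclass
class TrainedModel:
    """A fitted per-organ model plus the feature manifest it was trained on."""

    booster: XGBClassifier | None  # None for a constant predictor
    feature_names: tuple[str, ...]
    hyperparams: dict
    seed: int
    constant_probability: float | None = None
    cv_report: dict | None = None

    @property
    def is_constant(self) -> bool:
        return self.booster is None

    def _check_manifest(self, feature_names: Sequence[str]) -> None:
        if tuple(feature_names) != self.feature_names:
            raise ValidationError(
                "feature manifest mismatch: prediction columns differ from training"
            )

    def predict_proba(
        self, X: np.ndarray, feature_names: Sequence[str] | None = None
    ) -> np.ndarray:
        """P(organ correctly visualized) per row."""
        self._check_manifest(
            self.feature_names if feature_names is None else feature_names
        )
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.feature_names):
            raise ValidationError(
                f"expected {len(self.feature_names)} feature columns, got {X.shape}"
            )
        if self.is_constant:
            return np.full(X.shape[0], float(self.constant_probability))
        return self.booster.predict_proba(X)[:, 1]


def train_final(
    train: FeatureDataset, hyperparams: dict, seed: int = 0, cv_report: dict | None = None
) -> TrainedModel:
    """Fit the final model on the whole training set with chosen hyperparameters.

    Single-class training labels produce a constant predictor.
    """
    y = train.labels()
    classes = np.unique(y)
    if len(classes) < 2:
        return TrainedModel(
            booster=None,
            feature_names=tuple(FEATURE_COLUMNS),
            hyperparams={},
            seed=seed,
            constant_probability=float(classes[0]),
            cv_report=cv_report,
        )
    model = _make_booster(hyperparams, seed)
    model.fit(train.features(), y)
    return TrainedModel(
        booster=model,
        feature_names=tuple(FEATURE_COLUMNS),
        hyperparams=dict(hyperparams),
        seed=seed,
        cv_report=cv_report,
    )


@dataclasses.dataclass
class VideoVerdict:
    """Per-video judgment: per-organ probabilities/verdicts and the plane AND."""

    patient_id: str
    organ_probability: dict[OrganId, float]
    organ_verdict: dict[OrganId, int]
    plane_correct: int


@dataclasses.dataclass
class OrganModelSuite:
    """The eight per-organ models, applied jointly to produce video verdicts."""

    models: dict[OrganId, TrainedModel]

    def predict_video(
        self, rows: FeatureDataset, aggregation: str = "mean"
    ) -> VideoVerdict:
        """Verdict for one patient's rows (>= 1 window per organ).

        Window probabilities are pooled per organ — mean probability then a
        0.5 threshold by default, or a majority vote of window verdicts with
        ``aggregation="vote"`` — and the plane verdict is the AND over organs.
        """
        pids = set(rows.table["patient_id"].unique())
        if len(pids) != 1:
            raise ValidationError(f"expected rows for exactly one patient, got {pids}")
        patient_id = pids.pop()
        probs: dict[OrganId, float] = {}
        verdicts: dict[OrganId, int] = {}
        for organ in ORGANS:
            organ_rows = rows.for_organ(organ)
            if organ_rows.n_rows == 0:
                raise ValidationError(
                    f"no rows for organ {organ.value!r} of patient {patient_id!r}"
                )
            p = self.models[organ].predict_proba(organ_rows.features())
            if aggregation == "vote":
                verdict = int(np.mean(p > 0.5) > 0.5)
                prob = float(np.mean(p))
            elif aggregation == "mean":
                prob = float(np.mean(p))
                verdict = int(prob > 0.5)
            else:
                raise ValidationError(f"unknown aggregation {aggregation!r}")
            probs[organ] = prob
            verdicts[organ] = verdict
        plane = int(all(verdicts[o] == 1 for o in ORGANS))
        return VideoVerdict(patient_id, probs, verdicts, plane)

    def predict_dataset(
        self, dataset: FeatureDataset, aggregation: str = "mean"
    ) -> list[VideoVerdict]:
        out = []
        for pid in dict.fromkeys(dataset.table["patient_id"]):
            rows = FeatureDataset(
                dataset.table[dataset.table["patient_id"] == pid].reset_index(drop=True),
                dataset.windowing,
            )
            out.append(self.predict_video(rows, aggregation))
        return out


def train_suite(
    train: FeatureDataset,
    space: HyperparamSpace,
    k: int = 5,
) -> OrganModelSuite:
    """Per-organ random search + final fit; constant predictors for
    single-class organs."""
    models: dict[OrganId, TrainedModel] = {}
    for organ in ORGANS:
        organ_train = train.for_organ(organ)
        y = organ_train.labels()
        if len(np.unique(y)) < 2:
            models[organ] = train_final(organ_train, {}, seed=space.seed)
            continue
        search = random_search(organ_train, space, k=k)
        models[organ] = train_final(
            organ_train,
            search.best_params,
            seed=space.seed,
            cv_report={
                "best_cv_balanced_accuracy": search.best_score,
                "n_iter": space.n_iter,
                "k": k,
            },
        )
    return OrganModelSuite(models)


def save_suite(suite: OrganModelSuite, directory: str | Path) -> None:
    """Serialize: native XGBoost model files plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"feature_names": list(FEATURE_COLUMNS),
                      "feature_manifest": dict(zip(FEATURE_COLUMNS, FEATURE_NAMES_68)),
                      "organs": {}}
    for organ, model in suite.models.items():
        entry: dict = {
            "hyperparams": model.hyperparams,
            "seed": model.seed,
            "cv_report": model.cv_report,
        }
        if model.is_constant:
            entry["constant_probability"] = model.constant_probability
        else:
            fname = f"{organ.value}.ubj"
            model.booster.save_model(directory / fname)
            entry["model_file"] = fname
        manifest["organs"][organ.value] = entry
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_suite(directory: str | Path) -> OrganModelSuite:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    feature_names = tuple(manifest["feature_names"])
    models: dict[OrganId, TrainedModel] = {}
    for organ in ORGANS:
        entry = manifest["organs"][organ.value]
        if "constant_probability" in entry:
            models[organ] = TrainedModel(
                booster=None,
                feature_names=feature_names,
                hyperparams={},
                seed=entry["seed"],
                constant_probability=entry["constant_probability"],
                cv_report=entry.get("cv_report"),
            )
        else:
            booster = XGBClassifier()
            booster.load_model(directory / entry["model_file"])
            models[organ] = TrainedModel(
                booster=booster,
                feature_names=feature_names,
                hyperparams=entry["hyperparams"],
                seed=entry["seed"],
                cv_report=entry.get("cv_report"),
            )
    return OrganModelSuite(models)
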