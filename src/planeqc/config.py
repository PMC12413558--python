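"""End-to-end experiment orchestration: simulate → featurize → train →
predict → concordance.

A :class:`PipelineConfig` fully determines a run: one master seed is spawned
into per-stage sub-seeds, so reruns with the same config are bit-identical.
The experiment mirrors the study design: a cohort of correct/incorrect-plane
videos, a positional train/test split by patient (first ``n_train`` ids),
per-organ gradient-boosting models selected by grouped-CV random search, and
a concordance table of the model's test verdicts against the ground truth.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path
from typing import Sequence

import yaml

from .classifier import HyperparamSpace, OrganModelSuite, save_suite, train_suite
from .concordance import concordance_table, labels_to_frame, verdicts_to_frame
from .dataset import FeatureDataset, WindowingConfig, build_dataset, split_by_patient
from .io import LabelTable, ValidationError, write_labels, write_video
from .simulator import SimCohortConfig, simulate_cohort

logger = logging.getLogger("planeqc")


@dataclasses.dataclass
class PipelineConfig:
    """Everything one experiment needs, serializable to/from YAML."""

    simulator: SimCohortConfig = dataclasses.field(default_factory=SimCohortConfig)
    windowing: WindowingConfig = dataclasses.field(default_factory=WindowingConfig)
    search: HyperparamSpace = dataclasses.field(default_factory=HyperparamSpace)
    n_train: int = 60  # first n_train patients train, the rest test
    cv_folds: int = 5
    seed: int = 7
    write_videos: bool = False  # HDF5 cohort dump is optional (large)

    def __post_init__(self):
        # One master seed drives every stage: sub-seed 1 for simulation,
        # sub-seed 2 for the hyperparameter search.
        self.simulator = dataclasses.replace(self.simulator, seed=self.seed * 1000 + 1)
        self.search = dataclasses.replace(self.search, seed=self.seed * 1000 + 2)

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "simulator": dataclasses.asdict(self.simulator),
            "windowing": dataclasses.asdict(self.windowing),
            "search": dataclasses.asdict(self.search),
            "n_train": self.n_train,
            "cv_folds": self.cv_folds,
            "seed": self.seed,
            "write_videos": self.write_videos,
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("simulator", {})
        sim.pop("seed", None)
        win = raw.pop("windowing", {})
        search = raw.pop("search", {})
        search.pop("seed", None)
        for key in ("n_estimators", "max_depth", "learning_rate", "subsample",
                    "colsample_bytree", "reg_lambda"):
            if key in search and isinstance(search[key], list):
                search[key] = tuple(search[key])
        if "defect_mix" in sim and isinstance(sim["defect_mix"], list):
            sim["defect_mix"] = tuple(sim["defect_mix"])
        return cls(
            simulator=SimCohortConfig(**sim),
            windowing=WindowingConfig(**win),
            search=HyperparamSpace(**search),
            **raw,
        )


def _stage(name: str):
    logger.info("stage %s", name)
    return time.perf_counter()


def run_experiment(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Run the full pipeline; returns (and optionally writes) a JSON report.

    The report records row counts, the chosen hyperparameters and CV scores
    per organ, and the test concordance (kappa etc.) per endpoint.  With
    ``out_dir`` set, the cohort labels, datasets, model artifacts, verdicts
    and concordance table are written there.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    t0 = _stage("simulate")
    try:
        videos, labels = simulate_cohort(config.simulator)
    except Exception as exc:
        raise RuntimeError(f"stage simulate failed: {exc}") from exc
    patients = [v.patient_id for v in videos]
    if not 0 < config.n_train < len(patients):
        raise ValidationError(
            f"n_train={config.n_train} must split {len(patients)} patients non-trivially"
        )
    if out is not None:
        write_labels(labels, out / "labels.csv")
        if config.write_videos:
            vid_dir = out / "videos"
            vid_dir.mkdir(exist_ok=True)
            for v in videos:
                write_video(v, vid_dir / f"{v.patient_id}.h5")
    sim_s = time.perf_counter() - t0

    t0 = _stage("featurize")
    try:
        dataset = build_dataset(videos, labels, config.windowing)
    except Exception as exc:
        raise RuntimeError(f"stage featurize failed: {exc}") from exc
    del videos
    train_ids = patients[: config.n_train]
    test_ids = patients[config.n_train :]
    train_ds, test_ds = split_by_patient(dataset, train_ids, test_ids)
    if out is not None:
        train_ds.to_csv(out / "train.csv")
        test_ds.to_csv(out / "test.csv")
    feat_s = time.perf_counter() - t0

    t0 = _stage("train")
    try:
        suite = train_suite(train_ds, config.search, k=config.cv_folds)
    except Exception as exc:
        raise RuntimeError(f"stage train failed: {exc}") from exc
    if out is not None:
        save_suite(suite, out / "model")
    train_s = time.perf_counter() - t0

    t0 = _stage("predict")
    verdicts = suite.predict_dataset(test_ds)
    verdict_frame = verdicts_to_frame(verdicts)
    if out is not None:
        verdict_frame.to_csv(out / "verdicts.csv", index=False)
    pred_s = time.perf_counter() - t0

    t0 = _stage("concordance")
    truth_frame = labels_to_frame(labels)
    truth_test = truth_frame[truth_frame["patient_id"].isin(test_ids)]
    table = concordance_table(truth_test, verdict_frame)
    if out is not None:
        table.to_csv(out / "concordance.csv", index=False)
    conc_s = time.perf_counter() - t0

    report = {
        "seed": config.seed,
        "n_videos": len(patients),
        "n_label_rows": int(len(labels.organ_correct)),
        "n_dataset_rows": dataset.n_rows,
        "n_train_rows": train_ds.n_rows,
        "n_test_rows": test_ds.n_rows,
        "n_train_patients": len(train_ids),
        "n_test_patients": len(test_ids),
        "cv": {
            organ.value: model.cv_report
            for organ, model in suite.models.items()
            if model.cv_report is not None
        },
        "hyperparams": {
            organ.value: model.hyperparams for organ, model in suite.models.items()
        },
        "test_concordance": {
            row["endpoint"]: {
                "kappa": None if not row["agreement"] else row["kappa"],
                "agreement": row["agreement"],
                "mcnemar_p": None if not row["agreement"] else row["mcnemar_p"],
            }
            for row in table.to_dict("records")
        },
    }
    # Timings are logged, not reported: the report is bit-identical across reruns.
    logger.info(
        "timings: simulate %.1fs featurize %.1fs train %.1fs predict %.1fs "
        "concordance %.1fs", sim_s, feat_s, train_s, pred_s, conc_s,
    )
    if out is not None:
        (out / "report.json").write_text(json.dumps(report, indent=2))
    return report


def noise_sweep(
    noise_levels: Sequence[float],
    seeds: Sequence[int],
    base: PipelineConfig | None = None,
) -> dict[float, list[float]]:
    """Plane-verdict test kappa as the background noise rises toward the blob
    confidence.

    For each background-noise level, the full experiment is rerun for each
    seed and the test-set plane kappa against ground truth is collected.  As
    noise approaches the blob confidence the segmenter's confidence contrast
    collapses and agreement should degrade — the sanity direction check for
    the whole pipeline.
    """
    base = PipelineConfig() if base is None else base
    out: dict[float, list[float]] = {}
    for noise in noise_levels:
        kappas = []
        for seed in seeds:
            cfg = dataclasses.replace(
                base,
                simulator=dataclasses.replace(
                    base.simulator, background_noise=noise, allow_overlap=True
                ),
                seed=int(seed),
            )
            report = run_experiment(cfg)
            kappas.append(report["test_concordance"]["plane"]["kappa"])
        out[float(noise)] = kappas
    return out
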