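"""Window-level aggregation of frame features into the labeled tabular dataset.

Each per-organ frame-feature sequence is cut into windows of N frames
(N = 60 by default, non-overlapping).  Within a window, every one of the 17
frame features is summarized by its mean, population SD, maximum and minimum
across the window's frames, giving 68 features per (patient, organ, window)
row.  Windowing acts as data augmentation: several rows per patient and organ
instead of one.

Column order is frozen: for each frame feature f in canonical order, the four
aggregates f|mean, f|sd, f|max, f|min.  Serialized CSVs use columns
f001…f068 with a JSON sidecar mapping them back to names, so trained models
stay portable.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FRAME_FEATURE_NAMES, N_FRAME_FEATURES, extract_stack_features
from .io import LabelTable, SegmentationVideo, ValidationError
from .organs import ORGANS

AGGREGATORS: tuple[str, ...] = ("mean", "sd", "max", "min")

#: The 68 aggregated feature names, in frozen order.
FEATURE_NAMES_68: tuple[str, ...] = tuple(
    f"{feat}|{agg}" for feat in FRAME_FEATURE_NAMES for agg in AGGREGATORS
)

#: CSV column names f001…f068 (order matches FEATURE_NAMES_68).
FEATURE_COLUMNS: tuple[str, ...] = tuple(
    f"f{i + 1:03d}" for i in range(len(FEATURE_NAMES_68))
)

META_COLUMNS = ("patient_id", "organ", "window_index")


@dataclasses.dataclass(frozen=True)
class WindowingConfig:
    """How frame sequences are cut into windows.

    ``n_frames_per_window`` (N) defaults to 60; ``stride`` defaults to N, i.e.
    non-overlapping windows.  Videos shorter than N either collapse to a
    single whole-video window (default) or raise, per ``short_video_policy``.
    """

    n_frames_per_window: int = 60
    stride: int | None = None
    short_video_policy: str = "single_window"  # or "error"

    def __post_init__(self):
        if self.n_frames_per_window < 2:
            raise ValidationError("window length N must be >= 2")
        if self.stride is not None and self.stride < 1:
            raise ValidationError("stride must be >= 1")
        if self.short_video_policy not in ("single_window", "error"):
            raise ValidationError("short_video_policy: 'single_window' or 'error'")

    @property
    def effective_stride(self) -> int:
        return self.n_frames_per_window if self.stride is None else self.stride


def window_frames(n_frames: int, config: WindowingConfig) -> list[range]:
    """Half-open frame-index ranges of the windows inside an n_frames video.

    Windows are [i·stride, i·stride + N); a trailing partial window is
    discarded.  A video shorter than N yields one whole-video window under the
    single_window policy, else an error.
    """
    if n_frames < 1:
        raise ValidationError("video must have at least one frame")
    n = config.n_frames_per_window
    if n_frames < n:
        if config.short_video_policy == "error":
            raise ValidationError(
                f"video has {n_frames} frames, shorter than the window N={n}"
            )
        return [range(0, n_frames)]
    stride = config.effective_stride
    windows = []
    start = 0
    while start + n <= n_frames:
        windows.append(range(start, start + n))
        start += stride
    return windows


def aggregate_window(frame_features: np.ndarray) -> np.ndarray:
    """Aggregate a (n_frames, 17) block into the 68-vector.

    For each frame feature: mean, population SD, max, min across the window,
    interleaved per feature in the frozen order.
    """
    arr = np.asarray(frame_features, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] != N_FRAME_FEATURES:
        raise ValidationError(
            f"expected a non-empty (n_frames, {N_FRAME_FEATURES}) block, got {arr.shape}"
        )
    stats = np.stack(
        [arr.mean(axis=0), arr.std(axis=0), arr.max(axis=0), arr.min(axis=0)], axis=1
    )  # (17, 4)
    return stats.reshape(-1)  # feature-major: f0|mean, f0|sd, f0|max, f0|min, f1|mean, …


@dataclasses.dataclass
class FeatureDataset:
    """Tabular dataset: one row per (patient, organ, window).

    ``table`` has columns patient_id, organ, window_index, f001…f068, label.
    """

    table: pd.DataFrame
    windowing: WindowingConfig = dataclasses.field(default_factory=WindowingConfig)

    @property
    def n_rows(self) -> int:
        return len(self.table)

    @property
    def groups(self) -> np.ndarray:
        """Per-row patient ids, the grouping unit for all splits."""
        return self.table["patient_id"].to_numpy()

    def features(self) -> np.ndarray:
        return self.table[list(FEATURE_COLUMNS)].to_numpy(dtype=float)

    def labels(self) -> np.ndarray:
        return self.table["label"].to_numpy(dtype=int)

    def for_organ(self, organ) -> "FeatureDataset":
        name = organ.value if hasattr(organ, "value") else str(organ)
        return FeatureDataset(
            self.table[self.table["organ"] == name].reset_index(drop=True),
            self.windowing,
        )

    def to_csv(self, path: str | Path) -> None:
        """Write the table plus a JSON sidecar with config and feature manifest."""
        path = Path(path)
        self.table.to_csv(path, index=False)
        sidecar = {
            "windowing": dataclasses.asdict(self.windowing),
            "feature_manifest": dict(zip(FEATURE_COLUMNS, FEATURE_NAMES_68)),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureDataset":
        path = Path(path)
        table = pd.read_csv(path, dtype={"patient_id": str})
        windowing = WindowingConfig()
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            cfg = json.loads(sidecar.read_text()).get("windowing", {})
            windowing = WindowingConfig(**cfg)
        return cls(table, windowing)


def video_feature_rows(
    video: SegmentationVideo,
    labels: dict,
    config: WindowingConfig,
    tau: float = 0.5,
) -> list[dict]:
    """All (organ, window) rows for one video; labels keyed by OrganId."""
    windows = window_frames(video.n_frames, config)
    rows = []
    for organ in ORGANS:
        if organ not in labels:
            raise ValidationError(
                f"missing label for ({video.patient_id!r}, {organ.value!r})"
            )
        per_frame = extract_stack_features(video.organ_stack(organ), tau)
        for w_idx, window in enumerate(windows):
            vec = aggregate_window(per_frame[window.start : window.stop])
            row = {
                "patient_id": video.patient_id,
                "organ": organ.value,
                "window_index": w_idx,
            }
            row.update(dict(zip(FEATURE_COLUMNS, vec)))
            row["label"] = int(labels[organ])
            rows.append(row)
    return rows


def build_dataset(
    videos: list[SegmentationVideo],
    labels: LabelTable,
    config: WindowingConfig | None = None,
) -> FeatureDataset:
    """Assemble the labeled dataset from videos and their label table.

    Row order is deterministic: patient order as given, organs in canonical
    order, windows by index.
    """
    config = WindowingConfig() if config is None else config
    labels.validate()
    all_rows: list[dict] = []
    for video in videos:
        organ_labels = labels.organ_labels(video.patient_id)
        if len(organ_labels) != len(ORGANS):
            raise ValidationError(f"incomplete labels for {video.patient_id!r}")
        all_rows.extend(video_feature_rows(video, organ_labels, config))
    columns = list(META_COLUMNS) + list(FEATURE_COLUMNS) + ["label"]
    table = pd.DataFrame(all_rows, columns=columns)
    return FeatureDataset(table, config)


def split_by_patient(
    dataset: FeatureDataset, train_ids, test_ids
) -> tuple[FeatureDataset, FeatureDataset]:
    """Route rows by patient id; a patient never appears on both sides."""
    train_ids, test_ids = set(train_ids), set(test_ids)
    overlap = train_ids & test_ids
    if overlap:
        raise ValidationError(f"patients in both train and test: {sorted(overlap)}")
    present = set(dataset.table["patient_id"].unique())
    unrouted = present - train_ids - test_ids
    if unrouted:
        raise ValidationError(f"patients in neither split: {sorted(unrouted)}")
    is_train = dataset.table["patient_id"].isin(train_ids)
    train = FeatureDataset(
        dataset.table[is_train].reset_index(drop=True), dataset.windowing
    )
    test = FeatureDataset(
        dataset.table[~is_train].reset_index(drop=True), dataset.windowing
    )
    return train, test
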