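"""Read/write segmentation-probability videos (HDF5) and label tables (CSV).

On-disk video layout
--------------------
One HDF5 file per patient video.  Root attributes: ``patient_id`` (string),
``height``, ``width``, ``n_frames`` (integers).  One group per organ, named
exactly as in :data:`planeqc.organs.ORGAN_NAMES`; each group holds a dataset
``prob`` of shape ``(n_frames, height, width)``, float32, values in [0, 1].

Label CSV
---------
Header ``patient_id,organ,organ_correct`` with ``organ_correct`` in {0, 1},
exactly one row per (patient, organ).  The per-video plane verdict is never
stored: it is always derived as the AND of the eight organ flags, so the two
can never disagree.

Pixel convention: 0-based (row, column), origin top-left, row = vertical axis.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .organs import ORGAN_NAMES, ORGANS, OrganId, organ_from_name


class FormatError(ValueError):
    """The file does not match the expected on-disk layout."""


class ValidationError(ValueError):
    """The data violates a type invariant (range, duplication, consistency)."""


@dataclasses.dataclass
class SegmentationVideo:
    """Per-frame, per-organ probability maps for one patient video.

    ``frames`` maps each organ to a float32 array of shape
    ``(n_frames, height, width)`` with values in [0, 1].
    """

    patient_id: str
    frames: dict[OrganId, np.ndarray]
    height: int
    width: int

    @property
    def n_frames(self) -> int:
        return next(iter(self.frames.values())).shape[0]

    def organ_stack(self, organ: OrganId) -> np.ndarray:
        """The (n_frames, height, width) probability stack for one organ."""
        return self.frames[organ]

    def frame_map(self, organ: OrganId, frame: int) -> np.ndarray:
        """The (height, width) probability map of one organ in one frame."""
        return self.frames[organ][frame]

    def validate(self) -> "SegmentationVideo":
        missing = [o.value for o in ORGANS if o not in self.frames]
        if missing:
            raise FormatError(f"video {self.patient_id!r} missing organ(s): {missing}")
        n_frames = None
        for organ in ORGANS:
            arr = self.frames[organ]
            if arr.ndim != 3 or arr.shape[1:] != (self.height, self.width):
                raise FormatError(
                    f"organ {organ.value!r}: expected shape (n_frames, {self.height}, "
                    f"{self.width}), got {arr.shape}"
                )
            if n_frames is None:
                n_frames = arr.shape[0]
            elif arr.shape[0] != n_frames:
                raise FormatError(
                    f"organ {organ.value!r}: frame count {arr.shape[0]} != {n_frames}"
                )
            lo, hi = float(arr.min()), float(arr.max())
            if lo < 0.0 or hi > 1.0:
                raise ValidationError(
                    f"organ {organ.value!r}: probability values outside [0, 1] "
                    f"(range [{lo}, {hi}])"
                )
        if n_frames is None or n_frames < 1:
            raise ValidationError("video must contain at least one frame")
        return self


def write_video(video: SegmentationVideo, path: str | Path) -> None:
    """Write a video to the HDF5 layout documented in this module."""
    video.validate()
    with h5py.File(path, "w") as f:
        f.attrs["patient_id"] = video.patient_id
        f.attrs["height"] = video.height
        f.attrs["width"] = video.width
        f.attrs["n_frames"] = video.n_frames
        for organ in ORGANS:
            grp = f.create_group(organ.value)
            grp.create_dataset("prob", data=video.frames[organ].astype(np.float32))


def read_video(path: str | Path) -> SegmentationVideo:
    """Read a video from the HDF5 layout; validates shapes and the [0,1] range."""
    with h5py.File(path, "r") as f:
        try:
            patient_id = str(f.attrs["patient_id"])
            height = int(f.attrs["height"])
            width = int(f.attrs["width"])
        except KeyError as exc:
            raise FormatError(f"missing root attribute in {path}: {exc}") from None
        frames: dict[OrganId, np.ndarray] = {}
        for organ in ORGANS:
            if organ.value not in f:
                raise FormatError(f"{path}: missing organ group {organ.value!r}")
            grp = f[organ.value]
            if "prob" not in grp:
                raise FormatError(
                    f"{path}: organ group {organ.value!r} has no 'prob' dataset"
                )
            frames[organ] = np.asarray(grp["prob"], dtype=np.float32)
    return SegmentationVideo(patient_id, frames, height, width).validate()


@dataclasses.dataclass
class LabelTable:
    """Per-(patient, organ) correctness labels, plane verdict derived.

    ``organ_correct`` is a DataFrame with columns patient_id, organ,
    organ_correct (0/1); exactly one row per (patient, organ) with all eight
    organs present per patient.
    """

    organ_correct: pd.DataFrame

    @property
    def patients(self) -> list[str]:
        return sorted(self.organ_correct["patient_id"].unique())

    def organ_labels(self, patient_id: str) -> dict[OrganId, int]:
        sub = self.organ_correct[self.organ_correct["patient_id"] == patient_id]
        return {organ_from_name(r.organ): int(r.organ_correct) for r in sub.itertuples()}

    def plane_correct(self) -> pd.Series:
        """Derived per-patient plane verdict: AND of the eight organ flags."""
        return self.organ_correct.groupby("patient_id")["organ_correct"].min()

    def label(self, patient_id: str, organ: OrganId) -> int:
        sub = self.organ_correct
        m = (sub["patient_id"] == patient_id) & (sub["organ"] == organ.value)
        rows = sub.loc[m, "organ_correct"]
        if rows.empty:
            raise ValidationError(f"no label for ({patient_id!r}, {organ.value!r})")
        return int(rows.iloc[0])

    def validate(self) -> "LabelTable":
        df = self.organ_correct
        expected = {"patient_id", "organ", "organ_correct"}
        if not expected.issubset(df.columns):
            raise FormatError(f"label table needs columns {sorted(expected)}")
        dup = df.duplicated(subset=["patient_id", "organ"])
        if dup.any():
            first = df.loc[dup, ["patient_id", "organ"]].iloc[0]
            raise ValidationError(
                f"duplicate label row for ({first.patient_id!r}, {first.organ!r})"
            )
        for name in df["organ"].unique():
            organ_from_name(name)  # raises on unknown organs
        bad = ~df["organ_correct"].isin([0, 1])
        if bad.any():
            raise ValidationError("organ_correct must be 0 or 1")
        counts = df.groupby("patient_id")["organ"].nunique()
        incomplete = counts[counts != len(ORGANS)]
        if not incomplete.empty:
            raise ValidationError(
                f"patients without all {len(ORGANS)} organ labels: "
                f"{list(incomplete.index)}"
            )
        return self


def read_labels(path: str | Path) -> LabelTable:
    """Read a label CSV (patient_id, organ, organ_correct) and validate it."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    return LabelTable(df).validate()


def write_labels(labels: LabelTable, path: str | Path) -> None:
    labels.validate().organ_correct.to_csv(path, index=False)
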