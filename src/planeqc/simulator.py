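"""Synthetic segmentation-probability videos emulating the upstream CNN output.

The generator stands in for the per-frame organ segmenter run on dynamic
transperineal ultrasound.  Each video shows the eight pelvic organs under one
of three acquisition conditions:

``correct``
    All eight organs rendered as high-confidence elliptical blobs.
``displacement``
    Anteroposterior probe displacement: the anus, rectum and levator ani
    are not visualized — their maps contain only background noise.
``rotation``
    Image rotation: the uterus, anus, rectum and levator ani are not
    visualized, and the organs that remain get inflated background noise
    (the segmenter is less certain on a rotated plane).

Rendering model
---------------
Each present organ is an axis-aligned ellipse filled with a per-(video,
organ) confidence close to ``blob_confidence``, falling off linearly to the
background over a ~2-pixel rim.  Background pixels are i.i.d. uniform on
[0, 2·noise] where the per-video noise level is ``background_noise`` times a
per-video scale drawn uniform on [0.5, 1.5] (segmenter quality varies across
patients); values are clipped to [0, 1].  Organ centroids drift slowly and
monotonically downward across the video (≤ 10% of image height, a crude
Valsalva descent) and jitter frame-to-frame with SD ``jitter_sd`` pixels.

Labels are derived from the condition and cross-checked against what was
actually rendered.
"""

from __future__ import annotations

import dataclasses
from typing import Iterator

import numpy as np
import pandas as pd

from .io import LabelTable, SegmentationVideo, ValidationError
from .organs import ORGANS, OrganId

#: Organs lost when the probe is displaced along the anteroposterior axis.
DISPLACEMENT_ABSENT: frozenset[OrganId] = frozenset(
    {OrganId.anus, OrganId.rectum, OrganId.levator_ani}
)
#: Organs lost when the image is rotated off the midsagittal plane.
ROTATION_ABSENT: frozenset[OrganId] = frozenset(
    {OrganId.uterus, OrganId.anus, OrganId.rectum, OrganId.levator_ani}
)
#: Extra background-noise multiplier on organs still present in a rotated view.
ROTATION_NOISE_INFLATION = 1.5
#: Per-video background-noise scale range (segmenter quality varies by patient).
NOISE_SCALE_RANGE = (0.5, 1.5)
#: Per-(video, organ) blob-confidence jitter half-width.
CONFIDENCE_JITTER = 0.05

CONDITIONS = ("correct", "displacement", "rotation")


def absent_organs(condition: str) -> frozenset[OrganId]:
    if condition == "correct":
        return frozenset()
    if condition == "displacement":
        return DISPLACEMENT_ABSENT
    if condition == "rotation":
        return ROTATION_ABSENT
    raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")


@dataclasses.dataclass(frozen=True)
class SimCohortConfig:
    """Conditions for one synthetic cohort.

    Defaults mirror the study design: 45 correct-plane and 45 incorrect-plane
    videos, 60 frames per video, with clearly separable confidence contrast
    (blob 0.9 vs. background 0.1).
    """

    n_correct: int = 45
    n_incorrect: int = 45
    n_frames: int = 60
    height: int = 64
    width: int = 64
    blob_confidence: float = 0.9
    background_noise: float = 0.1
    jitter_sd: float = 2.0
    defect_mix: tuple[float, float] = (0.5, 0.5)  # (displacement, rotation)
    seed: int = 0
    allow_overlap: bool = False  # explicitly permit background_noise >= 0.5

    def validate(self) -> "SimCohortConfig":
        if self.n_correct < 0 or self.n_incorrect < 0:
            raise ValidationError("video counts must be non-negative")
        if self.n_correct + self.n_incorrect < 1:
            raise ValidationError("cohort must contain at least one video")
        if not (0.0 <= self.blob_confidence <= 1.0):
            raise ValidationError("blob_confidence must lie in [0, 1]")
        if not self.allow_overlap and not (
            self.blob_confidence > 0.5 > self.background_noise
        ):
            raise ValidationError(
                "separability requires blob_confidence > 0.5 > background_noise; "
                "set allow_overlap=True to override explicitly"
            )
        if abs(sum(self.defect_mix) - 1.0) > 1e-9 or min(self.defect_mix) < 0:
            raise ValidationError("defect_mix must be non-negative and sum to 1")
        if self.n_frames < 1 or self.height < 8 or self.width < 8:
            raise ValidationError("need n_frames >= 1 and image size >= 8x8")
        return self


@dataclasses.dataclass(frozen=True)
class OrganEllipse:
    """Nominal blob for one organ: centroid as image fractions, half-axes px."""

    center_row_frac: float
    center_col_frac: float
    half_row: float
    half_col: float


#: Default organ layout on the midsagittal view: cranioventral structures on
#: the image left, dorsocaudal on the right (fractions of image size).
DEFAULT_LAYOUT: dict[OrganId, OrganEllipse] = {
    OrganId.pubis: OrganEllipse(0.35, 0.15, 4.0, 4.0),
    OrganId.urethra: OrganEllipse(0.55, 0.27, 6.0, 3.0),
    OrganId.urinary_bladder: OrganEllipse(0.30, 0.35, 8.0, 9.0),
    OrganId.vagina: OrganEllipse(0.55, 0.45, 7.0, 4.0),
    OrganId.uterus: OrganEllipse(0.25, 0.57, 9.0, 7.0),
    OrganId.anus: OrganEllipse(0.68, 0.66, 5.0, 5.0),
    OrganId.rectum: OrganEllipse(0.45, 0.76, 8.0, 6.0),
    OrganId.levator_ani: OrganEllipse(0.72, 0.86, 6.0, 4.0),
}

OrganLayout = dict[OrganId, OrganEllipse]


def validate_layout(layout: OrganLayout, height: int, width: int) -> None:
    for organ, e in layout.items():
        r = e.center_row_frac * (height - 1)
        c = e.center_col_frac * (width - 1)
        if not (0 <= r <= height - 1 and 0 <= c <= width - 1):
            raise ValidationError(f"organ {organ.value!r} centroid outside image")


def _render_frame(
    height: int,
    width: int,
    center: tuple[float, float] | None,
    half_axes: tuple[float, float],
    confidence: float,
    noise_level: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One organ's map: background noise plus, if present, the elliptical blob."""
    frame = rng.uniform(0.0, 2.0 * noise_level, size=(height, width))
    if center is not None:
        rows = np.arange(height)[:, None]
        cols = np.arange(width)[None, :]
        a, b = half_axes
        d = np.sqrt(((rows - center[0]) / a) ** 2 + ((cols - center[1]) / b) ** 2)
        # Linear fall-off from d=1 to the background over a ~2 px rim.
        rim = 2.0 / min(a, b)
        w = np.clip((1.0 + rim - d) / rim, 0.0, 1.0)
        frame = w * confidence + (1.0 - w) * frame
    return np.clip(frame, 0.0, 1.0).astype(np.float32)


def simulate_video(
    patient_id: str,
    condition: str,
    config: SimCohortConfig,
    rng: np.random.Generator,
    layout: OrganLayout | None = None,
) -> tuple[SegmentationVideo, dict[OrganId, int]]:
    """Render one video under the given acquisition condition.

    Returns the video and its per-organ labels (1 = correctly visualized).
    """
    config.validate()
    layout = DEFAULT_LAYOUT if layout is None else layout
    validate_layout(layout, config.height, config.width)
    absent = absent_organs(condition)
    labels = {organ: int(organ not in absent) for organ in ORGANS}

    noise_scale = rng.uniform(*NOISE_SCALE_RANGE)
    base_noise = config.background_noise * noise_scale
    if condition == "rotation":
        present_noise = base_noise * ROTATION_NOISE_INFLATION
    else:
        present_noise = base_noise

    # Slow monotone descent (Valsalva) over the video, <= 10% of image height.
    descent_total = rng.uniform(0.0, 0.10) * config.height
    descent = np.linspace(0.0, descent_total, config.n_frames)

    frames: dict[OrganId, np.ndarray] = {}
    for organ in ORGANS:
        ellipse = layout[organ]
        confidence = float(
            np.clip(
                config.blob_confidence
                + rng.uniform(-CONFIDENCE_JITTER, CONFIDENCE_JITTER),
                0.0,
                1.0,
            )
        )
        base_center = (
            ellipse.center_row_frac * (config.height - 1),
            ellipse.center_col_frac * (config.width - 1),
        )
        stack = np.empty(
            (config.n_frames, config.height, config.width), dtype=np.float32
        )
        present = labels[organ] == 1
        noise_level = present_noise if present else base_noise
        for t in range(config.n_frames):
            if present:
                jr, jc = rng.normal(0.0, config.jitter_sd, size=2)
                center = (
                    float(np.clip(base_center[0] + descent[t] + jr, 0, config.height - 1)),
                    float(np.clip(base_center[1] + jc, 0, config.width - 1)),
                )
            else:
                center = None
            stack[t] = _render_frame(
                config.height,
                config.width,
                center,
                (ellipse.half_row, ellipse.half_col),
                confidence,
                noise_level,
                rng,
            )
        frames[organ] = stack

    video = SegmentationVideo(patient_id, frames, config.height, config.width)
    return video.validate(), labels


def cohort_conditions(config: SimCohortConfig) -> list[str]:
    """Deterministic per-patient conditions: a seeded permutation of the
    correct/incorrect assignment, with defects drawn per ``defect_mix``."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0xC0]))
    n = config.n_correct + config.n_incorrect
    defects = rng.choice(
        ["displacement", "rotation"], size=config.n_incorrect, p=list(config.defect_mix)
    )
    conditions = ["correct"] * config.n_correct + list(defects)
    order = rng.permutation(n)
    return [conditions[i] for i in order]


def patient_ids(n: int) -> list[str]:
    return [f"P{i + 1:03d}" for i in range(n)]


def iter_cohort(
    config: SimCohortConfig, layout: OrganLayout | None = None
) -> Iterator[tuple[SegmentationVideo, dict[OrganId, int], str]]:
    """Yield (video, organ labels, condition) per patient, deterministically.

    Each video gets its own RNG stream spawned from ``config.seed``, so the
    cohort is bit-reproducible and independent of consumption order.
    """
    config.validate()
    conditions = cohort_conditions(config)
    ids = patient_ids(len(conditions))
    seeds = np.random.SeedSequence([int(config.seed), 0xE1]).spawn(len(conditions))
    for pid, condition, seq in zip(ids, conditions, seeds):
        rng = np.random.default_rng(seq)
        video, labels = simulate_video(pid, condition, config, rng, layout)
        yield video, labels, condition


def simulate_cohort(
    config: SimCohortConfig, layout: OrganLayout | None = None
) -> tuple[list[SegmentationVideo], LabelTable]:
    """Materialize a whole cohort: videos plus the label table."""
    videos: list[SegmentationVideo] = []
    rows = []
    for video, labels, _condition in iter_cohort(config, layout):
        videos.append(video)
        for organ in ORGANS:
            rows.append(
                {
                    "patient_id": video.patient_id,
                    "organ": organ.value,
                    "organ_correct": labels[organ],
                }
            )
    table = LabelTable(pd.DataFrame(rows)).validate()
    return videos, table
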