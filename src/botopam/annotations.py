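"""Time-frequency bounding-box annotations and multi-label targets.

Annotators mark each sound with a bounding box (time extent within the
recording, frequency extent in Hz) carrying exactly one class; a 5-s segment
can therefore carry any subset of the target classes.  From the boxes this
module derives segment-level label sets, time-resolved training targets for
the classifier's 16 output columns, and the train/test split policies used
with heterogeneous sources (boat-based surveys split by session, the lodge
node by day, varzea recorders by seeded random halves).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from botopam.audio_io import SEGMENT_SECONDS

TARGET_CLASSES = ("click", "boat", "rain")
N_COLUMNS = 16  # classifier output columns per 5-s segment
COLUMN_SECONDS = SEGMENT_SECONDS / N_COLUMNS  # 0.3125 s

ANNOTATION_COLUMNS = [
    "source_id",
    "class",
    "t_start_s",
    "t_end_s",
    "f_low_hz",
    "f_high_hz",
    "annotator",
    "created_at",
]


@dataclass
class Annotation:
    """One bounding box: a single class over a time-frequency extent."""

    class_name: str
    t_start: float
    t_end: float
    f_low: float
    f_high: float
    source_id: str = ""
    annotator: str = ""

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ValueError(f"t_start must precede t_end ({self.t_start}, {self.t_end})")
        if not (0 <= self.f_low < self.f_high <= 48_000):
            raise ValueError(
                f"frequency bounds must satisfy 0 <= f_low < f_high <= 48000, "
                f"got ({self.f_low}, {self.f_high})"
            )


@dataclass
class SegmentLabelSet:
    """Multi-label assignment of one segment; background iff no labels."""

    segment_id: str
    labels: frozenset

    @property
    def is_background(self) -> bool:
        return len(self.labels) == 0


def read_annotation_csv(path: str | Path) -> list[Annotation]:
    df = pd.read_csv(path)
    missing = set(ANNOTATION_COLUMNS[:6]) - set(df.columns)
    if missing:
        raise ValueError(f"annotation CSV missing columns: {sorted(missing)}")
    df = df.rename(columns={"class": "class_name"})
    return [
        Annotation(
            class_name=row.class_name,
            t_start=row.t_start_s,
            t_end=row.t_end_s,
            f_low=row.f_low_hz,
            f_high=row.f_high_hz,
            source_id=row.source_id,
            annotator=getattr(row, "annotator", "") or "",
        )
        for row in df.itertuples(index=False)
    ]


def write_annotation_csv(path: str | Path, annotations: list[Annotation]) -> None:
    rows = [
        {
            "source_id": a.source_id,
            "class": a.class_name,
            "t_start_s": a.t_start,
            "t_end_s": a.t_end,
            "f_low_hz": a.f_low,
            "f_high_hz": a.f_high,
            "annotator": a.annotator,
            "created_at": "",
        }
        for a in annotations
    ]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, index=False)


def append_annotations(path: str | Path, annotations: list[Annotation]) -> None:
    """Append-only ingestion into a flat CSV annotation repository."""
    path = Path(path)
    if not path.exists():
        write_annotation_csv(path, annotations)
        return
    existing = read_annotation_csv(path)
    write_annotation_csv(path, existing + annotations)


def _segment_window(index: int) -> tuple[float, float]:
    return index * SEGMENT_SECONDS, (index + 1) * SEGMENT_SECONDS


def derive_segment_labels(
    annotations: list[Annotation],
    segments,
    classes: tuple[str, ...] = TARGET_CLASSES,
) -> dict[str, SegmentLabelSet]:
    """Assign each segment every class whose annotations overlap it in time.

    Any positive-duration overlap counts: clicks are a few hundred
    microseconds long, so a proportional minimum-overlap rule would erase
    them.  Background-subtype annotations (classes outside ``classes``) never
    produce labels.  Annotations outside every segment of their source are
    warned about and skipped.
    """
    by_source: dict[str, list] = {}
    for seg in segments:
        by_source.setdefault(seg.waveform.source_id, []).append(seg)

    labels: dict[str, set] = {seg.segment_id: set() for seg in segments}
    for ann in annotations:
        segs = by_source.get(ann.source_id, [])
        hit = False
        for seg in segs:
            t0, t1 = _segment_window(seg.index)
            if min(ann.t_end, t1) - max(ann.t_start, t0) > 0:
                hit = True
                if ann.class_name in classes:
                    labels[seg.segment_id].add(ann.class_name)
        if not hit:
            warnings.warn(
                f"annotation {ann.class_name}@[{ann.t_start},{ann.t_end}]s "
                f"of {ann.source_id!r} overlaps no segment; skipped",
                stacklevel=2,
            )
    return {
        sid: SegmentLabelSet(segment_id=sid, labels=frozenset(lbls))
        for sid, lbls in labels.items()
    }


def derive_column_targets(
    annotations: list[Annotation],
    segment,
    classes: tuple[str, ...] = TARGET_CLASSES,
    broadcast_segment_level: bool = False,
) -> np.ndarray:
    """Binary (16, n_classes) training target for one segment.

    Column ``j`` spans ``[5j/16, 5(j+1)/16)`` seconds of the segment and is
    positive for a class iff one of its annotations overlaps that span.  With
    ``broadcast_segment_level=True`` a class that overlaps the segment at all
    marks all 16 columns — the fallback when only segment-level labels exist.
    """
    t0, t1 = _segment_window(segment.index)
    targets = np.zeros((N_COLUMNS, len(classes)), dtype=np.float32)
    for ann in annotations:
        if ann.source_id != segment.waveform.source_id:
            continue
        if ann.class_name not in classes:
            continue
        if min(ann.t_end, t1) - max(ann.t_start, t0) <= 0:
            continue
        c = classes.index(ann.class_name)
        if broadcast_segment_level:
            targets[:, c] = 1.0
            continue
        for j in range(N_COLUMNS):
            col0 = t0 + j * COLUMN_SECONDS
            col1 = col0 + COLUMN_SECONDS
            if min(ann.t_end, col1) - max(ann.t_start, col0) > 0:
                targets[j, c] = 1.0
    return targets


def split_train_test(
    dataset: pd.DataFrame,
    policy: str,
    seed: int,
    group_column: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a segment table into disjoint train/test partitions.

    ``dataset`` must carry a ``segment_id`` column.  Policies:

    - ``"survey"``: split whole recording sessions (``group_column``,
      default ``session``) between partitions;
    - ``"lodge"``: split whole days (``group_column``, default ``date``);
    - ``"varzea"``: seeded random 50/50 split of individual segments.
    """
    if "segment_id" not in dataset.columns:
        raise ValueError("dataset must have a segment_id column")
    rng = np.random.default_rng(seed)
    if policy == "varzea":
        perm = rng.permutation(len(dataset))
        half = len(dataset) // 2
        train = dataset.iloc[np.sort(perm[:half])]
        test = dataset.iloc[np.sort(perm[half:])]
    elif policy in ("survey", "lodge"):
        col = group_column or ("session" if policy == "survey" else "date")
        if col not in dataset.columns:
            raise ValueError(f"policy {policy!r} needs a {col!r} column")
        groups = np.asarray(sorted(dataset[col].unique()))
        perm = rng.permutation(len(groups))
        half = len(groups) // 2
        train_groups = set(groups[perm[:half]])
        mask = dataset[col].isin(train_groups)
        train, test = dataset[mask], dataset[~mask]
    else:
        raise ValueError(f"unknown split policy {policy!r}")
    assert not set(train.segment_id) & set(test.segment_id)
    return train.reset_index(drop=True), test.reset_index(drop=True)


def labelset_to_vector(
    labels: frozenset | set, classes: tuple[str, ...] = TARGET_CLASSES
) -> np.ndarray:
    return np.array([1.0 if c in labels else 0.0 for c in classes], dtype=np.float32)
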