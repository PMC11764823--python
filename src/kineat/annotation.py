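"""Per-sample eating labels from evaluators' interval annotations.

Two independent evaluators mark, on the video clock, the start and stop
of every complete eating movement.  Once those intervals are mapped onto
the accelerometer clock they are rasterized to one boolean per raw
sample (eating = positive class) and the two evaluators are fused into
two label sets:

* *united* — samples labeled eating by at least one evaluator (OR);
* *intersected* — samples labeled eating by both evaluators (AND).

Intervals are half-open ``[start, stop)`` so a shared boundary sample is
never counted twice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ANNOTATION_COLUMNS = ("segment_id", "food_id", "evaluator", "start_s", "stop_s")


@dataclass
class AnnotationTrack:
    """One evaluator's per-sample boolean eating labels for a stream."""

    evaluator_id: str
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=bool)


@dataclass
class FusedLabels:
    """United (OR) and intersected (AND) fusion of two annotation tracks."""

    united: np.ndarray
    intersected: np.ndarray


def combine_labels(track_a: AnnotationTrack, track_b: AnnotationTrack) -> FusedLabels:
    """Fuse two evaluators' per-sample labels into united/intersected sets.

    Raises
    ------
    ValueError
        If the tracks differ in length (both lengths reported).
    """
    a, b = track_a.labels, track_b.labels
    if len(a) != len(b):
        raise ValueError(
            f"annotation tracks differ in length: "
            f"{track_a.evaluator_id}={len(a)}, {track_b.evaluator_id}={len(b)}"
        )
    return FusedLabels(united=a | b, intersected=a & b)


def rasterize_intervals(
    intervals: Iterable[tuple[float, float]], t_s: Sequence[float]
) -> np.ndarray:
    """Boolean mask of samples whose timestamp falls in any [start, stop).

    ``t_s`` are the sample timestamps on the same clock as the intervals
    (i.e. after any sync offset has been applied).
    """
    t = np.asarray(t_s, dtype=float)
    mask = np.zeros(t.shape, dtype=bool)
    for start, stop in intervals:
        mask |= (t >= start) & (t < stop)
    return mask


def write_annotation_json(annotations: pd.DataFrame, path: str | Path) -> None:
    """Write evaluator intervals as a JSON list of records."""
    missing = [c for c in ANNOTATION_COLUMNS if c not in annotations.columns]
    if missing:
        raise ValueError(f"annotation table lacks columns {missing}")
    records = annotations[list(ANNOTATION_COLUMNS)].to_dict(orient="records")
    Path(path).write_text(json.dumps(records, indent=1))


def read_annotation_json(path: str | Path) -> pd.DataFrame:
    """Read the JSON annotation format back into a table."""
    records = json.loads(Path(path).read_text())
    df = pd.DataFrame(records, columns=list(ANNOTATION_COLUMNS))
    df["start_s"] = df["start_s"].astype(float)
    df["stop_s"] = df["stop_s"].astype(float)
    return df
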