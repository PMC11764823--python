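"""Sliding windows and slope-based Information Units (IUs).

A *window* is a consecutive run of raw samples of fixed time-width (1-5
s; at 5 Hz that is 5-25 samples).  Each window is summarized into one
Information Unit: the ordinary-least-squares slope of every kinetic
variable against time within the window — 7 features when only the
dominant wrist is the source, 14 (dominant then non-dominant) when both
wrists are.  An IU is labeled eating under a criterion when *strictly
more than half* of its samples carry that criterion's eating label.

Windows are enumerated with a 1 s step by default and never cross a
food-item segment boundary, so every IU has a single food label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .annotation import FusedLabels
from .kinetics import KINETIC_VARIABLES

logger = logging.getLogger(__name__)

VALID_WIDTHS_S = (1, 2, 3, 4, 5)
#: "stacked" is a compatibility mode in which each wrist's window
#: becomes its own 7-feature IU (doubling the IU count) instead of the
#: default 14-feature concatenation.
SourceMode = Literal["full", "dominant", "stacked"]

#: wrist order fixing the feature layout of full-source IUs.
WRIST_ORDER = ("dominant", "nondominant")

#: columns identifying an IU ahead of its feature columns.
IU_META_COLUMNS = (
    "segment_id",
    "subject_id",
    "food_id",
    "start_s",
    "width_s",
    "eating_united",
    "eating_intersected",
)


@dataclass(frozen=True)
class WindowSpec:
    """Fixed-width sliding-window geometry at the 5 Hz watch rate."""

    width_s: int
    step_s: int = 1
    sample_rate_hz: float = 5.0

    def __post_init__(self) -> None:
        if self.width_s not in VALID_WIDTHS_S:
            raise ValueError(
                f"width_s must be one of {VALID_WIDTHS_S}, got {self.width_s!r}"
            )
        if self.step_s < 1:
            raise ValueError("step_s must be a positive integer")

    @property
    def samples_per_window(self) -> int:
        return int(round(self.width_s * self.sample_rate_hz))

    @property
    def samples_per_step(self) -> int:
        return int(round(self.step_s * self.sample_rate_hz))


def enumerate_windows(segment_len_s: float, spec: WindowSpec) -> np.ndarray:
    """Start times (s, segment-relative) of all windows fitting a segment.

    Starts are ``0, step, 2*step, ...`` with ``start + width <= L``;
    short segments yield an empty array.
    """
    if segment_len_s < 0:
        raise ValueError("segment length must be nonnegative")
    last = segment_len_s - spec.width_s
    if last < 0:
        return np.array([], dtype=float)
    n = int(np.floor(last / spec.step_s)) + 1
    return np.arange(n, dtype=float) * spec.step_s


def window_slope(values, sample_rate_hz: float = 5.0) -> float:
    """OLS slope of one window's values against time, per second.

    Time is taken as ``0, 1/rate, 2/rate, ...``; the closed form is
    ``sum((t - tbar) * (v - vbar)) / sum((t - tbar)**2)``.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise ValueError("a window needs at least two samples")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite values in window")
    t = np.arange(len(v)) / sample_rate_hz
    tc = t - t.mean()
    denom = float(tc @ tc)
    if denom == 0.0:
        raise ValueError("all timestamps equal; slope undefined")
    return float(tc @ (v - v.mean()) / denom)


def _slope_weights(n_samples: int, sample_rate_hz: float) -> np.ndarray:
    """Weights w such that slope = w @ window (centering v is a no-op)."""
    t = np.arange(n_samples) / sample_rate_hz
    tc = t - t.mean()
    return tc / (tc @ tc)


def feature_columns(source_mode: SourceMode) -> list[str]:
    """Ordered IU feature names for a source mode."""
    if source_mode == "stacked":
        # wrist-agnostic: either wrist's window fills the same 7 columns
        return [f"{var}_slope" for var in KINETIC_VARIABLES]
    wrists = WRIST_ORDER if source_mode == "full" else WRIST_ORDER[:1]
    return [f"{w}_{var}_slope" for w in wrists for var in KINETIC_VARIABLES]


def build_ius(
    frames: Mapping[str, pd.DataFrame],
    fused: FusedLabels,
    spec: WindowSpec,
    source_mode: SourceMode,
) -> pd.DataFrame:
    """Summarize time-aligned kinetic frames into an IU table.

    Parameters
    ----------
    frames
        Mapping from wrist name to that wrist's kinetic frame (raw axes
        plus derived channels) for one recording.  Frames must carry
        ``subject_id``, ``segment_id``, ``food_id`` and ``t_s`` columns
        and be sample-aligned across wrists.  ``dominant`` is always
        required; ``nondominant`` additionally for full source.
    fused
        Per-sample united/intersected eating labels, aligned with the
        frames.
    spec
        Window geometry.
    source_mode
        ``"dominant"`` (7 features) or ``"full"`` (14 features,
        dominant wrist first).

    Returns
    -------
    pandas.DataFrame
        One row per window: provenance and eating labels
        (:data:`IU_META_COLUMNS`) followed by the slope features.
    """
    if source_mode not in ("full", "dominant", "stacked"):
        raise ValueError(f"unknown source_mode {source_mode!r}")
    if source_mode == "stacked":
        # each wrist's window is its own IU with wrist-agnostic columns
        parts = []
        for wrist in WRIST_ORDER:
            sub = build_ius(
                {"dominant": frames[wrist]}, fused, spec, "dominant"
            )
            sub.columns = [c.replace("dominant_", "") for c in sub.columns]
            sub.insert(len(IU_META_COLUMNS), "wrist", wrist)
            parts.append(sub)
        return pd.concat(parts, ignore_index=True)
    wrists = WRIST_ORDER if source_mode == "full" else WRIST_ORDER[:1]
    for wrist in wrists:
        if wrist not in frames:
            raise ValueError(f"source mode {source_mode!r} requires a {wrist!r} frame")

    frames = {wrist: f.reset_index(drop=True) for wrist, f in frames.items()}
    dom = frames["dominant"]
    n = len(dom)
    for wrist in wrists[1:]:
        other = frames[wrist]
        if len(other) != n or not np.array_equal(
            other["t_s"].to_numpy(), dom["t_s"].to_numpy()
        ):
            raise ValueError("wrist frames are not time-aligned")
    if len(fused.united) != n or len(fused.intersected) != n:
        raise ValueError("fused labels are not aligned with the frames")

    w = spec.samples_per_window
    step = spec.samples_per_step
    weights = None  # computed lazily once a long-enough segment exists

    rows_meta: list[pd.DataFrame] = []
    rows_feat: list[np.ndarray] = []
    united = np.asarray(fused.united, dtype=bool)
    intersected = np.asarray(fused.intersected, dtype=bool)

    # segments in order of first appearance; windows never cross them
    for seg_id, seg_idx in dom.groupby("segment_id", sort=False).groups.items():
        idx = np.sort(np.asarray(seg_idx))
        m = len(idx)
        if m < w:
            continue
        if weights is None:
            weights = _slope_weights(w, spec.sample_rate_hz)
        starts = np.arange(0, m - w + 1, step)
        food_id = dom["food_id"].to_numpy()[idx[0]]
        subject_id = dom["subject_id"].to_numpy()[idx[0]]
        t0 = dom["t_s"].to_numpy()[idx[0]]

        feats = []
        for wrist in wrists:
            kf = frames[wrist]
            for var in KINETIC_VARIABLES:
                v = kf[var].to_numpy(dtype=float)[idx]
                wins = np.lib.stride_tricks.sliding_window_view(v, w)[::step]
                feats.append(wins @ weights)
        feats = np.column_stack(feats)

        def frac_eating(lbl: np.ndarray) -> np.ndarray:
            wins = np.lib.stride_tricks.sliding_window_view(
                lbl[idx].astype(np.int64), w
            )[::step]
            return wins.sum(axis=1)

        cnt_u = frac_eating(united)
        cnt_i = frac_eating(intersected)

        meta = pd.DataFrame(
            {
                "segment_id": seg_id,
                "subject_id": subject_id,
                "food_id": food_id,
                "start_s": t0 + starts / spec.sample_rate_hz,
                "width_s": spec.width_s,
                "eating_united": cnt_u * 2 > w,  # strictly more than 50%
                "eating_intersected": cnt_i * 2 > w,
            }
        )
        rows_meta.append(meta)
        rows_feat.append(feats)

    cols = feature_columns(source_mode)
    if not rows_meta:
        empty = pd.DataFrame(columns=list(IU_META_COLUMNS) + cols)
        return empty
    meta = pd.concat(rows_meta, ignore_index=True)
    feat = pd.DataFrame(np.vstack(rows_feat), columns=cols)
    return pd.concat([meta, feat], axis=1)
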