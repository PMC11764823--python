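"""Study I/O and orchestration of the stratified analysis grid.

A *study* bundles the raw kinetic CSV (both wrists, all subjects), the
two evaluators' annotation intervals (on the camera clock) and the
per-meal 25 FPS audio envelopes.  One *analysis* is a single cell of
the stratification grid: a window width (1-5 s) x a label criterion
(united/intersected) x a raw-data source (full/dominant); the default
grid enumerates all 5 x 2 x 2 = 20 cells.

Per cell the pipeline runs: derive kinetics -> clap sync -> label
fusion -> IU building -> CV mtry selection -> final forest -> OOB
one-vs-all metrics -> scaled Gini importance.

Kinetic CSV dialect (UTF-8, comma-separated, header required)::

    subject_id, wrist (dominant|nondominant), segment_id, food_id,
    t_s, x_mG, y_mG, z_mG

``segment_id`` is ``<subject>-<meal>-<food>``; rows with an empty
``food_id`` (pre-meal lead-in) take part in clock sync but never in
windows.  Audio envelopes live in one CSV per meal (columns ``frame``,
``level``).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from . import sync
from .annotation import (
    AnnotationTrack,
    FusedLabels,
    combine_labels,
    rasterize_intervals,
    read_annotation_json,
    write_annotation_json,
)
from .classify import (
    FoodMetrics,
    ForestSettings,
    ImportanceRow,
    fit_forest,
    oob_metrics,
    scaled_importance,
    select_mtry_cv,
)
from .kinetics import derive_kinetics
from .windows import SourceMode, WindowSpec, build_ius

logger = logging.getLogger(__name__)

KINETIC_CSV_COLUMNS = (
    "subject_id",
    "wrist",
    "segment_id",
    "food_id",
    "t_s",
    "x_mG",
    "y_mG",
    "z_mG",
)

_ID_COLUMNS = ("subject_id", "wrist", "segment_id", "food_id")

WRISTS = ("dominant", "nondominant")

#: half-width (s) of the audio search window around each segment start;
#: accommodates clock offsets up to ~5 s when segments last >= 11 s.
CLAP_SEARCH_HALFWIDTH_S = 5.5

#: length (s) of the watch-side clap search window from segment start.
ACCEL_CLAP_SEARCH_LEN_S = 4.0

#: audio envelopes are normalized to a unit clap peak.
AUDIO_MIN_PROMINENCE = 0.5


def meal_key_of(segment_id: str) -> str:
    """``<subject>-<meal>`` prefix of a ``<subject>-<meal>-<food>`` id."""
    return segment_id.rsplit("-", 1)[0]


@dataclass
class Study:
    """In-memory study: raw kinetics, annotations, audio envelopes."""

    kinetics: pd.DataFrame
    annotations: pd.DataFrame
    audio: dict[str, np.ndarray]
    sample_rate_hz: float = 5.0
    audio_rate_fps: float = 25.0


# ---------------------------------------------------------------------------
# CSV / JSON I/O


def write_kinetic_csv(kinetics: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in KINETIC_CSV_COLUMNS if c not in kinetics.columns]
    if missing:
        raise ValueError(f"kinetic table lacks columns {missing}")
    kinetics[list(KINETIC_CSV_COLUMNS)].to_csv(path, index=False)


def read_kinetic_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate the kinetic CSV dialect.

    Timestamps must be strictly increasing within each
    (subject, wrist, meal) stream; gaps relative to the nominal 5 Hz
    spacing are logged, non-monotone rows rejected with their position.
    """
    df = pd.read_csv(
        path,
        dtype={c: str for c in _ID_COLUMNS},
        keep_default_na=False,
        float_precision="round_trip",
    )
    missing = [c for c in KINETIC_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"kinetic CSV {path} lacks column(s) {missing}")
    for col in ("t_s", "x_mG", "y_mG", "z_mG"):
        df[col] = df[col].astype(float)
    meal = df["segment_id"].map(meal_key_of)
    for (subj, wrist, mk), grp in df.groupby(
        ["subject_id", "wrist", meal], sort=False
    ):
        t = grp["t_s"].to_numpy()
        dt = np.diff(t)
        if (dt <= 0).any():
            row = int(grp.index[1:][dt <= 0][0])
            raise ValueError(
                f"non-monotone timestamps in stream ({subj}, {wrist}, {mk}) "
                f"at row {row}"
            )
        nominal = 1.0 / 5.0
        gaps = int((dt > 1.5 * nominal).sum())
        if gaps:
            logger.warning(
                "stream (%s, %s, %s) has %d timestamp gaps", subj, wrist, mk, gaps
            )
    return df


def save_study(study: Study, out_dir: str | Path) -> None:
    """Serialize a study to ``kinetics.csv``, ``annotations.json``, ``audio/``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_kinetic_csv(study.kinetics, out / "kinetics.csv")
    write_annotation_json(study.annotations, out / "annotations.json")
    audio_dir = out / "audio"
    audio_dir.mkdir(exist_ok=True)
    for meal_key, env in sorted(study.audio.items()):
        pd.DataFrame(
            {"frame": np.arange(len(env)), "level": np.asarray(env, dtype=float)}
        ).to_csv(audio_dir / f"{meal_key}.csv", index=False)


def load_study(study_dir: str | Path) -> Study:
    d = Path(study_dir)
    kinetics = read_kinetic_csv(d / "kinetics.csv")
    annotations = read_annotation_json(d / "annotations.json")
    audio: dict[str, np.ndarray] = {}
    for f in sorted((d / "audio").glob("*.csv")):
        env = pd.read_csv(f, float_precision="round_trip")["level"].to_numpy(
            dtype=float
        )
        audio[f.stem] = env
    return Study(kinetics=kinetics, annotations=annotations, audio=audio)


# ---------------------------------------------------------------------------
# Preparation: kinetics + sync + label fusion (shared across grid cells)


@dataclass
class PreparedMeal:
    """One subject-meal after kinetics, sync and label fusion.

    ``frames`` and ``fused`` are restricted to food segments (lead-in
    rows dropped); ``offsets`` holds the per-segment clock offsets.
    """

    frames: dict[str, pd.DataFrame]
    fused: FusedLabels
    offsets: list[sync.ClockOffset]


def _segment_starts(frame: pd.DataFrame) -> list[tuple[str, float]]:
    seen: dict[str, float] = {}
    for seg, t in zip(frame["segment_id"], frame["t_s"]):
        if seg not in seen:
            seen[seg] = float(t)
    return list(seen.items())


def prepare_meal(
    study: Study, meal_frames: dict[str, pd.DataFrame], meal_key: str
) -> PreparedMeal:
    """Kinetics, clap sync and label fusion for one subject-meal."""
    frames = {
        wrist: derive_kinetics(f.sort_values("t_s").reset_index(drop=True))
        for wrist, f in meal_frames.items()
    }
    dom = frames["dominant"]
    t_s = dom["t_s"].to_numpy()
    power = dom["power_mG"].to_numpy()

    if meal_key not in study.audio:
        raise ValueError(f"study has no audio envelope for meal {meal_key}")
    env = study.audio[meal_key]

    offsets: list[sync.ClockOffset] = []
    food_segments = [
        (seg, t0)
        for seg, t0 in _segment_starts(dom)
        if dom.loc[dom["segment_id"] == seg, "food_id"].iloc[0] != ""
    ]
    for seg, t0 in food_segments:
        accel_idx = sync.detect_clap_peak(
            power,
            search_start_s=t0,
            search_len_s=ACCEL_CLAP_SEARCH_LEN_S,
            sample_rate=study.sample_rate_hz,
            min_prominence=sync.DEFAULT_MIN_PROMINENCE_MG,
            segment_id=seg,
        )
        audio_idx = sync.detect_clap_peak(
            env,
            search_start_s=max(0.0, t0 - CLAP_SEARCH_HALFWIDTH_S),
            search_len_s=2 * CLAP_SEARCH_HALFWIDTH_S,
            sample_rate=study.audio_rate_fps,
            min_prominence=AUDIO_MIN_PROMINENCE,
            segment_id=seg,
        )
        offsets.append(
            sync.align_streams(
                accel_idx,
                study.sample_rate_hz,
                audio_idx,
                study.audio_rate_fps,
                segment_id=seg,
            )
        )
    offset_by_segment = {o.segment_id: o.offset_s for o in offsets}

    # the evaluator roster is a property of the study; a meal in which an
    # evaluator marked nothing simply rasterizes to an all-false track
    evaluators = sorted(study.annotations["evaluator"].unique())
    if len(evaluators) != 2:
        raise ValueError(
            f"study needs exactly two evaluators, found {evaluators}"
        )
    ann = study.annotations
    ann = ann[ann["segment_id"].map(meal_key_of) == meal_key]
    tracks = []
    for ev in evaluators:
        rows = ann[ann["evaluator"] == ev]
        intervals = [
            (
                start - offset_by_segment.get(seg, 0.0),
                stop - offset_by_segment.get(seg, 0.0),
            )
            for seg, start, stop in zip(
                rows["segment_id"], rows["start_s"], rows["stop_s"]
            )
        ]
        tracks.append(AnnotationTrack(ev, rasterize_intervals(intervals, t_s)))
    fused = combine_labels(tracks[0], tracks[1])

    keep = (dom["food_id"] != "").to_numpy()
    frames = {w: f.loc[keep].reset_index(drop=True) for w, f in frames.items()}
    fused = FusedLabels(united=fused.united[keep], intersected=fused.intersected[keep])
    return PreparedMeal(frames=frames, fused=fused, offsets=offsets)


def prepare_study(study: Study) -> dict[str, PreparedMeal]:
    """Run kinetics, sync and label fusion for every subject-meal."""
    kin = study.kinetics
    meal = kin["segment_id"].map(meal_key_of)
    prepared: dict[str, PreparedMeal] = {}
    for meal_key, grp in kin.groupby(meal, sort=True):
        frames = {
            wrist: sub.drop(columns=[])
            for wrist, sub in grp.groupby("wrist", sort=False)
        }
        if "dominant" not in frames:
            raise ValueError(f"meal {meal_key} lacks a dominant-wrist stream")
        prepared[meal_key] = prepare_meal(study, frames, meal_key)
    return prepared


def offsets_table(prepared: Mapping[str, PreparedMeal]) -> pd.DataFrame:
    """Per-segment clock offsets as an exportable table."""
    rows = [
        {"segment_id": o.segment_id, "offset_s": o.offset_s}
        for pm in prepared.values()
        for o in pm.offsets
    ]
    return pd.DataFrame(rows, columns=["segment_id", "offset_s"])


# ---------------------------------------------------------------------------
# Grid configuration and execution


LabelCriterion = Literal["united", "intersected"]


@dataclass(frozen=True)
class AnalysisConfig:
    """One cell of the stratification grid plus forest settings."""

    width_s: int
    label_criterion: LabelCriterion
    source_mode: SourceMode
    step_s: int = 1
    n_trees: int = 500
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.label_criterion not in ("united", "intersected"):
            raise ValueError(f"unknown label criterion {self.label_criterion!r}")

    @property
    def window_spec(self) -> WindowSpec:
        return WindowSpec(width_s=self.width_s, step_s=self.step_s)

    @property
    def forest_settings(self) -> ForestSettings:
        return ForestSettings(
            n_trees=self.n_trees, cv_folds=self.cv_folds, seed=self.seed
        )


@dataclass
class StratifiedResult:
    """Outcome of one grid cell."""

    config: AnalysisConfig
    n_ius: int
    n_eating: int
    chosen_mtry: int
    cv_curve: dict[int, float]
    metrics: list[FoodMetrics]
    importances: list[ImportanceRow]


def default_grid(
    widths: Sequence[int] = (1, 2, 3, 4, 5),
    criteria: Sequence[str] = ("united", "intersected"),
    sources: Sequence[str] = ("full", "dominant"),
    step_s: int = 1,
    n_trees: int = 500,
    cv_folds: int = 5,
    seed: int = 0,
) -> list[AnalysisConfig]:
    """Cross-product grid of analysis configs (default 5 x 2 x 2 = 20)."""
    return [
        AnalysisConfig(
            width_s=w,
            label_criterion=c,
            source_mode=s,
            step_s=step_s,
            n_trees=n_trees,
            cv_folds=cv_folds,
            seed=seed,
        )
        for s, c, w in itertools.product(sources, criteria, widths)
    ]


def build_iu_table(
    prepared: Mapping[str, PreparedMeal], spec: WindowSpec, source_mode: SourceMode
) -> pd.DataFrame:
    """Concatenate IU tables over all prepared meals."""
    tables = [
        build_ius(pm.frames, pm.fused, spec, source_mode)
        for _, pm in sorted(prepared.items())
    ]
    tables = [t for t in tables if len(t)]
    if not tables:
        raise ValueError("no IUs could be built (segments shorter than the window?)")
    return pd.concat(tables, ignore_index=True)


def run_stratified_analysis(
    study: Study,
    config: AnalysisConfig,
    prepared: Mapping[str, PreparedMeal] | None = None,
    iu_table: pd.DataFrame | None = None,
) -> StratifiedResult:
    """Execute one grid cell end to end.

    ``prepared`` and ``iu_table`` allow the grid driver to share the
    sync/kinetics pass and per-(width, source) IU tables across cells.
    """
    if iu_table is None:
        if prepared is None:
            prepared = prepare_study(study)
        iu_table = build_iu_table(prepared, config.window_spec, config.source_mode)

    eating_col = f"eating_{config.label_criterion}"
    train = iu_table[iu_table[eating_col]].reset_index(drop=True)
    n_ius, n_eating = len(iu_table), len(train)
    logger.info(
        "cell (%s, %s, %d s): %d IUs, %d eating",
        config.source_mode,
        config.label_criterion,
        config.width_s,
        n_ius,
        n_eating,
    )

    settings = config.forest_settings
    chosen, curve = select_mtry_cv(train, settings)
    settings.mtry = chosen
    model = fit_forest(train, settings)
    all_foods = sorted(iu_table["food_id"].unique())
    metrics = oob_metrics(model, train, all_foods=all_foods)
    importances = scaled_importance(model)
    return StratifiedResult(
        config=config,
        n_ius=n_ius,
        n_eating=n_eating,
        chosen_mtry=chosen,
        cv_curve=curve,
        metrics=metrics,
        importances=importances,
    )


def run_full_grid(
    study: Study,
    grid: Sequence[AnalysisConfig] | None = None,
    out_dir: str | Path | None = None,
    keep_going: bool = False,
) -> tuple[list[StratifiedResult], pd.DataFrame]:
    """Run every grid cell, sharing preparation and IU tables.

    Returns the per-cell results and a summary table (one row per cell
    with IU and eating counts, feature count and chosen mtry).  With
    ``out_dir`` set, writes ``summary.csv``, ``metrics.csv`` and
    ``importance.csv``.
    """
    if grid is None:
        grid = default_grid()
    prepared = prepare_study(study)
    iu_cache: dict[tuple[int, int, str], pd.DataFrame] = {}
    results: list[StratifiedResult] = []
    for config in grid:
        key = (config.width_s, config.step_s, config.source_mode)
        if key not in iu_cache:
            iu_cache[key] = build_iu_table(
                prepared, config.window_spec, config.source_mode
            )
        try:
            results.append(
                run_stratified_analysis(
                    study, config, prepared=prepared, iu_table=iu_cache[key]
                )
            )
        except Exception:
            if not keep_going:
                logger.error(
                    "grid cell (%s, %s, %d s) failed",
                    config.source_mode,
                    config.label_criterion,
                    config.width_s,
                )
                raise
            logger.exception(
                "grid cell (%s, %s, %d s) failed; continuing",
                config.source_mode,
                config.label_criterion,
                config.width_s,
            )

    summary = summary_table(results)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out / "summary.csv", index=False)
        metrics_table(results).to_csv(out / "metrics.csv", index=False)
        importance_table(results).to_csv(out / "importance.csv", index=False)
    return results, summary


# ---------------------------------------------------------------------------
# Tabular exports


def _cell_columns(r: StratifiedResult) -> dict:
    return {
        "source": r.config.source_mode,
        "label_criterion": r.config.label_criterion,
        "width_s": r.config.width_s,
    }


def summary_table(results: Sequence[StratifiedResult]) -> pd.DataFrame:
    rows = [
        {
            **_cell_columns(r),
            "information_units": r.n_ius,
            "eating_labels": r.n_eating,
            "kinetic_variables": len(r.importances),
            "chosen_mtry": r.chosen_mtry,
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def metrics_table(results: Sequence[StratifiedResult]) -> pd.DataFrame:
    rows = [
        {
            **_cell_columns(r),
            "food_id": m.food_id,
            "sensitivity": m.sensitivity,
            "specificity": m.specificity,
            "support": m.support,
        }
        for r in results
        for m in r.metrics
    ]
    return pd.DataFrame(rows)


def importance_table(results: Sequence[StratifiedResult]) -> pd.DataFrame:
    rows = [
        {
            **_cell_columns(r),
            "variable": imp.variable_name,
            "raw_gini_decrease": imp.raw_gini_decrease,
            "scaled_0_100": imp.scaled_0_100,
        }
        for r in results
        for imp in r.importances
    ]
    return pd.DataFrame(rows)
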