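"""Window enumeration, slope features and IU labeling."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kineat.annotation import FusedLabels
from kineat.kinetics import KINETIC_VARIABLES, derive_kinetics
from kineat.windows import (
    WindowSpec,
    build_ius,
    enumerate_windows,
    feature_columns,
    window_slope,
)


@pytest.mark.parametrize(
    "L, width, expected",
    [(10, 1, 10), (10, 5, 6), (3, 5, 0), (5, 5, 1), (0, 1, 0)],
)
def test_enumerate_window_counts(L, width, expected):
    starts = enumerate_windows(L, WindowSpec(width))
    assert len(starts) == expected
    if expected:
        assert starts[0] == 0.0
        assert starts[-1] + width <= L


def test_window_spec_validation():
    with pytest.raises(ValueError):
        WindowSpec(6)
    with pytest.raises(ValueError):
        WindowSpec(2, step_s=0)
    assert WindowSpec(3).samples_per_window == 15


@pytest.mark.parametrize(
    "values, rate, expected",
    [
        ([7, 7, 7, 7, 7], 5.0, 0.0),
        ([0.0, 0.2, 0.4, 0.6, 0.8], 5.0, 1.0),
        ([0, 1, 2, 3, 4], 5.0, 5.0),
    ],
)
def test_window_slope_examples(values, rate, expected):
    assert window_slope(values, rate) == pytest.approx(expected, abs=1e-12)


def test_window_slope_rejects_degenerate_input():
    with pytest.raises(ValueError):
        window_slope([1.0], 5.0)
    with pytest.raises(ValueError):
        window_slope([1.0, np.nan, 2.0], 5.0)


@settings(derandomize=True, deadline=None)
@given(
    v=st.lists(
        st.floats(min_value=-1e3, max_value=1e3, allow_nan=False), min_size=2, max_size=25
    ),
    a=st.floats(min_value=-10, max_value=10, allow_nan=False),
    b=st.floats(min_value=-100, max_value=100, allow_nan=False),
)
def test_window_slope_linearity(v, a, b):
    v = np.asarray(v)
    base = window_slope(v, 5.0)
    scaled = window_slope(a * v + b, 5.0)
    assert scaled == pytest.approx(a * base, rel=1e-9, abs=1e-6)


def _toy_frames(n=20, two_wrists=True):
    rng = np.random.default_rng(1)
    frames = {}
    wrists = ("dominant", "nondominant") if two_wrists else ("dominant",)
    for wrist in wrists:
        raw = pd.DataFrame(
            {
                "subject_id": "s01",
                "wrist": wrist,
                "segment_id": "s01-lunch-04",
                "food_id": "04",
                "t_s": np.arange(n) / 5.0,
                "x_mG": rng.normal(0, 50, n),
                "y_mG": rng.normal(0, 50, n),
                "z_mG": 1000 + rng.normal(0, 50, n),
            }
        )
        frames[wrist] = derive_kinetics(raw)
    return frames


def test_build_ius_feature_lengths_by_source():
    frames = _toy_frames()
    fused = FusedLabels(np.zeros(20, bool), np.zeros(20, bool))
    dom = build_ius(frames, fused, WindowSpec(1), "dominant")
    full = build_ius(frames, fused, WindowSpec(1), "full")
    assert len(feature_columns("dominant")) == 7
    assert len(feature_columns("full")) == 14
    assert dom.filter(like="_slope").shape[1] == 7
    assert full.filter(like="_slope").shape[1] == 14
    # dominant wrist's 7 features come first in full mode
    assert list(full.filter(like="_slope").columns)[:7] == list(
        dom.filter(like="_slope").columns
    )


def test_iu_slopes_match_scalar_window_slope():
    frames = _toy_frames(two_wrists=False)
    fused = FusedLabels(np.zeros(20, bool), np.zeros(20, bool))
    ius = build_ius(frames, fused, WindowSpec(2), "dominant")
    v = frames["dominant"]["pitch_rad"].to_numpy()
    for i, start in enumerate(ius.start_s):
        lo = int(round(start * 5))
        expected = window_slope(v[lo : lo + 10], 5.0)
        assert ius["dominant_pitch_rad_slope"][i] == pytest.approx(expected, rel=1e-9)


def test_eating_label_requires_strict_majority():
    frames = _toy_frames(n=10, two_wrists=False)
    # window width 1 s = 5 samples; 3/5 eating -> labeled, 5/10 -> not
    united = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0], bool)
    fused = FusedLabels(united, np.zeros(10, bool))
    ius = build_ius(frames, fused, WindowSpec(1), "dominant")
    assert bool(ius.eating_united[0]) is True  # samples 0-4: 3 of 5
    assert bool(ius.eating_united[1]) is False  # samples 5-9: 0 of 5

    half = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0], bool)  # exactly 50% of 10
    fused = FusedLabels(half, np.zeros(10, bool))
    ius2 = build_ius(frames, fused, WindowSpec(2), "dominant")
    assert bool(ius2.eating_united[0]) is False


def test_intersected_labels_imply_united(tiny_prepared):
    from kineat.pipeline import build_iu_table

    for width in (1, 3, 5):
        iu = build_iu_table(tiny_prepared, WindowSpec(width), "dominant")
        assert not (iu.eating_intersected & ~iu.eating_united).any()


def test_windows_never_cross_segments():
    frames = _toy_frames(n=30, two_wrists=False)
    f = frames["dominant"].copy()
    f.loc[15:, "segment_id"] = "s01-lunch-06"
    f.loc[15:, "food_id"] = "06"
    fused = FusedLabels(np.zeros(30, bool), np.zeros(30, bool))
    ius = build_ius({"dominant": f}, fused, WindowSpec(2), "dominant")
    # each 15-sample segment admits (15-10)/5+1 = 2 windows of 2 s at 1 s step
    assert sorted(ius.food_id.unique()) == ["04", "06"]
    assert len(ius) == 4


def test_misaligned_frames_rejected():
    frames = _toy_frames()
    frames["nondominant"] = frames["nondominant"].iloc[:-1]
    fused = FusedLabels(np.zeros(20, bool), np.zeros(20, bool))
    with pytest.raises(ValueError, match="aligned"):
        build_ius(frames, fused, WindowSpec(1), "full")


def test_unknown_source_mode_rejected():
    frames = _toy_frames()
    fused = FusedLabels(np.zeros(20, bool), np.zeros(20, bool))
    with pytest.raises(ValueError, match="source_mode"):
        build_ius(frames, fused, WindowSpec(1), "both")


def test_stacked_mode_doubles_ius_with_wrist_agnostic_columns():
    frames = _toy_frames()
    fused = FusedLabels(np.zeros(20, bool), np.zeros(20, bool))
    dom = build_ius(frames, fused, WindowSpec(1), "dominant")
    stacked = build_ius(frames, fused, WindowSpec(1), "stacked")
    assert len(stacked) == 2 * len(dom)
    assert stacked.filter(like="_slope").shape[1] == 7
    assert "wrist" in stacked.columns
    assert sorted(stacked.wrist.unique()) == ["dominant", "nondominant"]
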