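"""Gesture profiles, meal simulation, annotators, separability dial."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from kineat.annotation import FusedLabels, rasterize_intervals
from kineat.kinetics import G_MG, derive_kinetics
from kineat.registry import ALL_FOOD_IDS, TWO_HANDED_FOODS, menu_items, total_raw_records
from kineat.synthetic import (
    GestureProfile,
    assign_menus,
    make_gesture_profile,
    simulate_annotators,
    simulate_subject_meal,
)
from kineat.windows import WindowSpec, build_ius

KINETIC_PARAMS = (
    "bite_period_s",
    "bite_duration_s",
    "pitch_amplitude_rad",
    "roll_amplitude_rad",
    "linear_accel_burst_mG",
    "noise_sd_mG",
    "bite_apex_fraction",
    "burst_azimuth_rad",
)


def test_registry_shape():
    assert len(ALL_FOOD_IDS) == 13
    assert len(menu_items("A")) == 7 and len(menu_items("B")) == 7
    assert set(menu_items("A")) & set(menu_items("B")) == {"02"}  # yogurt


def test_two_handed_foods_flagged():
    for fid in ALL_FOOD_IDS:
        prof = make_gesture_profile(fid, effect_size=1.7)
        assert prof.two_handed == (fid in TWO_HANDED_FOODS)
    assert make_gesture_profile("07", 0.0).two_handed  # meatballs, any effect


def test_unknown_food_id_rejected_with_valid_ids():
    with pytest.raises(ValueError, match="01"):
        make_gesture_profile("99", 1.0)


def test_zero_effect_yields_identical_kinetic_parameters():
    profs = [make_gesture_profile(fid, 0.0) for fid in ALL_FOOD_IDS]
    ref = profs[0]
    for p in profs[1:]:
        for name in KINETIC_PARAMS:
            assert getattr(p, name) == getattr(ref, name)
        assert p.nondominant_activity == 1.0  # flag cannot alter statistics


def test_profiles_diverge_with_effect_size():
    a = [make_gesture_profile(fid, 0.5) for fid in ALL_FOOD_IDS]
    b = [make_gesture_profile(fid, 2.0) for fid in ALL_FOOD_IDS]
    spread = lambda profs, name: np.ptp([getattr(p, name) for p in profs])
    for name in ("bite_period_s", "pitch_amplitude_rad", "noise_sd_mG"):
        assert spread(b, name) > spread(a, name) > 0


def test_profile_invariants_hold_at_large_effect():
    for fid in ALL_FOOD_IDS:
        p = make_gesture_profile(fid, 4.0)
        assert 0 < p.bite_duration_s < p.bite_period_s
        assert p.noise_sd_mG >= 0 and p.linear_accel_burst_mG >= 0
        assert 0.15 <= p.bite_apex_fraction <= 0.85


def test_segment_sample_count_is_rate_times_duration():
    prof = make_gesture_profile("04", 1.0)
    meal = simulate_subject_meal([prof], duration_per_item_s=60, seed=0, lead_in_s=6)
    dom = meal.streams["dominant"]
    assert (dom.food_id == "04").sum() == 300
    assert len(meal.clap_times_s) == 1


def test_same_seed_is_bit_identical():
    profs = [make_gesture_profile(f, 1.5) for f in ("04", "06")]
    m1 = simulate_subject_meal(profs, 20, seed=42)
    m2 = simulate_subject_meal(profs, 20, seed=42)
    for wrist in ("dominant", "nondominant"):
        pd.testing.assert_frame_equal(m1.streams[wrist], m2.streams[wrist])
    assert np.array_equal(m1.audio_envelope, m2.audio_envelope)
    assert m1.truth == m2.truth


def test_gravity_closure_without_gesture_or_noise():
    """Zero amplitudes, burst and noise leave pure gravity: power is
    exactly 1 G everywhere outside the clap transient."""
    prof = GestureProfile("04", 11.0, 7.0, 0.0, 0.0, 0.0, False, 0.0)
    meal = simulate_subject_meal([prof], duration_per_item_s=20, seed=0)
    dom = derive_kinetics(meal.streams["dominant"])
    power = dom.power_mG.to_numpy()
    clap = np.zeros(len(dom), bool)
    clap[int(meal.clap_times_s[0] * 5) : int(meal.clap_times_s[0] * 5) + 2] = True
    assert np.allclose(power[~clap], G_MG, atol=1e-9)
    assert np.allclose(dom.total_energy_mG.to_numpy()[~clap], 0.0, atol=1e-3)


def test_nondominant_wrist_idle_for_one_handed_food_at_default_effect():
    one_handed = make_gesture_profile("04", 2.0)  # risotto
    two_handed = make_gesture_profile("07", 2.0)  # meatballs
    m = simulate_subject_meal([one_handed, two_handed], 30, seed=1)
    nd = m.streams["nondominant"]
    sd_one = nd[nd.food_id == "04"].y_mG.iloc[5:].std()
    sd_two = nd[nd.food_id == "07"].y_mG.iloc[5:].std()
    assert sd_two > 3 * sd_one  # gesture only on the two-handed segment


def test_annotators_with_zero_jitter_match_truth():
    prof = make_gesture_profile("04", 1.0)
    meal = simulate_subject_meal([prof], 30, seed=2)
    t = meal.streams["dominant"].t_s.to_numpy()
    a, b = simulate_annotators(meal.truth, 0.0, seed=3, t_s=t)
    truth_mask = rasterize_intervals(
        [(iv.start_s, iv.stop_s) for iv in meal.truth], t
    )
    assert np.array_equal(a.labels, truth_mask)
    assert np.array_equal(b.labels, truth_mask)


def test_annotator_jitter_preserves_inclusion_and_interior():
    prof = make_gesture_profile("04", 1.0)
    meal = simulate_subject_meal([prof], 30, seed=4)
    t = meal.streams["dominant"].t_s.to_numpy()
    a, b = simulate_annotators(meal.truth, 0.3, seed=5, t_s=t)
    assert not np.array_equal(a.labels, b.labels)  # jitter separates evaluators
    assert np.any(a.labels & b.labels)  # interior samples agree


def test_empty_truth_gives_all_noneating():
    a, b = simulate_annotators([], 0.5, seed=0, t_s=np.arange(50) / 5)
    assert not a.labels.any() and not b.labels.any()


def test_negative_jitter_rejected():
    with pytest.raises(ValueError):
        simulate_annotators([], -0.1, seed=0, t_s=np.arange(5) / 5)


def test_menu_assignment_balanced():
    menus = assign_menus(20, seed=0)
    assert sorted(set(menus)) == ["A", "B"]
    assert abs(menus.count("A") - menus.count("B")) <= 1


def _mean_slope_vectors(effect_size: float) -> dict[str, np.ndarray]:
    profs = [make_gesture_profile(f, effect_size) for f in ALL_FOOD_IDS]
    meal = simulate_subject_meal(profs, duration_per_item_s=20, seed=77)
    frame = derive_kinetics(meal.streams["dominant"])
    t = frame.t_s.to_numpy()
    truth_mask = rasterize_intervals(
        [(iv.start_s, iv.stop_s) for iv in meal.truth], t
    )
    keep = (frame.food_id != "").to_numpy()
    ius = build_ius(
        {"dominant": frame.loc[keep]},
        FusedLabels(truth_mask[keep], truth_mask[keep]),
        WindowSpec(3),
        "dominant",
    )
    eating = ius[ius.eating_united]
    feats = eating.filter(like="_slope")
    return {
        f: feats[eating.food_id == f].mean().to_numpy() for f in ALL_FOOD_IDS
    }


def test_separability_dial_is_monotone():
    """Mean pairwise distance between per-food mean slope vectors is
    nondecreasing in effect size (fixed seed)."""
    dists = []
    for es in (0.0, 0.5, 1.0, 2.0):
        vecs = _mean_slope_vectors(es)
        foods = list(vecs)
        d = np.mean(
            [
                np.linalg.norm(vecs[a] - vecs[b])
                for i, a in enumerate(foods)
                for b in foods[i + 1 :]
            ]
        )
        dists.append(d)
    assert all(b >= a - 1e-9 for a, b in zip(dists, dists[1:]))
    assert dists[-1] > dists[0]


def test_table_totals_consistent():
    assert total_raw_records() == 278260
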