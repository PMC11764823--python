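"""Synthetic study generator: gesture-driven wrist kinetics with claps.

The generator emulates the shape of the original acquisition — 20
subjects, two menus of four meals, 13 food items, two wrists sampled at
5 Hz, a hand clap at the start of every food-item segment, a 25 FPS
audio envelope and two boundary-jittered annotators — while the gesture
dynamics themselves are free parameters.

Each food item gets a :class:`GestureProfile` whose parameters (bite
period and duration, pitch/roll amplitudes, linear-acceleration burst,
noise level) deviate from a common baseline by per-food offsets scaled
with a single ``effect_size`` dial: at 0 all foods share identical
kinetic statistics; larger values spread the profiles apart, making the
classes more separable.  The per-food offsets are balanced rank tables
(one modular permutation of 13 ranks per parameter) so that any two
foods differ along several parameters at once.

The signal model per wrist sample is a gravity vector rotated by the
instantaneous (pitch, roll) orientation — axis convention chosen so the
rest pose reads (0, 0, 1000) milli-G and the kinetics formulas recover
pitch and roll exactly — plus a linear-acceleration burst during each
bite and i.i.d. Gaussian noise.  The non-dominant wrist attenuates the
gesture by the profile's ``nondominant_activity`` (baseline noise only
for one-handed foods at the default effect size).  A clap is a decaying
2-sample +3000 milli-G transient on all three axes, mirrored as a
one-frame unit peak in the audio envelope.

All randomness flows from one explicit seed through per-purpose
``numpy.random.SeedSequence`` keys, so repeated calls are bit-identical
and modules can be exercised independently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import AnnotationTrack, rasterize_intervals
from .kinetics import G_MG
from .pipeline import Study
from .registry import ALL_FOOD_IDS, FOOD_REGISTRY, TWO_HANDED_FOODS, menu_items

logger = logging.getLogger(__name__)

#: clap transient: 2 samples of +3000 milli-G on every axis.
CLAP_AMPLITUDE_MG = 3000.0
CLAP_N_SAMPLES = 2

#: rest baseline recorded before the first clap of each meal, in s.
DEFAULT_LEAD_IN_S = 6.0

#: bites start this long after the segment's clap and stop this long
#: before the segment end.
BITE_HEAD_S = 3.0
BITE_TAIL_S = 2.0

#: unit direction of the linear-acceleration burst in the device frame.
_BURST_DIR = np.array([0.3, 0.8, 0.5]) / np.linalg.norm([0.3, 0.8, 0.5])

# baseline gesture parameters (effect_size = 0) and per-unit-effect
# spreads; per-food rank coefficients lie in [-1, 1].  A complete
# eating movement (plate -> mouth -> chewing -> plate) lasts ~7 s of an
# ~11 s bite cycle — longer than the widest (5 s) analysis window, so
# windows inside one movement see the limb's monotone trend.
_BASE = {
    "bite_period_s": (11.0, 0.75),
    "bite_duration_s": (7.0, 0.5),
    "pitch_amplitude_rad": (0.45, 0.20),
    "roll_amplitude_rad": (0.35, 0.15),
    "linear_accel_burst_mG": (200.0, 80.0),
    "noise_sd_mG": (30.0, 10.0),
    "bite_apex_fraction": (0.5, 0.15),
    "burst_azimuth_rad": (0.0, 0.45),
}

# one coprime multiplier per parameter; (m * i) mod 13 ranks the 13
# foods differently for each parameter, keeping the offsets balanced.
_RANK_MULTIPLIERS = {
    "bite_period_s": 1,
    "bite_duration_s": 2,
    "pitch_amplitude_rad": 5,
    "roll_amplitude_rad": 7,
    "linear_accel_burst_mG": 3,
    "noise_sd_mG": 11,
    "bite_apex_fraction": 6,
    "burst_azimuth_rad": 4,
}


def _rank_coeff(food_id: str, param: str) -> float:
    i = int(food_id)
    rank = (_RANK_MULTIPLIERS[param] * i) % 13  # 0..12, a permutation
    return (rank - 6) / 6.0


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Counter-keyed child generator; same (seed, key) -> same stream."""
    return np.random.default_rng(np.random.SeedSequence((int(seed),) + tuple(key)))


@dataclass(frozen=True)
class GestureProfile:
    """Kinetic parameters of one food item's eating gesture."""

    food_id: str
    bite_period_s: float
    bite_duration_s: float
    pitch_amplitude_rad: float
    roll_amplitude_rad: float
    linear_accel_burst_mG: float
    two_handed: bool
    noise_sd_mG: float
    #: gesture attenuation on the non-dominant wrist.  Two-handed foods
    #: keep 1; one-handed foods fade to pure baseline as the effect size
    #: grows (so at effect 0 the flag cannot alter signal statistics).
    nondominant_activity: float = 1.0
    #: where within the bite the orientation excursion peaks (0-1); the
    #: waveform is triangular, so rise and fall rates are food-specific.
    bite_apex_fraction: float = 0.5
    #: rotation (rad, about the device z axis) of the linear-acceleration
    #: burst direction — foods differ in how the burst projects on x/y.
    burst_azimuth_rad: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.bite_duration_s < self.bite_period_s:
            raise ValueError("bite_duration_s must lie in (0, bite_period_s)")
        for name in (
            "pitch_amplitude_rad",
            "roll_amplitude_rad",
            "linear_accel_burst_mG",
            "noise_sd_mG",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass(frozen=True)
class TruthInterval:
    """Ground-truth eating gesture, on the meal's accelerometer clock."""

    segment_id: str
    food_id: str
    start_s: float
    stop_s: float

    def __post_init__(self) -> None:
        if not self.stop_s > self.start_s >= 0:
            raise ValueError("need 0 <= start_s < stop_s")


@dataclass
class SyntheticMeal:
    """Two wrist streams, ground truth, claps and the audio envelope."""

    streams: dict[str, pd.DataFrame]
    truth: list[TruthInterval]
    audio_envelope: np.ndarray
    clap_times_s: list[float]
    audio_offset_s: float = 0.0


def make_gesture_profile(food_id: str, effect_size: float = 1.0) -> GestureProfile:
    """Deterministic food-id -> gesture-profile mapping.

    ``effect_size`` scales the per-food deviations from the common
    baseline: 0 gives all foods identical kinetic parameters (only the
    two-handed flag differs), larger values spread them apart.
    """
    if food_id not in FOOD_REGISTRY:
        raise ValueError(
            f"unknown food_id {food_id!r}; valid ids are {', '.join(ALL_FOOD_IDS)}"
        )
    if effect_size < 0:
        raise ValueError("effect_size must be nonnegative")

    params: dict[str, float] = {}
    for name, (base, spread) in _BASE.items():
        params[name] = base + spread * effect_size * _rank_coeff(food_id, name)
    # keep the profile physical at large effect sizes
    params["bite_duration_s"] = float(
        np.clip(params["bite_duration_s"], 0.5, 0.75 * params["bite_period_s"])
    )
    params["pitch_amplitude_rad"] = max(params["pitch_amplitude_rad"], 0.0)
    params["roll_amplitude_rad"] = max(params["roll_amplitude_rad"], 0.0)
    params["linear_accel_burst_mG"] = max(params["linear_accel_burst_mG"], 0.0)
    params["noise_sd_mG"] = max(params["noise_sd_mG"], 1.0)
    params["bite_apex_fraction"] = float(
        np.clip(params["bite_apex_fraction"], 0.15, 0.85)
    )

    two_handed = food_id in TWO_HANDED_FOODS
    return GestureProfile(
        food_id=food_id,
        two_handed=two_handed,
        nondominant_activity=1.0 if two_handed else max(0.0, 1.0 - effect_size),
        **params,
    )


def _bite_schedule(
    profile: GestureProfile, seg_start_s: float, seg_len_s: float, rng
) -> list[tuple[float, float]]:
    """Bite intervals (meal clock) for one segment, with phase jitter."""
    bites = []
    t = seg_start_s + BITE_HEAD_S
    end = seg_start_s + seg_len_s - BITE_TAIL_S
    d = profile.bite_duration_s
    while t + d <= end:
        bites.append((t, t + d))
        gap = profile.bite_period_s * (1.0 + 0.15 * float(rng.uniform(-1, 1)))
        t = max(t + gap, t + d + 0.2)
    return bites


def _gesture_signal(
    t: np.ndarray,
    bites: list[tuple[float, float]],
    profile: GestureProfile,
    activity: float,
    rng,
) -> np.ndarray:
    """Triaxial milli-G signal for one wrist over one segment's samples.

    ``activity`` scales the gesture amplitudes (1 on the dominant wrist;
    the profile's ``nondominant_activity`` on the other).
    """
    n = len(t)
    pitch = np.zeros(n)
    roll = np.zeros(n)
    lin = np.zeros((n, 3))
    if activity > 0:
        r = profile.bite_apex_fraction
        az = profile.burst_azimuth_rad
        ca, sa = np.cos(az), np.sin(az)
        dx, dy, dz = _BURST_DIR
        burst_dir = np.array([dx * ca - dy * sa, dx * sa + dy * ca, dz])
        for bs, be in bites:
            sel = (t >= bs) & (t < be)
            if not sel.any():
                continue
            tau = (t[sel] - bs) / (be - bs)
            # triangular excursion peaking at the apex fraction: rise and
            # fall rates (hence window slopes) are food-specific
            tri = np.where(tau < r, tau / r, (1.0 - tau) / (1.0 - r))
            pitch[sel] += activity * profile.pitch_amplitude_rad * tri
            roll[sel] += activity * profile.roll_amplitude_rad * tri
            # nonnegative burst: mean linear acceleration during a bite
            # scales with the profile, shifting power/energy levels
            lin[sel] += (
                activity * profile.linear_accel_burst_mG * np.sin(np.pi * tau)
            )[:, None] * burst_dir

    # gravity vector in the device frame under (pitch, roll); the rest
    # pose (0, 0, G) recovers pitch = roll = 0 under the kinetics formulas
    x = -G_MG * np.cos(pitch) * np.sin(roll)
    y = G_MG * np.sin(pitch)
    z = G_MG * np.cos(pitch) * np.cos(roll)
    sig = np.column_stack([x, y, z]) + lin
    if profile.noise_sd_mG > 0:
        sig = sig + rng.normal(0.0, profile.noise_sd_mG, size=(n, 3))
    return sig


def simulate_subject_meal(
    profiles: list[GestureProfile],
    duration_per_item_s: float = 60.0,
    sample_rate_hz: float = 5.0,
    seed: int = 0,
    *,
    subject_id: str = "s01",
    meal_name: str = "meal",
    audio_offset_s: float = 0.0,
    lead_in_s: float = DEFAULT_LEAD_IN_S,
) -> SyntheticMeal:
    """Simulate one subject-meal: one segment per profile, both wrists.

    Each segment opens with a clap spike (both wrists and the audio
    envelope); the audio clock runs ``audio_offset_s`` ahead of the
    accelerometer clock.  Timestamps, segment ids and truth intervals
    are on the accelerometer (meal) clock starting at 0; the lead-in
    rows carry an empty ``food_id``.
    """
    if not profiles:
        raise ValueError("need at least one gesture profile")
    if duration_per_item_s < 10:
        raise ValueError("duration_per_item_s must be >= 10 s")
    if sample_rate_hz <= 0:
        raise ValueError("sample_rate_hz must be positive")
    if lead_in_s + audio_offset_s < 0:
        raise ValueError("audio_offset_s may not precede the recording start")

    rate = sample_rate_hz
    n_lead = int(round(lead_in_s * rate))
    n_seg = int(round(duration_per_item_s * rate))
    n_total = n_lead + n_seg * len(profiles)
    t_all = np.arange(n_total) / rate

    seg_ids = np.empty(n_total, dtype=object)
    food_ids = np.empty(n_total, dtype=object)
    seg_ids[:n_lead] = f"{subject_id}-{meal_name}-pre"
    food_ids[:n_lead] = ""

    truth: list[TruthInterval] = []
    clap_times: list[float] = []
    signals = {w: np.zeros((n_total, 3)) for w in ("dominant", "nondominant")}

    # rest-pose lead-in (noise level of the first profile's baseline)
    lead_rng = {
        w: _rng(seed, 0, wi) for wi, w in enumerate(("dominant", "nondominant"))
    }
    for w in signals:
        base = np.zeros((n_lead, 3))
        base[:, 2] = G_MG
        signals[w][:n_lead] = base + lead_rng[w].normal(
            0.0, profiles[0].noise_sd_mG, size=(n_lead, 3)
        )

    for si, profile in enumerate(profiles):
        lo = n_lead + si * n_seg
        hi = lo + n_seg
        t = t_all[lo:hi]
        seg_start = lo / rate
        seg_id = f"{subject_id}-{meal_name}-{profile.food_id}"
        seg_ids[lo:hi] = seg_id
        food_ids[lo:hi] = profile.food_id
        clap_times.append(seg_start)

        bites = _bite_schedule(
            profile, seg_start, duration_per_item_s, _rng(seed, 1, si)
        )
        for bs, be in bites:
            truth.append(TruthInterval(seg_id, profile.food_id, bs, be))

        for wi, wrist in enumerate(("dominant", "nondominant")):
            activity = 1.0 if wrist == "dominant" else profile.nondominant_activity
            sig = _gesture_signal(
                t, bites, profile, activity, _rng(seed, 2, si, wi)
            )
            # decaying transient: the leading edge is always the peak
            decay = CLAP_AMPLITUDE_MG * 0.5 ** np.arange(min(CLAP_N_SAMPLES, n_seg))
            sig[: len(decay)] += decay[:, None]
            signals[wrist][lo:hi] = sig

    streams = {}
    for wrist, sig in signals.items():
        streams[wrist] = pd.DataFrame(
            {
                "subject_id": subject_id,
                "wrist": wrist,
                "segment_id": seg_ids,
                "food_id": food_ids,
                "t_s": t_all,
                "x_mG": sig[:, 0],
                "y_mG": sig[:, 1],
                "z_mG": sig[:, 2],
            }
        )

    fps = 25.0
    meal_len_s = n_total / rate
    n_frames = int(np.ceil((meal_len_s + max(audio_offset_s, 0.0) + 1.0) * fps))
    env_rng = _rng(seed, 3)
    env = np.abs(env_rng.normal(0.0, 0.02, size=n_frames))
    for ct in clap_times:
        frame = int(round((ct + audio_offset_s) * fps))
        if 0 <= frame < n_frames:
            env[frame] = 1.0

    return SyntheticMeal(
        streams=streams,
        truth=truth,
        audio_envelope=env,
        clap_times_s=clap_times,
        audio_offset_s=audio_offset_s,
    )


def jitter_truth_intervals(
    truth: list[TruthInterval], jitter_sd_s: float, seed: int, evaluator_index: int
) -> list[TruthInterval]:
    """One evaluator's reading of the truth: endpoints Gaussian-jittered.

    Endpoints are perturbed independently with zero-mean jitter; stops
    are clipped so every interval keeps a positive length and a
    nonnegative start.
    """
    if jitter_sd_s < 0:
        raise ValueError("jitter_sd_s must be nonnegative")
    rng = _rng(seed, 4, evaluator_index)
    out = []
    for iv in truth:
        start = iv.start_s + float(rng.normal(0.0, jitter_sd_s))
        stop = iv.stop_s + float(rng.normal(0.0, jitter_sd_s))
        start = max(start, 0.0)
        stop = max(stop, start + 0.1)
        out.append(TruthInterval(iv.segment_id, iv.food_id, start, stop))
    return out


def simulate_annotators(
    truth: list[TruthInterval],
    jitter_sd_s: float,
    seed: int,
    t_s: np.ndarray,
) -> tuple[AnnotationTrack, AnnotationTrack]:
    """Two evaluators' per-sample labels for a stream with timestamps ``t_s``."""
    tracks = []
    for ei in range(2):
        ivs = jitter_truth_intervals(truth, jitter_sd_s, seed, ei)
        labels = rasterize_intervals(
            [(iv.start_s, iv.stop_s) for iv in ivs], t_s
        )
        tracks.append(AnnotationTrack(f"E{ei + 1}", labels))
    return tracks[0], tracks[1]


def assign_menus(n_subjects: int, seed: int) -> list[str]:
    """Random balanced assignment of subjects to menus A and B."""
    half = n_subjects // 2
    menus = ["A"] * (n_subjects - half) + ["B"] * half
    _rng(seed, 5).shuffle(menus)
    return menus


def simulate_study(
    n_subjects: int = 20,
    effect_size: float = 2.0,
    duration_per_item_s: float = 60.0,
    sample_rate_hz: float = 5.0,
    seed: int = 0,
    jitter_sd_s: float = 0.3,
    audio_offset_range_s: tuple[float, float] = (0.5, 2.5),
    lead_in_s: float = DEFAULT_LEAD_IN_S,
) -> Study:
    """Generate a full synthetic study in the pipeline's input format.

    Subjects are randomly but evenly assigned to menus A and B; each
    subject eats their menu's four meals (7 food segments in total).
    Annotation intervals are exported on the camera clock, i.e. shifted
    by the meal's audio offset, exactly as the pipeline expects to undo
    via clap sync.
    """
    from .registry import MEAL_ORDER

    menus = assign_menus(n_subjects, seed)
    kin_rows: list[pd.DataFrame] = []
    ann_rows: list[dict] = []
    audio: dict[str, np.ndarray] = {}

    for subj_idx in range(n_subjects):
        subject_id = f"s{subj_idx + 1:02d}"
        menu = menus[subj_idx]
        items = menu_items(menu)
        meal_seed = _rng(seed, 6, subj_idx).integers(0, 2**31 - 1)
        offset_rng = _rng(seed, 7, subj_idx)
        for mi, meal_name in enumerate(MEAL_ORDER):
            meal_items = [
                fid for fid in items if FOOD_REGISTRY[fid].meal == meal_name
            ]
            if not meal_items:
                continue
            profiles = [make_gesture_profile(fid, effect_size) for fid in meal_items]
            audio_offset = float(offset_rng.uniform(*audio_offset_range_s))
            meal = simulate_subject_meal(
                profiles,
                duration_per_item_s=duration_per_item_s,
                sample_rate_hz=sample_rate_hz,
                seed=int(meal_seed) + mi,
                subject_id=subject_id,
                meal_name=meal_name,
                audio_offset_s=audio_offset,
                lead_in_s=lead_in_s,
            )
            for wrist in ("dominant", "nondominant"):
                kin_rows.append(meal.streams[wrist])
            for ei in range(2):
                ivs = jitter_truth_intervals(
                    meal.truth, jitter_sd_s, int(meal_seed) + mi, ei
                )
                for iv in ivs:
                    ann_rows.append(
                        {
                            "segment_id": iv.segment_id,
                            "food_id": iv.food_id,
                            "evaluator": f"E{ei + 1}",
                            "start_s": iv.start_s + audio_offset,
                            "stop_s": iv.stop_s + audio_offset,
                        }
                    )
            audio[f"{subject_id}-{meal_name}"] = meal.audio_envelope

    kinetics = pd.concat(kin_rows, ignore_index=True)
    annotations = pd.DataFrame(
        ann_rows, columns=["segment_id", "food_id", "evaluator", "start_s", "stop_s"]
    )
    return Study(
        kinetics=kinetics,
        annotations=annotations,
        audio=audio,
        sample_rate_hz=sample_rate_hz,
    )
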