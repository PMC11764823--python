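"""Clock alignment between watch streams and the camera's audio track.

The watches and the camera cannot synchronize electronically, so the
subject claps once at the start of every food-item segment.  The clap is
a sharp transient: a spike in the acceleration magnitude (power) on the
watches and a one-frame peak in the audio envelope.  Matching the two
peaks gives, per segment, the offset between the camera clock and the
accelerometer clock; annotation times (camera clock) minus that offset
land on the accelerometer clock.

Detection runs on the power channel, not a single axis, so it is
invariant to how the wrist happens to be oriented during the clap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: nominal sampling rates of the two devices.
ACCEL_RATE_HZ = 5.0
AUDIO_RATE_FPS = 25.0

#: default clap prominence above the search-window median, in milli-G,
#: for the watch power channel.
DEFAULT_MIN_PROMINENCE_MG = 1000.0


class NoClapFound(RuntimeError):
    """No sample in the search window was prominent enough to be a clap."""

    def __init__(self, segment_id: str | None, start_s: float, stop_s: float):
        self.segment_id = segment_id
        self.window = (start_s, stop_s)
        super().__init__(
            f"no clap peak in window [{start_s:g}, {stop_s:g}) s"
            + (f" of segment {segment_id}" if segment_id else "")
        )


@dataclass(frozen=True)
class ClockOffset:
    """Audio clap time minus accelerometer clap time, per segment."""

    segment_id: str | None
    offset_s: float


def detect_clap_peak(
    series: np.ndarray,
    search_start_s: float,
    search_len_s: float,
    sample_rate: float,
    min_prominence: float,
    segment_id: str | None = None,
) -> int:
    """Index (into ``series``) of the clap peak within a search window.

    The clap is taken as the global maximum of the window, provided it
    exceeds the window median by ``min_prominence``; ties break toward
    the earliest index (the leading edge of the transient).
    """
    if min_prominence <= 0:
        raise ValueError("min_prominence must be positive")
    series = np.asarray(series, dtype=float)
    lo = int(round(search_start_s * sample_rate))
    hi = int(round((search_start_s + search_len_s) * sample_rate))
    lo = max(lo, 0)
    hi = min(hi, len(series))
    if hi <= lo:
        raise ValueError(
            f"search window [{search_start_s:g}, {search_start_s + search_len_s:g}) s "
            f"is outside the series (length {len(series)} at {sample_rate:g} Hz)"
        )
    window = series[lo:hi]
    peak = int(np.argmax(window))  # first occurrence on ties
    if window[peak] <= np.median(window) + min_prominence:
        raise NoClapFound(segment_id, lo / sample_rate, hi / sample_rate)
    return lo + peak


def align_streams(
    accel_clap_idx: int,
    accel_rate_hz: float = ACCEL_RATE_HZ,
    audio_clap_idx: int = 0,
    audio_rate_fps: float = AUDIO_RATE_FPS,
    segment_id: str | None = None,
) -> ClockOffset:
    """Clock offset from matched clap peaks.

    ``offset_s = audio_clap_idx / audio_rate - accel_clap_idx / accel_rate``;
    subtracting it from camera-clock annotation times maps them onto the
    accelerometer clock.
    """
    if accel_clap_idx < 0 or audio_clap_idx < 0:
        raise ValueError("clap indices must be nonnegative")
    if accel_rate_hz <= 0 or audio_rate_fps <= 0:
        raise ValueError("sampling rates must be positive")
    offset = audio_clap_idx / audio_rate_fps - accel_clap_idx / accel_rate_hz
    return ClockOffset(segment_id=segment_id, offset_s=float(offset))
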