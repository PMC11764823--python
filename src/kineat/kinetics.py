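"""Per-sample kinetic variables from raw triaxial acceleration.

A wrist-worn watch reports acceleration on three device axes in milli-G
(1 G = 1000 milli-G, so a resting sensor reads a vector of magnitude
~1000).  From each raw sample four further channels are derived:

``pitch_rad``
    tilt of the gravity vector toward the y axis,
    ``atan2(y, sqrt(x**2 + z**2))``; always in [-pi/2, pi/2] because the
    second argument is nonnegative.
``roll_rad``
    rotation about the y axis, ``atan2(-x, z)``; in (-pi, pi].
``power_mG``
    Euclidean magnitude of the acceleration vector.
``total_energy_mG``
    the magnitude purged of the static 1 G contribution,
    ``sqrt(|power**2 - G**2|)``.  The absolute value keeps sub-1G power
    (possible during free-fall-like phases of a gesture) well defined.

The three raw axes plus these four channels are the seven *kinetic
variables* every downstream stage consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: one Earth gravity, in milli-G.  Fixed exactly; no site-specific correction.
G_MG = 1000.0

#: canonical ordering of the seven kinetic variables (per watch).
KINETIC_VARIABLES = (
    "x_mG",
    "y_mG",
    "z_mG",
    "pitch_rad",
    "roll_rad",
    "power_mG",
    "total_energy_mG",
)

RAW_AXES = ("x_mG", "y_mG", "z_mG")


@dataclass(frozen=True)
class KineticSample:
    """One raw sample augmented with the four derived channels."""

    x_mG: float
    y_mG: float
    z_mG: float
    pitch_rad: float
    roll_rad: float
    power_mG: float
    total_energy_mG: float


def kinetic_sample(x_mG: float, y_mG: float, z_mG: float) -> KineticSample:
    """Derive the kinetic variables for a single raw sample.

    Scalar counterpart of :func:`derive_kinetics`; convenient for
    spot-checks and small fixtures.
    """
    if not np.all(np.isfinite([x_mG, y_mG, z_mG])):
        raise ValueError(
            f"non-finite raw sample ({x_mG!r}, {y_mG!r}, {z_mG!r})"
        )
    pitch = float(np.arctan2(y_mG, np.hypot(x_mG, z_mG)))
    roll = float(np.arctan2(-x_mG, z_mG))
    power = float(np.sqrt(x_mG**2 + y_mG**2 + z_mG**2))
    energy = float(np.sqrt(abs(power**2 - G_MG**2)))
    return KineticSample(x_mG, y_mG, z_mG, pitch, roll, power, energy)


def derive_kinetics(raw: pd.DataFrame) -> pd.DataFrame:
    """Augment a raw sample table with the four derived kinetic channels.

    Parameters
    ----------
    raw
        Table with (at least) finite ``x_mG``, ``y_mG``, ``z_mG`` columns.
        All other columns are passed through unchanged.

    Returns
    -------
    pandas.DataFrame
        Copy of ``raw`` with ``pitch_rad``, ``roll_rad``, ``power_mG``
        and ``total_energy_mG`` appended.

    Raises
    ------
    ValueError
        If any axis value is non-finite; the message reports the first
        offending row position so the corrupt sample can be located.
    """
    for col in RAW_AXES:
        if col not in raw.columns:
            raise ValueError(f"raw sample table lacks column {col!r}")
    x = raw["x_mG"].to_numpy(dtype=float)
    y = raw["y_mG"].to_numpy(dtype=float)
    z = raw["z_mG"].to_numpy(dtype=float)

    bad = ~(np.isfinite(x) & np.isfinite(y) & np.isfinite(z))
    if bad.any():
        pos = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"non-finite acceleration at stream position {pos} "
            f"({bad.sum()} bad samples in total)"
        )

    # atan2(0, 0) -> 0 is the documented convention for the (physically
    # impossible) all-zero sample; count rather than fail.
    zero = (x == 0) & (y == 0) & (z == 0)
    if zero.any():
        logger.warning(
            "%d all-zero samples; pitch/roll set to 0 by convention",
            int(zero.sum()),
        )

    out = raw.copy()
    out["pitch_rad"] = np.arctan2(y, np.hypot(x, z))
    out["roll_rad"] = np.arctan2(-x, z)
    power = np.sqrt(x**2 + y**2 + z**2)
    out["power_mG"] = power
    out["total_energy_mG"] = np.sqrt(np.abs(power**2 - G_MG**2))
    return out
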