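"""Shared fixtures: small synthetic studies generated at test time."""

from __future__ import annotations

import warnings

import pytest

from kineat import simulate_study
from kineat.pipeline import prepare_study

# small-sample forests legitimately trip sklearn's "more classes than
# half the samples" heuristic on tiny fixtures
warnings.filterwarnings(
    "ignore", message=".*unique classes is greater than 50.*", category=UserWarning
)


@pytest.fixture(scope="session")
def tiny_study():
    """4 subjects (both menus), short segments; all 13 foods present."""
    return simulate_study(
        n_subjects=4, effect_size=2.0, duration_per_item_s=20.0, seed=7
    )


@pytest.fixture(scope="session")
def tiny_prepared(tiny_study):
    return prepare_study(tiny_study)
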