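"""Shared fixtures and deterministic hypothesis profile."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def symmetric_params():
    """Noiseless, perfectly symmetric trial with integer-sample strides."""
    from gaitsym.simulate import GaitSimParams

    return GaitSimParams(stride_frequency=1.0, n_strides=8)


@pytest.fixture
def study_params():
    """Study-condition variability (the generator defaults used cohort-wide)."""
    from gaitsym.simulate import GaitSimParams

    return GaitSimParams(stride_frequency=0.9, n_strides=10,
                         asymmetry_alpha=0.2, stride_jitter_cv=0.04,
                         harmonic_jitter_sd=0.35, noise_sd=0.3,
                         tilt_pitch=np.deg2rad(4.0), tilt_roll=np.deg2rad(-3.0))


@pytest.fixture
def small_cohort_table(rng):
    """Balanced integer-friendly cohort table: 3 groups x 3 conditions x 5 subjects."""
    import pandas as pd

    rows = []
    for gi, g in enumerate(["A", "B", "C"]):
        for s in range(5):
            pid = f"{g}{s}"
            base = 90 + 2 * gi + rng.normal(0, 1)
            for ci, c in enumerate(["Slow", "Comfortable", "Fast"]):
                rows.append({"participant_id": pid, "group": g, "condition": c,
                             "si": base + 0.5 * ci + rng.normal(0, 0.5),
                             "normalized_speed": 1.0 + 0.05 * ci + rng.normal(0, 0.02)})
    return pd.DataFrame(rows)
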