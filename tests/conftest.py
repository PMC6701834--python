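"""Shared fixtures: synthetic recordings are generated once per session.

The default study conditions (60 s, 4 channels, 20 kHz, artifact 50x the
largest unit) are expensive to process, so the fixtures that need them are
session-scoped and reused by the acceptance and validation tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from lasercomb import (
    bandpass_300_3000,
    default_config,
    generate_recording,
    run_pipeline,
)

DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def default_recording():
    """Default 60 s / 4 channel / 20 kHz contaminated recording + truth."""
    cfg = default_config(seed=DEFAULT_SEED)
    rec, gt = generate_recording(cfg)
    return cfg, rec, gt


@pytest.fixture(scope="session")
def default_bandpassed(default_recording):
    cfg, rec, _ = default_recording
    return bandpass_300_3000(rec)


@pytest.fixture(scope="session")
def default_sorted(default_recording):
    """Full pipeline output on the default recording."""
    cfg, rec, _ = default_recording
    return run_pipeline(rec, cfg.laser_on_interval, seed=DEFAULT_SEED)

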