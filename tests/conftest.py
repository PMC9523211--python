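"""Shared fixtures: seeded phantom clips and their full analyses.

Full-pipeline runs cost a few seconds each, so clips that several tests
inspect are analysed once per session.
"""

from __future__ import annotations

import numpy as np
import pytest

from epflow.config import RunConfig
from epflow.synthetic import (
    SyntheticSpec,
    WaveSpec,
    default_roi,
    generate_peristalsis_clip,
)
from epflow.waves import run_pipeline


@pytest.fixture(scope="session")
def run_config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def single_wave_case(run_config):
    """One forward (cervix-ward) wave at 20 px/s, plus its analysis."""
    spec = SyntheticSpec(waves=(WaveSpec(start_s=20.0, direction="forward"),), seed=11)
    clip, truth = generate_peristalsis_clip(spec)
    result = run_pipeline(clip, default_roi(spec), run_config, "single")
    return spec, clip, truth, result


@pytest.fixture(scope="session")
def two_wave_case(run_config):
    """Two forward waves, well separated in time."""
    spec = SyntheticSpec(
        waves=(
            WaveSpec(start_s=5.0, direction="forward"),
            WaveSpec(start_s=35.0, direction="forward"),
        ),
        seed=21,
    )
    clip, truth = generate_peristalsis_clip(spec)
    result = run_pipeline(clip, default_roi(spec), run_config, "double")
    return spec, clip, truth, result


@pytest.fixture(scope="session")
def static_case(run_config):
    """Speckle background plus noise only: no peristalsis at all."""
    spec = SyntheticSpec(waves=(), seed=5)
    clip, _ = generate_peristalsis_clip(spec)
    result = run_pipeline(clip, default_roi(spec), run_config, "static")
    return spec, clip, result


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)
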