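import dataclasses

import numpy as np
import pytest

from echoblob.presets import PAPER_PRESET
from echoblob.synth import simulate_cohort_in_memory
from echoblob.types import RoiMask, SubjectScan, UltrasoundFrame

TEST_SIZE = (128, 256)  # rows x cols used throughout the suite


def make_frame(pixels, spacing=(0.4, 0.4), frame_id="test"):
    return UltrasoundFrame(
        pixels=np.asarray(pixels, dtype=np.uint8),
        spacing_axial=spacing[0],
        spacing_lateral=spacing[1],
        frame_id=frame_id,
    )


def full_mask(frame):
    return RoiMask.from_array(np.ones(frame.shape, dtype=bool), frame)


def make_scan(subject_id, group, frames_pixels, spacing=(0.4, 0.4)):
    pairs = []
    for i, px in enumerate(frames_pixels):
        f = make_frame(px, spacing, frame_id=f"{subject_id}_f{i + 1}")
        pairs.append((f, full_mask(f)))
    return SubjectScan(subject_id=subject_id, group=group, frames=pairs)


@pytest.fixture(scope="session")
def paper_preset():
    return PAPER_PRESET


@pytest.fixture(scope="session")
def pure_speckle_healthy(paper_preset):
    """Healthy group params with inclusions switched off."""
    return dataclasses.replace(paper_preset["healthy"], inclusion_rate=0.0)


@pytest.fixture(scope="session")
def small_cohort(paper_preset):
    """A seeded in-memory 6+6 cohort at test scale, shared across tests."""
    return simulate_cohort_in_memory(
        paper_preset["healthy"],
        paper_preset["fm"],
        paper_preset["covariates"],
        n_per_group=6,
        seed=42,
        size=TEST_SIZE,
    )
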