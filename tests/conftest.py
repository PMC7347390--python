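"""Shared fixtures: synthetic models, records and one rendered video.

Everything is generated at test time from seeds; the rendered scene and the
long records are session-scoped because they are the expensive inputs that
several modules' tests share.
"""

from __future__ import annotations

import numpy as np
import pytest

from wormstates.record import AcquisitionConfig
from wormstates.synthetic import (
    SceneSpec,
    default_generator_model,
    generate_behavior_record,
    synthesize_video,
)


@pytest.fixture(scope="session")
def model():
    return default_generator_model()


@pytest.fixture(scope="session")
def ten_min_record(model):
    """10-minute record-level fixture with frequent eggs for detector tests."""
    spec = SceneSpec(duration=600.0, egg_rate_by_state=np.full(9, 2.0))
    return generate_behavior_record(model, spec, seed=5)


@pytest.fixture(scope="session")
def hour_record(model):
    """1-hour record without intensity profiles for the state-discovery tests."""
    spec = SceneSpec(duration=3600.0, intensity_samples=1)
    return generate_behavior_record(model, spec, seed=11)


@pytest.fixture(scope="session")
def video_scene(model, tmp_path_factory):
    """A 20-s rendered scene plus its extracted record (the image pipeline)."""
    from wormstates.pipeline import extract_record
    from wormstates.record import read_frame_sequence

    spec = SceneSpec(
        duration=20.0,
        acquisition=AcquisitionConfig(frame_shape=(768, 768)),
        egg_rate_by_state=np.full(9, 20.0),
    )
    out = tmp_path_factory.mktemp("scene") / "video"
    truth = synthesize_video(model, spec, seed=4, out_dir=out)
    record, stats = extract_record(read_frame_sequence(out), spec.acquisition)
    return {
        "spec": spec,
        "dir": out,
        "truth": truth,
        "record": record,
        "stats": stats,
    }
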