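import numpy as np
import pytest

from nirs_connectome.layout_io import (
    ChannelMap,
    HemoglobinRecording,
    make_default_layout,
)


@pytest.fixture(scope="session")
def layout80() -> ChannelMap:
    return make_default_layout(80)


@pytest.fixture
def tiny_layout() -> ChannelMap:
    """Five channels: two homolog pairs plus one midline channel."""
    return ChannelMap(
        channel_id=np.array([1, 2, 3, 4, 5]),
        source_id=np.array([1, 1, 2, 2, 3]),
        detector_id=np.array([1, 2, 1, 2, 3]),
        position=np.array(
            [
                [-50.0, 0.0, 60.0],
                [-50.0, -40.0, 50.0],
                [50.0, 0.0, 60.0],
                [50.0, -40.0, 50.0],
                [0.0, 80.0, 40.0],
            ]
        ),
        network_label=np.array(
            ["default", "visual", "default", "visual", "frontoparietal"]
        ),
        hemisphere=np.array(["left", "left", "right", "right", "midline"]),
        homolog_id=np.array([3, 4, 1, 2, 0]),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def make_recording(
    data: np.ndarray, fs: float = 17.0, subject_id: str = "s01"
) -> HemoglobinRecording:
    data = np.atleast_2d(np.asarray(data, dtype=float))
    return HemoglobinRecording(
        subject_id=subject_id,
        species="HbO",
        data=data,
        fs=fs,
        channel_ids=np.arange(1, data.shape[0] + 1),
    )
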