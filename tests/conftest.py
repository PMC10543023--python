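import numpy as np
import pandas as pd
import pytest

from nstream.stream_io import ChannelTable, Settings, _normalize_channel_frame


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def simple_table():
    """Three ECoG data channels plus one target channel."""
    frame = pd.DataFrame(
        {
            "name": ["ECOG_0", "ECOG_1", "ECOG_2", "MOV"],
            "type": ["ecog", "ecog", "ecog", "misc"],
            "status": "good",
            "used": 1,
            "target": [0, 0, 0, 1],
            "rereference": ["common_average"] * 3 + ["none"],
        }
    )
    return ChannelTable(_normalize_channel_frame(frame))


@pytest.fixture
def default_settings():
    return Settings(sampling_rate_hz=1000.0)
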