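import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from gazeaoi.core import AOITrack, Region, VideoMeta


@pytest.fixture
def meta() -> VideoMeta:
    """Full-HD 25 fps timeline, one minute long."""
    return VideoMeta(width=1920, height=1080, fps=25.0, n_frames=1500)


@pytest.fixture
def center_box_track(meta) -> AOITrack:
    """A static 400x400 rectangle AOI in the frame center."""
    box = Region.rectangle(760.0, 340.0, 1160.0, 740.0)
    return AOITrack(aoi_name="target", keyframes=((0, box), (meta.n_frames - 1, box)))
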