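import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from spikewell.io import PlateLayout, Recording

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable


@pytest.fixture
def layout() -> PlateLayout:
    return PlateLayout.default_12well()


def make_recording(
    spikes: list[tuple[float, str, str]],
    div: int = 10,
    duration_s: float = 900.0,
    layout: PlateLayout | None = None,
) -> Recording:
    """Recording from (time, well, electrode) triples."""
    layout = layout or PlateLayout.default_12well()
    events = pd.DataFrame(
        spikes, columns=["time_s", "well_id", "electrode_id"]
    ).assign(amplitude_mV=np.nan)
    events = events.sort_values("time_s", kind="mergesort").reset_index(drop=True)
    return Recording(div=div, duration_s=duration_s, events=events, layout=layout)


@pytest.fixture
def recording_builder():
    return make_recording
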