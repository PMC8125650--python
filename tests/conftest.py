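import numpy as np
import pandas as pd
import pytest

from gpsgait.io_gpx import SpeedTrace, TRACE_COLUMNS


def make_trace(speeds, start="2020-09-01T09:00:00Z", lat=47.47, lon=-0.55, session_id="test"):
    """A 1-Hz trace with the given km/h speed vector at a fixed location."""
    speeds = np.asarray(speeds, float)
    n = len(speeds)
    df = pd.DataFrame(
        {
            "time": pd.date_range(start, periods=n, freq="1s"),
            "lat": lat,
            "lon": lon,
            "ele_gps": 50.0,
            "ele_corrected": np.nan,
            "speed_kmh": speeds,
            "source": "raw",
        }
    )[TRACE_COLUMNS]
    return SpeedTrace(df, session_id=session_id)


@pytest.fixture
def trace_factory():
    return make_trace
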