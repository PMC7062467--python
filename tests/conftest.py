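import numpy as np
import pytest

from fictloc.core_signals import TimeSeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def make_ts():
    def _make(values, rate=1000.0, start=0.0, units="a.u.", channel=""):
        return TimeSeries(
            np.asarray(values, dtype=float),
            sampling_rate_hz=rate,
            start_time_s=start,
            units=units,
            channel_id=channel,
        )

    return _make
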