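import numpy as np
import pandas as pd
import pytest

from circfrail import EpochSeries


@pytest.fixture
def make_series():
    """Factory for synthetic epoch series with a 24-h cosine rhythm."""

    def _make(
        days=10,
        mesor=100.0,
        amplitude=50.0,
        acrophase=14.0,
        noise_sd=0.0,
        epoch_seconds=15.0,
        seed=0,
        start="2020-01-06 00:00:00",
        subject_id="test",
    ):
        n = int(round(days * 24 * 3600 / epoch_seconds))
        t = np.arange(n) * epoch_seconds / 3600.0
        rng = np.random.default_rng(seed)
        y = mesor + amplitude * np.cos(2 * np.pi * (t - acrophase) / 24.0)
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, size=n)
        y = np.maximum(y, 0.0)
        return EpochSeries(subject_id, pd.Timestamp(start), epoch_seconds, y)

    return _make


@pytest.fixture
def constant_series():
    n = int(2 * 24 * 3600 / 15)
    return EpochSeries(
        "const", pd.Timestamp("2020-01-06"), 15.0, np.full(n, 5.0)
    )
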