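import numpy as np
import pytest

from spikelight import (
    Alignment,
    Chr2Kinetics,
    Psth,
    Region,
    SortQuality,
    SpikeTrain,
)


@pytest.fixture
def kinetics() -> Chr2Kinetics:
    return Chr2Kinetics()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_train(
    timestamps,
    unit_id="u0",
    region=Region.PUTAMEN,
    quality=SortQuality.SINGLE,
    start=0.0,
    end=None,
    distance=None,
) -> SpikeTrain:
    ts = np.asarray(timestamps, dtype=float)
    if end is None:
        end = (ts[-1] + 1.0) if ts.size else start + 1.0
    return SpikeTrain(
        unit_id=unit_id,
        region=region,
        sort_quality=quality,
        timestamps=ts,
        recording_start=start,
        recording_end=end,
        distance_to_injection=distance,
    )


def make_psth(counts, n_pre, bin_width=8.125, n_trials=50,
              alignment=Alignment.TRAIN_ONSET) -> Psth:
    counts = np.asarray(counts, dtype=int)
    return Psth(
        alignment=alignment,
        bin_width=bin_width,
        n_bins_pre=n_pre,
        n_bins_post=counts.size - n_pre,
        counts=counts,
        n_trials=n_trials,
    )
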