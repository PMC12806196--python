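import numpy as np
import pandas as pd
import pytest

from moltsucc.data_model import CountTable, RelAbundTable, SampleMeta, to_relative


@pytest.fixture
def small_counts() -> CountTable:
    rng = np.random.default_rng(42)
    data = rng.integers(0, 50, size=(10, 20))
    data[:, 0] += 1  # guarantee nonzero rows
    return CountTable(pd.DataFrame(
        data,
        index=[f"s{i}" for i in range(10)],
        columns=[f"ASV{j:03d}" for j in range(20)],
    ))


@pytest.fixture
def small_rel(small_counts) -> RelAbundTable:
    return to_relative(small_counts)


def make_meta(sample_id, habitat="midgut", time_h=0.0, ck=False, **kw):
    return SampleMeta(sample_id=sample_id, habitat=habitat,
                      time_h=None if ck else time_h, is_premolt_ck=ck, **kw)
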