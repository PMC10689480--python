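import numpy as np
import pandas as pd
import pytest

from rangesqueeze.preprocessing import PipelineState


def make_records(rows, state=PipelineState.RAW):
    """Build a species range table from (species, mountain, min, max) tuples."""
    df = pd.DataFrame(rows, columns=["species_id", "mountain_id", "min_elev", "max_elev"])
    df.attrs["pipeline_state"] = state
    return df


def make_bands(mountain_id, lo, hi, **cols):
    """Contiguous 100 m band table over [lo, hi) with constant or per-band values."""
    lowers = np.arange(lo, hi, 100.0)
    df = pd.DataFrame(
        {
            "mountain_id": mountain_id,
            "band_lower": lowers,
            "band_upper": lowers + 100.0,
            "dtr": 10.0,
            "ts": 4.0,
            "mat": 15.0,
            "ap": 1000.0,
        }
    )
    for k, v in cols.items():
        df[k] = v
    return df


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
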