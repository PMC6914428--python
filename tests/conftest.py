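import numpy as np
import pandas as pd
import pytest

from hemibrain.io_core import RegionTable, SubjectRecord


def make_region_table(n_pairs: int, network_of_pair=None) -> RegionTable:
    """Canonical-order mirror-paired table with region_id == row index."""
    rows = []
    for hemi, offset in (("L", 0), ("R", n_pairs)):
        for pair in range(n_pairs):
            net = network_of_pair[pair] if network_of_pair is not None else 0
            rows.append(
                {
                    "region_id": offset + pair,
                    "hemisphere": hemi,
                    "pair_index": pair,
                    "name": f"net{net}_{hemi}{pair}",
                    "included": True,
                }
            )
    return RegionTable(pd.DataFrame(rows))


def make_subject(ts, subject_id="s0", age=30.0, sex=0, mean_fd=0.05):
    return SubjectRecord(
        subject_id=subject_id, age=age, sex=sex, mean_fd=mean_fd, timeseries=ts
    )


@pytest.fixture
def regions4():
    return make_region_table(2)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_symmetric(n, rng, scale=1.0, nonneg=False):
    a = rng.normal(size=(n, n)) * scale
    w = (a + a.T) / 2
    if nonneg:
        w = np.abs(w)
    np.fill_diagonal(w, 0.0)
    return w
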