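import numpy as np
import pandas as pd
import pytest

from tmakb.segment import NucleusSet
from tmakb.simulate import SimImageParams


def make_nucleus_set(p65, relb, dapi=None) -> NucleusSet:
    """Build a NucleusSet directly from per-nucleus mean intensities."""
    p65 = np.asarray(p65, dtype=float)
    relb = np.asarray(relb, dtype=float)
    n = p65.size
    records = pd.DataFrame(
        {
            "nucleus_id": np.arange(1, n + 1),
            "row": np.zeros(n),
            "col": np.zeros(n),
            "area_px": np.full(n, 30),
            "mean_dapi": dapi if dapi is not None else np.full(n, 0.8),
            "mean_relb": relb,
            "mean_p65": p65,
        }
    )
    return NucleusSet(labels=np.zeros((4, 4), dtype=np.int32), records=records)


@pytest.fixture
def fast_image_params():
    """Small, quick-to-render core used across image tests."""
    return SimImageParams(
        image_size=192,
        n_glands=5,
        nuclei_per_gland_range=(12, 18),
        seed=0,
    )
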