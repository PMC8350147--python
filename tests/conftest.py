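import numpy as np
import pandas as pd
import pytest

from placentaging import (
    CohortSpec,
    PhantomSpec,
    UNetSegmenter,
    fit_volume,
    simulate_cohort,
    simulate_multiecho_volume,
)

TE = np.array([13.8, 70.4, 127.0, 183.6])


@pytest.fixture(scope="session")
def cohort90() -> pd.DataFrame:
    """Reference normative cohort: 90 low-risk subjects, all scatter on T2*."""
    return simulate_cohort(CohortSpec(n_low_risk=90, n_high_risk=0, seed=0))


@pytest.fixture(scope="session")
def small_phantom_set():
    """Eight small phantoms (maps + truth masks): six train, two held out."""
    spec = PhantomSpec(grid_shape=(48, 48, 4), snr=50.0)
    cohort = simulate_cohort(CohortSpec(n_low_risk=8, n_high_risk=0, seed=12))
    maps, masks = [], []
    for i, row in cohort.iterrows():
        vol, mask = simulate_multiecho_volume(row, spec, seed=500 + i)
        maps.append(fit_volume(vol).t2s)
        masks.append(mask)
    return maps, masks


@pytest.fixture(scope="session")
def trained_segmenter(small_phantom_set):
    """U-net trained on the first six phantoms (32x32 patches, CPU scale)."""
    maps, masks = small_phantom_set
    seg = UNetSegmenter(patch_size=32, base_filters=8, n_iterations=300, seed=0)
    seg.fit(maps[:6], masks[:6])
    return seg
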