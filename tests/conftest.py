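import numpy as np
import pandas as pd
import pytest

from cfirs import CohortParams, generate_cohort, select_indicators
from cfirs.filtration import INDICATOR_COLUMNS, IndicatorSet


def make_indicators(lo, hi, direction, **stats) -> IndicatorSet:
    """Construct a minimal valid IndicatorSet from bounds and directions.

    Group min/max default to the pooled bounds; unspecified diagnostics are
    filled with placeholders.
    """
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    direction = np.asarray(direction, dtype=int)
    n = lo.size
    table = pd.DataFrame(
        {
            "overlap": stats.get("overlap", np.full(n, 0.5)),
            "smd": stats.get("smd", np.full(n, 1.0)),
            "p_raw": stats.get("p_raw", np.full(n, 0.001)),
            "p_adj": stats.get("p_adj", np.full(n, 0.01)),
            "direction": direction,
            "min_sp": stats.get("min_sp", lo),
            "max_sp": stats.get("max_sp", hi),
            "mean_sp": stats.get("mean_sp", np.where(direction == 1, hi, lo)),
            "min_sn": stats.get("min_sn", lo),
            "max_sn": stats.get("max_sn", hi),
            "mean_sn": stats.get("mean_sn", np.where(direction == 1, lo, hi)),
            "lo": lo,
            "hi": hi,
        },
        index=pd.Index([f"cfRNA_{i:04d}" for i in range(n)], name="feature_id"),
    )
    return IndicatorSet(table[INDICATOR_COLUMNS])


@pytest.fixture(scope="session")
def small_cohort():
    """500-feature cohort with a strong planted effect, plus its truth."""
    params = CohortParams(
        n_features=500, frac_informative=0.05, effect_size=2.5, seed=3
    )
    return generate_cohort(params)


@pytest.fixture(scope="session")
def small_indicators(small_cohort):
    np_m, pe_m, _ = small_cohort
    return select_indicators(np_m, pe_m)


@pytest.fixture
def toy_indicators():
    """Five-indicator set with mixed directions and assorted ranges."""
    return make_indicators(
        lo=[0.0, 1.0, 2.0, 0.5, 10.0],
        hi=[1.0, 3.0, 7.0, 2.5, 30.0],
        direction=[1, -1, 1, -1, 1],
    )
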