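from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest


def make_weather(
    n_days: int,
    start=date(2022, 5, 1),
    tmax=25.0,
    tmin=15.0,
    rainfall=0.0,
    irrigation=0.0,
    etp=0.0,
    **extra,
):
    """Constant daily weather frame, any column overridable with arrays."""
    def col(v):
        a = np.asarray(v, dtype=float)
        return np.full(n_days, a, dtype=float) if a.ndim == 0 else a

    base = {
        "date": [start + timedelta(days=i) for i in range(n_days)],
        "tmin": col(tmin),
        "tmax": col(tmax),
        "rainfall": col(rainfall),
        "irrigation": col(irrigation),
        "etp": col(etp),
    }
    for k, v in extra.items():
        base[k] = col(v)
    return pd.DataFrame(base)


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)
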