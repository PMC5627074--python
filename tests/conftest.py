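import numpy as np
import pandas as pd
import pytest

from hemimeth.methcall import add_levels, call_methylated, filter_units
from hemimeth.simdata import ErrorModel, simulate_methylome_counts


@pytest.fixture
def err_free():
    return ErrorModel(epsilon=0.0, delta=0.0)


@pytest.fixture
def err_default():
    return ErrorModel(epsilon=0.01, delta=0.0)


@pytest.fixture
def symmetric_units():
    """Factory: symmetric methylome unit table, called and filtered."""

    def make(n_sites=2000, coverage=30.0, seed=11, p_low=0.6, p_high=0.95):
        rng = np.random.default_rng(seed)
        pos = np.sort(rng.choice(np.arange(1, 400 * n_sites), size=n_sites, replace=False))
        p = rng.uniform(p_low, p_high, n_sites)
        units = simulate_methylome_counts(
            "chr1", pos, p, p, coverage, ErrorModel(), seed
        )
        units = filter_units(add_levels(units))
        return call_methylated(units)

    return make


def unit_row(M_plus, U_plus, M_minus, U_minus, chrom="chr1", pos=100):
    return pd.DataFrame(
        [
            {
                "chrom": chrom,
                "pos": pos,
                "M_plus": M_plus,
                "U_plus": U_plus,
                "M_minus": M_minus,
                "U_minus": U_minus,
            }
        ]
    )
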