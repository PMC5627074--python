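"""Empirical false-positive estimation by strand-shuffling reads.

At each CpG unit the pooled methylated/unmethylated read labels are
randomly re-dealt to the two strands while preserving each strand's
coverage exactly (a hypergeometric draw), erasing any true strand signal
but keeping the coverage structure — and hence filter and test power —
identical to the observed data. Repeating the site and region scans on
many such shuffled methylomes yields the expected count of false
asymmetry calls under the no-asymmetry null.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .methcall import add_levels
from .region_asym import region_scan
from .site_asym import flag_asymmetric_sites

__all__ = ["shuffle_unit", "shuffle_units", "false_positive_scan"]


def shuffle_units(
    units: pd.DataFrame, rng: np.random.Generator, mode: str = "hypergeometric"
) -> pd.DataFrame:
    """Strand-shuffle every unit's read labels; coverage per strand conserved.

    ``mode='hypergeometric'`` (default) deals the pooled M/U labels to the
    strands without replacement, so each strand keeps its exact coverage.
    ``mode='bernoulli'`` assigns every read to the plus strand
    independently with probability cov+/(cov+ + cov-); per-strand coverage
    is then only conserved in expectation.
    """
    units = units.copy()
    m_tot = (units["M_plus"] + units["M_minus"]).to_numpy(np.int64)
    u_tot = (units["U_plus"] + units["U_minus"]).to_numpy(np.int64)
    cov_p = (units["M_plus"] + units["U_plus"]).to_numpy(np.int64)
    if mode == "hypergeometric":
        m_p = rng.hypergeometric(m_tot, u_tot, cov_p)
        u_p = cov_p - m_p
    elif mode == "bernoulli":
        frac = cov_p / np.maximum(m_tot + u_tot, 1)
        m_p = rng.binomial(m_tot, frac)
        u_p = rng.binomial(u_tot, frac)
    else:
        raise ValueError(f"unknown shuffle mode: {mode!r}")
    units["M_plus"] = m_p
    units["U_plus"] = u_p
    units["M_minus"] = m_tot - m_p
    units["U_minus"] = u_tot - u_p
    return add_levels(units)


def shuffle_unit(unit, rng: np.random.Generator):
    """Shuffle a single unit (row-like with M_plus..U_minus); returns a Series."""
    df = pd.DataFrame(
        [
            {
                "M_plus": unit.M_plus,
                "U_plus": unit.U_plus,
                "M_minus": unit.M_minus,
                "U_minus": unit.U_minus,
            }
        ]
    )
    return shuffle_units(df, rng).iloc[0]


def false_positive_scan(
    units: pd.DataFrame,
    n_shuffles: int = 100,
    site_alpha: float = 0.05,
    region_params: dict | None = None,
    seed: int = 0,
    mode: str = "hypergeometric",
    scan_regions: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Re-run the site (and optionally region) scans on shuffled methylomes.

    ``units`` must already carry methylation calls; calls depend only on
    pooled counts, which shuffling conserves, so they are not recomputed.
    Each shuffle replicate draws from its own stream derived from
    ``(seed, replicate index)``.

    Returns (per-shuffle table with flagged site/region counts, summary
    dict with the number of shuffled datasets containing at least one
    flagged site/region and the totals across shuffles).
    """
    region_params = region_params or {}
    rows = []
    for rep in range(n_shuffles):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), rep]))
        shuffled = shuffle_units(units, rng, mode=mode)
        flagged = flag_asymmetric_sites(shuffled, alpha=site_alpha)
        n_sites = int(flagged["asymmetric"].sum())
        if scan_regions:
            _, regions = region_scan(flagged, **region_params)
            n_regions = len(regions)
        else:
            n_regions = 0
        rows.append({"shuffle": rep, "n_flagged_sites": n_sites, "n_flagged_regions": n_regions})
    per_shuffle = pd.DataFrame(rows)
    summary = {
        "n_shuffles": n_shuffles,
        "shuffles_with_sites": int((per_shuffle["n_flagged_sites"] > 0).sum()),
        "shuffles_with_regions": int((per_shuffle["n_flagged_regions"] > 0).sum()),
        "total_flagged_sites": int(per_shuffle["n_flagged_sites"].sum()),
        "total_flagged_regions": int(per_shuffle["n_flagged_regions"].sum()),
    }
    return per_shuffle, summary
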