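"""Strand-split methylation levels, binomial methylation calls, coverage filters.

A *CpG unit* is the dinucleotide treated as one locus with a cytosine on
each strand. Unit tables are pandas DataFrames with columns
``chrom, pos, M_plus, U_plus, M_minus, U_minus`` plus derived columns
(``b_plus, b_minus, delta_b, p_meth, q_meth, called_methylated``) added by
the operations below; a :class:`CpGUnit` dataclass mirrors one row.

The methylation level at a site-strand is ``b = M / (M + U)``. A unit is
called methylated when the pooled count of methylated reads across both
strands exceeds what the bisulfite non-conversion rate ``epsilon`` explains
(one-sided binomial test, BH-corrected): non-conversion is a floor on the
observed methylated fraction, not a two-sided null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CpGUnit",
    "methylation_level",
    "corrected_level",
    "units_from_calls",
    "add_levels",
    "call_methylated",
    "filter_units",
    "strand_correlation",
]


class UndefinedLevelError(ValueError):
    """Level requested at a site-strand with zero coverage."""


class UndefinedCorrelationError(ValueError):
    """Correlation requested with zero variance on a strand."""


@dataclass
class CpGUnit:
    chrom: str
    pos: int
    M_plus: int = 0
    U_plus: int = 0
    M_minus: int = 0
    U_minus: int = 0
    b_plus: float = np.nan
    b_minus: float = np.nan
    delta_b: float = np.nan
    called_methylated: bool = False
    q_meth: float = np.nan
    fisher_p: float = np.nan
    fisher_q: float = np.nan


def methylation_level(M: int, U: int) -> float:
    """b = M / (M + U); errors on zero coverage (filter such units first)."""
    if M < 0 or U < 0:
        raise ValueError("negative counts")
    if M + U == 0:
        raise UndefinedLevelError("methylation level undefined at zero coverage")
    return M / (M + U)


def corrected_level(b, epsilon: float = 0.01):
    """Non-conversion-corrected level: max(0, (b - eps) / (1 - eps)).

    Applied explicitly (amplicon workflows), never silently.
    """
    return np.maximum(0.0, (np.asarray(b, dtype=float) - epsilon) / (1.0 - epsilon))


def units_from_calls(calls: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a read-call frame into a unit-count table with levels."""
    if calls.empty:
        return add_levels(
            pd.DataFrame(columns=["chrom", "pos", "M_plus", "U_plus", "M_minus", "U_minus"])
        )
    counts = (
        calls.assign(meth=(calls["state"] == "M").astype(int))
        .groupby(["locus", "cpg_pos", "strand"])["meth"]
        .agg(M="sum", total="count")
        .reset_index()
    )
    counts["U"] = counts["total"] - counts["M"]
    wide = counts.pivot_table(
        index=["locus", "cpg_pos"], columns="strand", values=["M", "U"], fill_value=0
    )
    units = pd.DataFrame(
        {
            "M_plus": wide.get(("M", "plus"), 0),
            "U_plus": wide.get(("U", "plus"), 0),
            "M_minus": wide.get(("M", "minus"), 0),
            "U_minus": wide.get(("U", "minus"), 0),
        }
    ).reset_index()
    units = units.rename(columns={"locus": "chrom", "cpg_pos": "pos"})
    units = units.astype({c: int for c in ["M_plus", "U_plus", "M_minus", "U_minus"]})
    return add_levels(units.sort_values(["chrom", "pos"], ignore_index=True))


def add_levels(units: pd.DataFrame) -> pd.DataFrame:
    """Attach b_plus, b_minus (NaN at zero coverage) and delta_b = b+ - b-."""
    units = units.copy()
    for s in ("plus", "minus"):
        tot = units[f"M_{s}"] + units[f"U_{s}"]
        with np.errstate(invalid="ignore", divide="ignore"):
            units[f"b_{s}"] = np.where(tot > 0, units[f"M_{s}"] / tot.replace(0, np.nan), np.nan)
    units["delta_b"] = units["b_plus"] - units["b_minus"]
    return units


def call_methylated(
    units: pd.DataFrame, epsilon: float = 0.01, alpha: float = 0.05
) -> pd.DataFrame:
    """One-sided binomial methylation call on pooled strand counts, BH-adjusted.

    p = P[Binomial(M_tot + U_tot, epsilon) >= M_tot]; a unit is
    ``called_methylated`` when its BH q-value is below ``alpha``.
    """
    if not (0.0 < epsilon < 0.5):
        raise ValueError(f"epsilon must be in (0, 0.5): {epsilon}")
    units = units.copy()
    if units.empty:
        units["p_meth"] = pd.Series(dtype=float)
        units["q_meth"] = pd.Series(dtype=float)
        units["called_methylated"] = pd.Series(dtype=bool)
        return units
    m_tot = (units["M_plus"] + units["M_minus"]).to_numpy()
    n_tot = m_tot + (units["U_plus"] + units["U_minus"]).to_numpy()
    # upper tail P(X >= m) = sf(m - 1)
    p = stats.binom.sf(m_tot - 1, n_tot, epsilon)
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    units["p_meth"] = p
    units["q_meth"] = q
    units["called_methylated"] = q < alpha
    return units


def filter_units(
    units: pd.DataFrame,
    min_per_strand: int = 10,
    coverage_quantile: float = 0.95,
) -> pd.DataFrame:
    """Coverage filter: >= min reads on *each* strand, total <= the empirical
    coverage quantile.

    The quantile (linear interpolation) is computed over unit totals among
    units that already pass the per-strand minimum; ties at the cut are
    retained (only coverage strictly *above* the quantile is excluded).
    The realised cut is recorded in ``result.attrs['coverage_cut']`` and
    reused when refiltering an already-filtered table — the empirical cut
    belongs to the dataset it was estimated from, which makes the filter
    idempotent instead of repeatedly shaving the top tail.
    """
    if units.empty:
        return units.copy()
    cov_p = units["M_plus"] + units["U_plus"]
    cov_m = units["M_minus"] + units["U_minus"]
    keep = (cov_p >= min_per_strand) & (cov_m >= min_per_strand)
    passed = units[keep]
    if passed.empty:
        return passed.reset_index(drop=True)
    totals = (cov_p + cov_m)[keep]
    cut = units.attrs.get("coverage_cut")
    if cut is None:
        cut = float(totals.quantile(coverage_quantile, interpolation="linear"))
    out = passed[totals <= cut].reset_index(drop=True)
    out.attrs["coverage_cut"] = cut
    return out


def strand_correlation(units: pd.DataFrame) -> float:
    """Squared Pearson correlation of (b_plus, b_minus) over covered units."""
    sub = units.dropna(subset=["b_plus", "b_minus"])
    if len(sub) < 2:
        raise UndefinedCorrelationError("need >= 2 units with both strands covered")
    x = sub["b_plus"].to_numpy()
    y = sub["b_minus"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance on a strand")
    r, _ = stats.pearsonr(x, y)
    return float(r**2)
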