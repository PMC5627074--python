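"""Sliding-window detection of asymmetrically methylated regions.

Fixed-width genomic windows (default 1800 bp, advanced by a configurable
step) are testable when they contain at least ``min_meth_cpgs``
methylation-called CpG units covered on both strands. Within a testable
window a paired t-test compares per-CpG methylation levels between strands
(pairing is per CpG across strands, not per read); BH correction runs
across tested windows and overlapping flagged windows merge into maximal
regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["Window", "make_windows", "paired_t_window", "evaluate_windows", "flag_regions", "region_scan"]

#: Underflow-safe minimum p-value reported when the difference variance is
#: exactly zero but the mean difference is not.
P_UNDERFLOW = float(np.finfo(float).tiny)


@dataclass
class Window:
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive; end - start + 1 == window size
    b_plus: np.ndarray = field(default_factory=lambda: np.empty(0))
    b_minus: np.ndarray = field(default_factory=lambda: np.empty(0))
    t_stat: float = np.nan
    p: float = np.nan
    q: float = np.nan

    @property
    def n_members(self) -> int:
        return len(self.b_plus)


def _member_units(units: pd.DataFrame) -> pd.DataFrame:
    covered = (units["M_plus"] + units["U_plus"] > 0) & (
        units["M_minus"] + units["U_minus"] > 0
    )
    called = units.get("called_methylated")
    if called is None:
        raise ValueError("units must carry methylation calls (call_methylated first)")
    members = units[covered & called.fillna(False).astype(bool)]
    return members.sort_values(["chrom", "pos"], ignore_index=True)


def make_windows(
    units: pd.DataFrame,
    window_size: int = 1800,
    min_meth_cpgs: int = 8,
    step: int = 300,
) -> list[Window]:
    """Tile fixed-width windows over each chromosome and collect members.

    Only windows meeting the member minimum are returned (testable
    windows). Windows tile genomic coordinates: the start grid runs from
    just before the first member CpG to the last, advanced by ``step``.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    if window_size <= 0:
        raise ValueError("window_size must be > 0")
    members = _member_units(units)
    windows: list[Window] = []
    for chrom, sub in members.groupby("chrom", sort=True):
        pos = sub["pos"].to_numpy()
        bp = sub["b_plus"].to_numpy()
        bm = sub["b_minus"].to_numpy()
        first = max(1, int(pos[0]) - window_size + 1)
        starts = np.arange(first, int(pos[-1]) + 1, step)
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, starts + window_size - 1, side="right")
        for s, l, h in zip(starts, lo, hi):
            if h - l >= min_meth_cpgs:
                windows.append(
                    Window(
                        chrom=str(chrom),
                        start=int(s),
                        end=int(s + window_size - 1),
                        b_plus=bp[l:h],
                        b_minus=bm[l:h],
                    )
                )
    return windows


def paired_t_window(window: Window) -> tuple[float, float]:
    """Paired t-test on per-CpG strand differences within one window.

    Returns (t, two-sided p) with df = n - 1. Degenerate variance: all
    differences exactly zero gives (0, 1); zero variance with nonzero mean
    gives a signed infinite t and the underflow-safe minimum p.
    """
    d = np.asarray(window.b_plus, dtype=float) - np.asarray(window.b_minus, dtype=float)
    n = len(d)
    if n < 2:
        raise ValueError("paired t-test needs >= 2 member CpGs")
    mean = d.mean()
    sd = d.std(ddof=1)
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, 1.0
        return float(np.sign(mean) * np.inf), P_UNDERFLOW
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(max(p, P_UNDERFLOW))


def evaluate_windows(windows: list[Window]) -> pd.DataFrame:
    """Run the paired test on every window; return a tidy window table."""
    rows = []
    for w in windows:
        w.t_stat, w.p = paired_t_window(w)
        rows.append(
            {
                "chrom": w.chrom,
                "start": w.start,
                "end": w.end,
                "n_members": w.n_members,
                "mean_delta_b": float(np.mean(w.b_plus - w.b_minus)),
                "t_stat": w.t_stat,
                "p": w.p,
            }
        )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_members", "mean_delta_b", "t_stat", "p"]
    )


def flag_regions(window_table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """BH across tested windows; merge overlapping flagged windows.

    Returns maximal merged regions (chrom, start, end, n_windows, min_q).
    Idempotent and independent of window order.
    """
    if window_table.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_windows", "min_q"])
    wt = window_table.copy()
    _, q, _, _ = multipletests(wt["p"].to_numpy(), alpha=alpha, method="fdr_bh")
    wt["q"] = q
    flagged = wt[wt["q"] < alpha].sort_values(["chrom", "start"])
    regions = []
    for chrom, sub in flagged.groupby("chrom", sort=True):
        cur_start = cur_end = None
        nwin = 0
        minq = np.inf
        for row in sub.itertuples(index=False):
            if cur_start is None:
                cur_start, cur_end, nwin, minq = row.start, row.end, 1, row.q
            elif row.start <= cur_end:  # 1-based inclusive overlap
                cur_end = max(cur_end, row.end)
                nwin += 1
                minq = min(minq, row.q)
            else:
                regions.append((chrom, cur_start, cur_end, nwin, minq))
                cur_start, cur_end, nwin, minq = row.start, row.end, 1, row.q
        if cur_start is not None:
            regions.append((chrom, cur_start, cur_end, nwin, minq))
    return pd.DataFrame(regions, columns=["chrom", "start", "end", "n_windows", "min_q"])


def region_profile(units: pd.DataFrame, region) -> pd.DataFrame:
    """Per-CpG strand-difference profile inside one region."""
    inside = (
        (units["chrom"] == region.chrom)
        & (units["pos"] >= region.start)
        & (units["pos"] <= region.end)
    )
    return units.loc[inside, ["chrom", "pos", "b_plus", "b_minus", "delta_b"]].reset_index(
        drop=True
    )


def region_scan(
    units: pd.DataFrame,
    window_size: int = 1800,
    min_meth_cpgs: int = 8,
    step: int = 300,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full window scan: (tested window table with q, merged flagged regions)."""
    windows = make_windows(units, window_size, min_meth_cpgs, step)
    wt = evaluate_windows(windows)
    regions = flag_regions(wt, alpha)
    if not wt.empty:
        _, q, _, _ = multipletests(wt["p"].to_numpy(), alpha=alpha, method="fdr_bh")
        wt["q"] = q
    else:
        wt["q"] = pd.Series(dtype=float)
    return wt, regions
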