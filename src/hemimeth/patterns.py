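"""Methylation-pattern (epiallele) extraction and error-corrected frequency
estimation.

A *pattern* is the binary methylation string of one read across the ordered
reference CpGs of a locus (1 = methylated). Pattern extraction enforces the
amplicon filter contract: reads carrying calls at non-reference positions
(phantom CpGs) or not covering every reference CpG (truncated) are
discarded, so surviving patterns are equal-length strings over the same CpG
index; patterns below an abundance floor (default 1% of the sample-strand
coverage) are then removed.

True pattern frequencies per strand are recovered from observed pattern
counts by maximum likelihood under a per-site error channel
(non-conversion ``epsilon`` inflates observed methylation, inappropriate
conversion ``delta`` deflates it), fitted by EM over the observed pattern
support. Uncertainty in per-pattern strand differences comes from
resampling reads with replacement within each sample-strand stratum.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simdata import ErrorModel

__all__ = [
    "PatternTable",
    "PatternFreqEstimate",
    "extract_patterns",
    "count_possible_patterns",
    "estimate_frequencies_em",
    "strand_difference_bootstrap",
]

COUNT_COLUMNS = ["sample", "replicate", "group", "strand", "pattern", "count"]


class PatternError(ValueError):
    pass


@dataclass
class PatternTable:
    """Pattern counts per sample x strand for one locus."""

    locus_id: str
    cpg_positions: tuple[int, ...]
    counts: pd.DataFrame  # COUNT_COLUMNS

    def coverage(self) -> pd.DataFrame:
        """Total reads per (sample, strand)."""
        return (
            self.counts.groupby(["sample", "strand"], as_index=False)["count"]
            .sum()
            .rename(columns={"count": "coverage"})
        )

    def to_tsv(self, path) -> None:
        self.counts.assign(locus=self.locus_id).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, cpg_positions: tuple[int, ...]) -> "PatternTable":
        df = pd.read_csv(path, sep="\t", dtype={"pattern": str})
        locus = str(df["locus"].iloc[0]) if "locus" in df.columns and len(df) else "NA"
        return cls(locus, tuple(cpg_positions), df[COUNT_COLUMNS])


@dataclass
class PatternFreqEstimate:
    """Error-corrected pattern frequencies per (sample, strand)."""

    locus_id: str
    freqs: pd.DataFrame  # sample, strand, pattern, freq
    loglik: dict[tuple[str, str], float] = field(default_factory=dict)
    converged: dict[tuple[str, str], bool] = field(default_factory=dict)
    n_iter: dict[tuple[str, str], int] = field(default_factory=dict)

    def frequencies(self, sample: str, strand: str) -> dict[str, float]:
        sub = self.freqs[(self.freqs["sample"] == sample) & (self.freqs["strand"] == strand)]
        return dict(zip(sub["pattern"], sub["freq"]))


def count_possible_patterns(n_cpgs: int) -> int:
    """Number of possible methylation patterns over n CpGs: 2**n, exact."""
    if n_cpgs < 0:
        raise PatternError("n_cpgs must be >= 0")
    return 2**int(n_cpgs)


def extract_patterns(
    calls: pd.DataFrame,
    reference_cpgs,
    min_frac: float = 0.01,
    locus_id: str | None = None,
) -> PatternTable:
    """Collapse per-read calls into filtered pattern counts.

    Filter order: phantom-site reads out, truncated reads out, then the
    abundance floor (pattern count < ``min_frac`` x sample-strand coverage
    after the first two filters).
    """
    ref = tuple(sorted(int(p) for p in reference_cpgs))
    if not ref:
        raise PatternError("reference CpG set is empty")
    refset = set(ref)
    if locus_id is not None:
        calls = calls[calls["locus"] == locus_id]
    elif not calls.empty:
        loci = calls["locus"].unique()
        if len(loci) > 1:
            raise PatternError(f"calls span multiple loci {list(loci)}; pass locus_id")
        locus_id = str(loci[0])
    locus_id = locus_id or "NA"
    if calls.empty:
        return PatternTable(locus_id, ref, pd.DataFrame(columns=COUNT_COLUMNS))

    key = ["sample", "replicate", "group", "strand", "read_id"]
    phantom = calls.groupby(key)["cpg_pos"].transform(lambda s: (~s.isin(refset)).any())
    kept = calls[~phantom]
    # truncated: must cover every reference CpG exactly once
    cover = kept.groupby(key)["cpg_pos"].nunique()
    full_reads = cover[cover == len(ref)].index
    kept = kept.set_index(key).loc[kept.set_index(key).index.isin(full_reads)].reset_index()
    if kept.empty:
        return PatternTable(locus_id, ref, pd.DataFrame(columns=COUNT_COLUMNS))

    order = {p: i for i, p in enumerate(ref)}
    kept = kept.assign(
        _idx=kept["cpg_pos"].map(order), _bit=(kept["state"] == "M").astype(str)
    ).sort_values(key + ["_idx"])
    patterns = (
        kept.replace({"_bit": {"True": "1", "False": "0"}})
        .groupby(key)["_bit"]
        .agg("".join)
        .rename("pattern")
        .reset_index()
    )
    counts = (
        patterns.groupby(["sample", "replicate", "group", "strand", "pattern"])
        .size()
        .rename("count")
        .reset_index()
    )
    totals = counts.groupby(["sample", "strand"])["count"].transform("sum")
    counts = counts[counts["count"] >= min_frac * totals].reset_index(drop=True)
    return PatternTable(locus_id, ref, counts[COUNT_COLUMNS])


def _pattern_matrix(patterns: list[str]) -> np.ndarray:
    return np.array([[int(c) for c in p] for p in patterns], dtype=np.int8)


def _channel_matrix(obs: np.ndarray, true: np.ndarray, err: ErrorModel) -> np.ndarray:
    """A[o, t] = P(observed pattern o | true pattern t) under the error channel."""
    o = obs[:, None, :].astype(bool)
    t = true[None, :, :].astype(bool)
    n11 = (o & t).sum(axis=2)
    n01 = (o & ~t).sum(axis=2)  # observed methylated, truly not: epsilon
    n10 = (~o & t).sum(axis=2)  # observed unmethylated, truly methylated: delta
    n00 = (~o & ~t).sum(axis=2)
    eps, dlt = err.epsilon, err.delta
    with np.errstate(divide="ignore"):
        logA = (
            n11 * np.log(1.0 - dlt)
            + np.where(n10 > 0, n10 * np.log(dlt if dlt > 0 else 1.0), 0.0)
            + np.where(n01 > 0, n01 * np.log(eps if eps > 0 else 1.0), 0.0)
            + n00 * np.log(1.0 - eps)
        )
    A = np.exp(logA)
    A[(n10 > 0) & (dlt == 0)] = 0.0
    A[(n01 > 0) & (eps == 0)] = 0.0
    return A


def _em_stratum(
    patterns: list[str], counts: np.ndarray, err: ErrorModel, tol: float, max_iter: int
) -> tuple[np.ndarray, float, bool, int]:
    """EM over the observed support; returns (freqs, loglik, converged, iters)."""
    mat = _pattern_matrix(patterns)
    A = _channel_matrix(mat, mat, err)  # observed x true
    n = counts.astype(float)
    N = n.sum()
    f = n / N  # start at observed proportions
    prev_ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mix = A @ f  # P(observe o) per observed pattern
        if (mix <= 0).any():
            # an observed pattern with zero likelihood under current f:
            # reseed uniformly (can only happen with degenerate channels)
            f = np.full_like(f, 1.0 / len(f))
            mix = A @ f
        ll = float(n @ np.log(mix))
        if ll < prev_ll - 1e-9:
            raise PatternError(f"EM log-likelihood decreased: {prev_ll} -> {ll}")
        prev_ll = ll
        resp = (A * f[None, :]) / mix[:, None]  # responsibilities
        f_new = (n @ resp) / N
        f_new = f_new / f_new.sum()
        if np.max(np.abs(f_new - f)) < tol:
            f = f_new
            converged = True
            break
        f = f_new
    mix = A @ f
    ll = float(n @ np.log(np.maximum(mix, np.finfo(float).tiny)))
    return f, ll, converged, it


def estimate_frequencies_em(
    table: PatternTable,
    err: ErrorModel | None = None,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> PatternFreqEstimate:
    """Maximum-likelihood pattern frequencies per (sample, strand) by EM.

    The support is the observed (post-filter) pattern set of each stratum;
    frequencies are renormalised on that support every step and the
    log-likelihood is checked to be non-decreasing at every iteration.
    Non-convergence at ``max_iter`` is flagged, with the last iterate kept.
    """
    err = err or ErrorModel()
    rows, ll_map, conv_map, iter_map = [], {}, {}, {}
    for (sample, strand), sub in table.counts.groupby(["sample", "strand"]):
        pats = list(sub["pattern"])
        cnts = sub["count"].to_numpy()
        if cnts.sum() == 0:
            raise PatternError(f"stratum ({sample},{strand}) has zero reads")
        f, ll, conv, its = _em_stratum(pats, cnts, err, tol, max_iter)
        ll_map[(sample, strand)] = ll
        conv_map[(sample, strand)] = conv
        iter_map[(sample, strand)] = its
        for p, fv in zip(pats, f):
            rows.append({"sample": sample, "strand": strand, "pattern": p, "freq": float(fv)})
    freqs = pd.DataFrame(rows, columns=["sample", "strand", "pattern", "freq"])
    return PatternFreqEstimate(table.locus_id, freqs, ll_map, conv_map, iter_map)


def strand_difference_bootstrap(
    table: PatternTable,
    err: ErrorModel | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    ci: float = 0.95,
) -> pd.DataFrame:
    """Percentile CIs for per-pattern strand frequency differences.

    Reads are resampled with replacement within each (sample, strand)
    stratum; frequencies are re-estimated by EM on each resample; the CI
    is the percentile interval of (freq_plus - freq_minus) per pattern.
    Patterns absent from a strand's support contribute frequency 0 there.
    """
    err = err or ErrorModel()
    lo_q, hi_q = 100 * (1 - ci) / 2, 100 * (1 + ci) / 2
    out = []
    for sample, sub in table.counts.groupby("sample"):
        strata: dict[str, tuple[list[str], np.ndarray]] = {}
        for strand in ("plus", "minus"):
            ssub = sub[sub["strand"] == strand]
            if ssub["count"].sum() == 0 or ssub.empty:
                raise PatternError(f"stratum ({sample},{strand}) has zero reads")
            strata[strand] = (list(ssub["pattern"]), ssub["count"].to_numpy())
        support = sorted(set(strata["plus"][0]) | set(strata["minus"][0]))

        def freqs_of(counts_by_strand) -> dict[str, np.ndarray]:
            res = {}
            for strand, (pats, cnts) in counts_by_strand.items():
                keep = cnts > 0
                pats_k = [p for p, k in zip(pats, keep) if k]
                f, _, _, _ = _em_stratum(pats_k, cnts[keep], err, 1e-8, 10_000)
                fmap = dict(zip(pats_k, f))
                res[strand] = np.array([fmap.get(p, 0.0) for p in support])
            return res

        point = freqs_of(strata)
        point_diff = point["plus"] - point["minus"]
        rng = np.random.default_rng(
            np.random.SeedSequence([int(seed), zlib.crc32(str(sample).encode())])
        )
        diffs = np.empty((n_boot, len(support)))
        for b in range(n_boot):
            resampled = {}
            for strand, (pats, cnts) in strata.items():
                n = int(cnts.sum())
                resampled[strand] = (pats, rng.multinomial(n, cnts / cnts.sum()))
            fb = freqs_of(resampled)
            diffs[b] = fb["plus"] - fb["minus"]
        lo = np.percentile(diffs, lo_q, axis=0)
        hi = np.percentile(diffs, hi_q, axis=0)
        for i, p in enumerate(support):
            out.append(
                {
                    "sample": sample,
                    "pattern": p,
                    "diff": float(point_diff[i]),
                    "ci_low": float(lo[i]),
                    "ci_high": float(hi[i]),
                }
            )
    return pd.DataFrame(out, columns=["sample", "pattern", "diff", "ci_low", "ci_high"])
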