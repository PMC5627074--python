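"""Synthetic bisulfite methylation-call generator with known ground truth.

Two modes mirror the two arms of a strand-asymmetry study:

* **site mode** — genome-wide CpG units with independent per-strand
  methylation probabilities and Poisson-distributed read coverage, for
  testing site- and region-level asymmetry detection;
* **amplicon mode** — deep fixed-depth loci where each double-stranded DNA
  fragment carries a *pair* of methylation patterns (top strand, bottom
  strand) drawn from a joint distribution, so hemimethylation exists at the
  fragment level even when strand-averaged levels are symmetric.

Observed calls pass through a two-parameter error channel: an unmethylated
cytosine survives bisulfite conversion (and reads as methylated) with
probability ``epsilon`` (non-conversion, ~1% in practice), and a methylated
cytosine is inappropriately converted with probability ``delta`` (0 by
default).

Randomness is reproducible per locus: each locus draws from a stream derived
from ``(seed, locus_id)``, so individual loci can be regenerated without
replaying the whole simulation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ErrorModel",
    "SimSiteSpec",
    "SimLocusSpec",
    "ReadCall",
    "READ_CALL_COLUMNS",
    "simulate_site_calls",
    "simulate_methylome_counts",
    "simulate_amplicon_calls",
    "write_truth",
    "write_calls",
]

#: Canonical column order of a read-call table (one row = one CpG
#: observation on one read).
READ_CALL_COLUMNS = [
    "read_id",
    "sample",
    "replicate",
    "group",
    "locus",
    "strand",
    "cpg_pos",
    "state",
]


class SimulationError(ValueError):
    """Invalid simulation specification."""


@dataclass(frozen=True)
class ErrorModel:
    """Bisulfite error channel.

    Parameters
    ----------
    epsilon : float
        Probability an unmethylated C is read as methylated
        (non-conversion). Default 0.01.
    delta : float
        Probability a methylated C is read as unmethylated (inappropriate
        conversion). Default 0.
    """

    epsilon: float = 0.01
    delta: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.epsilon < 0.5):
            raise SimulationError(f"epsilon must be in [0, 0.5): {self.epsilon}")
        if not (0.0 <= self.delta < 0.5):
            raise SimulationError(f"delta must be in [0, 0.5): {self.delta}")

    def observed_prob(self, p_true: float | np.ndarray) -> float | np.ndarray:
        """Probability a call reads methylated given true methylation prob."""
        return p_true * (1.0 - self.delta) + (1.0 - np.asarray(p_true)) * self.epsilon


@dataclass(frozen=True)
class SimSiteSpec:
    """Ground truth for one CpG unit in site mode."""

    chrom: str
    pos: int
    p_meth_plus: float
    p_meth_minus: float
    coverage_plus: float
    coverage_minus: float

    def __post_init__(self) -> None:
        for p in (self.p_meth_plus, self.p_meth_minus):
            if not (0.0 <= p <= 1.0):
                raise SimulationError(f"methylation probability outside [0,1]: {p}")
        if self.coverage_plus <= 0 or self.coverage_minus <= 0:
            raise SimulationError("coverages must be > 0")


@dataclass(frozen=True)
class SimLocusSpec:
    """Ground truth for one amplicon locus.

    ``joint_pattern_dist`` maps ``(top_pattern, bottom_pattern)`` pairs of
    equal-length binary strings (over ``cpg_positions``) to probabilities.
    A fragment whose two strands carry different patterns is hemimethylated
    at the sites where they disagree.
    """

    locus_id: str
    cpg_positions: tuple[int, ...]
    joint_pattern_dist: dict[tuple[str, str], float]
    coverage_plus: int
    coverage_minus: int
    replicate_effects: dict[str, dict[tuple[str, str], float]] | None = None

    def __post_init__(self) -> None:
        n = len(self.cpg_positions)
        if n == 0:
            raise SimulationError("cpg_positions must be non-empty")
        self._validate_dist(self.joint_pattern_dist, n)
        if self.replicate_effects:
            for dist in self.replicate_effects.values():
                self._validate_dist(dist, n)
        if self.coverage_plus <= 0 or self.coverage_minus <= 0:
            raise SimulationError("coverages must be > 0")

    @staticmethod
    def _validate_dist(dist: dict[tuple[str, str], float], n: int) -> None:
        if not dist:
            raise SimulationError("joint_pattern_dist is empty")
        total = 0.0
        for (top, bot), p in dist.items():
            if len(top) != n or len(bot) != n:
                raise SimulationError(
                    f"pattern length mismatch: ({top!r}, {bot!r}) vs {n} CpGs"
                )
            if set(top) - {"0", "1"} or set(bot) - {"0", "1"}:
                raise SimulationError(f"patterns must be binary strings: {top!r}, {bot!r}")
            if p < 0:
                raise SimulationError("negative pattern probability")
            total += p
        if abs(total - 1.0) > 1e-9:
            raise SimulationError(f"pattern probabilities sum to {total}, not 1")

    def dist_for_replicate(self, replicate: str) -> dict[tuple[str, str], float]:
        if self.replicate_effects and replicate in self.replicate_effects:
            return self.replicate_effects[replicate]
        return self.joint_pattern_dist

    def true_strand_frequencies(self, replicate: str | None = None) -> pd.DataFrame:
        """Marginal true pattern frequencies per strand (tidy frame)."""
        dist = self.joint_pattern_dist if replicate is None else self.dist_for_replicate(replicate)
        rows: dict[tuple[str, str], float] = {}
        for (top, bot), p in dist.items():
            rows[("plus", top)] = rows.get(("plus", top), 0.0) + p
            rows[("minus", bot)] = rows.get(("minus", bot), 0.0) + p
        return pd.DataFrame(
            [
                {"locus": self.locus_id, "strand": s, "pattern": pat, "freq": f}
                for (s, pat), f in sorted(rows.items())
            ]
        )

    def true_site_levels(self, replicate: str | None = None) -> pd.DataFrame:
        """True per-site, per-strand methylation levels implied by the joint dist."""
        freqs = self.true_strand_frequencies(replicate)
        out = []
        for strand, sub in freqs.groupby("strand"):
            mat = np.array([[int(c) for c in p] for p in sub["pattern"]], dtype=float)
            levels = sub["freq"].to_numpy() @ mat
            for pos, lev in zip(self.cpg_positions, levels):
                out.append(
                    {"locus": self.locus_id, "strand": strand, "cpg_pos": pos, "level": lev}
                )
        return pd.DataFrame(out).sort_values(["cpg_pos", "strand"], ignore_index=True)


@dataclass(frozen=True)
class ReadCall:
    """One CpG observation on one read."""

    read_id: str
    sample: str
    replicate: str
    group: str
    locus: str
    strand: str
    cpg_pos: int
    state: str

    def __post_init__(self) -> None:
        if self.strand not in ("plus", "minus"):
            raise SimulationError(f"strand must be plus|minus: {self.strand}")
        if self.state not in ("M", "U"):
            raise SimulationError(f"state must be M|U: {self.state}")


def _locus_rng(seed: int, locus_id: str) -> np.random.Generator:
    """Independent stream per (seed, locus): loci reproduce in isolation."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(locus_id.encode())])
    )


def _empty_calls() -> pd.DataFrame:
    return pd.DataFrame(columns=READ_CALL_COLUMNS)


def simulate_site_calls(
    spec: SimSiteSpec,
    err: ErrorModel,
    seed: int,
    sample: str = "S1",
    replicate: str = "R1",
    group: str = "na",
) -> pd.DataFrame:
    """Simulate per-read calls at one CpG unit.

    Read counts per strand are Poisson around the spec coverage; each read
    is methylated with probability ``p_s(1-delta) + (1-p_s)epsilon``.
    Returns a read-call frame (`READ_CALL_COLUMNS`), deterministic given
    ``seed``.
    """
    rng = _locus_rng(seed, f"{spec.chrom}:{spec.pos}")
    frames = []
    for strand, p_true, cov in (
        ("plus", spec.p_meth_plus, spec.coverage_plus),
        ("minus", spec.p_meth_minus, spec.coverage_minus),
    ):
        n = int(rng.poisson(cov))
        if n == 0:
            continue
        p_obs = float(err.observed_prob(p_true))
        meth = rng.random(n) < p_obs
        frames.append(
            pd.DataFrame(
                {
                    "read_id": [f"{spec.chrom}:{spec.pos}:{strand}:{i}" for i in range(n)],
                    "sample": sample,
                    "replicate": replicate,
                    "group": group,
                    "locus": spec.chrom,
                    "strand": strand,
                    "cpg_pos": spec.pos,
                    "state": np.where(meth, "M", "U"),
                }
            )
        )
    if not frames:
        return _empty_calls()
    return pd.concat(frames, ignore_index=True)[READ_CALL_COLUMNS]


def simulate_methylome_counts(
    chrom: str,
    positions: np.ndarray,
    p_plus: np.ndarray,
    p_minus: np.ndarray,
    mean_coverage: float,
    err: ErrorModel,
    seed: int,
) -> pd.DataFrame:
    """Vectorised count-level site simulation for genome-scale methylomes.

    Distributionally identical to aggregating :func:`simulate_site_calls`
    over every site (Poisson coverage per strand, binomial methylated
    counts through the error channel) without materialising per-read rows.
    Returns a unit-count frame with columns
    ``chrom,pos,M_plus,U_plus,M_minus,U_minus``.
    """
    positions = np.asarray(positions, dtype=np.int64)
    p_plus = np.asarray(p_plus, dtype=float)
    p_minus = np.asarray(p_minus, dtype=float)
    if not (len(positions) == len(p_plus) == len(p_minus)):
        raise SimulationError("positions and probability arrays must align")
    if ((p_plus < 0) | (p_plus > 1) | (p_minus < 0) | (p_minus > 1)).any():
        raise SimulationError("methylation probabilities outside [0,1]")
    rng = _locus_rng(seed, chrom)
    n = len(positions)
    cov_p = rng.poisson(mean_coverage, size=n)
    cov_m = rng.poisson(mean_coverage, size=n)
    m_p = rng.binomial(cov_p, err.observed_prob(p_plus))
    m_m = rng.binomial(cov_m, err.observed_prob(p_minus))
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "M_plus": m_p,
            "U_plus": cov_p - m_p,
            "M_minus": m_m,
            "U_minus": cov_m - m_m,
        }
    )


def _apply_error(mat: np.ndarray, err: ErrorModel, rng: np.random.Generator) -> np.ndarray:
    """Flip true states through the error channel (mat is 0/1, any shape)."""
    u = rng.random(mat.shape)
    flip_down = (mat == 1) & (u < err.delta)
    flip_up = (mat == 0) & (u < err.epsilon)
    out = mat.copy()
    out[flip_down] = 0
    out[flip_up] = 1
    return out


def simulate_amplicon_calls(
    spec: SimLocusSpec,
    err: ErrorModel,
    n_replicates: int,
    seed: int,
    group: str = "na",
    sample_prefix: str | None = None,
) -> pd.DataFrame:
    """Simulate full-length amplicon reads for one locus.

    Each fragment draws a (top, bottom) pattern pair from the joint
    distribution; each strand is sequenced independently as one read whose
    per-site states pass through the error channel. Every read covers all
    reference CpGs (amplicon reads span the locus). Coverage is exact per
    strand (amplicon depth is fixed in practice, unlike shotgun data).
    """
    prefix = sample_prefix or group
    frames = []
    for r in range(1, n_replicates + 1):
        replicate = f"R{r}"
        sample = f"{prefix}{r}"
        rng = _locus_rng(seed, f"{spec.locus_id}/{sample}")
        dist = spec.dist_for_replicate(replicate)
        pairs = list(dist.keys())
        probs = np.array([dist[k] for k in pairs], dtype=float)
        probs = probs / probs.sum()
        n_frag = max(spec.coverage_plus, spec.coverage_minus)
        which = rng.choice(len(pairs), size=n_frag, p=probs)
        top = np.array(
            [[int(c) for c in pairs[w][0]] for w in which], dtype=np.int8
        )
        bot = np.array(
            [[int(c) for c in pairs[w][1]] for w in which], dtype=np.int8
        )
        for strand, mat, cov in (
            ("plus", top, spec.coverage_plus),
            ("minus", bot, spec.coverage_minus),
        ):
            obs = _apply_error(mat[:cov], err, rng)
            n_reads, n_cpg = obs.shape
            frames.append(
                pd.DataFrame(
                    {
                        "read_id": np.repeat(
                            [f"{sample}:{strand}:{i}" for i in range(n_reads)], n_cpg
                        ),
                        "sample": sample,
                        "replicate": replicate,
                        "group": group,
                        "locus": spec.locus_id,
                        "strand": strand,
                        "cpg_pos": np.tile(spec.cpg_positions, n_reads),
                        "state": np.where(obs.ravel() == 1, "M", "U"),
                    }
                )
            )
    if not frames:
        return _empty_calls()
    return pd.concat(frames, ignore_index=True)[READ_CALL_COLUMNS]


def write_calls(calls: pd.DataFrame, path) -> None:
    """Write a read-call frame as the canonical tab-separated table."""
    calls[READ_CALL_COLUMNS].to_csv(path, sep="\t", index=False)


def write_truth(spec, path) -> None:
    """Serialise simulation ground truth as TSV next to the simulated calls.

    Site specs yield per-strand true levels; locus specs yield true
    per-strand pattern frequencies and the implied per-site levels.
    """
    if isinstance(spec, SimSiteSpec):
        pd.DataFrame(
            [
                {
                    "chrom": spec.chrom,
                    "pos": spec.pos,
                    "strand": "plus",
                    "true_level": spec.p_meth_plus,
                },
                {
                    "chrom": spec.chrom,
                    "pos": spec.pos,
                    "strand": "minus",
                    "true_level": spec.p_meth_minus,
                },
            ]
        ).to_csv(path, sep="\t", index=False)
    elif isinstance(spec, SimLocusSpec):
        spec.true_strand_frequencies().to_csv(path, sep="\t", index=False)
    else:
        raise SimulationError(f"unknown spec type: {type(spec).__name__}")
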