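#!/usr/bin/env python
"""Generate the synthetic study datasets every later analysis step consumes.

Two arms, mirroring a strand-asymmetry study design:

* a WGBS-like methylome at combined-replicate depth (~60 reads/strand):
  5000 symmetrically methylated CpG units whose true levels follow a
  Beta(2, 0.5) mixture (most sites heavily methylated, a tail of partial
  methylation), plus one planted strongly hemimethylated site (true
  strand levels 0.92 / 0.05) and one planted asymmetric region (twelve
  CpGs with per-site strand offsets of 0.10-0.22 - too small for
  single-site tests, detectable only by the window scan);
* deep amplicon loci for two castes (queen / worker, three replicates
  each): a QNFC1-like single-CpG locus dominated by hemimethylated
  fragments, and two multi-CpG loci with caste- and strand-biased
  pattern mixtures.

Per-read calls go to scratch/sim/ (large, regenerable); ground-truth
tables go to results/sim_truth/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from hemimeth.simdata import (
    ErrorModel,
    SimLocusSpec,
    SimSiteSpec,
    simulate_amplicon_calls,
    simulate_site_calls,
    write_calls,
    write_truth,
)

SEED = 20170906
ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "sim"
TRUTH = ROOT / "results" / "sim_truth"

HEMI_POS = 2_000_000
REGION_POS = [3_000_000 + i * 150 for i in range(12)]

AMPLICON_LOCI = {
    # single CpG, plus-strand marginal 0.92, minus 0.05: hemimethylated fragments
    "qnfc1_like": {
        "cpgs": (50,),
        "dists": {
            "queen": {("1", "1"): 0.05, ("1", "0"): 0.87, ("0", "0"): 0.08},
            "worker": {("1", "1"): 0.05, ("1", "0"): 0.87, ("0", "0"): 0.08},
        },
    },
    # dominant pattern plus rare ones; bottom strand enriched for the
    # unmethylated pattern (cryptic asymmetry behind similar levels)
    "cabin1_like": {
        "cpgs": (10, 35, 60, 85),
        "dists": {
            "queen": {
                ("1111", "1111"): 0.55,
                ("1111", "0000"): 0.20,
                ("1101", "1101"): 0.15,
                ("0000", "0000"): 0.10,
            },
            "worker": {
                ("1111", "1111"): 0.35,
                ("1101", "1111"): 0.25,
                ("1101", "1101"): 0.25,
                ("0000", "0000"): 0.15,
            },
        },
    },
    "nadrin2_like": {
        "cpgs": (12, 30, 48),
        "dists": {
            "queen": {
                ("111", "111"): 0.30,
                ("110", "111"): 0.25,
                ("110", "110"): 0.25,
                ("000", "000"): 0.20,
            },
            "worker": {
                ("111", "111"): 0.30,
                ("110", "110"): 0.30,
                ("100", "110"): 0.20,
                ("000", "000"): 0.20,
            },
        },
        # replicate heterogeneity: one queen replicate carries its own
        # dominant pattern, as amplicon replicates do in practice
        "replicate_effects": {
            "queen": {
                "R2": {
                    ("111", "111"): 0.10,
                    ("110", "111"): 0.10,
                    ("110", "110"): 0.15,
                    ("011", "011"): 0.45,
                    ("000", "000"): 0.20,
                }
            }
        },
    },
}


def simulate_wgbs() -> pd.DataFrame:
    rng = np.random.default_rng(SEED)
    frames = []
    pos = np.sort(rng.choice(np.arange(1000, 2 * 10**6 - 1000), 5000, replace=False))
    levels = rng.beta(2.0, 0.5, len(pos))
    for p, level in zip(pos, levels):
        spec = SimSiteSpec("chr1", int(p), float(level), float(level), 60, 60)
        frames.append(simulate_site_calls(spec, ErrorModel(), seed=SEED + int(p)))
    hemi = SimSiteSpec("chr1", HEMI_POS, 0.92, 0.05, 60, 60)
    frames.append(simulate_site_calls(hemi, ErrorModel(), seed=SEED))
    write_truth(hemi, TRUTH / "hemimethylated_site.tsv")
    offsets = rng.uniform(0.10, 0.22, len(REGION_POS))
    region_rows = []
    for p, off in zip(REGION_POS, offsets):
        spec = SimSiteSpec("chr1", p, 0.6 + off / 2, 0.6 - off / 2, 60, 60)
        frames.append(simulate_site_calls(spec, ErrorModel(), seed=SEED + p))
        region_rows.append({"pos": p, "true_offset": off})
    pd.DataFrame(region_rows).to_csv(TRUTH / "asymmetric_region.tsv", sep="\t", index=False)
    return pd.concat(frames, ignore_index=True)


def simulate_amplicons() -> pd.DataFrame:
    frames = []
    for locus_id, cfg in AMPLICON_LOCI.items():
        for group, dist in cfg["dists"].items():
            spec = SimLocusSpec(
                locus_id, cfg["cpgs"], dist, 1000, 1000,
                replicate_effects=cfg.get("replicate_effects", {}).get(group),
            )
            frames.append(
                simulate_amplicon_calls(
                    spec, ErrorModel(), n_replicates=3, seed=SEED, group=group,
                    sample_prefix=group[0].upper(),
                )
            )
            write_truth(spec, TRUTH / f"{locus_id}.{group}.tsv")
    return pd.concat(frames, ignore_index=True)


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    TRUTH.mkdir(parents=True, exist_ok=True)
    wgbs = simulate_wgbs()
    write_calls(wgbs, SCRATCH / "wgbs_calls.tsv")
    print(f"WGBS-like methylome: {wgbs['cpg_pos'].nunique()} CpG units, "
          f"{wgbs['read_id'].nunique()} reads -> {SCRATCH / 'wgbs_calls.tsv'}")
    amp = simulate_amplicons()
    write_calls(amp, SCRATCH / "amplicon_calls.tsv")
    print(f"Amplicon loci: {sorted(amp['locus'].unique())}, "
          f"{amp['read_id'].nunique()} reads x 2 castes x 3 replicates "
          f"-> {SCRATCH / 'amplicon_calls.tsv'}")
    print(f"Ground truth written to {TRUTH}")


if __name__ == "__main__":
    main()
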