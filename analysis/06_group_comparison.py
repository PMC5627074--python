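#!/usr/bin/env python
"""Caste comparison of methylation-pattern frequencies.

Multinomial logistic model of pattern as a function of strand, replicate
and group (caste) per locus; reports the fraction of patterns whose
frequency differs between queens and workers (Wald p < 0.05 on the group
coefficient).
"""

from pathlib import Path

from hemimeth.pipeline import run_compare_groups
from analysis_loci import LOCI

ROOT = Path(__file__).resolve().parents[1]
CALLS = ROOT / "scratch" / "sim" / "amplicon_calls.tsv"
OUT = ROOT / "results" / "group_comparison"


def main() -> None:
    if not CALLS.exists():
        raise SystemExit(f"{CALLS} missing - run analysis/01_simulate.py first")
    res = run_compare_groups(
        {
            "inputs": {"calls": str(CALLS)},
            "output_dir": str(OUT),
            "patterns": {"loci": LOCI},
        }
    )
    for locus, r in res["loci"].items():
        print(f"{locus}: {100 * r['fraction_significant']:.0f}% of patterns differ "
              f"between castes (p < 0.05)")


if __name__ == "__main__":
    main()
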