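"""Epiallele extraction, the 2^n pattern space, EM estimation, bootstrap."""

import numpy as np
import pandas as pd
import pytest

from hemimeth.patterns import (
    COUNT_COLUMNS,
    PatternError,
    PatternTable,
    count_possible_patterns,
    estimate_frequencies_em,
    extract_patterns,
    strand_difference_bootstrap,
)
from hemimeth.simdata import ErrorModel, SimLocusSpec, simulate_amplicon_calls


def calls_row(read_id, pos, state, strand="plus", sample="S1"):
    return {
        "read_id": read_id,
        "sample": sample,
        "replicate": "R1",
        "group": "g",
        "locus": "L",
        "strand": strand,
        "cpg_pos": pos,
        "state": state,
    }


def make_table(counts_rows):
    df = pd.DataFrame(counts_rows, columns=COUNT_COLUMNS)
    n = len(df["pattern"].iloc[0])
    return PatternTable("L", tuple(range(1, n + 1)), df)


def stratum_counts(pattern_counts, strand="plus", sample="S1"):
    return [
        {"sample": sample, "replicate": "R1", "group": "g", "strand": strand,
         "pattern": p, "count": c}
        for p, c in pattern_counts.items()
    ]


class TestPatternSpace:
    @pytest.mark.parametrize("n,expected", [(15, 32768), (0, 1), (3, 8)])
    def test_powers_of_two(self, n, expected):
        assert count_possible_patterns(n) == expected

    def test_exact_at_large_n(self):
        assert count_possible_patterns(200) == 2**200

    def test_negative_rejected(self):
        with pytest.raises(PatternError):
            count_possible_patterns(-1)


class TestExtraction:
    def test_truncated_reads_dropped(self):
        rows = [calls_row("r1", p, "M") for p in (10, 20)]  # covers 2 of 3
        rows += [calls_row("r2", p, "M") for p in (10, 20, 30)]
        tab = extract_patterns(pd.DataFrame(rows), (10, 20, 30), min_frac=0)
        assert tab.counts["count"].sum() == 1
        assert tab.counts["pattern"].iloc[0] == "111"

    def test_phantom_site_reads_dropped(self):
        rows = [calls_row("r1", p, "M") for p in (10, 20, 30, 99)]  # 99 not in reference
        rows += [calls_row("r2", p, "U") for p in (10, 20, 30)]
        tab = extract_patterns(pd.DataFrame(rows), (10, 20, 30), min_frac=0)
        assert list(tab.counts["pattern"]) == ["000"]

    def test_abundance_floor_removes_rare_patterns(self):
        rows = stratum_counts({"11": 995, "01": 5})
        # rebuild read-level calls: 995 "11" reads and 5 "01" reads
        calls = []
        for i in range(995):
            calls += [calls_row(f"a{i}", 1, "M"), calls_row(f"a{i}", 2, "M")]
        for i in range(5):
            calls += [calls_row(f"b{i}", 1, "U"), calls_row(f"b{i}", 2, "M")]
        tab = extract_patterns(pd.DataFrame(calls), (1, 2), min_frac=0.01)
        assert list(tab.counts["pattern"]) == ["11"]  # 5 < 0.01 * 1000

    def test_surviving_patterns_share_length_and_index(self):
        spec = SimLocusSpec(
            "L", (3, 9, 20), {("110", "011"): 0.6, ("000", "000"): 0.4}, 300, 300
        )
        calls = simulate_amplicon_calls(spec, ErrorModel(), 2, seed=5)
        tab = extract_patterns(calls, (3, 9, 20))
        lens = tab.counts["pattern"].str.len().unique()
        assert list(lens) == [3]
        assert tab.counts["pattern"].nunique() <= min(
            count_possible_patterns(3), 600
        )

    def test_empty_reference_rejected(self):
        with pytest.raises(PatternError):
            extract_patterns(pd.DataFrame([calls_row("r", 1, "M")]), ())

    def test_tsv_roundtrip(self, tmp_path):
        tab = make_table(stratum_counts({"10": 7, "01": 3}))
        path = tmp_path / "p.tsv"
        tab.to_tsv(path)
        back = PatternTable.from_tsv(path, tab.cpg_positions)
        pd.testing.assert_frame_equal(
            back.counts.sort_values("pattern", ignore_index=True),
            tab.counts.sort_values("pattern", ignore_index=True),
        )


class TestEm:
    def test_identity_channel_returns_observed_proportions(self):
        tab = make_table(stratum_counts({"11": 60, "10": 25, "00": 15}))
        est = estimate_frequencies_em(tab, ErrorModel(epsilon=0.0, delta=0.0))
        f = est.frequencies("S1", "plus")
        assert f["11"] == pytest.approx(0.60)
        assert f["10"] == pytest.approx(0.25)
        assert f["00"] == pytest.approx(0.15)

    def test_single_cpg_closed_form_deconvolution(self):
        # f(1) = (phat - eps) / (1 - eps)
        tab = make_table(stratum_counts({"1": 300, "0": 700}))
        est = estimate_frequencies_em(tab, ErrorModel(epsilon=0.01, delta=0.0))
        assert est.frequencies("S1", "plus")["1"] == pytest.approx(
            (0.3 - 0.01) / 0.99, abs=1e-6
        )

    def test_two_sided_channel_closed_form(self):
        # with both error arms: phat = f(1-delta) + (1-f)eps
        eps, dlt, phat = 0.02, 0.03, 0.4
        tab = make_table(stratum_counts({"1": int(phat * 1000), "0": int((1 - phat) * 1000)}))
        est = estimate_frequencies_em(tab, ErrorModel(epsilon=eps, delta=dlt))
        expected = (phat - eps) / (1 - dlt - eps)
        assert est.frequencies("S1", "plus")["1"] == pytest.approx(expected, abs=1e-6)

    def test_frequencies_sum_to_one_per_stratum(self):
        tab = make_table(
            stratum_counts({"11": 50, "10": 30, "00": 20})
            + stratum_counts({"11": 10, "00": 90}, strand="minus")
        )
        est = estimate_frequencies_em(tab)
        sums = est.freqs.groupby(["sample", "strand"])["freq"].sum()
        assert np.allclose(sums, 1.0, atol=1e-6)
        assert all(est.converged.values())

    def test_recovery_on_simulated_locus(self):
        spec = SimLocusSpec(
            "L", (1, 2, 3),
            {("111", "111"): 0.5, ("110", "110"): 0.3, ("000", "000"): 0.2},
            3000, 3000,
        )
        calls = simulate_amplicon_calls(spec, ErrorModel(), 1, seed=42)
        tab = extract_patterns(calls, (1, 2, 3))
        est = estimate_frequencies_em(tab)
        truth = {"111": 0.5, "110": 0.3, "000": 0.2}
        f = est.frequencies(tab.counts["sample"].iloc[0], "plus")
        l1 = sum(abs(f.get(p, 0.0) - v) for p, v in truth.items())
        assert l1 < 0.05

    def test_zero_read_stratum_rejected(self):
        tab = make_table(stratum_counts({"1": 0}))
        with pytest.raises(PatternError):
            estimate_frequencies_em(tab)


class TestBootstrap:
    def test_degenerate_single_pattern_has_zero_width_ci(self):
        tab = make_table(
            stratum_counts({"11": 100}) + stratum_counts({"11": 100}, strand="minus")
        )
        ci = strand_difference_bootstrap(tab, n_boot=50, seed=1)
        assert (ci["ci_high"] - ci["ci_low"]).abs().max() == 0.0
        assert ci["diff"].abs().max() == 0.0

    def test_symmetric_strands_cover_zero(self):
        spec = SimLocusSpec(
            "L", (1, 2), {("11", "11"): 0.6, ("00", "00"): 0.4}, 400, 400
        )
        calls = simulate_amplicon_calls(spec, ErrorModel(), 1, seed=9)
        tab = extract_patterns(calls, (1, 2))
        ci = strand_difference_bootstrap(tab, n_boot=200, seed=9)
        covered = ((ci["ci_low"] <= 0) & (0 <= ci["ci_high"])).mean()
        assert covered >= 0.5  # small-sample property check; acceptance covers 95%

    def test_missing_stratum_rejected(self):
        tab = make_table(stratum_counts({"11": 100}))  # no minus reads
        with pytest.raises(PatternError):
            strand_difference_bootstrap(tab, n_boot=10, seed=1)
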