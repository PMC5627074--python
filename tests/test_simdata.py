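"""Simulator ground-truth contracts: error channel, coverage, determinism."""

import numpy as np
import pandas as pd
import pytest

from hemimeth.simdata import (
    ErrorModel,
    SimLocusSpec,
    SimSiteSpec,
    SimulationError,
    simulate_amplicon_calls,
    simulate_methylome_counts,
    simulate_site_calls,
    write_truth,
)


def meth_fraction(calls, strand):
    sub = calls[calls["strand"] == strand]
    return (sub["state"] == "M").mean(), len(sub)


class TestErrorModel:
    @pytest.mark.parametrize("eps,delta", [(-0.1, 0), (0.5, 0), (0, 0.5), (0, -1)])
    def test_rejects_invalid_rates(self, eps, delta):
        with pytest.raises(SimulationError):
            ErrorModel(epsilon=eps, delta=delta)

    def test_observed_probability_mixes_both_error_arms(self):
        em = ErrorModel(epsilon=0.01, delta=0.02)
        assert em.observed_prob(1.0) == pytest.approx(0.98)
        assert em.observed_prob(0.0) == pytest.approx(0.01)


class TestSiteMode:
    def test_saturated_site_without_error_is_all_methylated(self, err_free):
        spec = SimSiteSpec("chr1", 50, 1.0, 1.0, 200, 200)
        calls = simulate_site_calls(spec, err_free, seed=3)
        assert (calls["state"] == "M").all()

    def test_nonconversion_floor_on_unmethylated_strand(self):
        # p=0 with epsilon=0.01: observed fraction ~ Binomial(n, 0.01)
        spec = SimSiteSpec("chr1", 50, 0.0, 0.0, 1e5, 10)
        calls = simulate_site_calls(spec, ErrorModel(epsilon=0.01), seed=5)
        frac, n = meth_fraction(calls, "plus")
        assert abs(frac - 0.01) <= 3 * np.sqrt(0.01 * 0.99 / n)

    def test_hemimethylated_site_strand_difference(self, err_default):
        # strongly hemimethylated site: expected level difference ~ 0.87
        spec = SimSiteSpec("chr1", 50, 0.92, 0.05, 1000, 1000)
        calls = simulate_site_calls(spec, err_default, seed=7)
        bp, _ = meth_fraction(calls, "plus")
        bm, _ = meth_fraction(calls, "minus")
        assert abs((bp - bm) - 0.87) < 0.05

    def test_rejects_invalid_probability(self):
        with pytest.raises(SimulationError):
            SimSiteSpec("chr1", 1, 1.2, 0.5, 10, 10)

    def test_same_seed_reproduces_byte_identical_calls(self, err_default):
        spec = SimSiteSpec("chr1", 50, 0.4, 0.6, 100, 100)
        a = simulate_site_calls(spec, err_default, seed=9)
        b = simulate_site_calls(spec, err_default, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_count_mode_matches_read_mode_distribution(self, err_default):
        # vectorised count-level simulation agrees with aggregated reads
        n, cov, p = 400, 25.0, 0.7
        pos = np.arange(1, n + 1) * 100
        units = simulate_methylome_counts(
            "chrX", pos, np.full(n, p), np.full(n, p), cov, err_default, 21
        )
        tot = units[["M_plus", "U_plus", "M_minus", "U_minus"]].to_numpy().sum()
        assert abs(tot / (2 * n) - cov) < 3 * np.sqrt(cov / (2 * n))
        m = (units["M_plus"] + units["M_minus"]).sum()
        p_obs = float(err_default.observed_prob(p))
        assert abs(m / tot - p_obs) < 3 * np.sqrt(p_obs * (1 - p_obs) / tot)


class TestAmpliconMode:
    def test_fully_methylated_pair_without_error(self, err_free):
        spec = SimLocusSpec("L", (1, 5), {("11", "11"): 1.0}, 50, 50)
        calls = simulate_amplicon_calls(spec, err_free, n_replicates=1, seed=1)
        assert (calls["state"] == "M").all()

    def test_hemimethylation_by_construction(self, err_free):
        spec = SimLocusSpec("L", (1,), {("1", "0"): 1.0}, 80, 80)
        calls = simulate_amplicon_calls(spec, err_free, n_replicates=1, seed=2)
        bp, _ = meth_fraction(calls, "plus")
        bm, _ = meth_fraction(calls, "minus")
        assert bp == 1.0 and bm == 0.0

    def test_marginal_pattern_frequency_within_sampling_error(self, err_free):
        dist = {("11", "11"): 0.3, ("00", "00"): 0.5, ("10", "01"): 0.2}
        n = 4000
        spec = SimLocusSpec("L", (1, 5), dist, n, n)
        calls = simulate_amplicon_calls(spec, err_free, n_replicates=1, seed=4)
        plus = calls[calls["strand"] == "plus"]
        pat = (
            plus.assign(bit=(plus["state"] == "M").astype(int).astype(str))
            .sort_values(["read_id", "cpg_pos"])
            .groupby("read_id")["bit"]
            .agg("".join)
        )
        freq_11 = (pat == "11").mean()
        assert abs(freq_11 - 0.3) <= 3 * np.sqrt(0.3 * 0.7 / n)

    def test_every_read_covers_all_reference_cpgs(self, err_default):
        spec = SimLocusSpec("L", (3, 9, 20), {("101", "101"): 1.0}, 30, 30)
        calls = simulate_amplicon_calls(spec, err_default, n_replicates=2, seed=6)
        per_read = calls.groupby("read_id")["cpg_pos"].nunique()
        assert (per_read == 3).all()

    def test_pattern_length_mismatch_rejected(self):
        with pytest.raises(SimulationError):
            SimLocusSpec("L", (1, 5), {("1", "11"): 1.0}, 10, 10)

    def test_probabilities_must_sum_to_one(self):
        with pytest.raises(SimulationError):
            SimLocusSpec("L", (1,), {("1", "1"): 0.7}, 10, 10)


class TestTruth:
    def test_locus_truth_roundtrip_and_marginalization(self, tmp_path):
        dist = {("11", "10"): 0.4, ("01", "01"): 0.6}
        spec = SimLocusSpec("L", (2, 8), dist, 10, 10)
        path = tmp_path / "truth.tsv"
        write_truth(spec, path)
        back = pd.read_csv(path, sep="\t")
        for strand in ("plus", "minus"):
            assert back[back["strand"] == strand]["freq"].sum() == pytest.approx(1.0)
        # per-site truth equals sum of freq * indicator(site methylated)
        levels = spec.true_site_levels()
        lvl = levels.set_index(["strand", "cpg_pos"])["level"]
        assert lvl[("plus", 2)] == pytest.approx(0.4 * 1 + 0.6 * 0)
        assert lvl[("plus", 8)] == pytest.approx(0.4 * 1 + 0.6 * 1)
        assert lvl[("minus", 2)] == pytest.approx(0.4 * 1 + 0.6 * 0)
        assert lvl[("minus", 8)] == pytest.approx(0.6 * 1)

    def test_site_truth_roundtrip(self, tmp_path):
        spec = SimSiteSpec("chr2", 77, 0.9, 0.1, 30, 30)
        path = tmp_path / "truth.tsv"
        write_truth(spec, path)
        back = pd.read_csv(path, sep="\t").set_index("strand")["true_level"]
        assert back["plus"] == 0.9 and back["minus"] == 0.1
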