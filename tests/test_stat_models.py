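"""Multinomial pattern models and the strand linear mixed model."""

import numpy as np
import pandas as pd
import pytest

from hemimeth.stat_models import (
    ModelError,
    cells_from_table,
    compare_groups,
    fit_multinomial,
    fit_strand_lmm,
    lrt_factor,
)
from hemimeth.patterns import PatternTable, COUNT_COLUMNS


def cells(rows):
    return pd.DataFrame(rows)


def two_pattern_cells(a_plus, b_plus, a_minus, b_minus):
    return cells(
        [
            {"strand": "plus", "pattern": "A", "count": a_plus},
            {"strand": "plus", "pattern": "B", "count": b_plus},
            {"strand": "minus", "pattern": "A", "count": a_minus},
            {"strand": "minus", "pattern": "B", "count": b_minus},
        ]
    )


class TestMultinomialFit:
    def test_two_pattern_strand_coefficient_is_log_odds_ratio(self):
        fit = fit_multinomial(two_pattern_cells(80, 20, 40, 60), ["strand"])
        lor = np.log(20 / 80) - np.log(60 / 40)
        assert fit.reference == "A"
        assert fit.coef.loc["strand[plus]", "B"] == pytest.approx(lor, abs=1e-5)

    def test_matches_statsmodels_mnlogit(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(0)
        rows = []
        for strand, probs in (("plus", [0.5, 0.3, 0.2]), ("minus", [0.3, 0.3, 0.4])):
            cnt = rng.multinomial(500, probs)
            for p, c in zip(["AA", "AB", "BB"], cnt):
                rows.append({"strand": strand, "pattern": p, "count": c})
        df = cells(rows)
        fit = fit_multinomial(df, ["strand"])

        expanded = df.loc[df.index.repeat(df["count"])]
        cats = [fit.reference] + list(fit.patterns)
        y = expanded["pattern"].map({c: i for i, c in enumerate(cats)}).to_numpy()
        X = sm.add_constant((expanded["strand"] == "plus").astype(float).to_numpy())
        ref = sm.MNLogit(y, X).fit(disp=0)
        np.testing.assert_allclose(
            fit.coef.to_numpy(), np.asarray(ref.params), atol=1e-4
        )
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-4)

    def test_balanced_strands_give_null_coefficients(self):
        fit = fit_multinomial(two_pattern_cells(70, 30, 70, 30), ["strand"])
        assert abs(fit.coef.loc["strand[plus]", "B"]) < 1e-4
        red = fit_multinomial(two_pattern_cells(70, 30, 70, 30), [])
        dd, _, p = lrt_factor(fit, red)
        assert dd < 1e-6 and p > 0.99

    def test_strong_strand_effect_beats_null_by_large_deviance(self):
        rng = np.random.default_rng(1)
        rows = []
        for strand, pA in (("plus", 0.8), ("minus", 0.2)):
            cnt = rng.multinomial(5000, [pA, 1 - pA])
            for p, c in zip(["A", "B"], cnt):
                rows.append({"strand": strand, "pattern": p, "count": c})
        df = cells(rows)
        dd, _, p = lrt_factor(fit_multinomial(df, ["strand"]), fit_multinomial(df, []))
        assert dd > 1000
        assert p < 1e-100

    def test_separation_is_flagged_not_fatal(self):
        fit = fit_multinomial(two_pattern_cells(100, 0, 0, 100), ["strand"])
        assert fit.separation_suspected

    def test_single_level_factor_dropped_with_warning(self):
        df = two_pattern_cells(70, 30, 60, 40).assign(replicate="R1")
        with pytest.warns(UserWarning, match="single level"):
            fit = fit_multinomial(df, ["strand", "replicate"])
        assert fit.design == ("strand",)

    def test_needs_two_patterns(self):
        df = cells([{"strand": "plus", "pattern": "A", "count": 10}])
        with pytest.raises(ModelError):
            fit_multinomial(df, ["strand"])


class TestLrt:
    def test_identical_designs_give_zero_difference(self):
        df = two_pattern_cells(70, 30, 40, 60)
        a, b = fit_multinomial(df, ["strand"]), fit_multinomial(df, ["strand"])
        dd, dfree, p = lrt_factor(a, b)
        assert dd == 0.0 and dfree == 0 and p == 1.0

    def test_non_nested_designs_rejected(self):
        df = two_pattern_cells(70, 30, 40, 60).assign(replicate=["R1", "R1", "R2", "R2"])
        full = fit_multinomial(df, ["strand"])
        other = fit_multinomial(df, ["replicate"])
        with pytest.raises(ModelError):
            lrt_factor(full, other)

    def test_null_calibration_and_power(self):
        rng = np.random.default_rng(7)
        probs = np.array([0.5, 0.3, 0.2])
        pats = ["11", "10", "00"]

        def sim(p_plus, p_minus, n):
            rows = []
            for strand, pr in (("plus", p_plus), ("minus", p_minus)):
                for p, c in zip(pats, rng.multinomial(n, pr)):
                    rows.append({"strand": strand, "pattern": p, "count": c})
            df = cells(rows)
            return lrt_factor(fit_multinomial(df, ["strand"]), fit_multinomial(df, []))

        nsim = 150
        null_rej = sum(sim(probs, probs, 500)[2] < 0.05 for _ in range(nsim)) / nsim
        assert null_rej < 0.12  # ~5% nominal, loose Monte-Carlo band at 150 sims
        shifted = np.array([0.3, 0.5, 0.2])  # |delta freq| = 0.2 on two patterns
        power = sum(sim(probs, shifted, 1000)[2] < 0.05 for _ in range(60)) / 60
        assert power > 0.9


class TestCompareGroups:
    def make_group_cells(self, pA_by_group):
        rng = np.random.default_rng(11)
        rows = []
        for group, pA in pA_by_group.items():
            for rep in ("R1", "R2"):
                for strand in ("plus", "minus"):
                    cnt = rng.multinomial(800, [pA, 1 - pA])
                    for p, c in zip(["A", "B"], cnt):
                        rows.append(
                            {
                                "strand": strand,
                                "replicate": rep,
                                "group": group,
                                "pattern": p,
                                "count": c,
                            }
                        )
        return cells(rows)

    def test_group_exclusive_pattern_flagged(self):
        df = self.make_group_cells({"queen": 0.9, "worker": 0.1})
        res = compare_groups(df, ["strand", "replicate", "group"])
        assert res["fraction_significant"] == 1.0

    def test_label_swap_inverts_coefficient_sign(self):
        df = self.make_group_cells({"queen": 0.7, "worker": 0.3})
        res1 = compare_groups(df, ["strand", "replicate", "group"])
        swapped = df.assign(group=df["group"].map({"queen": "worker", "worker": "queen"}))
        res2 = compare_groups(swapped, ["strand", "replicate", "group"])
        c1 = res1["group_wald"]["coef"].to_numpy()
        c2 = res2["group_wald"]["coef"].to_numpy()
        np.testing.assert_allclose(c1, -c2, atol=1e-4)

    def test_single_group_rejected(self):
        df = self.make_group_cells({"queen": 0.5})
        with pytest.raises(ModelError):
            compare_groups(df, ["strand", "replicate", "group"])


class TestStrandLmm:
    def simulate_levels(self, beta, s2_sample, s2_resid, n_samples, n_units, seed):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(n_samples):
            re = rng.normal(0, np.sqrt(s2_sample))
            for strand, eff in (("plus", beta), ("minus", 0.0)):
                for u in range(n_units):
                    rows.append(
                        {
                            "sample": f"S{s}",
                            "strand": strand,
                            "unit": u,
                            "level": 0.4 + re + eff + rng.normal(0, np.sqrt(s2_resid)),
                        }
                    )
        return pd.DataFrame(rows)

    def test_zero_between_sample_variance_collapses_to_mean_difference(self):
        df = self.simulate_levels(0.2, 0.0, 0.004, 4, 30, seed=2)
        fit = fit_strand_lmm(df)
        plain = df[df.strand == "plus"].level.mean() - df[df.strand == "minus"].level.mean()
        assert fit.beta_strand == pytest.approx(plain, abs=1e-6)
        assert fit.sigma2_sample < 0.001

    def test_parameter_recovery(self):
        df = self.simulate_levels(0.2, 0.01, 0.005, 2, 50, seed=3)
        fit = fit_strand_lmm(df)
        assert abs(fit.beta_strand - 0.2) < 0.05
        assert fit.method == "lmm"

    def test_hemimethylated_amplicon_site_called_asymmetric(self):
        # three replicates, strand difference ~0.87 at one CpG
        rng = np.random.default_rng(4)
        rows = []
        for rep in range(3):
            n = 1000
            bp = rng.binomial(n, 0.92) / n
            bm = rng.binomial(n, 0.05) / n
            rows += [
                {"sample": f"Q{rep}", "strand": "plus", "unit": 0, "level": bp},
                {"sample": f"Q{rep}", "strand": "minus", "unit": 0, "level": bm},
            ]
        fit = fit_strand_lmm(pd.DataFrame(rows))
        assert fit.asymmetric
        assert abs(fit.beta_strand - 0.87) < 0.05

    def test_single_sample_falls_back_to_paired_t(self):
        df = self.simulate_levels(0.15, 0.0, 0.003, 1, 40, seed=5)
        with pytest.warns(UserWarning, match="paired t-test"):
            fit = fit_strand_lmm(df)
        assert fit.method == "paired_t"
        assert fit.p_strand < 0.05


def test_em_weighted_cells_mirror_raw_counts():
    rows = []
    for strand, c11, c00 in (("plus", 700, 300), ("minus", 400, 600)):
        rows += [
            {"sample": "S1", "replicate": "R1", "group": "g", "strand": strand,
             "pattern": "11", "count": c11},
            {"sample": "S1", "replicate": "R1", "group": "g", "strand": strand,
             "pattern": "00", "count": c00},
        ]
    tab = PatternTable("L", (1, 2), pd.DataFrame(rows, columns=COUNT_COLUMNS))
    raw = cells_from_table(tab)
    em = cells_from_table(tab, use_em=True)
    assert em["count"].sum() == pytest.approx(raw["count"].sum())
    # error-corrected effective counts stay close to raw at eps=1%
    m = raw.merge(em, on=["sample", "strand", "pattern"], suffixes=("_raw", "_em"))
    assert (m["count_raw"] - m["count_em"]).abs().max() < 0.03 * 1000
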