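"""Two-sample MR: harmonization rules, estimator oracles, robustness and
directionality."""

import numpy as np
import pandas as pd
import pytest

from sibmr import (
    harmonize,
    ivw,
    mr_egger,
    simulate_summary_stats,
    steiger,
    weighted_median,
    weighted_mode,
)


def stats_table(betas, alleles=None, eafs=None, ses=None, n=10_000):
    J = len(betas)
    alleles = alleles or [("A", "G")] * J
    return pd.DataFrame({
        "variant_id": [f"v{i}" for i in range(J)],
        "effect_allele": [a for a, _ in alleles],
        "other_allele": [b for _, b in alleles],
        "eaf": eafs if eafs is not None else [0.3] * J,
        "beta": betas,
        "se": ses if ses is not None else [0.02] * J,
        "n": n,
    })


def make_pairs(bx, by, sx=0.01, sy=0.02, eaf=0.3, n_exp=1e5, n_out=5e4):
    J = len(bx)
    return pd.DataFrame({
        "variant_id": [f"v{i}" for i in range(J)],
        "effect_allele": "A", "other_allele": "G",
        "eaf": np.full(J, eaf),
        "beta_exp": np.asarray(bx, float),
        "se_exp": np.full(J, sx),
        "beta_out": np.asarray(by, float),
        "se_out": np.full(J, sy),
        "n_exp": n_exp, "n_out": n_out,
    })


class TestHarmonize:
    def test_identical_coding_unchanged(self):
        exp = stats_table([0.1, 0.2])
        out = stats_table([0.05, -0.02])
        pairs = harmonize(exp, out)
        np.testing.assert_allclose(pairs["beta_out"], [0.05, -0.02])

    def test_swapped_alleles_flip_beta_and_eaf(self):
        exp = stats_table([0.1])
        out = stats_table([0.05], alleles=[("G", "A")], eafs=[0.7])
        pairs = harmonize(exp, out)
        assert pairs.loc[0, "beta_out"] == pytest.approx(-0.05)
        assert pairs.loc[0, "eaf_out"] == pytest.approx(0.3)

    def test_palindromic_intermediate_frequency_dropped(self):
        exp = stats_table([0.1, 0.2], alleles=[("A", "T"), ("A", "G")],
                          eafs=[0.5, 0.5])
        out = stats_table([0.0, 0.0], alleles=[("A", "T"), ("A", "G")],
                          eafs=[0.5, 0.5])
        pairs = harmonize(exp, out, palindrome_maf_limit=0.42)
        assert list(pairs["variant_id"]) == ["v1"]

    def test_idempotent_relabeling(self):
        exp, out = simulate_summary_stats(20, seed=1)
        once = harmonize(exp, out)
        exp2 = once.rename(columns={"beta_exp": "beta", "se_exp": "se",
                                    "n_exp": "n"})
        out2 = once.rename(columns={"beta_out": "beta", "se_out": "se",
                                    "n_out": "n"})[
            ["variant_id", "effect_allele", "other_allele", "eaf", "beta",
             "se", "n"]]
        twice = harmonize(exp2[["variant_id", "effect_allele", "other_allele",
                                "eaf", "beta", "se", "n"]], out2)
        np.testing.assert_allclose(twice["beta_out"], once["beta_out"])
        np.testing.assert_allclose(twice["beta_exp"], once["beta_exp"])

    def test_no_overlap_rejected(self):
        exp = stats_table([0.1])
        out = stats_table([0.1])
        out["variant_id"] = ["other"]
        with pytest.raises(ValueError):
            harmonize(exp, out)


class TestIvw:
    def test_single_variant_is_wald_ratio(self):
        pairs = make_pairs([0.1], [0.05])
        assert ivw(pairs).estimate == pytest.approx(0.5, abs=1e-12)

    def test_identical_ratios_reproduced_regardless_of_weights(self):
        pairs = make_pairs([0.1, 0.2, 0.4], [0.05, 0.1, 0.2],
                           sy=0.01)
        pairs["se_out"] = [0.01, 0.05, 0.2]
        assert ivw(pairs).estimate == pytest.approx(0.5, abs=1e-12)

    def test_matches_wls_through_origin_oracle(self):
        rng = np.random.default_rng(2)
        bx = rng.normal(0.1, 0.03, 5)
        by = -0.3 * bx + rng.normal(0, 0.01, 5)
        sy = rng.uniform(0.01, 0.05, 5)
        pairs = make_pairs(bx, by)
        pairs["se_out"] = sy
        w = 1 / sy**2
        oracle = np.sum(w * bx * by) / np.sum(w * bx**2)
        assert ivw(pairs).estimate == pytest.approx(oracle, abs=1e-10)

    def test_recovers_theta_from_simulated_stats(self):
        exp, out = simulate_summary_stats(100, theta=-0.2, seed=5)
        pairs = harmonize(exp, out)
        res = ivw(pairs)
        assert abs(res.estimate + 0.2) < 3 * res.se


class TestMrEgger:
    def test_line_through_origin_zero_intercept(self):
        bx = np.array([0.05, 0.1, 0.15, 0.2])
        pairs = make_pairs(bx, -0.4 * bx)
        res = mr_egger(pairs)
        assert res.intercept == pytest.approx(0.0, abs=1e-10)
        assert res.estimate == pytest.approx(-0.4, abs=1e-10)
        assert res.estimate == pytest.approx(ivw(pairs).estimate, abs=1e-10)

    def test_planted_intercept_recovered(self):
        rng = np.random.default_rng(3)
        ests, intercepts = [], []
        for rep in range(100):
            exp, out = simulate_summary_stats(
                50, theta=-0.2, pleiotropy_intercept=0.05,
                seed=1000 + rep)
            res = mr_egger(harmonize(exp, out))
            ests.append(res.estimate)
            intercepts.append(res.intercept)
        mc_se = np.std(intercepts) / np.sqrt(len(intercepts))
        assert abs(np.mean(intercepts) - 0.05) < 2 * mc_se + 1e-3
        mc_se_b = np.std(ests) / np.sqrt(len(ests))
        assert abs(np.mean(ests) + 0.2) < 3 * mc_se_b + 5e-3

    def test_requires_three_variants(self):
        with pytest.raises(ValueError):
            mr_egger(make_pairs([0.1, 0.2], [0.05, 0.1]))


class TestWeightedMedian:
    def test_median_of_equal_weight_ratios(self):
        # exposure SEs zero => all ratio weights equal => plain median
        pairs = make_pairs([0.1, 0.1, 0.1], [0.1, 0.2, 0.3], sx=0.0)
        res = weighted_median(pairs, n_boot=50, seed=1)
        assert res.estimate == pytest.approx(2.0, abs=1e-6)

    def test_dominant_variant_wins(self):
        pairs = make_pairs([0.1, 0.1, 0.1], [0.1, 0.3, 0.35])
        pairs["se_out"] = [0.001, 0.5, 0.5]  # >50% of weight on variant 0
        res = weighted_median(pairs, n_boot=50, seed=1)
        assert res.estimate == pytest.approx(1.0, abs=0.05)

    def test_robust_to_minority_invalid_instruments(self):
        rng = np.random.default_rng(6)
        J = 60
        bx = np.abs(rng.normal(0.1, 0.02, J))
        by = -0.2 * bx + rng.normal(0, 0.005, J)
        by[:20] += 0.15  # 1/3 of variants pleiotropic
        pairs = make_pairs(bx, by, sy=0.005)
        res = weighted_median(pairs, n_boot=100, seed=2)
        assert abs(res.estimate + 0.2) < 0.1
        # plain IVW is dragged away by the invalid third
        assert abs(ivw(pairs).estimate + 0.2) > abs(res.estimate + 0.2)


class TestWeightedMode:
    def test_common_ratio_reproduced(self):
        bx = np.array([0.08, 0.1, 0.12, 0.2])
        pairs = make_pairs(bx, 0.7 * bx)
        res = weighted_mode(pairs, n_boot=50, seed=3)
        assert res.estimate == pytest.approx(0.7, abs=0.02)

    def test_majority_weight_cluster_wins(self):
        rng = np.random.default_rng(7)
        bx = np.abs(rng.normal(0.1, 0.01, 20))
        by = 0.5 * bx + rng.normal(0, 0.001, 20)
        by[:6] = 2.0 * bx[:6] + rng.normal(0, 0.001, 6)
        pairs = make_pairs(bx, by, sy=0.005)
        res = weighted_mode(pairs, n_boot=50, seed=4)
        assert res.estimate == pytest.approx(0.5, abs=0.1)

    def test_invariant_to_duplication(self):
        bx = np.array([0.08, 0.1, 0.12, 0.15, 0.2])
        pairs = make_pairs(bx, 0.6 * bx + np.array([0, .001, -.001, .002, 0]))
        doubled = pd.concat([pairs, pairs], ignore_index=True)
        a = weighted_mode(pairs, n_boot=10, seed=5)
        b = weighted_mode(doubled, n_boot=10, seed=5)
        assert a.estimate == pytest.approx(b.estimate, abs=5e-3)


class TestSteiger:
    def test_clear_forward_direction(self):
        pairs = make_pairs([0.2, 0.25, 0.3], [0.02, 0.02, 0.03],
                           n_exp=100_000, n_out=100_000)
        ok, p = steiger(pairs)
        assert ok and p < 1e-6

    def test_equal_variance_boundary(self):
        pairs = make_pairs([0.1, 0.1], [0.1, 0.1])
        ok, p = steiger(pairs)
        assert not ok and p == pytest.approx(1.0, abs=1e-12)

    def test_reversal_flips_direction(self):
        pairs = make_pairs([0.2, 0.25, 0.3], [0.02, 0.02, 0.03])
        swapped = pairs.rename(columns={
            "beta_exp": "beta_out", "beta_out": "beta_exp",
            "se_exp": "se_out", "se_out": "se_exp",
            "n_exp": "n_out", "n_out": "n_exp"})
        ok_fwd, _ = steiger(pairs)
        ok_rev, _ = steiger(swapped)
        assert ok_fwd and not ok_rev

    def test_missing_eaf_rejected(self):
        pairs = make_pairs([0.1, 0.2], [0.05, 0.1])
        pairs.loc[0, "eaf"] = np.nan
        with pytest.raises(ValueError):
            steiger(pairs)


def test_all_estimators_agree_with_valid_homogeneous_instruments():
    """With no pleiotropy or heterogeneity, IVW, Egger slope, weighted median
    and weighted mode are mutually consistent."""
    exp, out = simulate_summary_stats(80, theta=-0.2, seed=9)
    pairs = harmonize(exp, out)
    est = {
        "ivw": ivw(pairs).estimate,
        "egger": mr_egger(pairs).estimate,
        "median": weighted_median(pairs, n_boot=50, seed=1).estimate,
        "mode": weighted_mode(pairs, n_boot=50, seed=1).estimate,
    }
    for name, e in est.items():
        assert abs(e + 0.2) < 0.08, (name, e)
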