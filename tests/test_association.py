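"""Association statistics: MAF, HWE, allele test, logistic models, splits."""

import math
from fractions import Fraction

import numpy as np
import pytest
from scipy.special import expit

from chbgrs.association import (
    additive_assoc,
    allele_test,
    bonferroni,
    compute_maf,
    conditional_assoc,
    fit_logistic,
    hwe_test,
    split_validate,
    summarize_snp,
)
from chbgrs.cohort_model import GenotypeCounts
from chbgrs.rounding import trunc2
from chbgrs.synthetic_data import SimulationConfig, simulate_cohort

from conftest import PRINTED_CIS, PRINTED_ORS, counts_pair


class TestMaf:
    @pytest.mark.parametrize(
        "counts,expected",
        [((550, 142, 7), 0.112), ((829, 91, 3), 0.053), ((10, 0, 0), 0.0)],
    )
    def test_published_values(self, counts, expected):
        assert round(compute_maf(GenotypeCounts(*counts)), 3) == expected

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            compute_maf(GenotypeCounts(0, 0, 0))


def _hwe_exact_oracle(counts: GenotypeCounts) -> float:
    """Full enumeration of heterozygote configurations with fixed allele counts."""
    n = counts.total
    n_rare = min(counts.n_minor_alleles, counts.n_major_alleles)
    weights = {}
    for h in range(n_rare % 2, n_rare + 1, 2):
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        weights[h] = Fraction(
            2**h * math.factorial(n),
            math.factorial(hom_r) * math.factorial(h) * math.factorial(hom_c),
        )
    total = sum(weights.values())
    p_obs = weights[counts.n_het]
    return float(sum(w for w in weights.values() if w <= p_obs) / total)


class TestHwe:
    def test_exact_proportions_give_p_one(self):
        # 25/50/25 sits exactly at p^2 : 2pq : q^2 for q = 0.5
        assert hwe_test(GenotypeCounts(25, 50, 25), "chi_square") == pytest.approx(1.0)

    def test_chi_square_null_at_expected_counts(self):
        # q = 0.1, n = 100: expected 81/18/1 equals observed
        assert hwe_test(GenotypeCounts(81, 18, 1), "chi_square") == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "counts", [(10, 10, 10), (50, 20, 5), (3, 4, 3), (30, 1, 9)]
    )
    def test_exact_matches_enumeration_oracle(self, counts):
        gc = GenotypeCounts(*counts)
        assert hwe_test(gc, "exact") == pytest.approx(_hwe_exact_oracle(gc), rel=1e-9)

    def test_monomorphic_returns_one_with_warning(self):
        with pytest.warns(UserWarning, match="monomorphic"):
            assert hwe_test(GenotypeCounts(20, 0, 0), "exact") == 1.0


def _oracle_or(case: GenotypeCounts, control: GenotypeCounts) -> float:
    a, b = case.n_minor_alleles, case.n_major_alleles
    c, d = control.n_minor_alleles, control.n_major_alleles
    return (a * d) / (b * c)


class TestAlleleTest:
    @pytest.mark.parametrize("snp_id", list(PRINTED_ORS))
    def test_or_matches_cross_product_oracle(self, snp_id):
        case, ctrl = counts_pair(snp_id)
        res = allele_test(case, ctrl)
        assert res.or_point == pytest.approx(_oracle_or(case, ctrl), rel=1e-12)

    @pytest.mark.parametrize("snp_id", list(PRINTED_ORS))
    def test_two_decimal_or_and_ci_match_published_table(self, snp_id):
        case, ctrl = counts_pair(snp_id)
        res = allele_test(case, ctrl)
        assert trunc2(res.or_point) == PRINTED_ORS[snp_id]
        assert (trunc2(res.ci_low), trunc2(res.ci_high)) == PRINTED_CIS[snp_id]

    def test_identical_groups_give_or_one(self):
        res = allele_test(GenotypeCounts(50, 30, 20), GenotypeCounts(50, 30, 20))
        assert res.or_point == pytest.approx(1.0)
        assert res.ci_low <= 1.0 <= res.ci_high

    def test_haldane_correction_on_zero_cell(self):
        # case (10,0,0) vs control (15,5,0): corrected cross product by hand
        res = allele_test(GenotypeCounts(10, 0, 0), GenotypeCounts(15, 5, 0))
        assert "haldane_correction" in res.flags
        assert res.or_point == pytest.approx((0.5 * 35.5) / (5.5 * 20.5), rel=1e-12)

    def test_woolf_ci_matches_statsmodels(self):
        from statsmodels.stats.contingency_tables import Table2x2

        case, ctrl = counts_pair("rs12614")
        res = allele_test(case, ctrl)
        tab = Table2x2(
            np.array([[case.n_minor_alleles, case.n_major_alleles],
                      [ctrl.n_minor_alleles, ctrl.n_major_alleles]])
        )
        assert res.or_point == pytest.approx(tab.oddsratio, rel=1e-12)
        lo, hi = tab.oddsratio_confint()
        assert res.ci_low == pytest.approx(lo, rel=1e-9)
        assert res.ci_high == pytest.approx(hi, rel=1e-9)

    def test_degenerate_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            allele_test(GenotypeCounts(10, 0, 0), GenotypeCounts(20, 0, 0))


class TestFitLogistic:
    def test_balanced_null_gives_zero_coefficients(self):
        X = np.array([[1, 0], [1, 0], [1, 1], [1, 1]], dtype=float)
        fit = fit_logistic([0, 1, 0, 1], X)
        assert np.allclose(fit.beta, 0.0, atol=1e-10)

    def test_saturated_2x2_equals_cross_product_ratio(self):
        # 30 exposed cases, 10 exposed controls, 20 unexposed cases, 40 unexposed controls
        y = np.r_[np.ones(30), np.zeros(10), np.ones(20), np.zeros(40)]
        x = np.r_[np.ones(40), np.zeros(60)]
        fit = fit_logistic(y, np.column_stack([np.ones(100), x]))
        assert math.exp(fit.beta[1]) == pytest.approx(6.0, rel=1e-8)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        n = 400
        x1 = rng.binomial(2, 0.3, n).astype(float)
        x2 = rng.normal(size=n)
        eta = -0.3 + 0.5 * x1 - 0.8 * x2
        y = (rng.random(n) < expit(eta)).astype(float)
        X = np.column_stack([np.ones(n), x1, x2])
        ours = fit_logistic(y, X)
        ref = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(ours.beta, ref.params, atol=1e-7)
        np.testing.assert_allclose(ours.se, ref.bse, atol=1e-6)

    def test_log_likelihood_non_decreasing_and_gradient_small(self, rng):
        n = 300
        x = rng.binomial(2, 0.2, n).astype(float)
        y = (rng.random(n) < expit(-0.5 + 0.6 * x)).astype(float)
        X = np.column_stack([np.ones(n), x])
        fit = fit_logistic(y, X)
        path = np.array(fit.log_likelihood_path)
        assert np.all(np.diff(path) >= -1e-9)
        mu = expit(X @ fit.beta)
        assert np.linalg.norm(X.T @ (y - mu)) < 1e-6

    def test_separation_is_flagged_not_raised(self):
        y = np.r_[np.zeros(10), np.ones(10)]
        x = y.copy()
        with pytest.warns(UserWarning, match="separation"):
            fit = fit_logistic(y, np.column_stack([np.ones(20), x]))
        assert "separation" in fit.flags

    def test_constant_column_rejected(self):
        X = np.column_stack([np.ones(10), np.full(10, 2.0)])
        with pytest.raises(ValueError, match="constant"):
            fit_logistic(np.r_[np.zeros(5), np.ones(5)], X)


class TestAdditiveAssoc:
    def test_fixture_rs12614_or_near_published(self, fixture_cohort):
        # unadjusted fit on count-expanded data brackets the covariate-adjusted 0.43
        res = additive_assoc(fixture_cohort, "rs12614")
        assert 0.40 <= res.or_point <= 0.48

    def test_single_binary_predictor_equals_2x2_cross_product(self):
        from chbgrs.cohort_model import expand_counts, SnpRecord

        # dosage only 0/1 -> logistic OR must equal collapsed 2x2 cross product
        specs = [(SnpRecord(snp_id="rs1"), GenotypeCounts(60, 40, 0), GenotypeCounts(80, 20, 0))]
        ds = expand_counts(specs, 100, 100)
        res = additive_assoc(ds, "rs1")
        assert res.or_point == pytest.approx((40 * 80) / (60 * 20), rel=1e-8)

    def test_monomorphic_snp_rejected(self):
        cfg = SimulationConfig(n_case=30, n_control=30, maf=(0.2,), odds_ratio=(1.0,), seed=1)
        ds = simulate_cohort(cfg)
        ds.dosages[:, 0] = 0.0
        with pytest.raises(ValueError, match="monomorphic"):
            additive_assoc(ds, "snp01")

    def test_covariate_adjustment_runs(self):
        cfg = SimulationConfig(n_case=300, n_control=300, maf=(0.3,), odds_ratio=(1.5,), seed=3)
        ds = simulate_cohort(cfg)
        res = additive_assoc(ds, "snp01", covariates=("age", "sex"))
        assert res.or_point > 0 and 0 < res.p_value <= 1


class TestConditionalAssoc:
    def test_identical_target_and_conditioning_rejected(self, fixture_cohort):
        with pytest.raises(ValueError, match="differ"):
            conditional_assoc(fixture_cohort, "rs12614", "rs12614")

    def test_duplicate_column_flags_collinear(self):
        cfg = SimulationConfig(n_case=200, n_control=200, maf=(0.3, 0.3),
                               odds_ratio=(1.5, 1.0), seed=7)
        ds = simulate_cohort(cfg)
        ds.dosages[:, 1] = ds.dosages[:, 0]  # r^2 = 1 with the target
        res = conditional_assoc(ds, "snp01", "snp02")
        assert "collinear" in res.flags
        assert res.p_value == 1.0

    def test_independent_conditioning_preserves_marginal_or(self):
        cfg = SimulationConfig(n_case=2000, n_control=2000, maf=(0.3, 0.3),
                               odds_ratio=(0.6, 1.0), seed=11)
        ds = simulate_cohort(cfg)
        marginal = additive_assoc(ds, "snp01")
        conditional = conditional_assoc(ds, "snp01", "snp02")
        assert abs(math.log(conditional.or_point) - math.log(marginal.or_point)) < 0.05


class TestBonferroni:
    @pytest.mark.parametrize(
        "p,m,expected",
        [(5.91e-10, 40, 2.364e-8), (3.10e-6, 40, 1.24e-4), (0.5, 40, 1.0)],
    )
    def test_correction(self, p, m, expected):
        assert bonferroni(p, m) == pytest.approx(expected, rel=1e-9)

    def test_invalid_m(self):
        with pytest.raises(ValueError):
            bonferroni(0.1, 0)


class TestSplitValidate:
    def test_strong_effect_concordant_across_splits(self, fixture_cohort):
        results = split_validate(fixture_cohort, "rs12614", 0.5, n_repeats=10, seed=4)
        ors = [r.train.or_point for r in results if r.train] + [
            r.test.or_point for r in results if r.test
        ]
        assert len(ors) == 20
        assert all(o < 1 for o in ors)

    def test_fixed_seed_reproducible(self, fixture_cohort):
        a = split_validate(fixture_cohort, "rs12614", 0.5, n_repeats=3, seed=9)
        b = split_validate(fixture_cohort, "rs12614", 0.5, n_repeats=3, seed=9)
        assert [r.train.or_point for r in a] == [r.train.or_point for r in b]

    def test_invalid_fraction_rejected(self, fixture_cohort):
        with pytest.raises(ValueError):
            split_validate(fixture_cohort, "rs12614", 1.5)


def test_summarize_snp_published_mafs(fixture_cohort):
    assert round(summarize_snp(fixture_cohort, "rs12614", "control").maf, 3) == 0.112
    assert round(summarize_snp(fixture_cohort, "rs12614", "case").maf, 3) == 0.053
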