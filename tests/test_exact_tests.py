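import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pixlrt import (
    CellCounts,
    RelativeRiskModel,
    combine_z,
    exchangeability_test,
    expected_counts,
    fit_joint_model,
    parent_only_lrt,
    pix_lrt,
    ssx_lrt,
)
from pixlrt.exact_tests import LOG_RISK_CAP
from pixlrt.risk import (
    EXCHANGEABLE_PRIOR,
    admissible_cells,
    matingsum_cell_probs,
    parent_pair_probs,
    transmission_prob,
)


def cells_from(sex, mapping):
    cc = CellCounts()
    for (m, f, c), n in mapping.items():
        cc.add(m, f, c, sex, n)
    return cc


# ---------------------------------------------------------------------------
# cell-probability tables
# ---------------------------------------------------------------------------

@settings(max_examples=60, deadline=None, derandomize=True)
@given(rb=st.floats(0.01, 100), r1=st.floats(0.01, 100), r2=st.floats(0.01, 100))
def test_probability_rows_normalize_for_any_positive_risks(rb, r1, r2):
    rr = RelativeRiskModel(r_boy=rb, r_girl_het=r1, r_girl_hom=r2)
    for sex in ("boy", "girl"):
        # transmission rows: Pr(C | M, F) sums to 1 within each mating type
        by_mt = {}
        for (m, f, c) in admissible_cells(sex):
            by_mt.setdefault((m, f), 0.0)
            by_mt[(m, f)] += transmission_prob(m, f, c, sex, rr)
        assert all(abs(v - 1) < 1e-12 for v in by_mt.values())
        # mating-sum rows: Pr(M, F, C | M+F) sums to 1 within each stratum
        by_sum = {}
        for (m, f, c), p in matingsum_cell_probs(sex, rr).items():
            by_sum[m + f] = by_sum.get(m + f, 0.0) + p
        assert all(abs(v - 1) < 1e-12 for v in by_sum.values())


def test_parent_pair_probs_reduce_to_exchangeability_null_at_rr_one():
    for sex in ("boy", "girl"):
        probs = parent_pair_probs(sex, RelativeRiskModel())
        for pair, p in probs.items():
            assert p == pytest.approx(EXCHANGEABLE_PRIOR[pair], abs=1e-12)


def test_parent_pair_fitted_probabilities_match_closed_forms():
    rb, r1, r2 = 1.7, 2.3, 3.1
    boys = parent_pair_probs("boy", RelativeRiskModel(r_boy=rb))
    assert boys[(1, 0)] == pytest.approx((1 + rb) / (2 + rb))
    assert boys[(0, 1)] == pytest.approx(1 / (2 + rb))
    assert boys[(1, 1)] == pytest.approx((1 + rb) / (1 + 2 * rb))
    assert boys[(2, 0)] == pytest.approx(rb / (1 + 2 * rb))
    girls = parent_pair_probs("girl", RelativeRiskModel(r_girl_het=r1, r_girl_hom=r2))
    assert girls[(1, 0)] == pytest.approx((1 + r1) / (1 + 2 * r1))
    assert girls[(0, 1)] == pytest.approx(r1 / (1 + 2 * r1))
    assert girls[(1, 1)] == pytest.approx((r1 + r2) / (2 * r1 + r2))
    assert girls[(2, 0)] == pytest.approx(r1 / (2 * r1 + r2))


# ---------------------------------------------------------------------------
# exchangeability test
# ---------------------------------------------------------------------------

class TestExchangeability:
    def test_exact_two_thirds_split_gives_zero(self):
        res = exchangeability_test({(1, 0): 40, (0, 1): 20, (1, 1): 40, (2, 0): 20})
        assert res.lrt == pytest.approx(0.0, abs=1e-12)
        assert res.alpha1_hat == pytest.approx(0.0)
        assert res.alpha2_hat == pytest.approx(0.0)
        assert res.df == 2

    def test_even_split_matches_binomial_oracle(self):
        # independent oracle: binomial log-likelihood ratio at p0=2/3, n=100
        oracle = 2 * (50 * math.log(0.5 / (2 / 3)) + 50 * math.log(0.5 / (1 / 3)))
        res = exchangeability_test({(1, 0): 50, (0, 1): 50})
        assert res.alpha1_hat == pytest.approx(-math.log(2))
        assert res.lrt == pytest.approx(oracle)
        assert res.df == 1 and "empty_stratum_2" in res.flags

    def test_alpha_parameterization_recovers_fitted_probability(self):
        # fitted alternative probability is 2 e^a1 / (1 + 2 e^a1)
        res = exchangeability_test({(1, 0): 70, (0, 1): 30})
        a1 = res.alpha1_hat
        assert 2 * math.exp(a1) / (1 + 2 * math.exp(a1)) == pytest.approx(0.7)


# ---------------------------------------------------------------------------
# per-sex LRTs against independent oracles
# ---------------------------------------------------------------------------

class TestSsxLrt:
    def test_balanced_transmissions_give_zero(self):
        cc = cells_from("boy", {(1, 0, 1): 121.155, (1, 0, 0): 121.155})
        res = ssx_lrt(cc, "boy")
        assert res.statistic == pytest.approx(0.0, abs=1e-8)
        assert res.rr.r_boy == pytest.approx(1.0, abs=1e-4)
        assert res.sign == 1

    def test_thirty_twenty_matches_binomial_oracle(self):
        oracle = 2 * (30 * math.log(0.6 / 0.5) + 20 * math.log(0.4 / 0.5))
        cc = cells_from("boy", {(1, 0, 1): 30, (1, 0, 0): 20})
        res = ssx_lrt(cc, "boy")
        assert res.rr.r_boy == pytest.approx(1.5, rel=1e-5)
        assert res.statistic == pytest.approx(oracle, rel=1e-8)
        assert res.n_informative == 50

    def test_girls_logadditive_pools_both_het_mother_strata(self):
        # both strata have transmission odds r1 : 1 under the constraint
        cc = cells_from("girl", {(1, 0, 1): 30, (1, 0, 0): 10,
                                 (1, 1, 2): 15, (1, 1, 1): 5})
        res = ssx_lrt(cc, "girl")
        assert res.rr.r_girl_het == pytest.approx(3.0, rel=1e-5)
        oracle = 2 * (45 * math.log(0.75 / 0.5) + 15 * math.log(0.25 / 0.5))
        assert res.statistic == pytest.approx(oracle, rel=1e-8)

    def test_no_informative_families_flagged(self):
        cc = cells_from("boy", {(0, 0, 0): 50})
        res = ssx_lrt(cc, "boy")
        assert math.isnan(res.statistic)
        assert "no_informative_families" in res.flags


class TestParentOnlyLrt:
    def test_null_proportions_give_zero(self):
        cc = cells_from("boy", {(1, 0, 0): 40, (0, 1, 0): 20,
                                (1, 1, 0): 40, (2, 0, 1): 20})
        res = parent_only_lrt(cc, "boy")
        assert res.statistic == pytest.approx(0.0, abs=1e-8)

    def test_single_stratum_mle_solves_score_equation(self):
        # mothers 80 vs fathers 20 in M+F=1: (1+R)/(2+R) = 0.8 -> R = 3
        res = parent_only_lrt({(1, 0): 80, (0, 1): 20}, "boy")
        assert res.rr.r_boy == pytest.approx(3.0, rel=1e-5)
        assert res.n_informative == 100

    def test_child_genotype_is_ignored(self):
        a = cells_from("boy", {(1, 0, 1): 50, (0, 1, 0): 20})
        b = cells_from("boy", {(1, 0, 0): 50, (0, 1, 0): 20})
        ra, rb = parent_only_lrt(a, "boy"), parent_only_lrt(b, "boy")
        assert ra.statistic == pytest.approx(rb.statistic)


class TestPixLrt:
    def test_uniform_thirds_give_zero(self):
        cc = cells_from("boy", {(0, 1, 0): 10, (1, 0, 0): 10, (1, 0, 1): 10,
                                (1, 1, 0): 7, (1, 1, 1): 7, (2, 0, 1): 7})
        res = pix_lrt(cc, "boy")
        assert res.statistic == pytest.approx(0.0, abs=1e-8)
        assert res.rr.r_boy == pytest.approx(1.0, abs=1e-4)

    def test_counts_more_informative_families_than_ssx(self):
        cc = cells_from("boy", {(1, 0, 1): 10, (0, 1, 0): 5, (2, 0, 1): 3,
                                (0, 0, 0): 7})
        assert pix_lrt(cc, "boy").n_informative == 18
        assert ssx_lrt(cc, "boy").n_informative == 10


def _grid_mle(loglik, lo=0.01, hi=100.0, n=1000):
    """Brute-force grid maximizer over R with one refinement pass."""
    grid = np.exp(np.linspace(math.log(lo), math.log(hi), n))
    vals = [loglik(r) for r in grid]
    i = int(np.argmax(vals))
    lo2 = grid[max(0, i - 1)]
    hi2 = grid[min(n - 1, i + 1)]
    grid2 = np.exp(np.linspace(math.log(lo2), math.log(hi2), n))
    vals2 = [loglik(r) for r in grid2]
    j = int(np.argmax(vals2))
    return grid2[j], vals2[j]


@pytest.mark.parametrize("method", ["ssx", "pix", "parent_only"])
def test_numeric_mle_agrees_with_grid_search_on_random_tables(method, rng):
    """The bounded 1-d maximizer matches an independent grid-search oracle."""
    fn = {"ssx": ssx_lrt, "pix": pix_lrt, "parent_only": parent_only_lrt}[method]
    n_checked = 0
    while n_checked < 50:
        sex = "boy" if rng.random() < 0.5 else "girl"
        counts = {cell: int(rng.integers(0, 20)) for cell in admissible_cells(sex)}
        cc = cells_from(sex, {k: v for k, v in counts.items() if v})
        res = fn(cc, sex, "logadditive_girls")
        if math.isnan(res.statistic) or "boundary" in res.flags:
            continue
        n_checked += 1

        def loglik(r):
            rr = (RelativeRiskModel(r_boy=r) if sex == "boy"
                  else RelativeRiskModel.logadditive(r))
            if method == "ssx":
                return sum(n * math.log(transmission_prob(m, f, c, sex, rr))
                           for (m, f, c), n in cc.sex_cells(sex).items() if n)
            if method == "pix":
                probs = matingsum_cell_probs(sex, rr)
                return sum(n * math.log(probs[k])
                           for k, n in cc.sex_cells(sex).items() if n)
            probs = parent_pair_probs(sex, rr)
            return sum(n * math.log(probs[k])
                       for k, n in cc.parent_margins(sex).items() if n)

        r_grid, ll_grid = _grid_mle(loglik)
        r_hat = res.rr.r_boy if sex == "boy" else res.rr.r_girl_het
        assert res.loglik_full >= ll_grid - 1e-9
        assert r_hat == pytest.approx(r_grid, rel=5e-3)


def test_lrt_nonnegative_and_mle_at_least_null(rng):
    for _ in range(20):
        counts = {cell: int(rng.integers(0, 30)) for cell in admissible_cells("boy")}
        cc = cells_from("boy", {k: v for k, v in counts.items() if v})
        res = pix_lrt(cc, "boy")
        if math.isnan(res.statistic):
            continue
        assert res.statistic >= 0
        assert res.loglik_full >= res.loglik_null - 1e-12


# ---------------------------------------------------------------------------
# combined Z
# ---------------------------------------------------------------------------

class TestCombineZ:
    def _res(self, sex, x, n, sign):
        from pixlrt.exact_tests import SexTestResult
        from pixlrt.risk import NULL_RR
        return SexTestResult("pix", sex, x, 1, sign, n, NULL_RR, 0.5, 0.0, 0.0)

    def test_both_zero_gives_zero(self):
        res = combine_z(self._res("boy", 0, 10, 1), self._res("girl", 0, 5, 1))
        assert res.z == 0.0

    def test_direct_formula_evaluation(self):
        res = combine_z(self._res("boy", 4, 300, 1), self._res("girl", 1, 100, 1))
        assert res.z == pytest.approx((math.sqrt(1200) + math.sqrt(100)) / math.sqrt(400))

    def test_single_sex_degeneracy(self):
        res = combine_z(self._res("boy", 4, 300, -1), None)
        assert res.z == pytest.approx(-2.0)

    def test_requires_one_df_inputs(self):
        bad = self._res("girl", 4, 100, 1)
        bad.df = 2
        with pytest.raises(ValueError, match="1-df"):
            combine_z(self._res("boy", 4, 300, 1), bad)

    def test_no_information_flagged(self):
        res = combine_z(self._res("boy", 4, 0, 1), None)
        assert math.isnan(res.z) and "undefined" in res.flags


def test_ssx_and_parent_only_signed_roots_independent_under_null(rng):
    """On null data the transmission and parent-only components are
    statistically independent: their signed roots are uncorrelated."""
    from pixlrt import PopulationScenario, SimSpec, Subpopulation, sample_triads, tabulate

    scen = PopulationScenario(
        subpops=(Subpopulation(1.0, 0.3, 0.1, 0.1),),
        rr=RelativeRiskModel(), n_families=150, sex_design="boys_only")
    reps = 300
    datasets = sample_triads(SimSpec(scenario=scen, seed=991, n_snps=reps))
    zs, zp = [], []
    for ds in datasets:
        cc = tabulate(ds.records)
        a = ssx_lrt(cc, "boy")
        b = parent_only_lrt(cc, "boy")
        zs.append(a.sign * math.sqrt(a.statistic))
        zp.append(b.sign * math.sqrt(b.statistic))
    corr = np.corrcoef(zs, zp)[0, 1]
    assert abs(corr) < 3 / math.sqrt(reps)


# ---------------------------------------------------------------------------
# pooled constrained fits
# ---------------------------------------------------------------------------

class TestJointModel:
    def test_identical_null_proportions_give_zero(self, null_scenario):
        cc = expected_counts(null_scenario)
        for hyp in ("xinactivation", "joint_logadditive", "xinactivation_null"):
            fit = fit_joint_model(cc, hyp)
            assert fit.lrt == pytest.approx(0.0, abs=1e-6)

    def test_joint_logadditive_recovers_truth_on_expected_counts(self):
        from pixlrt import PopulationScenario, Subpopulation
        scen = PopulationScenario(
            subpops=(Subpopulation(1.0, 0.3, 0.01, 0.01),),
            rr=RelativeRiskModel(r_boy=4.0, r_girl_het=2.0, r_girl_hom=4.0,
                                 mode="joint_logadditive"),
            n_families=1000, sex_design="both_proportional")
        fit = fit_joint_model(expected_counts(scen), "joint_logadditive")
        assert math.log(fit.rr.r_girl_het) == pytest.approx(math.log(2.0), abs=1e-4)
        assert fit.rr.r_boy == pytest.approx(4.0, rel=1e-3)
        assert fit.df == 1

    def test_null_calibration_of_joint_logadditive(self, rng):
        """Under a true global null the 1-df LRT has mean ~1 over replicates."""
        from pixlrt import PopulationScenario, SimSpec, Subpopulation, sample_triads, tabulate
        scen = PopulationScenario(
            subpops=(Subpopulation(1.0, 0.3, 0.1, 0.1),),
            rr=RelativeRiskModel(mode="joint_logadditive"),
            n_families=200, sex_design="both_proportional")
        stats = []
        for ds in sample_triads(SimSpec(scenario=scen, seed=17, n_snps=150)):
            stats.append(fit_joint_model(tabulate(ds.records), "joint_logadditive").lrt)
        # mean of chi2(1) is 1; se ~ sqrt(2/150)
        assert np.mean(stats) == pytest.approx(1.0, abs=4 * math.sqrt(2 / 150))

    def test_unknown_hypothesis_rejected(self, null_scenario):
        with pytest.raises(ValueError, match="hypothesis"):
            fit_joint_model(expected_counts(null_scenario), "recessive")
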