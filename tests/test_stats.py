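"""Statistics battery vs independent oracles (enumeration, closed form,
Monte Carlo, scipy cross-checks)."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from ctcscope import (
    CartridgeError,
    bin_counts,
    bin_ctc,
    bin_tdev,
    chi2_2x2,
    cohort_report,
    mann_whitney,
    paired_t,
    simulate_cohort,
    spearman,
)
from ctcscope.synthetic import STAGE_CNPC, STAGE_CRPC, TIMEPOINT_BASELINE


def exact_mw_p(a, b, mid_p=False):
    """Independent enumeration oracle: permutation distribution of U.

    ``mid_p=True`` counts half of the probability mass at the observed U
    (the discrete counterpart of an uncorrected normal approximation).
    """
    a, b = list(a), list(b)
    pooled = np.array(a + b, dtype=float)
    ranks = sps.rankdata(pooled)
    n_a, n = len(a), len(pooled)
    u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2
    us = np.array(
        [
            ranks[list(idx)].sum() - n_a * (n_a + 1) / 2
            for idx in combinations(range(n), n_a)
        ]
    )
    eps = 1e-9
    atom = (np.abs(us - u_obs) <= eps).mean()
    lo = (us <= u_obs + eps).mean()
    hi = (us >= u_obs - eps).mean()
    if mid_p:
        lo, hi = lo - atom / 2, hi - atom / 2
    return min(1.0, 2 * min(lo, hi))


class TestMannWhitney:
    def test_identical_samples_degenerate(self):
        r = mann_whitney([3, 3, 3], [3, 3])
        assert r.p_two_sided == 1.0 and r.degenerate
        assert r.mean_rank_a == r.mean_rank_b

    def test_symmetric_samples_equal_mean_ranks(self):
        r = mann_whitney([1, 2, 3, 4], [4, 3, 2, 1])
        assert r.mean_rank_a == pytest.approx(r.mean_rank_b)
        assert r.p_two_sided == pytest.approx(1.0)

    def test_separated_pairs_exact_third(self):
        r = mann_whitney([1, 2], [3, 4])
        assert r.U == 0
        assert r.method == "exact"
        assert r.p_two_sided == pytest.approx(1 / 3)

    def test_exact_branch_matches_enumeration_oracle(self, rng):
        for _ in range(25):
            n_a = int(rng.integers(2, 9))
            n_b = int(rng.integers(2, 9))
            a = rng.integers(0, 6, n_a)  # ties likely
            b = rng.integers(0, 6, n_b)
            if len(set(a.tolist() + b.tolist())) == 1:
                continue
            r = mann_whitney(a, b)
            assert r.method == "exact"
            assert r.p_two_sided == pytest.approx(exact_mw_p(a, b))

    def test_normal_approximation_close_to_exact(self, rng):
        """The uncorrected normal p tracks the enumeration mid-p at n=6,7
        and never exceeds the conservative (inclusive) exact p by much."""
        for _ in range(10):
            a = rng.normal(0, 1, 6)
            b = rng.normal(0.5, 1, 7)
            r = mann_whitney(a, b, method="normal")
            assert abs(r.p_two_sided - exact_mw_p(a, b, mid_p=True)) <= 0.05
            assert r.p_two_sided <= exact_mw_p(a, b) + 0.02

    def test_scipy_cross_check_large_samples(self, rng):
        a = rng.normal(0, 1, 40)
        b = rng.normal(0.6, 1, 35)
        r = mann_whitney(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic", use_continuity=False)
        assert r.U == pytest.approx(ref.statistic)
        assert r.p_two_sided == pytest.approx(ref.pvalue, rel=1e-6)

    @settings(max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 30, 12).astype(float)
        b = rng.integers(0, 30, 15).astype(float)
        r1 = mann_whitney(a, b)
        r2 = mann_whitney(np.exp(a / 10), np.exp(b / 10))
        assert r1.p_two_sided == pytest.approx(r2.p_two_sided)

    def test_empty_sample_rejected(self):
        with pytest.raises(CartridgeError):
            mann_whitney([], [1, 2])


class TestSpearman:
    def test_perfect_and_reversed(self, rng):
        x = rng.normal(size=10)
        assert spearman(x, x).rho == pytest.approx(1.0)
        order = np.sort(x)
        assert spearman(order, order[::-1]).rho == pytest.approx(-1.0)

    def test_matches_rank_difference_formula_tie_free(self, rng):
        for _ in range(10):
            x = rng.permutation(9).astype(float)
            y = rng.normal(size=9)
            while len(set(y)) < 9:  # pragma: no cover
                y = rng.normal(size=9)
            d = sps.rankdata(x) - sps.rankdata(y)
            n = len(x)
            rho_formula = 1 - 6 * (d**2).sum() / (n * (n**2 - 1))
            assert spearman(x, y).rho == pytest.approx(rho_formula)

    def test_scipy_cross_check_with_ties(self, rng):
        x = rng.integers(0, 5, 30).astype(float)
        y = x + rng.integers(0, 3, 30)
        r = spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert r.rho == pytest.approx(ref.statistic)
        assert r.p_two_sided == pytest.approx(ref.pvalue, rel=1e-6)

    def test_constant_input_degenerate(self):
        r = spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert r.degenerate and math.isnan(r.rho)

    @settings(max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_bounded_and_transform_invariant(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        r = spearman(x, y)
        assert -1 <= r.rho <= 1
        r2 = spearman(np.expm1(x), y**3)
        # expm1 is increasing; cube is increasing
        assert r2.rho == pytest.approx(r.rho)


class TestChi2:
    def test_published_ctc_presence_table(self):
        """CTC-positive/negative by stage: 56/48 vs 48/18 -> p = 0.014."""
        r = chi2_2x2([[56, 48], [48, 18]])
        assert r.df == 1
        assert round(r.p, 3) == 0.014

    def test_balanced_table_is_null(self):
        r = chi2_2x2([[10, 10], [10, 10]])
        assert r.chi2 == 0.0 and r.p == pytest.approx(1.0)

    def test_invariant_under_row_and_column_swap(self):
        t = np.array([[9, 3], [4, 11]])
        r1 = chi2_2x2(t)
        r2 = chi2_2x2(t[::-1, ::-1])
        assert r1.chi2 == pytest.approx(r2.chi2)

    def test_expected_counts_returned(self):
        r = chi2_2x2([[56, 48], [48, 18]])
        assert r.expected.sum() == pytest.approx(170)

    def test_zero_margin_rejected(self):
        with pytest.raises(CartridgeError, match="margin"):
            chi2_2x2([[0, 0], [3, 4]])

    def test_monte_carlo_null_agreement_small_tables(self, rng):
        """Pearson p within 0.02 of a multinomial resampling null.

        Tables are drawn in the regime where the chi-square approximation
        is applicable (all expected counts >= 8); the Monte-Carlo p uses
        the mid-p tie convention, the discrete counterpart of the
        continuous tail probability.
        """
        n_draws = 100_000
        checked = 0
        while checked < 4:
            t = rng.integers(2, 26, size=(2, 2))
            total = t.sum()
            exp = np.outer(t.sum(axis=1), t.sum(axis=0)) / total
            if not (30 <= total <= 80) or exp.min() < 8:
                continue
            checked += 1
            r = chi2_2x2(t)
            p_row = t.sum(axis=1) / total
            p_col = t.sum(axis=0) / total
            probs = np.outer(p_row, p_col).ravel()
            sims = rng.multinomial(total, probs, size=n_draws).reshape(
                n_draws, 2, 2
            )
            row = sims.sum(axis=2, keepdims=True)
            col = sims.sum(axis=1, keepdims=True)
            with np.errstate(divide="ignore", invalid="ignore"):
                e = row * col / total
                stat = np.where(e > 0, (sims - e) ** 2 / e, 0.0).sum((1, 2))
            p_hi = float((stat >= r.chi2 - 1e-9).mean())
            p_strict = float((stat > r.chi2 + 1e-9).mean())
            p_mc = p_strict + 0.5 * (p_hi - p_strict)
            assert abs(r.p - p_mc) <= 0.02


class TestPairedT:
    def test_no_change_is_null(self):
        pre = [4, 8, 15, 16]
        r = paired_t(pre, pre)
        assert r.t == 0.0 and r.p_two_sided == 1.0 and r.degenerate

    def test_hand_computed_statistic(self):
        r = paired_t([0, 0, 0], [1, 2, 3])
        assert r.t == pytest.approx(2 * math.sqrt(3))
        assert r.df == 2

    def test_scipy_cross_check(self, rng):
        pre = rng.poisson(10, 20).astype(float)
        post = pre * 0.4 + rng.normal(0, 1, 20)
        r = paired_t(pre, post)
        ref = sps.ttest_rel(post, pre)
        assert r.t == pytest.approx(ref.statistic)
        assert r.p_two_sided == pytest.approx(ref.pvalue)

    def test_simulated_post_adt_decline_detected(self):
        """Default decline model: paired p < 0.05 at n = 31 in most seeds
        (full 100-seed sweep in the acceptance suite)."""
        sig = 0
        for seed in range(20):
            t = simulate_cohort(n_per_stage=40, seed=seed, n_paired=31)
            base = t[t["timepoint"] == TIMEPOINT_BASELINE].set_index(
                "patient_id"
            )
            post = t[t["timepoint"] == "POST_ADT_6M"].set_index("patient_id")
            pre = base.loc[post.index]
            r = paired_t(pre["ctc"], post["ctc"])
            sig += r.p_two_sided < 0.05
        assert sig >= 16


class TestBinning:
    def test_ctc_boundaries(self):
        cats = bin_ctc([0, 1, 4, 5, 17]).tolist()
        assert cats == ["0", "1-4", "1-4", ">=5", ">=5"]

    def test_tdev_boundary_50_in_lower_bin(self):
        assert bin_tdev([50]).tolist() == ["<=50"]
        assert bin_tdev([51]).tolist() == [">50"]

    def test_cross_tabulations_shapes(self):
        t = simulate_cohort(n_per_stage=100, seed=0)
        tables = bin_counts(t)
        assert tables["ctc_presence"].shape == (2, 2)
        assert tables["tdev_bins"].shape == (2, 2)
        assert tables["ctc_bins"].to_numpy().sum() == 200


class TestCohortReport:
    def test_empty_table_rejected(self):
        with pytest.raises(CartridgeError):
            cohort_report(pd.DataFrame())

    def test_single_stage_descriptives_only(self):
        t = simulate_cohort(n_per_stage=30, seed=0)
        t = t[t["stage"] == STAGE_CNPC]
        rep = cohort_report(t)
        assert (rep.descriptives["stage"] == STAGE_CNPC).all()
        assert not (rep.tests["test"] == "mann_whitney").any()

    def test_full_battery_and_direction(self):
        t = simulate_cohort(n_per_stage=500, seed=5, n_paired=31)
        rep = cohort_report(t)
        med = rep.descriptives.set_index(["stage", "marker"])["median"]
        assert med[(STAGE_CRPC, "ctc")] > med[(STAGE_CNPC, "ctc")]
        tests = set(rep.tests["test"])
        assert {"mann_whitney", "chi2_ctc_presence", "chi2_tdev_le50",
                "spearman_ctc_tdev", "paired_t_post_adt"} <= tests
        assert "## Tests" in rep.markdown
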