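import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dtiphantom.agreement import (
    bland_altman,
    bootstrap_cv_ci,
    bootstrap_diff,
    ci_overlap_significant,
    cv_percent,
    exact_rank_sum,
    grouped_cv,
)
from dtiphantom.agreement import test_battery as battery


def md_table(rows):
    """rows: (site, seq, scan, tube, md)."""
    return pd.DataFrame(
        [
            {"site": s, "sequence_class": q, "scan": m, "tube": j, "metric": "MD", "roi_mean": v}
            for s, q, m, j, v in rows
        ]
    )


class TestBlandAltman:
    def test_identical_pairs_degenerate(self):
        res = bland_altman([(1.0, 1.0), (2.0, 2.0)])
        assert res.mean_diff == 0.0
        assert res.loa_low == res.loa_high == 0.0
        assert np.isnan(res.regression_r2)

    def test_constant_offset(self):
        res = bland_altman([(1.0, 1.5), (2.0, 2.5), (3.0, 3.5)])
        assert res.mean_diff == pytest.approx(0.5)
        assert res.loa_high - res.loa_low == pytest.approx(0.0, abs=1e-12)

    def test_hand_arithmetic(self):
        res = bland_altman([(1.0, 2.0), (3.0, 3.0), (5.0, 4.0)])
        assert res.mean_diff == pytest.approx(0.0)
        assert res.loa_low == pytest.approx(-1.96)
        assert res.loa_high == pytest.approx(1.96)

    def test_swap_flips_mean_keeps_width(self):
        pairs = [(1.0, 2.2), (3.0, 2.9), (5.5, 4.0), (2.0, 2.4)]
        fwd = bland_altman(pairs)
        rev = bland_altman([(b, a) for a, b in pairs])
        assert fwd.mean_diff == pytest.approx(-rev.mean_diff)
        assert (fwd.loa_high - fwd.loa_low) == pytest.approx(rev.loa_high - rev.loa_low)

    def test_needs_two_pairs(self):
        with pytest.raises(ValueError):
            bland_altman([(1.0, 2.0)])


class TestBootstrap:
    def test_constant_differences(self):
        res = bootstrap_diff([0.4] * 5, n=200, seed=0)
        assert res.median == res.ci_low == res.ci_high == pytest.approx(0.4)

    def test_invariant_ci_contains_median(self):
        rng = np.random.default_rng(0)
        for seed in range(5):
            res = bootstrap_diff(rng.normal(size=12), n=500, seed=seed)
            assert res.ci_low <= res.median <= res.ci_high

    def test_disjoint_cis_significant(self):
        a = bootstrap_diff([0.0, 0.1, -0.1, 0.05], seed=0)
        b = bootstrap_diff([2.0, 2.1, 1.9, 2.05], seed=0)
        assert ci_overlap_significant(a, b)
        assert not ci_overlap_significant(a, a)

    def test_coverage_of_zero_mean(self):
        """The percentile CI covers the true mean (0) in >= 90% of trials."""
        rng = np.random.default_rng(123)
        hits = 0
        for seed in range(50):
            diffs = rng.normal(0.0, 1.0, size=100)
            res = bootstrap_diff(diffs, n=400, seed=seed)
            hits += res.ci_low <= 0.0 <= res.ci_high
        assert hits >= 45

    def test_ci_narrows_with_more_data(self):
        """Expected CI width shrinks as the number of differences grows."""
        rng = np.random.default_rng(5)
        widths = []
        for size in (8, 32, 128):
            w = []
            for seed in range(10):
                res = bootstrap_diff(rng.normal(size=size), n=400, seed=seed)
                w.append(res.ci_high - res.ci_low)
            widths.append(np.mean(w))
        assert widths[0] > widths[1] > widths[2]

    def test_deterministic_under_seed(self):
        d = [0.1, -0.2, 0.3, 0.0, 0.05]
        assert bootstrap_diff(d, seed=9) == bootstrap_diff(d, seed=9)


class TestGroupedCV:
    def test_identical_values_zero(self):
        qa = md_table([("A", "PGSE", 1, 1, 1.0e-3), ("A", "PGSE", 2, 1, 1.0e-3)])
        res = grouped_cv(qa, "scans")
        assert res.cv_pct == 0.0

    def test_site_means_hand_value(self):
        qa = md_table(
            [(s, "PGSE", 1, 1, v) for s, v in zip("ABC", (1.0e-3, 1.1e-3, 0.9e-3))]
        )
        res = grouped_cv(qa, "sites", context="PGSE")
        assert res.cv_pct == pytest.approx(10.0)

    def test_rescaling_invariance(self):
        rows = [(s, "PGSE", 1, 1, v) for s, v in zip("ABCD", (1.0, 1.2, 0.8, 1.1))]
        a = grouped_cv(md_table(rows), "sites", context="PGSE")
        rows2 = [(s, q, m, j, 7.5 * v) for s, q, m, j, v in rows]
        b = grouped_cv(md_table(rows2), "sites", context="PGSE")
        assert a.cv_pct == pytest.approx(b.cv_pct)

    def test_injected_scatter_recovered_exactly(self):
        """Deterministic site biases produce exactly their sample CV."""
        biases = np.array([0.01, -0.02, 0.03, 0.0, -0.015])
        base = 1.05e-3
        qa = md_table(
            [(f"S{i}", "PGSE", 1, 1, base * (1 + b)) for i, b in enumerate(biases)]
        )
        expected = np.std(1 + biases, ddof=1) / np.mean(1 + biases) * 100.0
        res = grouped_cv(qa, "sites", context="PGSE")
        assert res.cv_pct == pytest.approx(expected, abs=1e-9)

    def test_sequence_pair_same_site(self):
        qa = md_table(
            [("A", "PGSE", 1, 1, 1.0e-3), ("A", "SE", 1, 1, 1.1e-3)]
        )
        res = grouped_cv(qa, "sequences", context=("PGSE", "SE"))
        expected = cv_percent(np.array([1.0e-3, 1.1e-3]))
        assert res.cv_pct == pytest.approx(expected)

    def test_disjoint_sequence_groups_pooled(self):
        qa = md_table(
            [("A", "SE", 1, 1, 1.0e-3), ("B", "STEAM", 1, 1, 1.1e-3), ("C", "SE", 1, 1, 0.9e-3)]
        )
        res = grouped_cv(qa, "sequences", context=("SE", "STEAM"))
        expected = cv_percent(np.array([1.0e-3, 1.1e-3, 0.9e-3]))
        assert res.cv_pct == pytest.approx(expected)

    def test_small_group_skipped_with_warning(self):
        qa = md_table([("A", "PGSE", 1, 1, 1.0e-3)])
        with pytest.warns(UserWarning):
            res = grouped_cv(qa, "scans")
        assert res.n_groups == 0


class TestTestBattery:
    def test_one_sample_t_on_reference(self):
        res = battery([1.0, 1.0, 1.0], "one_sample_t", reference=1.0)
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_one_sample_t_matches_scipy(self):
        x = [1.01, 0.98, 1.05, 1.02]
        res = battery(x, "one_sample_t", reference=1.0)
        ref = stats.ttest_1samp(x, 1.0)
        assert res.pvalue == pytest.approx(ref.pvalue)

    def test_rank_sum_identical_groups(self):
        res = battery([1.0, 1.0, 1.0], "rank_sum", other=[1.0, 1.0, 1.0])
        assert res.pvalue == 1.0

    def test_rank_sum_separated_groups_exact(self):
        # only 2 of the C(6,3)=20 rank assignments are this extreme
        res = battery([1.0, 2.0, 3.0], "rank_sum", other=[4.0, 5.0, 6.0])
        assert res.pvalue == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_exact_rank_sum_matches_scipy_exact(self, seed):
        """For tie-free samples the enumeration agrees with the independent
        exact distribution."""
        rng = np.random.default_rng(seed)
        x = rng.normal(size=5)
        y = rng.normal(0.5, size=6)
        ours = exact_rank_sum(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert ours.pvalue == pytest.approx(ref.pvalue, abs=1e-12)

    def test_rank_sum_large_n_normal_approx(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        res = battery(x, "rank_sum", other=y)
        ref = stats.ranksums(x, y)
        assert res.mode == "rank_sum_normal"
        assert res.pvalue == pytest.approx(ref.pvalue, abs=1e-9)

    def test_welch_t_matches_scipy(self):
        x = [1.0, 1.2, 0.9, 1.1]
        y = [2.0, 2.5, 1.5, 2.2, 1.9]
        res = battery(x, "welch_t", other=y)
        ref = stats.ttest_ind(x, y, equal_var=False)
        assert res.pvalue == pytest.approx(ref.pvalue)

    def test_shapiro_on_normal_sample(self):
        rng = np.random.default_rng(1)
        res = battery(rng.normal(size=30), "shapiro_wilk")
        assert 0.0 < res.pvalue <= 1.0

    def test_ci_overlap_rule_is_conservative(self):
        """Type-I error of the disjoint-CI rule on identical distributions
        stays below 5%."""
        rng = np.random.default_rng(77)
        false_pos = 0
        trials = 100
        for t in range(trials):
            a = bootstrap_diff(rng.normal(size=10), n=300, seed=2 * t)
            b = bootstrap_diff(rng.normal(size=10), n=300, seed=2 * t + 1)
            false_pos += ci_overlap_significant(a, b)
        assert false_pos / trials < 0.05


class TestBootstrapCvCi:
    def test_ci_brackets_point_estimate(self):
        values = np.array([1.0, 1.02, 0.97, 1.05, 0.99])
        res = bootstrap_cv_ci(values, n=500, seed=0)
        assert res.ci_low <= res.median <= res.ci_high
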