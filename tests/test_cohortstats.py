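"""Normality checks, rank/t tests and the multi-study Bonferroni scan."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from prskit.cohortstats import (
    GroupedScores,
    bonferroni_alpha,
    group_scores,
    ks_normality,
    mann_whitney,
    read_labels,
    scan_studies,
    threshold_labels,
    welch_t,
)


class TestKSNormality:
    def test_statistic_matches_bruteforce_cdf_gap_maximization(self):
        # D maximized over the 2n candidate gaps between the empirical step
        # function and the fitted normal CDF, computed independently here
        x = np.array([1.0, 2.0, 3.0, 4.0, 10.0])
        m, s = x.mean(), x.std(ddof=1)
        cdf = stats.norm.cdf(np.sort(x), m, s)
        n = len(x)
        brute_d = max(
            max((i + 1) / n - cdf[i], cdf[i] - i / n) for i in range(n)
        )
        d, p = ks_normality(x)
        assert d == pytest.approx(brute_d, abs=1e-12)
        assert 0 < p <= 1

    def test_constant_sample_is_non_normal(self):
        with pytest.warns(UserWarning):
            d, p = ks_normality([2.0] * 10)
        assert (d, p) == (1.0, 0.0)

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_normality([1.0, 2.0])

    def test_normal_draws_rarely_rejected(self):
        # fitted-parameter KS without small-sample correction is
        # conservative, so well above 90% of normal draws should pass
        hits = 0
        for seed in range(100):
            x = np.random.default_rng(seed).normal(1.0, 0.2, size=500)
            _, p = ks_normality(x)
            hits += p > 0.05
        assert hits >= 90


def exact_mwu_oracle(a, b):
    """Two-sided exact Mann-Whitney p by full labeling enumeration."""
    a, b = list(a), list(b)
    combined = a + b
    n_a = len(a)

    def u_stat(xs, ys):
        return sum(
            1.0 if x > y else 0.5 if x == y else 0.0
            for x in xs for y in ys
        )

    u_obs = u_stat(a, b)
    us = [
        u_stat([combined[i] for i in subset],
               [combined[i] for i in range(len(combined)) if i not in subset])
        for subset in map(set, itertools.combinations(range(len(combined)), n_a))
    ]
    n_le = sum(u <= u_obs + 1e-9 for u in us)
    n_ge = sum(u >= u_obs - 1e-9 for u in us)
    return u_obs, min(1.0, 2.0 * min(n_le, n_ge) / len(us))


class TestMannWhitney:
    def test_fully_separated_groups_exact_p(self):
        # U = 0; only 2 of the C(6,3)=20 labelings are as extreme
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_groups_u_is_half_product(self):
        u, _ = mann_whitney([1, 2, 3], [1, 2, 3])
        assert u == pytest.approx(4.5)

    def test_random_4v4_matches_enumeration(self):
        rng = np.random.default_rng(17)
        a, b = rng.normal(size=4), rng.normal(1.0, 1.0, size=4)
        u, p = mann_whitney(a, b)
        u_oracle, p_oracle = exact_mwu_oracle(a, b)
        assert u == pytest.approx(u_oracle)
        assert p == pytest.approx(p_oracle)

    @settings(max_examples=60, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_u_complements_sum_to_product(self, seed):
        rng = np.random.default_rng(seed)
        n_a, n_b = int(rng.integers(1, 15)), int(rng.integers(1, 15))
        vals = rng.choice([0.0, 0.5, 1.0, 2.0, 3.0], size=n_a + n_b)
        a, b = vals[:n_a], vals[n_a:]
        u_a, _ = mann_whitney(a, b)
        u_b, _ = mann_whitney(b, a)
        assert u_a + u_b == pytest.approx(n_a * n_b)

    def test_asymptotic_path_matches_scipy(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=30)
        b = rng.normal(0.5, 1.0, size=25)
        u, p = mann_whitney(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
        assert u == pytest.approx(float(ref.statistic))
        assert p == pytest.approx(float(ref.pvalue), rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestWelchT:
    def test_identical_groups(self):
        t, p, _ = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, p) == (0.0, 1.0)

    def test_hand_computed_example(self):
        # means 2 vs 3, each variance 1 with n=3: t = -1/sqrt(2/3), df = 4
        t, p, df = welch_t([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-1.224744871391589, rel=1e-12)
        assert df == pytest.approx(4.0)
        assert p == pytest.approx(0.28786413472669053, rel=1e-9)

    def test_matches_scipy(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(size=12), rng.normal(0.3, 2.0, size=20)
        t, p, _ = welch_t(a, b)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(float(ref.statistic), rel=1e-12)
        assert p == pytest.approx(float(ref.pvalue), rel=1e-9)

    def test_location_shift_increases_magnitude(self):
        a = [1.0, 2.0, 3.0, 4.0]
        b = [1.5, 2.5, 3.5, 4.5]
        t1, _, _ = welch_t(a, b)
        t2, _, _ = welch_t(a, [x + 1.0 for x in b])
        assert abs(t2) > abs(t1)

    def test_both_constant_equal_is_null(self):
        t, p, _ = welch_t([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)


def _grouped(study_id, a, b):
    return GroupedScores(study_id, "t", np.asarray(a, float), np.asarray(b, float))


class TestScan:
    def test_bonferroni_arithmetic(self):
        assert bonferroni_alpha(0.05, 10) == pytest.approx(0.005)

    def test_five_comparisons_give_adjusted_alpha_0_01(self):
        assert bonferroni_alpha(0.05, 5) == pytest.approx(0.01)
        grouped = [_grouped(f"S{i}", [1, 2, 3], [4, 5, 6]) for i in range(5)]
        results = scan_studies(grouped, family_alpha=0.05)
        assert all(r.adjusted_alpha == pytest.approx(0.01) for r in results)

    def test_significance_flag_consistent_and_sorted(self):
        rng = np.random.default_rng(2)
        grouped = [
            _grouped("null", rng.normal(size=20), rng.normal(size=20)),
            _grouped("shifted", rng.normal(size=20), rng.normal(2.0, 1.0, size=20)),
        ]
        results = scan_studies(grouped)
        assert [r.p_value for r in results] == sorted(r.p_value for r in results)
        for r in results:
            assert r.significant == (r.p_value < r.adjusted_alpha)
        assert results[0].study_id == "shifted" and results[0].significant

    def test_order_invariance(self):
        rng = np.random.default_rng(4)
        grouped = [_grouped(f"S{i}", rng.normal(size=10), rng.normal(size=10))
                   for i in range(6)]
        r1 = scan_studies(grouped)
        r2 = scan_studies(list(reversed(grouped)))
        assert [(r.study_id, r.significant) for r in r1] == \
               [(r.study_id, r.significant) for r in r2]

    def test_small_group_skipped_with_warning_and_excluded_from_divisor(self):
        grouped = [_grouped("ok", [1, 2, 3], [4, 5, 6]),
                   _grouped("tiny", [1.0], [2.0, 3.0])]
        with pytest.warns(UserWarning, match="tiny"):
            results = scan_studies(grouped, family_alpha=0.05)
        assert [r.study_id for r in results] == ["ok"]
        assert results[0].adjusted_alpha == pytest.approx(0.05)

    def test_permuted_labels_control_false_positives(self):
        # under the null, unadjusted rejections track alpha and
        # Bonferroni-adjusted rejections nearly vanish
        rng = np.random.default_rng(12)
        n_studies = 200
        grouped = [_grouped(f"S{i:03d}", rng.normal(size=25), rng.normal(size=25))
                   for i in range(n_studies)]
        results = scan_studies(grouped, family_alpha=0.05)
        unadjusted = sum(r.p_value < 0.05 for r in results) / n_studies
        adjusted = sum(r.significant for r in results) / n_studies
        assert 0.01 <= unadjusted <= 0.10
        assert adjusted <= 0.01


def test_group_scores_and_labels_round_trip(tmp_path):
    df = pd.DataFrame({
        "sample": ["a", "b", "c", "d"],
        "studyID": ["S1"] * 4,
        "trait": ["t"] * 4,
        "score": [1.0, 2.0, 3.0, 4.0],
    })
    labels = threshold_labels({"a": 0.0, "b": 0.5, "c": 1.0, "d": 2.0}, 1.0)
    grouped = group_scores(df, labels)
    assert len(grouped) == 1
    g = grouped[0]
    # 'high' < 'low' lexicographically -> group A is the high-rating group
    np.testing.assert_allclose(sorted(g.group_a), [3.0, 4.0])
    np.testing.assert_allclose(sorted(g.group_b), [1.0, 2.0])

    path = tmp_path / "labels.tsv"
    path.write_text("sampleID\tgroup\na\thigh\nb\tlow\n")
    assert read_labels(path) == {"a": "high", "b": "low"}
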