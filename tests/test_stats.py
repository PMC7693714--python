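"""Statistical layer: t-test vs a permutation oracle, ANOVA identities and
type-I calibration, studentized-range quantiles vs numerical integration, and
Duncan's test vs a brute-force span oracle."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate
from scipy import stats as sps

import cyanomd as cm
from cyanomd.stats import (
    GroupedSample,
    duncan_critical_range,
    duncan_mrt,
    one_way_anova,
    t_test,
)


class TestTTest:
    def test_identical_samples_null(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        stat, p = t_test(a, a.copy())
        assert stat == 0.0
        assert p == 1.0

    def test_sign_flip_symmetry(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 6), rng.normal(0.5, 1, 6)
        _, p1 = t_test(a, b)
        _, p2 = t_test(-a, -b)
        assert p1 == pytest.approx(p2)

    def test_constant_equal_samples(self):
        stat, p = t_test([5.0, 5.0, 5.0], [5.0, 5.0])
        assert (stat, p) == (0.0, 1.0)

    def test_paired_matches_scipy(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 8)
        b = a + rng.normal(0.3, 0.5, 8)
        stat, p = t_test(a, b, paired=True)
        ref = sps.ttest_rel(a, b)
        assert stat == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_agrees_with_exhaustive_permutation_oracle(self):
        """Student p on a small near-normal sample tracks the exact permutation p."""
        a = np.array([2.1, 3.4, 2.9, 3.8])
        b = np.array([4.0, 4.9, 4.4, 5.6])
        t_obs, p_student = t_test(a, b)
        pooled = np.concatenate([a, b])
        n = len(a)
        count = total = 0
        for idx in itertools.combinations(range(len(pooled)), n):
            mask = np.zeros(len(pooled), dtype=bool)
            mask[list(idx)] = True
            t_perm, _ = sps.ttest_ind(pooled[mask], pooled[~mask], equal_var=True)
            total += 1
            if abs(t_perm) >= abs(t_obs) - 1e-12:
                count += 1
        p_perm = count / total
        assert abs(p_student - p_perm) <= 0.02


class TestAnova:
    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 10), rng.normal(0.8, 1, 12)
        res = one_way_anova(GroupedSample({"a": a, "b": b}))
        t_stat, t_p = t_test(a, b)
        assert res.F == pytest.approx(t_stat**2, rel=1e-9)
        assert res.p == pytest.approx(t_p, rel=1e-9)

    def test_constant_groups_zero_f(self):
        res = one_way_anova(GroupedSample({"a": [3.0, 3.0], "b": [3.0, 3.0, 3.0]}))
        assert res.F == 0.0
        assert res.p == 1.0

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(5)
        groups = {f"g{i}": rng.normal(i * 0.3, 1, 9) for i in range(4)}
        res = one_way_anova(GroupedSample(groups))
        ref = sps.f_oneway(*groups.values())
        assert res.F == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_shift_invariance(self):
        rng = np.random.default_rng(6)
        groups = {f"g{i}": rng.normal(0, 1, 7) for i in range(3)}
        shifted = {k: v + 123.4 for k, v in groups.items()}
        a = one_way_anova(GroupedSample(groups))
        b = one_way_anova(GroupedSample(shifted))
        assert a.F == pytest.approx(b.F, rel=1e-9)

    def test_null_type_i_error_calibrated(self):
        """Simulated null (k=4, n=10, 5000 reps): rejection rate in [0.04, 0.06]."""
        rng = np.random.default_rng(12345)
        k, n, reps = 4, 10, 5000
        x = rng.normal(size=(reps, k, n))
        gm = x.mean(axis=(1, 2), keepdims=True)
        ss_between = n * ((x.mean(axis=2, keepdims=True) - gm) ** 2).sum(axis=(1, 2))
        ss_within = ((x - x.mean(axis=2, keepdims=True)) ** 2).sum(axis=(1, 2))
        F = (ss_between / (k - 1)) / (ss_within / (k * n - k))
        pvals = sps.f.sf(F, k - 1, k * n - k)
        rate = (pvals < 0.05).mean()
        assert 0.04 <= rate <= 0.06


def studentized_range_cdf_oracle(q, k, df):
    """Numerical integration of the studentized range CDF, independent of
    scipy.stats.studentized_range: conditional on the scaled sample SD s
    (s^2 ~ chi2_df / df), the range probability integrates over the normal
    order-statistic kernel."""

    def range_cdf_given_s(w):
        f = lambda z: sps.norm.pdf(z) * (sps.norm.cdf(z) - sps.norm.cdf(z - w)) ** (k - 1)
        val, _ = integrate.quad(f, -8, 8, limit=200)
        return k * val

    def integrand(s):
        # density of s: s = sqrt(chi2_df/df)
        dens = 2 * s * df * sps.chi2.pdf(df * s * s, df)
        return dens * range_cdf_given_s(q * s)

    val, _ = integrate.quad(integrand, 1e-6, 5, limit=200)
    return val


class TestStudentizedRange:
    @pytest.mark.parametrize("k,df", [(2, 10), (3, 20), (4, 12)])
    def test_quantiles_match_integration_oracle(self, k, df):
        alpha = 0.05
        q = sps.studentized_range.ppf(1 - alpha, k, df)
        assert studentized_range_cdf_oracle(q, k, df) == pytest.approx(1 - alpha, abs=1e-3)

    def test_protection_level(self):
        assert cm.stats.duncan_protection_level(0.05, 2) == pytest.approx(0.05)
        assert cm.stats.duncan_protection_level(0.05, 3) == pytest.approx(1 - 0.95**2)


def duncan_oracle_groupings(means_sorted, ranges):
    """Brute force: apply the R_p rule to every ordered span, then report the
    maximal homogeneous spans as letter groups."""
    k = len(means_sorted)
    homog = {}
    for i in range(k):
        for j in range(i, k):
            span = j - i + 1
            homog[(i, j)] = span == 1 or (means_sorted[i] - means_sorted[j]) <= ranges[span]
    # closure: subspans of a homogeneous span are homogeneous
    for (i, j), ok in sorted(homog.items(), key=lambda kv: kv[0][1] - kv[0][0], reverse=True):
        if ok:
            for a in range(i, j + 1):
                for b in range(a, j + 1):
                    homog[(a, b)] = True
    spans = [s for s, ok in homog.items() if ok]
    return sorted(s for s in spans if not any(o != s and o[0] <= s[0] and s[1] <= o[1]
                                              for o in spans))


class TestDuncan:
    def test_identical_groups_share_one_letter(self):
        rng = np.random.default_rng(7)
        base = rng.normal(10, 1, 8)
        gs = GroupedSample({"a": base, "b": base + 0.01, "c": base - 0.01})
        res = duncan_mrt(gs)
        assert set(res.means["letters"]) == {"a"}
        assert not any(res.different.values())

    def test_two_groups_reduce_to_alpha_level_range_test(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(0, 1, 10), rng.normal(2.0, 1, 10)
        gs = GroupedSample({"a": a, "b": b})
        anova = one_way_anova(gs)
        res = duncan_mrt(gs, anova)
        r2 = duncan_critical_range(0.05, 2, anova.df_within, anova.ms_within, 10)
        expected_diff = abs(a.mean() - b.mean()) > r2
        assert res.different[("a", "b")] == expected_diff
        # alpha_2 = alpha: the span-2 quantile is the plain alpha-level one
        q_plain = sps.studentized_range.ppf(0.95, 2, anova.df_within)
        assert r2 == pytest.approx(q_plain * np.sqrt(anova.ms_within / 10))

    def test_four_group_fixture_matches_span_oracle(self):
        rng = np.random.default_rng(9)
        gs = GroupedSample({
            "g1": rng.normal(0.0, 1, 10),
            "g2": rng.normal(1.0, 1, 10),
            "g3": rng.normal(5.0, 1, 10),
            "g4": rng.normal(9.0, 1, 10),
        })
        res = duncan_mrt(gs)
        means_sorted = res.means["mean"].to_numpy()
        oracle_spans = duncan_oracle_groupings(means_sorted, res.critical_ranges)
        # letter groups as (start, end) index spans in the sorted order
        letters = res.means["letters"].tolist()
        got_spans = []
        for letter in sorted(set("".join(letters))):
            idx = [i for i, ls in enumerate(letters) if letter in ls]
            got_spans.append((min(idx), max(idx)))
        assert sorted(got_spans) == oracle_spans

    @given(seed=st.integers(0, 500))
    @settings(max_examples=40, deadline=None)
    def test_letter_spans_contiguous(self, seed):
        """If two means share a letter, every mean between them shares it."""
        rng = np.random.default_rng(seed)
        k = int(rng.integers(3, 6))
        groups = {f"g{i}": rng.normal(rng.uniform(0, 4), 1, int(rng.integers(4, 9)))
                  for i in range(k)}
        res = duncan_mrt(GroupedSample(groups))
        letters = res.means["letters"].tolist()
        for letter in set("".join(letters)):
            idx = [i for i, ls in enumerate(letters) if letter in ls]
            assert idx == list(range(min(idx), max(idx) + 1))

    def test_unbalanced_uses_harmonic_mean(self):
        rng = np.random.default_rng(10)
        gs = GroupedSample({"a": rng.normal(0, 1, 4), "b": rng.normal(3, 1, 12)})
        anova = one_way_anova(gs)
        res = duncan_mrt(gs, anova)
        n_h = 2 / (1 / 4 + 1 / 12)
        expect = duncan_critical_range(0.05, 2, anova.df_within, anova.ms_within, n_h)
        assert res.critical_ranges[2] == pytest.approx(expect)


class TestMarkVsReference:
    def test_flags_shifted_groups(self):
        rng = np.random.default_rng(11)
        ref = rng.normal(100, 2, 30)
        gs = GroupedSample({
            "2": ref,
            "7": rng.normal(99.8, 2, 30),  # indistinguishable
            "14": rng.normal(80, 2, 30),  # clearly shifted
        })
        marks = cm.mark_vs_reference(gs, "2").set_index("group")
        assert bool(marks.loc["14", "significant"])
        assert not bool(marks.loc["7", "significant"])
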