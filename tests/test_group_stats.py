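"""Two-group battery: routing, tests, effect sizes, FDR and power.

The published group summaries (means, SDs, n = 21 per group) that are
recomputable from the comparison table serve as fixed oracles for Hedges' g;
Mann-Whitney and BH-FDR are checked against brute-force enumeration written
independently here.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from respmech.group_stats import (
    GroupSample,
    bh_fdr,
    compare_outcomes,
    hedges_g,
    hedges_g_from_samples,
    mann_whitney,
    rank_biserial_ci,
    route_test,
    sample_size_two_sample_t,
    t_test,
)


def gs(values, outcome="o", group="LP"):
    return GroupSample(outcome, group, np.asarray(values, dtype=float))


class TestRouting:
    def test_normal_samples_route_t(self):
        rng = np.random.default_rng(0)
        a, b = gs(rng.normal(0, 1, 21)), gs(rng.normal(0.3, 1, 21))
        assert route_test(a, b) == "t"

    def test_heavy_skew_routes_mann_whitney(self):
        rng = np.random.default_rng(2)
        a = gs(np.exp(rng.normal(0, 1.5, 21)))
        b = gs(rng.normal(0, 1, 21))
        assert route_test(a, b) == "mann_whitney"

    def test_tiny_group_falls_back_with_warning(self):
        with pytest.warns(UserWarning, match="n < 3"):
            assert route_test(gs([1.0, 2.0]), gs([1.0, 2.0, 3.0])) == "mann_whitney"


class TestTTest:
    def test_identical_samples(self):
        t, p = t_test(gs([1.0, 2.0, 3.0]), gs([1.0, 2.0, 3.0]))
        assert (t, p) == (0.0, 1.0)

    def test_large_separation(self):
        _, p = t_test(gs([1.0, 2.0, 3.0]), gs([11.0, 12.0, 13.0]))
        assert p < 0.001

    def test_hand_computed_value(self):
        """a={1,2,3,4} vs b={2,3,4,5}: pooled t = -1.095, p ≈ 0.315."""
        t, p = t_test(gs([1, 2, 3, 4]), gs([2, 3, 4, 5]))
        assert t == pytest.approx(-1.0954, abs=1e-4)
        assert p == pytest.approx(0.3153, abs=1e-3)

    def test_degenerate_zero_variance(self):
        with pytest.warns(UserWarning, match="zero variance"):
            _, p = t_test(gs([2.0, 2.0]), gs([5.0, 5.0]))
        assert p == 0.0


def brute_force_mw(x, y):
    """Exact two-sided p from the full permutation null of U."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    m = n1 * len(y) / 2.0
    u_obs = sum(
        1.0 if xi > yj else 0.5 if xi == yj else 0.0 for xi in x for yj in y
    )
    stats_null = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        xa = pooled[list(idx)]
        ya = np.delete(pooled, list(idx))
        u = sum(1.0 if xi > yj else 0.5 if xi == yj else 0.0 for xi in xa for yj in ya)
        stats_null.append(u)
    stats_null = np.asarray(stats_null)
    return float(np.mean(np.abs(stats_null - m) >= abs(u_obs - m) - 1e-12))


class TestMannWhitney:
    def test_complete_dominance(self):
        u, _, r = mann_whitney(gs([2.0, 3.0]), gs([0.0, 1.0]))
        assert u == 4.0 and r == 1.0

    def test_interleaved_example(self):
        u, _, r = mann_whitney(gs([1.0, 3.0]), gs([2.0, 4.0]))
        assert u == 1.0 and r == -0.5

    def test_exact_p_matches_enumeration_for_all_partitions(self):
        """Every split of {1..8} into 4+4 gives the enumeration p-value."""
        values = np.arange(1.0, 9.0)
        for idx in itertools.combinations(range(8), 4):
            x = values[list(idx)]
            y = np.delete(values, list(idx))
            _, p, _ = mann_whitney(gs(x), gs(y))
            assert p == pytest.approx(brute_force_mw(x, y), abs=1e-12)

    def test_ties_fall_back_to_corrected_normal(self):
        x = gs([1.0, 2.0, 2.0, 3.0])
        y = gs([2.0, 3.0, 4.0, 5.0])
        _, p, r = mann_whitney(x, y)
        assert 0.0 <= p <= 1.0 and -1.0 <= r <= 1.0

    def test_rank_biserial_ci_brackets_estimate(self):
        rng = np.random.default_rng(0)
        a, b = gs(rng.normal(1.0, 1, 21)), gs(rng.normal(0.0, 1, 21))
        _, _, r = mann_whitney(a, b)
        lo, hi = rank_biserial_ci(a, b, seed=1)
        assert lo <= r <= hi
        assert (lo, hi) == rank_biserial_ci(a, b, seed=1)  # seeded determinism


class TestHedgesG:
    # printed group summaries (mean, SD, n=21 each) and the published g
    PUBLISHED = [
        ((1.28, 0.36), (0.81, 0.37), 1.26),  # KWH inspiratory time
        ((2.04, 0.69), (0.93, 0.58), 1.71),  # KWH expiratory time
        ((0.54, 0.24), (0.73, 0.16), -0.91),  # WHM CCF Z
        ((41.00, 5.41), (31.16, 6.97), 1.55),  # WHM trailing ankle frontal
        ((20.05, 6.06), (12.64, 4.59), 1.35),  # WHM trailing ankle transverse
        ((85.52, 15.50), (70.82, 14.71), 0.95),  # WHM leading knee sagittal
        ((46.04, 10.76), (35.01, 7.26), 1.18),  # WHIC following knee sagittal
        ((63.67, 15.29), (50.47, 13.24), 0.91),  # RM leading ankle sagittal
    ]

    @pytest.mark.parametrize("a,b,expected", PUBLISHED)
    def test_reproduces_published_effect_sizes(self, a, b, expected):
        g, _, _ = hedges_g(a[0], a[1], 21, b[0], b[1], 21)
        assert g == pytest.approx(expected, abs=0.01)

    def test_published_ci_upper_bound(self):
        """KWH expiratory time: 95% CI upper bound prints as 2.42."""
        _, _, hi = hedges_g(2.04, 0.69, 21, 0.93, 0.58, 21)
        assert hi == pytest.approx(2.42, abs=0.01)

    def test_identical_groups_zero(self):
        g, lo, hi = hedges_g(5.0, 1.0, 21, 5.0, 1.0, 21)
        assert g == 0.0 and lo < 0.0 < hi

    def test_antisymmetry_under_group_swap(self):
        g1, lo1, hi1 = hedges_g(2.04, 0.69, 21, 0.93, 0.58, 21)
        g2, lo2, hi2 = hedges_g(0.93, 0.58, 21, 2.04, 0.69, 21)
        assert g2 == pytest.approx(-g1, abs=1e-12)
        assert (lo2, hi2) == pytest.approx((-hi1, -lo1), abs=1e-12)

    def test_sample_based_wrapper_agrees(self):
        rng = np.random.default_rng(4)
        a, b = gs(rng.normal(1, 1, 15)), gs(rng.normal(0, 1, 18))
        g, _, _ = hedges_g_from_samples(a, b)
        expected, _, _ = hedges_g(
            a.values.mean(), a.values.std(ddof=1), 15,
            b.values.mean(), b.values.std(ddof=1), 18,
        )
        assert g == expected

    def test_zero_pooled_sd_raises(self):
        with pytest.raises(ZeroDivisionError):
            hedges_g(1.0, 0.0, 10, 2.0, 0.0, 10)


def brute_force_bh(p):
    """q_(i) = min_{j >= i} p_(j) m / j, restored to input order."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for pos, i in enumerate(order):
        q[i] = min(
            p[order[k]] * m / (k + 1) for k in range(pos, m)
        )
    return np.minimum(q, 1.0)


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.05])[0] == pytest.approx(0.05)

    def test_hand_step_up(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=12))
    def test_matches_brute_force_tail_min(self, pvals):
        np.testing.assert_allclose(bh_fdr(pvals), brute_force_bh(pvals), atol=1e-12)

    def test_families_corrected_independently(self):
        p = [0.01, 0.04, 0.01, 0.04]
        fam = ["a", "a", "b", "b"]
        joint = bh_fdr(p, fam)
        np.testing.assert_allclose(joint[:2], bh_fdr(p[:2]))
        np.testing.assert_allclose(joint[2:], bh_fdr(p[2:]))

    def test_monotone_in_p_within_family(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0, 1, 30)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestSampleSize:
    def test_published_power_analysis(self):
        """d = 0.9, alpha = 0.05, power = 0.8 requires 42 participants."""
        n, total = sample_size_two_sample_t(0.9, 0.05, 0.8)
        assert total == 42

    def test_medium_effect_reference_value(self):
        n, _ = sample_size_two_sample_t(0.5, 0.05, 0.8)
        assert n == 64

    def test_monotone_in_effect(self):
        ns = [sample_size_two_sample_t(d)[0] for d in (0.3, 0.5, 0.8, 1.2)]
        assert all(a >= b for a, b in zip(ns, ns[1:]))

    def test_cross_checked_against_statsmodels(self):
        from statsmodels.stats.power import TTestIndPower

        for d in (0.4, 0.9):
            n, _ = sample_size_two_sample_t(d)
            analytic = TTestIndPower().solve_power(
                effect_size=d, alpha=0.05, power=0.8, alternative="two-sided"
            )
            assert n == math.ceil(analytic)


class TestBattery:
    @staticmethod
    def cohort(shift=0.0, n_out=6, seed=0):
        rng = np.random.default_rng(seed)
        samples, families = {}, {}
        for i in range(n_out):
            mu = shift if i == 0 else 0.0
            samples[f"o{i}"] = (
                gs(rng.normal(mu, 1, 21), f"o{i}", "LP"),
                gs(rng.normal(0.0, 1, 21), f"o{i}", "BP"),
            )
            families[f"o{i}"] = "fam"
        return samples, families

    def test_shifted_outcome_has_smallest_q(self):
        samples, families = self.cohort(shift=1.5)
        results = compare_outcomes(samples, families)
        by_q = sorted(results, key=lambda c: c.q)
        assert by_q[0].outcome == "o0"
        assert by_q[0].significant

    def test_participant_order_irrelevant(self):
        samples, families = self.cohort(shift=1.0)
        permuted = {
            k: (gs(v[0].values[::-1], k, "LP"), gs(v[1].values[::-1], k, "BP"))
            for k, v in samples.items()
        }
        r1 = compare_outcomes(samples, families)
        r2 = compare_outcomes(permuted, families)
        for c1, c2 in zip(r1, r2):
            assert c1.p == pytest.approx(c2.p, abs=1e-12)
            assert c1.q == pytest.approx(c2.q, abs=1e-12)

    def test_one_bad_outcome_does_not_abort(self):
        samples, families = self.cohort()
        samples["broken"] = (
            gs([1.0, 1.0, 1.0], "broken", "LP"),
            gs([1.0, 1.0, 1.0], "broken", "BP"),
        )
        results = compare_outcomes(samples, families)
        assert len(results) == len(samples)
        ok = [c for c in results if c.outcome != "broken"]
        assert all(np.isfinite(c.p) for c in ok)

    def test_descriptives_follow_route(self):
        samples, families = self.cohort()
        for c in compare_outcomes(samples, families):
            if c.route == "t":
                assert "±" in c.desc_a
            elif c.route == "mann_whitney":
                assert "(" in c.desc_a
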