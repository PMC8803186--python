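"""The test core: risk tables, weights, scores, exact/MC/asymptotic p-values."""

import itertools
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctot import (
    ConfigurationError,
    ValidationError,
    asymptotic_pvalue,
    build_risk_table,
    ctot_test,
    exact_permutation_pvalue,
    fh_weights,
    km_left_limits,
    linear_statistic,
    logrank_scores,
    montecarlo_permutation_pvalue,
)
from conftest import (
    dataset_arrays,
    make_dataset,
    oracle_exact_pvalue,
    oracle_statistic,
    random_censored_dataset,
)


def prepared_rows(data, p=0.0, q=0.0):
    rows = build_risk_table(data)
    km_left_limits(rows)
    fh_weights(rows, p, q)
    return rows


class TestRiskTable:
    def test_hand_enumerated_example(self, three_row_dataset):
        rows = build_risk_table(three_row_dataset)
        expect = [  # (d, p_d, p_d1, o_d, o_d1, e_d1, v_d1)
            (1, 4, 2, 1, 1, 0.5, 0.25),
            (2, 3, 1, 1, 0, 1 / 3, 2 / 9),
            (3, 2, 1, 1, 1, 0.5, 0.25),
        ]
        assert len(rows) == 3
        for row, (d, p, p1, o, o1, e1, v1) in zip(rows, expect):
            assert (row.d, row.p_d, row.p_d1, row.o_d, row.o_d1) == (d, p, p1, o, o1)
            assert row.e_d1 == pytest.approx(e1)
            assert row.v_d1 == pytest.approx(v1)

    def test_symmetric_margins_give_e1_half_of_o(self):
        data = make_dataset([(1, 1)] * 5, [(1, 1)] * 5)
        (row,) = build_risk_table(data)
        assert row.p_d1 == row.p_d2 == 5
        assert row.e_d1 == pytest.approx(row.o_d / 2)

    def test_all_censored_gives_empty_table(self):
        data = make_dataset([(1, 0), (2, 0)], [(3, 0)])
        assert build_risk_table(data) == []

    @pytest.mark.parametrize("seed", range(8))
    def test_moments_match_brute_force_hypergeometric(self, seed):
        rng = np.random.default_rng(seed)
        data = random_censored_dataset(rng)
        for row in build_risk_table(data):
            if row.p_d > 12:
                continue
            # enumerate the conditional distribution of O_d1 directly
            lo = max(0, row.o_d - row.p_d2)
            hi = min(row.o_d, row.p_d1)
            total = comb(row.p_d, row.o_d)
            pmf = {
                o1: comb(row.p_d1, o1) * comb(row.p_d2, row.o_d - o1) / total
                for o1 in range(lo, hi + 1)
            }
            mean = sum(o1 * p for o1, p in pmf.items())
            var = sum((o1 - mean) ** 2 * p for o1, p in pmf.items())
            assert row.e_d1 == pytest.approx(mean, abs=1e-12)
            assert row.v_d1 == pytest.approx(var, abs=1e-12)
            if row.p_d <= 1:
                assert row.v_d1 == 0.0

    def test_balance_of_observed_minus_expected(self, three_row_dataset):
        for row in build_risk_table(three_row_dataset):
            e_d2 = row.o_d * row.p_d2 / row.p_d
            assert (row.o_d1 - row.e_d1) + (row.o_d2 - e_d2) == pytest.approx(0.0)


class TestKmAndWeights:
    def test_left_limits_product_formula(self, three_row_dataset):
        rows = km_left_limits(build_risk_table(three_row_dataset))
        assert [r.s_minus for r in rows] == pytest.approx([1.0, 0.75, 0.5])

    def test_single_event_point_has_unit_left_limit(self):
        data = make_dataset([(2, 1)], [(3, 0), (4, 0)])
        rows = km_left_limits(build_risk_table(data))
        assert rows[0].s_minus == 1.0

    def test_no_censoring_steps_of_one_over_n(self):
        n = 6
        data = make_dataset([(i, 1) for i in range(3)],
                            [(i + 10, 1) for i in range(3)])
        rows = km_left_limits(build_risk_table(data))
        assert [r.s_minus for r in rows] == pytest.approx(
            [1 - j / n for j in range(n)])

    def test_unit_weights_at_p_q_zero(self, three_row_dataset):
        rows = prepared_rows(three_row_dataset, 0, 0)
        assert all(r.w_d == 1.0 for r in rows)

    def test_first_point_weight_zero_when_q_positive(self, three_row_dataset):
        rows = prepared_rows(three_row_dataset, 0, 1)
        assert rows[0].w_d == 0.0

    def test_p1_weights_equal_left_limits(self, three_row_dataset):
        rows = prepared_rows(three_row_dataset, 1, 0)
        assert [r.w_d for r in rows] == pytest.approx([1.0, 0.75, 0.5])

    def test_negative_exponent_rejected(self, three_row_dataset):
        rows = km_left_limits(build_risk_table(three_row_dataset))
        with pytest.raises(ValidationError):
            fh_weights(rows, -1, 0)


class TestLinearStatisticAndScores:
    def test_hand_summed_example(self, three_row_dataset):
        u, v = linear_statistic(prepared_rows(three_row_dataset))
        assert u == pytest.approx(2 / 3)
        assert v == pytest.approx(0.25 + 2 / 9 + 0.25)

    def test_mirror_image_groups_give_zero(self):
        data = make_dataset([(1, 1), (2, 1), (5, 0)], [(1, 1), (2, 1), (5, 0)])
        u, _ = linear_statistic(prepared_rows(data))
        assert u == pytest.approx(0.0)

    def test_empty_table_gives_zero_zero(self):
        assert linear_statistic([]) == (0.0, 0.0)

    @pytest.mark.parametrize("p,q", list(itertools.product([0, 0.5, 1], repeat=2)))
    @pytest.mark.parametrize("seed", range(6))
    def test_group1_score_sum_equals_u(self, seed, p, q):
        rng = np.random.default_rng(100 + seed)
        data = random_censored_dataset(rng)
        rows = prepared_rows(data, p, q)
        u, _ = linear_statistic(rows)
        scores = logrank_scores(data, rows)
        groups = np.array([o.group for o in data.observations])
        assert scores[groups == 1].sum() == pytest.approx(u, abs=1e-10)

    def test_untied_uncensored_scores_are_classic_logrank_scores(self):
        data = make_dataset([(1, 1), (4, 1)], [(2, 1), (3, 1)])
        rows = prepared_rows(data)
        scores = logrank_scores(data, rows)
        values = np.array([o.delta_y for o in data.observations])
        n = len(values)
        cumhaz = {
            v: sum(1.0 / (n - r) for r in range(int(np.sum(values < v)) + 1))
            for v in values
        }
        expected = [1.0 - cumhaz[v] for v in values]
        assert scores == pytest.approx(expected)

    _obs_pairs = st.lists(
        st.tuples(st.integers(1, 8).map(lambda k: 0.5 * k), st.integers(0, 1)),
        min_size=2, max_size=6,
    )

    @settings(derandomize=True, deadline=None, max_examples=60)
    @given(g1=_obs_pairs, g2=_obs_pairs)
    def test_score_sum_identity_holds_for_arbitrary_data(self, g1, g2):
        data = make_dataset(g1, g2)
        rows = prepared_rows(data, 0.5, 0.5)
        u, _ = linear_statistic(rows)
        scores = logrank_scores(data, rows)
        groups = np.array([o.group for o in data.observations])
        assert scores[groups == 1].sum() == pytest.approx(u, abs=1e-10)

    def test_censored_before_first_detection_scores_zero(self):
        data = make_dataset([(0.5, 0), (3, 1)], [(2, 1), (4, 1)])
        rows = prepared_rows(data)
        scores = logrank_scores(data, rows)
        assert scores[0] == 0.0


class TestPermutationPvalues:
    def test_four_score_enumeration(self):
        p = exact_permutation_pvalue([1.5, 0.5, -0.5, -1.5], 2)
        assert p == pytest.approx(1 / 3)

    def test_all_equal_scores_give_one(self):
        assert exact_permutation_pvalue([2.0] * 6, 3) == 1.0

    def test_denominator_is_binomial_coefficient(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=10)
        p = exact_permutation_pvalue(scores, 5)
        assert (p * 252) == pytest.approx(round(p * 252))
        assert 0 < p <= 1

    def test_enumeration_limit_exceeded_points_to_montecarlo(self):
        with pytest.raises(ConfigurationError, match="montecarlo"):
            exact_permutation_pvalue(list(range(30)), 15, enumeration_limit=100)

    def test_montecarlo_close_to_exact(self):
        scores = [1.5, 0.5, -0.5, -1.5]
        B = 100_000
        p = montecarlo_permutation_pvalue(scores, 2, B=B, seed=0)
        se = np.sqrt((1 / 3) * (2 / 3) / B)
        assert abs(p - 1 / 3) < 3 * se

    def test_montecarlo_all_equal_scores_give_one(self):
        assert montecarlo_permutation_pvalue([1.0] * 6, 3, B=1000, seed=0) == 1.0

    def test_montecarlo_seed_stability(self):
        rng = np.random.default_rng(11)
        scores = rng.normal(size=12)
        B = 20_000
        p1 = montecarlo_permutation_pvalue(scores, 6, B=B, seed=1)
        p2 = montecarlo_permutation_pvalue(scores, 6, B=B, seed=2)
        bound = 4 * np.sqrt(max(p1, 1 / B) * (1 - min(p1, 1 - 1 / B)) / B)
        assert abs(p1 - p2) <= bound
        assert p1 == montecarlo_permutation_pvalue(scores, 6, B=B, seed=1)


class TestAsymptotic:
    def test_zero_statistic_gives_one(self):
        assert asymptotic_pvalue(0.0, 1.0) == pytest.approx(1.0)

    def test_normal_quantile_identity(self):
        assert asymptotic_pvalue(1.959964, 1.0) == pytest.approx(0.05, abs=1e-6)

    def test_three_row_example(self):
        p = asymptotic_pvalue(2 / 3, 0.25 + 2 / 9 + 0.25)
        assert p == pytest.approx(0.4327, abs=2e-4)

    def test_zero_variance_gives_one(self):
        assert asymptotic_pvalue(1.0, 0.0) == 1.0


class TestCtotTest:
    @pytest.mark.parametrize("seed", range(30))
    def test_exact_p_matches_naive_relabeling_oracle(self, seed):
        rng = np.random.default_rng(1000 + seed)
        data = random_censored_dataset(rng)
        values, phi, n1 = dataset_arrays(data)
        res = ctot_test(data, pvalue_mode="auto")
        expected = oracle_exact_pvalue(values, phi, n1)
        assert res.p_value == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("p,q", [(0, 0), (0.5, 0.5), (1, 0), (0, 1)])
    def test_weighted_exact_p_matches_oracle(self, p, q):
        rng = np.random.default_rng(77)
        for _ in range(5):
            data = random_censored_dataset(rng)
            values, phi, n1 = dataset_arrays(data)
            res = ctot_test(data, fh_p=p, fh_q=q)
            expected = oracle_exact_pvalue(values, phi, n1, fh_p=p, fh_q=q)
            assert res.p_value == pytest.approx(expected, abs=1e-10)

    def test_monotone_transform_leaves_pvalue_unchanged(self):
        rng = np.random.default_rng(5)
        data = random_censored_dataset(rng)
        transformed = make_dataset(
            [(np.exp(o.delta_y / 4), o.phi) for o in data.observations if o.group == 1],
            [(np.exp(o.delta_y / 4), o.phi) for o in data.observations if o.group == 2],
        )
        r1 = ctot_test(data)
        r2 = ctot_test(transformed)
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)

    def test_all_censored_is_degenerate_nonrejection(self):
        data = make_dataset([(1, 0), (2, 0)], [(3, 0), (4, 0)])
        res = ctot_test(data)
        assert res.degenerate and res.p_value == 1.0
        assert res.degenerate_reason == "no detection points"

    def test_group_swap_negates_u_and_keeps_two_sided_p(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            data = random_censored_dataset(rng)
            g1 = [(o.delta_y, o.phi) for o in data.observations if o.group == 1]
            g2 = [(o.delta_y, o.phi) for o in data.observations if o.group == 2]
            swapped = make_dataset(g2, g1)
            r1, r2 = ctot_test(data), ctot_test(swapped)
            assert r1.statistic_u == pytest.approx(-r2.statistic_u, abs=1e-10)
            assert r1.p_value == pytest.approx(r2.p_value, abs=1e-10)

    def test_exact_test_validity_by_enumeration(self):
        # over the uniform distribution of labelings, P(p <= a) <= a
        rng = np.random.default_rng(21)
        data = random_censored_dataset(rng, max_per_group=4)
        values, phi, n1 = dataset_arrays(data)
        n = len(values)
        pvals = []
        for subset in itertools.combinations(range(n), n1):
            order = list(subset) + [i for i in range(n) if i not in subset]
            v = [values[i] for i in order]
            e = [phi[i] for i in order]
            pvals.append(oracle_exact_pvalue(v, e, n1))
        pvals = np.array(pvals)
        for alpha in [0.01, 0.05, 0.1, 0.25, 0.5, 0.9, 1.0]:
            assert np.mean(pvals <= alpha) <= alpha + 1e-12

    def test_one_sided_alternatives_are_complementary(self):
        data = make_dataset([(1, 1), (2, 1), (3, 1)], [(4, 1), (5, 1), (6, 0)])
        greater = ctot_test(data, alternative="rate1_greater")
        less = ctot_test(data, alternative="rate1_less")
        # observed labeling is counted in both tails, so the sum exceeds 1
        assert greater.p_value < less.p_value
        assert greater.p_value + less.p_value >= 1.0

    def test_asymptotic_agrees_with_lifelines_logrank(self):
        lifelines_stats = pytest.importorskip("lifelines.statistics")
        rng = np.random.default_rng(13)
        for _ in range(10):
            data = random_censored_dataset(rng)
            res = ctot_test(data, pvalue_mode="asymptotic")
            if res.degenerate:
                continue
            g1 = [o for o in data.observations if o.group == 1]
            g2 = [o for o in data.observations if o.group == 2]
            ref = lifelines_stats.logrank_test(
                [o.delta_y for o in g1], [o.delta_y for o in g2],
                event_observed_A=[o.phi for o in g1],
                event_observed_B=[o.phi for o in g2],
            )
            assert res.z ** 2 == pytest.approx(ref.test_statistic, rel=1e-8)
            assert res.p_value == pytest.approx(ref.p_value, rel=1e-8)
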