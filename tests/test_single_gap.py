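"""Per-fly fractions, box statistics, and the Wilcoxon rank-sum machinery."""

import numpy as np
import pytest
from scipy import stats as sstats

from ringgap import (
    ApproachEvent,
    ApproachLog,
    CatwalkSetup,
    Stars,
    ValidationError,
    box_stats,
    compare_to_control,
    per_fly_fractions,
    rank_sum_test,
    simulate_catwalk_session,
    star_code,
)


def make_log(per_fly, gap=3.0, line_id="test"):
    """per_fly: list of (n_attempt, n_fall, n_cross) triples over 10 approaches."""
    events = []
    for fly_id, (n_att, n_fall, n_cross) in enumerate(per_fly):
        for k in range(1, 11):
            attempted = k <= n_att
            fell = attempted and k <= n_fall
            crossed = attempted and not fell and (n_fall < k <= n_fall + n_cross)
            events.append(ApproachEvent(fly_id, k, attempted, fell, crossed))
    return ApproachLog(line_id=line_id, setup=CatwalkSetup(gap_width=gap), events=events)


class TestPerFlyFractions:
    def test_control_anchor_fractions(self):
        stats = per_fly_fractions(make_log([(10, 0, 7)]))
        assert stats[0].frac_attempt == 1.0
        assert stats[0].frac_cross == 0.7

    def test_no_attempts_all_zero(self):
        s = per_fly_fractions(make_log([(0, 0, 0)]))[0]
        assert s.frac_attempt == s.frac_fall == s.frac_cross == s.frac_fall_given_attempt == 0.0

    def test_fall_fraction_both_readings(self):
        s = per_fly_fractions(make_log([(4, 2, 0)]))[0]
        assert s.frac_fall == pytest.approx(0.2)
        assert s.frac_fall_given_attempt == pytest.approx(0.5)

    def test_wrong_approach_count_rejected(self):
        log = make_log([(5, 0, 3)])
        log.events = log.events[:-1]
        with pytest.raises(ValidationError):
            per_fly_fractions(log)

    def test_fractions_are_multiples_of_tenth(self):
        log = simulate_catwalk_session("control", CatwalkSetup(gap_width=3.0), 30, seed=0)
        for s in per_fly_fractions(log):
            for v in (s.frac_attempt, s.frac_fall, s.frac_cross):
                assert round(v * 10) == pytest.approx(v * 10)
            assert s.frac_cross <= s.frac_attempt
            assert s.frac_fall <= s.frac_attempt


class TestBoxStats:
    def test_constant_list_collapses(self):
        b = box_stats([0.4] * 6)
        assert b.q10 == b.q25 == b.median == b.q75 == b.q90 == 0.4

    def test_eleven_point_grid_median(self):
        b = box_stats(np.arange(0, 1.05, 0.1))
        assert b.median == pytest.approx(0.5)

    def test_interpolated_quartiles_1_to_10(self):
        b = box_stats(range(1, 11))
        assert b.q25 == pytest.approx(3.25)
        assert b.q75 == pytest.approx(7.75)

    def test_ordering_and_empty(self):
        b = box_stats([3, 1, 4, 1, 5, 9, 2, 6])
        assert b.q10 <= b.q25 <= b.median <= b.q75 <= b.q90
        with pytest.raises(ValidationError):
            box_stats([])


class TestRankSum:
    def test_two_vs_two_enumeration(self):
        _, p = rank_sum_test([1, 2], [3, 4])
        assert p == pytest.approx(1 / 3)

    def test_three_vs_three_enumeration(self):
        _, p = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        _, p = rank_sum_test([2, 2, 2], [2, 2, 2])
        assert p == 1.0

    def test_fully_separated_ten_vs_ten(self):
        from math import comb

        _, p = rank_sum_test(list(range(10)), list(range(100, 110)))
        assert p == pytest.approx(2 / comb(20, 10))

    def test_exact_agrees_with_independent_oracle_up_to_6_plus_6(self):
        rng = np.random.default_rng(7)
        for n_a in range(1, 7):
            for n_b in range(1, 7):
                for _ in range(3):
                    a = rng.normal(size=n_a)
                    b = rng.normal(size=n_b) + rng.normal()
                    _, p = rank_sum_test(a, b)
                    oracle = sstats.mannwhitneyu(a, b, alternative="two-sided",
                                                 method="exact").pvalue
                    assert p == pytest.approx(float(oracle), abs=1e-12)

    def test_exact_and_normal_paths_agree_on_10_plus_10(self):
        # tie-free samples straddling the enumeration cutoff
        rng = np.random.default_rng(8)
        for _ in range(20):
            a = rng.normal(size=10)
            b = rng.normal(size=10) + rng.normal(scale=0.5)
            _, p_exact = rank_sum_test(a, b)
            p_norm = float(
                sstats.mannwhitneyu(a, b, alternative="two-sided",
                                    method="asymptotic", use_continuity=True).pvalue
            )
            assert abs(p_exact - p_norm) <= 0.01

    def test_both_methods_available_explicitly(self):
        rng = np.random.default_rng(9)
        a = rng.normal(size=8)
        b = rng.normal(size=8) + 0.5
        _, p_exact = rank_sum_test(a, b, method="exact")
        _, p_asym = rank_sum_test(a, b, method="asymptotic")
        _, p_auto = rank_sum_test(a, b)
        assert p_auto == p_exact       # pooled n=16 <= 20
        assert abs(p_exact - p_asym) <= 0.02

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            rank_sum_test([], [1.0])
        with pytest.raises(ValidationError):
            rank_sum_test([1.0], [2.0], method="bogus")


class TestStars:
    @pytest.mark.parametrize(
        "p,expected",
        [
            (0.04, Stars.ONE),
            (0.009, Stars.TWO),
            (0.0009, Stars.THREE),
            (0.05, Stars.NS),      # strict inequality at the threshold
            (0.01, Stars.ONE),
            (0.001, Stars.TWO),
            (0.9, Stars.NS),
        ],
    )
    def test_threshold_coding(self, p, expected):
        assert star_code(p) is expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            star_code(1.5)


class TestCompareToControl:
    def test_identical_data_is_ns(self):
        log = make_log([(8, 0, 6), (5, 0, 3), (10, 1, 7)] * 4)
        comps = compare_to_control([log], [log])
        assert comps
        for c in comps:
            assert c.p_value == 1.0
            assert c.stars is Stars.NS

    def test_separated_ten_vs_ten_exact_p(self):
        from math import comb

        line = make_log([(10, 0, 9)] * 10)
        ctrl = make_log([(1, 0, 1)] * 10)
        comps = compare_to_control([line], [ctrl])
        by_metric = {c.metric: c for c in comps}
        assert by_metric["frac_attempt"].p_value == pytest.approx(2 / comb(20, 10))

    def test_missing_width_skipped_with_warning(self):
        line = make_log([(5, 0, 3)] * 10, gap=5.0)
        ctrl = make_log([(5, 0, 3)] * 10, gap=2.5)
        with pytest.warns(UserWarning):
            assert compare_to_control([line], [ctrl]) == []

    def test_enhanced_gain_drives_significant_extra_attempts_at_5mm(self):
        # C2-block-like perception (g=1.6) vs control at an insurmountable gap
        setup = CatwalkSetup(gap_width=5.0)
        signif, direction = 0, 0
        for seed in range(20):
            block = simulate_catwalk_session("overeager", setup, 15, seed=seed)
            ctrl = simulate_catwalk_session("control", setup, 15, seed=seed + 500)
            comps = compare_to_control([block], [ctrl])
            c = next(c for c in comps if c.metric == "frac_attempt")
            a = np.median([f.frac_attempt for f in per_fly_fractions(block)])
            b = np.median([f.frac_attempt for f in per_fly_fractions(ctrl)])
            signif += c.stars is not Stars.NS
            direction += a > b
        assert direction == 20
        assert signif >= 18

    def test_holm_adjustment_never_decreases_p(self):
        line = make_log([(10, 0, 8)] * 8)
        ctrl = make_log([(4, 0, 2)] * 8)
        raw = compare_to_control([line], [ctrl])
        adj = compare_to_control([line], [ctrl], holm=True)
        for r, a in zip(raw, adj):
            assert a.p_value >= r.p_value
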