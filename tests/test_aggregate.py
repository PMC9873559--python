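import numpy as np
import pytest

from seatea import aggregate
from seatea.aggregate import (
    average_cost,
    cheapest_fraction,
    constraint_overlap,
    farm_growth_rate,
    supply_curve,
)


class TestCheapestFraction:
    def test_full_fraction_selects_all_valid_cells(self, rng):
        cost = rng.uniform(1, 10, size=20)
        cost[3] = np.nan
        mask = cheapest_fraction(cost, np.ones(20), 1.0)
        assert mask.sum() == 19 and not mask[3]

    def test_uniform_costs_tie_break_by_index(self):
        mask = cheapest_fraction(np.ones(10), np.ones(10), 0.3)
        np.testing.assert_array_equal(np.flatnonzero(mask), [0, 1, 2])

    def test_ten_cell_toy_matches_sort_oracle(self, rng):
        cost = rng.permutation(10).astype(float)
        mask = cheapest_fraction(cost, np.ones(10), 0.3)
        assert set(np.flatnonzero(mask)) == set(np.argsort(cost)[:3])

    def test_nested_for_growing_fractions(self, rng):
        cost = rng.uniform(0, 1, 50)
        area = rng.uniform(0.5, 2.0, 50)
        small = cheapest_fraction(cost, area, 0.1)
        large = cheapest_fraction(cost, area, 0.4)
        assert (small <= large).all()

    def test_no_valid_cells_rejected(self):
        with pytest.raises(ValueError):
            cheapest_fraction(np.full(5, np.nan), np.ones(5), 0.5)


class TestAverageCost:
    def test_uniform_cost_under_both_weightings(self):
        mask = np.ones(4, bool)
        cost = np.full(4, 7.0)
        assert average_cost(mask, cost, np.ones(4)) == 7.0
        assert average_cost(mask, cost, np.ones(4), benefit=np.array([1, 2, 3, 4.0])) == 7.0

    def test_benefit_weighted_hand_arithmetic(self):
        mask = np.ones(2, bool)
        got = average_cost(
            mask, np.array([100.0, 300.0]), np.ones(2), benefit=np.array([3.0, 1.0])
        )
        assert got == pytest.approx(150.0)

    def test_zero_benefit_cell_does_not_move_average(self):
        mask = np.ones(3, bool)
        cost = np.array([100.0, 300.0, 999.0])
        benefit = np.array([3.0, 1.0, 0.0])
        assert average_cost(mask, cost, np.ones(3), benefit) == pytest.approx(150.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            average_cost(np.zeros(3, bool), np.ones(3), np.ones(3))


class TestSupplyCurve:
    def test_uniform_benefit_density_gives_linear_benefit(self):
        cost = np.arange(10, dtype=float)
        curve = supply_curve(cost, np.full(10, 2.0), np.ones(10), max_fraction=1.0)
        np.testing.assert_allclose(np.diff(curve["benefit_gt_yr"]), 2.0 / 1e9)

    def test_marginal_cost_non_decreasing(self, rng):
        cost = rng.uniform(0, 100, 50)
        curve = supply_curve(cost, rng.uniform(0, 5, 50), np.ones(50), max_fraction=0.5)
        assert (np.diff(curve["marginal_cost"]) >= 0).all()

    def test_twenty_cell_toy_matches_prefix_enumeration(self, rng):
        cost = rng.permutation(20).astype(float)
        benefit = rng.uniform(1, 3, 20)
        area = rng.uniform(0.5, 2, 20)
        curve = supply_curve(cost, benefit, area, max_fraction=1.0)
        order = np.argsort(cost)
        for k in range(1, 21):
            prefix = order[:k]
            row = curve.iloc[k - 1]
            assert row["area_km2"] == pytest.approx(area[prefix].sum())
            assert row["benefit_gt_yr"] == pytest.approx(
                (benefit[prefix] * area[prefix]).sum() / 1e9
            )
            assert row["average_cost"] == pytest.approx(
                (cost[prefix] * benefit[prefix] * area[prefix]).sum()
                / (benefit[prefix] * area[prefix]).sum()
            )

    def test_full_curve_recovers_total_benefit(self, rng):
        benefit = rng.uniform(0, 5, 30)
        area = rng.uniform(0.5, 2, 30)
        curve = supply_curve(rng.uniform(0, 9, 30), benefit, area, max_fraction=1.0)
        assert curve["benefit_gt_yr"].iloc[-1] == pytest.approx((benefit * area).sum() / 1e9)


class TestFarmGrowthRate:
    @pytest.mark.parametrize(
        "target,horizon,expected_pct",
        [
            (90_000, 30, 12),
            (400_000, 30, 18),
            (90_000, 10, 42),
            (130_000, 30, 14),
        ],
    )
    def test_published_expansion_rates(self, target, horizon, expected_pct):
        """Scaling from today's ~2,700 km^2 reproduces the printed rates."""
        res = farm_growth_rate(target, 2700.0, horizon)
        assert round(res.annual_growth_rate_pct) == expected_pct

    def test_no_growth_needed_at_current_area(self):
        res = farm_growth_rate(2700.0, 2700.0, 30)
        assert res.annual_growth_rate_pct == 0.0
        assert res.fold_increase == 1.0

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            farm_growth_rate(-1.0, 2700.0, 30)
        with pytest.raises(ValueError):
            farm_growth_rate(90_000.0, 2700.0, 0.0)


class TestConstraintOverlap:
    def test_disjoint_masks_give_zero(self):
        mask = np.array([True, True, False])
        ship = np.array([False, False, True])
        out = constraint_overlap(mask, ship, np.zeros(3, bool), np.ones(3))
        assert out == {"shipping": 0.0, "mpa": 0.0, "either": 0.0}

    def test_selection_inside_mpa_gives_one(self):
        mask = np.array([True, True, False])
        mpa = np.array([True, True, True])
        out = constraint_overlap(mask, np.zeros(3, bool), mpa, np.ones(3))
        assert out["mpa"] == 1.0 and out["either"] == 1.0

    def test_random_masks_match_counting_oracle(self, rng):
        mask = rng.random(50) < 0.5
        ship = rng.random(50) < 0.3
        mpa = rng.random(50) < 0.2
        area = rng.uniform(0.5, 2, 50)
        out = constraint_overlap(mask, ship, mpa, area)
        denom = area[mask].sum()
        assert out["shipping"] == pytest.approx(area[mask & ship].sum() / denom)
        assert out["mpa"] == pytest.approx(area[mask & mpa].sum() / denom)
        assert out["either"] == pytest.approx(area[mask & (ship | mpa)].sum() / denom)


class TestCheapnessBeatsRandomSelection:
    def test_cheapest_mask_average_below_random_equal_area_masks(self, rng):
        cost = rng.lognormal(5, 1, 500)
        benefit = rng.uniform(0.5, 3, 500)
        area = np.ones(500)
        mask = cheapest_fraction(cost, area, 0.1)
        cheap_avg = average_cost(mask, cost, area, benefit)
        k = mask.sum()
        worse = 0
        for _ in range(50):
            rand_mask = np.zeros(500, bool)
            rand_mask[rng.choice(500, size=k, replace=False)] = True
            if average_cost(rand_mask, cost, area, benefit) >= cheap_avg:
                worse += 1
        assert worse == 50


class TestHypothesisProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        costs=st.lists(st.floats(0.1, 1e4), min_size=4, max_size=40),
        f1=st.floats(0.05, 0.5),
        f2=st.floats(0.5, 1.0),
    )
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_cheapest_fraction_nested_and_supply_totals(self, costs, f1, f2):
        cost = np.asarray(costs)
        area = np.ones_like(cost)
        small = cheapest_fraction(cost, area, f1)
        large = cheapest_fraction(cost, area, f2)
        assert (small <= large).all()
        curve = supply_curve(cost, np.ones_like(cost), area, max_fraction=1.0)
        assert (np.diff(curve["marginal_cost"]) >= -1e-12).all()
        assert curve["benefit_gt_yr"].iloc[-1] == pytest.approx(area.sum() / 1e9)

    @given(
        target=st.floats(1.0, 1e7),
        current=st.floats(1.0, 1e5),
        horizon=st.floats(1.0, 100.0),
    )
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_growth_rate_consistent_with_fold_increase(self, target, current, horizon):
        res = farm_growth_rate(target, current, horizon)
        assert res.fold_increase == pytest.approx(target / current)
        rebuilt = (1 + res.annual_growth_rate_pct / 100) ** horizon
        assert rebuilt == pytest.approx(res.fold_increase, rel=1e-9)
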