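"""Lorenz/Gini, agglomeration degrees, densities, growth rates."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from equipanel import (
    AgglomerationRow,
    GeneratorConfig,
    ResourcePanel,
    avg_annual_growth,
    classify_agglomeration,
    classify_gini,
    density,
    generate_panel,
    gini,
    gini_by_area,
    gini_by_population,
    hrad,
    hrad_pad_ratio,
    lorenz,
    pad,
)
from equipanel.measures import DegenerateInputError, InsufficientUnitsError

from conftest import pairwise_gini

units_strategy = st.lists(
    st.tuples(
        st.floats(0.05, 50.0, allow_nan=False),
        st.floats(0.0, 100.0, allow_nan=False),
    ),
    min_size=2,
    max_size=12,
).filter(lambda us: sum(r for _, r in us) > 1e-6)


class TestLorenz:
    def test_single_unit_is_trivial_curve(self):
        c = lorenz([(3.0, 7.0)])
        assert np.allclose(c.x, [0, 1]) and np.allclose(c.y, [0, 1])

    def test_hand_cumulated_two_units(self):
        c = lorenz([(1, 0), (1, 1)])
        assert np.allclose(c.x, [0, 0.5, 1]) and np.allclose(c.y, [0, 0, 1])

    def test_equal_densities_give_diagonal(self):
        c = lorenz([(b, 2 * b) for b in (1.0, 5.0, 0.5, 3.0)])
        assert np.allclose(c.x, c.y)

    def test_all_zero_resources_rejected(self):
        with pytest.raises(DegenerateInputError):
            lorenz([(1, 0), (2, 0)])

    def test_non_positive_base_rejected(self):
        with pytest.raises(ValueError):
            lorenz([(0, 1), (1, 1)])

    @settings(derandomize=True, max_examples=200)
    @given(units_strategy)
    def test_curve_lies_below_diagonal(self, units):
        c = lorenz(units)
        assert np.all(c.y <= c.x + 1e-9)


class TestGini:
    def test_diagonal_gives_zero(self):
        assert gini(lorenz([(b, b) for b in (1, 2, 3)])) == pytest.approx(0, abs=1e-12)

    def test_two_unit_half(self):
        assert gini(lorenz([(1, 0), (1, 1)])) == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize("n", [2, 5, 31])
    def test_single_holder_limit(self, n):
        units = [(1.0, 0.0)] * (n - 1) + [(1.0, 10.0)]
        assert gini(lorenz(units)) == pytest.approx((n - 1) / n, abs=1e-12)

    @settings(derandomize=True, max_examples=300)
    @given(units_strategy)
    def test_trapezoid_equals_pairwise_oracle(self, units):
        bases = [b for b, _ in units]
        res = [r for _, r in units]
        assert gini(lorenz(units)) == pytest.approx(
            pairwise_gini(bases, res), abs=1e-10
        )

    @settings(derandomize=True, max_examples=100)
    @given(units_strategy, st.floats(0.01, 100.0), st.floats(0.01, 100.0))
    def test_scale_invariance(self, units, a, b):
        scaled = [(a * u, b * r) for u, r in units]
        assert gini(lorenz(scaled)) == pytest.approx(gini(lorenz(units)), abs=1e-9)

    @settings(derandomize=True, max_examples=100)
    @given(units_strategy, st.randoms(use_true_random=False))
    def test_permutation_invariance(self, units, rnd):
        shuffled = list(units)
        rnd.shuffle(shuffled)
        assert gini(lorenz(shuffled)) == pytest.approx(gini(lorenz(units)), abs=1e-10)

    @settings(derandomize=True, max_examples=100)
    @given(units_strategy)
    def test_replication_invariance(self, units):
        assert gini(lorenz(units + units)) == pytest.approx(
            gini(lorenz(units)), abs=1e-12
        )

    @settings(derandomize=True, max_examples=100)
    @given(units_strategy)
    def test_bounded_by_one_minus_min_base_share(self, units):
        total = sum(b for b, _ in units)
        bound = 1.0 - min(b for b, _ in units) / total
        assert 0.0 <= gini(lorenz(units)) <= bound + 1e-12


class TestPanelGini:
    def test_equal_per_capita_density_gives_zero(self, equal_density_panel):
        for region in ("eastern", "central", "western"):
            assert gini_by_population(
                equal_density_panel, region, 2018, "beds"
            ) == pytest.approx(0, abs=1e-9)

    def test_equal_per_km2_density_gives_zero(self, equal_density_panel):
        assert gini_by_area(
            equal_density_panel, "western", 2018, "beds"
        ) == pytest.approx(0, abs=1e-9)

    def test_agrees_with_pairwise_oracle_on_regions(self, default_panel):
        for region in ("eastern", "central", "western"):
            df = default_panel.year_slice(2018, region=region)
            expect = pairwise_gini(df["population"], df["beds"].astype(float))
            assert gini_by_population(
                default_panel, region, 2018, "beds"
            ) == pytest.approx(expect, abs=1e-10)

    def test_insufficient_units_rejected(self):
        import pandas as pd

        panel = ResourcePanel(pd.DataFrame({
            "province": ["Qinghai"], "year": [2018], "population": [6e6],
            "area_km2": [7.2e5], "beds": [20000],
        }))
        with pytest.raises(InsufficientUnitsError):
            gini_by_population(panel, "western", 2018, "beds")

    def test_area_gini_exceeds_population_gini_under_eastern_skew(self):
        # paired comparison: with geography-skewed densities and widely
        # dispersed areas, geographic equity is worse than demographic equity
        offsets = {"eastern": 2.5, "central": 1.2, "western": 0.6}
        diffs = []
        for seed in range(10):
            panel = generate_panel(GeneratorConfig(
                seed=seed, region_density_offsets=offsets
            ))
            diffs.append(
                gini_by_area(panel, None, 2018, "beds")
                - gini_by_population(panel, None, 2018, "beds")
            )
        assert np.mean(diffs) > 0
        assert np.mean(np.array(diffs) > 0) >= 0.9


class TestClassifyGini:
    @pytest.mark.parametrize(
        "g,label",
        [
            (0.15, "absolute equality"),
            (0.2, "absolute equality"),
            (0.25, "relative equality"),
            (0.3, "relative equality"),
            (0.35, "reasonable equity"),
            (0.4, "reasonable equity"),
            (0.45, "relative inequality"),
            (0.5, "relative inequality"),
            (0.61, "serious inequality"),
        ],
    )
    def test_band_membership(self, g, label):
        assert classify_gini(g).label == label

    def test_monotone_in_g(self):
        order = [classify_gini(g).label for g in np.linspace(0, 1, 101)]
        ranks = {lbl: i for i, lbl in enumerate(dict.fromkeys(order))}
        assert sorted(order, key=ranks.get) == order

    @pytest.mark.parametrize("g", [-0.01, 1.01])
    def test_domain_errors(self, g):
        with pytest.raises(ValueError):
            classify_gini(g)


class TestAgglomeration:
    def test_homogeneous_unit_is_one(self):
        assert hrad(10, 5, 100, 50) == pytest.approx(1.0)
        assert pad(10, 5, 100, 50) == pytest.approx(1.0)

    def test_direct_substitution(self):
        assert hrad(30, 1, 40, 4) == pytest.approx(3.0)
        assert pad(90, 1, 100, 10) == pytest.approx(9.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_area_weighted_mean_is_one_on_partitions(self, seed):
        rng = np.random.default_rng(seed)
        k = rng.integers(2, 9)
        areas = rng.uniform(0.5, 100, k)
        resources = rng.uniform(0.0, 50, k)
        resources[rng.integers(k)] += 1.0  # ensure a positive total
        pops = rng.uniform(1, 1000, k)
        hr = [hrad(resources[i], areas[i], resources.sum(), areas.sum())
              for i in range(k)]
        pd_ = [pad(pops[i], areas[i], pops.sum(), areas.sum()) for i in range(k)]
        w = areas / areas.sum()
        assert np.dot(w, hr) == pytest.approx(1.0, abs=1e-12)
        assert np.dot(w, pd_) == pytest.approx(1.0, abs=1e-12)

    def test_zero_area_rejected(self):
        with pytest.raises(ZeroDivisionError):
            hrad(1, 0, 10, 10)

    @pytest.mark.parametrize(
        "h,p,expected",
        [
            (23.324, 8.840, 2.639),   # highly over-concentrated municipality
            (3.257, 3.990, 0.816),    # densely populated region
            (1.789, 1.707, 1.048),
            (1.0, 1.0, 1.0),
        ],
    )
    def test_ratio_reproduces_published_cells(self, h, p, expected):
        assert hrad_pad_ratio(h, p) == pytest.approx(expected, abs=0.002)

    def test_ratio_equals_per_capita_density_ratio(self):
        rng = np.random.default_rng(3)
        hr, a, p = rng.uniform(1, 100, 3)
        hr_n, a_n, p_n = rng.uniform(100, 1000, 3)
        ratio = hrad_pad_ratio(hrad(hr, a, hr_n, a_n), pad(p, a, p_n, a_n))
        assert ratio == pytest.approx((hr / p) / (hr_n / p_n), rel=1e-12)

    def test_ratio_zero_pad_rejected(self):
        with pytest.raises(ZeroDivisionError):
            hrad_pad_ratio(1.0, 0.0)

    def test_row_validates_ratio_field(self):
        with pytest.raises(ValueError):
            AgglomerationRow(unit="x", hrad=2.0, pad=1.0, ratio=1.5)

    def test_classification_bands(self):
        fair = AgglomerationRow.build("u", 1.0, 1.0)
        assert [l.label for l in classify_agglomeration(fair)] == ["fair", "fair"]
        near = AgglomerationRow.build("u", 26.541, 26.528)  # ratio ~ 1.0005
        assert classify_agglomeration(near)[1].label == "fair"
        low = AgglomerationRow.build("u", 0.4, 1.0)
        geo, _ = classify_agglomeration(low)
        assert geo.label == "under-served"


class TestDensityAndGrowth:
    def test_zero_count(self):
        assert density(0, 12345) == 0.0

    def test_per_ten_thousand_people(self):
        assert density(500, 1_000_000) == pytest.approx(5.0)

    def test_density_ratio_equals_hrad_on_area_base(self):
        rng = np.random.default_rng(1)
        hr, a = rng.uniform(1, 100, 2)
        hr_n, a_n = rng.uniform(100, 1000, 2)
        assert density(hr, a) / density(hr_n, a_n) == pytest.approx(
            hrad(hr, a, hr_n, a_n), rel=1e-12
        )

    def test_zero_base_rejected(self):
        with pytest.raises(ZeroDivisionError):
            density(1, 0)

    def test_constant_series_zero_growth(self):
        assert avg_annual_growth([5.0] * 8) == pytest.approx(0.0)
        assert avg_annual_growth([5.0] * 8, mode="arithmetic") == pytest.approx(0.0)

    def test_doubling_over_ten_values(self):
        series = list(np.linspace(100, 200, 10))
        assert avg_annual_growth([100] * 9 + [200]) == pytest.approx(
            100 * (2 ** (1 / 9) - 1), abs=1e-9
        )
        assert avg_annual_growth(series) == pytest.approx(8.006, abs=1e-3)

    def test_modes_agree_to_first_order_for_small_growth(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            rates = rng.uniform(-0.02, 0.02, 9)
            series = 100 * np.cumprod(np.concatenate([[1.0], 1 + rates]))
            geo = avg_annual_growth(series)
            ari = avg_annual_growth(series, mode="arithmetic")
            assert abs(geo - ari) < 0.1  # percentage points

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            avg_annual_growth([10.0])
        with pytest.raises(ValueError):
            avg_annual_growth([0.0, 1.0])
        with pytest.raises(ValueError):
            avg_annual_growth([1.0, -1.0, 2.0], mode="arithmetic")
        with pytest.raises(ValueError):
            avg_annual_growth([1.0, 2.0], mode="harmonic")
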