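import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from asgm_hg.emissions import (
    EmissionSeries,
    ProxySeries,
    cumulative_emissions,
    extrapolate_by_proxy,
    read_emissions_csv,
    read_proxies_csv,
    regional_share,
    total_series,
    write_emissions_csv,
    write_proxies_csv,
)

YEARS = np.arange(2000, 2010)


def make_series(mass, region="rest-of-world", years=None):
    years = YEARS[: len(mass)] if years is None else years
    return EmissionSeries(region=region, years=years, mass=np.asarray(mass, float))


class TestEmissionSeries:
    def test_rejects_unordered_years(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            EmissionSeries("global", [2000, 2000, 2001], [1, 1, 1])

    def test_rejects_negative_mass(self):
        with pytest.raises(ValueError, match="non-negative"):
            EmissionSeries("global", [2000, 2001], [1, -1])

    def test_rejects_unknown_scenario(self):
        with pytest.raises(ValueError, match="scenario"):
            EmissionSeries("global", [2000], [1], scenario="imagined")


class TestCumulative:
    def test_constant_rate_hand_sum(self):
        s = make_series([10.0] * 5)
        assert cumulative_emissions(s, (2000, 2004)) == pytest.approx(50.0)

    def test_single_year_window(self):
        s = make_series([3.0, 7.0, 11.0])
        assert cumulative_emissions(s, (2001, 2001)) == pytest.approx(7.0)

    def test_empty_window_rejected(self):
        s = make_series([1.0, 2.0])
        with pytest.raises(ValueError):
            cumulative_emissions(s, (2005, 2004))
        with pytest.raises(ValueError):
            cumulative_emissions(s, (1990, 1995))

    @given(st.lists(st.floats(0, 1e4), min_size=4, max_size=10),
           st.integers(1, 8))
    @settings(deadline=None)
    def test_additive_over_disjoint_windows(self, mass, split):
        split = min(split, len(mass) - 1)
        years = np.arange(2000, 2000 + len(mass))
        s = make_series(mass, years=years)
        left = cumulative_emissions(s, (2000, 2000 + split - 1))
        right = cumulative_emissions(s, (2000 + split, int(years[-1])))
        whole = cumulative_emissions(s, (2000, int(years[-1])))
        assert left + right == pytest.approx(whole, rel=1e-12, abs=1e-9)


class TestRegionalShare:
    def test_single_region_is_everything(self):
        s = make_series([5.0, 5.0])
        shares = regional_share([s], (2000, 2001))
        assert shares == {"rest-of-world": pytest.approx(1.0)}

    def test_printed_inventory_split(self):
        # 4,970 and 4,470 of a 15,400 t total round to 32% and 29%
        totals = {"Sub-Saharan Africa": 4970.0, "South America": 4470.0,
                  "tropical Asia": 2610.0, "rest-of-world": 3350.0}
        series = [make_series([v], region=k, years=np.array([2000]))
                  for k, v in totals.items()]
        shares = regional_share(series, (2000, 2000))
        assert round(shares["Sub-Saharan Africa"] * 100) == 32
        assert round(shares["South America"] * 100) == 29
        assert round(shares["tropical Asia"] * 100) == 17

    @given(st.lists(st.floats(0.01, 1e3), min_size=2, max_size=6))
    @settings(deadline=None)
    def test_partition_sums_to_one(self, masses):
        series = [make_series([m], region=f"R{i}", years=np.array([2000]))
                  for i, m in enumerate(masses)]
        shares = regional_share(series, (2000, 2000))
        assert sum(shares.values()) == pytest.approx(1.0, abs=1e-12)

    def test_zero_total_rejected(self):
        s = make_series([0.0])
        with pytest.raises(ValueError, match="zero total"):
            regional_share([s], (2000, 2000))


class TestTotalSeries:
    def test_sums_aligned_regions(self):
        a = make_series([1.0, 2.0], region="A")
        b = make_series([3.0, 4.0], region="B")
        tot = total_series([a, b])
        assert tot.mass == pytest.approx([4.0, 6.0])

    def test_rejects_misaligned_years(self):
        a = make_series([1.0, 2.0])
        b = make_series([1.0], years=np.array([2005]))
        with pytest.raises(ValueError, match="year axis"):
            total_series([a, b])


class TestProxyExtrapolation:
    base = EmissionSeries("global", np.arange(2008, 2013),
                          np.array([700, 720, 760, 790, 800.0]))

    def proxy(self, name, ratio_2021):
        years = np.arange(2012, 2022)
        path = ratio_2021 ** ((years - 2012) / 9.0)
        return ProxySeries(name, years, path)

    def test_constant_proxy_is_identity(self):
        p = self.proxy("gold_supply", 1.0)
        ext = extrapolate_by_proxy(self.base, [p], (2013, 2021))
        assert ext.per_proxy["gold_supply"].mass == pytest.approx(
            np.full(9, 800.0))
        assert ext.mean.mass == pytest.approx(np.full(9, 800.0))

    def test_doubled_proxy_doubles_emission(self):
        p = ProxySeries("gold_price", np.array([2012, 2013]),
                        np.array([1.0, 2.0]))
        ext = extrapolate_by_proxy(self.base, [p], (2013, 2013))
        assert ext.per_proxy["gold_price"].mass[0] == pytest.approx(1600.0)

    def test_mean_lies_within_proxy_envelope(self):
        proxies = [self.proxy(n, r) for n, r in
                   [("gold_price", 0.75), ("gold_demand", 1.19),
                    ("mine_production", 1.25), ("gold_supply", 1.06)]]
        ext = extrapolate_by_proxy(self.base, proxies, (2013, 2021))
        stack = np.array([s.mass for s in ext.per_proxy.values()])
        assert np.all(ext.mean.mass >= stack.min(axis=0) - 1e-9)
        assert np.all(ext.mean.mass <= stack.max(axis=0) + 1e-9)

    def test_missing_base_year_rejected(self):
        p = ProxySeries("gold_demand", np.array([2015, 2016]),
                        np.array([1.0, 1.1]))
        with pytest.raises(KeyError):
            extrapolate_by_proxy(self.base, [p], (2015, 2016))

    def test_mean_rebasing_uses_trailing_average(self):
        p = ProxySeries("gold_price", np.arange(2010, 2014),
                        np.array([1.0, 1.0, 4.0, 4.0]))
        ext = extrapolate_by_proxy(self.base, [p], (2013, 2013),
                                   rebase="mean", rebase_years=3)
        # anchor = mean(1.0, 1.0, 4.0) = 2.0, so 2013 scales by 4/2
        assert ext.mean.mass[0] == pytest.approx(1600.0)

    def test_unknown_rebase_rejected(self):
        p = self.proxy("gold_price", 1.0)
        with pytest.raises(ValueError, match="rebase"):
            extrapolate_by_proxy(self.base, [p], (2013, 2014), rebase="oops")


def test_emission_and_proxy_csv_roundtrip(tmp_path):
    series = [make_series([1.5, 2.5], region="A"),
              make_series([3.0, 4.0], region="B")]
    path = tmp_path / "emissions.csv"
    write_emissions_csv(series, path)
    back = read_emissions_csv(path)
    assert {s.region for s in back} == {"A", "B"}
    for orig, new in zip(series, sorted(back, key=lambda s: s.region)):
        assert np.allclose(orig.mass, new.mass)

    proxies = [ProxySeries("gold_price", np.array([2012, 2013]),
                           np.array([1.0, 0.9]))]
    ppath = tmp_path / "proxies.csv"
    write_proxies_csv(proxies, ppath)
    back = read_proxies_csv(ppath)
    assert back[0].name == "gold_price"
    assert np.allclose(back[0].value, [1.0, 0.9])
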