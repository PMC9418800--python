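"""Synthetic study inputs.

The real analysis draws on external inventories that are out of scope here:
a gridded emission inventory, a UN-FAO-based food intake database,
literature food MeHg concentrations, and demographic / economic databases.
This module generates stand-ins with the statistical structure the analysis
assumes, so every stage of the pipeline runs and is testable end to end.

Two entry points:

:func:`generate_world`
    A fully random world from a :class:`SyntheticWorldConfig`; deterministic
    given the seed.
:func:`calibrated_world`
    The default configuration anchored to published global aggregates
    (regional emission totals, gold production and price points, global
    loss endpoints), used by the acceptance checks.  Country-level values
    remain synthetic: per-country results of the real study depend on
    unpublished inventories and are deliberately not reproduced.

Intakes and concentrations are log-normal across countries — the standard
right-skewed consumption assumption.  Country time series are back-cast
from the final year with constant demographic and economic growth rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .economics import GoldMarket
from .emissions import EMISSION_REGIONS, EmissionSeries, ProxySeries

#: Reporting continents for loss aggregation.
CONTINENTS = (
    "Europe", "Asia", "North America", "Africa", "South America", "Oceania",
)

#: Published global anchors carried alongside the synthetic bundle:
#: 1970/2012 gold production (t) and price (USD/oz), global monetised loss
#: endpoints and cumulative loss/revenue (USD), 2012 endpoint split,
#: miner-community statistics, and the all-sources global MeHg loss.
PUBLISHED_ANCHORS = {
    "gold_production_1970_t": 86.0,
    "gold_production_2012_t": 590.0,
    "gold_price_1970_usd_oz": 35.0,
    "gold_price_2005_usd_oz": 420.0,
    "gold_price_2012_usd_oz": 1776.0,
    "loss_1970_usd": 0.59e9,
    "loss_2012_usd": 7.1e9,
    "cumulative_loss_usd": 154e9,
    "cumulative_revenue_usd": 319e9,
    "H_IQ_2012_usd": 3.8e9,
    "H_FHA_2012_usd": 3.4e9,
    "n_miners": 15e6,
    "retort_unit_cost_usd": 20.0,
    "total_mehg_loss_usd": 117e9,
    "miner_loss_fraction": 0.04,
}


@dataclass(frozen=True)
class SyntheticWorldConfig:
    """Knobs of the synthetic world.

    Emission trajectories are exponential per region, scaled so each
    region's 1970-2012 total matches ``regional_totals_t`` and the global
    series grows by ``emission_growth_factor`` over the window.  Intake and
    concentration distributions are log-normal with the given location
    (median) and log-scale.  Demography and income are drawn for the final
    year and back-cast with the stated annual growth rates.
    """

    n_countries: int = 20
    seed: int = 0
    start_year: int = 1970
    end_year: int = 2012
    regional_totals_t: dict = field(default_factory=lambda: {
        "Sub-Saharan Africa": 4970.0,
        "South America": 4470.0,
        "tropical Asia": 2610.0,
        "rest-of-world": 3350.0,
    })
    emission_growth_factor: float = 6.8
    # median kg person^-1 day^-1 and log-scale, per category
    intake_median: dict = field(default_factory=lambda: {
        "seafood": 0.020, "fwfish": 0.008, "rice": 0.10,
    })
    intake_sigma: dict = field(default_factory=lambda: {
        "seafood": 0.8, "fwfish": 0.8, "rice": 1.0,
    })
    # median ug kg^-1 and log-scale, per category
    conc_median: dict = field(default_factory=lambda: {
        "seafood": 100.0, "fwfish": 80.0, "rice": 2.0,
    })
    conc_sigma: dict = field(default_factory=lambda: {
        "seafood": 0.4, "fwfish": 0.4, "rice": 0.5,
    })
    pop_median: float = 2.0e7          # adults, final year
    pop_sigma: float = 1.0
    gender_split: float = 0.5
    newborn_rate: float = 0.012        # births per adult per year
    fha_incidence: dict = field(default_factory=lambda: {
        "male": 0.0020, "female": 0.0012,
    })
    bw_range: tuple = (55.0, 80.0)     # kg
    gdp_pc_median: float = 15_000.0    # PPP USD, final year
    gdp_pc_sigma: float = 0.9
    pop_growth: float = 0.015          # yr^-1
    newborn_growth: float = 0.003      # yr^-1
    gdp_growth: float = 0.033          # yr^-1
    # proxy index in 2021 relative to 2012, per proxy
    proxy_2021_ratios: dict = field(default_factory=lambda: {
        "gold_price": 0.75, "gold_demand": 1.1875,
        "mine_production": 1.25, "gold_supply": 1.0625,
    })

    def __post_init__(self):
        if self.n_countries < 1:
            raise ValueError("need at least one country")
        if self.end_year <= self.start_year:
            raise ValueError("end_year must follow start_year")
        if self.emission_growth_factor <= 0:
            raise ValueError("growth factor must be positive")
        for d in (self.intake_sigma, self.conc_sigma):
            if any(v <= 0 for v in d.values()):
                raise ValueError("log-scales must be positive")
        if any(v < 0 for v in self.regional_totals_t.values()):
            raise ValueError("regional totals must be non-negative")
        if not 0 < self.gender_split < 1:
            raise ValueError("gender split must lie in (0, 1)")
        if any(not 0 <= v <= 1 for v in self.fha_incidence.values()):
            raise ValueError("incidence rates must lie in [0, 1]")


@dataclass(frozen=True)
class World:
    """Complete input bundle for one end-to-end run."""

    config: SyntheticWorldConfig
    emissions: tuple            # per-region EmissionSeries, asgm_only
    countries: pd.DataFrame     # one row per country: profile parameters
    gold: GoldMarket
    proxies: tuple              # ProxySeries covering 2012-2021
    anchors: dict = field(default_factory=dict)

    @property
    def years(self) -> np.ndarray:
        return self.emissions[0].years

    def total_emissions(self) -> EmissionSeries:
        from .emissions import total_series
        return total_series(list(self.emissions))

    def country_year_table(self, years=None) -> pd.DataFrame:
        """Expand static country profiles into a country-year table.

        Population, newborns and income are back-cast from the final year
        with the configured constant growth rates; intakes, concentrations,
        incidence and body weight are held constant.
        """
        cfg = self.config
        years = self.years if years is None else np.asarray(years, dtype=int)
        rows = []
        for _, c in self.countries.iterrows():
            for y in years:
                dy = y - cfg.end_year
                rows.append({
                    "country": c["country"], "continent": c["continent"],
                    "year": int(y),
                    "intake_seafood": c["intake_seafood"],
                    "intake_fwfish": c["intake_fwfish"],
                    "intake_rice": c["intake_rice"],
                    "conc_seafood": c["conc_seafood"],
                    "conc_fwfish": c["conc_fwfish"],
                    "conc_rice": c["conc_rice"],
                    "bw_kg": c["bw_kg"],
                    "pop_male": c["pop_male"] * (1 + cfg.pop_growth) ** dy,
                    "pop_female": c["pop_female"] * (1 + cfg.pop_growth) ** dy,
                    "fha_male": c["fha_male"], "fha_female": c["fha_female"],
                    "newborns": c["newborns"] * (1 + cfg.newborn_growth) ** dy,
                    "ppp_gdp_pc": c["ppp_gdp_pc"] * (1 + cfg.gdp_growth) ** dy,
                })
        return pd.DataFrame(rows)


def _exponential_series(total: float, years: np.ndarray, factor: float) -> np.ndarray:
    """Exponential trajectory with a given endpoint ratio and window sum."""
    n = years.size
    if factor == 1.0:
        return np.full(n, total / n)
    g = factor ** (1.0 / (n - 1))
    e0 = total * (g - 1.0) / (g ** n - 1.0)
    return e0 * g ** np.arange(n)


def _gold_market(cfg: SyntheticWorldConfig, anchors: dict) -> GoldMarket:
    years = np.arange(cfg.start_year, cfg.end_year + 1)
    prod = _piecewise_geometric(years, {
        cfg.start_year: anchors["gold_production_1970_t"],
        cfg.end_year: anchors["gold_production_2012_t"],
    })
    price = _piecewise_geometric(years, {
        cfg.start_year: anchors["gold_price_1970_usd_oz"],
        2005: anchors["gold_price_2005_usd_oz"],
        cfg.end_year: anchors["gold_price_2012_usd_oz"],
    })
    return GoldMarket(years=years, production_t=prod, price_usd_oz=price)


def _piecewise_geometric(years: np.ndarray, knots: dict) -> np.ndarray:
    ky = np.array(sorted(knots))
    kv = np.array([knots[y] for y in ky], dtype=float)
    return np.exp(np.interp(years, ky, np.log(kv)))


def _proxies(cfg: SyntheticWorldConfig) -> tuple:
    years = np.arange(cfg.end_year, 2022)
    span = years[-1] - years[0]
    out = []
    for name, ratio in cfg.proxy_2021_ratios.items():
        path = ratio ** ((years - years[0]) / span)
        out.append(ProxySeries(name=name, years=years, value=path))
    return tuple(out)


def generate_world(config: SyntheticWorldConfig) -> World:
    """Draw a complete synthetic input bundle; deterministic given the seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    years = np.arange(cfg.start_year, cfg.end_year + 1)

    emissions = tuple(
        EmissionSeries(
            region=region, years=years,
            mass=_exponential_series(
                cfg.regional_totals_t.get(region, 0.0), years,
                cfg.emission_growth_factor,
            ),
            scenario="asgm_only",
        )
        for region in EMISSION_REGIONS
    )

    rows = []
    for i in range(cfg.n_countries):
        pop = cfg.pop_median * rng.lognormal(0.0, cfg.pop_sigma)
        row = {
            "country": f"C{i + 1:02d}",
            "continent": CONTINENTS[i % len(CONTINENTS)],
            "bw_kg": rng.uniform(*cfg.bw_range),
            "pop_male": pop * cfg.gender_split,
            "pop_female": pop * (1 - cfg.gender_split),
            "fha_male": cfg.fha_incidence["male"],
            "fha_female": cfg.fha_incidence["female"],
            "newborns": pop * cfg.newborn_rate,
            "ppp_gdp_pc": cfg.gdp_pc_median * rng.lognormal(0.0, cfg.gdp_pc_sigma),
        }
        for cat in ("seafood", "fwfish", "rice"):
            row[f"intake_{cat}"] = cfg.intake_median[cat] * rng.lognormal(
                0.0, cfg.intake_sigma[cat])
            row[f"conc_{cat}"] = cfg.conc_median[cat] * rng.lognormal(
                0.0, cfg.conc_sigma[cat])
        rows.append(row)
    countries = pd.DataFrame(rows)

    anchors = dict(PUBLISHED_ANCHORS)
    return World(
        config=cfg,
        emissions=emissions,
        countries=countries,
        gold=_gold_market(cfg, anchors),
        proxies=_proxies(cfg),
        anchors=anchors,
    )


def calibrated_world(seed: int = 0) -> World:
    """The default synthetic world anchored to published global aggregates.

    Regional emission totals reproduce the inventory's 1970-2012 regional
    split, the gold market passes through the printed production / price
    points, and :attr:`World.anchors` carries the published global loss and
    miner-community figures used by the comparison arithmetic.
    """
    return generate_world(SyntheticWorldConfig(seed=seed))


def anchor_loss_series(world: World) -> pd.Series:
    """Global monetised-loss trajectory through the published endpoints.

    Exponential between the 1970 and 2012 loss anchors (USD yr^-1), indexed
    by year; the implied average growth rate is what the trend statistics
    recompute.
    """
    a = world.anchors
    years = world.years
    n = years.size
    factor = a["loss_2012_usd"] / a["loss_1970_usd"]
    g = factor ** (1.0 / (n - 1))
    return pd.Series(a["loss_1970_usd"] * g ** np.arange(n), index=years)


# ---------------------------------------------------------------------------
# CSV bundle round-trip: one directory, the same dialects the other modules
# read (emissions.csv, proxies.csv, countries.csv, gold.csv, anchors.csv)
# ---------------------------------------------------------------------------

def write_world(world: World, outdir) -> None:
    from .economics import write_gold_csv
    from .emissions import write_emissions_csv, write_proxies_csv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_emissions_csv(list(world.emissions), outdir / "emissions.csv")
    write_proxies_csv(list(world.proxies), outdir / "proxies.csv")
    world.countries.to_csv(outdir / "countries.csv", index=False)
    write_gold_csv(world.gold, outdir / "gold.csv")
    pd.Series(world.anchors, name="value").rename_axis("key").to_csv(
        outdir / "anchors.csv")


def read_world(indir, config: SyntheticWorldConfig | None = None) -> World:
    from .economics import read_gold_csv
    from .emissions import read_emissions_csv, read_proxies_csv

    indir = Path(indir)
    cfg = config or SyntheticWorldConfig()
    anchors = pd.read_csv(indir / "anchors.csv", index_col="key")["value"].to_dict()
    return World(
        config=cfg,
        emissions=tuple(read_emissions_csv(indir / "emissions.csv")),
        countries=pd.read_csv(indir / "countries.csv"),
        gold=read_gold_csv(indir / "gold.csv"),
        proxies=tuple(read_proxies_csv(indir / "proxies.csv")),
        anchors=anchors,
    )
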