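"""Annual mercury emission series from artisanal and small-scale gold mining.

Emissions are carried at regional (not gridded) resolution: every downstream
consumer in this package needs only global or regional annual totals.  Two
scenarios are distinguished: ``asgm_only`` (the mining source alone) and
``all_sources`` (all anthropogenic plus natural emissions, used as the
baseline of the source-attribution differencing).

Beyond bookkeeping (cumulative totals, regional shares), the module
extrapolates an emission series past its final inventory year by scaling it
with economic proxy indices (gold price, gold demand, mine production, gold
supply), the standard trick for a source whose activity is driven by the
gold market but whose direct statistics stop earlier.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Reporting regions of the emission inventory.
EMISSION_REGIONS = (
    "Sub-Saharan Africa",
    "South America",
    "tropical Asia",
    "rest-of-world",
)

SCENARIOS = ("asgm_only", "all_sources")

PROXY_NAMES = ("gold_price", "gold_demand", "mine_production", "gold_supply")


@dataclass(frozen=True)
class EmissionSeries:
    """Annual Hg mass emitted by one region under one scenario.

    Parameters
    ----------
    region
        Region label; conventionally one of :data:`EMISSION_REGIONS` or
        ``"global"`` for an aggregate.
    years
        Strictly increasing integer years.
    mass
        Hg emitted per year, metric tons yr^-1, non-negative.
    scenario
        ``"asgm_only"`` or ``"all_sources"``.
    """

    region: str
    years: np.ndarray
    mass: np.ndarray
    scenario: str = "asgm_only"

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=int)
        mass = np.asarray(self.mass, dtype=float)
        if years.ndim != 1 or mass.shape != years.shape:
            raise ValueError("years and mass must be 1-D arrays of equal length")
        if years.size == 0:
            raise ValueError("empty emission series")
        if np.any(np.diff(years) <= 0):
            raise ValueError("years must be strictly increasing")
        if np.any(mass < 0):
            raise ValueError("emission mass must be non-negative")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "mass", mass)

    def mass_in(self, year: int) -> float:
        """Emission in a single year (t yr^-1)."""
        idx = np.flatnonzero(self.years == year)
        if idx.size == 0:
            raise KeyError(f"year {year} not in series")
        return float(self.mass[idx[0]])

    def window(self, start: int, end: int) -> "EmissionSeries":
        """Sub-series restricted to start..end inclusive."""
        sel = (self.years >= start) & (self.years <= end)
        if not sel.any():
            raise ValueError(f"window {start}-{end} outside series years")
        return replace(self, years=self.years[sel], mass=self.mass[sel])


@dataclass(frozen=True)
class ProxySeries:
    """Economic activity index used to extrapolate emissions.

    ``value`` is in arbitrary index units; only ratios to the base year are
    ever used, so the normalisation is immaterial.
    """

    name: str
    years: np.ndarray
    value: np.ndarray

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=int)
        value = np.asarray(self.value, dtype=float)
        if years.ndim != 1 or value.shape != years.shape:
            raise ValueError("years and value must be 1-D arrays of equal length")
        if np.any(np.diff(years) <= 0):
            raise ValueError("years must be strictly increasing")
        if np.any(value <= 0):
            raise ValueError("proxy values must be positive")
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "value", value)

    def value_in(self, year: int) -> float:
        idx = np.flatnonzero(self.years == year)
        if idx.size == 0:
            raise KeyError(f"proxy {self.name!r} has no value for {year}")
        return float(self.value[idx[0]])


def cumulative_emissions(series: EmissionSeries, window: tuple[int, int]) -> float:
    """Total Hg mass emitted over ``window = (start, end)``, inclusive, in t.

    Raises ``ValueError`` if the window does not intersect the series.
    """
    start, end = window
    if end < start:
        raise ValueError("empty window")
    return float(series.window(start, end).mass.sum())


def total_series(
    series_by_region: Sequence[EmissionSeries], region: str = "global"
) -> EmissionSeries:
    """Sum regional series (aligned on years) into a single aggregate series."""
    if not series_by_region:
        raise ValueError("no series to aggregate")
    years = series_by_region[0].years
    scenario = series_by_region[0].scenario
    for s in series_by_region[1:]:
        if not np.array_equal(s.years, years):
            raise ValueError("regional series must share the same year axis")
        if s.scenario != scenario:
            raise ValueError("cannot mix scenarios in one aggregate")
    mass = np.sum([s.mass for s in series_by_region], axis=0)
    return EmissionSeries(region=region, years=years, mass=mass, scenario=scenario)


def regional_share(
    series_by_region: Sequence[EmissionSeries], window: tuple[int, int]
) -> dict[str, float]:
    """Fraction of the all-region cumulative total contributed by each region.

    Shares are in [0, 1] and sum to 1 over an exhaustive region partition.
    A zero all-region total is an error.
    """
    totals = {s.region: cumulative_emissions(s, window) for s in series_by_region}
    grand = sum(totals.values())
    if grand <= 0:
        raise ValueError("zero total emissions in window; shares undefined")
    return {region: t / grand for region, t in totals.items()}


@dataclass(frozen=True)
class ProxyExtrapolation:
    """Per-proxy extrapolated emission series and their unweighted mean."""

    per_proxy: dict[str, EmissionSeries]
    mean: EmissionSeries


def extrapolate_by_proxy(
    base: EmissionSeries,
    proxies: Iterable[ProxySeries],
    window: tuple[int, int],
    rebase: str = "final",
    rebase_years: int = 3,
) -> ProxyExtrapolation:
    """Extend an emission series beyond its inventory using market proxies.

    Each proxy yields ``emission(t) = emission(base year) * proxy(t) /
    proxy(base year)``: plain index scaling anchored at the final inventory
    year.  The multi-proxy mean is the unweighted average of the per-proxy
    series.

    Parameters
    ----------
    rebase
        ``"final"`` anchors each proxy on its value in the base (final
        inventory) year; ``"mean"`` anchors on the proxy's average over the
        last ``rebase_years`` inventory years, which damps a single
        anomalous base-year quotation.
    """
    start, end = window
    if end < start:
        raise ValueError("empty extrapolation window")
    base_year = int(base.years[-1])
    base_emission = float(base.mass[-1])
    years = np.arange(start, end + 1)

    per_proxy: dict[str, EmissionSeries] = {}
    for proxy in proxies:
        if rebase == "final":
            anchor = proxy.value_in(base_year)
        elif rebase == "mean":
            sel = (proxy.years <= base_year) & (proxy.years > base_year - rebase_years)
            if not sel.any():
                raise KeyError(
                    f"proxy {proxy.name!r} has no values in the rebase window"
                )
            anchor = float(proxy.value[sel].mean())
        else:
            raise ValueError(f"unknown rebase mode {rebase!r}")
        mass = np.array(
            [base_emission * proxy.value_in(int(y)) / anchor for y in years]
        )
        per_proxy[proxy.name] = EmissionSeries(
            region=base.region, years=years, mass=mass, scenario=base.scenario
        )

    if not per_proxy:
        raise ValueError("no proxies supplied")
    mean_mass = np.mean([s.mass for s in per_proxy.values()], axis=0)
    mean = EmissionSeries(
        region=base.region, years=years, mass=mean_mass, scenario=base.scenario
    )
    return ProxyExtrapolation(per_proxy=per_proxy, mean=mean)


# ---------------------------------------------------------------------------
# CSV interfaces: columns year, region, scenario, mass_t / year, proxy, value
# ---------------------------------------------------------------------------

def read_emissions_csv(path) -> list[EmissionSeries]:
    df = pd.read_csv(path)
    out = []
    for (region, scenario), grp in df.groupby(["region", "scenario"], sort=False):
        grp = grp.sort_values("year")
        out.append(
            EmissionSeries(
                region=region,
                years=grp["year"].to_numpy(),
                mass=grp["mass_t"].to_numpy(),
                scenario=scenario,
            )
        )
    return out


def write_emissions_csv(series: Sequence[EmissionSeries], path) -> None:
    frames = [
        pd.DataFrame(
            {
                "year": s.years,
                "region": s.region,
                "scenario": s.scenario,
                "mass_t": s.mass,
            }
        )
        for s in series
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_proxies_csv(path) -> list[ProxySeries]:
    df = pd.read_csv(path)
    out = []
    for name, grp in df.groupby("proxy", sort=False):
        grp = grp.sort_values("year")
        out.append(
            ProxySeries(
                name=name, years=grp["year"].to_numpy(), value=grp["value"].to_numpy()
            )
        )
    return out


def write_proxies_csv(proxies: Sequence[ProxySeries], path) -> None:
    frames = [
        pd.DataFrame({"year": p.years, "proxy": p.name, "value": p.value})
        for p in proxies
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
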