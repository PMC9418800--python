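"""Gold-market accounting and risk-benefit comparisons.

Revenue from mined gold (production x price), the ratio of monetised health
losses to that revenue, compound growth rates of annual series, and the
arithmetic of simple intervention programmes (retort distribution) and of
the global-versus-miner risk comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Troy ounces per metric ton.
TROY_OZ_PER_TON = 32_150.7


@dataclass(frozen=True)
class GoldMarket:
    """Annual production (t), price (USD per troy oz) and revenue (USD)."""

    years: np.ndarray
    production_t: np.ndarray
    price_usd_oz: np.ndarray

    def __post_init__(self):
        years = np.asarray(self.years, dtype=int)
        prod = np.asarray(self.production_t, dtype=float)
        price = np.asarray(self.price_usd_oz, dtype=float)
        if not (years.shape == prod.shape == price.shape):
            raise ValueError("years, production and price must align")
        if np.any(prod < 0) or np.any(price < 0):
            raise ValueError("production and price must be non-negative")
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "production_t", prod)
        object.__setattr__(self, "price_usd_oz", price)

    @property
    def revenue(self) -> np.ndarray:
        """USD per year."""
        return self.production_t * TROY_OZ_PER_TON * self.price_usd_oz

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "year": self.years, "production_t": self.production_t,
            "price_usd_oz": self.price_usd_oz, "revenue_usd": self.revenue,
        })


def gold_revenue(production_t: float, price_per_oz: float) -> float:
    """Gross value of mined gold, USD: production x 32,150.7 oz/t x price."""
    if production_t < 0 or price_per_oz < 0:
        raise ValueError("production and price must be non-negative")
    return production_t * TROY_OZ_PER_TON * price_per_oz


@dataclass(frozen=True)
class LossEarningRatio:
    """Annual and cumulative ratio of health loss to gold revenue."""

    years: np.ndarray
    annual: np.ndarray          # NaN where revenue is zero
    cumulative: float           # sum(loss) / sum(revenue)


def loss_earning_ratio(
    loss: pd.Series, revenue: pd.Series
) -> LossEarningRatio:
    """Elementwise and sum-over-sum ratio of two aligned annual series.

    Years with zero revenue yield NaN in the annual ratio (flagged, not
    raised); the cumulative ratio uses the sums and requires a positive
    total revenue.
    """
    loss = pd.Series(loss).sort_index()
    revenue = pd.Series(revenue).sort_index()
    if not loss.index.equals(revenue.index):
        raise ValueError("loss and revenue series must share the same years")
    if float(revenue.sum()) <= 0:
        raise ValueError("total revenue must be positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        annual = np.where(revenue.to_numpy() > 0,
                          loss.to_numpy() / revenue.to_numpy(), np.nan)
    return LossEarningRatio(
        years=loss.index.to_numpy(dtype=int),
        annual=annual,
        cumulative=float(loss.sum() / revenue.sum()),
    )


def geometric_growth_rate(v_start: float, v_end: float, n_years: int) -> float:
    """Average compound annual growth rate over ``n_years``."""
    if v_start <= 0 or v_end <= 0:
        raise ValueError("values must be positive")
    if n_years < 1:
        raise ValueError("n_years must be at least 1")
    return (v_end / v_start) ** (1.0 / n_years) - 1.0


def intervention_cost(n_miners: float, unit_cost: float) -> float:
    """Total cost of equipping each miner with one unit (e.g. a retort)."""
    if n_miners < 0 or unit_cost < 0:
        raise ValueError("inputs must be non-negative")
    return n_miners * unit_cost


def miner_vs_global_ratio(
    global_annual_loss: float, total_mehg_loss: float, miner_fraction: float
) -> float:
    """Ratio of the general-population loss to the miner-community loss.

    The miner-community loss is approximated as ``miner_fraction`` of the
    all-sources global MeHg loss.
    """
    if total_mehg_loss <= 0 or miner_fraction <= 0:
        raise ValueError("miner loss denominator must be positive")
    if global_annual_loss < 0:
        raise ValueError("loss must be non-negative")
    return global_annual_loss / (miner_fraction * total_mehg_loss)


def read_gold_csv(path) -> GoldMarket:
    df = pd.read_csv(path).sort_values("year")
    return GoldMarket(
        years=df["year"].to_numpy(),
        production_t=df["production_t"].to_numpy(),
        price_usd_oz=df["price_usd_oz"].to_numpy(),
    )


def write_gold_csv(market: GoldMarket, path) -> None:
    market.to_frame().to_csv(path, index=False)
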