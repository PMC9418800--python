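"""Monetisation of health impacts.

IQ decrements are valued at the lifelong earning loss (EL) per IQ point and
fatal heart attacks at the value of statistical life (VSL).  Both reference
values are quoted for a reference economy in a stated currency-year; they
are transferred to other countries by scaling with PPP-adjusted GDP per
capita raised to an income elasticity (benefit transfer), and moved between
currency-years with user-supplied price-index factors.  Time series of
losses are discounted to a base year at a constant annual rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .dose_response import HealthImpact


@dataclass(frozen=True)
class EconParams:
    """Valuation parameters.

    ``EL_ref`` (USD per IQ point) and ``VSL_ref`` (USD per death) are quoted
    in ``el_currency_year`` / ``vsl_currency_year`` dollars for an economy
    with PPP GDP per capita ``ref_income``.  ``cpi_factors`` maps calendar
    year -> price index (any consistent base); currency conversion uses
    index ratios.  ``elasticity`` is the income elasticity of the benefit
    transfer; 1 is pure proportional scaling.
    """

    EL_ref: float = 18_832.0
    el_currency_year: int = 2008
    VSL_ref: float = 6.3e6
    vsl_currency_year: int = 2005
    ref_income: float = 48_000.0
    elasticity: float = 1.0
    discount_rate: float = 0.03
    discount_base_year: int = 2020
    cpi_factors: Mapping[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_CPI)
    )

    def __post_init__(self):
        if self.EL_ref <= 0 or self.VSL_ref <= 0 or self.ref_income <= 0:
            raise ValueError("monetary reference values must be positive")
        if not 0 <= self.discount_rate < 1:
            raise ValueError("discount rate must lie in [0, 1)")

    @classmethod
    def default(cls) -> "EconParams":
        ref = resources.files("asgm_hg.data").joinpath("valuation_default.yaml")
        d = yaml.safe_load(ref.read_text())
        d["cpi_factors"] = {int(k): float(v) for k, v in d["cpi_factors"].items()}
        return cls(**d)


# US CPI-U annual averages (1982-84 = 100), used as default currency-year
# adjustment factors.
_DEFAULT_CPI = {
    2005: 195.3,
    2008: 215.3,
    2012: 229.6,
    2020: 258.8,
}


@dataclass(frozen=True)
class MonetizedImpact:
    """Monetised loss for one country-year, split by endpoint (USD yr^-1)."""

    H_IQ: float
    H_FHA: float
    currency_year: int
    country: str = ""
    year: int = 0

    def __post_init__(self):
        if self.H_IQ < 0 or self.H_FHA < 0:
            raise ValueError("monetised losses must be non-negative")

    @property
    def H_total(self) -> float:
        return self.H_IQ + self.H_FHA


def benefit_transfer(
    ref_value: float, ref_income: float, target_income: float, elasticity: float = 1.0
) -> float:
    """Transfer a reference monetary value to another economy.

    ``value = ref_value * (target_income / ref_income) ** elasticity`` with
    incomes as PPP-adjusted GDP per capita.
    """
    if ref_income <= 0 or target_income <= 0:
        raise ValueError("incomes must be positive")
    return ref_value * (target_income / ref_income) ** elasticity


def currency_adjust(
    value: float, from_year: int, to_year: int, cpi_factors: Mapping[int, float]
) -> float:
    """Move a dollar amount between currency-years by price-index ratio."""
    if from_year == to_year:
        return value
    try:
        f_from = cpi_factors[from_year]
        f_to = cpi_factors[to_year]
    except KeyError as exc:
        raise KeyError(f"no price-index factor for year {exc.args[0]}") from exc
    return value * f_to / f_from


def monetize(
    impact: HealthImpact,
    EL: float,
    VSL: float,
    currency_year: int = 2020,
    country: str = "",
    year: int = 0,
) -> MonetizedImpact:
    """Value a health impact: ``H = EL * dIQ + VSL * dCF``."""
    if EL < 0 or VSL < 0:
        raise ValueError("unit values must be non-negative")
    return MonetizedImpact(
        H_IQ=EL * impact.dIQ_total, H_FHA=VSL * impact.dCF,
        currency_year=currency_year, country=country, year=year,
    )


def attribute_value(
    H_baseline: MonetizedImpact, H_counterfactual: MonetizedImpact
) -> MonetizedImpact:
    """Loss attributable to a source: baseline minus source-removed, per
    endpoint component."""
    if H_baseline.currency_year != H_counterfactual.currency_year:
        raise ValueError("currency-years differ")
    d_iq = H_baseline.H_IQ - H_counterfactual.H_IQ
    d_fha = H_baseline.H_FHA - H_counterfactual.H_FHA
    if d_iq < -1e-9 * max(H_baseline.H_IQ, 1.0) or \
       d_fha < -1e-9 * max(H_baseline.H_FHA, 1.0):
        raise ValueError("negative attribution: counterfactual exceeds baseline")
    return MonetizedImpact(
        H_IQ=max(d_iq, 0.0), H_FHA=max(d_fha, 0.0),
        currency_year=H_baseline.currency_year,
        country=H_baseline.country, year=H_baseline.year,
    )


def discount_series(
    values: Mapping[int, float] | pd.Series,
    rate: float,
    base_year: int,
) -> tuple[pd.Series, float]:
    """Discount an annual series to a base year.

    Each year's value is multiplied by ``(1 + rate) ** (base_year - year)``,
    so years before the base appreciate and years after depreciate.
    Returns the discounted series and its sum.
    """
    s = pd.Series(dict(values)) if not isinstance(values, pd.Series) else values
    factors = (1.0 + rate) ** (base_year - s.index.to_numpy(dtype=float))
    out = s * factors
    return out, float(out.sum())
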