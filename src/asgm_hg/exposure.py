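"""Dietary methylmercury exposure per country-year.

Total exposure is the intake-weighted sum of MeHg concentrations over the
three food categories that dominate human MeHg intake — seafood, freshwater
fish, and rice — normalised by body weight.  The share attributable to a
single emission source scales each category by the source's simulated
contribution to the environmental compartment that feeds it: plankton MeHg
for seafood, atmospheric deposition for freshwater fish, and soil total Hg
for rice.  Linear scaling of food concentration with environmental level is
a conservative (upper-limit) attribution; no time lag is applied between
environmental levels, food concentrations, and intake.

Each category may carry several strata (fish trophic levels, rice source
regions) with their own intake and concentration; strata are summed within
the category.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CATEGORIES = ("seafood", "fwfish", "rice")


def _as_strata(x) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if np.any(arr < 0):
        raise ValueError("intakes and concentrations must be non-negative")
    return arr


@dataclass(frozen=True)
class FoodIntakeProfile:
    """Per-capita intake by category (kg person^-1 day^-1), per stratum."""

    seafood: np.ndarray = field(default_factory=lambda: np.zeros(1))
    fwfish: np.ndarray = field(default_factory=lambda: np.zeros(1))
    rice: np.ndarray = field(default_factory=lambda: np.zeros(1))

    def __post_init__(self):
        for cat in CATEGORIES:
            object.__setattr__(self, cat, _as_strata(getattr(self, cat)))


@dataclass(frozen=True)
class FoodMeHgProfile:
    """MeHg concentration by category (ug kg^-1), same strata as intake."""

    seafood: np.ndarray = field(default_factory=lambda: np.zeros(1))
    fwfish: np.ndarray = field(default_factory=lambda: np.zeros(1))
    rice: np.ndarray = field(default_factory=lambda: np.zeros(1))

    def __post_init__(self):
        for cat in CATEGORIES:
            object.__setattr__(self, cat, _as_strata(getattr(self, cat)))


@dataclass(frozen=True)
class ExposureRecord:
    """Per-capita MeHg intake (ug per kg body weight per day)."""

    E_baseline: float
    E_ASGM: float
    BW: float

    def __post_init__(self):
        if self.BW <= 0:
            raise ValueError("body weight must be positive")
        if self.E_baseline < 0 or self.E_ASGM < 0:
            raise ValueError("exposures must be non-negative")


def _category_doses(intake: FoodIntakeProfile, conc: FoodMeHgProfile) -> np.ndarray:
    """ug day^-1 per category, strata summed."""
    doses = []
    for cat in CATEGORIES:
        i = getattr(intake, cat)
        c = getattr(conc, cat)
        if i.shape != c.shape:
            raise ValueError(f"stratum mismatch for {cat}: {i.shape} vs {c.shape}")
        doses.append(float(np.dot(i, c)))
    return np.array(doses)


def baseline_exposure(
    intake: FoodIntakeProfile, conc: FoodMeHgProfile, BW: float
) -> ExposureRecord:
    """Total dietary MeHg exposure: sum of intake x concentration over all
    categories and strata, per kg body weight (ug kg-bw^-1 day^-1)."""
    if BW <= 0:
        raise ValueError("body weight must be positive")
    e = _category_doses(intake, conc).sum() / BW
    return ExposureRecord(E_baseline=e, E_ASGM=0.0, BW=BW)


def asgm_exposure(
    intake: FoodIntakeProfile,
    conc: FoodMeHgProfile,
    BW: float,
    ratios: tuple[float, float, float],
) -> ExposureRecord:
    """Source-attributable exposure.

    ``ratios = (rD, rP, rS)`` are the source's simulated shares of
    atmospheric deposition, plankton MeHg, and soil Hg; the seafood term is
    scaled by rP, freshwater fish by rD, and rice by rS.  Each ratio must
    lie in [0, 1] — the linear scaling is an upper-limit attribution, so a
    ratio above one is rejected rather than extrapolated.
    """
    rD, rP, rS = ratios
    for name, r in (("rD", rD), ("rP", rP), ("rS", rS)):
        if not 0 <= r <= 1:
            raise ValueError(f"{name} must lie in [0, 1], got {r}")
    if BW <= 0:
        raise ValueError("body weight must be positive")
    doses = _category_doses(intake, conc)  # seafood, fwfish, rice
    e_base = doses.sum() / BW
    e_asgm = float(np.dot(doses, [rP, rD, rS])) / BW
    return ExposureRecord(E_baseline=e_base, E_ASGM=e_asgm, BW=BW)


def read_intake_csv(path) -> dict:
    """Read a long-format country intake table.

    Columns: country, year, category, stratum, intake_kg_day, mehg_ug_kg,
    bw_kg.  Returns ``{(country, year): (FoodIntakeProfile, FoodMeHgProfile,
    bw_kg)}`` with strata ordered by their stratum label within each
    category.
    """
    df = pd.read_csv(path)
    out = {}
    for (country, year), grp in df.groupby(["country", "year"]):
        intakes, concs = {}, {}
        for cat in CATEGORIES:
            sub = grp[grp["category"] == cat].sort_values("stratum")
            if len(sub):
                intakes[cat] = sub["intake_kg_day"].to_numpy()
                concs[cat] = sub["mehg_ug_kg"].to_numpy()
        bw = float(grp["bw_kg"].iloc[0])
        out[(country, int(year))] = (
            FoodIntakeProfile(**intakes), FoodMeHgProfile(**concs), bw)
    return out
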