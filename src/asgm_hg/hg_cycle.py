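"""Reduced-complexity annual-step global mercury cycle.

A six-compartment linear box model stands in for a full 3D
atmosphere-land-ocean transport system: atmosphere, three soil pools
(fast / slow / armored, distinguished by turnover time against microbial
respiration), surface ocean, and subsurface ocean.  All transfers are
first-order annual fractions, so the whole system is linear in emissions:
scenarios superpose, and the contribution of one source can be diagnosed by
running it alone against an all-sources baseline and taking ratios of the
simulated fields.

Three diagnostics feed the exposure equations downstream:

``D``
    Global-mean *net* atmosphere-to-surface mercury flux (gross deposition
    minus prompt re-emission from soils and evasion from the surface ocean),
    in ug m^-2 yr^-1.  The net convention is deliberate: it is the flux that
    actually accumulates in watersheds and drives freshwater-fish MeHg, and
    it reproduces the damped response of deposition to emission growth that
    legacy re-emission causes (surface reservoirs loaded by past deposition
    return ever more mercury to the air, so the net flux grows more slowly
    than the primary emissions do).  Gross deposition from a linear system
    started empty can only grow *faster* than emissions, never slower.
``P``
    Global-mean plankton MeHg concentration (fmol L^-1), proportional to the
    surface-ocean mercury burden through a fixed methylation-plus-uptake
    yield.  Plankton ecosystem dynamics are out of scope; the subsurface
    box dilutes the surface signal with upwelled water that is less
    influenced by a recent source.
``S``
    Global-mean soil total Hg concentration (arbitrary mass-fraction units),
    proportional to the summed soil-pool burden.  The soil holds a very
    large legacy reserve, so a young source perturbs ``S`` only weakly.

Mass is conserved exactly: at every step the change in total stored mass
equals emissions minus permanent losses (sediment burial and riverine
export), which is asserted by tests to 1e-9 relative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .emissions import EmissionSeries

COMPARTMENTS = (
    "atmosphere",
    "fast_soil",
    "slow_soil",
    "armored_soil",
    "surface_ocean",
    "subsurface_ocean",
)

#: Earth surface area used to convert a global deposited mass (t yr^-1)
#: into a mean areal flux (ug m^-2 yr^-1).
EARTH_AREA_M2 = 5.1e14

_UG_PER_TON = 1e12


@dataclass(frozen=True)
class BoxModelParams:
    """First-order annual transfer coefficients of the six-box cycle.

    All coefficients are annual fractions (yr^-1, applied as discrete annual
    steps); for each compartment the outgoing fractions must sum to at most
    one.  ``baseline_total_emission_t`` is the constant all-sources primary
    emission rate whose steady state initialises the baseline scenario.
    ``plankton_yield_fmol_per_t`` and ``soil_yield_per_t`` convert
    compartment burdens into the ``P`` and ``S`` diagnostics.
    """

    # atmosphere
    dep_total: float            # fraction of airborne Hg deposited per year
    dep_land_fraction: float    # of deposition, share delivered to land
    # fast soil (leaf litter + organic topsoil; years-scale turnover)
    fast_reemit: float
    fast_to_slow: float
    fast_to_armored: float
    fast_export: float          # riverine export to coastal sediment (loss)
    # slow soil (decadal turnover)
    slow_reemit: float
    slow_to_armored: float
    # armored soil (mineral-bound, centennial-millennial)
    armored_reemit: float
    armored_burial: float
    # surface ocean
    ocean_evasion: float
    ocean_to_subsurface: float
    # subsurface ocean
    upwelling: float
    subsurface_burial: float
    # scenario and diagnostic scaling
    baseline_total_emission_t: float
    plankton_yield_fmol_per_t: float
    soil_yield_per_t: float

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if value < 0:
                raise ValueError(f"{name} must be non-negative, got {value}")
        if not 0 <= self.dep_land_fraction <= 1:
            raise ValueError("dep_land_fraction must lie in [0, 1]")
        outgoing = {
            "atmosphere": self.dep_total,
            "fast_soil": self.fast_reemit + self.fast_to_slow
            + self.fast_to_armored + self.fast_export,
            "slow_soil": self.slow_reemit + self.slow_to_armored,
            "armored_soil": self.armored_reemit + self.armored_burial,
            "surface_ocean": self.ocean_evasion + self.ocean_to_subsurface,
            "subsurface_ocean": self.upwelling + self.subsurface_burial,
        }
        for comp, total in outgoing.items():
            if total > 1 + 1e-12:
                raise ValueError(
                    f"outgoing annual fractions of {comp} sum to {total:.3f} > 1"
                )

    @classmethod
    def from_dict(cls, d: dict) -> "BoxModelParams":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "BoxModelParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "BoxModelParams":
        """Packaged coefficients, calibrated to present-day source-attribution
        anchors (see the shipped ``box_model_default.yaml``)."""
        ref = resources.files("asgm_hg.data").joinpath("box_model_default.yaml")
        return cls.from_dict(yaml.safe_load(ref.read_text()))

    def transition_matrix(self) -> np.ndarray:
        """Column-stochastic-minus-losses annual transfer matrix M.

        ``state_next = M @ state_in``; column sums equal 1 minus that
        compartment's permanent-loss fraction.
        """
        A, F, L, R, O, U = range(6)
        M = np.zeros((6, 6))
        M[A, A] = 1 - self.dep_total
        M[F, A] = self.dep_total * self.dep_land_fraction
        M[O, A] = self.dep_total * (1 - self.dep_land_fraction)

        M[A, F] = self.fast_reemit
        M[L, F] = self.fast_to_slow
        M[R, F] = self.fast_to_armored
        M[F, F] = 1 - (self.fast_reemit + self.fast_to_slow
                       + self.fast_to_armored + self.fast_export)

        M[A, L] = self.slow_reemit
        M[R, L] = self.slow_to_armored
        M[L, L] = 1 - (self.slow_reemit + self.slow_to_armored)

        M[A, R] = self.armored_reemit
        M[R, R] = 1 - (self.armored_reemit + self.armored_burial)

        M[A, O] = self.ocean_evasion
        M[U, O] = self.ocean_to_subsurface
        M[O, O] = 1 - (self.ocean_evasion + self.ocean_to_subsurface)

        M[O, U] = self.upwelling
        M[U, U] = 1 - (self.upwelling + self.subsurface_burial)
        return M

    def loss_vector(self) -> np.ndarray:
        """Permanent-loss fraction per compartment (burial / export)."""
        return np.array([
            0.0, self.fast_export, 0.0, self.armored_burial,
            0.0, self.subsurface_burial,
        ])


@dataclass(frozen=True)
class Diagnostics:
    """Environmental fields for one year."""

    D: float  # net atmosphere-to-surface flux, ug m^-2 yr^-1
    P: float  # plankton MeHg, fmol L^-1
    S: float  # soil total Hg, arbitrary mass-fraction units


@dataclass(frozen=True)
class ScenarioFields:
    """Yearly trajectories of the diagnostics and compartment masses."""

    scenario: str
    years: np.ndarray
    D: np.ndarray
    P: np.ndarray
    S: np.ndarray
    masses: np.ndarray          # (n_years, 6) state at the start of each year
    burial: np.ndarray          # permanent loss during each year, t

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"year": self.years, "scenario": self.scenario,
                           "D_ug_m2_yr": self.D, "P_fmol_L": self.P,
                           "S_index": self.S, "burial_t": self.burial})
        for i, comp in enumerate(COMPARTMENTS):
            df[f"mass_{comp}_t"] = self.masses[:, i]
        return df


def _diagnose(m_in: np.ndarray, params: BoxModelParams) -> Diagnostics:
    gross_dep = params.dep_total * m_in[0]
    reemit = (params.fast_reemit * m_in[1] + params.slow_reemit * m_in[2]
              + params.armored_reemit * m_in[3] + params.ocean_evasion * m_in[4])
    d_flux = (gross_dep - reemit) * _UG_PER_TON / EARTH_AREA_M2
    p = params.plankton_yield_fmol_per_t * m_in[4]
    s = params.soil_yield_per_t * (m_in[1] + m_in[2] + m_in[3])
    return Diagnostics(D=d_flux, P=p, S=s)


def step_annual(
    state: np.ndarray, emission: float, params: BoxModelParams
) -> tuple[np.ndarray, Diagnostics, float]:
    """Advance the cycle one year.

    The year's emission is injected into the atmosphere, diagnostics are
    evaluated on the injected state (so a pulse is seen by the fields of
    its own year), then first-order transfers move mass.  Returns
    ``(next_state, diagnostics, burial_t)`` with the mass balance
    ``sum(next) - sum(state) = emission - burial`` holding to rounding.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (6,):
        raise ValueError("state must be a length-6 vector")
    if np.any(state < 0):
        raise ValueError("compartment masses must be non-negative")
    if emission < 0:
        raise ValueError("emission must be non-negative")
    m_in = state.copy()
    m_in[0] += emission
    diag = _diagnose(m_in, params)
    nxt = params.transition_matrix() @ m_in
    burial = float(params.loss_vector() @ m_in)
    return nxt, diag, burial


def steady_state(emission_rate: float, params: BoxModelParams) -> np.ndarray:
    """Fixed point of the annual step under a constant emission rate.

    Solves ``m = M (m + e b)`` for the start-of-year state ``m``; the
    permanent losses then exactly balance the emissions.
    """
    M = params.transition_matrix()
    b = np.zeros(6)
    b[0] = emission_rate
    return np.linalg.solve(np.eye(6) - M, M @ b)


def run_scenario(
    emissions: EmissionSeries,
    params: BoxModelParams,
    init: np.ndarray | str | None = None,
) -> ScenarioFields:
    """Run the cycle over an emission series.

    ``init`` may be ``None`` / ``"zero"`` (empty compartments, the
    convention for a single-source scenario), ``"steady"`` (the steady
    state of the first-year emission rate, the convention for an
    all-sources baseline), or an explicit length-6 state.
    """
    if init is None or (isinstance(init, str) and init == "zero"):
        state = np.zeros(6)
    elif isinstance(init, str) and init == "steady":
        state = steady_state(float(emissions.mass[0]), params)
    elif isinstance(init, str):
        raise ValueError(f"unknown init mode {init!r}")
    else:
        state = np.asarray(init, dtype=float)

    n = emissions.years.size
    D = np.empty(n)
    P = np.empty(n)
    S = np.empty(n)
    masses = np.empty((n, 6))
    burial = np.empty(n)
    for i in range(n):
        masses[i] = state
        state, diag, burial[i] = step_annual(state, float(emissions.mass[i]), params)
        D[i], P[i], S[i] = diag.D, diag.P, diag.S
    return ScenarioFields(
        scenario=emissions.scenario, years=emissions.years.copy(),
        D=D, P=P, S=S, masses=masses, burial=burial,
    )


def baseline_scenario(
    years: Sequence[int], params: BoxModelParams, emission_rate: float | None = None
) -> ScenarioFields:
    """All-sources baseline: constant emissions run from their steady state."""
    years = np.asarray(years, dtype=int)
    rate = params.baseline_total_emission_t if emission_rate is None else emission_rate
    series = EmissionSeries(
        region="global", years=years, mass=np.full(years.size, rate),
        scenario="all_sources",
    )
    return run_scenario(series, params, init="steady")


def attribution_ratios(
    asgm: ScenarioFields, baseline: ScenarioFields, year: int
) -> tuple[float, float, float]:
    """Source contribution (rD, rP, rS) in a year, each clipped to [0, 1].

    The single-source and baseline fields are compared at one year; ratios
    above one (possible only through numerical noise or a mis-specified
    baseline) are clipped with a warning, and a non-positive baseline field
    is an error.
    """
    out = []
    for fields in ("D", "P", "S"):
        ia = np.flatnonzero(asgm.years == year)
        ib = np.flatnonzero(baseline.years == year)
        if ia.size == 0 or ib.size == 0:
            raise KeyError(f"year {year} absent from one of the scenarios")
        num = float(getattr(asgm, fields)[ia[0]])
        den = float(getattr(baseline, fields)[ib[0]])
        if den <= 0:
            raise ValueError(f"baseline {fields} is non-positive in {year}")
        r = num / den
        if r > 1:
            warnings.warn(
                f"attribution ratio for {fields} exceeds 1 ({r:.3f}); clipping",
                stacklevel=2,
            )
        out.append(min(max(r, 0.0), 1.0))
    return tuple(out)  # type: ignore[return-value]
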