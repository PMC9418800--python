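"""Health endpoints of dietary MeHg exposure.

Two endpoints are modelled.  Prenatal exposure lowers the IQ of newborns
through a linear, no-threshold chain: daily intake -> blood Hg (beta) ->
hair Hg (lambda) -> IQ points (gamma).  Chronic adult exposure raises
fatal-heart-attack (FHA) mortality through a log-linear relation saturating
at the baseline incidence, damped by a subjective uncertainty weight omega
that reflects the thinner epidemiological evidence for the cardiovascular
endpoint.

Source attribution is done by differencing the endpoint at the full
exposure and at the exposure with the source removed, which matters for
the concave FHA relation (the same exposure increment causes fewer extra
deaths on top of a high baseline).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml


@dataclass(frozen=True)
class DoseResponseParams:
    """Toxicokinetic and dose-effect coefficients.

    beta
        Blood Hg per unit daily intake (ug L^-1 per ug day^-1), from a
        one-compartment toxicokinetic model.
    lambda_
        Hair-to-blood concentration ratio (ug g^-1 per ug L^-1); the
        conventional 250:1 ratio gives 0.25.
    gamma
        IQ points lost per unit hair Hg (points per ug g^-1).
    phi
        FHA dose-effect coefficient per unit hair Hg ((ug g^-1)^-1).
    omega
        Subjective FHA uncertainty weight, in [0, 1].
    """

    beta: float = 0.8
    lambda_: float = 0.25
    gamma: float = 0.18
    phi: float = 0.066
    omega: float = 0.5

    def __post_init__(self):
        for name in ("beta", "lambda_", "gamma", "phi", "omega"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.omega > 1:
            raise ValueError("omega must not exceed 1")

    @classmethod
    def default(cls) -> "DoseResponseParams":
        ref = resources.files("asgm_hg.data").joinpath("dose_response_default.yaml")
        d = yaml.safe_load(ref.read_text())
        return cls(**d)

    @property
    def hair_per_intake(self) -> float:
        """Hair Hg (ug g^-1) per unit daily intake (ug day^-1)."""
        return self.lambda_ * self.beta


@dataclass(frozen=True)
class Demography:
    """Population structure of one country-year.

    ``pop`` maps gender -> adult population; ``fha_incidence`` maps gender
    -> baseline fatal-heart-attack rate (deaths person^-1 yr^-1).
    """

    pop: dict[str, float]
    fha_incidence: dict[str, float]
    newborns: float
    BW: float

    def __post_init__(self):
        if set(self.pop) != set(self.fha_incidence):
            raise ValueError("pop and fha_incidence must cover the same genders")
        for g, p in self.pop.items():
            if p < 0:
                raise ValueError("population must be non-negative")
            rate = self.fha_incidence[g]
            if not 0 <= rate <= 1:
                raise ValueError("incidence rate must lie in [0, 1]")
        if self.newborns < 0:
            raise ValueError("newborns must be non-negative")
        if self.BW <= 0:
            raise ValueError("body weight must be positive")


@dataclass(frozen=True)
class HealthImpact:
    """Endpoint changes for a population-year."""

    dIQ_total: float   # IQ points lost by the newborn cohort, points yr^-1
    dCF: float         # extra fatal heart attacks, deaths yr^-1
    dIQ_per_newborn: float = 0.0

    def __post_init__(self):
        if self.dIQ_total < -1e-12 or self.dCF < -1e-12:
            raise ValueError("health impacts must be non-negative")


def iq_decrement(
    dE: float, BW: float, params: DoseResponseParams, newborns: float
) -> HealthImpact:
    """Linear no-threshold IQ loss.

    Per newborn: ``gamma * lambda * beta * dE * BW`` with ``dE`` in
    ug kg-bw^-1 day^-1 so that ``dE * BW`` is the daily intake in ug day^-1.
    The cohort total multiplies by the year's births.
    """
    if dE < 0:
        raise ValueError("dE must be non-negative; attribute upstream")
    per = params.gamma * params.lambda_ * params.beta * dE * BW
    return HealthImpact(dIQ_total=per * newborns, dCF=0.0, dIQ_per_newborn=per)


def fha_deaths(
    dE: float, BW: float, params: DoseResponseParams, demog: Demography
) -> float:
    """Excess fatal heart attacks from exposure ``dE``.

    ``sum_g POP_g * Cf_g * omega * (1 - exp(-phi*lambda*beta*dE*BW))``:
    strictly increasing and concave in dose, saturating at
    ``omega * sum_g POP_g * Cf_g``.
    """
    if dE < 0:
        raise ValueError("dE must be non-negative")
    x = params.phi * params.lambda_ * params.beta * dE * BW
    frac = -np.expm1(-x)
    return float(sum(
        demog.pop[g] * demog.fha_incidence[g] * params.omega * frac
        for g in demog.pop
    ))


def attributable_impact(
    E_baseline: float,
    E_ASGM: float,
    BW: float,
    params: DoseResponseParams,
    demog: Demography,
) -> HealthImpact:
    """Endpoint change attributable to a source, by differencing.

    The endpoint is evaluated at the full exposure and at the exposure with
    the source's share removed; the difference is the attributable impact.
    For the linear IQ endpoint this reduces to evaluating the source share
    directly; for the concave FHA endpoint the difference is smaller than a
    from-zero evaluation of the same share.
    """
    if not 0 <= E_ASGM <= E_baseline + 1e-15:
        raise ValueError("require 0 <= E_ASGM <= E_baseline")
    iq = iq_decrement(E_ASGM, BW, params, demog.newborns)
    cf = (fha_deaths(E_baseline, BW, params, demog)
          - fha_deaths(E_baseline - E_ASGM, BW, params, demog))
    return HealthImpact(
        dIQ_total=iq.dIQ_total, dCF=max(cf, 0.0),
        dIQ_per_newborn=iq.dIQ_per_newborn,
    )


def read_demography_csv(path) -> dict:
    """Read a long-format demography table.

    Columns: country, year, gender, pop, fha_incidence, newborns, bw_kg.
    Returns ``{(country, year): Demography}``; newborns and body weight are
    taken from the first row of each group (they are not gender-specific).
    """
    df = pd.read_csv(path)
    out = {}
    for (country, year), grp in df.groupby(["country", "year"]):
        out[(country, int(year))] = Demography(
            pop=dict(zip(grp["gender"], grp["pop"].astype(float))),
            fha_incidence=dict(zip(grp["gender"],
                                   grp["fha_incidence"].astype(float))),
            newborns=float(grp["newborns"].iloc[0]),
            BW=float(grp["bw_kg"].iloc[0]),
        )
    return out
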